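"""Selection truth tables, assay callers and tallies."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cytoswap import genetics, synthetic
from cytoswap.config import SimulationConfig
from cytoswap.genetics import (
    Call,
    CrisprCall,
    LocusAllele,
    Medium,
    Plasmid,
    Spore,
    Tetrad,
    TsCall,
    call_crispr_replacement,
    call_population_complementation,
    call_tetrad_complementation,
    call_ts_complementation,
    marker_segregation,
    media_viability,
    spore_viability,
    tally_replaceability,
)


def _all_spore_states():
    for allele, plasmid, compl, alive in itertools.product(
        LocusAllele, Plasmid, (False, True), (False, True)
    ):
        yield Spore(allele, plasmid, compl, alive)


class TestMediaViability:
    def test_truth_table_exhaustive(self):
        """Every spore state x medium matches an independently written rule set.

        The reference rules re-derive viability from the biology: survival
        needs an intrinsic live spore plus a functional essential gene
        (wild-type allele or complementing human gene on the plasmid);
        G418 selects the kanMX deletion, -Ura selects URA3 plasmids, and
        5-FOA kills every URA3 carrier.
        """
        for s in _all_spore_states():
            rescued = s.plasmid is Plasmid.HUMAN_GENE and s.human_gene_complements
            essential_ok = s.locus_allele is LocusAllele.WT or rescued
            alive = s.intrinsically_viable and essential_ok
            expected = {
                Medium.YPD: alive,
                Medium.YPD_G418: alive and s.locus_allele is LocusAllele.DELETION,
                Medium.SC_URA: alive and s.plasmid is not Plasmid.NONE,
                Medium.SC_URA_G418: alive
                and s.plasmid is not Plasmid.NONE
                and s.locus_allele is LocusAllele.DELETION,
                Medium.FOA: s.intrinsically_viable
                and s.locus_allele is LocusAllele.WT
                and s.plasmid is Plasmid.NONE,
            }
            for medium, want in expected.items():
                assert media_viability(s, medium) == want, (s, medium)

    def test_foa_and_ura_selection_mutually_exclusive(self):
        """No live spore can grow on both 5-FOA and SC-Ura: the former
        requires losing the URA3 plasmid the latter selects for."""
        for s in _all_spore_states():
            assert not (
                media_viability(s, Medium.FOA) and media_viability(s, Medium.SC_URA)
            )

    @pytest.mark.parametrize(
        "spore, medium, viable",
        [
            (Spore(LocusAllele.WT), Medium.FOA, True),
            (Spore(LocusAllele.DELETION, Plasmid.HUMAN_GENE, True), Medium.YPD_G418, True),
            (Spore(LocusAllele.DELETION, Plasmid.HUMAN_GENE, True), Medium.FOA, False),
            (Spore(LocusAllele.DELETION, Plasmid.EMPTY_VECTOR), Medium.YPD, False),
        ],
    )
    def test_selection_anchors(self, spore, medium, viable):
        assert media_viability(spore, medium) is viable

    def test_unknown_medium_rejected(self):
        with pytest.raises(ValueError):
            media_viability(Spore(LocusAllele.WT), "YPG")


def _ideal_tetrads(config, complementing):
    return synthetic.simulate_tetrads(config, complementing=complementing)


class TestTetradCaller:
    def test_ideal_complementing_and_noncomplementing(self, ideal_config):
        assert call_tetrad_complementation(
            _ideal_tetrads(ideal_config, True)
        ) is Call.COMPLEMENTS
        assert call_tetrad_complementation(
            _ideal_tetrads(ideal_config, False)
        ) is Call.NOT_COMPLEMENTS

    def test_noncomplementing_tetrads_have_two_viable_spores(self, ideal_config):
        for t in _ideal_tetrads(ideal_config, False):
            viable = [s for s in t.spores if media_viability(s, Medium.YPD)]
            assert len(viable) == 2
            assert all(s.locus_allele is LocusAllele.WT for s in viable)

    def test_all_dead_is_indeterminate_with_warning(self):
        spores = tuple(
            Spore(a, intrinsically_viable=False)
            for a in (LocusAllele.WT, LocusAllele.WT,
                      LocusAllele.DELETION, LocusAllele.DELETION)
        )
        with pytest.warns(UserWarning):
            assert call_tetrad_complementation([Tetrad(spores)]) is Call.INDETERMINATE

    def test_realistic_retention_still_called_complementing(self):
        """Imperfect plasmid transmission and viability: the documented
        Monte-Carlo conditions call complementation in >= 95/100 seeds."""
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, n_tetrads=50,
                                   plasmid_retention=0.6, spore_viability=0.95)
            tets = synthetic.simulate_tetrads(cfg, complementing=True)
            hits += call_tetrad_complementation(tets) is Call.COMPLEMENTS
        assert hits >= 95

    def test_tetrad_requires_two_two_segregation(self):
        spores = tuple(Spore(LocusAllele.WT) for _ in range(4))
        with pytest.raises(ValueError, match="2:2"):
            Tetrad(spores)


class TestOtherCallers:
    @pytest.mark.parametrize(
        "plus, minus, expected",
        [(200, 250, Call.COMPLEMENTS), (0, 300, Call.NOT_COMPLEMENTS),
         (9, 9, Call.NOT_COMPLEMENTS), (10, 10, Call.COMPLEMENTS)],
    )
    def test_population_threshold(self, plus, minus, expected):
        assert call_population_complementation(plus, minus, min_cfu=10) is expected

    @pytest.mark.parametrize(
        "human, empty, expected",
        [
            ((True, True), (True, False), TsCall.COMPLEMENTS),
            ((False, False), (True, False), TsCall.TOXIC),
            ((True, False), (True, False), TsCall.NOT_COMPLEMENTS),
            ((True, True), (True, True), TsCall.NOT_COMPLEMENTS),  # leaky ts allele
        ],
    )
    def test_ts_caller(self, human, empty, expected):
        growth = {
            ("human", "permissive"): human[0],
            ("human", "restrictive"): human[1],
            ("empty", "permissive"): empty[0],
            ("empty", "restrictive"): empty[1],
        }
        assert call_ts_complementation(growth) is expected

    def test_ts_missing_condition(self):
        with pytest.raises(ValueError, match="missing"):
            call_ts_complementation({("human", "permissive"): True})

    @pytest.mark.parametrize(
        "with_t, without_t, pcr, seq, expected",
        [
            (40, 0, True, True, CrisprCall.REPLACED),
            (5, 20, True, True, CrisprCall.BACKGROUND),
            (0, 0, False, False, CrisprCall.NOT_REPLACED),
            (40, 0, True, False, CrisprCall.NOT_REPLACED),
        ],
    )
    def test_crispr_caller(self, with_t, without_t, pcr, seq, expected):
        assert call_crispr_replacement(with_t, without_t, pcr, seq) is expected


class TestSegregationScoring:
    def test_viability_percent_arithmetic(self, ideal_config):
        tets = _ideal_tetrads(ideal_config, True)[:8]
        # kill exactly one spore: 31/32 viable -> 96.9%
        tets[0].spores[0].intrinsically_viable = False
        assert spore_viability(tets) == 96.9
        for s in tets[0].spores:
            s.intrinsically_viable = True
        assert spore_viability(tets) == 100.0
        for t in tets[:5]:
            t.spores[1].intrinsically_viable = False
        assert spore_viability(tets) == 84.4  # 27/32

    def test_ideal_markers_segregate_two_two(self, ideal_config):
        tets = _ideal_tetrads(ideal_config, True)
        for marker in ("MAT", "LYS2", "MET15"):
            assert marker_segregation(tets, marker).fraction_2to2 == 1.0

    def test_unknown_marker_rejected(self, ideal_config):
        with pytest.raises(KeyError):
            marker_segregation(_ideal_tetrads(ideal_config, True), "ADE2")

    def test_strict_mode_matches_binomial_oracle(self):
        """With per-spore viability p, fully scoreable tetrads occur at rate
        p^4; the observed rate lands within 3 binomial SEs."""
        p = 0.9
        n = 1000
        cfg = SimulationConfig(seed=7, n_tetrads=n, plasmid_retention=1.0,
                               spore_viability=p)
        tets = synthetic.simulate_tetrads(cfg, complementing=True)
        res = marker_segregation(tets, "MAT", strict=True)
        expect = p ** 4
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(res.n_informative / res.n_total - expect) <= 3 * se

    def test_invariant_under_reordering(self, ideal_config):
        tets = _ideal_tetrads(ideal_config, True)
        tets[0].spores[0].intrinsically_viable = False
        rng = np.random.default_rng(0)
        shuffled = [
            Tetrad(tuple(rng.permutation(np.array(t.spores, dtype=object))))
            for t in tets
        ]
        rng.shuffle(shuffled)
        assert spore_viability(shuffled) == spore_viability(tets)
        assert (
            marker_segregation(shuffled, "MAT").fraction_2to2
            == marker_segregation(tets, "MAT").fraction_2to2
        )


class TestTally:
    def test_fixture_totals_and_percentages(self):
        tally = tally_replaceability(synthetic.generate_assay_fixture(0))
        assert tally.totals == (62, 50, 13)
        assert tally.pct_tested_of_curated == 81
        assert tally.pct_complementing_of_tested == 26
        assert tally.n_families_with_hit == 5
        fam = tally.per_family
        assert fam["n_curated"].sum() == tally.totals[0]
        assert fam["n_tested"].sum() == tally.totals[1]
        assert fam["n_complementing"].sum() == tally.totals[2]
        assert (fam["n_complementing"] <= fam["n_tested"]).all()
        assert (fam["n_tested"] <= fam["n_curated"]).all()

    def test_per_family_complementing_counts(self):
        fam = tally_replaceability(synthetic.generate_assay_fixture(0)).per_family
        assert fam.loc["actin", ["n_tested", "n_complementing"]].tolist() == [7, 2]
        assert fam.loc["myosin_heavy", ["n_tested", "n_complementing"]].tolist() == [14, 4]
        assert fam.loc["septin", ["n_curated", "n_complementing"]].tolist() == [13, 4]
        assert fam.loc["tubulin_beta", ["n_tested", "n_complementing"]].tolist() == [9, 2]
        assert fam.loc["tubulin_gamma", ["n_tested", "n_complementing"]].tolist() == [2, 1]
        assert fam.loc["myosin_light", "n_complementing"] == 0
        assert fam.loc["tubulin_alpha", "n_complementing"] == 0

    def test_noncomplementing_share_noted(self):
        tally = tally_replaceability(synthetic.generate_assay_fixture(0))
        assert any("74%" in n for n in tally.notes)

    def test_empty_table(self):
        empty = pd.DataFrame(
            columns=["human_gene", "yeast_gene", "family", "assay", "outcome"]
        )
        tally = tally_replaceability(empty)
        assert tally.totals == (0, 0, 0)
        assert tally.pct_complementing_of_tested is None

    def test_conflicting_duplicates_rejected(self):
        fx = synthetic.generate_assay_fixture(0)
        conflict = fx.iloc[[0]].assign(outcome="not_complements")
        with pytest.raises(ValueError, match="conflict"):
            tally_replaceability(pd.concat([fx, conflict], ignore_index=True))
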