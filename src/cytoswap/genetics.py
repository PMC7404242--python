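"""Selection-media truth tables and complementation-assay calling.

Cross-species complementation of an essential yeast gene by its human
ortholog is scored through three assay designs:

* **Tetrad assay** — sporulate a heterozygous diploid (one allele replaced by
  a kanMX cassette conferring G418 resistance) carrying a URA3-marked CEN
  plasmid with the human gene; dissect tetrads.  A successful complementation
  shows 2:2 segregation of the deletion with survival of deletion spores on
  YPD+G418 and failure to grow on 5-FOA (which kills URA3-expressing cells,
  i.e. plasmid-dependent growth).
* **Temperature-sensitive (ts) assay** — a ts allele inactivates the yeast
  gene at the restrictive temperature; the human gene complements if its
  transformants grow at both temperatures while empty-vector controls fail
  at the restrictive one.
* **CRISPR replacement** — the human ORF is recombined into the native yeast
  locus after a Cas9 cut in the essential gene; survival itself is the
  selection, confirmed by junction PCR and sequencing.

A population-level variant of the sporulation assay scores colony-forming
units on spore-selective media with and without G418.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusAllele",
    "Plasmid",
    "Medium",
    "Call",
    "TsCall",
    "CrisprCall",
    "Spore",
    "Tetrad",
    "ReplaceabilityTally",
    "SegregationResult",
    "media_viability",
    "call_tetrad_complementation",
    "call_population_complementation",
    "call_ts_complementation",
    "call_crispr_replacement",
    "spore_viability",
    "marker_segregation",
    "tally_replaceability",
    "FAMILIES",
]

FAMILIES = (
    "actin",
    "myosin_heavy",
    "myosin_light",
    "septin",
    "tubulin_alpha",
    "tubulin_beta",
    "tubulin_gamma",
)


class LocusAllele(str, enum.Enum):
    WT = "WT"
    DELETION = "deletion"  # kanMX replacement, G418-resistant


class Plasmid(str, enum.Enum):
    NONE = "none"
    EMPTY_VECTOR = "empty_vector"  # URA3-marked, no human ORF
    HUMAN_GENE = "human_gene"      # URA3-marked, human ORF


class Medium(str, enum.Enum):
    YPD = "YPD"
    YPD_G418 = "YPD_G418"
    SC_URA = "SC_URA"
    FOA = "FOA"
    SC_URA_G418 = "SC_URA_G418"


class Call(str, enum.Enum):
    COMPLEMENTS = "complements"
    NOT_COMPLEMENTS = "not_complements"
    INDETERMINATE = "indeterminate"


class TsCall(str, enum.Enum):
    COMPLEMENTS = "complements"
    NOT_COMPLEMENTS = "not_complements"
    TOXIC = "toxic"


class CrisprCall(str, enum.Enum):
    REPLACED = "replaced"
    NOT_REPLACED = "not_replaced"
    BACKGROUND = "background"


@dataclass
class Spore:
    """One haploid spore from a dissected tetrad."""

    locus_allele: LocusAllele
    plasmid: Plasmid = Plasmid.NONE
    human_gene_complements: bool = False
    intrinsically_viable: bool = True
    aux_markers: dict = field(default_factory=dict)


@dataclass
class Tetrad:
    """Four spores from one meiosis of a heterozygous diploid.

    The locus alleles always segregate 2 WT : 2 deletion among the four
    spores (single-locus Mendelian segregation); viability thinning happens
    per spore, not by removing spores.
    """

    spores: tuple

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise ValueError(f"a tetrad has exactly 4 spores, got {len(self.spores)}")
        n_del = sum(s.locus_allele is LocusAllele.DELETION for s in self.spores)
        if n_del != 2:
            raise ValueError(f"locus alleles must segregate 2:2, got {n_del} deletion spores")


def media_viability(spore: Spore, medium: Medium | str) -> bool:
    """Whether a spore grows on the given selection medium.

    Base viability requires the spore to be intrinsically alive and to carry
    a working copy of the essential gene: either the wild-type allele, or a
    complementing human gene on the plasmid.  Selections then apply on top:
    G418 requires the kanMX deletion allele, -Ura requires a URA3 plasmid,
    and 5-FOA kills any URA3-bearing (plasmid-carrying) cell.
    """
    medium = Medium(medium)
    base = spore.intrinsically_viable and (
        spore.locus_allele is LocusAllele.WT
        or (spore.plasmid is Plasmid.HUMAN_GENE and spore.human_gene_complements)
    )
    if medium is Medium.YPD:
        return base
    if medium is Medium.YPD_G418:
        return base and spore.locus_allele is LocusAllele.DELETION
    if medium is Medium.SC_URA:
        return base and spore.plasmid is not Plasmid.NONE
    if medium is Medium.SC_URA_G418:
        return (
            base
            and spore.plasmid is not Plasmid.NONE
            and spore.locus_allele is LocusAllele.DELETION
        )
    if medium is Medium.FOA:
        # 5-FOA counter-selection: URA3-bearing cells die; only plasmid-free
        # wild-type spores survive (plasmid-free deletion spores are dead
        # anyway, lacking the essential gene).
        return (
            spore.intrinsically_viable
            and spore.locus_allele is LocusAllele.WT
            and spore.plasmid is Plasmid.NONE
        )
    raise ValueError(f"unknown medium: {medium}")  # pragma: no cover


def _tetrad_flags(tetrad: Tetrad) -> tuple[bool, bool]:
    """(informative, consistent_with_complementation) for one tetrad.

    Informative means at least one deletion spore grew on YPD: a tetrad
    whose deletion spores all died cannot distinguish non-complementation
    from meiotic plasmid loss, so it carries no evidence either way.
    """
    viable_del = [
        s
        for s in tetrad.spores
        if s.locus_allele is LocusAllele.DELETION and media_viability(s, Medium.YPD)
    ]
    informative = bool(viable_del)
    consistent = informative and all(
        media_viability(s, Medium.YPD_G418) and not media_viability(s, Medium.FOA)
        for s in viable_del
    )
    return informative, consistent


def call_tetrad_complementation(
    tetrads: Sequence[Tetrad], min_consistent_fraction: float = 0.75
) -> Call:
    """Call complementation from dissected tetrads.

    A tetrad is informative when at least one deletion spore is viable, and
    consistent with complementation when every viable deletion spore grows
    on YPD+G418 and fails on 5-FOA (plasmid-dependent rescue).  The assay
    calls ``complements`` when the consistent fraction among informative
    tetrads reaches ``min_consistent_fraction``; ``not_complements`` when
    deletion spores are uniformly inviable while wild-type spores grew (the
    classic two-viable-spore pattern); and ``indeterminate`` otherwise —
    including the failed-dissection case of no viable spores at all, which
    warns.
    """
    if not tetrads:
        raise ValueError("need at least one tetrad")
    any_viable = any(
        media_viability(s, Medium.YPD) for t in tetrads for s in t.spores
    )
    if not any_viable:
        warnings.warn("no viable spores in any tetrad; call is indeterminate")
        return Call.INDETERMINATE
    flags = [_tetrad_flags(t) for t in tetrads]
    informative = [c for inf, c in flags if inf]
    if not informative:
        return Call.NOT_COMPLEMENTS  # deletion spores uniformly inviable
    frac = sum(informative) / len(informative)
    if frac >= min_consistent_fraction:
        return Call.COMPLEMENTS
    return Call.INDETERMINATE


def call_population_complementation(
    cfu_plus_g418: int, cfu_minus_g418: int, min_cfu: int = 10
) -> Call:
    """Population-level sporulation assay on spore-selective media +/- G418.

    Complementation requires proliferation both with G418 (selecting
    deletion-allele spores, which need the human gene) and without it
    (selecting wild-type spores); both colony counts must reach ``min_cfu``.
    """
    if cfu_plus_g418 < 0 or cfu_minus_g418 < 0:
        raise ValueError("colony counts must be >= 0")
    if cfu_plus_g418 >= min_cfu and cfu_minus_g418 >= min_cfu:
        return Call.COMPLEMENTS
    return Call.NOT_COMPLEMENTS


def call_ts_complementation(growth: Mapping[tuple[str, str], bool]) -> TsCall:
    """Call a temperature-sensitive rescue assay.

    ``growth`` maps (plasmid, temperature) with plasmid in {"human",
    "empty"} and temperature in {"permissive", "restrictive"} to a binary
    grew/failed flag.  Complementation: the human-gene transformant grows at
    both temperatures while the empty vector grows only at the permissive
    one.  Toxicity: the human gene kills growth even at the permissive
    temperature while the control grows.
    """
    required = {
        (p, t) for p in ("human", "empty") for t in ("permissive", "restrictive")
    }
    missing = required - set(growth)
    if missing:
        raise ValueError(f"missing ts assay conditions: {sorted(missing)}")
    h_perm = growth[("human", "permissive")]
    h_rest = growth[("human", "restrictive")]
    e_perm = growth[("empty", "permissive")]
    e_rest = growth[("empty", "restrictive")]
    if h_perm and h_rest and e_perm and not e_rest:
        return TsCall.COMPLEMENTS
    if not h_perm and e_perm:
        return TsCall.TOXIC
    return TsCall.NOT_COMPLEMENTS


def call_crispr_replacement(
    colonies_with_template: int,
    colonies_without_template: int,
    junction_pcr_ok: bool = False,
    sequence_ok: bool = False,
) -> CrisprCall:
    """Call a CRISPR locus-replacement assay.

    Survival after the Cas9 cut is itself the selection: replacement requires
    colonies in the presence of the human repair template, plus junction-PCR
    and sequence confirmation.  If the no-template control yields at least as
    many colonies, survivors are escaper/uncut background.
    """
    if colonies_with_template < 0 or colonies_without_template < 0:
        raise ValueError("colony counts must be >= 0")
    if colonies_without_template >= colonies_with_template and colonies_without_template > 0:
        return CrisprCall.BACKGROUND
    if colonies_with_template > 0 and junction_pcr_ok and sequence_ok:
        return CrisprCall.REPLACED
    return CrisprCall.NOT_REPLACED


def spore_viability(tetrads: Sequence[Tetrad]) -> float:
    """Percent of spores viable on YPD, to one decimal (e.g. 31/32 -> 96.9)."""
    if not tetrads:
        raise ValueError("need at least one tetrad")
    viable = sum(
        media_viability(s, Medium.YPD) for t in tetrads for s in t.spores
    )
    return round(100.0 * viable / (4 * len(tetrads)), 1)


@dataclass
class SegregationResult:
    marker: str
    fraction_2to2: float
    n_informative: int
    n_total: int


def marker_segregation(
    tetrads: Sequence[Tetrad], marker: str, strict: bool = True
) -> SegregationResult:
    """Fraction of tetrads in which a marker segregates 2:2.

    In strict mode a tetrad is informative only when all four spores are
    viable (scoreable); otherwise tetrads are scored on their viable spores,
    counting a tetrad as 2:2-consistent when no allele appears more than
    twice.
    """
    if not tetrads:
        raise ValueError("need at least one tetrad")
    for t in tetrads:
        for s in t.spores:
            if marker not in s.aux_markers:
                raise KeyError(f"marker {marker!r} not scored on spores")
    n_informative = 0
    n_2to2 = 0
    for t in tetrads:
        alive = [s for s in t.spores if media_viability(s, Medium.YPD)]
        if strict:
            if len(alive) < 4:
                continue
            n_informative += 1
            counts = pd.Series([s.aux_markers[marker] for s in alive]).value_counts()
            if len(counts) == 2 and (counts == 2).all():
                n_2to2 += 1
        else:
            if not alive:
                continue
            n_informative += 1
            counts = pd.Series([s.aux_markers[marker] for s in alive]).value_counts()
            if (counts <= 2).all():
                n_2to2 += 1
    frac = n_2to2 / n_informative if n_informative else float("nan")
    return SegregationResult(marker, frac, n_informative, len(tetrads))


@dataclass
class ReplaceabilityTally:
    """Per-family and total curated/tested/complementing counts."""

    per_family: pd.DataFrame  # index family, cols n_curated/n_tested/n_complementing
    totals: tuple[int, int, int]
    pct_tested_of_curated: int | None
    pct_complementing_of_tested: int | None
    n_families_with_hit: int
    notes: list = field(default_factory=list)


_REQUIRED_COLS = {"human_gene", "yeast_gene", "family", "assay", "outcome"}


def tally_replaceability(records: pd.DataFrame) -> ReplaceabilityTally:
    """Tally replaceability over assay records.

    A human gene counts as tested if any of its assays was performed and as
    complementing if any assay of any of its ortholog pairs returned
    ``complements`` ("at least one of the three assay types").  Duplicate
    records for the same (pair, assay) must agree; conflicts raise.
    """
    missing = _REQUIRED_COLS - set(records.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    if records.empty:
        empty = pd.DataFrame(
            columns=["n_curated", "n_tested", "n_complementing"], dtype=int
        )
        return ReplaceabilityTally(empty, (0, 0, 0), None, None, 0,
                                   notes=["empty record table; percentages undefined"])
    dup = records.groupby(["human_gene", "yeast_gene", "assay"])["outcome"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(
            f"conflicting duplicate records for {list(conflicts.index[:5])}"
        )
    records = records.drop_duplicates(["human_gene", "yeast_gene", "assay"])

    per_gene = records.groupby("human_gene").agg(
        family=("family", "first"),
        tested=("outcome", lambda o: bool((o != "not_tested").any())),
        complementing=("outcome", lambda o: bool((o == "complements").any())),
    )
    fam = per_gene.groupby("family").agg(
        n_curated=("tested", "size"),
        n_tested=("tested", "sum"),
        n_complementing=("complementing", "sum"),
    )
    fam = fam.reindex([f for f in FAMILIES if f in fam.index]).astype(int)
    totals = (
        int(fam["n_curated"].sum()),
        int(fam["n_tested"].sum()),
        int(fam["n_complementing"].sum()),
    )
    n_cur, n_tst, n_cmp = totals
    pct_tested = round(100 * n_tst / n_cur) if n_cur else None
    pct_compl = round(100 * n_cmp / n_tst) if n_tst else None
    notes = []
    if n_tst:
        pct_not = round(100 * (n_tst - n_cmp) / n_tst)
        notes.append(
            f"computed non-complementing share is {pct_not}% "
            f"({n_tst - n_cmp}/{n_tst}); all percentages recomputed from counts"
        )
    return ReplaceabilityTally(
        per_family=fam,
        totals=totals,
        pct_tested_of_curated=pct_tested,
        pct_complementing_of_tested=pct_compl,
        n_families_with_hit=int((fam["n_complementing"] > 0).sum()),
        notes=notes,
    )
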