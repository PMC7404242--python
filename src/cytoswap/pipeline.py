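"""End-to-end pipeline orchestration and run configuration.

A :class:`RunConfig` carries one master seed, per-stage parameter blocks and
an output directory; :func:`run_pipeline` executes the full synthetic demo —
simulate, complementation calling, growth kinetics, imaging morphometrics,
phenocopy enrichment — and writes a single versioned JSON report plus a
resolved-config snapshot.  Stage failures abort with the stage name; partial
outputs are retained with a MANIFEST flagging incompleteness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import genetics, growth, imaging, io, phenocopy, synthetic
from .config import ConfigurationError, SimulationConfig

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0.0"

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "REPORT_SCHEMA_VERSION"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_KNOWN_KEYS = {"seed", "output_dir", "log_level", "simulation", "genetics",
               "growth", "imaging", "phenocopy"}


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "cytoswap_run"
    log_level: str = "info"
    simulation: dict = field(default_factory=dict)
    genetics: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    imaging: dict = field(default_factory=dict)
    phenocopy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.log_level not in ("debug", "info", "warning"):
            raise ConfigurationError(f"invalid log_level: {self.log_level}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def sim_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig.from_dict(sim)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "output_dir": self.output_dir,
            "log_level": self.log_level, "simulation": self.simulation,
            "genetics": self.genetics, "growth": self.growth,
            "imaging": self.imaging, "phenocopy": self.phenocopy,
        }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic demo pipeline and write ``report.json``.

    Returns the report dict.  All randomness flows from ``config.seed``
    through named per-stage substreams.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    sim = config.sim_config()
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
    }
    completed: list[str] = []
    try:
        stage = "simulate+call-complementation"
        fixture = synthetic.generate_assay_fixture(config.seed)
        io.write_tsv(fixture, out / "assay_fixture.tsv")
        tally = genetics.tally_replaceability(fixture)
        min_frac = config.genetics.get("min_consistent_fraction", 0.75)
        tet_c = synthetic.simulate_tetrads(sim, complementing=True)
        tet_n = synthetic.simulate_tetrads(sim, complementing=False)
        io.write_tsv(io.tetrads_to_frame(tet_c), out / "tetrads_complementing.tsv")
        report["tallies"] = {
            "totals": list(tally.totals),
            "pct_tested_of_curated": tally.pct_tested_of_curated,
            "pct_complementing_of_tested": tally.pct_complementing_of_tested,
            "n_families_with_hit": tally.n_families_with_hit,
            "per_family": tally.per_family.to_dict(orient="index"),
            "notes": tally.notes,
        }
        report["tetrad_calls"] = {
            "complementing_sim": genetics.call_tetrad_complementation(tet_c, min_frac).value,
            "noncomplementing_sim": genetics.call_tetrad_complementation(tet_n, min_frac).value,
            "spore_viability_pct": genetics.spore_viability(tet_c),
        }
        completed.append(stage)

        stage = "growth"
        gcfg = dict(config.growth)
        fit_points = gcfg.get("fit_points", 9)
        wt_curves, wt_truth = synthetic.simulate_growth_curves(sim, strain="WT")
        quarter_rate = sim.growth_params.max_rate_per_min / 4.0
        hu_curves, hu_truth = synthetic.simulate_growth_curves(
            sim, strain="humanized", rate=quarter_rate
        )
        io.write_growth_csv(
            growth.curves_to_frame(wt_curves + hu_curves), out / "growth_curves.csv"
        )
        def _fit(curves):
            pooled = growth.pool_replicates(
                [growth.preprocess(c, smooth_window=5) for c in curves]
            )
            return growth.doubling_time(pooled, fit_points=fit_points)
        wt_stats, hu_stats = _fit(wt_curves), _fit(hu_curves)
        dratio, sratio = growth.compare_to_wildtype(hu_stats, wt_stats)
        report["growth"] = {
            "wt_doubling_min": wt_stats.doubling_time_min,
            "humanized_doubling_min": hu_stats.doubling_time_min,
            "doubling_ratio": dratio,
            "saturation_ratio": sratio,
            "true_wt_doubling_min": wt_truth["doubling_time_min"],
        }
        completed.append(stage)

        stage = "imaging"
        icfg = dict(config.imaging)
        k_nuclei = icfg.get("k_nuclei", 3)
        bright_wt, dapi_wt, truth_wt = synthetic.render_cell_field(
            sim, strain_shape=(600.0, 1.2), k_nuclei=1
        )
        bright_hu, dapi_hu, truth_hu = synthetic.render_cell_field(
            sim, strain_shape=(900.0, 3.0), k_nuclei=k_nuclei
        )
        io.write_image(bright_wt, out / "field_wt_bright.tiff")
        io.write_image(bright_hu, out / "field_humanized_bright.tiff")
        params = imaging.SegmentationParams(**icfg.get("segmentation", {}))
        meas = {}
        for name, img, dap in (
            ("WT", bright_wt, dapi_wt),
            ("humanized", bright_hu, dapi_hu),
        ):
            mask = imaging.segment_cells(img, params)
            df = imaging.measure_cells(mask, field_id=f"{name}_f0")
            df = df.merge(imaging.count_nuclei(dap, mask), on="cell_id", how="left")
            meas[name] = df
        io.write_tsv(meas["humanized"], out / "cell_measurements_humanized.tsv")
        cmp_ = imaging.compare_strain_sizes(
            meas["humanized"]["area_px2"], meas["WT"]["area_px2"],
            strain="humanized", reference="WT",
        )
        report["imaging"] = {
            "n_cells_wt": int(len(meas["WT"])),
            "n_cells_humanized": int(len(meas["humanized"])),
            "planted_cells_per_field": sim.image_params.n_cells,
            "size_comparison": {
                "t": cmp_.t_statistic, "p": cmp_.p_value, "stars": cmp_.stars,
            },
            "modal_nuclei_humanized": int(meas["humanized"]["n_nuclei"].mode().iat[0]),
            "qc": imaging.qc_dataset(meas["humanized"], min_fields=1, min_cells=1),
        }
        completed.append(stage)

        stage = "phenocopy"
        pcfg = dict(config.phenocopy)
        morph, inter, truth = synthetic.simulate_morphology_database(
            sim,
            preset=pcfg.get("preset", "elongated"),
            focal_gene=pcfg.get("focal", "CDC10"),
            interaction_type=pcfg.get("type", "genetic"),
        )
        io.write_tsv(morph, out / "morphology.tsv")
        io.write_tsv(inter, out / "interactions.tsv")
        scores = phenocopy.classify_by_zscore(
            phenocopy.budded_circularity(morph),
            threshold_sd=pcfg.get("threshold_sd", 2.0),
        )
        morph_class = "elongated" if truth["shift"] >= 0 else "circular"
        res = phenocopy.enrichment(
            scores, inter, truth["focal_gene"], truth["interaction_type"],
            morph_class, min_evidence=pcfg.get("min_evidence", 2),
        )
        report["enrichment"] = {
            "focal_gene": res.focal_gene, "interaction_type": res.interaction_type,
            "morph_class": res.morph_class, "k": res.k, "K": res.K,
            "n": res.n, "N": res.N, "p": res.p,
        }
        completed.append(stage)
    except Exception as exc:
        (out / "MANIFEST.json").write_text(
            json.dumps({"complete": False, "completed_stages": completed,
                        "failed_stage": stage, "error": str(exc)}, indent=2)
        )
        raise PipelineError(stage, exc) from exc

    (out / "MANIFEST.json").write_text(
        json.dumps({"complete": True, "completed_stages": completed}, indent=2)
    )
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
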