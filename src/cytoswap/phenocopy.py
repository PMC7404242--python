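"""Morphology-database phenocopy enrichment.

Humanized strains with abnormal morphologies (round actin-humanized cells,
elongated septin-humanized cells) phenocopy deletions of their yeast
ortholog's interaction partners.  The analysis scores every deletion strain
by the long-to-short mother-cell axis ratio of its budded cells (C103/C104,
a circularity/elongation index), classifies the z-score tails (circular at
z <= -threshold, elongated at z >= +threshold), restricts the focal gene's
interactors to well-evidenced, morphology-measured partners, and tests the
tail overlap with an exact upper-tail hypergeometric probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "budded_circularity",
    "classify_by_zscore",
    "filter_interactors",
    "hypergeom_upper",
    "enrichment",
    "EnrichmentResult",
]

_BUDDED = ("B", "C")


def budded_circularity(
    records: pd.DataFrame, method: str = "mean_of_ratios"
) -> pd.DataFrame:
    """Per-strain budded-cell circularity index (C103/C104 ratio).

    With ``method="mean_of_ratios"`` (default) the strain score is the mean
    over its budded cell-type rows (B, C) of each row's C103/C104;
    ``method="ratio_of_means"`` divides pooled means instead.  Strains with
    no budded rows are dropped (logged).  Unbudded (A) rows are ingested but
    unused by this statistic.
    """
    required = {"strain", "cell_type", "C103", "C104"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"morphology table missing columns: {sorted(missing)}")
    if (records["C104"] <= 0).any():
        raise ValueError("C104 must be positive")
    if (records["C103"] < records["C104"]).any():
        raise ValueError("C103 (long axis) must be >= C104 (short axis)")
    budded = records[records["cell_type"].isin(_BUDDED)]
    n_dropped = records["strain"].nunique() - budded["strain"].nunique()
    if n_dropped:
        logger.info("dropped %d strains with no budded (B/C) rows", n_dropped)
    if method == "mean_of_ratios":
        ratio = (
            (budded["C103"] / budded["C104"])
            .groupby(budded["strain"])
            .mean()
        )
    elif method == "ratio_of_means":
        g = budded.groupby("strain")
        ratio = g["C103"].mean() / g["C104"].mean()
    else:
        raise ValueError(f"unknown method: {method}")
    return ratio.rename("ratio").reset_index()


def classify_by_zscore(
    scores: pd.DataFrame, threshold_sd: float = 2.0, log_scale: bool = False
) -> pd.DataFrame:
    """Standardize circularity ratios and classify distribution tails.

    z-scores are computed across all scored strains on the raw ratio (or its
    log with ``log_scale``); ``circular`` at z <= -threshold, ``elongated``
    at z >= +threshold, ``normal`` between.  Zero spread yields all-normal
    with a warning.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 strains to standardize")
    out = scores.copy()
    x = np.log(out["ratio"].to_numpy()) if log_scale else out["ratio"].to_numpy()
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn("zero spread in circularity ratios; all strains classified normal")
        out["z"] = 0.0
        out["morph_class"] = "normal"
        return out
    out["z"] = (x - x.mean()) / sd
    out["morph_class"] = np.select(
        [out["z"] <= -threshold_sd, out["z"] >= threshold_sd],
        ["circular", "elongated"],
        default="normal",
    )
    return out


def filter_interactors(
    interactions: pd.DataFrame,
    focal: str,
    interaction_type: str,
    min_evidence: int = 2,
    measured_strains: set | None = None,
) -> set:
    """A priori-filtered interactor set of a focal gene.

    Keeps partners of ``focal`` with the requested interaction type,
    evidence reported at least ``min_evidence`` times, and (when given)
    morphology coverage in ``measured_strains``.
    """
    required = {"focal_gene", "partner", "interaction_type", "evidence_count"}
    missing = required - set(interactions.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    sel = interactions[
        (interactions["focal_gene"] == focal)
        & (interactions["interaction_type"] == interaction_type)
        & (interactions["evidence_count"] >= min_evidence)
        & (interactions["partner"] != focal)
    ]
    partners = set(sel["partner"])
    if measured_strains is not None:
        partners &= set(measured_strains)
    return partners


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts successes when drawing ``n`` items without replacement from a
    universe of ``N`` containing ``K`` successes.  Computed by summing
    log-space terms (stable for genome-scale N); no continuity correction.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap of a morphology class with an interactor set."""

    focal_gene: str
    interaction_type: str
    morph_class: str
    k: int  # overlap
    K: int  # filtered interactors
    n: int  # class size
    N: int  # universe (scored strains)
    p: float


def enrichment(
    scores: pd.DataFrame,
    interactions: pd.DataFrame,
    focal: str,
    interaction_type: str,
    morph_class: str,
    min_evidence: int = 2,
    universe: str = "scored",
) -> EnrichmentResult:
    """Interactor enrichment in a morphology class.

    ``scores`` must carry ``morph_class`` (see :func:`classify_by_zscore`).
    The universe defaults to all scored strains; ``universe`` may be an
    integer-like alternative size (e.g. the full collection) for
    sensitivity analysis.
    """
    if "morph_class" not in scores.columns:
        raise ValueError("scores must be classified first (missing morph_class)")
    measured = set(scores["strain"])
    partners = filter_interactors(
        interactions, focal, interaction_type, min_evidence, measured
    )
    members = set(scores.loc[scores["morph_class"] == morph_class, "strain"])
    N = len(measured) if universe == "scored" else int(universe)
    k = len(partners & members)
    K = len(partners)
    n = len(members)
    p = 1.0 if n == 0 else hypergeom_upper(k, K, n, N)
    return EnrichmentResult(
        focal_gene=focal, interaction_type=interaction_type,
        morph_class=morph_class, k=k, K=K, n=n, N=N, p=p,
    )
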