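# Methods

## Scope and shape

The package models the computational workflow of a humanization screen:
assay calling from selection logic, growth kinetics, cell morphometrics,
and a morphology-database enrichment analysis, with a synthetic-data layer
that generates every input with planted ground truth. It deliberately does
not model wet-lab steps (cloning, sporulation media, guide design) or
sequence-level data.

## Genetics: selection logic and callers

A spore's fate on a medium is a pure function of its state. Base viability
requires an intrinsically live spore and a functional copy of the essential
gene — the wild-type allele, or a complementing human gene on the plasmid.
Selections compose on top: G418 requires the kanMX deletion allele, −Ura
requires a URA3 plasmid, and 5-FOA kills every URA3 carrier, so only
plasmid-free wild-type spores survive it. The truth table is exhaustively
enumerated in the tests.

The tetrad caller scores a tetrad as *informative* when at least one
deletion spore grew on YPD. Tetrads whose deletion spores all died are
deliberately uninformative: with a CEN plasmid transmitted imperfectly
through meiosis, a dead deletion pair cannot distinguish
non-complementation from plasmid loss. A tetrad is *consistent* when every
viable deletion spore grows on YPD+G418 and fails on 5-FOA. The call is
`complements` when the consistent fraction of informative tetrads reaches
`min_consistent_fraction` (default 0.75 — the assay is described as binary,
so a majority-with-margin rule is exposed as a flag rather than asserted),
`not_complements` when wild-type spores grew but no deletion spore ever did
(the classic two-viable-spore pattern), and `indeterminate` otherwise.

The population caller requires both colony counts (± G418 spore selections)
to reach `min_cfu` (default 10; the threshold's existence is part of the
assay design, its value is this package's choice). The ts caller treats
growth per condition as binary and separates toxicity (human gene kills the
permissive-temperature control) from non-complementation; quantitative ts
growth belongs to the growth module. The CRISPR caller requires surviving
colonies with the repair template plus junction-PCR and sequence
confirmation, and flags escaper-dominated plates (no-template colonies ≥
template colonies) as background.

Gene-level tallies deduplicate across assays: a human gene complements if
any assay of any of its ortholog pairs complements. Percentages are always
recomputed from counts and rounded to integer percent; the tally notes the
computed non-complementing share explicitly.

## Growth kinetics

The generator's model is logistic with an explicit lag:
OD(t) = K·OD0·e^{r(t−lag)} / (K + OD0·(e^{r(t−lag)} − 1)) for t ≥ lag,
plus additive Gaussian read noise, clipped at zero. Defaults: lag 120 min,
r = ln2/100 per min (100-min doubling), K = 1.2 OD, OD0 = 0.05,
noise sd 0.01, readings every 15 min for 48 h (193 samples). These are the
package's stated recovery targets, not field constants.

Estimation slides a `fit_points`-long window (default 9 points = 2 h) over
ln OD and takes least-squares slopes. Three refinements matter at realistic
noise, where the raw maximum window slope is biased (upward by noise at low
OD, downward by saturation):

* windows whose mean OD has not cleared 1.5× the inoculum are excluded from
  the maximum — they contain read noise, not growth;
* when the curve has plateaued (final window slope < 0.1× max), each window
  slope is divided by (1 − OD/K̂), K̂ = mean of the final 5% of readings,
  and the specific rate is the median over growth-phase windows (slope >
  0.5× max, OD < 0.8 K̂) — for a logistic curve this corrected quantity is
  constant through the growth phase, so the median is robust;
* when the curve decelerates without plateauing (e.g. a quarter-rate strain
  in a 48-h window) the corrected-window estimate is unreliable and a full
  logistic least-squares fit is used instead; a still-exponential curve
  keeps the raw maximum slope, which is exact on noiseless data.

`method="window_max"` (plain maximum) and `method="logistic"` are exposed.
Saturation biomass is the mean of the final 5% of readings; lag is the
first time OD exceeds 1.5× its initial value (a convention). Doubling time
is ln2/rate, null when no positive growth is detected. Replicates are
summarized as mean/SD/n with nulls excluded, and curves on a common
schedule can be pooled point-wise before fitting.

## Imaging

The renderer draws cells as dark elliptical rims on a light background
(rim ≈ 2 px, drawn just inside the true boundary so the filled outline
equals the planted ellipse), places them without overlap by rejection
sampling, keeps them clear of the border, and adds Gaussian noise
(default 0.02 on a 0–1 intensity scale; 512×512 px fields, pixel units
throughout — no micron calibration). The DAPI channel puts k Gaussian
spots along the major axis per cell (k > 1 emulates the multinucleate
phenotype of defective cytokinesis).

Segmentation is edge-based: Gaussian smoothing (sigma 2 px) → Sobel
gradient magnitude → Otsu threshold → morphological closing (disk 2) →
hole filling → fractional-radius erosion by sigma + 1.4 px (the smoothing
chain places the outer detected edge that far outside the true boundary;
the pull-back was calibrated on noiseless renders and keeps mean areas
within ~3%) → border clearing → labeling → area filter. The pipeline is
fully deterministic. Axes come from second central moments
(equivalent-ellipse axes); nuclei are local maxima of the smoothed DAPI
channel within each component (min distance 5 px, relative threshold 0.3).
Dataset QC requires ≥ 10 fields of view and ≥ 2000 cells (inclusive).
Size distributions are compared with a Welch t-test (a pooled-variance
flag exists) and binned as *** (p ≤ 0.001), ** (≤ 0.01), * (≤ 0.05), NS.

Touching mother–bud pairs segment as one component; no watershed split is
applied by default. Reported cell counts are post-filter.

## Phenocopy enrichment

Per strain, the circularity index is the mean over budded cell-type rows
(B, C) of C103/C104; a pooled ratio-of-means variant is exposed. Unbudded
(A) rows are ingested but unused by the statistic. z-scores are computed on
raw ratios across all scored strains (a log-scale flag exists); circular is
z ≤ −2 and elongated z ≥ +2 by default. The universe N of the
hypergeometric test is the set of scored strains, since classification
requires a score; an alternative N can be passed for sensitivity analysis.
Interactor sets are restricted a priori to the focal gene's partners of the
requested type with ≥ 2 evidence reports and morphology coverage. The
upper-tail probability is computed exactly in log space (gammaln +
logsumexp); the test is one-sided with no multiple-testing correction.

The database generator draws, per strain and cell type, a positive short
axis (lognormal around 18 units) and a Gaussian log axis-ratio
(mean 0.25, sd 0.10 — a typical budded axis ratio of ~1.3 with ~10%
spread), clipped so ratio ≥ 1, over 4718 strains. A planted subset of 20
strains (the focal gene's designated interactors) is shifted by ±1.0 on
the log ratio for the elongated/circular presets; a null preset plants no
shift. These defaults were fixed by a Monte-Carlo calibration study run
before the analysis code: under the null the enrichment rejects at
p ≤ 0.05 in ≈ 2% of seeds (the hypergeometric test is discrete, hence
conservative), the elongated class holds ≈ 2.8% of strains, and the
planted alternative is detected at p < 0.01 in ~100% of seeds. The
interaction table also carries under-evidenced partners, partners of the
other interaction type, and an unmeasured partner, so the filters are
exercised.

## Synthetic assay fixture

The packaged assay table reproduces the study-scale tallies: 62 curated
human genes, 50 tested, 13 complementing, five of seven families with at
least one hit; 13 human × 7 yeast septins give the 91-assay septin space.
The five families with printed per-family numbers are fully tested (actin
2/7, heavy myosin 4/14, septin 4/13 against the one rescuable background,
β-tubulin 2/9, γ-tubulin 1/2); the two never-complementing families close
the totals with light myosin 12 curated / 3 tested and α-tubulin 5 curated
/ 2 tested. Complementing identities are the named genes where known;
remaining flags are a documented synthetic allocation. Two stated
pair-level figures (106 testable pairs; 89 of 109 assayed) are recorded as
fixture metadata without reconciliation.

## What the generators do and do not emulate

Tetrads assume a single Mendelian locus with independent Bernoulli plasmid
transmission per spore (default retention 0.9) and independent intrinsic
spore death — no linkage, gene conversion, aneuploidy, or vegetative
plasmid loss dynamics. Growth curves are single-well logistic with i.i.d.
noise — no evaporation, well-position, or diauxic effects. Rendered cells
are non-overlapping rim ellipses — sufficient for edge-detection and
moment-based measurement, not photorealistic bright-field texture, and no
budded mother–daughter geometry. The morphology database plants a single
shifted interactor set — real deletion-collection phenotypes are
heterogeneous and correlated. Passing tests therefore demonstrate the
pipeline's correctness on data obeying these models, not performance on
real micrographs or database extracts.

## Reproducibility and problem sizes

All randomness flows from one seed through named, CRC-keyed substreams, so
each stage can be re-run in isolation and equal seeds give byte-identical
outputs. The test and acceptance suites use 10–200 seeds per Monte-Carlo
claim, 25-cell 512-px fields, triplicate 193-point curves, and the full
4718-strain database — sizes chosen so the complete suite runs in well
under a minute of compute per stage while keeping binomial noise on
reported rates at a few percent.
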