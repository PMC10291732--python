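# Methods

`pulmotree` implements a location-specific analysis workflow for
monopodial pulmonary vascular trees: vessel segments are classified into
homogeneous groups by competing schemes, the scheme whose groups are most
homogeneous in morphometric feature space is selected, and experimental
groups are then compared feature by feature both globally and within each
group of the selected classification.  This note documents the models,
the numerical choices and the limits of what the synthetic validation can
show.

## The data model

A skeletonized vessel tree is a rooted tree whose edges ("segments") are
the vessel stretches between consecutive branch points, each with a
unique integer id, a centerline length and a mean lumen radius in
micrometres.  Orientation is always derived from the declared root, never
from file row order, so trees survive arbitrary skeletonization output.
Chains through degree-2 nodes are contracted into single segments
(lengths add; radii combine as the length-weighted mean; the most
proximal id survives), because a node that does not branch is not a
segment boundary.  Disjoint trees from a damaged sample can be merged
under an artificial root connected by artificial, measurement-free
segments; artificial segments are labelled for bookkeeping but excluded
from every feature table and statistic, so a repair can never create a
phantom vessel group.

Per-segment morphometry comes from repeated cross-section observations:
lumen diameter `A`, outer diameter `B` (lumen plus both media walls; the
adventitia is excluded), and optionally a smooth-muscle layer count.  The
wall thickness of one observation is `(B − A) / 2`.  Observations are
averaged per segment; the wall is averaged per observation rather than
recomputed from averaged diameters (for complete `A`,`B` pairs the two
coincide by linearity, so the choice is conservative), and the layer
count is averaged over the observations where it exists.

## Classification schemes

Four positional schemes operate on the contracted tree:

* **Generations** — branch points passed from the root; the main trunk
  segment is generation 0 (Weibel convention).
* **Horsfield orders** — terminal segments are order 1, every parent is
  `max(child orders) + 1`.
* **Strahler orders** — like Horsfield, but the order increments only
  where at least two children attain the running maximum (the standard
  multifurcation rule), collapsing the side branches of a dominant trunk.
* **Fractal generations** — diameter-aware: at each branch point the
  largest-radius child continues its parent's generation iff its radius
  is at least `alpha` times the parent's (default `alpha = 0.8`,
  configurable and recorded with the result; radius ties break toward the
  smaller segment id); all other children start a new generation; the
  root is generation 1.

Label origins (generations 0; orders/Strahler 1; fractal 1) are fixed
conventions, documented rather than configurable.

The morphometric scheme is a Gaussian mixture model on the raw,
unstandardized (lumen, wall) matrix, with full covariance per component —
mixture fitting with unconstrained covariance is affine-equivariant, so
feature scaling is immaterial.  EM runs to a mean log-likelihood change
below 1e-8 (at most 500 iterations) from the best of 10 k-means++
initializations under an explicit seed (package default 20230626).  The
component count is chosen by BIC in the larger-is-better convention
`BIC = 2 log L − m ln n` with `m = (k−1) + kd + kd(d+1)/2`; all candidate
fits are retained so BIC near-ties (within 10 units, configurable) can
additionally be scored with the validity index below.  "Local" mode fits
one mixture per sample; "global" mode pools all samples and maps the
shared components back.  Components are renumbered so component 1 has the
largest mean lumen.  A covariance whose determinant falls below 1e-12 is
treated as collapse and reported as an error suggesting the opt-in
variance floor (1e-6 of the mean feature variance); a vanishing numerical
ridge (1e-10 of the mean feature variance) is always present because the
Cholesky-based E-step requires strict positive definiteness.

## Scheme evaluation and selection

Every scheme is scored with the Davies–Bouldin index in the same
(lumen, wall) feature space the mixture model uses — the only internally
consistent choice when positional schemes are judged by morphometric
homogeneity.  With `S_i` the mean Euclidean distance of group *i*'s rows
to their centroid and `M_ij` the centroid distance,

    DB = (1/k) · Σ_i max_{j≠i} (S_i + S_j) / M_ij ,

lower is better; coincident centroids yield +∞.  Segments without
measurements, and groups left without measured members, are dropped
before scoring.  Per-sample schemes are summarized by the arithmetic mean
of the per-sample scores; pooled-fit schemes are scored once on the
concatenated rows.  The scheme with the lowest global score is selected,
ties resolved toward fewer groups, then by name.  Report tables round to
two decimals with half-up ties (plain binary rounding would turn a mean
of 2.245 into 2.24); full precision is kept internally.

## Group statistics

Each feature (lumen, wall, layers) is compared between the two groups
with the two-sided Mann–Whitney U test, once on all measured segments
pooled per group and once within every cluster of the selected scheme.
The exact null distribution is used for tie-free samples with
`n·m ≤ 400`; otherwise the normal approximation with tie and continuity
correction.  The reported U is the conventional `min(U_x, nm − U_x)`, so
results are invariant to swapping the groups.  Stars follow `* p < 0.05`,
`** p < 0.01`.  For significant strata the effect strength

    r = |Φ⁻¹(p/2)| / √N

is attached, with `N = n_A + n_B` *of that stratum* — the only choice
that makes `r` comparable across strata — and binned as 0.1–0.3 weak,
0.3–0.5 medium, ≥ 0.5 strong (< 0.1 none; bands closed on the left).
No multiple-testing correction is applied by default, matching the
uncorrected pilot-study design the workflow emulates; an optional
Benjamini–Hochberg flag is available.  An empty stratum in either group
is reported as a row with missing statistics, never dropped silently.
Segment measurements are pooled per group; animal-level random effects
are out of scope and acknowledged as a limitation of the emulated design.

## The synthetic cohort generator

The generator emulates the study conditions the package is validated
under: two groups of two animals, one monopodial arterial tree each.

**Trees.**  Branching has two regimes.  The main axial trunk advances in
steps of `max(length_to_radius·r, lateral_spacing)`, tapering by
`trunk_taper = 0.965` per step and shedding one thin lateral per step
(`lateral_ratio = 0.3` of the trunk radius, lognormal jitter cv 0.15);
branches off the trunk taper fast (`peripheral_taper = 0.75`) with
relatively large daughters (`peripheral_ratio = 0.55`), giving bushy but
shallow peripheral subtrees.  The two regimes are essential: a single
self-similar rule pins the ratio of longest to median root–leaf path near
2, whereas the long-trunk monopodial architecture being emulated requires
roughly 3 or more.  Branches stop below `min_radius = 5.5 µm`; steps
whose lateral falls below that threshold create no branch point, so the
returned tree is already contracted.  Defaults were calibrated once
against the magnitudes of week-old rabbit lungs — about 300 segments per
tree of which roughly half carry a lumen above the detection limit — and
frozen.

**Ground truth.**  lumen = 2·radius; wall = 2 µm + 0.08·lumen; layer
count = round(1 + 9·lumen/(lumen + 150)), a saturating curve from 1 layer
in precapillary vessels to ~10 in the main trunk.

**Planted effects.**  The treated group's ground truth is altered on
lumen quantiles, never on fitted clusters, so recovery through the
pipeline is a genuine test: lumen × (1 − 0.2) below the 33rd percentile,
wall × (1 + 0.15) above the 67th, +0.6 layers below the 33rd (defaults;
all configurable).  Quantiles are computed among segments whose baseline
lumen is at least the detection limit — group differences are statements
about observable vessels, and with roughly half of all segments below the
imaging limit a quantile over everything would plant the entire effect
inside the censored zone.

**Measurement model.**  Segments below the 17 µm detection limit are
never observed.  Visibility is judged on the *baseline* (pre-effect)
lumen: which segments enter the tree is decided by tomographic
detectability of the anatomy, while the fine-resolution microscopy
measurements reflect the altered lumen.  (Censoring the altered lumen
instead truncates both groups at the same boundary and cancels the
planted shift — and contradicts the emulated setting, where the treated
group's trees were not smaller.)  Each visible segment is observed 1–3
times with multiplicative lognormal noise (cv 0.05) on `A` and `B`;
layer counts are recorded for ~72 % of observations and are off by one
with probability 0.2, reflecting genuine counting ambiguity.

**What passing tests do not show.**  The generator's wall is affine in
lumen up to noise and its clusters are artifacts of tree geometry, not of
vascular biology; real data have biological scatter, spatially correlated
measurement error, registration failures and observer drift that the
model omits.  Recovery results therefore validate the *machinery*
(classification, selection, stratified testing), not field performance.

## Numerical choices and degenerate inputs

* Seeds: every stochastic entry point takes an explicit seed; cohort
  generation draws independent per-animal substreams from the cohort
  seed.
* Davies–Bouldin with fewer than two non-empty groups is an error naming
  the scheme; coincident centroids give +∞ and such schemes can never be
  selected.
* `fit_gmm` requires `n > k·d`; `select_k` skips failing candidate
  counts and errors only when all fail.
* Effect strength is only defined for `p` strictly inside (0, 1);
  `p ≥ 0.05` rows carry no effect value, mirroring how such workflows
  report effects only for significant shifts.
* Half-up two-decimal rounding is applied only at the reporting layer.

## Known limitations

* Positional orderings inherit every defect of the input skeleton:
  missing side branches merge segments and deflate orders — the package
  reproduces, rather than repairs, this failure mode.
* Group comparisons pool segments across animals within a group
  (n = 2 animals per group in the emulated design); p-values quantify
  segment-level, not animal-level, evidence.
* The Davies–Bouldin comparison across schemes with very different group
  counts is descriptive; the index is not penalized for the number of
  groups beyond its built-in averaging.
* The problem sizes used in tests and the acceptance script (trees of a
  few hundred segments, 20 replicate cohorts) are the package's chosen
  study scale for a desk-size validation of a pilot design.
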