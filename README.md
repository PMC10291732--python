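# pulmotree

Location-specific morphometry of monopodial pulmonary vascular trees.

## The problem

Rodent and rabbit lungs branch *monopodially*: one long central artery
tapers gradually while shedding much thinner lateral branches.  When two
experimental groups are compared (for example a hyperoxia model of
bronchopulmonary dysplasia against normoxic controls), pathology that is
confined to one compartment of this heterogeneous tree — narrowed
precapillary lumina, thickened proximal walls — is easily diluted to
invisibility in a whole-lung comparison.  The remedy is to first classify
every vessel segment into groups that are homogeneous in morphology and
function, and then compare the groups between cohorts *per group*.

`pulmotree` implements that workflow for skeletonized vessel trees
(GraphML or CSV edge lists; per-segment length and mean radius in µm)
with per-segment morphometric measurements (lumen diameter `A`, outer
diameter `B`, smooth-muscle layer count; wall thickness is `(B − A)/2`):

* **vessel_graph** — validated rooted-tree model, degree-2 contraction,
  artificial-root merging of damaged samples, GraphML/CSV I/O;
* **ordering** — generations, Horsfield orders, Strahler orders and
  diameter-aware fractal generations;
* **morphometry** — averaging of repeated cross-section observations
  into per-segment feature tables;
* **clustering** — Gaussian-mixture classification of the (lumen, wall)
  plane, per sample or pooled, with the component count chosen by BIC
  (`BIC = 2 log L − m ln n`, larger is better);
* **evaluation** — Davies–Bouldin scoring
  `DB = (1/k)·Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ` of every scheme in morphometric
  feature space and selection of the best (lowest) scheme;
* **group_stats** — two-sided Mann–Whitney U tests per feature, globally
  and per cluster, with effect strength `r = |Φ⁻¹(p/2)|/√N` binned as
  weak/medium/strong;
* **synthetic_data** — a calibrated generator of monopodial trees,
  ground-truth morphometry, a detection-limit/noise measurement model and
  two-group cohorts with effects planted on ground-truth lumen quantiles;
* **pipeline** / `pulmotree` CLI — simulate → classify → evaluate →
  select → compare, with CSV/JSON/Markdown outputs.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from pulmotree import RunConfig, CohortConfig, run_pipeline
from pulmotree.evaluation import evaluation_table
from pulmotree.group_stats import comparison_table

rc = RunConfig(mode="synthetic", cohort=CohortConfig(seed=1),
               seed=1, k_range=(1, 6), outdir="run1")
res = run_pipeline(rc)
print(evaluation_table(res.evaluations).fillna("").to_string(index=False))
comp = comparison_table(res.comparisons).round({"p": 4, "effect_r": 3})
print(comp[comp.feature == "lumen"].fillna("").to_string(index=False))
```

prints the scheme-comparison table of a synthetic 2-vs-2 cohort
(per-sample and global Davies–Bouldin scores; lower is better):

```
       scheme groups  NOX1   NOX2   HYX1   HYX2  global
  generations  49–50  92.8  67.05  78.26  65.31   75.86
       orders  49–50  1.38   1.36   1.91   0.95    1.40
     strahler      5   0.7   0.75   0.86   0.69    0.75
      fractal      6  2.66   2.44   2.46   3.31    2.72
    gmm_local    3–4  0.61    0.6   0.57   0.58    0.59
gmm_global_k5      5                               0.55
```

Generations produce ~50 nearly singleton groups on a monopodial tree and
score terribly; Strahler orders collapse the trunk into few, fairly
homogeneous groups; the pooled Gaussian mixture wins and is used for the
group comparison.  Its lumen rows:

```
feature stratum  n_A  n_B       U      p stars effect_r category
  lumen  global  365  343 56243.0 0.0195     *    0.088     none
  lumen       1   20   20   199.0 0.9893
  lumen       2   52   41   891.0 0.1769
  lumen       3   79   80  2743.0 0.1513
  lumen       4   93  148  4609.0 0.0000    **    0.278     weak
  lumen       5  121   54  1223.0 0.0000    **    0.499   medium
```

The cohort was generated with a 20 % lumen reduction planted in the
treated group's smallest observable vessels (below the 33rd lumen
percentile).  Globally the shift is barely visible (p ≈ 0.02, negligible
effect); stratified by cluster it is absent from the large-vessel
clusters and concentrates, with a far stronger effect, in the
smallest-vessel clusters — exactly the localization the workflow exists
to provide.

The same run from the shell:

```sh
pulmotree run-all --seed 1 --outdir run1
```

writes `scheme_evaluation.csv`, `assignments.csv`, `comparison.csv`,
`manifest.json`, `report.md` and `run.log` into `run1/`, plus the
generated trees and observation tables under `run1/data/` so the run can
be repeated from files (`pulmotree simulate`, `classify`, `evaluate`,
`compare` expose the individual stages).

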