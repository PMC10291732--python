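"""End-to-end analysis pipeline: simulate/load -> classify -> evaluate ->
select -> compare, with all tables written to an output directory.

The pipeline reproduces the analysis design of a two-group vascular
morphometry study: every classification scheme (positional orderings and
Gaussian-mixture clusterings, local and global) is scored with the
Davies-Bouldin index in lumen/wall feature space; the best-scoring scheme
is selected; and the experimental groups are then compared feature by
feature, globally and within each group of the selected scheme.

Outputs (all plain text) in the run directory:

* ``data/<sample>.graphml`` and ``data/<sample>_observations.csv`` — the
  input data (exported in synthetic mode so a run can be repeated from
  files),
* ``scheme_evaluation.csv`` — the scheme-comparison table,
* ``assignments.csv`` — segment-to-group labels of the selected scheme,
* ``comparison.csv`` — the stratified group-comparison table,
* ``manifest.json`` — config, seed and library versions,
* ``report.md`` — human-readable summary rendered from the CSVs,
* ``run.log`` — every exclusion (artificial, unmeasured, empty strata).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import DEFAULT_SEED, GMMFit, gmm_classify
from .evaluation import (
    SchemeEvaluation,
    evaluate_scheme,
    evaluation_table,
    select_best_scheme,
)
from .group_stats import ComparisonResult, compare_groups, comparison_table
from .morphometry import aggregate_observations, feature_matrix, read_observations
from .ordering import (
    ClassificationResult,
    fractal_generations,
    generations,
    horsfield_orders,
    strahler_orders,
)
from .synthetic_data import CohortConfig, generate_cohort
from .vessel_graph import VesselTree, contract_degree2, read_tree, write_tree

__all__ = ["RunConfig", "SampleInput", "RunResult", "run_pipeline", "render_report"]

log = logging.getLogger("pulmotree")

ALL_SCHEMES = ("generations", "orders", "strahler", "fractal", "gmm_local", "gmm_global")


@dataclass(frozen=True)
class SampleInput:
    """One sample in files mode: where its tree and observations live."""

    sample_id: str
    group: str
    tree_path: str
    observations_path: str
    tree_format: str = "graphml"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # or "files"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    files: list[SampleInput] = field(default_factory=list)
    schemes: tuple[str, ...] = ALL_SCHEMES
    k_range: tuple[int, int] = (1, 6)
    gmm_k: int | None = None  # force a fixed component count
    near_tie_bic: float = 10.0  # report extra global-GMM k within this BIC margin
    fractal_alpha: float = 0.8
    db_features: tuple[str, ...] = ("lumen", "wall")
    stats_features: tuple[str, ...] = ("lumen", "wall", "layers")
    bh_correct: bool = False
    seed: int = DEFAULT_SEED
    outdir: str = "pulmotree_run"

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one scheme is required")
        unknown = set(self.schemes) - set(ALL_SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes {sorted(unknown)}")


@dataclass
class RunResult:
    """In-memory bundle of everything a run produced."""

    samples: dict[str, VesselTree]
    groups: dict[str, str]
    tables: dict[str, pd.DataFrame]
    classifications: dict[str, dict[str, ClassificationResult]]
    gmm_fits: dict[str, dict[str, GMMFit]]
    evaluations: list[SchemeEvaluation]
    best_scheme: SchemeEvaluation
    comparisons: list[ComparisonResult]
    outdir: Path


def _labelled_features(
    table: pd.DataFrame,
    classification: ClassificationResult,
    features,
    sample_id: str,
) -> tuple[np.ndarray, np.ndarray] | None:
    """(X, per-row labels) for the measured segments a scheme labelled."""
    ids, X = feature_matrix(table, features)
    labels = classification.measured_labels()
    mask = np.array([int(i) in labels for i in ids])
    n_drop = int((~mask).sum())
    if n_drop:
        log.info(
            "%s/%s: %d measured segments without a label excluded from scoring",
            sample_id, classification.scheme, n_drop,
        )
    if not mask.any():
        return None
    y = np.array([labels[int(i)] for i in ids[mask]])
    return X[mask], y


def _load_samples(config: RunConfig):
    trees: dict[str, VesselTree] = {}
    groups: dict[str, str] = {}
    observations: dict[str, pd.DataFrame] = {}
    if config.mode == "synthetic":
        for s in generate_cohort(config.cohort):
            trees[s.sample_id] = s.tree
            groups[s.sample_id] = s.group
            observations[s.sample_id] = s.observations
    elif config.mode == "files":
        if not config.files:
            raise ValueError("files mode requires at least one SampleInput")
        for f in config.files:
            try:
                tree = read_tree(f.tree_path, format=f.tree_format)
            except Exception as exc:
                raise RuntimeError(
                    f"sample {f.sample_id}: cannot read tree {f.tree_path}: {exc}"
                ) from exc
            try:
                obs = read_observations(f.observations_path)
            except Exception as exc:
                raise RuntimeError(
                    f"sample {f.sample_id}: cannot read observations "
                    f"{f.observations_path}: {exc}"
                ) from exc
            trees[f.sample_id] = contract_degree2(tree)
            groups[f.sample_id] = f.group
            observations[f.sample_id] = obs
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return trees, groups, observations


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "data").mkdir(exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> RunResult:
    trees, groups, observations = _load_samples(config)

    tables: dict[str, pd.DataFrame] = {}
    for sample_id, tree in trees.items():
        n_art = sum(1 for s in tree.segments.values() if s.is_artificial)
        if n_art:
            log.info("%s: %d artificial segments excluded from measurement", sample_id, n_art)
        obs = observations[sample_id]
        table = aggregate_observations(obs)
        n_unmeasured = len(tree.segments) - n_art - len(table)
        log.info(
            "%s: %d of %d real segments measured (%d unmeasured)",
            sample_id, len(table), len(tree.segments) - n_art, n_unmeasured,
        )
        tables[sample_id] = table
        write_tree(tree, outdir / "data" / f"{sample_id}.graphml", "graphml")
        obs.to_csv(outdir / "data" / f"{sample_id}_observations.csv", index=False)

    # -- classification -----------------------------------------------------
    positional = {
        "generations": generations,
        "orders": horsfield_orders,
        "strahler": strahler_orders,
        "fractal": lambda t: fractal_generations(t, alpha=config.fractal_alpha),
    }
    classifications: dict[str, dict[str, ClassificationResult]] = {}
    for scheme in config.schemes:
        if scheme in positional:
            classifications[scheme] = {
                sid: positional[scheme](tree) for sid, tree in trees.items()
            }

    gmm_fits: dict[str, dict[str, GMMFit]] = {}
    krange = range(config.k_range[0], config.k_range[1] + 1)
    if "gmm_local" in config.schemes:
        res, fits = gmm_classify(
            tables, mode="local", k_range=krange, seed=config.seed,
            features=config.db_features, k=config.gmm_k,
        )
        classifications["gmm_local"] = res
        gmm_fits["gmm_local"] = fits
    global_variants: dict[str, dict[str, ClassificationResult]] = {}
    if "gmm_global" in config.schemes:
        res, fits = gmm_classify(
            tables, mode="global", k_range=krange, seed=config.seed,
            features=config.db_features, k=config.gmm_k,
        )
        best_fit = fits["global"]
        global_variants[f"gmm_global_k{best_fit.k}"] = res
        gmm_fits["gmm_global"] = fits
        # Near-ties in BIC are also worth scoring with the validity index,
        # as when the pooled BIC narrowly prefers one more component than
        # every per-sample fit does.
        if config.gmm_k is None:
            candidates = [f for key, f in fits.items() if key.startswith("global_k")]
            for cand in candidates:
                if cand.k != best_fit.k and best_fit.bic - cand.bic <= config.near_tie_bic:
                    res_k, _ = gmm_classify(
                        tables, mode="global", k_range=krange, seed=config.seed,
                        features=config.db_features, k=cand.k,
                    )
                    global_variants[f"gmm_global_k{cand.k}"] = res_k
                    log.info(
                        "global GMM: k=%d within %.1f BIC of k=%d; scored as well",
                        cand.k, config.near_tie_bic, best_fit.k,
                    )

    # -- evaluation ---------------------------------------------------------
    evaluations: list[SchemeEvaluation] = []
    eval_assignments: dict[str, dict[str, ClassificationResult]] = {}
    for scheme, per_sample_cls in classifications.items():
        if scheme.startswith("gmm_global"):
            continue
        per_sample = {}
        for sid, cls in per_sample_cls.items():
            lf = _labelled_features(tables[sid], cls, config.db_features, sid)
            if lf is not None and len(np.unique(lf[1])) >= 2:
                per_sample[sid] = lf
            else:
                log.warning("%s/%s: fewer than 2 usable groups; sample skipped", sid, scheme)
        if not per_sample:
            log.warning("%s: no usable sample; scheme skipped", scheme)
            continue
        evaluations.append(evaluate_scheme(scheme, per_sample, pooled=False))
        eval_assignments[scheme] = per_sample_cls
    for scheme, per_sample_cls in global_variants.items():
        per_sample = {
            sid: lf
            for sid, cls in per_sample_cls.items()
            if (lf := _labelled_features(tables[sid], cls, config.db_features, sid))
            is not None
        }
        evaluations.append(evaluate_scheme(scheme, per_sample, pooled=True))
        eval_assignments[scheme] = per_sample_cls

    if not evaluations:
        raise RuntimeError("no scheme could be evaluated")
    best = select_best_scheme(evaluations)
    log.info("selected scheme: %s (global DB %.4f)", best.scheme, best.global_db)

    sample_ids = list(trees)
    eval_df = evaluation_table(evaluations, sample_ids=sample_ids)
    eval_df.to_csv(outdir / "scheme_evaluation.csv", index=False)

    best_assignments = eval_assignments[best.scheme]
    rows = []
    for sid, cls in best_assignments.items():
        for seg_id in sorted(cls.labels):
            rows.append({"sample_id": sid, "segment_id": seg_id, "cluster": cls.labels[seg_id]})
    pd.DataFrame(rows).to_csv(outdir / "assignments.csv", index=False)

    # -- group comparison ---------------------------------------------------
    comparisons: list[ComparisonResult] = []
    if len(set(groups.values())) == 2:
        comparisons = compare_groups(
            tables, best_assignments, groups,
            features=config.stats_features, bh_correct=config.bh_correct,
        )
        for r in comparisons:
            if r.p is None:
                log.warning(
                    "comparison %s/%s: stratum empty in one group (n_A=%d, n_B=%d)",
                    r.feature, r.stratum, r.n_a, r.n_b,
                )
        comparison_table(comparisons).to_csv(outdir / "comparison.csv", index=False)
    else:
        log.warning("group comparison skipped: need exactly 2 groups")

    manifest = {
        "pulmotree_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "samples": {sid: groups[sid] for sid in sample_ids},
        "selected_scheme": best.scheme,
        "versions": _library_versions(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    render_report(outdir)
    return RunResult(
        samples=trees,
        groups=groups,
        tables=tables,
        classifications={**classifications, **global_variants},
        gmm_fits=gmm_fits,
        evaluations=evaluations,
        best_scheme=best,
        comparisons=comparisons,
        outdir=outdir,
    )


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }


def render_report(outdir: str | Path) -> str:
    """Render report.md from the CSV tables of a finished run.

    Every number is taken verbatim from a CSV cell; nothing is recomputed.
    Returns the markdown text (also written to ``report.md``).
    """
    outdir = Path(outdir)
    eval_path = outdir / "scheme_evaluation.csv"
    if not eval_path.exists():
        raise FileNotFoundError(f"no run bundle at {outdir} (missing {eval_path.name})")
    lines = ["# pulmotree run report", ""]

    eval_df = pd.read_csv(eval_path)
    lines += ["## Scheme evaluation (Davies–Bouldin index; lower is better)", ""]
    lines += _md_table(eval_df)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        lines += ["", f"Selected scheme: **{manifest['selected_scheme']}**", ""]

    comp_path = outdir / "comparison.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        lines += ["## Group comparison", ""]
        if comp.empty:
            lines += ["No comparisons were computed (empty comparison table).", ""]
        else:
            comp = comp.copy()
            for col in ("U", "p", "effect_r"):
                comp[col] = comp[col].map(
                    lambda v: "" if pd.isna(v) else f"{v:.4g}"
                )
            lines += _md_table(comp.fillna(""))
            lines += ["", "Significance: *p < 0.05 and **p < 0.01", ""]
    else:
        lines += ["## Group comparison", "", "Comparison section omitted: no two-group comparison in this run.", ""]

    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text


def _md_table(df: pd.DataFrame) -> list[str]:
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    rule = "|" + "|".join(" --- " for _ in df.columns) + "|"
    rows = [
        "| " + " | ".join("" if (isinstance(v, float) and np.isnan(v)) else str(v) for v in rec) + " |"
        for rec in df.itertuples(index=False)
    ]
    return [header, rule, *rows]
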