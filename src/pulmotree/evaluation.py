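"""Davies-Bouldin scoring of vessel groupings and best-scheme selection.

Every classification scheme — positional (generations, orders, Strahler,
fractal) or morphometric (Gaussian mixture) — partitions the measured
segments into groups.  The Davies-Bouldin index scores how homogeneous and
well separated those groups are in morphometric feature space (the same
unstandardized lumen/wall matrix the mixture model consumes):

    DB = (1/k) * sum_i max_{j != i} (S_i + S_j) / M_ij

with S_i the mean Euclidean distance of group-i rows to their centroid and
M_ij the distance between centroids.  Lower is better; coincident
centroids yield +inf.

Schemes computed per sample are summarized by the arithmetic mean of the
per-sample scores ("global average"); schemes fitted on the pooled data of
all samples are scored once on the pooled feature matrix.  The scheme with
the lowest global score wins, ties resolved toward fewer groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "SchemeEvaluation",
    "davies_bouldin",
    "evaluate_scheme",
    "select_best_scheme",
    "global_average",
    "round2",
    "evaluation_table",
]


def round2(x: float) -> float:
    """Round to 2 decimals with half-up ties, as printed report tables do.

    Plain binary float rounding turns e.g. a mean of 2.245 into 2.24; the
    half-up rule on the shortest decimal representation gives 2.25.
    """
    if not np.isfinite(x):
        return float(x)
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def davies_bouldin(features: np.ndarray, labels) -> float:
    """Davies-Bouldin index of a labelled feature matrix (lower = better).

    ``labels`` is one group label per row.  Uses Euclidean within-group
    scatter (mean distance to centroid) and Euclidean centroid separation.
    Returns +inf when two group centroids coincide.  Raises ``ValueError``
    with fewer than two non-empty groups.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(list(labels))
    if len(y) != X.shape[0]:
        raise ValueError("one label per feature row required")
    groups = np.unique(y)
    k = len(groups)
    if k < 2:
        raise ValueError(
            f"Davies-Bouldin requires >= 2 non-empty groups (got {k})"
        )
    centroids = np.vstack([X[y == g].mean(axis=0) for g in groups])
    scatter = np.array(
        [np.linalg.norm(X[y == g] - centroids[i], axis=1).mean() for i, g in enumerate(groups)]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    off_diag = ~np.eye(k, dtype=bool)
    if np.any(sep[off_diag] == 0.0):
        return float("inf")
    np.fill_diagonal(sep, 1.0)  # diagonal is masked below; avoid 0/0
    ratio = (scatter[:, None] + scatter[None, :]) / sep
    ratio[~off_diag] = -np.inf
    return float(np.mean(ratio.max(axis=1)))


def global_average(per_sample_scores) -> float:
    """The cross-sample summary: arithmetic mean of per-sample DB scores."""
    scores = [float(s) for s in per_sample_scores]
    if not scores:
        raise ValueError("no per-sample scores")
    return float(np.mean(scores))


@dataclass
class SchemeEvaluation:
    """One row of the scheme-comparison table."""

    scheme: str
    n_groups_range: tuple[int, int]
    per_sample_db: dict[str, float] = field(default_factory=dict)
    global_db: float = float("nan")

    @property
    def groups_label(self) -> str:
        lo, hi = self.n_groups_range
        return str(lo) if lo == hi else f"{lo}–{hi}"


def evaluate_scheme(
    scheme: str,
    per_sample: dict[str, tuple[np.ndarray, np.ndarray]],
    pooled: bool = False,
) -> SchemeEvaluation:
    """Score one scheme across samples.

    ``per_sample`` maps sample_id to (feature matrix, per-row labels),
    restricted to measured, non-artificial segments; groups without any
    measured member simply never appear.  For per-sample schemes
    (``pooled=False``) the DB index is computed per sample and the global
    score is their arithmetic mean.  For schemes fitted on pooled data
    (``pooled=True``) the rows of all samples are concatenated and scored
    once; no per-sample scores are reported.
    """
    if not per_sample:
        raise ValueError("no samples to evaluate")
    counts = [len(np.unique(np.asarray(list(labels)))) for _, labels in per_sample.values()]
    if pooled:
        X = np.vstack([np.asarray(f, dtype=float) for f, _ in per_sample.values()])
        y = np.concatenate([np.asarray(list(l)) for _, l in per_sample.values()])
        n_groups = len(np.unique(y))
        return SchemeEvaluation(
            scheme=scheme,
            n_groups_range=(n_groups, n_groups),
            per_sample_db={},
            global_db=davies_bouldin(X, y),
        )
    per_db = {
        sample_id: davies_bouldin(f, l) for sample_id, (f, l) in per_sample.items()
    }
    return SchemeEvaluation(
        scheme=scheme,
        n_groups_range=(min(counts), max(counts)),
        per_sample_db=per_db,
        global_db=global_average(per_db.values()),
    )


def select_best_scheme(evaluations) -> SchemeEvaluation:
    """Pick the scheme with minimal global DB score.

    Ties are broken toward fewer groups (the simpler partition), then
    lexicographically by scheme name.  Raises if every score is infinite.
    """
    evals = list(evaluations)
    finite = [e for e in evals if np.isfinite(e.global_db)]
    if not finite:
        raise ValueError("no evaluation has a finite global Davies-Bouldin score")
    return min(
        finite, key=lambda e: (e.global_db, e.n_groups_range[1], e.n_groups_range[0], e.scheme)
    )


def evaluation_table(
    evaluations, sample_ids: list[str] | None = None, rounded: bool = True
) -> pd.DataFrame:
    """Render evaluations as the scheme-comparison table (one scheme per row,
    per-sample columns plus a Global column)."""
    evals = list(evaluations)
    if sample_ids is None:
        seen: list[str] = []
        for e in evals:
            for s in e.per_sample_db:
                if s not in seen:
                    seen.append(s)
        sample_ids = seen
    fmt = round2 if rounded else float
    rows = []
    for e in evals:
        row: dict[str, object] = {"scheme": e.scheme, "groups": e.groups_label}
        for s in sample_ids:
            row[s] = fmt(e.per_sample_db[s]) if s in e.per_sample_db else float("nan")
        row["global"] = fmt(e.global_db)
        rows.append(row)
    return pd.DataFrame(rows, columns=["scheme", "groups", *sample_ids, "global"])
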