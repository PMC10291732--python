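"""Morphometry-based vessel classification with Gaussian mixture models.

Vessel cross-section features (lumen diameter and wall thickness, in
micrometres, used raw and unstandardized) are modelled as a mixture of
full-covariance multivariate Gaussians fitted by expectation-maximization.
The number of components is chosen by the Bayesian information criterion in
the larger-is-better convention

    BIC(k) = 2 * log L - m * ln(n),     m = (k - 1) + k*d + k*d*(d+1)/2,

so that among candidate component counts the highest BIC wins.  All
candidate fits are kept so near-ties can additionally be compared with a
cluster-validity index (see :mod:`pulmotree.evaluation`).

Two classification modes mirror how a multi-animal study is analysed:
``local`` fits one mixture per sample; ``global`` pools the feature rows of
all samples, fits once, and maps the shared components back onto each
sample's segments.  Components are renumbered so that component 1 has the
largest mean lumen ("large vessels"), the last the smallest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .morphometry import feature_matrix
from .ordering import ClassificationResult

__all__ = [
    "GMMFit",
    "CovarianceCollapseError",
    "fit_gmm",
    "select_k",
    "gmm_classify",
    "n_free_parameters",
    "loglik_trace",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20230626
_EM_TOL = 1e-8
_EM_MAX_ITER = 500
_EM_N_INIT = 10
_COLLAPSE_DET = 1e-12


class CovarianceCollapseError(RuntimeError):
    """A mixture component collapsed onto degenerate data."""


def n_free_parameters(k: int, d: int) -> int:
    """Free parameters of a k-component, d-dimensional full-covariance GMM."""
    return (k - 1) + k * d + k * d * (d + 1) // 2


@dataclass
class GMMFit:
    """A converged Gaussian mixture fit on one feature matrix."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    log_likelihood: float
    bic: float
    n: int
    assignments: dict[int, int] = field(default_factory=dict)
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Maximum-responsibility component (1..k) for each row of X."""
        return self._gm.predict(np.asarray(X, dtype=float)) + 1

    # the fitted sklearn object, kept for prediction; not part of equality
    _gm: GaussianMixture | None = None


def _variance_floor(X: np.ndarray) -> float:
    v = float(np.mean(np.var(X, axis=0)))
    return 1e-6 * v if v > 0 else 1e-6


def fit_gmm(
    features: np.ndarray,
    k: int,
    seed: int = DEFAULT_SEED,
    segment_ids: np.ndarray | None = None,
    variance_floor: bool = False,
) -> GMMFit:
    """Fit a k-component full-covariance Gaussian mixture by EM.

    EM runs to convergence (mean log-likelihood change below 1e-8 or 500
    iterations) from the best of 10 k-means++-style initializations drawn
    from ``seed``.  ``variance_floor=True`` adds a small ridge
    (1e-6 of the mean feature variance) to every covariance diagonal, which
    rescues datasets with exactly duplicated rows.

    Raises :class:`CovarianceCollapseError` when a component covariance
    degenerates (determinant below 1e-12 without the floor), and
    ``ValueError`` when n <= k * d.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if n <= k * d:
        raise ValueError(f"need n > k*d rows to fit k={k} in {d}-D (got n={n})")
    # without the opt-in floor, keep only a vanishing numerical ridge so the
    # Cholesky inside EM stays feasible; genuine collapse is still detected
    # by the determinant check below
    reg = _variance_floor(X) if variance_floor else 1e-4 * _variance_floor(X)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=_EM_TOL,
        max_iter=_EM_MAX_ITER,
        n_init=_EM_N_INIT,
        init_params="k-means++",
        reg_covar=reg,
        random_state=np.random.RandomState(seed % (2**32)),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        try:
            gm.fit(X)
        except ValueError as exc:  # sklearn's ill-defined covariance error
            raise CovarianceCollapseError(
                "mixture covariance collapsed during EM; re-run with "
                "variance_floor=True to regularize degenerate data"
            ) from exc
    dets = np.linalg.det(gm.covariances_)
    if not variance_floor and np.any(dets < _COLLAPSE_DET):
        raise CovarianceCollapseError(
            f"component covariance determinant {dets.min():.3g} < {_COLLAPSE_DET}; "
            "re-run with variance_floor=True"
        )
    ll = float(gm.score(X) * n)
    bic = 2.0 * ll - n_free_parameters(k, d) * np.log(n)
    hard = gm.predict(X) + 1
    if segment_ids is None:
        assignments = {int(i): int(c) for i, c in enumerate(hard)}
    else:
        assignments = {int(s): int(c) for s, c in zip(segment_ids, hard)}
    return GMMFit(
        k=k,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        log_likelihood=ll,
        bic=float(bic),
        n=n,
        assignments=assignments,
        converged=bool(gm.converged_),
        _gm=gm,
    )


def loglik_trace(
    features: np.ndarray, k: int, seed: int = DEFAULT_SEED, n_iter: int = 50
) -> np.ndarray:
    """Total log-likelihood after each EM iteration from one initialization.

    Steps a single-initialization EM one iteration at a time (warm start)
    and records the total log-likelihood; EM guarantees the trace is
    non-decreasing.  Used to verify the monotonicity property.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=0.0,
        max_iter=1,
        n_init=1,
        init_params="k-means++",
        warm_start=True,
        reg_covar=1e-10,
        random_state=np.random.RandomState(seed % (2**32)),
    )
    trace = []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for _ in range(n_iter):
            gm.fit(X)
            trace.append(gm.score(X) * n)
    return np.asarray(trace)


def select_k(
    features: np.ndarray,
    k_range=range(1, 7),
    seed: int = DEFAULT_SEED,
    segment_ids: np.ndarray | None = None,
    variance_floor: bool = False,
) -> tuple[int, list[GMMFit]]:
    """Fit every candidate component count and pick the best by BIC.

    Returns (best_k, fits); the full fit list is kept so near-ties in BIC
    can be re-examined with a cluster-validity index, as is good practice
    when two component counts score almost equally.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    fits: list[GMMFit] = []
    errors: list[str] = []
    for k in ks:
        try:
            fits.append(
                fit_gmm(features, k, seed=seed, segment_ids=segment_ids,
                        variance_floor=variance_floor)
            )
        except (ValueError, CovarianceCollapseError) as exc:
            errors.append(f"k={k}: {exc}")
    if not fits:
        raise RuntimeError("all mixture fits failed: " + "; ".join(errors))
    best = max(fits, key=lambda f: f.bic)
    return best.k, fits


def _relabel_largest_lumen_first(fit: GMMFit, lumen_col: int = 0) -> dict[int, int]:
    """Permutation old component -> new label with 1 = largest mean lumen."""
    order = np.argsort(-fit.means[:, lumen_col], kind="stable")
    return {int(old) + 1: int(new) + 1 for new, old in enumerate(order)}


def gmm_classify(
    tables: dict[str, pd.DataFrame],
    mode: str = "global",
    k_range=range(1, 7),
    seed: int = DEFAULT_SEED,
    features=("lumen", "wall"),
    k: int | None = None,
    variance_floor: bool = False,
) -> tuple[dict[str, ClassificationResult], dict[str, GMMFit]]:
    """Classify measured segments of every sample by Gaussian mixture.

    ``tables`` maps sample_id to a MeasurementTable.  In ``local`` mode one
    mixture is fitted per sample; in ``global`` mode all samples' feature
    rows are pooled, one mixture is fitted, and its components are mapped
    back to each sample's segments.  ``k`` forces a fixed component count;
    otherwise the count is selected by BIC over ``k_range``.  Component
    labels are renumbered so label 1 is the component with the largest mean
    lumen.

    Returns (per-sample ClassificationResult, fits keyed by sample_id, or
    by "global" for the pooled fit).
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    if not tables:
        raise ValueError("no samples given")
    lumen_col = list(features).index("lumen") if "lumen" in features else 0
    krange = [k] if k is not None else k_range

    results: dict[str, ClassificationResult] = {}
    fits: dict[str, GMMFit] = {}
    if mode == "local":
        for sample_id, table in tables.items():
            ids, X = feature_matrix(table, features)
            best_k, all_fits = select_k(
                X, krange, seed=seed, segment_ids=ids, variance_floor=variance_floor
            )
            fit = next(f for f in all_fits if f.k == best_k)
            perm = _relabel_largest_lumen_first(fit, lumen_col)
            labels = {sid: perm[c] for sid, c in fit.assignments.items()}
            results[sample_id] = ClassificationResult(
                "gmm_local",
                labels,
                parameters={"k": best_k, "bic": fit.bic, "sample_id": sample_id},
            )
            fits[sample_id] = fit
    else:
        all_ids: list[tuple[str, int]] = []
        blocks = []
        for sample_id, table in tables.items():
            ids, X = feature_matrix(table, features)
            all_ids.extend((sample_id, int(i)) for i in ids)
            blocks.append(X)
        pooled = np.vstack(blocks)
        best_k, all_fits = select_k(
            pooled, krange, seed=seed, variance_floor=variance_floor
        )
        fit = next(f for f in all_fits if f.k == best_k)
        perm = _relabel_largest_lumen_first(fit, lumen_col)
        hard = [perm[c] for c in (fit.assignments[i] for i in range(fit.n))]
        per_sample: dict[str, dict[int, int]] = {s: {} for s in tables}
        for (sample_id, seg_id), label in zip(all_ids, hard):
            per_sample[sample_id][seg_id] = label
        for sample_id in tables:
            results[sample_id] = ClassificationResult(
                "gmm_global",
                per_sample[sample_id],
                parameters={"k": best_k, "bic": fit.bic, "pooled_n": fit.n},
            )
        fits["global"] = fit
        for f in all_fits:  # keep candidates so callers can examine BIC near-ties
            fits[f"global_k{f.k}"] = f
    return results, fits
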