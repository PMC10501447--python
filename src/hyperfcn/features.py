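"""Feature extraction and two-stage (t-test -> LASSO) feature selection.

Connectivity matrices are symmetric, so only the strictly lower triangle is
vectorized (row-major: (1,0), (2,0), (2,1), ...).  Selection proceeds in a
fixed order: a per-feature two-sample t-test between the diagnostic groups
keeps features with p below a threshold, then an L1-regularised least-squares
regression (LASSO) of the class labels on the surviving features retains the
nonzero-weight support.  The LASSO never resurrects a feature the t-test
removed.

The LASSO objective is the sum-of-squares form

    (1/2) * sum_l (k_l - y_l^T w)^2 + lambda * ||w||_1

with labels k_l in {-1, +1} and no intercept.  scikit-learn's coordinate
descent minimises (1/(2n)) ||k - Y w||^2 + alpha ||w||_1, so lambda maps to
alpha = lambda / n; the mapping is applied internally and ``lambda`` is
always the sum-of-squares penalty above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso

from .fcn import SYMMETRY_TOL, ConnectivityMatrix


@dataclass
class FeatureVector:
    """Lower-triangle vectorization of one subject's connectivity matrix."""

    values: np.ndarray
    source_kind: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class SelectedFeatures:
    """Result of the two-stage selection.

    ``ttest_kept`` holds 0-based indices into the full feature vector;
    ``lasso_weights`` is aligned with ``ttest_kept``; ``lasso_support`` holds
    full-vector indices of the nonzero weights (a subset of ``ttest_kept``).
    """

    ttest_pvalues: np.ndarray
    ttest_kept: np.ndarray
    lasso_weights: np.ndarray
    lasso_support: np.ndarray
    p_threshold: float
    lam: float
    objective: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not set(self.lasso_support.tolist()) <= set(self.ttest_kept.tolist()):
            raise ValueError("LASSO support must be a subset of the t-test survivors")


def n_lower_triangle(n: int) -> int:
    """Number of strictly-lower-triangle cells of an n x n matrix."""
    return n * (n - 1) // 2


def lower_triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the fixed feature ordering (row-major, i > j)."""
    return np.tril_indices(n, k=-1)


def vectorize_lower_triangle(cm: ConnectivityMatrix | np.ndarray) -> FeatureVector | np.ndarray:
    """Extract the strictly-lower-triangle entries in the fixed order.

    Accepts either a :class:`ConnectivityMatrix` (returns a
    :class:`FeatureVector`) or a bare symmetric array (returns an array).
    """
    if isinstance(cm, ConnectivityMatrix):
        vec = cm.values[lower_triangle_indices(cm.n)]
        return FeatureVector(values=vec, source_kind=cm.kind, subject_id=cm.subject_id)
    m = np.asarray(cm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(m - m.T).max() > SYMMETRY_TOL:
        raise ValueError("matrix is not symmetric within tolerance")
    return m[lower_triangle_indices(m.shape[0])]


def devectorize_lower_triangle(values: np.ndarray, n: int) -> np.ndarray:
    """Rebuild the symmetric matrix (unit diagonal) from its feature vector."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != n_lower_triangle(n):
        raise ValueError(
            f"expected {n_lower_triangle(n)} values for n={n}, got {values.size}"
        )
    out = np.eye(n)
    rows, cols = lower_triangle_indices(n)
    out[rows, cols] = values
    out[cols, rows] = values
    return out


def feature_pair(index: int, n: int) -> tuple[int, int]:
    """Map a feature index to its (row, col) ROI/hyperedge pair (0-based, row > col)."""
    rows, cols = lower_triangle_indices(n)
    return int(rows[index]), int(cols[index])


def feature_names(n: int, prefix: str = "roi") -> list[str]:
    """1-based pair labels ("roi_i|roi_j", i > j) in the fixed feature order."""
    rows, cols = lower_triangle_indices(n)
    return [f"{prefix}_{i + 1}|{prefix}_{j + 1}" for i, j in zip(rows, cols)]


def ttest_filter(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float,
    equal_var: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sample t-test between the two diagnostic groups.

    Welch's unequal-variance variant by default (``equal_var=True`` pools).
    Returns (p-values, indices of features with p < p_threshold).  Features
    that are constant within both groups get p = 1 when the group means agree
    (no signal) and p = 0 when they differ (perfect separation).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be a subjects x d matrix aligned with labels")
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    a = X[y == classes[0]]
    b = X[y == classes[1]]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-feature edge cases
        result = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        pvalues = np.asarray(result.pvalue, dtype=float)
    degenerate = ~np.isfinite(pvalues)
    if degenerate.any():
        same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
        pvalues[degenerate & same_mean] = 1.0
        pvalues[degenerate & ~same_mean] = 0.0
    kept = np.flatnonzero(pvalues < p_threshold)
    return pvalues, kept


def lasso_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float) -> float:
    """Sum-of-squares LASSO objective (1/2)||y - Xw||^2 + lam*||w||_1."""
    resid = y - X @ w
    return 0.5 * float(resid @ resid) + lam * float(np.abs(w).sum())


def lasso_select(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """L1-regularised least-squares selection on (already standardized) features.

    Labels are the +/-1 class codes used as the regression target.  Returns
    (weights over the input features, support indices, objective value).
    An empty feature matrix yields an empty support with a warning rather
    than an error.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be a subjects x d matrix aligned with labels")
    n, d = X.shape
    if d == 0:
        warnings.warn("no features entered the LASSO stage; empty support", UserWarning)
        return np.zeros(0), np.zeros(0, dtype=int), lasso_objective(X, y, np.zeros(0), lam)
    if lam == 0:
        w, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        model = Lasso(
            alpha=lam / n, fit_intercept=False, tol=tol, max_iter=max_iter
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter at tiny tol
            model.fit(X, y)
        w = model.coef_.astype(float)
    support = np.flatnonzero(w != 0.0)
    return w, support, lasso_objective(X, y, w, lam)


def two_stage_select(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float,
    lam: float,
    equal_var: bool = False,
) -> SelectedFeatures:
    """t-test filter followed by LASSO on the survivors (the fixed order)."""
    pvalues, kept = ttest_filter(features, labels, p_threshold, equal_var=equal_var)
    X = np.asarray(features, dtype=float)
    w, support_local, objective = lasso_select(X[:, kept], labels, lam)
    return SelectedFeatures(
        ttest_pvalues=pvalues,
        ttest_kept=kept,
        lasso_weights=w,
        lasso_support=kept[support_local] if kept.size else np.zeros(0, dtype=int),
        p_threshold=p_threshold,
        lam=lam,
        objective=objective,
    )


def fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean/sd from training data; zero sd maps to 1 (no scaling)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def apply_scaler(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd
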