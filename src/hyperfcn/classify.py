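"""Linear-SVM classification, decision-score fusion and nested cross-validation.

Each connectivity view (low-order FCN, hypergraph high-order FCN, optionally
the correlation-of-correlations baseline) yields one feature matrix per
cohort.  A linear soft-margin SVM is trained per view on the features
surviving the two-stage selection; the FUSION method averages the two views'
signed decision scores with fixed weights 0.5/0.5 and thresholds at zero.

Generalisation is estimated with a nested stratified 10-fold protocol: the
outer loop holds out each fold once; the inner loop (a second stratified
10-fold over the outer-training set) picks the hyperparameter triple
(p, lambda, gamma) with the highest mean inner accuracy, ties resolved
towards the smallest p, then lambda, then gamma (the most parsimonious
model).  Every statistic — feature standardisation, t-test, LASSO, SVM — is
computed from training data only.

Labels: patients (ASD) are the positive class +1, controls (NC) are -1.
A fused or single-view score of exactly 0 predicts the control class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import features as ft

#: canonical method names and the views they read from
METHOD_VIEWS = {
    "C_LON": ("low_order",),
    "C_HON": ("corr_of_corr",),
    "H-C_HON": ("hypergraph_hon",),
    "FUSION": ("low_order", "hypergraph_hon"),
}

DEFAULT_METHODS = ("C_LON", "H-C_HON", "FUSION")

#: metrics whose denominator can vanish; reported as 0 and flagged then
_RATIO_METRICS = ("acc", "sen", "spe", "ppv", "npv", "f1")


@dataclass
class HyperparameterGrid:
    """Search grids for the three tuned hyperparameters.

    ``p_grid`` — t-test p-value thresholds, default 0.01..0.10 step 0.01;
    ``lambda_grid`` — LASSO penalties, default 0.1..0.9 step 0.1;
    ``gamma_grid`` — SVM soft-margin cost constants, default 2^-4..2^4.
    """

    p_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1, 11) * 0.01, 10)
    )
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1, 10) * 0.1, 10)
    )
    gamma_grid: np.ndarray = field(
        default_factory=lambda: 2.0 ** np.arange(-4, 5)
    )

    def __post_init__(self) -> None:
        for name in ("p_grid", "lambda_grid", "gamma_grid"):
            g = np.asarray(getattr(self, name), dtype=float).ravel()
            if g.size == 0:
                raise ValueError(f"{name} must be nonempty")
            if not (np.diff(g) > 0).all():
                raise ValueError(f"{name} must be sorted strictly ascending")
            setattr(self, name, g)


@dataclass
class MetricsReport:
    """Confusion counts and the derived scalar metrics.

    ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP),
    BAC = (SEN+SPE)/2, PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    F1 = harmonic mean of PPV and SEN.  A metric whose denominator is zero
    is reported as 0 and listed in ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    bac: float
    ppv: float
    npv: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "SEN": self.sen, "SPE": self.spe, "BAC": self.bac,
            "PPV": self.ppv, "NPV": self.npv, "F1": self.f1,
            "undefined": list(self.undefined),
        }


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Derive the seven evaluation metrics from confusion counts."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("at least one test subject is required")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total
    sen = ratio(tp, tp + fn, "SEN")
    spe = ratio(tn, tn + fp, "SPE")
    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    if ppv + sen == 0:
        undefined.append("F1")
        f1 = 0.0
    else:
        f1 = 2 * ppv * sen / (ppv + sen)
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        acc=acc, sen=sen, spe=spe, bac=(sen + spe) / 2,
        ppv=ppv, npv=npv, f1=f1, undefined=tuple(undefined),
    )


def train_linear_svm(features: np.ndarray, labels: np.ndarray, gamma: float) -> SVC:
    """Fit a linear soft-margin SVM with cost constant ``gamma``.

    ``gamma`` plays the role of the usual cost C: it trades margin width
    against training errors.  Returns the fitted classifier; use
    ``decision_function`` for signed margin scores.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a subjects x d feature matrix with at least 1 feature")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 training subjects per class")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    model = SVC(kernel="linear", C=gamma)
    model.fit(X, y)
    return model


def fuse_decision_scores(score_lon, score_hchon):
    """Fixed-weight fusion of two signed decision scores: 0.5*(s0 + s1)."""
    a = np.asarray(score_lon, dtype=float)
    b = np.asarray(score_hchon, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("decision scores must be finite")
    fused = 0.5 * (a + b)
    return float(fused) if fused.ndim == 0 else fused


def predict_from_scores(scores) -> np.ndarray:
    """+1 (patient) when the score is strictly positive, else -1 (control)."""
    return np.where(np.asarray(scores, dtype=float) > 0, 1, -1)


@dataclass
class ViewFoldResult:
    """Per-view outcome of one outer fold."""

    p_threshold: float
    lam: float
    gamma: float
    inner_accuracy: float
    support: np.ndarray          # full-feature-space indices of the final LASSO support
    weights: np.ndarray          # LASSO weights aligned with ``support``
    test_scores: np.ndarray


@dataclass
class FoldResult:
    index: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    views: dict[str, ViewFoldResult]
    scores: dict[str, np.ndarray]       # method -> fused/raw test scores
    predictions: dict[str, np.ndarray]  # method -> +/-1 predictions


@dataclass
class CVReport:
    """Full record of one nested cross-validation run."""

    seed: int
    methods: tuple[str, ...]
    views: tuple[str, ...]
    subject_ids: list[str]
    labels: np.ndarray                       # +/-1 per subject
    folds: list[FoldResult]
    metrics: dict[str, MetricsReport]
    selection_frequency: dict[str, np.ndarray]  # view -> per-feature fold counts
    n_features: dict[str, int]
    outer_folds: int
    inner_folds: int
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "methods": list(self.methods),
            "views": list(self.views),
            "threshold": self.threshold,
            "outer_folds": self.outer_folds,
            "inner_folds": self.inner_folds,
            "subject_ids": list(self.subject_ids),
            "labels": self.labels.astype(int).tolist(),
            "folds": [
                {
                    "index": f.index,
                    "test_subject_ids": [self.subject_ids[i] for i in f.test_indices],
                    "views": {
                        v: {
                            "p": r.p_threshold,
                            "lambda": r.lam,
                            "gamma": r.gamma,
                            "inner_accuracy": r.inner_accuracy,
                            "support": r.support.astype(int).tolist(),
                            "weights": r.weights.tolist(),
                            "test_scores": r.test_scores.tolist(),
                        }
                        for v, r in f.views.items()
                    },
                    "scores": {m: s.tolist() for m, s in f.scores.items()},
                    "predictions": {
                        m: p.astype(int).tolist() for m, p in f.predictions.items()
                    },
                }
                for f in self.folds
            ],
            "metrics": {m: r.as_dict() for m, r in self.metrics.items()},
            "selection_frequency": {
                v: {int(i): int(c) for i, c in enumerate(freq) if c}
                for v, freq in self.selection_frequency.items()
            },
            "n_features": dict(self.n_features),
        }


def _as_pm1(labels: np.ndarray) -> np.ndarray:
    """Accept {0,1} or {-1,+1} label codes; return +/-1 with patients = +1."""
    y = np.asarray(labels).ravel().astype(int)
    vals = set(np.unique(y).tolist())
    if vals <= {0, 1}:
        return np.where(y == 1, 1, -1)
    if vals <= {-1, 1}:
        return y
    raise ValueError(f"labels must be coded 0/1 or -1/+1, got values {sorted(vals)}")


def _fit_view(
    X_train: np.ndarray,
    y_train: np.ndarray,
    p_threshold: float,
    lam: float,
    gamma: float,
    equal_var: bool,
):
    """Standardize, select and fit one view on training data only.

    Returns (predict_scores(X_raw) -> scores, support, weights); the support
    may be empty, in which case scores are identically 0 (control predicted).
    """
    mean, sd = ft.fit_scaler(X_train)
    Xz = ft.apply_scaler(X_train, mean, sd)
    sel = ft.two_stage_select(Xz, y_train, p_threshold, lam, equal_var=equal_var)
    support = sel.lasso_support
    if support.size == 0:
        return (lambda X: np.zeros(np.asarray(X).shape[0])), support, np.zeros(0)
    model = train_linear_svm(Xz[:, support], y_train, gamma)

    def predict_scores(X_raw: np.ndarray) -> np.ndarray:
        Xs = ft.apply_scaler(np.asarray(X_raw, dtype=float), mean, sd)[:, support]
        return model.decision_function(Xs)

    weights = sel.lasso_weights[np.isin(sel.ttest_kept, support)]
    return predict_scores, support, weights


def _tune_view(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid,
    inner_splits: list[tuple[np.ndarray, np.ndarray]],
    equal_var: bool,
) -> tuple[float, float, float, float]:
    """Pick (p, lambda, gamma) maximizing mean inner-fold accuracy.

    Hyperparameter points whose selection stage keeps no features score
    chance accuracy (0.5).  Ties resolve to the smallest p, then lambda,
    then gamma (argmax over the grid in C order does exactly this).
    """
    P, L, G = len(grid.p_grid), len(grid.lambda_grid), len(grid.gamma_grid)
    acc = np.zeros((P, L, G))
    for train_idx, val_idx in inner_splits:
        ytr, yva = y[train_idx], y[val_idx]
        mean, sd = ft.fit_scaler(X[train_idx])
        Xtr = ft.apply_scaler(X[train_idx], mean, sd)
        Xva = ft.apply_scaler(X[val_idx], mean, sd)
        pvals, _ = ft.ttest_filter(Xtr, ytr, 1.0, equal_var=equal_var)
        for ip, p in enumerate(grid.p_grid):
            kept = np.flatnonzero(pvals < p)
            if kept.size == 0:
                acc[ip] += 0.5
                continue
            Xtr_kept, Xva_kept = Xtr[:, kept], Xva[:, kept]
            for il, lam in enumerate(grid.lambda_grid):
                _, supp, _ = ft.lasso_select(Xtr_kept, ytr, lam)
                if supp.size == 0:
                    acc[ip, il] += 0.5
                    continue
                Xtr_s, Xva_s = Xtr_kept[:, supp], Xva_kept[:, supp]
                for ig, gamma in enumerate(grid.gamma_grid):
                    model = train_linear_svm(Xtr_s, ytr, gamma)
                    pred = predict_from_scores(model.decision_function(Xva_s))
                    acc[ip, il, ig] += float(np.mean(pred == yva))
    acc /= len(inner_splits)
    ip, il, ig = np.unravel_index(int(np.argmax(acc)), acc.shape)
    return (
        float(grid.p_grid[ip]),
        float(grid.lambda_grid[il]),
        float(grid.gamma_grid[ig]),
        float(acc[ip, il, ig]),
    )


def nested_cross_validation(
    view_features: dict[str, np.ndarray],
    labels: np.ndarray,
    subject_ids: list[str] | None = None,
    grid: HyperparameterGrid | None = None,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    seed: int = 0,
    outer_folds: int = 10,
    inner_folds: int = 10,
    equal_var: bool = False,
    threshold: float | None = None,
) -> CVReport:
    """Nested stratified k-fold evaluation of the connectivity methods.

    ``view_features`` maps view names ("low_order", "hypergraph_hon",
    optionally "corr_of_corr") to subjects x d matrices.  Hyperparameters
    are tuned independently per view in the inner loop; FUSION reuses the
    two single-view models and averages their decision scores with fixed
    weights 0.5/0.5.  Test predictions are pooled over outer folds into one
    MetricsReport per method.
    """
    grid = grid or HyperparameterGrid()
    y = _as_pm1(labels)
    n = y.size
    if n < 20:
        raise ValueError(f"need at least 20 subjects for nested CV, got {n}")
    if min((y == 1).sum(), (y == -1).sum()) == 0:
        raise ValueError("both classes must be present")

    needed_views: list[str] = []
    for m in methods:
        if m not in METHOD_VIEWS:
            raise ValueError(f"unknown method {m!r}; choose from {sorted(METHOD_VIEWS)}")
        for v in METHOD_VIEWS[m]:
            if v not in needed_views:
                needed_views.append(v)
    for v in needed_views:
        if v not in view_features:
            raise ValueError(f"method set {methods} requires view {v!r}")
        if np.asarray(view_features[v]).shape[0] != n:
            raise ValueError(f"view {v!r} row count does not match labels")
    if subject_ids is None:
        subject_ids = [f"subject_{i:03d}" for i in range(n)]

    min_class = min((y == 1).sum(), (y == -1).sum())
    if outer_folds > min_class:
        raise ValueError(
            f"cannot stratify {outer_folds} outer folds with only {min_class} "
            "subjects in the smaller class; reduce the fold count"
        )
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    inner_seeds = np.random.SeedSequence(seed).generate_state(outer_folds) % (2**31)

    folds: list[FoldResult] = []
    all_scores: dict[str, np.ndarray] = {m: np.zeros(n) for m in methods}
    all_preds: dict[str, np.ndarray] = {m: np.zeros(n, dtype=int) for m in methods}
    sel_freq = {
        v: np.zeros(np.asarray(view_features[v]).shape[1], dtype=int)
        for v in needed_views
    }

    for k, (train_idx, test_idx) in enumerate(outer.split(np.zeros(n), y)):
        ytr = y[train_idx]
        inner_min = min((ytr == 1).sum(), (ytr == -1).sum())
        if inner_min < inner_folds:
            raise ValueError(
                f"outer fold {k}: cannot stratify {inner_folds} inner folds with "
                f"{inner_min} subjects in the smaller class; reduce the fold count"
            )
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=int(inner_seeds[k])
        )
        inner_splits = list(inner.split(np.zeros(train_idx.size), ytr))

        view_results: dict[str, ViewFoldResult] = {}
        for v in needed_views:
            X = np.asarray(view_features[v], dtype=float)
            p_best, lam_best, gamma_best, inner_acc = _tune_view(
                X[train_idx], ytr, grid, inner_splits, equal_var
            )
            predict_scores, support, weights = _fit_view(
                X[train_idx], ytr, p_best, lam_best, gamma_best, equal_var
            )
            view_results[v] = ViewFoldResult(
                p_threshold=p_best,
                lam=lam_best,
                gamma=gamma_best,
                inner_accuracy=inner_acc,
                support=support,
                weights=weights,
                test_scores=predict_scores(X[test_idx]),
            )
            sel_freq[v][support] += 1

        fold_scores: dict[str, np.ndarray] = {}
        fold_preds: dict[str, np.ndarray] = {}
        for m in methods:
            mviews = METHOD_VIEWS[m]
            if len(mviews) == 1:
                s = view_results[mviews[0]].test_scores
            else:
                s = fuse_decision_scores(
                    view_results[mviews[0]].test_scores,
                    view_results[mviews[1]].test_scores,
                )
            fold_scores[m] = np.asarray(s, dtype=float)
            fold_preds[m] = predict_from_scores(s)
            all_scores[m][test_idx] = fold_scores[m]
            all_preds[m][test_idx] = fold_preds[m]

        folds.append(
            FoldResult(
                index=k,
                train_indices=train_idx,
                test_indices=test_idx,
                views=view_results,
                scores=fold_scores,
                predictions=fold_preds,
            )
        )

    metrics = {
        m: compute_metrics(
            tp=int(((all_preds[m] == 1) & (y == 1)).sum()),
            tn=int(((all_preds[m] == -1) & (y == -1)).sum()),
            fp=int(((all_preds[m] == 1) & (y == -1)).sum()),
            fn=int(((all_preds[m] == -1) & (y == 1)).sum()),
        )
        for m in methods
    }

    return CVReport(
        seed=seed,
        methods=tuple(methods),
        views=tuple(needed_views),
        subject_ids=list(subject_ids),
        labels=y,
        folds=folds,
        metrics=metrics,
        selection_frequency=sel_freq,
        n_features={v: int(np.asarray(view_features[v]).shape[1]) for v in needed_views},
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        threshold=threshold,
    )


@dataclass
class RankedFeature:
    """One feature in the selection-frequency ranking."""

    index: int                 # 0-based position in the lower-triangle vector
    count: int                 # outer folds in which the feature was selected
    mean_abs_weight: float     # mean |LASSO weight| over the folds selecting it
    pair: tuple[int, int]      # 1-based (larger, smaller) node pair


def selection_frequency_ranking(report: CVReport, view: str) -> list[RankedFeature]:
    """Rank a view's features by how often they survived selection.

    Descending by fold count, ties broken by descending mean absolute LASSO
    weight, then ascending feature index.  Features never selected are
    omitted.  An empty ranking (no feature ever selected) triggers a warning.
    """
    import warnings as _warnings

    if view not in report.selection_frequency:
        raise ValueError(f"view {view!r} not present in this report")
    freq = report.selection_frequency[view]
    d = freq.size
    n_nodes = int(round((1 + np.sqrt(1 + 8 * d)) / 2))
    weight_sums = np.zeros(d)
    for fold in report.folds:
        r = fold.views[view]
        weight_sums[r.support] += np.abs(r.weights)
    selected = np.flatnonzero(freq)
    if selected.size == 0:
        _warnings.warn(f"no feature of view {view!r} was ever selected", UserWarning)
        return []
    mean_w = weight_sums[selected] / freq[selected]
    order = sorted(
        range(selected.size),
        key=lambda k: (-freq[selected[k]], -mean_w[k], selected[k]),
    )
    ranked = []
    for k in order:
        idx = int(selected[k])
        i, j = ft.feature_pair(idx, n_nodes)
        ranked.append(
            RankedFeature(
                index=idx,
                count=int(freq[idx]),
                mean_abs_weight=float(mean_w[k]),
                pair=(i + 1, j + 1),
            )
        )
    return ranked
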