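"""Construction of low-order and high-order functional connectivity networks.

Three network estimators operate on a subject's regional fMRI time series
(T timepoints x N regions of interest):

* the low-order FCN ``C_LON`` — the Pearson correlation matrix of the ROI
  time series;
* the classical high-order FCN ``C_HON`` — the "correlation of correlations",
  i.e. Pearson correlations between rows of ``C_LON`` after excluding the
  two entries belonging to the pair itself;
* the hypergraph high-order FCN ``H-C_HON`` — each ROI j defines a hyperedge
  e_j containing every ROI whose low-order correlation with j reaches a
  threshold t; the member series of each hyperedge are averaged and the
  correlations between the averaged (hyperedge) series form the network.

All three return symmetric matrices with unit diagonal and entries in
[-1, 1].  Pairs for which Pearson correlation is undefined (a constant
series or a zero-variance exclusion vector) are imputed to 0 — the neutral
no-association value — and recorded in ``degenerate_pairs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: absolute tolerance for symmetry / identity assertions on connectivity matrices
SYMMETRY_TOL = 1e-10

LOW_ORDER = "low_order"
CORR_OF_CORR = "corr_of_corr"
HYPERGRAPH_HON = "hypergraph_hon"

_KINDS = frozenset({LOW_ORDER, CORR_OF_CORR, HYPERGRAPH_HON})


class DegenerateCorrelationWarning(UserWarning):
    """Raised when an undefined Pearson correlation is imputed to 0."""


@dataclass
class RoiTimeSeries:
    """One subject's regional time-series matrix (T timepoints x N ROIs).

    Each column holds the mean BOLD signal of one region of interest.
    ``label`` is the diagnostic class: 1 for patients (ASD), 0 for controls
    (NC), ``None`` when unknown.
    """

    data: np.ndarray
    roi_labels: list[str] | None = None
    subject_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D matrix (timepoints x ROIs)")
        t, n = self.data.shape
        if t < 4 or n < 4:
            raise ValueError(
                f"need at least 4 timepoints and 4 ROIs, got {t} timepoints x {n} ROIs"
            )
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at timepoint {bad[0] + 1}, ROI {bad[1] + 1}"
                + (f" ({self.roi_labels[bad[1]]})" if self.roi_labels else "")
            )
        if self.roi_labels is not None and len(self.roi_labels) != n:
            raise ValueError(
                f"got {len(self.roi_labels)} ROI labels for {n} ROIs"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 (NC), 1 (ASD) or None")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N connectivity matrix with unit diagonal.

    ``kind`` distinguishes the estimator that produced it; ``degenerate_pairs``
    lists (i, j) index pairs (i < j, 0-based) whose correlation was undefined
    and imputed to 0.
    """

    values: np.ndarray
    kind: str
    degenerate_pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.abs(v - v.T).max() > SYMMETRY_TOL:
            raise ValueError("connectivity matrix is not symmetric")
        if np.abs(np.diag(v) - 1.0).max() > SYMMETRY_TOL:
            raise ValueError("connectivity matrix diagonal must be 1")
        if v.min() < -1.0 - SYMMETRY_TOL or v.max() > 1.0 + SYMMETRY_TOL:
            raise ValueError("connectivity entries must lie in [-1, 1]")
        self.degenerate_pairs = frozenset(
            (int(i), int(j)) for i, j in self.degenerate_pairs
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class HypergraphIncidence:
    """Binary incidence matrix H (N ROIs x N hyperedges) at threshold ``t``.

    Column j is hyperedge e_j: H[i, j] = 1 iff ROI i belongs to the
    neighbourhood of ROI j at the given correlation threshold.  Each
    hyperedge contains its own central ROI (the self-correlation is 1).
    """

    H: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H)
        if self.H.ndim != 2 or self.H.shape[0] != self.H.shape[1]:
            raise ValueError("incidence matrix must be square (N ROIs x N hyperedges)")
        if not np.isin(self.H, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        self.H = self.H.astype(np.uint8)
        if not (np.diag(self.H) == 1).all():
            raise ValueError("each hyperedge must contain its central ROI")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")

    @property
    def n(self) -> int:
        return self.H.shape[0]

    def members(self, j: int) -> np.ndarray:
        """0-based indices of the ROIs in hyperedge e_j."""
        return np.flatnonzero(self.H[:, j])


@dataclass
class HyperedgeSeries:
    """Averaged time series per hyperedge (T timepoints x N hyperedges)."""

    data: np.ndarray
    source_threshold: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("hyperedge series must be a 2-D matrix")


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation of two vectors; None when undefined (zero variance)."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return None
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _column_correlations(data: np.ndarray, context: str) -> tuple[np.ndarray, set[tuple[int, int]]]:
    """Correlation matrix of the columns of ``data`` with degenerate handling."""
    n = data.shape[1]
    sd = data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)
    degenerate: set[tuple[int, int]] = set()
    if constant.size:
        for i in constant:
            for j in range(n):
                if i != j:
                    degenerate.add((min(int(i), j), max(int(i), j)))
        warnings.warn(
            f"{context}: {constant.size} constant series; "
            "undefined correlations imputed to 0",
            DegenerateCorrelationWarning,
            stacklevel=3,
        )
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr, degenerate


def build_low_order_fcn(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix of the ROI time series (the low-order FCN)."""
    corr, degenerate = _column_correlations(
        ts.data, f"subject {ts.subject_id or '<unnamed>'}"
    )
    return ConnectivityMatrix(
        values=corr,
        kind=LOW_ORDER,
        degenerate_pairs=frozenset(degenerate),
        subject_id=ts.subject_id,
    )


def build_corr_of_corr_fcn(lon: ConnectivityMatrix) -> ConnectivityMatrix:
    """Correlation-of-correlations high-order FCN (the classical baseline).

    Entry (i, j) correlates row i with row j of the low-order FCN after
    deleting positions i and j from both rows, so each compared profile
    has length N - 2 and the pair's own entries cannot inflate the score.
    """
    if lon.kind != LOW_ORDER:
        raise ValueError(f"expected a low_order matrix, got kind {lon.kind!r}")
    n = lon.n
    if n <= 3:
        raise ValueError(
            f"correlation-of-correlations needs at least 4 ROIs, got {n} "
            "(exclusion vectors would have length < 2)"
        )
    values = lon.values
    out = np.eye(n)
    degenerate: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            keep = np.delete(np.arange(n), (i, j))
            r = _pearson(values[i, keep], values[j, keep])
            if r is None:
                degenerate.add((i, j))
                r = 0.0
            out[i, j] = out[j, i] = r
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} ROI pairs had zero-variance exclusion profiles; "
            "imputed to 0",
            DegenerateCorrelationWarning,
            stacklevel=2,
        )
    return ConnectivityMatrix(
        values=out,
        kind=CORR_OF_CORR,
        degenerate_pairs=frozenset(degenerate),
        subject_id=lon.subject_id,
    )


def build_incidence(
    lon: ConnectivityMatrix, t: float, absolute: bool = False
) -> HypergraphIncidence:
    """Threshold the low-order FCN into a hypergraph incidence matrix.

    ROI i joins hyperedge e_j when its correlation with ROI j reaches ``t``.
    The comparison is signed by default (c_ij >= t keeps only positively
    correlated regions); with ``absolute=True`` the magnitude |c_ij| >= t is
    used instead.  One hyperedge per ROI, and every hyperedge contains its
    central ROI because the self-correlation is 1.
    """
    if lon.kind != LOW_ORDER:
        raise ValueError(f"expected a low_order matrix, got kind {lon.kind!r}")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    values = np.abs(lon.values) if absolute else lon.values
    H = (values >= t).astype(np.uint8)
    np.fill_diagonal(H, 1)
    return HypergraphIncidence(H=H, threshold=float(t))


def average_hyperedge_series(
    ts: RoiTimeSeries, hg: HypergraphIncidence
) -> HyperedgeSeries:
    """Per-timepoint mean of the raw member-ROI series of each hyperedge."""
    if hg.n != ts.n_rois:
        raise ValueError(
            f"incidence matrix is {hg.n}x{hg.n} but subject has {ts.n_rois} ROIs"
        )
    counts = hg.H.sum(axis=0).astype(float)
    data = (ts.data @ hg.H) / counts
    return HyperedgeSeries(data=data, source_threshold=hg.threshold)


def build_hypergraph_hon(
    hs: HyperedgeSeries, subject_id: str = ""
) -> ConnectivityMatrix:
    """Hypergraph high-order FCN: correlations between hyperedge series."""
    corr, degenerate = _column_correlations(
        hs.data, f"hyperedge series (t={hs.source_threshold})"
    )
    return ConnectivityMatrix(
        values=corr,
        kind=HYPERGRAPH_HON,
        degenerate_pairs=frozenset(degenerate),
        subject_id=subject_id,
    )


def build_all_networks(
    ts: RoiTimeSeries,
    threshold: float,
    absolute: bool = False,
    include_corr_of_corr: bool = False,
) -> dict[str, ConnectivityMatrix]:
    """Convenience: build every network kind for one subject.

    Returns a mapping kind -> ConnectivityMatrix with keys ``low_order``,
    ``hypergraph_hon`` and (optionally) ``corr_of_corr``.
    """
    lon = build_low_order_fcn(ts)
    hg = build_incidence(lon, threshold, absolute=absolute)
    hs = average_hyperedge_series(ts, hg)
    out = {
        LOW_ORDER: lon,
        HYPERGRAPH_HON: build_hypergraph_hon(hs, subject_id=ts.subject_id),
    }
    if include_corr_of_corr:
        out[CORR_OF_CORR] = build_corr_of_corr_fcn(lon)
    return out
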