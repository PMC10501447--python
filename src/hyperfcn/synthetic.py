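"""Seeded synthetic cohorts of regional time series with known group structure.

Each subject's T x N matrix is drawn as T independent samples from a
zero-mean multivariate normal whose correlation matrix has a block
(community) structure: ``within_block_corr`` inside each of ``n_blocks``
communities and ``between_block_corr`` elsewhere.  The patient group's
matrix additionally differs at a small set of ``discriminative_pairs`` by
``effect_size`` — these pairs are the planted ground truth that the feature
selection stage should recover.  White measurement noise of standard
deviation ``noise_sd`` is added on top (it attenuates all observable
correlations by the factor 1/(1 + noise_sd^2), which the ground-truth
record reports).

Modified correlation matrices are repaired to symmetric positive definite
form by clipping eigenvalues at 1e-6 and re-normalising to unit diagonal;
the realised (post-repair) effect sizes are reported alongside the
requested ones since the repair can perturb them slightly.

Randomness is hierarchical: subject s of group g draws from an independent
generator seeded with (seed, g, s), so adding subjects never changes the
data of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcn import RoiTimeSeries
from .features import lower_triangle_indices, n_lower_triangle

_EIG_FLOOR = 1e-6


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort.

    Defaults emulate the shape of a single-site resting-state cohort:
    45 patients + 47 controls, 170 timepoints x 116 regions, 8 latent
    communities.
    """

    n_per_group: tuple[int, int] = (45, 47)      # (patients/ASD, controls/NC)
    n_timepoints: int = 170
    n_rois: int = 116
    n_blocks: int = 8
    within_block_corr: float = 0.6
    between_block_corr: float = 0.05
    discriminative_pairs: tuple[tuple[int, int], ...] | None = None
    effect_size: float = 0.5
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("each group needs at least one subject")
        if self.n_timepoints < 4 or self.n_rois < 4:
            raise ValueError("need at least 4 timepoints and 4 ROIs")
        if not 1 <= self.n_blocks <= self.n_rois:
            raise ValueError("n_blocks must lie in [1, n_rois]")
        if not 0.0 < self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in (0, 1)")
        if not -1.0 < self.between_block_corr < self.within_block_corr:
            raise ValueError("between_block_corr must be below within_block_corr")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.discriminative_pairs is None:
            self.discriminative_pairs = default_discriminative_pairs(
                self.n_rois, self.n_blocks
            )
        pairs = []
        seen = set()
        for i, j in self.discriminative_pairs:
            i, j = int(i), int(j)
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"invalid ROI pair ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate discriminative pair {key}")
            seen.add(key)
            pairs.append(key)
        self.discriminative_pairs = tuple(pairs)


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    discriminative_pairs: tuple[tuple[int, int], ...]  # 0-based (i, j), i < j
    feature_indices: np.ndarray      # positions in the lower-triangle vector
    requested_effect: float
    realized_effects: np.ndarray     # per pair, after SPD repair (noise-free scale)
    attenuation: float               # factor noise applies to observable correlations
    blocks: np.ndarray               # ROI -> community assignment
    corr_nc: np.ndarray              # latent correlation matrix, control group
    corr_asd: np.ndarray             # latent correlation matrix, patient group

    def to_dict(self) -> dict:
        return {
            "discriminative_pairs_1based": [
                [i + 1, j + 1] for i, j in self.discriminative_pairs
            ],
            "feature_indices": self.feature_indices.astype(int).tolist(),
            "requested_effect": self.requested_effect,
            "realized_effects": self.realized_effects.tolist(),
            "attenuation": self.attenuation,
            "blocks": self.blocks.astype(int).tolist(),
        }


def block_assignment(n_rois: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal community assignment of ROIs to blocks."""
    chunks = np.array_split(np.arange(n_rois), n_blocks)
    return np.concatenate([np.full(len(c), b) for b, c in enumerate(chunks)])


def default_discriminative_pairs(
    n_rois: int, n_blocks: int, n_pairs: int = 5
) -> tuple[tuple[int, int], ...]:
    """Five cross-community ROI pairs, deterministic in (n_rois, n_blocks).

    Pair k links the k-th ROI of block k with the k-th ROI of the next block
    (cyclically), so the baseline correlation at every planted pair is the
    low between-block value and a positive effect is easy to inject.
    """
    blocks = block_assignment(n_rois, n_blocks)
    members = [np.flatnonzero(blocks == b) for b in range(n_blocks)]
    pairs = []
    for k in range(n_pairs):
        ba = members[k % n_blocks]
        bb = members[(k + 1) % n_blocks]
        if n_blocks == 1:
            i = ba[(2 * k) % len(ba)]
            j = ba[(2 * k + 1) % len(ba)]
        else:
            i = ba[k % len(ba)]
            j = bb[k % len(bb)]
        key = (int(min(i, j)), int(max(i, j)))
        if key not in pairs:
            pairs.append(key)
    return tuple(pairs)


def _nearest_spd_correlation(R: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and re-normalise to unit diagonal."""
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    vals = np.clip(vals, _EIG_FLOOR, None)
    S = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def group_correlation_matrices(
    spec: SyntheticCohortSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(control R, patient R, realised per-pair effects) for a cohort spec."""
    blocks = block_assignment(spec.n_rois, spec.n_blocks)
    same_block = blocks[:, None] == blocks[None, :]
    base = np.where(same_block, spec.within_block_corr, spec.between_block_corr)
    np.fill_diagonal(base, 1.0)

    modified = base.copy()
    for i, j in spec.discriminative_pairs:
        target = base[i, j] + spec.effect_size
        if target > 0.9:  # keep the perturbed matrix comfortably correlation-like
            target = base[i, j] - spec.effect_size
        modified[i, j] = modified[j, i] = np.clip(target, -0.9, 0.9)

    R_nc = _nearest_spd_correlation(base)
    R_asd = _nearest_spd_correlation(modified)
    for name, R in (("control", R_nc), ("patient", R_asd)):
        eigmin = float(np.linalg.eigvalsh(R).min())
        if eigmin <= 0:
            raise ValueError(
                f"{name} covariance is not positive definite after repair "
                f"(min eigenvalue {eigmin:.3e}); offending pairs: "
                f"{spec.discriminative_pairs}"
            )
    realized = np.array(
        [R_asd[i, j] - R_nc[i, j] for i, j in spec.discriminative_pairs]
    )
    return R_nc, R_asd, realized


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[RoiTimeSeries], GroundTruth]:
    """Draw a labelled cohort and its planted ground truth.

    Deterministic given ``spec.seed``; patients carry label 1, controls 0.
    """
    R_nc, R_asd, realized = group_correlation_matrices(spec)
    rows, cols = lower_triangle_indices(spec.n_rois)
    pos = {(int(r), int(c)): k for k, (r, c) in enumerate(zip(rows, cols))}
    feature_indices = np.array(
        [pos[(max(i, j), min(i, j))] for i, j in spec.discriminative_pairs], dtype=int
    )
    blocks = block_assignment(spec.n_rois, spec.n_blocks)
    truth = GroundTruth(
        discriminative_pairs=spec.discriminative_pairs,
        feature_indices=feature_indices,
        requested_effect=spec.effect_size,
        realized_effects=realized,
        attenuation=1.0 / (1.0 + spec.noise_sd**2),
        blocks=blocks,
        corr_nc=R_nc,
        corr_asd=R_asd,
    )

    roi_labels = [f"ROI_{i + 1:03d}" for i in range(spec.n_rois)]
    chol = {1: np.linalg.cholesky(R_asd), 0: np.linalg.cholesky(R_nc)}
    n_asd, n_nc = spec.n_per_group
    cohort: list[RoiTimeSeries] = []
    for label, group_size, tag in ((1, n_asd, "asd"), (0, n_nc, "nc")):
        for s in range(group_size):
            rng = np.random.default_rng([spec.seed, label, s])
            data = rng.standard_normal((spec.n_timepoints, spec.n_rois)) @ chol[label].T
            if spec.noise_sd > 0:
                data = data + spec.noise_sd * rng.standard_normal(data.shape)
            cohort.append(
                RoiTimeSeries(
                    data=data,
                    roi_labels=roi_labels,
                    subject_id=f"{tag}_{s:03d}",
                    label=label,
                )
            )
    return cohort, truth


def cohort_feature_matrices(
    cohort: list[RoiTimeSeries],
    threshold: float,
    absolute: bool = False,
    include_corr_of_corr: bool = False,
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Build per-view feature matrices for a labelled cohort.

    Returns (view -> subjects x d matrix, labels in {0,1}, subject ids).
    Helper shared by the pipeline, tests and the acceptance script.
    """
    from .fcn import build_all_networks
    from .features import vectorize_lower_triangle

    views: dict[str, list[np.ndarray]] = {}
    labels = []
    ids = []
    for ts in cohort:
        if ts.label is None:
            raise ValueError(f"subject {ts.subject_id!r} has no diagnostic label")
        nets = build_all_networks(
            ts, threshold, absolute=absolute, include_corr_of_corr=include_corr_of_corr
        )
        for kind, cm in nets.items():
            views.setdefault(kind, []).append(vectorize_lower_triangle(cm.values))
        labels.append(ts.label)
        ids.append(ts.subject_id)
    return (
        {k: np.vstack(v) for k, v in views.items()},
        np.asarray(labels, dtype=int),
        ids,
    )


def expected_feature_count(n_rois: int) -> int:
    """Dimensionality of one view's feature vector for ``n_rois`` regions."""
    return n_lower_triangle(n_rois)
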