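"""Voxel volumes, RI point clouds, and voxel-to-cloud sampling.

A reconstructed single-cell volume is a set of voxels v_i = (x_i, y_i, z_i,
n_i) where n_i is the refractive index; sampling turns it into a much smaller
point cloud P = {p_j = (x_j, y_j, z_j, n_j)}, M << N.  Because the RI
histogram of a cell is heavily skewed towards the low-RI cytoplasm, plain
uniform (random) sampling drowns the high-RI organelles.  Segmented
equilibrium sampling fixes this: normalize the RI range, split it into L
equal-width intervals, draw an equal quota from each interval, and fill any
interval's deficit by drawing uniformly from the still-unsampled points of
the other intervals, so the output always has exactly M points and every one
of them is a genuine input point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyForegroundError,
    InsufficientPointsError,
    InvalidConfigError,
)

__all__ = [
    "VoxelVolume",
    "RIPointCloud",
    "SamplerConfig",
    "voxel_to_points",
    "threshold_mask",
    "random_sample",
    "segmented_equilibrium_sample",
    "normalize_unit_sphere",
    "interval_histogram",
]

#: physical RI bounds used by the fixed-range normalization mode
FIXED_RI_RANGE = (1.33, 1.40)


@dataclass
class VoxelVolume:
    """A single-channel RI grid with isotropic voxel spacing (um/voxel).

    Coordinates follow the 0-based convention: voxel (i, j, k) sits at
    (i, j, k) * spacing micrometres.
    """

    ri: np.ndarray  # 3D float array of refractive indices
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.ri = np.asarray(self.ri)
        if self.ri.ndim != 3 or self.ri.size == 0:
            raise InvalidConfigError("ri grid must be a non-empty 3D array")
        if not np.all(np.isfinite(self.ri)):
            raise InvalidConfigError("ri grid contains non-finite values")


@dataclass
class RIPointCloud:
    """M points of (x, y, z, n).  ``xyz`` is (M, 3) in micrometres (or unit-
    sphere units once ``normalized``); ``ri`` always carries raw physical RI
    regardless of coordinate normalization."""

    xyz: np.ndarray
    ri: np.ndarray
    normalized: bool = False
    label: int | None = None

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=np.float64))
        self.ri = np.asarray(self.ri, dtype=np.float64).ravel()
        if self.xyz.shape != (len(self.ri), 3):
            raise InvalidConfigError(
                f"xyz shape {self.xyz.shape} inconsistent with {len(self.ri)} RI values"
            )
        if len(self.ri) < 1:
            raise InvalidConfigError("a point cloud needs at least one point")

    def __len__(self) -> int:
        return len(self.ri)

    def take(self, idx: np.ndarray) -> "RIPointCloud":
        """Subset/reorder by index array (duplicates allowed)."""
        return RIPointCloud(self.xyz[idx], self.ri[idx], self.normalized, self.label)


@dataclass(frozen=True)
class SamplerConfig:
    """Voxel-to-cloud sampler settings: target count M, number of RI
    intervals L, and how the RI range is normalized before interval division
    ("per-cell" min-max over the cloud, or the fixed physical range
    [1.33, 1.40])."""

    M: int = 10_000
    L: int = 6
    mode: str = "segmented"  # "random" | "segmented"
    seed: int = 0
    ri_normalization: str = "per-cell"  # "per-cell" | "fixed-range"

    def validate(self) -> None:
        if self.L < 1:
            raise InvalidConfigError(f"L must be >= 1, got {self.L}")
        if self.M < 1 or self.L > self.M:
            raise InvalidConfigError(f"need 1 <= L <= M, got L={self.L}, M={self.M}")
        if self.mode not in ("random", "segmented"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.ri_normalization not in ("per-cell", "fixed-range"):
            raise InvalidConfigError(
                f"unknown ri_normalization {self.ri_normalization!r}"
            )


def voxel_to_points(volume: VoxelVolume, mask: np.ndarray) -> RIPointCloud:
    """Enumerate every foreground voxel as a point: coordinates are
    voxel index * spacing, RI copied unchanged."""
    mask = np.asarray(mask, bool)
    if mask.shape != volume.ri.shape:
        raise InvalidConfigError(
            f"mask shape {mask.shape} != grid shape {volume.ri.shape}"
        )
    if not mask.any():
        raise EmptyForegroundError("mask selects no voxels")
    idx = np.argwhere(mask)
    return RIPointCloud(idx * float(volume.spacing), volume.ri[mask])


def threshold_mask(volume: VoxelVolume, medium_ri: float = 1.33, delta: float = 0.003) -> np.ndarray:
    """Convenience foreground mask: RI above medium + delta.  Real pipelines
    use a dedicated segmentation step; this is for phantoms and demos only."""
    return volume.ri > (medium_ri + delta)


def _normalized_ri(cloud: RIPointCloud, mode: str) -> np.ndarray:
    """Map RI to [0, 1] for interval division."""
    ri = cloud.ri
    if mode == "fixed-range":
        lo, hi = FIXED_RI_RANGE
    else:
        lo, hi = float(ri.min()), float(ri.max())
    width = hi - lo
    if width <= 0:  # all-equal RI: one degenerate interval
        return np.zeros_like(ri)
    return np.clip((ri - lo) / width, 0.0, 1.0)


def _interval_index(cloud: RIPointCloud, L: int, mode: str) -> np.ndarray:
    u = _normalized_ri(cloud, mode)
    return np.minimum((u * L).astype(np.int64), L - 1)


def random_sample(cloud: RIPointCloud, M: int, seed: int = 0) -> RIPointCloud:
    """Uniform sampling without replacement (the traditional baseline)."""
    if M > len(cloud):
        raise InsufficientPointsError(f"requested M={M} from cloud of {len(cloud)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cloud), size=M, replace=False)
    return cloud.take(idx)


def segmented_equilibrium_sample(cloud: RIPointCloud, config: SamplerConfig) -> RIPointCloud:
    """Segmented equilibrium sampling.

    The (normalized) RI range is split into ``L`` equal-width intervals with
    per-interval quotas of floor(M/L), the remainder going to the lowest-index
    intervals.  Each interval contributes min(quota, available) points drawn
    without replacement; the total deficit is then supplemented by a uniform
    draw from the pooled not-yet-sampled points of the other intervals.
    Output: exactly M distinct input points.
    """
    config.validate()
    if config.mode != "segmented":
        raise InvalidConfigError("segmented_equilibrium_sample requires mode='segmented'")
    M, L = config.M, config.L
    n = len(cloud)
    if M > n:
        raise InsufficientPointsError(f"requested M={M} from cloud of {n}")
    rng = np.random.default_rng(config.seed)

    bins = _interval_index(cloud, L, config.ri_normalization)
    quotas = np.full(L, M // L, dtype=np.int64)
    quotas[: M % L] += 1

    chosen: list[np.ndarray] = []
    taken = np.zeros(n, dtype=bool)
    for b in range(L):
        members = np.flatnonzero(bins == b)
        k = min(quotas[b], len(members))
        if k > 0:
            pick = rng.choice(members, size=k, replace=False)
            chosen.append(pick)
            taken[pick] = True
    deficit = M - int(taken.sum())
    if deficit > 0:
        pool = np.flatnonzero(~taken)
        extra = rng.choice(pool, size=deficit, replace=False)
        chosen.append(extra)
    idx = np.concatenate(chosen)
    return cloud.take(idx)


def normalize_unit_sphere(cloud: RIPointCloud) -> RIPointCloud:
    """Centre coordinates at the centroid and scale by the maximum centroid
    distance so the farthest point sits on the unit sphere.  RI unchanged.
    An all-coincident cloud maps to the origin (scale guard = 1)."""
    xyz = cloud.xyz - cloud.xyz.mean(axis=0)
    scale = float(np.linalg.norm(xyz, axis=1).max())
    if scale <= 0:
        scale = 1.0
    return RIPointCloud(xyz / scale, cloud.ri.copy(), normalized=True, label=cloud.label)


def interval_histogram(
    cloud: RIPointCloud, L: int, ri_normalization: str = "per-cell"
) -> np.ndarray:
    """Per-interval point counts over L equal-width intervals of the
    normalized RI range.  Counts always sum to M."""
    if L < 1:
        raise InvalidConfigError(f"L must be >= 1, got {L}")
    bins = _interval_index(cloud, L, ri_normalization)
    return np.bincount(bins, minlength=L)
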