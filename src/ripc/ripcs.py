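"""RIPCS: the refractive-index point cloud selector.

Networks want a fixed-cardinality input.  RIPCS reduces an M-point RI cloud
to a K-point training set S = S_FPS u S_RI (default K = 1024):

* **FPS** (farthest point sampling, default 800 points) greedily maximizes
  the minimum distance to the already-selected set, giving uniform spatial
  coverage of the cell.  It looks only at coordinates, never at RI.
* **RIIES** (RI-interval-enhanced sampling, default 224 points) draws from a
  fixed RI band - [1.345, 1.355], where nucleoli live - so the structures
  that actually separate the classes are guaranteed representation.  If the
  band holds fewer than the requested count, its points are replicated in
  shuffled cyclic order until the count is met (multiplicities differ by at
  most one).

The union is realized as multiset concatenation: a point picked by both
samplers appears twice, which is what keeps |S| = K exactly.  Randomized
selection doubles as data augmentation during training; a deterministic FPS
start (farthest from the centroid, lexicographic tie-break) is available for
reproducible inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyIntervalError, InsufficientPointsError, InvalidConfigError
from .voxelcloud import RIPointCloud, normalize_unit_sphere


def _fps_greedy(xyz: np.ndarray, first: int, k: int) -> np.ndarray:
    """Greedy FPS inner loop: k indices starting from ``first``."""
    n = xyz.shape[0]
    sel = np.empty(k, dtype=np.int64)
    sel[0] = first
    mind = np.empty(n, dtype=np.float64)
    for j in range(n):
        d = 0.0
        for c in range(3):
            t = xyz[j, c] - xyz[first, c]
            d += t * t
        mind[j] = d
    for i in range(1, k):
        nxt = 0
        best = -1.0
        for j in range(n):
            if mind[j] > best:
                best = mind[j]
                nxt = j
        sel[i] = nxt
        for j in range(n):
            d = 0.0
            for c in range(3):
                t = xyz[j, c] - xyz[nxt, c]
                d += t * t
            if d < mind[j]:
                mind[j] = d
    return sel


try:  # optional numba acceleration of the O(k*n) greedy loop
    from numba import njit

    _fps_greedy = njit(cache=False, fastmath=False)(_fps_greedy)
except ImportError:  # pragma: no cover - numba is an optional speedup
    def _fps_greedy(xyz, first, k):  # numpy-vectorized fallback
        n = len(xyz)
        sel = np.empty(k, dtype=np.int64)
        sel[0] = first
        mind = ((xyz - xyz[first]) ** 2).sum(axis=1)
        for i in range(1, k):
            nxt = int(np.argmax(mind))
            sel[i] = nxt
            np.minimum(mind, ((xyz - xyz[nxt]) ** 2).sum(axis=1), out=mind)
        return sel

__all__ = [
    "RIPCSConfig",
    "TrainingPointSet",
    "farthest_point_sample",
    "riies_sample",
    "ripcs_select",
]

#: provenance tags stored per point
PROV_FPS = 0
PROV_RIIES = 1

#: nucleolar RI band
DEFAULT_RI_INTERVAL = (1.345, 1.355)


@dataclass(frozen=True)
class RIPCSConfig:
    K: int = 1024
    n_fps: int = 800
    n_riies: int = 224
    ri_interval: tuple[float, float] = DEFAULT_RI_INTERVAL
    seed: int = 0
    fps_start: str = "random"  # "random" | "deterministic"

    def validate(self) -> None:
        if self.n_fps < 0 or self.n_riies < 0 or self.n_fps + self.n_riies != self.K:
            raise InvalidConfigError(
                f"n_fps + n_riies must equal K: {self.n_fps} + {self.n_riies} != {self.K}"
            )
        lo, hi = self.ri_interval
        if not (1.0 < lo <= hi < 2.0):
            raise InvalidConfigError(f"implausible RI interval ({lo}, {hi})")
        if self.fps_start not in ("random", "deterministic"):
            raise InvalidConfigError(f"unknown fps_start {self.fps_start!r}")


@dataclass
class TrainingPointSet:
    """The K-point network input: unit-sphere coordinates, raw RI, and a
    per-point provenance tag (0 = FPS, 1 = RIIES)."""

    xyz: np.ndarray  # (K, 3) unit-sphere normalized
    ri: np.ndarray  # (K,) raw physical RI
    provenance: np.ndarray  # (K,) uint8
    label: int | None = None

    def __len__(self) -> int:
        return len(self.ri)


def _deterministic_start(xyz: np.ndarray) -> int:
    """Point farthest from the centroid; ties broken by lexicographic
    (x, y, z) order.  Independent of input point order up to exact ties."""
    d = ((xyz - xyz.mean(axis=0)) ** 2).sum(axis=1)
    cand = np.flatnonzero(d == d.max())
    order = np.lexsort((xyz[cand, 2], xyz[cand, 1], xyz[cand, 0]))
    return int(cand[order[0]])


def farthest_point_sample(
    xyz: np.ndarray,
    k: int,
    start: int | str = "deterministic",
    seed: int | None = None,
) -> np.ndarray:
    """Greedy farthest point sampling on coordinates.

    Returns k distinct indices: the start point, then repeatedly the point
    maximizing the minimum Euclidean distance to everything selected so far.
    ``start`` may be an index, "deterministic" (farthest from centroid,
    lexicographic tie-break) or "random" (seeded).
    """
    xyz = np.asarray(xyz, dtype=np.float64)
    n = len(xyz)
    if not 1 <= k <= n:
        raise InsufficientPointsError(f"k={k} out of range for cloud of {n}")
    if start == "random":
        first = int(np.random.default_rng(seed).integers(n))
    elif start == "deterministic":
        first = _deterministic_start(xyz)
    else:
        first = int(start)
    return _fps_greedy(np.ascontiguousarray(xyz), first, k)


def riies_sample(
    cloud: RIPointCloud,
    k: int,
    ri_interval: tuple[float, float] = DEFAULT_RI_INTERVAL,
    seed: int | None = None,
) -> np.ndarray:
    """Indices (a multiset) of k points with RI in the closed band.

    Band holding >= k points: uniform draw without replacement.  Fewer: every
    band point is replicated cyclically in shuffled order, so multiplicities
    differ by at most one and the result still has exactly k entries.
    """
    lo, hi = ri_interval
    band = np.flatnonzero((cloud.ri >= lo) & (cloud.ri <= hi))
    if band.size == 0:
        raise EmptyIntervalError(
            f"no points with RI in [{lo}, {hi}]; cloud RI range is "
            f"[{cloud.ri.min():.4f}, {cloud.ri.max():.4f}]"
        )
    rng = np.random.default_rng(seed)
    if band.size >= k:
        return rng.choice(band, size=k, replace=False)
    perm = rng.permutation(band)
    reps = -(-k // band.size)  # ceil
    return np.tile(perm, reps)[:k]


def ripcs_select(cloud: RIPointCloud, config: RIPCSConfig | None = None) -> TrainingPointSet:
    """Build the hybrid K-point training set S = S_FPS u S_RI.

    The input cloud is unit-sphere normalized first if it is not already
    (RIIES always sees raw RI).  The concatenated multiset keeps duplicates
    across the two subsets, is shuffled under the config seed, and carries a
    per-point provenance tag.
    """
    config = config or RIPCSConfig()
    config.validate()
    if config.n_fps > len(cloud):
        raise InsufficientPointsError(
            f"n_fps={config.n_fps} exceeds cloud size {len(cloud)}"
        )
    if not cloud.normalized:
        cloud = normalize_unit_sphere(cloud)
    ss = np.random.SeedSequence(config.seed).spawn(3)

    parts: list[np.ndarray] = []
    tags: list[np.ndarray] = []
    if config.n_fps > 0:
        start = "deterministic" if config.fps_start == "deterministic" else "random"
        fps_idx = farthest_point_sample(
            cloud.xyz,
            config.n_fps,
            start=start,
            seed=int(ss[0].generate_state(1)[0] % (2**31)),
        )
        parts.append(fps_idx)
        tags.append(np.full(len(fps_idx), PROV_FPS, np.uint8))
    if config.n_riies > 0:
        ri_idx = riies_sample(
            cloud,
            config.n_riies,
            config.ri_interval,
            seed=int(ss[1].generate_state(1)[0] % (2**31)),
        )
        parts.append(ri_idx)
        tags.append(np.full(len(ri_idx), PROV_RIIES, np.uint8))

    idx = np.concatenate(parts)
    prov = np.concatenate(tags)
    order = np.random.default_rng(ss[2]).permutation(len(idx))
    idx, prov = idx[order], prov[order]
    return TrainingPointSet(cloud.xyz[idx].copy(), cloud.ri[idx].copy(), prov, cloud.label)
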