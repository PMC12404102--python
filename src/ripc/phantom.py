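"""Synthetic 3D refractive-index (RI) cell phantoms.

Holographic tomography reconstructs, per voxel, the refractive index of a
cell sitting in medium of RI ~1.330.  Real single-cell volumes have a very
characteristic RI histogram: the bulk cytoplasm occupies a narrow low-RI band
just above the medium, nucleoli sit in 1.345-1.355, and a handful of lipid
droplets reach up to ~1.38, so the lowest of a few equal-width RI intervals
outnumbers the highest by orders of magnitude.  This module generates voxel
volumes with that statistical structure so the whole sampling/classification
pipeline can be exercised and validated without microscope data.

Three classes stand in for high / moderate / low cell viability.  They differ
in nucleolar number, size and mean RI (the features the classifier is meant
to pick up); the direction of the RI shift across classes is a configurable
synthetic convention, not a biological claim.

Geometry is deliberately simple - a randomly oriented ellipsoidal cell, an
interior nucleus ellipsoid, spherical nucleoli and droplets - which is enough
to give farthest point sampling non-trivial structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSpecError
from .voxelcloud import VoxelVolume

__all__ = [
    "ClassParams",
    "PhantomSpec",
    "LabeledVolume",
    "generate_phantom",
    "generate_dataset",
]

N_CLASSES = 3


@dataclass(frozen=True)
class ClassParams:
    """Per-class organelle parameters.

    Defaults encode the class contrast: nucleolar count 2/3/4 and mean
    nucleolar RI 1.352/1.350/1.348 for classes 0/1/2, monotone in both so the
    classes are recoverable from either geometry or RI.
    """

    n_nucleoli: int
    nucleolus_radius_um: float
    nucleolus_mean_ri: float
    n_droplets: int = 6


DEFAULT_CLASS_PARAMS: tuple[ClassParams, ...] = (
    ClassParams(2, 1.4, 1.352),
    ClassParams(3, 1.3, 1.350),
    ClassParams(4, 1.2, 1.348),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the phantom generator.

    ``grid_shape`` defaults to 160 x 160 x 105 voxels at 0.2 um spacing,
    i.e. the same 32 x 32 x 21 um physical field as a 320 x 320 x 210 grid at
    0.1 um (available via :meth:`full_scale`) with 1/8 the voxel count.
    All RI intervals are dimensionless refractive indices.
    """

    grid_shape: tuple[int, int, int] = (160, 160, 105)
    voxel_spacing: float = 0.2  # micrometres per voxel, isotropic
    medium_ri: float = 1.330
    cytoplasm_ri_range: tuple[float, float] = (1.335, 1.345)
    nucleolus_ri_range: tuple[float, float] = (1.345, 1.355)
    droplet_ri_range: tuple[float, float] = (1.355, 1.380)
    cell_semiaxes_um: tuple[float, float, float] = (8.0, 7.0, 5.5)
    class_params: tuple[ClassParams, ...] = DEFAULT_CLASS_PARAMS
    noise_sigma: float = 0.0015  # RI std dev added everywhere (0 = clean)
    seed: int = 0

    @classmethod
    def full_scale(cls, **kwargs) -> "PhantomSpec":
        """The 320 x 320 x 210 grid at 0.1 um spacing."""
        return cls(grid_shape=(320, 320, 210), voxel_spacing=0.1, **kwargs)

    def validate(self) -> None:
        nx, ny, nz = self.grid_shape
        if min(nx, ny, nz) < 1:
            raise InvalidSpecError(f"zero-size grid {self.grid_shape}")
        if self.voxel_spacing <= 0:
            raise InvalidSpecError("voxel_spacing must be positive")
        for name in ("cytoplasm_ri_range", "nucleolus_ri_range", "droplet_ri_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidSpecError(f"empty RI interval {name}=({lo}, {hi})")
            if lo < 1.33 or hi > 1.40:
                raise InvalidSpecError(f"{name}=({lo}, {hi}) outside [1.33, 1.40]")
        nlo, nhi = self.nucleolus_ri_range
        if nlo < 1.345 or nhi > 1.355:
            raise InvalidSpecError("nucleolus_ri_range must lie within [1.345, 1.355]")
        if len(self.class_params) != N_CLASSES:
            raise InvalidSpecError("class_params must define exactly 3 classes")
        # the jittered cell (<=1.15x semiaxes, +-0.5 um centre) must fit the grid
        field_um = np.array(self.grid_shape) * self.voxel_spacing
        need = 2 * 1.15 * np.array(self.cell_semiaxes_um) + 1.0
        if np.any(need > field_um):
            raise InvalidSpecError(
                f"grid field {tuple(field_um)} um too small for cell semiaxes "
                f"{self.cell_semiaxes_um} um"
            )


@dataclass
class LabeledVolume:
    """A phantom volume with its foreground mask and class label."""

    volume: VoxelVolume
    mask: np.ndarray  # boolean, same shape as the RI grid
    label: int


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _unit_ball(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v /= max(np.linalg.norm(v), 1e-12)
    return v * rng.uniform() ** (1 / 3)


def generate_phantom(spec: PhantomSpec, label: int, seed: int | None = None) -> LabeledVolume:
    """Generate one labelled RI phantom.

    Deterministic given ``(spec, label, seed)``.  With ``noise_sigma=0`` every
    foreground voxel RI lies inside [cytoplasm lo, droplet hi] and every
    background voxel equals ``medium_ri`` exactly.
    """
    spec.validate()
    if label not in range(N_CLASSES):
        raise InvalidSpecError(f"label must be in 0..2, got {label}")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(label)]))
    cp = spec.class_params[label]

    nx, ny, nz = spec.grid_shape
    sp = float(spec.voxel_spacing)
    xs = (np.arange(nx, dtype=np.float32) * sp)[:, None, None]
    ys = (np.arange(ny, dtype=np.float32) * sp)[None, :, None]
    zs = (np.arange(nz, dtype=np.float32) * sp)[None, None, :]

    centre = np.array([nx, ny, nz], float) * sp / 2 + rng.uniform(-0.5, 0.5, 3)
    axes = np.array(spec.cell_semiaxes_um) * rng.uniform(0.85, 1.15, 3)
    rot = _random_rotation(rng)

    dx, dy, dz = xs - centre[0], ys - centre[1], zs - centre[2]

    def ellipse_q(c, ax, r):
        """Squared normalized ellipsoidal radius field for centre c, axes ax, rotation r."""
        q = np.zeros((nx, ny, nz), np.float32)
        for k in range(3):
            u = (dx - (c[0] - centre[0])) * r[0, k] \
                + (dy - (c[1] - centre[1])) * r[1, k] \
                + (dz - (c[2] - centre[2])) * r[2, k]
            q += (u / ax[k]) ** 2
        return q

    q_cell = ellipse_q(centre, axes, rot)
    mask = q_cell <= 1.0

    ri = np.full((nx, ny, nz), spec.medium_ri, np.float32)
    clo, chi = spec.cytoplasm_ri_range
    cw = chi - clo
    # cytoplasm: mildly denser towards the centre, confined to the lower half
    # of the cytoplasm band so the low-RI interval dominates the histogram
    ri[mask] = clo + cw * (0.05 + 0.40 * (1.0 - np.sqrt(q_cell[mask])))

    # nucleus: interior ellipsoid, slightly elevated RI (still cytoplasm band)
    n_centre = centre + rot @ (rng.uniform(-0.10, 0.10, 3) * axes)
    n_axes = 0.55 * axes
    q_nuc = ellipse_q(n_centre, n_axes, rot)
    nuc = (q_nuc <= 1.0) & mask
    ri[nuc] = clo + cw * (0.30 + 0.25 * (1.0 - np.sqrt(q_nuc[nuc])))

    def paint_sphere(pos, radius, value):
        d2 = (xs - pos[0]) ** 2 + (ys - pos[1]) ** 2 + (zs - pos[2]) ** 2
        ri[(d2 <= radius**2) & mask] = value

    # nucleoli: class-dependent count/size/mean RI, placed inside the nucleus
    nlo, nhi = spec.nucleolus_ri_range
    for _ in range(cp.n_nucleoli):
        pos = n_centre + rot @ (_unit_ball(rng) * 0.60 * n_axes)
        radius = cp.nucleolus_radius_um * rng.uniform(0.85, 1.15)
        value = float(np.clip(rng.normal(cp.nucleolus_mean_ri, 0.001), nlo, nhi))
        paint_sphere(pos, radius, value)

    # lipid droplets: small, sparse, high RI, in the outer cytoplasm
    dlo, dhi = spec.droplet_ri_range
    dw = dhi - dlo
    for _ in range(cp.n_droplets):
        v = rng.normal(size=3)
        v /= max(np.linalg.norm(v), 1e-12)
        pos = centre + rot @ (v * rng.uniform(0.60, 0.88) * axes)
        radius = rng.uniform(0.30, 0.45)
        value = dlo + dw * rng.uniform(0.08, 0.92)
        paint_sphere(pos, radius, value)

    if spec.noise_sigma > 0:
        ri += rng.normal(0.0, spec.noise_sigma, ri.shape).astype(np.float32)

    return LabeledVolume(VoxelVolume(ri, sp), mask, int(label))


def generate_dataset(
    spec: PhantomSpec, n_per_class: tuple[int, int, int], seed: int = 0
) -> list[LabeledVolume]:
    """Generate ``n_per_class[c]`` phantoms per class, each from a distinct
    derived seed.  Label order is class 0 block, class 1 block, class 2 block;
    the whole collection is reproducible from ``seed``."""
    if len(n_per_class) != N_CLASSES or any(n < 1 for n in n_per_class):
        raise InvalidSpecError(f"need >=1 sample per class, got {n_per_class}")
    out: list[LabeledVolume] = []
    for c in range(N_CLASSES):
        for i in range(n_per_class[c]):
            child = int(
                np.random.SeedSequence([int(seed), c, i]).generate_state(1)[0] % (2**31)
            )
            out.append(generate_phantom(spec, c, seed=child))
    return out
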