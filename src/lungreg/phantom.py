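"""Synthetic thoracic phantoms with ground-truth lung masks and tumors.

The generator emulates the gross intensity structure of a thoracic CT at
the working (downsized) resolution: a bright ellipsoidal body on dark
background containing two dark ellipsoidal lung fields, optionally with a
bright spherical tumor of 10–60 mm diameter inside one lung and mild
additive Gaussian noise. It exists so every stage of the registration
pipeline — segmentation, pre-alignment, metric evaluation, parameter
search — can be exercised and scored against known ground truth without
patient data.

Default geometry mimics a 512×512 exam with 1.28 mm axial pixels and 5 mm
slices downsized to 128×128 (axial spacing 5.12 mm), cropped to the
thorax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import LungMask
from .transforms import AffineParams, to_matrix, resample
from .volumes import Volume

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "make_thorax",
    "insert_tumor",
    "perturb",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity levels of a synthetic thorax."""

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (5.12, 5.12, 5.0)
    body_intensity: float = 0.6
    lung_intensity: float = 0.1
    tumor_intensity: float = 0.6  # soft-tissue level: bright against lung
    background_intensity: float = 0.0
    #: body ellipsoid half-axes as fractions of the grid extent
    body_axes: tuple[float, float, float] = (0.46, 0.40, 0.48)
    #: lung ellipsoid half-axes as fractions of the grid extent
    lung_axes: tuple[float, float, float] = (0.17, 0.24, 0.36)
    #: lateral offset of each lung center, fraction of X
    lung_offset: float = 0.20
    noise_sd: float = 0.01
    seed: int | None = 0

    def __post_init__(self) -> None:
        for name in ("body_intensity", "lung_intensity", "tumor_intensity",
                     "background_intensity"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if min(self.shape) < 8:
            raise ValueError(f"phantom shape {self.shape} too small to hold lungs")


def _ellipsoid(shape, center, half_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, half_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_thorax(spec: PhantomSpec = PhantomSpec()) -> tuple[Volume, LungMask]:
    """Generate a synthetic thorax and its exact lung mask.

    With ``noise_sd == 0`` voxel values take exactly the three configured
    levels. Generation is bit-reproducible for a fixed seed.
    """
    X, Y, Z = spec.shape
    cx, cy, cz = (X - 1) / 2.0, (Y - 1) / 2.0, (Z - 1) / 2.0
    body = _ellipsoid(spec.shape, (cx, cy, cz),
                      (spec.body_axes[0] * X, spec.body_axes[1] * Y, spec.body_axes[2] * Z))
    lung_half = (spec.lung_axes[0] * X, spec.lung_axes[1] * Y, spec.lung_axes[2] * Z)
    offset = spec.lung_offset * X
    left = _ellipsoid(spec.shape, (cx - offset, cy, cz), lung_half)
    right = _ellipsoid(spec.shape, (cx + offset, cy, cz), lung_half)
    lungs = left | right
    if not lungs.any():
        raise ValueError("degenerate geometry: no lung voxels")
    if (lungs & ~body).any():
        raise ValueError("invalid geometry: lungs extend outside the body")

    data = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    data[body] = spec.body_intensity
    data[lungs] = spec.lung_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = np.clip(data + rng.normal(0.0, spec.noise_sd, spec.shape), 0.0, 1.0)
    vol = Volume(data=data, spacing=spec.spacing, normalized=True)
    return vol, LungMask(data=lungs)


def left_lung_center(spec: PhantomSpec) -> tuple[float, float, float]:
    """Voxel center of the left lung ellipsoid — a safe tumor site."""
    X, Y, Z = spec.shape
    return ((X - 1) / 2.0 - spec.lung_offset * X, (Y - 1) / 2.0, (Z - 1) / 2.0)


def insert_tumor(
    v: Volume,
    mask: LungMask,
    diameter_mm: float,
    center: tuple[float, float, float],
    intensity: float = 0.6,
) -> Volume:
    """Paint a bright spherical tumor of ``diameter_mm`` into the lung.

    The sphere is rasterized in millimetres, respecting anisotropic
    spacing — with 5 mm slices a 10 mm tumor may span only a couple of
    sections, which mirrors real thick-slice exams. At least the center
    voxel is always set. The whole sphere must lie inside the lung mask.
    """
    if not 10.0 <= diameter_mm <= 60.0:
        warnings.warn(
            f"tumor diameter {diameter_mm} mm outside the studied 10-60 mm range",
            stacklevel=2,
        )
    if mask.shape != v.shape:
        raise ValueError("mask and volume shapes differ")
    radius = diameter_mm / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in v.shape)]
    dist2 = np.zeros(v.shape, dtype=np.float64)
    for g, c, sp in zip(grids, center, v.spacing):
        dist2 = dist2 + ((g - c) * sp) ** 2
    sphere = dist2 <= radius**2
    cidx = tuple(int(round(c)) for c in center)
    if not sphere.any():
        sphere = np.zeros(v.shape, dtype=bool)
        sphere[cidx] = True  # degenerate sub-voxel sphere
    outside = sphere & ~mask.data
    if outside.any():
        first = tuple(int(x) for x in np.argwhere(outside)[0])
        raise ValueError(
            f"tumor sphere exits the lung mask, first offending voxel {first}"
        )
    out = v.copy()
    out.data[sphere] = intensity
    return out


@dataclass(frozen=True)
class PerturbationSpec:
    """Random misalignment drawn from small fixed sets.

    Matching the follow-up simulation protocol: translation of 1 or 2
    voxels per axis, rotation of −1° or −2° per axis, uniform scale 1.01
    and shear −0.01. ``symmetric=True`` additionally randomizes the signs
    of translations and rotations for broader testing.
    """

    translation_choices: tuple[float, ...] = (1.0, 2.0)
    rotation_choices: tuple[float, ...] = (-1.0, -2.0)
    scale: float = 1.01
    shear: float = -0.01
    symmetric: bool = False
    seed: int | None = 0
    identity: bool = False  # override: apply no transformation at all


def draw_perturbation(spec: PerturbationSpec) -> AffineParams:
    """Draw the ground-truth affine parameters for one perturbation."""
    if spec.identity:
        return AffineParams()
    rng = np.random.default_rng(spec.seed)
    t = rng.choice(spec.translation_choices, size=3)
    r = rng.choice(spec.rotation_choices, size=3)
    if spec.symmetric:
        t = t * rng.choice([-1.0, 1.0], size=3)
        r = r * rng.choice([-1.0, 1.0], size=3)
    return AffineParams(
        t=tuple(float(x) for x in t),
        r=tuple(float(x) for x in r),
        s=(spec.scale,) * 3,
        h=(spec.shear,) * 3,
    )


def perturb(
    v: Volume,
    spec: PerturbationSpec = PerturbationSpec(),
    center: tuple[float, float, float] | None = None,
) -> tuple[Volume, AffineParams]:
    """Apply a randomly drawn affine misalignment to a volume.

    Returns the resampled volume together with the ground-truth parameters
    so recovery can be scored. Rotation/scale/shear act about ``center``
    (default: the volume center).
    """
    params = draw_perturbation(spec)
    if center is None:
        center = tuple((s - 1) / 2.0 for s in v.shape)
    m = to_matrix(params, center=center, spacing=v.spacing)
    return resample(v, m), params
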