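"""3D affine transforms: parameterization, composition, resampling.

The search space has 12 parameters: translation (voxels of the fixed
grid), rotation (degrees about the x, y, z axes), per-axis scale, and
three upper-triangular shear coefficients. Matrices are 4×4 homogeneous
and act on voxel coordinates; rotation/scale/shear are applied in physical
(mm) space about a configurable center — normally the fixed exam's lung
center of mass — so anisotropic voxel spacing is respected.

Composition order (fixed and documented; the search treats parameters
independently, so any consistent order works)::

    M = T(t) · C · D⁻¹ · Rz · Ry · Rx · S · H · D · C⁻¹

where C recenters on ``center`` (voxels) and D = diag(spacing) converts
voxels to mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import Volume

__all__ = [
    "AffineParams",
    "PARAM_NAMES",
    "to_matrix",
    "resample",
    "compose",
    "invert",
    "identity_matrix",
]

PARAM_NAMES = ("tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz", "hxy", "hxz", "hyz")


@dataclass(frozen=True)
class AffineParams:
    """The 12 affine search parameters. Identity: t=0, r=0, s=1, h=0."""

    t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    r: tuple[float, float, float] = (0.0, 0.0, 0.0)
    s: tuple[float, float, float] = (1.0, 1.0, 1.0)
    h: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.s):
            raise ValueError(f"scale factors must be positive, got {self.s}")

    def as_vector(self) -> np.ndarray:
        return np.array(self.t + self.r + self.s + self.h, dtype=np.float64)

    @classmethod
    def from_vector(cls, vec) -> "AffineParams":
        v = np.asarray(vec, dtype=np.float64)
        if v.shape != (12,):
            raise ValueError(f"expected 12 parameters, got shape {v.shape}")
        return cls(t=tuple(v[0:3]), r=tuple(v[3:6]), s=tuple(v[6:9]), h=tuple(v[9:12]))

    def replace_param(self, name: str, value: float) -> "AffineParams":
        vec = self.as_vector()
        vec[PARAM_NAMES.index(name)] = value
        return AffineParams.from_vector(vec)

    def get_param(self, name: str) -> float:
        return float(self.as_vector()[PARAM_NAMES.index(name)])

    def to_json(self) -> str:
        return json.dumps(dict(zip(PARAM_NAMES, self.as_vector().tolist())))

    @classmethod
    def from_json(cls, text: str) -> "AffineParams":
        d = json.loads(text)
        return cls.from_vector([d[k] for k in PARAM_NAMES])


def _translation(t) -> np.ndarray:
    m = np.eye(4)
    m[:3, 3] = t
    return m


def _rotations(rx: float, ry: float, rz: float) -> np.ndarray:
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rxm = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rym = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rzm = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rzm @ rym @ rxm


def to_matrix(
    p: AffineParams,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Build the 4×4 voxel-space homogeneous matrix for ``p``.

    ``center`` is the rotation/scale/shear center in voxel coordinates;
    ``spacing`` converts voxels to mm so angles mean the same thing on
    anisotropic grids. Translation is in voxels of the target grid.
    """
    lin_mm = _rotations(*p.r) @ np.diag(p.s) @ np.array(
        [[1.0, p.h[0], p.h[1]], [0.0, 1.0, p.h[2]], [0.0, 0.0, 1.0]]
    )
    d = np.diag(spacing)
    lin_vox = np.linalg.inv(d) @ lin_mm @ d
    core = np.eye(4)
    core[:3, :3] = lin_vox
    c = np.asarray(center, dtype=np.float64)
    return _translation(p.t) @ _translation(c) @ core @ _translation(-c)


def identity_matrix() -> np.ndarray:
    return np.eye(4)


def compose(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Matrix product; applying ``compose(a, b)`` equals applying b then a."""
    return np.asarray(outer) @ np.asarray(inner)


def invert(m: np.ndarray) -> np.ndarray:
    return np.linalg.inv(np.asarray(m))


def resample(
    moving: Volume,
    matrix: np.ndarray,
    out_shape: tuple[int, int, int] | None = None,
    order: int = 1,
    cval: float = 0.0,
) -> Volume:
    """Pull the moving volume through ``matrix`` onto the output grid.

    Output voxel x takes the moving volume's value at ``matrix⁻¹ · x`` via
    trilinear interpolation (``order=1``; use 0 for masks). Voxels mapping
    outside the field of view are filled with ``cval`` (background 0).
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4×4 matrix, got {m.shape}")
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise ValueError("singular transform matrix cannot be resampled")
    shape = tuple(out_shape) if out_shape is not None else moving.shape
    if np.allclose(m, np.eye(4)) and shape == moving.shape:
        return moving.copy()
    minv = np.linalg.inv(m)
    data = ndimage.affine_transform(
        np.asarray(moving.data, dtype=np.float64),
        minv[:3, :3],
        offset=minv[:3, 3],
        output_shape=shape,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=order > 1,
    )
    out = moving.copy()
    out.data = data
    return out
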