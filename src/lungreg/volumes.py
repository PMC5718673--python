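"""Volume I/O and grid-level operations.

A :class:`Volume` is a 3D intensity grid indexed ``(i, j, k)`` where ``i``
and ``j`` are the two axial axes (X, Y) and ``k`` the longitudinal axis (Z).
Indices are 0-based; cuboids are half-open. Voxel spacing is in millimetres.
Every other module builds on these conventions.

Supported on-disk formats: NIfTI (.nii / .nii.gz, via nibabel), MetaImage
(.mha / .mhd, via SimpleITK) and — read-only, for fixtures — a directory of
2D raster slices stacked along Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "Cuboid",
    "read_volume",
    "write_volume",
    "normalize",
    "downsize_axial",
    "mip_crop",
]

_SLICE_EXTENSIONS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class Volume:
    """3D grayscale volume with voxel spacing and provenance flags."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    normalized: bool = False
    cropped: bool = False
    downsized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"every shape component must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class Cuboid:
    """Half-open axis-aligned voxel box: ``lo`` inclusive, ``hi`` exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"cuboid must satisfy lo < hi componentwise: {self.lo} vs {self.hi}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "slice_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise ValueError(f"cannot infer volume format from {path}")


def read_volume(
    path: str | Path,
    format: str | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> Volume:
    """Read a volume from disk with intensities as stored (no normalization).

    Parameters
    ----------
    path:
        File (NIfTI / MetaImage) or directory of 2D slices.
    format:
        One of ``{"nifti", "metaimage", "slice_dir"}``; inferred from the
        path when omitted.
    spacing:
        Voxel spacing override in mm. Required for slice directories, which
        carry no spacing metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
        sp = spacing or tuple(float(z) for z in img.header.get_zooms()[:3])
        return Volume(data=np.asarray(data, dtype=np.float64), spacing=sp)

    if fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); our convention is (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        sp = spacing or tuple(float(z) for z in img.GetSpacing())
        return Volume(data=np.asarray(data, dtype=np.float64), spacing=sp)

    if fmt == "slice_dir":
        if spacing is None:
            raise ValueError("slice directories carry no spacing metadata; pass spacing=")
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS)
        if not files:
            raise ValueError(f"no slice images found in {path}")
        lowered = [f.name.lower() for f in files]
        if len(set(lowered)) != len(lowered):
            raise ValueError("ambiguous slice ordering: filenames differ only by case")
        slices = []
        for f in files:
            arr = np.asarray(iio.imread(f))
            if arr.ndim == 3:  # collapse RGB(A) fixtures to grayscale
                arr = arr[..., :3].mean(axis=-1)
            if arr.ndim != 2:
                raise ValueError(f"slice {f} is not a 2D image")
            slices.append(arr.T)  # image rows are y → transpose to (x, y)
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
        data = np.stack(slices, axis=2).astype(np.float64)
        return Volume(data=data, spacing=spacing)

    raise ValueError(f"unknown format {fmt!r}")


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume to NIfTI or MetaImage, storing spacing in the header."""
    path = Path(path)
    fmt = _infer_format(path) if path.suffix else "slice_dir"
    if fmt == "nifti":
        affine = np.diag(list(v.spacing) + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float64), affine), str(path))
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(np.asarray(v.data, dtype=np.float64).transpose(2, 1, 0))
        img.SetSpacing(v.spacing)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError("slice directories are read-only fixtures; write NIfTI or MetaImage")


def normalize(v: Volume) -> Volume:
    """Linearly rescale intensities so min → 0 and max → 1.

    A constant volume has no scale; it maps to all-zeros with a warning so
    degenerate inputs remain processable.
    """
    data = np.asarray(v.data, dtype=np.float64)
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        warnings.warn("normalize: constant-intensity volume maps to all zeros", stacklevel=2)
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return replace(v, data=out, normalized=True)


def downsize_axial(v: Volume, target_xy: int) -> Volume:
    """Reduce the two axial dimensions to ``target_xy`` by block averaging.

    The longitudinal dimension is kept constant and the axial spacing grows
    by the inverse ratio, preserving physical extent. Block averaging acts
    as an anti-alias filter, keeping the similarity metrics stable. Only
    integer reduction factors are supported; upsampling is out of scope.
    """
    X, Y, Z = v.shape
    if target_xy > X or target_xy > Y:
        raise ValueError(f"target {target_xy} exceeds axial size {(X, Y)}; upsampling unsupported")
    if X % target_xy or Y % target_xy:
        raise ValueError(f"target {target_xy} must divide the axial sizes {(X, Y)} exactly")
    fx, fy = X // target_xy, Y // target_xy
    data = v.data.reshape(target_xy, fx, target_xy, fy, Z).mean(axis=(1, 3))
    sx, sy, sz = v.spacing
    return replace(v, data=data, spacing=(sx * fx, sy * fy, sz), downsized=True)


def mip_crop(v: Volume, mask, margin: int = 0) -> tuple[Volume, Cuboid]:
    """Crop to the smallest cuboid containing the lung mask, plus a margin.

    Returns the restricted volume and the (clipped) cuboid. The cuboid is
    the tight bounding box of mask voxels dilated by ``margin`` voxels on
    every face and clipped to the volume extent.
    """
    mask_data = np.asarray(getattr(mask, "data", mask), dtype=bool)
    if mask_data.shape != v.shape:
        raise ValueError(f"mask shape {mask_data.shape} != volume shape {v.shape}")
    coords = np.argwhere(mask_data)
    if coords.size == 0:
        raise ValueError("empty mask: lung segmentation failed upstream")
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + margin, v.shape)
    box = Cuboid(lo=tuple(int(x) for x in lo), hi=tuple(int(x) for x in hi))
    out = replace(v, data=v.data[box.slices].copy(), cropped=True)
    return out, box
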