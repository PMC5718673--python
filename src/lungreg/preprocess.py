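"""Preprocessing: denoising, lung extraction, center-of-mass pre-alignment.

The registration pipeline denoises each exam with a geometric mean filter,
extracts the pulmonary region as a binary volume, and uses the difference
of the two lung centers of mass as the initial translation — a cheap coarse
alignment that the parameter search then refines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .volumes import Volume

__all__ = [
    "LungMask",
    "SegmentationError",
    "geometric_mean_filter",
    "segment_lungs",
    "center_of_mass",
    "prealign",
]

# floor applied before the window product; a single zero pixel would
# otherwise annihilate the whole neighborhood
GEOMETRIC_EPS = 1.0 / 1024.0


class SegmentationError(ValueError):
    """No plausible pulmonary region could be extracted."""


@dataclass
class LungMask:
    """Binary pulmonary-region volume aligned with its parent Volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def geometric_mean_filter(v: Volume, window: tuple[int, int] = (3, 3)) -> Volume:
    """Slice-wise geometric mean filter with an m×n axial window.

    Each output pixel is the product of the gray levels in its m×n
    neighborhood raised to 1/(m·n). It smooths multiplicative CT noise
    while preserving more edge detail than the arithmetic mean. Borders are
    edge-replicated; intensities are floored at ``GEOMETRIC_EPS`` so zero
    background pixels do not zero out entire windows.
    """
    m, n = window
    if m < 1 or n < 1 or m % 2 == 0 or n % 2 == 0:
        raise ValueError(f"window sides must be odd and >= 1, got {window}")
    if m == 1 and n == 1:
        return v.copy()
    log_data = np.log(np.maximum(np.asarray(v.data, dtype=np.float64), GEOMETRIC_EPS))
    # mean of logs over the window == log of the geometric mean
    out = np.empty_like(log_data)
    for k in range(v.shape[2]):
        out[:, :, k] = ndimage.uniform_filter(log_data[:, :, k], size=(m, n), mode="nearest")
    return replace(v, data=np.exp(out))


def segment_lungs(v: Volume, max_components: int = 2) -> LungMask:
    """Extract the pulmonary region from a normalized thoracic volume.

    Lungs are air-filled, so they appear as the large low-intensity
    components interior to the bright body: threshold with Otsu's method,
    keep the dark side, discard components touching the axial image border
    (air outside the patient), retain the largest ``max_components``
    components in 3D, and fill holes slice by slice so dense structures
    inside the lungs (vessels, tumors) are included in the region.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if not v.normalized and (data.min() < 0 or data.max() > 1):
        raise ValueError("segment_lungs expects a normalized volume (intensities in [0, 1])")
    if data.min() == data.max():
        raise SegmentationError("constant volume has no lung candidates")

    # candidate thresholds, two-class Otsu first; when the image carries a
    # dominant background class the two-class split can separate background
    # from everything else and leave no air inside the body, so fall back
    # to the three-class thresholds from dark to bright
    thresholds = [float(threshold_otsu(data))]
    try:
        thresholds += [float(t) for t in threshold_multiotsu(data, classes=3)]
    except ValueError:
        pass  # fewer than 3 distinct gray levels

    # Otsu thresholds are 256-bin centers; a discrete gray level belonging
    # to the boundary bin can sit up to half a bin above the returned
    # value, so compare with half-bin slack (negligible for continuous data)
    half_bin = (data.max() - data.min()) / 512.0
    keep: list[int] = []
    for thresh in thresholds:
        dark = data <= thresh + half_bin
        if not dark.any():
            continue
        labels, n_labels = ndimage.label(dark)
        if n_labels == 0:
            continue
        border = np.zeros_like(dark)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border_labels = set(np.unique(labels[border & dark]))
        sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n_labels + 1))
        keep = [
            int(lab)
            for lab in np.argsort(sizes)[::-1] + 1
            if lab not in border_labels
        ][:max_components]
        if keep:
            break
    if not keep:
        raise SegmentationError(
            "no interior low-intensity component at any candidate threshold"
        )

    mask = np.isin(labels, keep)
    for k in range(mask.shape[2]):
        mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    return LungMask(data=mask)


def center_of_mass(mask: LungMask) -> tuple[float, float, float]:
    """Unweighted mean voxel coordinate of the mask, in (fractional) voxels."""
    coords = np.argwhere(mask.data)
    if coords.size == 0:
        raise ValueError("empty mask has no center of mass")
    cx, cy, cz = coords.mean(axis=0)
    return float(cx), float(cy), float(cz)


def prealign(fixed_mask: LungMask, moving_mask: LungMask) -> tuple[float, float, float]:
    """Translation (voxels) aligning the moving lung centroid onto the fixed one.

    Returns ``center_of_mass(fixed) - center_of_mass(moving)``; applying it
    to the moving volume makes the two mass centers coincide.
    """
    cf = center_of_mass(fixed_mask)
    cm = center_of_mass(moving_mask)
    return tuple(f - m for f, m in zip(cf, cm))  # type: ignore[return-value]
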