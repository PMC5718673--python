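"""End-to-end pair registration: preprocessing chain + search strategy.

Order of operations for a pair of exams: normalize → denoise (for
segmentation) → segment lungs → optional axial downsize → crop both
exams to the union lung cuboid (one common grid) → center-of-mass
pre-alignment → parameter search. The three-stage metric report (raw,
after pre-alignment, after search) is computed for all six metrics on the
final common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .preprocess import (
    LungMask,
    center_of_mass,
    geometric_mean_filter,
    prealign,
    segment_lungs,
)
from .registration import (
    RegistrationResult,
    SearchSchedule,
    STRATEGIES,
)
from .transforms import AffineParams, to_matrix, resample
from .volumes import Cuboid, Volume, downsize_axial, normalize

__all__ = ["MetricReport", "PairResult", "preprocess_exam", "register_pair"]


@dataclass(frozen=True)
class MetricReport:
    """One metric's value at the three pipeline stages."""

    name: str
    start_value: float
    prealigned_value: float
    final_value: float

    @property
    def gain(self) -> float:
        """Signed final-minus-prealigned change of this metric."""
        return self.final_value - self.prealigned_value

    @property
    def interval_width(self) -> float:
        """Size of the interval between the prealigned and final values.

        The per-run sensitivity statistic: how strongly this metric
        responds to the alignment change produced by the search. For the
        metric the search optimized this equals ``gain`` (which is then
        guaranteed non-negative).
        """
        return abs(self.final_value - self.prealigned_value)


@dataclass
class PairResult:
    """Everything produced by one pair registration."""

    result: RegistrationResult
    reports: dict[str, MetricReport]
    prealign_translation: tuple[float, float, float]
    cuboid: Cuboid | None
    fixed: Volume
    moving: Volume
    fixed_mask: LungMask
    moving_mask: LungMask
    center: tuple[float, float, float]


def preprocess_exam(
    v: Volume,
    mask: LungMask | None = None,
    filter_window: tuple[int, int] = (3, 3),
    target_xy: int | None = None,
) -> tuple[Volume, LungMask]:
    """Normalize, segment (unless a mask is supplied) and optionally downsize.

    The geometric mean filter is applied only to the segmentation input;
    similarity metrics are evaluated on the unfiltered normalized volume.
    """
    vol = v if v.normalized else normalize(v)
    if mask is None:
        mask = segment_lungs(geometric_mean_filter(vol, filter_window))
    if target_xy is not None and target_xy < vol.shape[0]:
        vol = downsize_axial(vol, target_xy)
        fx = v.shape[0] // target_xy
        fy = v.shape[1] // target_xy
        coarse = mask.data.reshape(target_xy, fx, target_xy, fy, v.shape[2]).mean(axis=(1, 3))
        mask = LungMask(data=coarse >= 0.5)
    return vol, mask


def _union_cuboid(a: LungMask, b: LungMask, margin: int, shape) -> Cuboid:
    coords = np.vstack([np.argwhere(a.data), np.argwhere(b.data)])
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + margin, shape)
    return Cuboid(lo=tuple(int(x) for x in lo), hi=tuple(int(x) for x in hi))


def register_pair(
    fixed: Volume,
    moving: Volume,
    metric: str = "r",
    method: str = "stepwise",
    fixed_mask: LungMask | None = None,
    moving_mask: LungMask | None = None,
    schedule: SearchSchedule | None = None,
    bins: int = _metrics.DEFAULT_BINS,
    target_xy: int | None = None,
    crop: bool = True,
    crop_margin: int = 2,
    method_options: dict | None = None,
) -> PairResult:
    """Register ``moving`` onto ``fixed`` and report all six metrics.

    Both exams are cropped to the union of their lung bounding boxes so
    they stay on a single common grid (cropping each to its own cuboid
    would decouple their coordinates). The center-of-mass translation is
    folded into the search start, and rotations/scales/shears act about
    the fixed exam's lung centroid.
    """
    if method not in STRATEGIES:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(STRATEGIES)}")
    fvol, fmask = preprocess_exam(fixed, mask=fixed_mask, target_xy=target_xy)
    mvol, mmask = preprocess_exam(moving, mask=moving_mask, target_xy=target_xy)
    if fvol.shape != mvol.shape:
        raise ValueError(
            f"fixed and moving grids differ after preprocessing: "
            f"{fvol.shape} vs {mvol.shape}"
        )

    box: Cuboid | None = None
    if crop:
        box = _union_cuboid(fmask, mmask, crop_margin, fvol.shape)
        fvol = Volume(fvol.data[box.slices].copy(), fvol.spacing,
                      normalized=fvol.normalized, cropped=True)
        mvol = Volume(mvol.data[box.slices].copy(), mvol.spacing,
                      normalized=mvol.normalized, cropped=True)
        fmask = LungMask(fmask.data[box.slices].copy())
        mmask = LungMask(mmask.data[box.slices].copy())

    shift = prealign(fmask, mmask)
    start = AffineParams(t=shift)
    center = center_of_mass(fmask)

    kwargs = dict(method_options or {})
    if method == "stepwise":
        kwargs.setdefault("schedule", schedule or SearchSchedule.from_width(fvol.shape[0]))
    result = STRATEGIES[method](
        fvol, mvol, metric=metric, start=start, center=center, bins=bins, **kwargs
    )

    reports = _three_stage_reports(fvol, mvol, start, result.params, center, bins)
    return PairResult(
        result=result,
        reports=reports,
        prealign_translation=shift,
        cuboid=box,
        fixed=fvol,
        moving=mvol,
        fixed_mask=fmask,
        moving_mask=mmask,
        center=center,
    )


def _three_stage_reports(fvol, mvol, start, final, center, bins):
    stages = {}
    for label, params in (("start", AffineParams()), ("prealigned", start),
                          ("final", final)):
        m = to_matrix(params, center=center, spacing=fvol.spacing)
        warped = resample(mvol, m, out_shape=fvol.shape)
        stages[label] = {mv.name: mv.value for mv in
                         _metrics.evaluate_all(fvol, warped, bins=bins)}
    return {
        name: MetricReport(
            name=name,
            start_value=stages["start"][name],
            prealigned_value=stages["prealigned"][name],
            final_value=stages["final"][name],
        )
        for name in _metrics.METRIC_NAMES
    }
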