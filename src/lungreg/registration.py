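"""Registration strategies over the 12-parameter affine space.

The package's central method is :func:`stepwise_register`, a hierarchical
per-parameter search: each transform parameter is optimized on its own
coarse-to-fine grid while all others are held at their current best, in
the order translation → rotation-x → rotation-y → rotation-z → scale →
shear, and the whole sweep is repeated for a second pass from the pass-1
optimum with halved ranges. Because parameters are searched one at a time,
the number of metric evaluations grows *additively* in the parameters
instead of multiplicatively as in the exhaustive grid baseline
(:func:`grid_register`), which is the source of the method's speed.

Two derivative-free optimizers are provided for comparison:
Nelder–Mead simplex (:func:`simplex_register`, via scipy) and coordinate
pattern search (:func:`pattern_search_register`).

All strategies maximize a normalized similarity metric (default:
correlation) and share the convention that the moving volume is resampled
onto the fixed grid before each metric evaluation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .metrics import DEFAULT_BINS, get_metric
from .transforms import PARAM_NAMES, AffineParams, to_matrix, resample
from .volumes import Volume

__all__ = [
    "SearchSchedule",
    "RegistrationResult",
    "RegistrationError",
    "stepwise_register",
    "grid_register",
    "sequential_grid_register",
    "simplex_register",
    "pattern_search_register",
]

# parameter-group membership and the fixed visiting order of the search
_GROUP_OF = {
    "tx": "translation", "ty": "translation", "tz": "translation",
    "rx": "rotation", "ry": "rotation", "rz": "rotation",
    "sx": "scale", "sy": "scale", "sz": "scale",
    "hxy": "shear", "hxz": "shear", "hyz": "shear",
}
_SEARCH_ORDER = ("tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz", "hxy", "hxz", "hyz")


class RegistrationError(RuntimeError):
    """The search aborted (invalid schedule or metric failure)."""


@dataclass(frozen=True)
class GroupSchedule:
    """Coarse-to-fine grid for one parameter group."""

    initial_step: float
    initial_range: float  # symmetric half-range about the start value
    stop_threshold: float
    halving_factor: float = 2.0

    def __post_init__(self) -> None:
        if not (self.initial_step > self.stop_threshold > 0):
            raise ValueError(
                f"need initial_step > stop_threshold > 0, got "
                f"{self.initial_step} vs {self.stop_threshold}"
            )
        if self.initial_range < self.initial_step:
            raise ValueError("range must be at least one step wide")
        if self.halving_factor <= 1:
            raise ValueError("halving factor must exceed 1")

    def step_sequence(self) -> list[float]:
        """Steps actually used: start at initial_step, divide until below stop."""
        steps = []
        s = self.initial_step
        while s >= self.stop_threshold:
            steps.append(s)
            s /= self.halving_factor
        return steps


@dataclass(frozen=True)
class SearchSchedule:
    """Per-group search grids plus the pass count.

    The canonical schedule derives the translation grid from the exam
    width: step = width/8 over ±width/4, halving until the step drops
    below one voxel. Rotation searches ±15° with a 7.5° step, scale
    1 ± 0.14 with step 0.07, shear ±0.14 with step 0.07. Stop thresholds
    for rotation/scale/shear are roughly sub-voxel at a 128-voxel field
    and configurable.
    """

    translation: GroupSchedule
    rotation: GroupSchedule
    scale: GroupSchedule
    shear: GroupSchedule
    passes: int = 2

    @classmethod
    def from_width(
        cls,
        width: float,
        passes: int = 2,
        rotation_stop: float = 0.25,
        scale_stop: float = 0.005,
        shear_stop: float = 0.005,
    ) -> "SearchSchedule":
        return cls(
            translation=GroupSchedule(width / 8.0, width / 4.0, 1.0),
            rotation=GroupSchedule(7.5, 15.0, rotation_stop),
            scale=GroupSchedule(0.07, 0.14, scale_stop),
            shear=GroupSchedule(0.07, 0.14, shear_stop),
            passes=passes,
        )

    def group(self, name: str) -> GroupSchedule:
        return getattr(self, name)


@dataclass
class RegistrationResult:
    """Outcome of one strategy run.

    ``initial_value`` is the metric at the start parameters (after any
    pre-alignment folded into them); the search contract guarantees
    ``final_value >= initial_value``. ``iterations`` counts metric
    evaluations — the only strategy-independent cost unit.
    """

    params: AffineParams
    metric_name: str
    initial_value: float
    final_value: float
    iterations: int
    trace: list[tuple[str, float, float]] = field(default_factory=list)


class _Objective:
    """Metric evaluation with caching and an evaluation counter."""

    def __init__(self, fixed: Volume, moving: Volume, metric: str,
                 center, bins: int = DEFAULT_BINS):
        self.fixed = fixed
        self.moving = moving
        self.metric_name = metric
        self.metric = get_metric(metric)
        self.center = center
        self.bins = bins
        self.evaluations = 0
        self._cache: dict[tuple, float] = {}

    def __call__(self, params: AffineParams) -> float:
        key = tuple(np.round(params.as_vector(), 9))
        if key in self._cache:
            return self._cache[key]
        m = to_matrix(params, center=self.center, spacing=self.fixed.spacing)
        warped = resample(self.moving, m, out_shape=self.fixed.shape)
        if self.metric_name.lower() in ("nh", "nmi"):
            mv = self.metric(self.fixed, warped, bins=self.bins)
        else:
            mv = self.metric(self.fixed, warped)
        if not math.isfinite(mv.value):
            raise RegistrationError(
                f"metric {self.metric_name} returned non-finite value at {params}"
            )
        self.evaluations += 1
        self._cache[key] = mv.value
        return mv.value


def _make_objective(fixed, moving, metric, center, bins):
    if center is None:
        center = tuple((s - 1) / 2.0 for s in fixed.shape)
    return _Objective(fixed, moving, metric, center, bins)


def _search_one_parameter(
    objective: _Objective,
    params: AffineParams,
    name: str,
    step0: float,
    stop: float,
    halving: float,
    trace: list,
) -> tuple[AffineParams, float]:
    """Coarse-to-fine line search on one parameter, all others held fixed.

    Each round evaluates five candidates (center ± {1, 2}·step), recenters
    on the best, and halves the step until it drops below the stop
    threshold. Ties prefer the candidate closest to the group's entry
    value (smallest change), then the first enumerated.
    """
    entry = params.get_param(name)
    center_val = entry
    best_params = params
    best_val = objective(params)
    step = step0
    is_scale = _GROUP_OF[name] == "scale"
    while step >= stop:
        candidates = [center_val + k * step for k in (-2, -1, 0, 1, 2)]
        if is_scale:
            candidates = [c for c in candidates if c > 1e-6]
        best_cand = None  # (value, |cand-entry|, enum index, cand, params)
        for idx, cand in enumerate(candidates):
            p = best_params.replace_param(name, cand)
            val = objective(p)
            trace.append((name, cand, val))
            key = (-val, abs(cand - entry), idx)
            if best_cand is None or key < best_cand[0]:
                best_cand = (key, cand, p, val)
        _, cand, p, val = best_cand
        if val >= best_val:
            best_val, best_params, center_val = val, p, cand
        step /= halving
    return best_params, best_val


def stepwise_register(
    fixed: Volume,
    moving: Volume,
    metric: str = "r",
    schedule: SearchSchedule | None = None,
    start: AffineParams | None = None,
    center: tuple[float, float, float] | None = None,
    bins: int = DEFAULT_BINS,
) -> RegistrationResult:
    """Hierarchical per-parameter affine search (the package's main method).

    Parameters are refined one at a time in a fixed order, each on its own
    coarse-to-fine grid; the full sweep is run ``schedule.passes`` times,
    later passes restarting every group from the previous optimum with the
    range and step divided by the halving factor. ``start`` should already
    contain the center-of-mass pre-alignment translation.
    """
    if schedule is None:
        schedule = SearchSchedule.from_width(fixed.shape[0])
    objective = _make_objective(fixed, moving, metric, center, bins)
    params = start or AffineParams()
    initial_value = objective(params)
    best_val = initial_value
    trace: list[tuple[str, float, float]] = []

    for pass_idx in range(schedule.passes):
        shrink = schedule.translation.halving_factor ** pass_idx
        for name in _SEARCH_ORDER:
            g = schedule.group(_GROUP_OF[name])
            step0 = g.initial_step / shrink
            if step0 < g.stop_threshold:
                continue  # range already refined below resolution
            params, best_val = _search_one_parameter(
                objective, params, name, step0, g.stop_threshold,
                g.halving_factor, trace,
            )
    return RegistrationResult(
        params=params,
        metric_name=metric,
        initial_value=initial_value,
        final_value=best_val,
        iterations=objective.evaluations,
        trace=trace,
    )


def grid_register(
    fixed: Volume,
    moving: Volume,
    metric: str = "r",
    grid: dict[str, list[float]] | None = None,
    start: AffineParams | None = None,
    center: tuple[float, float, float] | None = None,
    bins: int = DEFAULT_BINS,
    max_candidates: int = 20000,
) -> RegistrationResult:
    """Exhaustive Cartesian-product search (the traditional baseline).

    Every combination of the per-parameter value lists is evaluated, so
    the cost is the *product* of the grid sizes — tractable only for tiny
    grids, which is exactly the point of comparing against it. Grid values
    are offsets from ``start`` for translation/rotation/shear and factors
    applied to the start scale.
    """
    grid = grid or {}
    unknown = set(grid) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    start = start or AffineParams()
    names = [n for n in _SEARCH_ORDER if n in grid]
    value_lists = [grid[n] for n in names]
    total = int(np.prod([len(v) for v in value_lists])) if names else 1
    if total > max_candidates:
        raise RegistrationError(
            f"grid of {total} candidates exceeds cap {max_candidates}; "
            "shrink the per-parameter lists or raise max_candidates"
        )
    objective = _make_objective(fixed, moving, metric, center, bins)
    initial_value = objective(start)
    best_val, best_params = initial_value, start
    trace: list[tuple[str, float, float]] = []
    for combo in itertools.product(*value_lists) if names else [()]:
        p = start
        for name, delta in zip(names, combo):
            base = p.get_param(name)
            value = base * delta if _GROUP_OF[name] == "scale" else base + delta
            p = p.replace_param(name, value)
        val = objective(p)
        trace.append(("grid", float(len(trace)), val))
        if val > best_val:
            best_val, best_params = val, p
    return RegistrationResult(
        params=best_params, metric_name=metric, initial_value=initial_value,
        final_value=best_val, iterations=objective.evaluations, trace=trace,
    )


def sequential_grid_register(
    fixed: Volume,
    moving: Volume,
    metric: str = "r",
    grid: dict[str, list[float]] | None = None,
    start: AffineParams | None = None,
    center: tuple[float, float, float] | None = None,
    bins: int = DEFAULT_BINS,
    passes: int = 1,
) -> RegistrationResult:
    """Per-parameter sweep over explicit value lists (matched-grid variant).

    Searches exactly the same per-parameter candidate values as
    :func:`grid_register` would, but one parameter at a time holding the
    others at their current best — so the evaluation count is the *sum*
    of the grid sizes rather than their product. Used for like-for-like
    cost comparisons between the hierarchical and exhaustive strategies.
    Grid values are offsets from ``start`` (factors for scale).
    """
    grid = grid or {}
    unknown = set(grid) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    start = start or AffineParams()
    objective = _make_objective(fixed, moving, metric, center, bins)
    initial_value = objective(start)
    best_params, best_val = start, initial_value
    trace: list[tuple[str, float, float]] = []
    for _ in range(passes):
        for name in _SEARCH_ORDER:
            if name not in grid:
                continue
            base = start.get_param(name)
            for delta in grid[name]:
                value = base * delta if _GROUP_OF[name] == "scale" else base + delta
                p = best_params.replace_param(name, value)
                val = objective(p)
                trace.append((name, value, val))
                if val > best_val:
                    best_val, best_params = val, p
    return RegistrationResult(
        params=best_params, metric_name=metric, initial_value=initial_value,
        final_value=best_val, iterations=objective.evaluations, trace=trace,
    )


# simplex / pattern search: per-group step sizes used to scale the
# 12-dimensional space (voxels, degrees, scale and shear are not comparable
# units, so each coordinate gets its own natural increment)
_DEFAULT_DELTAS = {
    "translation": 2.0, "rotation": 2.0, "scale": 0.05, "shear": 0.05,
}


def _deltas_vector(deltas: dict[str, float]) -> np.ndarray:
    return np.array([deltas[_GROUP_OF[n]] for n in PARAM_NAMES])


def simplex_register(
    fixed: Volume,
    moving: Volume,
    metric: str = "r",
    start: AffineParams | None = None,
    center: tuple[float, float, float] | None = None,
    bins: int = DEFAULT_BINS,
    deltas: dict[str, float] | None = None,
    maxfev: int = 2000,
    xatol: float = 0.05,
    fatol: float = 1e-6,
) -> RegistrationResult:
    """Nelder–Mead simplex over the 12 parameters, minimizing 1 − metric.

    Standard reflection/expansion/contraction/shrink coefficients
    (1, 2, 0.5, 0.5). The initial simplex offsets each coordinate by its
    group's natural increment (voxels for translation, degrees for
    rotation, …).
    """
    start = start or AffineParams()
    objective = _make_objective(fixed, moving, metric, center, bins)
    initial_value = objective(start)
    d = _deltas_vector(deltas or _DEFAULT_DELTAS)
    x0 = start.as_vector()
    simplex = np.vstack([x0] + [x0 + d[i] * np.eye(12)[i] for i in range(12)])

    def cost(x: np.ndarray) -> float:
        x = x.copy()
        x[6:9] = np.maximum(x[6:9], 1e-3)  # keep scales positive
        return 1.0 - objective(AffineParams.from_vector(x))

    res = minimize(
        cost, x0, method="Nelder-Mead",
        options=dict(initial_simplex=simplex, maxfev=maxfev,
                     xatol=xatol, fatol=fatol),
    )
    x = res.x.copy()
    x[6:9] = np.maximum(x[6:9], 1e-3)
    best_params = AffineParams.from_vector(x)
    best_val = objective(best_params)
    if best_val < initial_value:  # never return a point worse than the start
        best_params, best_val = start, initial_value
    return RegistrationResult(
        params=best_params, metric_name=metric, initial_value=initial_value,
        final_value=best_val, iterations=objective.evaluations, trace=[],
    )


def pattern_search_register(
    fixed: Volume,
    moving: Volume,
    metric: str = "r",
    start: AffineParams | None = None,
    center: tuple[float, float, float] | None = None,
    bins: int = DEFAULT_BINS,
    deltas: dict[str, float] | None = None,
    tolerances: dict[str, float] | None = None,
    max_iterations: int = 10000,
) -> RegistrationResult:
    """Coordinate pattern search: poll ±step on each parameter in turn.

    Each iteration polls the 24-point pattern (±step_i on every
    coordinate); on improvement the incumbent moves to the best probe and
    the mesh is kept, otherwise every step is halved. The search stops
    when all steps fall below their group tolerances.
    """
    start = start or AffineParams()
    objective = _make_objective(fixed, moving, metric, center, bins)
    initial_value = objective(start)
    steps = _deltas_vector(deltas or _DEFAULT_DELTAS).copy()
    tols = _deltas_vector(tolerances or
                          {"translation": 0.5, "rotation": 0.25,
                           "scale": 0.005, "shear": 0.005})
    x = start.as_vector()
    best_val = initial_value
    trace: list[tuple[str, float, float]] = []
    while np.any(steps >= tols) and objective.evaluations < max_iterations:
        best_probe = None
        for i in range(12):
            if steps[i] < tols[i]:
                continue
            for sign in (+1.0, -1.0):
                probe = x.copy()
                probe[i] += sign * steps[i]
                if 6 <= i < 9 and probe[i] <= 0:
                    continue
                val = objective(AffineParams.from_vector(probe))
                trace.append((PARAM_NAMES[i], float(probe[i]), val))
                if val > best_val and (best_probe is None or val > best_probe[0]):
                    best_probe = (val, probe)
        if best_probe is None:
            steps /= 2.0
        else:
            best_val, x = best_probe[0], best_probe[1]
    return RegistrationResult(
        params=AffineParams.from_vector(x), metric_name=metric,
        initial_value=initial_value, final_value=best_val,
        iterations=objective.evaluations, trace=trace,
    )


STRATEGIES = {
    "stepwise": stepwise_register,
    "grid": grid_register,
    "sequential": sequential_grid_register,
    "simplex": simplex_register,
    "pattern": pattern_search_register,
}
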