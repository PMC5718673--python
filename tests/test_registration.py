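import itertools

import numpy as np
import pytest

from lungreg import PhantomSpec, make_thorax
from lungreg.registration import (
    GroupSchedule,
    RegistrationError,
    SearchSchedule,
    grid_register,
    pattern_search_register,
    sequential_grid_register,
    simplex_register,
    stepwise_register,
)
from lungreg.transforms import AffineParams, to_matrix, resample
from lungreg.volumes import Volume


@pytest.fixture(scope="module")
def small_thorax():
    """Coarse 32-voxel thorax: fast enough for many registrations."""
    spec = PhantomSpec(shape=(32, 32, 24), spacing=(10.24, 10.24, 10.0), seed=21)
    return make_thorax(spec)


@pytest.fixture(scope="module")
def shifted_pair(small_thorax):
    vol, _ = small_thorax
    m = to_matrix(AffineParams(t=(2, 1, 0)))
    return vol, resample(vol, m)


class TestSchedule:
    def test_width_128_step_sequence(self):
        sched = SearchSchedule.from_width(128)
        assert sched.translation.step_sequence() == [16, 8, 4, 2, 1]

    def test_rotation_scale_shear_initial_grids(self):
        sched = SearchSchedule.from_width(128)
        assert sched.rotation.initial_step == 7.5
        assert sched.rotation.initial_range == 15.0
        assert sched.scale.initial_step == 0.07
        assert sched.scale.initial_range == 0.14
        assert sched.shear.initial_step == 0.07

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            GroupSchedule(initial_step=0.5, initial_range=1.0, stop_threshold=1.0)
        with pytest.raises(ValueError):
            GroupSchedule(initial_step=2.0, initial_range=1.0, stop_threshold=0.5)


class TestStepwise:
    def test_self_registration_returns_identity(self, small_thorax):
        vol, _ = small_thorax
        res = stepwise_register(vol, vol, metric="r")
        assert res.final_value == pytest.approx(1.0)
        assert res.initial_value == pytest.approx(1.0)
        vec = res.params.as_vector()
        np.testing.assert_allclose(vec[:3], 0.0, atol=1.0)  # below stop threshold
        np.testing.assert_allclose(vec[3:6], 0.0, atol=0.25)

    def test_recovers_known_translation(self, shifted_pair):
        fixed, moving = shifted_pair
        res = stepwise_register(fixed, moving, metric="r")
        # moving = fixed pushed by (2,1,0); recovery is the inverse
        np.testing.assert_allclose(res.params.t, (-2, -1, 0), atol=1.0)
        assert res.final_value > res.initial_value

    def test_trace_monotone_over_parameter_completions(self, shifted_pair):
        fixed, moving = shifted_pair
        res = stepwise_register(fixed, moving, metric="r")
        # best-so-far after each parameter is non-decreasing
        best = res.initial_value
        for name in ("tx", "ty", "tz", "rx"):
            vals = [v for n, _, v in res.trace if n == name]
            if vals:
                assert max(vals) >= best - 1e-12
                best = max(max(vals), best)
        assert res.final_value >= res.initial_value

    def test_evaluation_count_additive_not_multiplicative(self, shifted_pair):
        fixed, moving = shifted_pair
        res = stepwise_register(fixed, moving, metric="r")
        sched = SearchSchedule.from_width(fixed.shape[0])
        per_param_rounds = sum(
            len(GroupSchedule(g.initial_step / 2**p, g.initial_range / 2**p,
                              g.stop_threshold).step_sequence())
            for p in range(2)
            for g in [sched.translation] * 3 + [sched.rotation] * 3
            + [sched.scale] * 3 + [sched.shear] * 3
            if g.initial_step / 2**p >= g.stop_threshold
        )
        # five candidates per round is the hard ceiling; caching reuses repeats
        assert res.iterations <= 5 * per_param_rounds


class TestGrid:
    def test_single_point_grid(self, small_thorax):
        vol, _ = small_thorax
        res = grid_register(vol, vol, metric="r", grid={"tx": [0.0]})
        assert res.iterations == 1
        assert res.final_value == pytest.approx(1.0)

    def test_matches_brute_force_argmax(self, shifted_pair):
        fixed, moving = shifted_pair
        values = [-3.0, -2.0, -1.0, 0.0, 1.0]
        res = grid_register(fixed, moving, metric="r",
                            grid={"tx": values, "ty": values})
        # independent enumeration of the same Cartesian product
        best = None
        from lungreg.metrics import correlation

        for dx, dy in itertools.product(values, values):
            warped = resample(moving, to_matrix(AffineParams(t=(dx, dy, 0))),
                              out_shape=fixed.shape)
            v = correlation(fixed, warped).value
            if best is None or v > best[0]:
                best = (v, dx, dy)
        assert res.final_value == pytest.approx(best[0])
        assert res.params.t[:2] == pytest.approx((best[1], best[2]))

    def test_cap_refused_with_guidance(self, small_thorax):
        vol, _ = small_thorax
        grid = {n: list(range(10)) for n in ("tx", "ty", "tz", "rx", "ry")}
        with pytest.raises(RegistrationError, match="cap"):
            grid_register(vol, vol, grid=grid, max_candidates=100)

    def test_identity_selected_when_present(self, small_thorax):
        vol, _ = small_thorax
        res = grid_register(vol, vol, metric="r", grid={"tx": [-1.0, 0.0, 1.0]})
        assert res.params.t[0] == 0.0


class TestSequentialGrid:
    def test_cost_is_sum_not_product(self, shifted_pair):
        fixed, moving = shifted_pair
        grid = {"tx": [-2.0, -1.0, 0.0, 1.0], "ty": [-2.0, -1.0, 0.0, 1.0]}
        seq = sequential_grid_register(fixed, moving, metric="r", grid=grid)
        exh = grid_register(fixed, moving, metric="r", grid=grid)
        assert seq.iterations < exh.iterations
        assert seq.iterations <= 1 + 4 + 4
        assert exh.final_value >= seq.final_value - 1e-12


def quadratic_volume_pair():
    """Tiny pair whose correlation surface is smooth and unimodal in tx."""
    rng = np.random.default_rng(5)
    base = Volume(rng.random((16, 12, 8)) + 0.5, normalized=False)
    moved = resample(base, to_matrix(AffineParams(t=(1.5, 0, 0))))
    return base, moved


class TestSimplex:
    def test_start_at_optimum_stays(self, small_thorax):
        vol, _ = small_thorax
        res = simplex_register(vol, vol, metric="r", maxfev=200)
        assert res.final_value == pytest.approx(1.0, abs=1e-6)

    def test_recovers_shift_within_voxel(self, shifted_pair):
        fixed, moving = shifted_pair
        res = simplex_register(fixed, moving, metric="r", maxfev=600)
        np.testing.assert_allclose(res.params.t, (-2, -1, 0), atol=1.0)

    def test_never_worse_than_start(self, shifted_pair):
        fixed, moving = shifted_pair
        res = simplex_register(fixed, moving, metric="r", maxfev=60)
        assert res.final_value >= res.initial_value


class TestPatternSearch:
    def test_maximum_at_start_only_shrinks(self, small_thorax):
        vol, _ = small_thorax
        res = pattern_search_register(vol, vol, metric="r", max_iterations=2000)
        assert res.final_value == pytest.approx(1.0)
        np.testing.assert_allclose(res.params.as_vector(),
                                   AffineParams().as_vector(), atol=1e-9)

    def test_recovers_shift_within_voxel(self, shifted_pair):
        fixed, moving = shifted_pair
        res = pattern_search_register(fixed, moving, metric="r")
        np.testing.assert_allclose(res.params.t, (-2, -1, 0), atol=1.0)
        assert res.final_value >= res.initial_value


def test_all_strategies_agree_on_identical_pair(small_thorax):
    vol, _ = small_thorax
    finals = [
        stepwise_register(vol, vol, metric="r").final_value,
        grid_register(vol, vol, metric="r", grid={"tx": [-1.0, 0.0, 1.0]}).final_value,
        simplex_register(vol, vol, metric="r", maxfev=100).final_value,
        pattern_search_register(vol, vol, metric="r").final_value,
    ]
    np.testing.assert_allclose(finals, 1.0, atol=1e-9)
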