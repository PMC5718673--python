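"""Metric correctness against independent brute-force oracles.

The oracles below re-derive every figure of merit with explicit Python
triple loops and dictionary histograms — no numpy vectorization shared
with the implementation — so agreement to 1e-10 is a genuine
cross-check.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lungreg.metrics import (
    METRIC_NAMES,
    correlation,
    evaluate_all,
    joint_histogram,
    ndisparity,
    nentropy,
    nmi,
    nsad,
    nssd,
)
from lungreg.volumes import Volume


# ---------------------------------------------------------------- oracles
def oracle_nssd(a, b):
    X, Y, Z = a.shape
    imax = max(a.max(), b.max())
    total = 0.0
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                total += (a[i, j, k] - b[i, j, k]) ** 2
    return 1.0 - total / (X * Y * Z * imax**2)


def oracle_nsad(a, b):
    X, Y, Z = a.shape
    imax = max(a.max(), b.max())
    total = 0.0
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                total += abs(a[i, j, k] - b[i, j, k])
    return 1.0 - total / (X * Y * Z * imax)


def oracle_correlation(a, b):
    num = sa = sb = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                num += a[i, j, k] * b[i, j, k]
                sa += a[i, j, k] ** 2
                sb += b[i, j, k] ** 2
    return num / math.sqrt(sa * sb)


def oracle_ndisparity(a, b):
    X, Y, Z = a.shape
    imax = max(a.max(), b.max())
    disagreements = 0
    for i in range(X):
        for j in range(Y):
            for k in range(Z):
                if (a[i, j, k] > imax / 2) != (b[i, j, k] > imax / 2):
                    disagreements += 1
    return 1.0 - disagreements / (X * Y * Z)


def oracle_joint_counts(a, b, bins):
    counts: dict[tuple[int, int], int] = {}
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                ba = min(int(a[i, j, k] * bins), bins - 1)
                bb = min(int(b[i, j, k] * bins), bins - 1)
                counts[(ba, bb)] = counts.get((ba, bb), 0) + 1
    return counts


def oracle_nentropy(a, b, bins):
    counts = oracle_joint_counts(a, b, bins)
    n = a.size
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return 1.75 - h


def oracle_nmi(a, b, bins):
    counts = oracle_joint_counts(a, b, bins)
    n = a.size
    pa: dict[int, float] = {}
    pb: dict[int, float] = {}
    for (ia, ib), c in counts.items():
        pa[ia] = pa.get(ia, 0.0) + c / n
        pb[ib] = pb.get(ib, 0.0) + c / n
    ha = -sum(p * math.log2(p) for p in pa.values())
    hb = -sum(p * math.log2(p) for p in pb.values())
    mi = sum(
        (c / n) * math.log2((c / n) / (pa[ia] * pb[ib]))
        for (ia, ib), c in counts.items()
    )
    return 2.0 * mi / (ha + hb)


ORACLES = {
    "nSSD": (nssd, oracle_nssd, False),
    "nSAD": (nsad, oracle_nsad, False),
    "R": (correlation, oracle_correlation, False),
    "nD": (ndisparity, oracle_ndisparity, False),
    "nH": (nentropy, oracle_nentropy, True),
    "nMI": (nmi, oracle_nmi, True),
}


@pytest.mark.parametrize("name", list(ORACLES))
@pytest.mark.parametrize("trial", range(5))
def test_matches_brute_force_oracle(name, trial, rng):
    impl, oracle, histogram_based = ORACLES[name]
    a = rng.random((5, 4, 3))
    b = rng.random((5, 4, 3))
    if histogram_based:
        got = impl(Volume(a, normalized=True), Volume(b, normalized=True), bins=8).value
        want = oracle(a, b, 8)
    else:
        got = impl(Volume(a, normalized=True), Volume(b, normalized=True)).value
        want = oracle(a, b)
    assert got == pytest.approx(want, abs=1e-10)


# ---------------------------------------------------------- hand examples
def vol(*values):
    return Volume(np.array(values, dtype=float).reshape(len(values), 1, 1),
                  normalized=True)


def test_nssd_hand_sum():
    assert nssd(vol(0, 0.5, 1), vol(1, 0.5, 0)).value == pytest.approx(1 - 2 / 3)


def test_nsad_hand_sum():
    assert nsad(vol(0, 0.5, 1), vol(1, 0.5, 0)).value == pytest.approx(1 - 2 / 3)


def test_correlation_hand_value():
    assert correlation(vol(1, 0), vol(1, 1)).value == pytest.approx(1 / math.sqrt(2))


def test_correlation_disjoint_support_is_zero():
    assert correlation(vol(1, 0, 2), vol(0, 3, 0)).value == 0.0


def test_correlation_all_zero_errors():
    with pytest.raises(ValueError):
        correlation(vol(0, 0), vol(1, 1))


def test_ndisparity_one_of_four():
    a = vol(0.9, 0.9, 0.1, 0.1)
    b = vol(0.9, 0.1, 0.1, 0.1)
    assert ndisparity(a, b).value == pytest.approx(0.75)


def test_ndisparity_complementary_binaries():
    assert ndisparity(vol(1, 0, 1), vol(0, 1, 0)).value == 0.0


def test_joint_histogram_diagonal_and_top_bin():
    h = joint_histogram(vol(0, 1), vol(0, 1), bins=2)
    np.testing.assert_array_equal(h.counts, [[1, 0], [0, 1]])
    assert h.n == 2


def test_joint_histogram_rejects_single_bin(small_pair):
    with pytest.raises(ValueError):
        joint_histogram(*small_pair, bins=1)


def test_nentropy_constant_pair_is_offset():
    # single occupied cell: joint entropy 0, score = the 1.75 offset
    assert nentropy(vol(0.3, 0.3), vol(0.7, 0.7), bins=4).value == pytest.approx(1.75)


def test_nentropy_uniform_four_cells():
    a = vol(0.1, 0.1, 0.9, 0.9)
    b = vol(0.1, 0.9, 0.1, 0.9)
    assert nentropy(a, b, bins=2).value == pytest.approx(1.75 - 2.0)


def test_nentropy_two_level_identity():
    a = vol(0.0, 1.0)
    assert nentropy(a, a, bins=2).value == pytest.approx(1.75 - 1.0)


def test_nmi_identical_two_level():
    a = vol(0, 1, 0, 1)
    assert nmi(a, a, bins=2).value == pytest.approx(1.0)


def test_nmi_perfectly_dependent_diagonal():
    # joint distribution [[0.5,0],[0,0.5]]: MI = 1 bit, H(A)=H(B)=1 bit
    assert nmi(vol(0, 1), vol(0, 1), bins=2).value == pytest.approx(1.0)


def test_nmi_both_constant_errors():
    with pytest.raises(ValueError):
        nmi(vol(0.5, 0.5), vol(0.5, 0.5), bins=4)


def test_independent_volumes_near_zero_mi(rng):
    a = Volume(rng.random((24, 24, 24)), normalized=True)
    b = Volume(rng.random((24, 24, 24)), normalized=True)
    assert nmi(a, b, bins=8).value == pytest.approx(0.0, abs=0.01)


# ------------------------------------------------------------- properties
@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    arrays(np.float64, (4, 3, 2), elements=st.floats(0, 1)),
    arrays(np.float64, (4, 3, 2), elements=st.floats(0, 1)),
)
def test_symmetry_and_bounds(a, b):
    va, vb = Volume(a, normalized=True), Volume(b, normalized=True)
    for fwd, rev in zip(evaluate_all(va, vb, bins=8), evaluate_all(vb, va, bins=8)):
        if fwd.error is None and rev.error is None:
            assert fwd.value == pytest.approx(rev.value, abs=1e-10)
        if fwd.error is None and fwd.name in ("nSSD", "nSAD", "nD"):
            assert -1e-12 <= fwd.value <= 1 + 1e-12
        if fwd.error is None and fwd.name in ("R", "nMI"):
            assert -1e-9 <= fwd.value <= 1 + 1e-9


def test_identity_pairs_score_one(rng):
    a = Volume(rng.random((6, 5, 4)), normalized=True)
    for mv in evaluate_all(a, a, bins=8):
        if mv.name == "nH":
            h = joint_histogram(a, a, bins=8)
            assert mv.value == pytest.approx(1.75 - h.joint_entropy())
        else:
            assert mv.value == pytest.approx(1.0)


def test_evaluate_all_complete_and_nssd_below_nsad(small_pair):
    out = evaluate_all(*small_pair)
    assert [mv.name for mv in out] == list(METRIC_NAMES)
    values = {mv.name: mv.value for mv in out}
    assert all(np.isfinite(v) for v in values.values())
    # |d| <= 1 on normalized images so d^2 <= |d|: nSSD >= ... penalty smaller
    assert values["nSSD"] >= values["nSAD"] - 1e-12


def test_evaluate_all_records_errors_instead_of_raising():
    a = vol(0.5, 0.5)
    out = {mv.name: mv for mv in evaluate_all(a, a, bins=4)}
    assert out["nMI"].error is not None and math.isnan(out["nMI"].value)
    assert out["nSSD"].error is None
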