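"""Normalized similarity metrics for pairs of equally shaped volumes.

All six figures of merit are rescaled so that (with the exception of the
joint-entropy score nH, which is an offset rather than a ratio) two
coincident images score 1 and two maximally different images score 0:

* ``nssd``  — 1 − ΣΔ² / (X·Y·Z·Imax²), normalized sum of squared differences
* ``nsad``  — 1 − Σ|Δ| / (X·Y·Z·Imax), normalized sum of absolute differences
* ``correlation`` (R) — Σ A·B / sqrt(ΣA² · ΣB²)
* ``ndisparity`` (nD) — 1 − mean XOR of the half-Imax binarizations
* ``nentropy`` (nH)   — 1.75 − H(A,B), H the joint Shannon entropy in bits
* ``nmi``   — 2·MI(A,B) / (H(A) + H(B)), the symmetric-uncertainty form

Imax is the joint maximum over both images. Displaced comparisons are
realized by resampling the moving volume onto the fixed grid first (see
:mod:`lungreg.transforms`); the metrics themselves always compare grids of
identical shape. Histogram-based metrics use a uniform joint histogram on
[0,1]² with 64 bins by default; intensity 1 falls in the last bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import Volume

__all__ = [
    "JointHistogram",
    "MetricValue",
    "METRIC_NAMES",
    "nssd",
    "nsad",
    "correlation",
    "ndisparity",
    "joint_histogram",
    "nentropy",
    "nmi",
    "evaluate_all",
    "get_metric",
]

METRIC_NAMES = ("nSSD", "nSAD", "R", "nD", "nH", "nMI")

#: offset constant for the joint-entropy score
ENTROPY_OFFSET = 1.75

DEFAULT_BINS = 64


@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float
    error: str | None = None


@dataclass(frozen=True)
class JointHistogram:
    """Joint intensity histogram of two normalized volumes."""

    counts: np.ndarray
    bins: int
    n: int

    @property
    def joint_p(self) -> np.ndarray:
        return self.counts / self.n

    def marginal_entropies(self) -> tuple[float, float]:
        p = self.joint_p
        return _entropy(p.sum(axis=1)), _entropy(p.sum(axis=0))

    def joint_entropy(self) -> float:
        return _entropy(self.joint_p.ravel())

    def mutual_information(self) -> float:
        ha, hb = self.marginal_entropies()
        return ha + hb - self.joint_entropy()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _as_array(v) -> np.ndarray:
    return np.asarray(v.data if isinstance(v, Volume) else v, dtype=np.float64)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    aa, bb = _as_array(a), _as_array(b)
    if aa.shape != bb.shape:
        raise ValueError(f"shape mismatch: {aa.shape} vs {bb.shape}")
    return aa, bb


def nssd(a, b) -> MetricValue:
    """Normalized sum of squared differences; 1 for coincident images."""
    aa, bb = _pair(a, b)
    imax = max(aa.max(), bb.max())
    if imax == 0:
        return MetricValue("nSSD", 1.0)  # both all-zero: no differences possible
    n1 = aa.size * imax**2
    return MetricValue("nSSD", float(1.0 - np.square(aa - bb).sum() / n1))


def nsad(a, b) -> MetricValue:
    """Normalized sum of absolute differences; 1 for coincident images."""
    aa, bb = _pair(a, b)
    imax = max(aa.max(), bb.max())
    if imax == 0:
        return MetricValue("nSAD", 1.0)
    n2 = aa.size * imax
    return MetricValue("nSAD", float(1.0 - np.abs(aa - bb).sum() / n2))


def correlation(a, b) -> MetricValue:
    """Normalized cross-correlation R = ΣAB / sqrt(ΣA²·ΣB²); 1 iff B ∝ A."""
    aa, bb = _pair(a, b)
    denom = np.sqrt(np.square(aa).sum() * np.square(bb).sum())
    if denom == 0:
        raise ValueError("correlation undefined for an all-zero volume")
    return MetricValue("R", float((aa * bb).sum() / denom))


def ndisparity(a, b) -> MetricValue:
    """1 − fraction of voxels whose half-Imax binarizations disagree (XOR)."""
    aa, bb = _pair(a, b)
    imax = max(aa.max(), bb.max())
    al = aa > imax / 2.0
    bl = bb > imax / 2.0
    return MetricValue("nD", float(1.0 - np.logical_xor(al, bl).mean()))


def joint_histogram(a, b, bins: int = DEFAULT_BINS) -> JointHistogram:
    """Joint histogram over uniform bins on [0,1]²; 1 lands in the top bin."""
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    aa, bb = _pair(a, b)
    counts, _, _ = np.histogram2d(
        aa.ravel(), bb.ravel(), bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    return JointHistogram(counts=counts, bins=bins, n=aa.size)


def nentropy(a, b, bins: int = DEFAULT_BINS) -> MetricValue:
    """Joint-entropy score 1.75 − H(A,B) in bits; not clamped to [0,1]."""
    h = joint_histogram(a, b, bins=bins)
    return MetricValue("nH", ENTROPY_OFFSET - h.joint_entropy())


def nmi(a, b, bins: int = DEFAULT_BINS) -> MetricValue:
    """Normalized mutual information 2·MI/(H(A)+H(B)) ∈ [0,1]."""
    h = joint_histogram(a, b, bins=bins)
    ha, hb = h.marginal_entropies()
    if ha + hb == 0:
        raise ValueError("nMI undefined when both volumes are constant")
    return MetricValue("nMI", float(2.0 * h.mutual_information() / (ha + hb)))


def evaluate_all(a, b, bins: int = DEFAULT_BINS) -> list[MetricValue]:
    """Evaluate all six metrics on one (already resampled) pair.

    Per-metric failures (e.g. a degenerate constant volume) are recorded in
    the returned :class:`MetricValue` rather than raised, so a full report
    row is always produced.
    """
    out: list[MetricValue] = []
    for name in METRIC_NAMES:
        try:
            out.append(get_metric(name)(a, b, bins=bins) if name in ("nH", "nMI")
                       else get_metric(name)(a, b))
        except ValueError as exc:
            out.append(MetricValue(name, float("nan"), error=str(exc)))
    return out


_REGISTRY = {
    "nssd": nssd,
    "nsad": nsad,
    "r": correlation,
    "nd": ndisparity,
    "nh": nentropy,
    "nmi": nmi,
}
_CANONICAL = {"nssd": "nSSD", "nsad": "nSAD", "r": "R", "nd": "nD", "nh": "nH", "nmi": "nMI"}


def get_metric(name: str):
    """Look up a metric by name (case-insensitive: nSSD, nSAD, R, nD, nH, nMI)."""
    key = name.lower()
    if key not in _REGISTRY:
        raise KeyError(f"unknown metric {name!r}; choose from {sorted(_REGISTRY)}")
    return _REGISTRY[key]


def canonical_name(name: str) -> str:
    return _CANONICAL[name.lower()]
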