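"""Response features: zero-lag correlation, mean rates, LFP spectral peaks.

The central similarity measure is the Pearson correlation coefficient of two
EPSP-smoothed spike trains x(t), y(t) of equal length n,

    Corr = sum_t (x(t) - <x>)(y(t) - <y>)
           / sqrt(sum_t (x(t) - <x>)^2 * sum_t (y(t) - <y>)^2),

evaluated at zero lag.  Traces with zero variance (e.g. no spikes in the
analysed segment) carry no discriminative evidence; their correlation is
defined as 0 with a logged warning so sparse data never aborts a
cross-validation run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocessing import BinnedSpikeTrain, EPSPTrace, LFPTrace

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentSpec",
    "FeatureVector",
    "correlation",
    "mean_rate",
    "rate_vector_50ms",
    "mean_abs_amplitude",
    "top_frequencies",
    "slice_trace",
]

FEATURE_KINDS = ("corr-template", "trace", "rate300", "rate50x6", "spec5")
_KIND_LENGTHS = {"rate300": 1, "rate50x6": 6, "spec5": 5}


@dataclass(frozen=True)
class SegmentSpec:
    """An analysis window [start, start + length) in seconds within a trial."""

    start: float
    length: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("segment start must be >= 0")
        if self.length <= 0:
            raise ValueError("segment length must be positive")

    def bin_slice(self, bin_width: float, t0: float = 0.0) -> slice:
        i0 = int(round((self.start - t0) / bin_width))
        i1 = i0 + int(round(self.length / bin_width))
        return slice(i0, i1)


@dataclass(frozen=True)
class FeatureVector:
    """Ordered real features extracted from one trial response."""

    values: np.ndarray
    kind: str
    source: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        want = _KIND_LENGTHS.get(self.kind)
        if want is not None and np.asarray(self.values).size != want:
            raise ValueError(f"{self.kind} requires exactly {want} entries")


def slice_trace(trace: EPSPTrace, segment: SegmentSpec) -> np.ndarray:
    """Extract a segment's values from an EPSP trace (1-ms grid)."""
    sl = segment.bin_slice(trace.bin_width, trace.t0)
    if sl.stop > trace.values.size:
        raise ValueError("segment extends past the trace")
    return trace.values[sl]


def correlation(x: np.ndarray | EPSPTrace, y: np.ndarray | EPSPTrace) -> float:
    """Zero-lag Pearson correlation of two equal-length trace segments."""
    xv = x.values if isinstance(x, EPSPTrace) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, EPSPTrace) else np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError(f"trace lengths differ ({xv.size} vs {yv.size})")
    if xv.size < 2:
        raise ValueError("need at least 2 samples")
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    den = np.sqrt((dx @ dx) * (dy @ dy))
    if den == 0.0:
        logger.warning("zero-variance trace in correlation; returning 0")
        return 0.0
    return float(np.clip((dx @ dy) / den, -1.0, 1.0))


def mean_rate(train: BinnedSpikeTrain, segment: SegmentSpec) -> float:
    """Mean firing rate (spikes/s) over the segment."""
    sl = segment.bin_slice(train.bin_width, train.t0)
    if sl.stop > train.counts.size:
        raise ValueError("segment extends past the trial")
    return float(train.counts[sl].sum() / segment.length)


def rate_vector_50ms(train: BinnedSpikeTrain, segment: SegmentSpec) -> np.ndarray:
    """Mean rates over six consecutive 50-ms windows of a 300-ms segment."""
    if abs(segment.length - 0.300) > 1e-9:
        raise ValueError("rate_vector_50ms requires a 300-ms segment")
    return np.array([
        mean_rate(train, SegmentSpec(segment.start + k * 0.050, 0.050))
        for k in range(6)
    ])


def mean_abs_amplitude(lfp: LFPTrace, segment: SegmentSpec) -> float:
    """Mean absolute LFP amplitude over the segment (the LFP 'rate' feature)."""
    i0 = int(round(segment.start * lfp.sample_rate))
    i1 = int(round((segment.start + segment.length) * lfp.sample_rate))
    if i1 > lfp.values.size:
        raise ValueError("segment extends past the LFP trace")
    return float(np.mean(np.abs(lfp.values[i0:i1])))


def top_frequencies(lfp: LFPTrace, segment: SegmentSpec, k: int = 5) -> np.ndarray:
    """Frequencies (Hz) of the k most prominent LFP power-spectrum peaks.

    Hann-windowed periodogram of the segment, zero-padded x4 for peak
    localisation; peaks are local maxima ranked by power (descending), ties
    broken toward the lower frequency.  If fewer than k local maxima exist,
    the list is padded from the global power ranking of the remaining bins
    and a warning is logged.
    """
    i0 = int(round(segment.start * lfp.sample_rate))
    i1 = int(round((segment.start + segment.length) * lfp.sample_rate))
    seg = lfp.values[i0:i1]
    if seg.size < 8:
        raise ValueError("segment too short for spectral peak estimation")
    nfft = 4 * seg.size
    freqs, pxx = signal.periodogram(seg, fs=lfp.sample_rate, window="hann",
                                    nfft=nfft)
    peaks, _ = signal.find_peaks(pxx)
    order = peaks[np.lexsort((freqs[peaks], -pxx[peaks]))]
    if order.size < k:
        logger.warning("only %d spectral peaks found; padding to %d", order.size, k)
        rest = np.setdiff1d(np.arange(pxx.size), order)
        rest = rest[np.lexsort((freqs[rest], -pxx[rest]))]
        order = np.concatenate([order, rest])
    return freqs[order[:k]]
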