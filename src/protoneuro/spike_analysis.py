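"""Spontaneous spike detection and spike-train statistics.

Detects discrete depolarization-like events in potential recordings and
summarizes their amplitude and inter-spike-period distributions (quartiles,
moments, skewness, Pearson kurtosis), the per-window spike frequency in
spikes per minute, and RMS-based activity-phase segmentation.

Detection is prominence-based (``scipy.signal.find_peaks``): an event is a
local maximum with topographic prominence above ``min_prominence`` and at
least ``min_separation`` seconds from its neighbours.  Amplitude is defined
as the prominence, which is robust to the slow baseline drift these
recordings show.  The recordings this targets never state a detection
criterion, so both thresholds are explicit parameters; defaults (2 mV,
60 s) suit minute-scale protocell spiking and must be lowered for
fast-period trains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import ValidationError, VoltageTrace

__all__ = [
    "SpikeTrain",
    "DistributionSummary",
    "detect_spikes",
    "interspike_periods",
    "spike_frequency",
    "segment_phases",
    "summarize_distribution",
]


@dataclass
class SpikeTrain:
    """Detected spike times (s) and amplitudes (mV, prominence above baseline)."""

    times: np.ndarray
    amplitudes: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValidationError("times and amplitudes must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("spike times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValidationError("amplitudes must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DistributionSummary:
    """Quartiles, moments and shape statistics of one sample.

    ``kurtosis`` is the Pearson (non-excess) convention: a normal
    distribution scores 3.  ``skewness``/``kurtosis`` are ``None`` when the
    sample is degenerate or too small (n < 3 for skewness, n < 4 for
    kurtosis).
    """

    n: int
    mean: float
    sd: float
    min: float
    max: float
    q25: float
    q50: float
    q75: float
    skewness: float | None
    kurtosis: float | None


def detect_spikes(trace: VoltageTrace, min_prominence: float = 2.0,
                  min_separation: float = 60.0) -> SpikeTrain:
    """Detect spikes as prominent local maxima.

    Parameters
    ----------
    min_prominence : float
        Minimum topographic prominence in mV.
    min_separation : float
        Minimum spacing between accepted peaks in seconds.

    Returns an empty train when nothing qualifies.  Deterministic and
    invariant under adding a constant to the trace.
    """
    if len(trace) < 3:
        raise ValidationError("trace too short for detection")
    dt = trace.sample_interval
    if dt is None:
        dt = float(np.median(np.diff(trace.t)))
    distance = max(int(round(min_separation / dt)), 1)
    idx, props = sps.find_peaks(trace.v, prominence=min_prominence, distance=distance)
    return SpikeTrain(trace.t[idx], props["prominences"], source_label=trace.label)


def interspike_periods(train: SpikeTrain) -> np.ndarray:
    """Successive differences of spike times, in seconds (length n-1)."""
    if len(train) < 2:
        warnings.warn("fewer than 2 spikes; no periods", stacklevel=2)
        return np.empty(0)
    return np.diff(train.times)


def spike_frequency(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike rate over ``[t0, t1)`` in spikes per minute."""
    t0, t1 = window
    if t1 <= t0:
        raise ValidationError("window must have t1 > t0")
    count = int(np.count_nonzero((train.times >= t0) & (train.times < t1)))
    return count * 60.0 / (t1 - t0)


def segment_phases(trace: VoltageTrace, boundaries=None, window: float = 1000.0,
                   thresholds=None) -> list[tuple[tuple[float, float], float]]:
    """Per-window RMS of the mean-subtracted signal.

    With explicit ``boundaries`` (interior split times), returns one
    ``((t0, t1), V_rms)`` entry per segment.  Without boundaries, the trace
    is tiled into windows of ``window`` seconds; if ``thresholds`` (ascending
    RMS levels) are given, contiguous windows falling in the same threshold
    band are merged into phases and the pooled RMS per phase is returned.
    """
    t, v = trace.t, trace.v
    if boundaries is not None:
        edges = [t[0], *sorted(boundaries), t[-1]]
        if edges[0] < t[0] or edges[-1] > t[-1] or any(
                b <= t[0] or b >= t[-1] for b in boundaries):
            raise ValidationError("boundaries must lie inside the trace span")
    else:
        edges = list(np.arange(t[0], t[-1], window)) + [t[-1]]
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (t >= a) & (t < b) if b < t[-1] else (t >= a) & (t <= b)
        seg = v[mask]
        rms = float(np.sqrt(np.mean((seg - seg.mean()) ** 2))) if seg.size else 0.0
        out.append(((float(a), float(b)), rms))
    if boundaries is None and thresholds is not None:
        levels = np.asarray(sorted(thresholds), dtype=float)
        merged: list[tuple[list[float], list[float]]] = []
        last_band = None
        for (a, b), rms in out:
            band = int(np.searchsorted(levels, rms))
            if band == last_band:
                merged[-1][0][1] = b
                merged[-1][1].append(rms)
            else:
                merged.append(([a, b], [rms]))
                last_band = band
        out = [((a, b), float(np.sqrt(np.mean(np.square(r))))) for (a, b), r in merged]
    return out


def summarize_distribution(samples) -> DistributionSummary:
    """Quartiles, mean/SD, extremes, skewness and Pearson kurtosis.

    Quartiles use linear interpolation.  Central moments use the 1/n
    convention: skewness ``g = m3 / m2^(3/2)`` and kurtosis ``k = m4 / m2^2``
    (normal -> 3).  Degenerate samples yield ``None`` shape statistics.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples")
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    m = float(x.mean())
    m2 = float(np.mean((x - m) ** 2))
    skew = kurt = None
    if m2 > 0:
        if x.size >= 3:
            skew = float(np.mean((x - m) ** 3) / m2 ** 1.5)
        if x.size >= 4:
            kurt = float(np.mean((x - m) ** 4) / m2 ** 2)
    return DistributionSummary(
        n=int(x.size), mean=m, sd=float(x.std(ddof=1)),
        min=float(x.min()), max=float(x.max()),
        q25=float(q25), q50=float(q50), q75=float(q75),
        skewness=skew, kurtosis=kurt,
    )
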