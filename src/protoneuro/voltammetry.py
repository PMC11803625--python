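"""Cyclic-voltammetry feature extraction.

Segments multi-cycle voltammograms into individual triangular sweeps and
computes the per-cycle descriptors used to compare protocell redox
chemistry: anodic/cathodic peak potentials and currents, peak separation
``dEp = Epa - Epc``, peak-current ratio ``|ipa/ipc|``, integrated charge Q,
exponential charge decay ``Q(n) = Q0 exp(-alpha n)``, reversibility index
``eta = |ipa/ipc| / dEp``, electron-transfer efficiency
``eps = |ipa * ipc| / dEp``, zero-crossing potential/current, hysteresis
(loop) area, and summary statistics over cycles.

Sign conventions: ``ipa`` is reported positive and ``ipc`` negative; ratio
and efficiency use absolute values.  Charge integrates ``|i|`` (total charge
passed) so that Q is positive and decays with cycling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_io import ValidationError, Voltammogram

__all__ = [
    "CycleFeatures",
    "CVSummary",
    "PeaksNotFound",
    "segment_cycles",
    "split_sweeps",
    "find_redox_peaks",
    "peak_separation",
    "peak_ratio",
    "integrated_charge",
    "fit_charge_decay",
    "decay_rate",
    "reversibility_index",
    "transfer_efficiency",
    "efficiency_enhancement",
    "zero_crossings",
    "hysteresis_area",
    "extract_features",
    "summarize",
]


class PeaksNotFound(ValueError):
    """No redox peak exceeds the noise floor in this cycle."""


@dataclass
class CycleFeatures:
    """Per-cycle scalar descriptors (V, uA, uC, uA*V)."""

    cycle: int
    epa: float
    epc: float
    ipa: float
    ipc: float
    delta_ep: float
    ratio: float
    q: float
    ezc: float
    izc: float
    hyst_area: float
    i_max: float
    i_min: float


@dataclass
class CVSummary:
    """Mean and sample SD of each feature over cycles."""

    n_cycles: int
    mean: dict
    sd: dict


def segment_cycles(vg: Voltammogram) -> Voltammogram:
    """Assign 1-based cycle indices at sweep reversals from the potential minimum.

    A cycle is one forward plus one reverse sweep; boundaries are placed at
    local minima of the potential signal.  Raises ``ValidationError`` if the
    sweep is monotone (fewer than one full triangle).
    """
    if vg.cycle is not None and vg.n_cycles >= 1:
        return vg
    e = vg.e
    de = np.sign(np.diff(e))
    # reversal points: direction changes from falling to rising -> cycle start
    turns = np.flatnonzero((de[:-1] != de[1:]) & (de[1:] != 0)) + 1
    if de.size == 0 or np.all(de >= 0) or np.all(de <= 0):
        raise ValidationError("potential sweep is monotone; no full cycle present")
    starts = [0]
    for k in turns:
        # start a new cycle where the sweep turns upward (minimum of the triangle)
        if de[k] > 0 and de[k - 1] < 0 and k - starts[-1] > 2:
            starts.append(k)
    starts.append(e.size)
    cycles = np.empty(e.size, dtype=int)
    n = 0
    for a, b in zip(starts[:-1], starts[1:]):
        seg = de[a:max(b - 1, a)]
        if seg.size and (seg > 0).any() and (seg < 0).any():
            n += 1
            cycles[a:b] = n
        elif n > 0:
            cycles[a:b] = n  # trailing partial sweep folds into last cycle
        else:
            cycles[a:b] = 1
    if n < 1:
        raise ValidationError("no complete forward+reverse cycle found")
    return Voltammogram(vg.e, vg.i, cycles, vg.scan_rate)


def split_sweeps(cycle: Voltammogram) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split one cycle into (e_fwd, i_fwd, e_rev, i_rev) by sweep direction."""
    e, i = cycle.e, cycle.i
    de = np.diff(e)
    apex = int(np.argmax(e))
    if apex < 2 or apex > e.size - 3:
        # fall back on sign of initial slope
        rising = de[0] > 0
        apex = int(np.argmax(e)) if rising else int(np.argmin(e))
    return e[:apex + 1], i[:apex + 1], e[apex:], i[apex:]


def find_redox_peaks(cycle: Voltammogram, noise_floor: float = 0.0,
                     baseline_subtract: bool = False) -> tuple[float, float, float, float]:
    """Locate anodic/cathodic peaks of one cycle.

    Returns ``(epa, ipa, epc, ipc)``: the forward-sweep current maximum and
    the reverse-sweep current minimum with their potentials.  ``ipa`` is the
    maximum (positive by convention), ``ipc`` the minimum (negative).

    Raises
    ------
    PeaksNotFound
        If neither extremum exceeds ``noise_floor`` in magnitude.
    """
    e_fwd, i_fwd, e_rev, i_rev = split_sweeps(cycle)
    if e_fwd.size < 10 or e_rev.size < 10:
        raise ValidationError("need at least 10 samples per sweep")
    if baseline_subtract:
        i_fwd = i_fwd - np.linspace(i_fwd[0], i_fwd[-1], i_fwd.size)
        i_rev = i_rev - np.linspace(i_rev[0], i_rev[-1], i_rev.size)
    ka = int(np.argmax(i_fwd))
    kc = int(np.argmin(i_rev))
    ipa, ipc = float(i_fwd[ka]), float(i_rev[kc])
    if abs(ipa) <= noise_floor and abs(ipc) <= noise_floor:
        raise PeaksNotFound("no redox peak exceeds the noise floor")
    return float(e_fwd[ka]), ipa, float(e_rev[kc]), ipc


def peak_separation(epa: float, epc: float) -> float:
    """Peak separation ``dEp = Epa - Epc`` in volts."""
    return epa - epc


def peak_ratio(ipa: float, ipc: float) -> float:
    """Peak-current ratio ``|ipa / ipc|`` (dimensionless)."""
    if ipc == 0:
        raise ValidationError("ipc is zero; ratio undefined")
    return abs(ipa / ipc)


def integrated_charge(cycle: Voltammogram, scan_rate: float | None = None,
                      signed: bool = False) -> float:
    """Integrated charge of one cycle in microcoulombs.

    Trapezoidal integral of ``|i|`` (or signed ``i`` if ``signed``) over
    time, with ``dt = |dE| / scan_rate``.
    """
    nu = cycle.scan_rate if scan_rate is None else scan_rate
    if nu <= 0:
        raise ValidationError("scan_rate must be positive")
    dt = np.abs(np.diff(cycle.e)) / nu
    t = np.concatenate([[0.0], np.cumsum(dt)])
    y = cycle.i if signed else np.abs(cycle.i)
    return float(np.trapezoid(y, t))


def fit_charge_decay(q_series: Sequence[float]) -> tuple[float, float, float]:
    """Fit ``Q(n) = Q0 * exp(-alpha * n)`` to per-cycle charges.

    Unweighted least squares on ``log Q`` versus cycle number (1-based).
    Returns ``(q0, alpha, residual_variance)``.

    Raises
    ------
    ValidationError
        For fewer than 5 cycles or non-positive charges.
    """
    q = np.asarray(q_series, dtype=float)
    if q.size < 5:
        raise ValidationError("need at least 5 cycles to fit the decay")
    if np.any(q <= 0):
        raise ValidationError("charges must be positive for the log-linear fit")
    n = np.arange(1, q.size + 1, dtype=float)
    slope, intercept = np.polyfit(n, np.log(q), 1)
    resid = np.log(q) - (slope * n + intercept)
    dof = max(q.size - 2, 1)
    return float(np.exp(intercept)), float(-slope), float(resid @ resid / dof)


def decay_rate(series: Sequence[float]) -> np.ndarray:
    """Per-cycle relative change in percent; first element is NaN.

    ``rate(n) = (x(n) - x(n-1)) / x(n-1) * 100``; cycles whose predecessor
    is zero get NaN.
    """
    x = np.asarray(series, dtype=float)
    out = np.full(x.size, np.nan)
    prev = x[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        out[1:] = np.where(prev != 0, (x[1:] - prev) / prev * 100.0, np.nan)
    return out


def reversibility_index(ipa: float, ipc: float, delta_ep: float) -> float:
    """Reversibility index ``eta = |ipa/ipc| / dEp`` in 1/V."""
    if delta_ep <= 0:
        raise ValidationError("delta_ep must be positive")
    return peak_ratio(ipa, ipc) / delta_ep


def transfer_efficiency(ipa: float, ipc: float, delta_ep: float) -> float:
    """Electron-transfer efficiency ``eps = |ipa * ipc| / dEp`` in uA^2/V."""
    if delta_ep <= 0:
        raise ValidationError("delta_ep must be positive")
    return abs(ipa * ipc) / delta_ep


def efficiency_enhancement(eps_ref: float, eps_mod: float) -> float:
    """Efficiency enhancement ``(eps_mod - eps_ref) / eps_ref * 100`` percent."""
    if eps_ref <= 0:
        raise ValidationError("reference efficiency must be positive")
    return (eps_mod - eps_ref) / eps_ref * 100.0


def zero_crossings(cycle: Voltammogram) -> tuple[float, float]:
    """Zero-crossing potential and the opposing-sweep current there.

    ``Ezc`` is the potential of the first sign change of the current on the
    forward sweep (linear interpolation between the bracketing samples);
    ``Izc`` is the reverse-sweep current interpolated at that potential —
    nonzero whenever the loop has hysteresis at the crossing.

    Raises
    ------
    ValidationError
        If the forward-sweep current never changes sign.
    """
    e_fwd, i_fwd, e_rev, i_rev = split_sweeps(cycle)
    sign = np.sign(i_fwd)
    idx = np.flatnonzero((sign[:-1] != sign[1:]) & (sign[:-1] != 0))
    if idx.size == 0:
        raise ValidationError("forward-sweep current has no sign change")
    k = int(idx[0])
    # linear interpolation for the root between samples k and k+1
    frac = i_fwd[k] / (i_fwd[k] - i_fwd[k + 1])
    ezc = float(e_fwd[k] + frac * (e_fwd[k + 1] - e_fwd[k]))
    # reverse sweep is sampled at decreasing potential; flip for interp
    order = np.argsort(e_rev)
    izc = float(np.interp(ezc, e_rev[order], i_rev[order]))
    return ezc, izc


def hysteresis_area(cycle: Voltammogram, close_tol: float = 1e-9) -> float:
    """Absolute shoelace area of the closed I-V loop, in uA*V.

    Open loops (endpoints differing by more than ``close_tol`` relative to
    the loop span) are closed by joining the endpoints.
    """
    x, y = cycle.e, cycle.i
    # shoelace implicitly closes the polygon; tolerance kept for the contract
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return area


def extract_features(vg: Voltammogram, noise_floor: float = 0.0,
                     baseline_subtract: bool = False) -> list[CycleFeatures]:
    """Compute :class:`CycleFeatures` for every cycle of a segmented voltammogram."""
    vg = segment_cycles(vg)
    rows: list[CycleFeatures] = []
    for n in range(1, vg.n_cycles + 1):
        cyc = vg.cycle_slice(n)
        epa, ipa, epc, ipc = find_redox_peaks(cyc, noise_floor, baseline_subtract)
        dep = peak_separation(epa, epc)
        try:
            ezc, izc = zero_crossings(cyc)
        except ValidationError:
            ezc, izc = math.nan, math.nan
        rows.append(CycleFeatures(
            cycle=n, epa=epa, epc=epc, ipa=ipa, ipc=ipc,
            delta_ep=dep, ratio=peak_ratio(ipa, ipc),
            q=integrated_charge(cyc),
            ezc=ezc, izc=izc,
            hyst_area=hysteresis_area(cyc),
            i_max=float(cyc.i.max()), i_min=float(cyc.i.min()),
        ))
    return rows


_SUMMARY_FIELDS = ("epa", "epc", "ipa", "ipc", "delta_ep", "ratio", "q",
                   "ezc", "izc", "hyst_area", "i_max", "i_min")


def summarize(features: Sequence[CycleFeatures]) -> CVSummary:
    """Mean and sample SD (N-1) of every feature over cycles, plus current extremes."""
    if not features:
        raise ValidationError("no cycles to summarize")
    mean, sd = {}, {}
    for name in _SUMMARY_FIELDS:
        vals = np.array([getattr(f, name) for f in features], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            mean[name], sd[name] = math.nan, math.nan
            continue
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return CVSummary(n_cycles=len(features), mean=mean, sd=sd)
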