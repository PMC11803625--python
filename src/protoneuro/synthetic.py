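"""Synthetic electrochemical signal generators.

Produces the three input modalities with the statistical structure the
analysis modules assume, so the full pipeline can be exercised without any
recorded data:

* spiking voltage traces with phase-dependent Poisson spike rates and
  truncated-normal spike amplitudes riding on correlated baseline noise,
* multi-cycle triangular-sweep voltammograms with paired Gaussian redox
  peaks whose per-cycle charge decays exponentially,
* impedance spectra of an R(RC)(RC) ladder circuit on a logarithmic
  frequency grid with multiplicative complex noise.

All generators are deterministic for a fixed seed.

Baseline noise is an Ornstein–Uhlenbeck process rather than white noise:
recorded protocell baselines wander on a timescale of seconds to minutes,
and the correlation time is what separates a "stable baseline" system from
one showing "rapid fluctuations" when traces are later binarized for
complexity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_io import ImpedanceSpectrum, ValidationError, VoltageTrace, Voltammogram

__all__ = [
    "PhaseSpec",
    "BurstSpec",
    "CVSpec",
    "CircuitParams",
    "gen_spike_trace",
    "gen_burst_trace",
    "gen_voltammogram",
    "gen_spectrum",
    "log_frequency_grid",
    "p_like_phases",
    "ps_like_phases",
    "psp_like_phases",
    "SYSTEM_PRESETS",
]


@dataclass
class PhaseSpec:
    """One activity phase of a spiking voltage trace.

    Parameters
    ----------
    t_start, t_end : float
        Phase window in seconds.
    spike_rate : float
        Poisson spike rate, spikes per minute.
    amp_mean, amp_sd : float
        Spike-amplitude distribution (mV), normal truncated at zero.
    baseline : float
        Resting potential during the phase (mV).
    noise_sd : float
        Stationary SD of the baseline noise (mV).
    noise_tau : float
        Correlation time of the baseline noise (s).  Long values give a
        slowly wandering, "quiet" baseline; short values give rapid
        fluctuations.
    drift_to : float or None
        If set, the baseline ramps linearly from ``baseline`` to this value
        across the phase (slow trends are ubiquitous in long recordings).
    slow_amp, slow_period : float
        Optional slow sinusoidal component (mV, s) superimposed on the
        baseline, emulating large-scale potential oscillations.
    """

    t_start: float
    t_end: float
    spike_rate: float
    amp_mean: float
    amp_sd: float
    baseline: float = 0.0
    noise_sd: float = 0.0
    noise_tau: float = 10.0
    drift_to: float | None = None
    slow_amp: float = 0.0
    slow_period: float = 10_000.0

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValidationError("phase must have t_end > t_start")
        if self.spike_rate < 0 or self.amp_sd < 0 or self.noise_sd < 0:
            raise ValidationError("rates and SDs must be non-negative")
        if self.noise_tau <= 0:
            raise ValidationError("noise_tau must be positive")


@dataclass
class BurstSpec:
    """Parameters of a burst-like oscillatory trace.

    Defaults follow the burst regime reported for serotonin/paroxetine
    protocells: peaks at ~16.2 mV, quiescent baseline ~5.8 mV, burst
    envelope time constant 200 s, oscillation frequency 1.8 per minute.
    """

    v_max: float = 16.2
    v_min: float = 5.8
    tau: float = 200.0
    freq: float = 1.8
    duration: float = 4000.0

    def __post_init__(self):
        if self.v_max <= self.v_min:
            raise ValidationError("v_max must exceed v_min")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.duration <= self.tau:
            raise ValidationError("duration must exceed tau")


@dataclass
class CVSpec:
    """Synthetic cyclic-voltammogram parameters.

    A triangular potential sweep between ``e_min`` and ``e_max`` at
    ``scan_rate``; each cycle carries a Gaussian anodic peak at ``epa0`` on
    the forward sweep and a Gaussian cathodic peak at ``epc0`` on the
    reverse sweep, with peak currents damped by ``exp(-alpha*(n-1))`` on
    cycle ``n``.
    """

    e_min: float = -0.2
    e_max: float = 0.7
    scan_rate: float = 0.1
    n_cycles: int = 100
    epa0: float = 0.30
    epc0: float = 0.134
    ipa0: float = 3.53
    ipc0: float = -17.6
    alpha: float = 0.01
    peak_width: float = 0.05
    noise_sd: float = 0.0
    samples_per_sweep: int = 250

    def __post_init__(self):
        if self.e_max <= self.e_min:
            raise ValidationError("e_max must exceed e_min")
        if self.n_cycles < 1:
            raise ValidationError("need at least one cycle")
        if self.alpha < 0:
            raise ValidationError("alpha must be non-negative")
        if not (self.e_min < self.epa0 < self.e_max):
            raise ValidationError("anodic peak potential outside sweep window")
        if not (self.e_min < self.epc0 < self.e_max):
            raise ValidationError("cathodic peak potential outside sweep window")


@dataclass
class CircuitParams:
    """R(RC)(RC) ladder: series R1, then two parallel RC elements.

    Defaults are the fitted interfacial model of the serotonin/paroxetine
    protocell spectrum: R1 = 590.2 Ohm (solution resistance), R2 = 715.9 Ohm
    with C1 = 0.436 nF, and R3 = 13.12 MOhm with C2 = 3426 nF.
    """

    r1: float = 590.2
    r2: float = 715.9
    c1: float = 0.436e-9
    r3: float = 13.12e6
    c2: float = 3426e-9

    def __post_init__(self):
        for name in ("r1", "r2", "c1", "r3", "c2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.c1, self.r3, self.c2])


def _ou_noise(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck noise with SD ``sd`` and correlation time ``tau``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    rho = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(max(1.0 - rho * rho, 1e-300))
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + eps[k - 1]
    return x


def _truncated_normal(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated at zero by rejection (amplitudes are positive)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 8))
        draw = draw[draw > 0]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _dead_time_poisson(t_start: float, t_end: float, rate_per_s: float,
                       refractory: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson event times with dead time, preserving the nominal mean rate.

    With a refractory period ``r`` the exponential hazard is inflated to
    ``lam' = lam / (1 - lam * r)`` so that the mean inter-event interval
    stays ``1 / lam``.  Requires ``lam * r < 1``.
    """
    if rate_per_s <= 0:
        return np.empty(0)
    occupancy = rate_per_s * refractory
    if occupancy >= 1:
        raise ValidationError("refractory period incompatible with spike rate")
    hazard = rate_per_s / (1.0 - occupancy)
    times = []
    t = t_start + rng.exponential(1.0 / hazard)
    while t < t_end:
        times.append(t)
        t += refractory + rng.exponential(1.0 / hazard)
    return np.asarray(times)


def gen_spike_trace(phases: Sequence[PhaseSpec], dt: float = 1.0, seed: int = 0,
                    spike_tau: float = 30.0, refractory: float = 0.0,
                    label: str = "") -> VoltageTrace:
    """Generate a spiking voltage trace over a sequence of activity phases.

    Spike times within each phase follow a homogeneous Poisson process at
    the phase's rate (optionally with a dead time ``refractory`` seconds,
    rate-preserving); amplitudes are normal truncated at zero; each spike is
    an instantaneous rise followed by an exponential decay with time
    constant ``spike_tau`` (s), added to the phase baseline plus correlated
    noise.

    The returned trace carries the ground truth as attributes
    ``true_spike_times`` and ``true_spike_amps`` for detector validation.

    Raises
    ------
    ValidationError
        If ``dt`` is not positive or the phases overlap / are unordered.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if not phases:
        raise ValidationError("need at least one phase")
    phases = list(phases)
    for a, b in zip(phases, phases[1:]):
        if b.t_start < a.t_end:
            raise ValidationError("phases must be ordered and non-overlapping")
    rng = np.random.default_rng(seed)
    t0, t1 = phases[0].t_start, phases[-1].t_end
    t = np.arange(t0, t1, dt)
    v = np.zeros_like(t)
    spike_t_all = []
    spike_a_all = []
    for ph in phases:
        mask = (t >= ph.t_start) & (t < ph.t_end)
        n = int(mask.sum())
        base = np.full(n, ph.baseline)
        if ph.drift_to is not None:
            base = np.linspace(ph.baseline, ph.drift_to, n)
        if ph.slow_amp:
            base = base + ph.slow_amp * np.sin(2 * np.pi * (t[mask] - ph.t_start) / ph.slow_period)
        v[mask] = base + _ou_noise(n, dt, ph.noise_sd, ph.noise_tau, rng)
        # keep onsets at least 2 samples from the trace end so every spike
        # template has a resolvable peak sample
        times = _dead_time_poisson(ph.t_start, min(ph.t_end, t1 - 2 * dt),
                                   ph.spike_rate / 60.0, refractory, rng)
        if times.size:
            amps = _truncated_normal(ph.amp_mean, ph.amp_sd, times.size, rng)
            spike_t_all.append(times)
            spike_a_all.append(amps)
    times = np.concatenate(spike_t_all) if spike_t_all else np.empty(0)
    amps = np.concatenate(spike_a_all) if spike_a_all else np.empty(0)
    # superimpose spike templates (snap each onset to the sample grid so the
    # full amplitude is visible at the peak sample)
    for ts, amp in zip(times, amps):
        k0 = int(np.searchsorted(t, ts))
        if k0 >= t.size:
            continue
        span = min(t.size - k0, max(int(8 * spike_tau / dt), 1))
        rel = t[k0:k0 + span] - t[k0]
        v[k0:k0 + span] += amp * np.exp(-rel / spike_tau)
    trace = VoltageTrace(t, v, label=label)
    trace.true_spike_times = times
    trace.true_spike_amps = amps
    return trace


def gen_burst_trace(spec: BurstSpec, dt: float = 1.0, seed: int = 0,
                    label: str = "") -> VoltageTrace:
    """Generate a burst-like oscillation between ``v_min`` and ``v_max``.

    The trace is a raised sinusoid at ``spec.freq`` (per minute) whose
    depth is modulated by a logistic burst envelope with time constant
    ``spec.tau``: oscillations grow in over ~``tau`` seconds and recur with
    a burst period of ``10 * tau``.  The returned potential stays within
    ``[v_min, v_max]`` up to a small numerical epsilon.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    t = np.arange(0.0, spec.duration, dt)
    amp = spec.v_max - spec.v_min
    omega = 2 * np.pi * spec.freq / 60.0
    if spec.freq == 0:
        return VoltageTrace(t, np.full_like(t, spec.v_min), label=label)
    burst_period = 10.0 * spec.tau
    phase = (t % burst_period)
    envelope = 1.0 / (1.0 + np.exp(-(phase - spec.tau) / (spec.tau / 4.0)))
    osc = 0.5 * (1.0 - np.cos(omega * t))  # in [0, 1], starts at baseline
    v = spec.v_min + amp * envelope * osc
    return VoltageTrace(t, v, label=label)


def _triangle_sweep(spec: CVSpec) -> tuple[np.ndarray, np.ndarray]:
    """One triangular cycle: forward e_min->e_max then reverse back."""
    m = spec.samples_per_sweep
    fwd = np.linspace(spec.e_min, spec.e_max, m, endpoint=False)
    rev = np.linspace(spec.e_max, spec.e_min, m, endpoint=False)
    e = np.concatenate([fwd, rev])
    direction = np.concatenate([np.ones(m), -np.ones(m)])
    return e, direction


def gen_voltammogram(spec: CVSpec, seed: int = 0) -> Voltammogram:
    """Generate a multi-cycle voltammogram with decaying Gaussian redox peaks.

    On cycle ``n`` both peak currents are scaled by ``exp(-alpha*(n-1))``,
    so the per-cycle integrated charge decays geometrically with ratio
    ``exp(-alpha)`` (exactly, at zero noise).
    """
    rng = np.random.default_rng(seed)
    e1, direction = _triangle_sweep(spec)
    e_parts, i_parts, c_parts = [], [], []
    for n in range(1, spec.n_cycles + 1):
        damp = math.exp(-spec.alpha * (n - 1))
        i_fwd = spec.ipa0 * damp * np.exp(-0.5 * ((e1 - spec.epa0) / spec.peak_width) ** 2)
        i_rev = spec.ipc0 * damp * np.exp(-0.5 * ((e1 - spec.epc0) / spec.peak_width) ** 2)
        i = np.where(direction > 0, i_fwd, i_rev)
        if spec.noise_sd:
            i = i + rng.normal(0.0, spec.noise_sd, size=i.size)
        e_parts.append(e1)
        i_parts.append(i)
        c_parts.append(np.full(e1.size, n, dtype=int))
    return Voltammogram(np.concatenate(e_parts), np.concatenate(i_parts),
                        np.concatenate(c_parts), spec.scan_rate)


def log_frequency_grid(f_min: float, f_max: float, points_per_decade: float) -> np.ndarray:
    """Logarithmically spaced frequencies at a fixed density per decade.

    The grid steps by ``1/points_per_decade`` decades starting at ``f_min``;
    the point count is ``floor(decades * points_per_decade) + 1`` (e.g.
    11 decades at 12.3 points per decade gives 136 points).
    """
    if f_min <= 0 or f_max <= f_min:
        raise ValidationError("need 0 < f_min < f_max")
    if points_per_decade <= 0:
        raise ValidationError("points_per_decade must be positive")
    decades = math.log10(f_max / f_min)
    n = int(math.floor(decades * points_per_decade + 1e-9)) + 1
    exponents = math.log10(f_min) + np.arange(n) / points_per_decade
    return 10.0 ** exponents


def gen_spectrum(params: CircuitParams, f_min: float = 1e-5, f_max: float = 1e6,
                 points_per_decade: float = 12.3, noise_frac: float = 0.0,
                 seed: int = 0, label: str = "") -> ImpedanceSpectrum:
    """Generate an impedance spectrum of the R(RC)(RC) circuit.

    Noise is multiplicative complex Gaussian: each impedance point is
    scaled by ``1 + noise_frac * (g1 + i*g2)`` with independent standard
    normals ``g1, g2``.
    """
    from .impedance import circuit_impedance  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    f = log_frequency_grid(f_min, f_max, points_per_decade)
    z = circuit_impedance(params, f)
    if noise_frac:
        g = rng.normal(0.0, noise_frac, size=f.size) + 1j * rng.normal(0.0, noise_frac, size=f.size)
        z = z * (1.0 + g)
    return ImpedanceSpectrum(f, z.real, z.imag, label=label)


# --- System analog presets -------------------------------------------------
#
# Desk-scale analogs of the three studied systems, shaped by the reported
# phenomenology: the pristine proteinoid (P) shows sparse isolated spikes
# (12-22 mV) on a stable baseline; proteinoid-serotonin (PS) shows sustained
# 10-15 mV baseline activity with rapid fluctuations, large slow potential
# oscillations and the fastest spiking (1.2/min); the serotonin-paroxetine
# system (PSP) passes through quiescent -> transition -> high-activity phases
# with spike rates rising from 0.2 to 1.8 per minute and RMS noise growing
# from ~2 to ~7 mV.  Durations are scaled to `duration` seconds while phase
# proportions, rates and amplitude statistics are preserved.
#
# Each analog carries a slow near-periodic potential oscillation (period
# duration/10, the default analysis window) emulating the recurrent
# large-scale oscillations all three recordings show; its amplitude relative
# to the fast noise encodes how regular each system's activity is.

def p_like_phases(duration: float = 30_000.0) -> list[PhaseSpec]:
    """Pristine-proteinoid analog: sparse large spikes, quiet stable baseline."""
    return [PhaseSpec(0.0, duration, spike_rate=60.0 / 664.45,
                      amp_mean=7.62, amp_sd=4.69,
                      baseline=2.0, noise_sd=0.75, noise_tau=120.0,
                      slow_amp=1.0, slow_period=duration / 10.0)]


def ps_like_phases(duration: float = 30_000.0) -> list[PhaseSpec]:
    """Proteinoid-serotonin analog: rapid fluctuations, large slow oscillations."""
    return [PhaseSpec(0.0, duration, spike_rate=1.2,
                      amp_mean=14.87, amp_sd=7.80,
                      baseline=12.0, noise_sd=4.0, noise_tau=2.0,
                      slow_amp=18.0, slow_period=duration / 10.0)]


def psp_like_phases(duration: float = 30_000.0) -> list[PhaseSpec]:
    """Serotonin-paroxetine analog: quiescent / transition / high-activity phases."""
    b1, b2 = duration * (30_000.0 / 185_000.0), duration * (90_000.0 / 185_000.0)
    period = duration / 10.0
    return [
        PhaseSpec(0.0, b1, spike_rate=0.2, amp_mean=10.84, amp_sd=4.36,
                  baseline=2.0, noise_sd=1.5, noise_tau=20.0,
                  slow_amp=1.0, slow_period=period),
        PhaseSpec(b1, b2, spike_rate=0.9, amp_mean=10.84, amp_sd=4.36,
                  baseline=2.0, drift_to=8.0, noise_sd=2.5, noise_tau=15.0,
                  slow_amp=4.0, slow_period=period),
        PhaseSpec(b2, duration, spike_rate=1.8, amp_mean=10.84, amp_sd=4.36,
                  baseline=10.0, noise_sd=3.5, noise_tau=10.0,
                  slow_amp=8.0, slow_period=period),
    ]


SYSTEM_PRESETS = {
    "P": p_like_phases,
    "PS": ps_like_phases,
    "PSP": psp_like_phases,
}
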