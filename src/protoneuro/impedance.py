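"""Electrochemical impedance analysis and R(RC)(RC) equivalent-circuit fitting.

The circuit is a solution resistance R1 in series with two parallel RC
elements (charge-transfer resistance / double-layer capacitance at two
interfaces):

    Z(w) = R1 + R2 / (1 + j w R2 C1) + R3 / (1 + j w R3 C2),   w = 2 pi f

Fitting is complex nonlinear least squares with modulus weighting
``w_k = 1 / |Z_obs(f_k)|^2``, i.e. the residual vector stacks the real and
imaginary parts of ``(Z_obs - Z_model) / |Z_obs|``.  Relative residuals are
essential here: protocell spectra span from ~hundreds of ohms at high
frequency to tens of megaohms at the DC limit, and unit weighting would let
the largest arc swallow the fit.  Parameters are optimized in log space,
which both enforces positivity and accommodates capacitances spanning
nanofarad to microfarad scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .signal_io import ImpedanceSpectrum, ValidationError
from .synthetic import CircuitParams

__all__ = [
    "FitResult",
    "SpectrumSummary",
    "circuit_impedance",
    "magnitude_phase",
    "summarize_spectrum",
    "percent_difference",
    "initial_guess",
    "fit_circuit",
]


@dataclass
class FitResult:
    """Outcome of an equivalent-circuit fit.

    ``chi2`` is the modulus-weighted residual sum normalized by
    ``2*n_points - n_params`` (real and imaginary parts each count as an
    observation).  ``param_errors`` are relative standard errors in percent,
    from the Jacobian at the solution.
    """

    params: CircuitParams
    param_errors: dict
    chi2: float
    n_iter: int
    converged: bool


@dataclass
class SpectrumSummary:
    """Magnitude/phase summary of one spectrum (Ohm, degrees)."""

    mean_z: float
    max_z: float
    min_z: float
    mean_phase: float


def circuit_impedance(params: CircuitParams, f) -> np.ndarray:
    """Complex impedance of the R(RC)(RC) circuit at frequencies ``f`` (Hz)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("frequencies must be positive")
    w = 2 * np.pi * f
    z = (params.r1
         + params.r2 / (1 + 1j * w * params.r2 * params.c1)
         + params.r3 / (1 + 1j * w * params.r3 * params.c2))
    return z


def magnitude_phase(z_re, z_im) -> tuple[np.ndarray, np.ndarray]:
    """``|Z| = sqrt(re^2 + im^2)`` and phase ``atan2(im, re)`` in degrees."""
    z_re = np.asarray(z_re, dtype=float)
    z_im = np.asarray(z_im, dtype=float)
    return np.hypot(z_re, z_im), np.degrees(np.arctan2(z_im, z_re))


def summarize_spectrum(spec: ImpedanceSpectrum) -> SpectrumSummary:
    """Arithmetic mean/max/min of |Z| over frequencies and mean |phase|.

    Phase is summarized as the mean absolute angle: capacitive spectra have
    negative phase but are conventionally reported positive.
    """
    mod, ph = magnitude_phase(spec.z_re, spec.z_im)
    return SpectrumSummary(mean_z=float(mod.mean()), max_z=float(mod.max()),
                           min_z=float(mod.min()), mean_phase=float(np.abs(ph).mean()))


def percent_difference(a: float, b: float) -> float:
    """Signed percent difference of ``b`` relative to reference ``a``."""
    if a == 0:
        raise ValidationError("reference value must be nonzero")
    return (b - a) / a * 100.0


def initial_guess(spec: ImpedanceSpectrum) -> CircuitParams:
    """Heuristic starting point from the data.

    R1 from the high-frequency |Z| floor; R1+R2+R3 from the largest real
    part (DC limit); the split between R2 and R3 and both capacitances from
    the apex frequencies of the -Z'' profile on the log-frequency grid.
    """
    mod, _ = magnitude_phase(spec.z_re, spec.z_im)
    order = np.argsort(spec.f)
    f = spec.f[order]
    neg_im = -spec.z_im[order]
    r1 = max(float(mod.min()), 1e-12)
    r_total = max(float(spec.z_re.max()), r1 * 1.01)
    # split remaining resistance: big arc (low f) gets the bulk
    r_rest = max(r_total - r1, r1 * 0.1)
    r3 = r_rest * 0.95
    r2 = max(r_rest - r3, r1 * 0.05)
    # apex of an RC semicircle sits at w = 1/(R C)
    hi = f > np.sqrt(f[0] * f[-1])
    lo = ~hi
    def apex(mask, r):
        if mask.any() and np.any(neg_im[mask] > 0):
            fa = f[mask][int(np.argmax(neg_im[mask]))]
            return 1.0 / (2 * np.pi * fa * r)
        return 1.0 / (2 * np.pi * np.sqrt(f[0] * f[-1]) * r)
    c1 = apex(hi, r2)
    c2 = apex(lo, r3)
    return CircuitParams(r1=r1, r2=r2, c1=c1, r3=r3, c2=c2)


def fit_circuit(spec: ImpedanceSpectrum, init: CircuitParams | None = None,
                max_iter: int = 200) -> FitResult:
    """Fit the R(RC)(RC) model to a measured spectrum.

    Complex nonlinear least squares minimizing
    ``sum_k |Z_obs(f_k) - Z_model(f_k)|^2 / |Z_obs(f_k)|^2`` over
    log-parameterized positive circuit values.  Deterministic given ``init``
    (defaults to :func:`initial_guess`).

    Requires at least 10 frequencies spanning at least 3 decades.
    """
    if len(spec) < 10:
        raise ValidationError("need at least 10 frequency points")
    if math.log10(spec.f.max() / spec.f.min()) < 3:
        raise ValidationError("spectrum must span at least 3 decades")
    if init is None:
        init = initial_guess(spec)
    z_obs = spec.z
    mod = np.abs(z_obs)
    if np.any(mod == 0):
        raise ValidationError("observed |Z| contains zeros; cannot weight")
    theta0 = np.log(init.as_array())

    def residuals(theta):
        p = CircuitParams(*np.exp(theta))
        diff = (z_obs - circuit_impedance(p, spec.f)) / mod
        return np.concatenate([diff.real, diff.imag])

    sol = least_squares(residuals, theta0, method="lm", max_nfev=max_iter * 10)
    params = CircuitParams(*np.exp(sol.x))
    dof = max(2 * len(spec) - 5, 1)
    chi2 = float(2 * sol.cost / dof)  # cost is half the residual sum
    # relative parameter errors from the Jacobian in log space:
    # for log parameters, the covariance diagonal is already (dp/p)^2
    errors = {}
    names = ("r1", "r2", "c1", "r3", "c2")
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (2 * sol.cost / dof)
        rel = np.sqrt(np.clip(np.diag(cov), 0, None)) * 100.0
        errors = dict(zip(names, rel.tolist()))
    except np.linalg.LinAlgError:
        errors = {k: math.nan for k in names}
    return FitResult(params=params, param_errors=errors, chi2=chi2,
                     n_iter=int(sol.nfev), converged=bool(sol.success))
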