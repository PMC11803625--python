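"""Information-theoretic "consciousness-like" metrics for voltage traces.

Four scalar metrics characterize how much structure a recording carries and
how strongly its successive parts hang together:

* **LZW complexity** ``C_LZW = |D(s)| / |s|`` — the number of phrases
  emitted by Lempel-Ziv-Welch compression of the median-binarized signal,
  normalized by signal length.  Near 0 for constant signals, maximal for
  incompressible ones.
* **PCI** (perturbational-complexity-style index)
  ``PCI = C_whole - mean_i(C_i)`` — how much more complex the whole signal
  is than the average of its windows, each binarized by its own threshold.
* **Integration score** ``I = mean_i R(x_i, x_{i+1})`` — average zero-lag
  Pearson correlation of consecutive equal-length windows; 1 for strictly
  periodic signals at the window length, ~0 for independent windows.
* **Integrated information** ``Phi = H(X) - mean_i MI(X_i, X_{i+1})`` in
  bits — global histogram entropy minus average mutual information between
  consecutive windows.

All metrics operate on data-relative thresholds and bin edges, so they are
invariant under positive affine transforms of the potential.  Consecutive-
window averages divide by the number of pairs (N-1) by default; the divisor
is configurable (``divisor="windows"`` divides by N instead).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import ValidationError, VoltageTrace

__all__ = [
    "ComplexityReport",
    "binarize",
    "lzw_complexity",
    "lzw_phrase_count",
    "pci",
    "integration_score",
    "integrated_information",
    "consciousness_report",
]


@dataclass
class ComplexityReport:
    """The four complexity metrics of one trace, with the settings used."""

    label: str
    c_lzw: float
    pci: float
    integration: float
    phi: float
    n_windows: int
    bins: int
    divisor: str = "pairs"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def binarize(trace_or_values, method: str = "median") -> str:
    """Binarize a trace: '1' where v exceeds the threshold, else '0'.

    The threshold is the median (default) or mean of the values, making the
    symbol string invariant under adding a constant or positive rescaling.
    """
    v = trace_or_values.v if isinstance(trace_or_values, VoltageTrace) else np.asarray(
        trace_or_values, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 samples to binarize")
    if method == "median":
        thr = float(np.median(v))
    elif method == "mean":
        thr = float(np.mean(v))
    else:
        raise ValidationError(f"unknown binarization method {method!r}")
    bits = np.where(v > thr, "1", "0")
    return "".join(bits.tolist())


def lzw_phrase_count(s: str) -> int:
    """Number of output codes emitted by LZW compression of ``s``.

    The dictionary is initialized with the alphabet of single symbols
    ('0' and '1' for binary strings); each emitted code corresponds to the
    longest dictionary match, after which the match extended by one symbol
    joins the dictionary.
    """
    if not s:
        raise ValidationError("empty string")
    dictionary = {"0": 0, "1": 1}
    for ch in set(s) - set("01"):
        dictionary[ch] = len(dictionary)
    w = ""
    emitted = 0
    for ch in s:
        wc = w + ch
        if wc in dictionary:
            w = wc
        else:
            emitted += 1  # code for w
            dictionary[wc] = len(dictionary)
            w = ch
    if w:
        emitted += 1
    return emitted


def lzw_complexity(s: str) -> float:
    """LZW complexity ``C = |D(s)| / |s|``: emitted phrases per symbol."""
    return lzw_phrase_count(s) / len(s)


def _windows(v: np.ndarray, n_windows: int) -> list[np.ndarray]:
    """Split into ``n_windows`` equal non-overlapping windows, truncating the remainder."""
    if n_windows < 2:
        raise ValidationError("need at least 2 windows")
    wlen = v.size // n_windows
    if wlen < 2:
        raise ValidationError("windows would contain fewer than 2 samples")
    return [v[k * wlen:(k + 1) * wlen] for k in range(n_windows)]


def pci(trace: VoltageTrace, n_windows: int = 10, method: str = "median") -> float:
    """Whole-minus-parts complexity: ``C_whole - mean_i C_i``.

    The whole-signal term is evaluated over the same windows as the parts —
    each window of the *globally* binarized signal versus each window
    binarized by its *own* threshold — so that both terms compare strings of
    equal length (per-symbol LZW complexity is length-dependent, and mixing
    lengths would bias the difference).  A constant trace, or any
    concatenation of identical windows, scores exactly 0.
    """
    v = trace.v
    wins = _windows(v, n_windows)
    wlen = wins[0].size
    global_bits = binarize(v[: n_windows * wlen], method)
    c_whole = float(np.mean([
        lzw_complexity(global_bits[k * wlen:(k + 1) * wlen])
        for k in range(n_windows)]))
    c_parts = float(np.mean([lzw_complexity(binarize(w, method)) for w in wins]))
    return c_whole - c_parts


def _pair_mean(values: list[float], n_windows: int, divisor: str) -> float:
    total = float(np.sum(values))
    if divisor == "pairs":
        return total / (n_windows - 1)
    if divisor == "windows":
        return total / n_windows
    raise ValidationError(f"unknown divisor {divisor!r}")


def integration_score(trace: VoltageTrace, n_windows: int = 10,
                      divisor: str = "pairs") -> float:
    """Mean Pearson correlation of consecutive windows (zero lag).

    Zero-variance windows contribute a correlation of 0 with a warning.
    """
    wins = _windows(trace.v, n_windows)
    rs = []
    for a, b in zip(wins[:-1], wins[1:]):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            warnings.warn("zero-variance window; correlation set to 0", stacklevel=2)
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return _pair_mean(rs, n_windows, divisor)


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def integrated_information(trace: VoltageTrace, n_windows: int = 10, bins: int = 16,
                           divisor: str = "pairs") -> float:
    """``Phi = H(X) - mean_i MI(X_i, X_{i+1})`` in bits.

    ``H(X)`` is the Shannon entropy of the whole-signal histogram over
    ``bins`` equal-width bins spanning ``[min v, max v]``; mutual
    information pairs samples at the same offset within consecutive windows
    and uses the same global bin edges on both axes.  A constant trace (or
    any degenerate binning with all mass in one bin) yields 0 with a warning.
    """
    if bins < 2:
        raise ValidationError("need at least 2 bins")
    v = trace.v
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        warnings.warn("degenerate binning: constant signal, Phi = 0", stacklevel=2)
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    h_whole = _entropy_bits(np.histogram(v, bins=edges)[0])
    wins = _windows(v, n_windows)
    mis = []
    for a, b in zip(wins[:-1], wins[1:]):
        joint = np.histogram2d(a, b, bins=(edges, edges))[0]
        h_a = _entropy_bits(joint.sum(axis=1))
        h_b = _entropy_bits(joint.sum(axis=0))
        h_ab = _entropy_bits(joint.ravel())
        mis.append(max(h_a + h_b - h_ab, 0.0))
    return h_whole - _pair_mean(mis, n_windows, divisor)


def consciousness_report(trace: VoltageTrace, n_windows: int = 10, bins: int = 16,
                         method: str = "median", divisor: str = "pairs") -> ComplexityReport:
    """Bundle all four metrics for one trace under a single configuration."""
    s = binarize(trace, method)
    return ComplexityReport(
        label=trace.label,
        c_lzw=lzw_complexity(s),
        pci=pci(trace, n_windows, method),
        integration=integration_score(trace, n_windows, divisor),
        phi=integrated_information(trace, n_windows, bins, divisor),
        n_windows=n_windows, bins=bins, divisor=divisor,
    )
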