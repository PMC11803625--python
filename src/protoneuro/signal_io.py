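"""Core signal containers and CSV input/output.

Three containers cover the raw measurement modalities of a protocell
electrochemistry workflow:

* :class:`VoltageTrace` — spontaneous potential recordings (seconds / millivolts),
* :class:`Voltammogram` — multi-cycle cyclic-voltammetry sweeps (volts / microamperes),
* :class:`ImpedanceSpectrum` — complex impedance versus frequency (hertz / ohms).

Canonical internal units are fixed (s, mV for traces; V, uA for voltammetry;
Hz, Ohm for impedance) so every downstream statistic is reported in the units
the literature uses.  Potentiostat CSV dialects differ, so all readers accept a
``column_map`` that renames/locates columns and declares source units.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VoltageTrace",
    "Voltammogram",
    "ImpedanceSpectrum",
    "FormatError",
    "ValidationError",
    "read_trace",
    "read_voltammogram",
    "read_spectrum",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed into the expected columns."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


# conversion factors into canonical units, keyed by declared source unit
_TIME_FACTORS = {"s": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0}
_POTENTIAL_MV = {"mv": 1.0, "v": 1000.0, "uv": 1e-3}
_POTENTIAL_V = {"v": 1.0, "mv": 1e-3}
_CURRENT_UA = {"ua": 1.0, "a": 1e6, "ma": 1e3, "na": 1e-3}
_IMPEDANCE_OHM = {"ohm": 1.0, "kohm": 1e3, "mohm": 1e6}


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class VoltageTrace:
    """Potential-vs-time recording in seconds and millivolts.

    ``sample_interval`` is the uniform spacing if the trace is uniformly
    sampled (detected on construction), else ``None``.
    """

    t: np.ndarray
    v: np.ndarray
    label: str = ""
    sample_interval: float | None = field(default=None)

    def __post_init__(self):
        self.t = _as_1d(self.t, "t")
        self.v = _as_1d(self.v, "v")
        if self.t.size != self.v.size:
            raise ValidationError("t and v must have equal length")
        if self.t.size < 2:
            raise ValidationError("trace needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.v)):
            raise ValidationError("trace contains non-finite values")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("t must be strictly increasing")
        if self.sample_interval is None and np.allclose(dt, dt[0], rtol=1e-6, atol=0):
            self.sample_interval = float(dt[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


@dataclass
class Voltammogram:
    """Cyclic-voltammetry samples in volts and microamperes.

    ``cycle`` holds the 1-based cycle index per sample; it may be all zeros
    to mean "not yet segmented" (see :func:`protoneuro.voltammetry.segment_cycles`).
    """

    e: np.ndarray
    i: np.ndarray
    cycle: np.ndarray | None = None
    scan_rate: float = 0.1

    def __post_init__(self):
        self.e = _as_1d(self.e, "e")
        self.i = _as_1d(self.i, "i")
        if self.e.size != self.i.size:
            raise ValidationError("e and i must have equal length")
        if not (np.all(np.isfinite(self.e)) and np.all(np.isfinite(self.i))):
            raise ValidationError("voltammogram contains non-finite values")
        if self.scan_rate <= 0:
            raise ValidationError("scan_rate must be positive")
        if self.cycle is not None:
            self.cycle = np.asarray(self.cycle, dtype=int)
            if self.cycle.size != self.e.size:
                raise ValidationError("cycle index length mismatch")
            labels = np.unique(self.cycle)
            if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
                raise ValidationError("cycle indices must be contiguous starting at 1")

    @property
    def n_cycles(self) -> int:
        return 0 if self.cycle is None else int(self.cycle.max())

    def cycle_slice(self, n: int) -> "Voltammogram":
        """Return the samples of cycle ``n`` as a single-cycle voltammogram."""
        if self.cycle is None:
            raise ValidationError("voltammogram has no cycle indices; segment first")
        mask = self.cycle == n
        if not mask.any():
            raise ValidationError(f"no samples for cycle {n}")
        return Voltammogram(self.e[mask], self.i[mask],
                            np.ones(int(mask.sum()), dtype=int), self.scan_rate)

    def __len__(self) -> int:
        return self.e.size


@dataclass
class ImpedanceSpectrum:
    """Per-frequency complex impedance, rectangular form, in Hz and Ohm.

    Sign convention: capacitive points have ``z_im < 0``; the Nyquist
    "-Z''" ordinate is ``-z_im``.
    """

    f: np.ndarray
    z_re: np.ndarray
    z_im: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.f = _as_1d(self.f, "f")
        self.z_re = _as_1d(self.z_re, "z_re")
        self.z_im = _as_1d(self.z_im, "z_im")
        if not (self.f.size == self.z_re.size == self.z_im.size):
            raise ValidationError("f, z_re, z_im must have equal length")
        if self.f.size == 0:
            raise ValidationError("spectrum is empty")
        if np.any(self.f <= 0):
            raise ValidationError("frequencies must be positive")
        for arr in (self.f, self.z_re, self.z_im):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("spectrum contains non-finite values")

    @property
    def z(self) -> np.ndarray:
        """Complex impedance array."""
        return self.z_re + 1j * self.z_im

    def __len__(self) -> int:
        return self.f.size


def _sniff_read(path) -> pd.DataFrame:
    """Read a delimited text file, sniffing among comma/tab/semicolon."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"empty file: {path}")
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    return df


def _pick(df: pd.DataFrame, key, default_names: Sequence[str], what: str) -> np.ndarray:
    """Resolve a column by mapped name/index or by default header names."""
    col = None
    if key is not None:
        if isinstance(key, int):
            if key >= df.shape[1]:
                raise FormatError(f"column index {key} out of range for {what}")
            col = df.iloc[:, key]
        else:
            if key not in df.columns:
                raise FormatError(f"column {key!r} for {what} not found")
            col = df[key]
    else:
        lower = {str(c).strip().lower(): c for c in df.columns}
        for name in default_names:
            if name in lower:
                col = df[lower[name]]
                break
        if col is None:
            raise FormatError(
                f"cannot locate {what} column (tried {list(default_names)}); "
                "provide a column_map")
    values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).all():
        raise FormatError(f"{what} column is non-numeric")
    return values


def read_trace(path, column_map: Mapping | None = None) -> VoltageTrace:
    """Read a potential-vs-time CSV/TSV into a :class:`VoltageTrace`.

    ``column_map`` keys: ``time``, ``potential`` (names or 0-based indices),
    ``time_unit`` (s/ms/min/h), ``potential_unit`` (mV/V/uV), ``label``.
    """
    cmap = dict(column_map or {})
    df = _sniff_read(path)
    t = _pick(df, cmap.get("time"), ("time", "t", "time_s", "seconds"), "time")
    v = _pick(df, cmap.get("potential"), ("potential", "v", "voltage", "mv"), "potential")
    t = t * _TIME_FACTORS[str(cmap.get("time_unit", "s")).lower()]
    v = v * _POTENTIAL_MV[str(cmap.get("potential_unit", "mV")).lower()]
    return VoltageTrace(t, v, label=str(cmap.get("label", Path(path).stem)))


def read_voltammogram(path, column_map: Mapping | None = None) -> Voltammogram:
    """Read a (potential, current[, cycle]) CSV into a :class:`Voltammogram`.

    The cycle column is optional; absent cycles are assigned later by
    ``segment_cycles``.  ``column_map`` keys: ``potential``, ``current``,
    ``cycle``, ``scan_rate`` (V/s), ``potential_unit``, ``current_unit``.
    """
    cmap = dict(column_map or {})
    df = _sniff_read(path)
    e = _pick(df, cmap.get("potential"), ("potential", "e", "voltage"), "potential")
    i = _pick(df, cmap.get("current"), ("current", "i"), "current")
    e = e * _POTENTIAL_V[str(cmap.get("potential_unit", "V")).lower()]
    i = i * _CURRENT_UA[str(cmap.get("current_unit", "uA")).lower()]
    cycle = None
    cyc_key = cmap.get("cycle")
    lower = {str(c).strip().lower(): c for c in df.columns}
    if cyc_key is not None or "cycle" in lower:
        cycle = _pick(df, cyc_key, ("cycle", "n"), "cycle").astype(int)
    return Voltammogram(e, i, cycle, scan_rate=float(cmap.get("scan_rate", 0.1)))


def read_spectrum(path, column_map: Mapping | None = None) -> ImpedanceSpectrum:
    """Read an impedance spectrum CSV into rectangular form.

    Accepts either (z_re, z_im) columns or polar (|Z|, phase in degrees)
    columns, converting the latter to rectangular.  ``column_map`` keys:
    ``frequency``, ``zreal``, ``zimag`` or ``zmod``, ``zphase``,
    ``impedance_unit`` (ohm/kohm/mohm), ``label``.
    """
    cmap = dict(column_map or {})
    df = _sniff_read(path)
    f = _pick(df, cmap.get("frequency"), ("frequency", "f", "freq", "hz"), "frequency")
    scale = _IMPEDANCE_OHM[str(cmap.get("impedance_unit", "ohm")).lower()]
    lower = {str(c).strip().lower() for c in df.columns}
    polar_requested = "zmod" in cmap or "zphase" in cmap
    polar_detected = bool({"zmod", "|z|", "zphase", "phase"} & lower) and not (
        {"zreal", "z_re", "zre"} & lower)
    if polar_requested or polar_detected:
        mod = _pick(df, cmap.get("zmod"), ("zmod", "|z|", "magnitude"), "|Z|") * scale
        ph = _pick(df, cmap.get("zphase"), ("zphase", "phase", "phi"), "phase")
        z_re = mod * np.cos(np.deg2rad(ph))
        z_im = mod * np.sin(np.deg2rad(ph))
    else:
        z_re = _pick(df, cmap.get("zreal"), ("zreal", "z_re", "zre", "re"), "Z'") * scale
        z_im = _pick(df, cmap.get("zimag"), ("zimag", "z_im", "zim", "im"), "Z''") * scale
    return ImpedanceSpectrum(f, z_re, z_im, label=str(cmap.get("label", Path(path).stem)))


def write_report(results, path) -> Path:
    """Write analysis results to CSV (plus a human-readable .txt summary).

    ``results`` may be a DataFrame, a list of dataclasses/dicts, or a single
    mapping.  Values round-trip through :func:`read_report` within float
    precision.  Returns the CSV path.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        df = results
    elif isinstance(results, Mapping):
        df = pd.DataFrame([results])
    else:
        rows = []
        for r in results:
            if hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    summary = path.with_suffix(".txt")
    with open(summary, "w") as fh:
        fh.write(f"rows: {len(df)}\ncolumns: {', '.join(map(str, df.columns))}\n")
        if len(df):
            desc = df.select_dtypes("number")
            if not desc.empty:
                fh.write(desc.describe().to_string())
                fh.write("\n")
    return path


def read_report(path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_report`."""
    return pd.read_csv(path)
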