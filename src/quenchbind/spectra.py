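"""Spectral data containers, CSV I/O, and signal utilities.

A :class:`Spectrum` is a 1-D wavelength/value series (emission, excitation,
absorbance, synchronous-scan or circular-dichroism data); an :class:`EEM`
is an excitation-emission matrix.  The module also provides linear-grid
resampling, Savitzky-Golay second derivatives, prominence-filtered peak
picking with parabolic sub-gridpoint refinement, and the inner-filter
correction applied to raw fluorescence intensities before any quenching
analysis.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "EEM",
    "SPECTRUM_KINDS",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_eem_csv",
    "write_eem_csv",
    "correct_inner_filter",
    "resample_to_grid",
    "second_derivative",
    "find_peaks",
]

SPECTRUM_KINDS = ("emission", "excitation", "absorbance", "cd", "synchronous")


@dataclass
class Spectrum:
    """A single-channel spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelengths in nm, strictly increasing, length >= 2.
    values : array-like
        Intensities (arbitrary units), absorbances (AU, must be >= 0) or
        mean residue ellipticities (deg·cm²·dmol⁻¹), matching
        ``wavelengths`` in length.
    kind : str
        One of ``emission``, ``excitation``, ``absorbance``, ``cd``,
        ``synchronous``.
    meta : dict
        Free-form labels (temperature in K, Δλ offset in nm, analyte
        concentrations in M, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "emission"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}")
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if len(self.wavelengths) != len(self.values):
            raise ValueError(
                f"length mismatch: {len(self.wavelengths)} wavelengths vs {len(self.values)} values"
            )
        if len(self.wavelengths) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.wavelengths)) or not np.all(np.isfinite(self.values)):
            raise ValueError("wavelengths and values must be finite")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind == "absorbance" and np.any(self.values < 0):
            raise ValueError("absorbance values must be >= 0")

    def __len__(self) -> int:
        return len(self.wavelengths)

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at ``wavelength`` (nm); no extrapolation."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if wavelength < lo or wavelength > hi:
            raise ValueError(f"{wavelength} nm outside spectral range [{lo}, {hi}] nm")
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, values=self.values * factor, meta=dict(self.meta))

    def plot(self, ax=None, **kwargs):
        """Quick-look line plot; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavelengths, self.values, **kwargs)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel({"absorbance": "absorbance (AU)", "cd": "MRE (deg·cm²·dmol⁻¹)"}.get(
            self.kind, "intensity (a.u.)"))
        return ax


@dataclass
class EEM:
    """Excitation-emission matrix: intensities indexed ``[excitation][emission]``."""

    ex_wavelengths: np.ndarray
    em_wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ex_wavelengths = np.asarray(self.ex_wavelengths, dtype=float)
        self.em_wavelengths = np.asarray(self.em_wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ex_wavelengths.size == 0 or self.em_wavelengths.size == 0:
            raise ValueError("EEM axes must be non-empty")
        if np.any(np.diff(self.ex_wavelengths) <= 0) or np.any(np.diff(self.em_wavelengths) <= 0):
            raise ValueError("EEM wavelength axes must be strictly increasing")
        if self.intensities.shape != (len(self.ex_wavelengths), len(self.em_wavelengths)):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match axes "
                f"({len(self.ex_wavelengths)}, {len(self.em_wavelengths)})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("EEM intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("EEM intensities must be >= 0")


def _sniff_delimiter(sample: str) -> str:
    # comma or tab only; fall back to comma
    first_line = sample.splitlines()[0] if sample.splitlines() else ""
    return "\t" if first_line.count("\t") >= first_line.count(",") and "\t" in first_line else ","


def read_spectrum_csv(path, kind: str = "emission") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV or TSV file.

    A single header line is auto-detected (first row non-numeric).  Rows
    are sorted ascending by wavelength; duplicate wavelengths are an error.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    wl, vals = [], []
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    for lineno, row in enumerate(reader, start=1):
        row = [c.strip() for c in row if c.strip() != ""]
        if not row:
            continue
        if len(row) < 2:
            raise ValueError(f"{path}: line {lineno}: expected two columns, got {row!r}")
        try:
            w, v = float(row[0]), float(row[1])
        except ValueError:
            if lineno == 1 and not wl:
                continue  # header
            raise ValueError(f"{path}: line {lineno}: non-numeric payload {row!r}") from None
        wl.append(w)
        vals.append(v)
    if len(wl) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    wl = np.asarray(wl)
    vals = np.asarray(vals)
    order = np.argsort(wl, kind="stable")
    wl, vals = wl[order], vals[order]
    if np.any(np.diff(wl) == 0):
        dup = wl[np.where(np.diff(wl) == 0)[0][0]]
        raise ValueError(f"{path}: duplicate wavelength {dup} nm")
    return Spectrum(wl, vals, kind=kind, meta={"source": str(path)})


def write_spectrum_csv(s: Spectrum, path, header: bool = True) -> None:
    """Write a spectrum as a two-column CSV, round-tripping values exactly."""
    path = Path(path)
    lines = []
    if header:
        lines.append("wavelength_nm,value")
    for w, v in zip(s.wavelengths, s.values):
        lines.append(f"{float(w)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_eem_csv(path) -> EEM:
    """Read an EEM matrix CSV: first row = emission grid, first column = excitation grid."""
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delim) if any(c.strip() for c in r)]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise ValueError(f"{path}: EEM matrix needs at least one excitation and one emission point")
    em = np.asarray([float(c) for c in rows[0][1:]])
    ex = np.asarray([float(r[0]) for r in rows[1:]])
    inten = np.asarray([[float(c) for c in r[1:]] for r in rows[1:]])
    return EEM(ex, em, inten, meta={"source": str(path)})


def write_eem_csv(eem: EEM, path) -> None:
    path = Path(path)
    lines = ["," + ",".join(repr(float(w)) for w in eem.em_wavelengths)]
    for i, ex in enumerate(eem.ex_wavelengths):
        lines.append(repr(float(ex)) + "," + ",".join(repr(float(v)) for v in eem.intensities[i]))
    path.write_text("\n".join(lines) + "\n")


def correct_inner_filter(F_obs, A_ex, A_em, mode: str = "standard"):
    """Correct fluorescence intensities for the inner-filter effect.

    The inner-filter effect attenuates both the excitation beam and the
    emitted light in proportion to the sample's absorbance at the two
    wavelengths, biasing measured intensities downward.  The standard
    correction is

        F_cor = F_obs · 10^((A_ex + A_em) / 2).

    ``mode="literature_alt"`` instead applies F_obs · e^((A_ex − A_em)/2),
    a variant that circulates in the albumin-binding literature; for
    matched absorbances it is a no-op and cannot remove the attenuation,
    so it is retained for comparison only and is never the default.

    Accepts scalars or arrays; all absorbances must be >= 0.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValueError("absorbances must be >= 0")
    if np.any(F_obs < 0):
        raise ValueError("observed intensity must be >= 0")
    if mode == "standard":
        out = F_obs * 10.0 ** ((A_ex + A_em) / 2.0)
    elif mode == "literature_alt":
        out = F_obs * np.exp((A_ex - A_em) / 2.0)
    else:
        raise ValueError(f"unknown inner-filter mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def resample_to_grid(s: Spectrum, grid) -> Spectrum:
    """Linearly interpolate ``s`` onto ``grid`` (nm, ascending). No extrapolation."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < s.wavelengths[0] or grid.max() > s.wavelengths[-1]:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] nm outside source range "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}] nm (no extrapolation)"
        )
    vals = np.interp(grid, s.wavelengths, s.values)
    return Spectrum(grid, vals, kind=s.kind, meta=dict(s.meta))


def second_derivative(s: Spectrum, window: int = 7) -> Spectrum:
    """Smoothed second derivative via a quadratic Savitzky-Golay filter.

    Requires a uniform wavelength grid; ``window`` is an odd point count
    >= 3 and < len(s).  The first and last ``window // 2`` output points
    are padded with the nearest interior estimate.
    """
    steps = np.diff(s.wavelengths)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform wavelength grid: resample_to_grid onto a uniform grid first")
    n = len(s)
    if window < 3 or window % 2 == 0 or window >= n:
        raise ValueError(f"window must be odd, >= 3 and < {n}; got {window}")
    d2 = savgol_filter(s.values, window, polyorder=2, deriv=2, delta=float(steps[0]), mode="interp")
    half = window // 2
    d2[:half] = d2[half]
    d2[-half:] = d2[-half - 1]
    meta = dict(s.meta)
    meta["derivative_order"] = 2
    return Spectrum(s.wavelengths, d2, kind=s.kind, meta=meta)


def find_peaks(s: Spectrum, min_prominence: float = 0.05):
    """Local maxima with prominence above ``min_prominence`` × max(values).

    Peak positions are refined by parabolic interpolation through the three
    points bracketing each discrete maximum; ties between equal adjacent
    maxima break toward the lower wavelength.  Returns a list of
    ``(wavelength_nm, value)`` sorted by wavelength (possibly empty).
    """
    if not 0 < min_prominence <= 1:
        raise ValueError("min_prominence must be in (0, 1]")
    y = s.values
    vmax = y.max()
    span = vmax - y.min()
    if span == 0:
        return []
    idx, props = _scipy_find_peaks(y, prominence=min_prominence * abs(vmax), plateau_size=1)
    # plateau tie-break toward lower wavelength
    idx = props.get("left_edges", idx)
    out = []
    for i in idx:
        i = int(i)
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            step = s.wavelengths[i + 1] - s.wavelengths[i] if delta >= 0 else s.wavelengths[i] - s.wavelengths[i - 1]
            wl = s.wavelengths[i] + delta * step
            val = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
        else:
            wl, val = s.wavelengths[i], y[i]
        out.append((float(wl), float(val)))
    out.sort(key=lambda p: p[0])
    return out
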