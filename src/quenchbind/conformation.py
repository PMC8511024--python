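"""Conformational and microenvironment diagnostics.

Three complementary probes of ligand-induced structural change in the
protein:

* synchronous fluorescence (constant excitation-emission offset Δλ;
  Δλ = 15 nm isolates tyrosine, Δλ = 60 nm tryptophan) — a red-shift of
  the band maximum on binding indicates increased polarity around the
  residue class, a blue-shift increased hydrophobicity;
* the 3-D excitation-emission matrix, with the first-order Rayleigh
  ridge (peak A, λ_em = λ_ex), the Trp/Tyr band (peak B, ex≈280/em≈340)
  and the polypeptide band (peak C, ex≈236/em≈335);
* far-UV circular dichroism, summarized as α-helix content from the mean
  residue ellipticity at 208 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .constants import (
    BSA_MEAN_RESIDUE_WEIGHT,
    CANONICAL_EEM_PEAKS,
    EEM_MATCH_RADIUS_NM,
    MRE208_COIL,
    MRE208_HELIX,
)
from .spectra import EEM, Spectrum, find_peaks

__all__ = [
    "ShiftReport",
    "EEMPeak",
    "synchronous_shift_analysis",
    "extract_3d_peaks",
    "helix_content_from_cd",
    "mre_from_ellipticity",
]


@dataclass
class ShiftReport:
    """Synchronous-fluorescence comparison of free vs ligand-bound protein."""

    residue_class: str          # "Tyr" (Δλ=15) or "Trp" (Δλ=60)
    delta_lambda: float         # nm
    lambda_max_free: float      # nm
    lambda_max_bound: float     # nm
    shift: float                # nm, signed bound − free
    quench_fraction: float      # fractional intensity loss at free λ_max
    interpretation: str         # increased_polarity | increased_hydrophobicity | no_change

    def summary(self) -> str:
        return (f"{self.residue_class} (Δλ = {self.delta_lambda:g} nm): "
                f"λ_max {self.lambda_max_free:.1f} → {self.lambda_max_bound:.1f} nm "
                f"(shift {self.shift:+.1f} nm), quench {100 * self.quench_fraction:.1f}% "
                f"→ {self.interpretation}")


_RESIDUE_CLASS = {15: "Tyr", 60: "Trp"}


def synchronous_shift_analysis(free: Spectrum, bound: Spectrum, delta_lambda: float,
                               shift_tolerance: float = 1.0,
                               min_prominence: float = 0.05) -> ShiftReport:
    """Compare synchronous-scan band maxima of free and ligand-bound protein.

    λ_max is the largest prominence-filtered peak of each spectrum; the
    signed shift (bound − free) beyond ``shift_tolerance`` (default 1 nm,
    a typical instrument step) is interpreted as increased polarity
    (red-shift) or increased hydrophobicity (blue-shift).  The quench
    fraction is the relative intensity loss at the free λ_max.
    """
    residue = _RESIDUE_CLASS.get(int(round(delta_lambda)), f"Δλ={delta_lambda:g}")
    peaks_free = find_peaks(free, min_prominence)
    peaks_bound = find_peaks(bound, min_prominence)
    if not peaks_free or not peaks_bound:
        raise ValueError("no detectable peak in free and/or bound synchronous spectrum")
    wl_free, val_free = max(peaks_free, key=lambda p: p[1])
    wl_bound, _ = max(peaks_bound, key=lambda p: p[1])
    shift = wl_bound - wl_free
    if shift > shift_tolerance:
        interp = "increased_polarity"
    elif shift < -shift_tolerance:
        interp = "increased_hydrophobicity"
    else:
        interp = "no_change"
    quench = 1.0 - bound.value_at(wl_free) / val_free if val_free > 0 else 0.0
    return ShiftReport(residue, float(delta_lambda), wl_free, wl_bound,
                       float(shift), float(quench), interp)


@dataclass
class EEMPeak:
    label: str  # "A" (Rayleigh), "B", "C", or "other"
    ex: float   # nm
    em: float   # nm
    intensity: float


def extract_3d_peaks(eem: EEM, rayleigh_band_halfwidth: float = 5.0,
                     canonical: dict | None = None,
                     match_radius: float = EEM_MATCH_RADIUS_NM,
                     min_intensity_frac: float = 0.05) -> list[EEMPeak]:
    """Locate and label the characteristic peaks of an excitation-emission
    matrix.

    Peak A is the intensity maximum along the first-order Rayleigh
    scattering ridge |λ_em − λ_ex| <= ``rayleigh_band_halfwidth``.  Off the
    ridge, strict 8-neighbour local maxima above
    ``min_intensity_frac`` × dynamic range are labeled by proximity to the
    canonical coordinates (B: Trp/Tyr, C: polypeptide) when within
    ``match_radius`` nm, else "other".
    """
    if canonical is None:
        canonical = CANONICAL_EEM_PEAKS
    Z = eem.intensities
    if Z.size == 0:
        raise ValueError("empty EEM")
    exg, emg = eem.ex_wavelengths, eem.em_wavelengths
    dm = np.abs(emg[None, :] - exg[:, None])
    ridge = dm <= rayleigh_band_halfwidth
    peaks: list[EEMPeak] = []
    if ridge.any():
        masked = np.where(ridge, Z, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), Z.shape)
        if np.isfinite(masked[i, j]) and Z[i, j] > 0:
            peaks.append(EEMPeak("A", float(exg[i]), float(emg[j]), float(Z[i, j])))
    # off-ridge local maxima
    zmin, zmax = float(Z.min()), float(Z.max())
    thresh = zmin + min_intensity_frac * (zmax - zmin)
    if zmax > zmin:
        local_max = Z == ndimage.maximum_filter(Z, size=3, mode="nearest")
        cand = local_max & ~ridge & (Z > thresh)
        for i, j in zip(*np.where(cand)):
            if not _is_plateau_leader(Z, int(i), int(j)):
                continue
            ex, em = float(exg[i]), float(emg[j])
            label = "other"
            for name, (cex, cem) in canonical.items():
                if np.hypot(ex - cex, em - cem) <= match_radius:
                    label = name
                    break
            peaks.append(EEMPeak(label, ex, em, float(Z[i, j])))
    order = {"A": 0, "B": 1, "C": 2}
    peaks.sort(key=lambda p: (order.get(p.label, 3), -p.intensity))
    return peaks


def _is_plateau_leader(Z, i, j) -> bool:
    """Tie-break flat plateaus: among equal-valued neighbours keep only the
    lowest (excitation, emission) index cell."""
    i0, j0 = max(i - 1, 0), max(j - 1, 0)
    patch = Z[i0:i + 2, j0:j + 2]
    ii, jj = np.where(patch == Z[i, j])
    coords = sorted(zip(ii + i0, jj + j0))
    return coords[0] == (i, j)


def mre_from_ellipticity(theta_deg: np.ndarray | float, path_length_cm: float,
                         concentration_g_per_ml: float,
                         mean_residue_weight: float = BSA_MEAN_RESIDUE_WEIGHT):
    """Convert raw ellipticity θ (deg) to mean residue ellipticity
    (deg·cm²·dmol⁻¹): MRE = θ·MRW / (10·l·c) with l in cm and c in g/mL."""
    if path_length_cm <= 0 or concentration_g_per_ml <= 0:
        raise ValueError("path length and concentration must be > 0")
    return np.asarray(theta_deg, dtype=float) * mean_residue_weight / (
        10.0 * path_length_cm * concentration_g_per_ml)


def helix_content_from_cd(cd: Spectrum) -> float:
    """Percent α-helix from the mean residue ellipticity at 208 nm.

    Uses the standard single-wavelength estimator
    %α = 100·(−MRE(208) − 4000)/(33000 − 4000), anchored at the coil
    (−4000) and pure-helix (−33000) limits; values outside [0, 100] are
    clipped with a warning.  The spectrum must cover 208 nm and be in
    MRE units (convert raw ellipticity with :func:`mre_from_ellipticity`).
    """
    mre208 = cd.value_at(208.0)  # raises if 208 nm is out of range
    pct = 100.0 * (-mre208 - (-MRE208_COIL)) / ((-MRE208_HELIX) - (-MRE208_COIL))
    if pct < -1e-9 or pct > 100 + 1e-9:
        warnings.warn(f"helix estimator out of range ({pct:.1f}%); clipping to [0, 100]",
                      stacklevel=2)
    pct = float(np.clip(pct, 0.0, 100.0))
    return pct
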