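"""Förster resonance energy transfer (FRET) between a protein donor and a
bound small-molecule acceptor.

The pipeline: the spectral overlap integral J between the donor's emission
and the acceptor's molar absorptivity,

    J = ∫ F(λ)·ε(λ)·λ⁴ dλ / ∫ F(λ) dλ        [M⁻¹·cm⁻¹·nm⁴],

feeds the Förster radius

    R0 = 0.211 · (κ²·Φ_D·J / n⁴)^(1/6)        [Å, returned in nm],

where κ² is the dipole orientation factor (presets 0.667 for dynamic and
0.475 for static averaging), Φ_D the donor quantum yield and n the medium
refractive index.  The transfer efficiency E = 1 − F/F0 then gives the
donor-acceptor distance r = R0·((1−E)/E)^(1/6), i.e. the inversion of
E = R0⁶/(R0⁶ + r⁶).  FRET distances are considered physically meaningful
in the 2-8 nm window and within 0.5·R0 to 1.5·R0.

Unit path for R0: with λ in nm and ε in M⁻¹·cm⁻¹ the constant 0.211
yields R0 in Å; the return value is divided by 10 to give nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KAPPA2_DYNAMIC, KAPPA2_STATIC
from .spectra import Spectrum, resample_to_grid

__all__ = [
    "FretResult",
    "overlap_integral",
    "forster_radius",
    "transfer_efficiency",
    "donor_acceptor_distance",
    "assess_fret_validity",
    "epsilon_from_absorbance",
    "fret_analysis",
]

#: FRET is physically meaningful between these donor-acceptor distances (nm).
FRET_RANGE_NM = (2.0, 8.0)


def overlap_integral(donor_emission: Spectrum, acceptor_epsilon: Spectrum) -> float:
    """Spectral overlap integral J in M⁻¹·cm⁻¹·nm⁴.

    Both spectra are resampled to a common 1 nm grid over the intersection
    of their wavelength ranges (which must span at least 5 nm) and the
    integrals are taken by the composite trapezoid rule.
    """
    lo = max(donor_emission.wavelengths[0], acceptor_epsilon.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1], acceptor_epsilon.wavelengths[-1])
    if hi - lo < 5.0:
        raise ValueError(f"spectra overlap only {max(hi - lo, 0):.1f} nm (< 5 nm)")
    grid = np.arange(lo, hi + 0.5, 1.0)
    grid = grid[grid <= hi]
    F = resample_to_grid(donor_emission, grid).values
    eps = resample_to_grid(acceptor_epsilon, grid).values
    denom = np.trapezoid(F, grid)
    if denom <= 0:
        raise ValueError("donor emission integrates to zero over the overlap region")
    num = np.trapezoid(F * eps * grid**4, grid)
    return float(num / denom)


def forster_radius(J: float, kappa2: float, phi_D: float, refractive_index: float) -> float:
    """Förster radius R0 in nm from J (M⁻¹·cm⁻¹·nm⁴), κ², Φ_D and n."""
    if refractive_index <= 0:
        raise ValueError("refractive index must be > 0")
    if not 0 <= kappa2 <= 4:
        raise ValueError("orientation factor κ² must be in [0, 4]")
    if J < 0 or phi_D < 0:
        raise ValueError("J and Φ_D must be >= 0")
    r0_angstrom = 0.211 * (kappa2 * phi_D * J / refractive_index**4) ** (1.0 / 6.0)
    return r0_angstrom / 10.0  # Å → nm


def transfer_efficiency(F: float, F0: float) -> float:
    """Transfer efficiency E = 1 − F/F0 from donor intensities with and
    without the acceptor."""
    if F0 <= 0:
        raise ValueError("F0 must be > 0")
    if F < 0 or F > F0:
        raise ValueError("need 0 <= F <= F0")
    return 1.0 - F / F0


def donor_acceptor_distance(E: float, R0: float) -> float:
    """Distance r (nm) from efficiency E ∈ (0, 1) and Förster radius R0,
    inverting E = R0⁶/(R0⁶ + r⁶)."""
    if not 0 < E < 1:
        raise ValueError("E must be strictly between 0 and 1 (distance unbounded/zero otherwise)")
    if R0 <= 0:
        raise ValueError("R0 must be > 0")
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)


def assess_fret_validity(r: float, R0: float) -> tuple[bool, list[str]]:
    """Check r against the 2-8 nm window and the 0.5·R0-1.5·R0 band
    (bounds inclusive); returns (valid, list of failed-bound reasons)."""
    if r <= 0 or R0 <= 0:
        raise ValueError("r and R0 must be > 0")
    reasons = []
    if not FRET_RANGE_NM[0] <= r <= FRET_RANGE_NM[1]:
        reasons.append(f"outside {FRET_RANGE_NM[0]:g}-{FRET_RANGE_NM[1]:g} nm")
    if not 0.5 * R0 <= r <= 1.5 * R0:
        reasons.append("outside 0.5·R0-1.5·R0")
    return (not reasons, reasons)


def epsilon_from_absorbance(absorbance: Spectrum, concentration_M: float,
                            path_length_cm: float = 1.0) -> Spectrum:
    """Convert an absorbance spectrum to molar absorptivity ε = A/(c·l),
    M⁻¹·cm⁻¹."""
    if concentration_M <= 0 or path_length_cm <= 0:
        raise ValueError("concentration and path length must be > 0")
    meta = dict(absorbance.meta)
    meta["units"] = "M-1 cm-1"
    return Spectrum(absorbance.wavelengths, absorbance.values / (concentration_M * path_length_cm),
                    kind=absorbance.kind, meta=meta)


@dataclass
class FretResult:
    """Full FRET characterization under one or more κ² assumptions."""

    J: float  # M⁻¹·cm⁻¹·nm⁴
    E: float
    phi_D: float
    refractive_index: float
    R0_by_kappa2: dict = field(default_factory=dict)  # κ² -> nm
    r_by_kappa2: dict = field(default_factory=dict)   # κ² -> nm
    valid: dict = field(default_factory=dict)         # κ² -> bool
    reasons: dict = field(default_factory=dict)       # κ² -> list[str]

    def summary(self) -> str:
        lines = [
            "FRET analysis",
            "-------------",
            f"J             {self.J:.4g} M⁻¹·cm⁻¹·nm⁴",
            f"E             {self.E:.4f}   (Φ_D = {self.phi_D:g}, n = {self.refractive_index:g})",
        ]
        for k2 in sorted(self.R0_by_kappa2):
            r = self.r_by_kappa2.get(k2)
            ok = self.valid.get(k2)
            lines.append(f"κ² = {k2:<6g} R0 = {self.R0_by_kappa2[k2]:.2f} nm   "
                         f"r = {r:.2f} nm   {'valid' if ok else 'INVALID: ' + '; '.join(self.reasons[k2])}")
        return "\n".join(lines)


def fret_analysis(donor_emission: Spectrum, acceptor_epsilon: Spectrum,
                  F: float, F0: float, phi_D: float = 0.15,
                  refractive_index: float = 1.336,
                  kappa2: tuple = (KAPPA2_STATIC, KAPPA2_DYNAMIC)) -> FretResult:
    """End-to-end FRET characterization from spectra and one titration point.

    Computes J, then R0, r and the validity assessment for each κ² preset.
    """
    J = overlap_integral(donor_emission, acceptor_epsilon)
    E = transfer_efficiency(F, F0)
    res = FretResult(J=J, E=E, phi_D=phi_D, refractive_index=refractive_index)
    for k2 in kappa2:
        R0 = forster_radius(J, k2, phi_D, refractive_index)
        res.R0_by_kappa2[k2] = R0
        if 0 < E < 1 and R0 > 0:
            r = donor_acceptor_distance(E, R0)
            res.r_by_kappa2[k2] = r
            ok, why = assess_fret_validity(r, R0)
            res.valid[k2] = ok
            res.reasons[k2] = why
    return res
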