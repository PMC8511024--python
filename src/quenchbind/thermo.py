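"""Van't Hoff thermodynamics of the binding equilibrium.

ln K_A is regressed on 1/T:

    ln K_A = −ΔH°/(R·T) + ΔS°/R

so ΔH° = −R·slope and ΔS° = R·intercept, with the Gibbs energy at each
temperature from ΔG° = ΔH° − T·ΔS°.  The sign pattern of (ΔH°, ΔS°) maps
to the dominant non-covalent force via the Ross-Subramanian rules.

Units follow the conventional mixed bookkeeping: ΔH° and ΔG° in kJ·mol⁻¹,
ΔS° in J·mol⁻¹·K⁻¹ (the type signatures make this explicit; conversions
are centralized here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .constants import KCAL_TO_KJ, R_GAS

__all__ = [
    "ThermoResult",
    "VantHoffModel",
    "fit_vant_hoff",
    "gibbs_free_energy",
    "classify_binding_forces",
    "kcal_to_kj",
]

#: |ΔH°| (kJ·mol⁻¹) or |ΔS°| (J·mol⁻¹·K⁻¹) below which the force call is
#: flagged as weak evidence.
WEAK_EVIDENCE_TOL = 1.0


def gibbs_free_energy(dH: float, dS: float, T: float) -> float:
    """ΔG°(T) = ΔH° − T·ΔS° in kJ·mol⁻¹ (dH in kJ·mol⁻¹, dS in J·mol⁻¹·K⁻¹)."""
    if T <= 0:
        raise ValueError("temperature must be > 0 K")
    return dH - T * dS / 1000.0


def classify_binding_forces(dH: float, dS: float) -> str:
    """Ross-Subramanian sign rules for the dominant non-covalent force.

    (−, −) → hydrogen bonding / van der Waals; (−, +) → electrostatic;
    (+, +) → hydrophobic; (+, −) → flagged ``invalid`` (thermodynamically
    implausible for a spontaneous association).  A value of exactly zero
    is treated as non-negative.
    """
    if dH < 0 and dS < 0:
        return "hbond_vdw"
    if dH < 0:
        return "electrostatic"
    if dS >= 0:
        return "hydrophobic"
    return "invalid"


def kcal_to_kj(e: float) -> float:
    """Convert kcal·mol⁻¹ to kJ·mol⁻¹ (thermochemical calorie, ×4.184)."""
    return e * KCAL_TO_KJ


@dataclass
class ThermoResult:
    """Fitted Van't Hoff thermodynamics for a binding equilibrium."""

    dH: float  # kJ·mol⁻¹
    dS: float  # J·mol⁻¹·K⁻¹
    dH_se: float
    dS_se: float
    r2_vanthoff: float
    dG_by_T: dict  # K -> kJ·mol⁻¹
    force_class: str
    weak_evidence: bool
    nobs: int

    @property
    def spontaneous(self) -> dict:
        """Per-temperature spontaneity: ΔG°(T) < 0."""
        return {T: g < 0 for T, g in self.dG_by_T.items()}

    def gibbs(self, T: float) -> float:
        return gibbs_free_energy(self.dH, self.dS, T)

    def predicted_KA(self, T: float) -> float:
        """K_A(T) regenerated from the fitted line (M⁻¹)."""
        return float(np.exp(-self.dH * 1000.0 / (R_GAS * T) + self.dS / R_GAS))

    def summary(self) -> str:
        lines = [
            "Van't Hoff thermodynamics",
            "-------------------------",
            f"ΔH°           {self.dH:.3f} ± {self.dH_se:.3f} kJ·mol⁻¹",
            f"ΔS°           {self.dS:.3f} ± {self.dS_se:.3f} J·mol⁻¹·K⁻¹",
            f"r²            {self.r2_vanthoff:.4f}   (n = {self.nobs})",
            f"force class   {self.force_class}" + ("  (weak evidence)" if self.weak_evidence else ""),
        ]
        for T in sorted(self.dG_by_T):
            g = self.dG_by_T[T]
            lines.append(f"ΔG°({T:.0f} K)   {g:.3f} kJ·mol⁻¹  "
                         f"({'spontaneous' if g < 0 else 'nonspontaneous'})")
        return "\n".join(lines)


class VantHoffModel:
    """Linear Van't Hoff model for binding constants measured at several
    temperatures.

    Parameters
    ----------
    KA_by_T : mapping
        Temperature (K) → binding constant K_A (M⁻¹); at least two distinct
        temperatures, all K_A > 0.
    """

    def __init__(self, KA_by_T: Mapping[float, float]):
        temps = np.asarray(sorted(KA_by_T), dtype=float)
        if len(temps) < 2:
            raise ValueError("Van't Hoff fit needs K_A at >= 2 temperatures")
        if len(np.unique(temps)) != len(temps):
            raise ValueError("duplicate temperatures")
        KA = np.asarray([KA_by_T[T] for T in temps], dtype=float)
        if np.any(KA <= 0):
            raise ValueError("all binding constants must be > 0")
        if np.any(temps <= 0):
            raise ValueError("temperatures must be > 0 K")
        self.temperatures = temps
        self.KA = KA

    def fit(self) -> ThermoResult:
        x = 1.0 / self.temperatures
        y = np.log(self.KA)
        if len(x) == 2:
            # closed form; linregress SEs are undefined at 0 dof
            slope = (y[1] - y[0]) / (x[1] - x[0])
            intercept = y[0] - slope * x[0]
            slope_se = intercept_se = float("nan")
            r2 = 1.0
        else:
            lr = stats.linregress(x, y)
            slope, intercept = float(lr.slope), float(lr.intercept)
            slope_se, intercept_se = float(lr.stderr), float(lr.intercept_stderr)
            r2 = float(lr.rvalue**2)
        dH = -R_GAS * slope / 1000.0  # kJ·mol⁻¹
        dS = R_GAS * intercept        # J·mol⁻¹·K⁻¹
        dH_se = R_GAS * slope_se / 1000.0 if np.isfinite(slope_se) else float("nan")
        dS_se = R_GAS * intercept_se if np.isfinite(intercept_se) else float("nan")
        dG = {float(T): gibbs_free_energy(dH, dS, float(T)) for T in self.temperatures}
        force = classify_binding_forces(dH, dS)
        weak = abs(dH) < WEAK_EVIDENCE_TOL or abs(dS) < WEAK_EVIDENCE_TOL
        return ThermoResult(dH, dS, dH_se, dS_se, r2, dG, force, weak, len(x))


def fit_vant_hoff(KA_by_T: Mapping[float, float]) -> ThermoResult:
    """Convenience wrapper: ``VantHoffModel(KA_by_T).fit()``."""
    return VantHoffModel(KA_by_T).fit()
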