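"""Synthetic fluorometer output with known ground truth.

Every analysis stage in this package can be exercised without instrument
data: titrations are generated from the Hill isotherm with binding
constants laid exactly on a Van't Hoff line, emission/absorptivity pairs
and synchronous scans as Gaussian bands, CD curves as helix/coil basis
mixtures, and excitation-emission matrices as a Rayleigh ridge plus
Gaussian peaks.  The defaults reproduce the study conditions for a serum
albumin (4 µM, emission maximum 340 nm, excitation 280 nm) titrated with
a quinoline-type ligand (absorption maximum 254 nm) over eleven quencher
concentrations from 0 to 170 µM at 290/300/310 K.

Measurement noise is multiplicative Gaussian (constant relative error);
negative draws are resampled so intensities stay positive.  All
stochastic output is reproducible from the ``seed`` field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_Q_GRID_UM, R_GAS
from .spectra import EEM, Spectrum
from .quenching import TitrationSeries

__all__ = [
    "SimulationConfig",
    "simulate_titration_series",
    "simulate_spectra_pair",
    "simulate_synchronous_set",
    "simulate_cd_spectrum",
    "simulate_eem",
    "truncated_gaussian",
]


def truncated_gaussian(grid: np.ndarray, center: float, width: float,
                       amplitude: float = 1.0, support_sigmas: float = 5.0) -> np.ndarray:
    """Gaussian band with compact support (zero beyond ``support_sigmas``·σ),
    so that nominally disjoint bands have exactly zero product."""
    x = (np.asarray(grid, dtype=float) - center) / width
    y = amplitude * np.exp(-0.5 * x**2)
    y[np.abs(x) > support_sigmas] = 0.0
    return y


@dataclass
class SimulationConfig:
    """Ground truth and design of a quenching titration experiment.

    ``dH`` (kJ·mol⁻¹) and ``dS`` (J·mol⁻¹·K⁻¹) set K_A(T) on an exact
    Van't Hoff line; ``hill_n`` the cooperativity; ``Q_grid`` the quencher
    concentrations in M (default: the 11-point 0-170 µM design);
    ``mechanism`` selects the static (ground-state complex, Hill isotherm)
    or dynamic (collisional, Arrhenius-activated Ksv) generative model;
    ``ife`` optionally distorts the output with the inverse of the
    standard inner-filter correction, attaching per-point absorbances.
    """

    dH: float = -27.617
    dS: float = -11.033
    hill_n: float = 1.0
    temperatures: tuple = (290.0, 300.0, 310.0)
    Q_grid: tuple = tuple(q * 1e-6 for q in DEFAULT_Q_GRID_UM)  # M
    F0: float = 1000.0
    noise_rel: float = 0.0
    mechanism: str = "static"
    ife: str = "none"
    seed: int = 0
    # dynamic-mechanism parameters: reference Ksv at min(temperatures) and a
    # positive activation energy so Ksv rises with temperature
    ksv_ref: float = 1e2
    activation_energy_kJ: float = 20.0
    # inner-filter distortion: ligand molar absorptivities at the excitation
    # and emission wavelengths (M⁻¹·cm⁻¹), 1 cm path
    eps_ex: float = 2000.0
    eps_em: float = 300.0

    def __post_init__(self):
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        Q = np.asarray(self.Q_grid, dtype=float)
        if Q[0] != 0 or np.any(np.diff(Q) <= 0):
            raise ValueError("Q_grid must ascend from 0")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")
        if self.mechanism not in ("static", "dynamic"):
            raise ValueError("mechanism must be 'static' or 'dynamic'")
        if self.ife not in ("none", "standard"):
            raise ValueError("ife must be 'none' or 'standard'")

    def KA(self, T: float) -> float:
        """Binding constant (M⁻¹) from the Van't Hoff line."""
        return float(np.exp(-self.dH * 1000.0 / (R_GAS * T) + self.dS / R_GAS))

    def Ksv_dynamic(self, T: float) -> float:
        """Collisional Stern-Volmer constant: Arrhenius-activated, increasing in T."""
        Tref = min(self.temperatures)
        Ea = self.activation_energy_kJ * 1000.0
        return float(self.ksv_ref * np.exp(-Ea / R_GAS * (1.0 / T - 1.0 / Tref)))


def _multiplicative_noise(rng: np.random.Generator, values: np.ndarray, rel: float) -> np.ndarray:
    """Per-point multiplicative Gaussian noise; non-positive draws resampled."""
    if rel == 0:
        return values.copy()
    out = values * (1.0 + rel * rng.standard_normal(len(values)))
    bad = out <= 0
    while np.any(bad):
        out[bad] = values[bad] * (1.0 + rel * rng.standard_normal(int(bad.sum())))
        bad = out <= 0
    return out


def simulate_titration_series(cfg: SimulationConfig) -> tuple[list[TitrationSeries], dict]:
    """Generate one titration series per temperature plus a truth record.

    Static mechanism: F = F0·(1 − K_A·Qⁿ/(1 + K_A·Qⁿ)) with K_A(T) from the
    Van't Hoff line.  Dynamic mechanism: F = F0/(1 + Ksv(T)·Q) with
    Arrhenius-activated Ksv rising in temperature.  With ``ife="standard"``
    the emitted intensities are attenuated by 10^(−(A_ex+A_em)/2) with
    absorbances proportional to [Q], and the per-point absorbances are
    attached to each series so the standard correction recovers the clean
    signal exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    Q = np.asarray(cfg.Q_grid, dtype=float)
    series = []
    truth = {
        "mechanism": cfg.mechanism, "dH": cfg.dH, "dS": cfg.dS, "hill_n": cfg.hill_n,
        "F0": cfg.F0, "noise_rel": cfg.noise_rel, "seed": cfg.seed,
        "KA_by_T": {}, "Ksv_by_T": {},
    }
    for T in cfg.temperatures:
        if cfg.mechanism == "static":
            KA = cfg.KA(T)
            occ = KA * Q**cfg.hill_n / (1.0 + KA * Q**cfg.hill_n)
            F = cfg.F0 * (1.0 - occ)
            truth["KA_by_T"][T] = KA
            if cfg.hill_n == 1.0:
                truth["Ksv_by_T"][T] = KA  # algebraically identical at n = 1
        else:
            Ksv = cfg.Ksv_dynamic(T)
            F = cfg.F0 / (1.0 + Ksv * Q)
            truth["Ksv_by_T"][T] = Ksv
        F = _multiplicative_noise(rng, F, cfg.noise_rel)
        kw = {}
        if cfg.ife == "standard":
            A_ex = cfg.eps_ex * Q
            A_em = cfg.eps_em * Q
            F = F * 10.0 ** (-(A_ex + A_em) / 2.0)
            kw = {"A_ex": A_ex, "A_em": A_em}
        series.append(TitrationSeries(temperature=float(T), Q=Q.copy(), F=F,
                                      label=f"simulated {cfg.mechanism}", **kw))
    return series, truth


def simulate_spectra_pair(donor_center: float = 340.0, donor_width: float = 25.0,
                          acceptor_center: float = 254.0, acceptor_width: float = 18.0,
                          acceptor_epsilon_max: float = 8000.0,
                          tail_into_donor: float = 0.05,
                          acceptor_shape: str = "gaussian",
                          grid=None, noise_rel: float = 0.0,
                          seed: int = 0) -> tuple[Spectrum, Spectrum]:
    """Donor emission and acceptor molar-absorptivity spectra as Gaussian
    bands on a common grid.

    ``tail_into_donor`` scales a secondary acceptor shoulder centred on the
    donor band (the red tail of the acceptor's absorption that actually
    overlaps the emission); 0 with disjoint main bands gives exactly zero
    overlap.  ``acceptor_shape="constant"`` replaces the acceptor with a
    flat ε = ``acceptor_epsilon_max``, for which the overlap integral has
    a closed analytic form.
    """
    if grid is None:
        grid = np.arange(230.0, 451.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    donor_vals = truncated_gaussian(grid, donor_center, donor_width, 1000.0)
    if acceptor_shape == "constant":
        eps = np.full_like(grid, acceptor_epsilon_max)
    elif acceptor_shape == "gaussian":
        eps = truncated_gaussian(grid, acceptor_center, acceptor_width, acceptor_epsilon_max)
        if tail_into_donor > 0:
            eps = eps + truncated_gaussian(grid, donor_center, donor_width,
                                           tail_into_donor * acceptor_epsilon_max)
    else:
        raise ValueError(f"unknown acceptor_shape {acceptor_shape!r}")
    if noise_rel > 0:
        donor_vals = np.clip(donor_vals * (1 + noise_rel * rng.standard_normal(len(grid))), 0, None)
        eps = np.clip(eps * (1 + noise_rel * rng.standard_normal(len(grid))), 0, None)
    donor = Spectrum(grid, donor_vals, kind="emission", meta={"center_nm": donor_center})
    acceptor = Spectrum(grid, eps, kind="absorbance",
                        meta={"center_nm": acceptor_center, "units": "M-1 cm-1"})
    return donor, acceptor


def simulate_synchronous_set(base_peak: float, shift: float, quench_factors,
                             width: float = 12.0, delta_lambda: float = 60.0,
                             grid=None, noise_rel: float = 0.0,
                             seed: int = 0) -> list[Spectrum]:
    """Series of synchronous-scan bands with progressive quenching and an
    optional progressive centre shift (total ``shift`` nm over the series)."""
    quench_factors = np.asarray(quench_factors, dtype=float)
    if np.any(quench_factors <= 0) or np.any(quench_factors > 1):
        raise ValueError("quench_factors must be in (0, 1]")
    if grid is None:
        lo = base_peak - 6 * width - abs(shift)
        hi = base_peak + 6 * width + abs(shift)
        grid = np.arange(lo, hi + 0.5, 0.5)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    nsteps = max(len(quench_factors) - 1, 1)
    out = []
    for i, f in enumerate(quench_factors):
        center = base_peak + shift * (i / nsteps if len(quench_factors) > 1 else 1.0)
        vals = truncated_gaussian(grid, center, width, 1000.0 * f)
        if noise_rel > 0:
            vals = np.clip(vals * (1 + noise_rel * rng.standard_normal(len(grid))), 0, None)
        out.append(Spectrum(grid, vals, kind="synchronous",
                            meta={"delta_lambda_nm": delta_lambda, "step": i}))
    return out


def simulate_cd_spectrum(helix_fraction: float, grid=None) -> Spectrum:
    """Far-UV CD curve (mean residue ellipticity) for a given α-helix fraction.

    Linear combination of a helix basis (negative bands at 208 and 222 nm)
    and a coil basis, scaled so that MRE(208) = −(4000 + 29000·f) exactly —
    the inverse of the single-wavelength helix estimator.  The grid must
    cover 200-260 nm and contain the 208 nm point.
    """
    if not 0 <= helix_fraction <= 1:
        raise ValueError("helix_fraction must be in [0, 1]")
    if grid is None:
        grid = np.arange(200.0, 261.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > 200 or grid[-1] < 260:
        raise ValueError("grid must cover 200-260 nm")
    # basis shapes, each normalized to its value at 208 nm
    helix_shape = (-np.exp(-0.5 * ((grid - 208.0) / 9.0) ** 2)
                   - 0.95 * np.exp(-0.5 * ((grid - 222.0) / 10.0) ** 2))
    coil_shape = -np.exp(-0.5 * ((grid - 200.0) / 12.0) ** 2)
    h208 = np.interp(208.0, grid, helix_shape)
    c208 = np.interp(208.0, grid, coil_shape)
    helix_basis = helix_shape * (-33000.0 / h208)  # MRE(208) = −33000
    coil_basis = coil_shape * (-4000.0 / c208)     # MRE(208) = −4000
    vals = helix_fraction * helix_basis + (1.0 - helix_fraction) * coil_basis
    return Spectrum(grid, vals, kind="cd", meta={"helix_fraction": helix_fraction})


def simulate_eem(ex_grid=None, em_grid=None, ridge_intensity: float = 200.0,
                 peak_B: float = 900.0, peak_C: float = 500.0,
                 width: float = 10.0, noise_rel: float = 0.0,
                 seed: int = 0) -> EEM:
    """Excitation-emission matrix with a first-order Rayleigh ridge and
    Gaussian peaks at the canonical Trp/Tyr (280, 340) and polypeptide
    (236, 335) coordinates."""
    if ex_grid is None:
        ex_grid = np.arange(220.0, 351.0, 2.0)
    if em_grid is None:
        em_grid = np.arange(220.0, 451.0, 2.0)
    ex_grid = np.asarray(ex_grid, dtype=float)
    em_grid = np.asarray(em_grid, dtype=float)
    EX, EM = np.meshgrid(ex_grid, em_grid, indexing="ij")
    Z = ridge_intensity * np.exp(-0.5 * ((EM - EX) / 3.0) ** 2)
    for amp, (cex, cem) in ((peak_B, (280.0, 340.0)), (peak_C, (236.0, 335.0))):
        Z += amp * np.exp(-0.5 * (((EX - cex) / width) ** 2 + ((EM - cem) / width) ** 2))
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        Z = np.clip(Z * (1 + noise_rel * rng.standard_normal(Z.shape)), 0, None)
    return EEM(ex_grid, em_grid, Z)
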