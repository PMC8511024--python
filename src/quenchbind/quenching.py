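"""Stern-Volmer and Hill analyses of fluorescence quenching titrations.

The titration design: a fixed concentration of fluorescent protein (the
donor, e.g. serum albumin at 4 µM) is equilibrated with increasing
quencher (ligand) concentrations [Q]; the emission intensity F at the
donor's emission maximum is recorded per temperature after inner-filter
correction.

Two regression models are provided in a Model/Results style:

* :class:`SternVolmerModel` — ordinary least squares of F0/F on [Q]
  (Stern-Volmer plot).  The slope is the Stern-Volmer constant Ksv (M⁻¹)
  and kq = Ksv/τ0 is the bimolecular quenching rate constant.
* :class:`HillModel` — the binding isotherm in fractional-quenching form,
  (F0−F)/F0 = K_A·[Q]ⁿ / (1 + K_A·[Q]ⁿ), fitted nonlinearly (default)
  with starting values from the linearized log-log regression, or the
  linearized fit itself.

Also here: the quenching-mechanism classifier (static vs dynamic from the
temperature trend of Ksv and the magnitude of kq) and the site-marker
displacement comparison of binding constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import KQ_DIFFUSION_LIMIT, TAU0_DEFAULT
from .spectra import correct_inner_filter

__all__ = [
    "TitrationSeries",
    "SternVolmerModel",
    "SternVolmerResults",
    "HillModel",
    "HillResults",
    "MechanismCall",
    "Displacement",
    "fit_stern_volmer",
    "fit_hill",
    "classify_quenching_mechanism",
    "displacement_ratio",
    "read_titration_csv",
    "write_titration_csv",
]


@dataclass
class TitrationSeries:
    """One temperature's quenching titration: corrected intensities F over [Q].

    ``Q`` is in M, non-negative and strictly increasing with ``Q[0] == 0``
    (the zero point defines F0).  ``A_ex``/``A_em`` optionally carry the
    per-point absorbances at the excitation and emission wavelengths for
    inner-filter correction.
    """

    temperature: float  # K
    Q: np.ndarray  # M
    F: np.ndarray  # arbitrary units, inner-filter corrected unless stated
    lambda_ex: float = 280.0
    lambda_em: float = 340.0
    label: str = ""
    A_ex: np.ndarray | None = None
    A_em: np.ndarray | None = None

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.Q) != len(self.F):
            raise ValueError("Q and F lengths differ")
        if self.Q[0] != 0:
            raise ValueError("first titration point must be Q = 0 (defines F0)")
        if np.any(np.diff(self.Q) <= 0):
            raise ValueError("Q must be strictly increasing")
        if np.any(self.F <= 0):
            raise ValueError("all intensities must be > 0")
        for name in ("A_ex", "A_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                if len(a) != len(self.Q):
                    raise ValueError(f"{name} length differs from Q")
                setattr(self, name, a)

    @property
    def F0(self) -> float:
        return float(self.F[0])

    def __len__(self) -> int:
        return len(self.Q)

    def corrected(self, mode: str = "standard") -> "TitrationSeries":
        """Apply the inner-filter correction using the attached absorbances."""
        if self.A_ex is None or self.A_em is None:
            raise ValueError("series carries no absorbance data for inner-filter correction")
        F = correct_inner_filter(self.F, self.A_ex, self.A_em, mode=mode)
        return replace(self, F=F, A_ex=None, A_em=None)


def read_titration_csv(path) -> list[TitrationSeries]:
    """Read titration tables: columns temperature_K, Q_uM, F (one file may hold
    several temperatures).  Concentrations are converted from µM to M."""
    df = pd.read_csv(path, sep=None, engine="python")
    needed = {"temperature_K", "Q_uM", "F"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}, found {list(df.columns)}")
    out = []
    for temp, grp in df.groupby("temperature_K", sort=True):
        grp = grp.sort_values("Q_uM")
        kw = {}
        for col, name in (("A_ex", "A_ex"), ("A_em", "A_em")):
            if col in grp.columns:
                kw[name] = grp[col].to_numpy()
        out.append(
            TitrationSeries(
                temperature=float(temp),
                Q=grp["Q_uM"].to_numpy() * 1e-6,
                F=grp["F"].to_numpy(),
                label=str(Path(path)),
                **kw,
            )
        )
    return out


def write_titration_csv(series: Sequence[TitrationSeries], path) -> None:
    frames = []
    for s in series:
        d = {"temperature_K": s.temperature, "Q_uM": s.Q * 1e6, "F": s.F}
        if s.A_ex is not None:
            d["A_ex"] = s.A_ex
        if s.A_em is not None:
            d["A_em"] = s.A_em
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stern-Volmer


@dataclass
class SternVolmerResults:
    """Results of a Stern-Volmer regression F0/F = intercept + Ksv·[Q]."""

    Ksv: float  # M⁻¹
    Ksv_se: float
    intercept: float
    intercept_se: float
    r2: float
    tau0: float  # s
    temperature: float  # K
    nobs: int
    constrained: bool
    warnings: list = field(default_factory=list)

    @property
    def kq(self) -> float:
        """Bimolecular quenching rate constant Ksv/τ0, M⁻¹·s⁻¹."""
        return self.Ksv / self.tau0

    def summary(self) -> str:
        lines = [
            "Stern-Volmer fit",
            "----------------",
            f"T                 {self.temperature:.1f} K",
            f"n obs             {self.nobs}",
            f"Ksv               {self.Ksv:.4g} ± {self.Ksv_se:.2g} M⁻¹",
            f"intercept         {self.intercept:.4f}" + ("  (fixed)" if self.constrained else f" ± {self.intercept_se:.2g}"),
            f"r²                {self.r2:.4f}",
            f"kq = Ksv/τ0       {self.kq:.4g} M⁻¹ s⁻¹  (τ0 = {self.tau0:g} s)",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


class SternVolmerModel:
    """Ordinary least squares of F0/F versus quencher concentration.

    Parameters
    ----------
    series : TitrationSeries
        Inner-filter-corrected intensities; the Q = 0 point contributes
        the exact (0, 1) datum.
    tau0 : float
        Unquenched fluorophore lifetime in s (default 1e-8, the value
        conventionally assumed for Trp when no lifetime instrument is
        available); only used to derive kq.
    noise_tol : float
        Relative tolerance above F0 beyond which an intensity *increase*
        is flagged as anti-quenching in the results' warnings.
    """

    def __init__(self, series: TitrationSeries, tau0: float = TAU0_DEFAULT, noise_tol: float = 0.02):
        if int(np.sum(series.Q > 0)) < 3:
            raise ValueError("Stern-Volmer fit needs at least 3 titration points with Q > 0")
        self.series = series
        self.tau0 = float(tau0)
        self.noise_tol = float(noise_tol)

    def fit(self, constrain_intercept: bool = False) -> SternVolmerResults:
        s = self.series
        x = s.Q
        y = s.F0 / s.F
        warns = []
        if np.any(s.F > s.F0 * (1 + self.noise_tol)):
            warns.append("anti-quenching: intensity rises above F0 beyond noise tolerance")
        if constrain_intercept:
            # slope of (y - 1) through the origin
            sxx = float(np.sum(x * x))
            slope = float(np.sum(x * (y - 1.0))) / sxx
            resid = y - (1.0 + slope * x)
            dof = max(len(x) - 1, 1)
            slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
            r2 = float(np.clip(r2, 0.0, 1.0))
            return SternVolmerResults(slope, slope_se, 1.0, 0.0, r2, self.tau0,
                                      s.temperature, len(x), True, warns)
        lr = stats.linregress(x, y)
        r2 = float(lr.rvalue**2) if np.std(y) > 0 else 1.0
        return SternVolmerResults(float(lr.slope), float(lr.stderr), float(lr.intercept),
                                  float(lr.intercept_stderr), r2, self.tau0,
                                  s.temperature, len(x), False, warns)


def fit_stern_volmer(t: TitrationSeries, tau0: float = TAU0_DEFAULT,
                     constrain_intercept: bool = False) -> SternVolmerResults:
    """Convenience wrapper: ``SternVolmerModel(t, tau0).fit(constrain_intercept)``."""
    return SternVolmerModel(t, tau0=tau0).fit(constrain_intercept=constrain_intercept)


# ---------------------------------------------------------------------------
# Hill binding isotherm


@dataclass
class HillResults:
    """Results of a Hill-isotherm fit: binding constant K_A (M⁻¹) and
    cooperativity coefficient n (n = 1: noncooperative)."""

    KA: float  # M⁻¹
    KA_se: float
    n: float
    n_se: float
    r2: float
    method: str  # "nonlinear" | "linearized"
    temperature: float
    nobs: int
    label: str = ""
    warnings: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Hill binding fit",
            "----------------",
            f"T                 {self.temperature:.1f} K",
            f"method            {self.method}",
            f"n obs             {self.nobs}",
            f"K_A               {self.KA:.4g} ± {self.KA_se:.2g} M⁻¹",
            f"Hill n            {self.n:.3f} ± {self.n_se:.2g}",
            f"r²                {self.r2:.4f}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


class HillModel:
    """Hill binding isotherm fitted to fractional quenching.

    The response is y = (F0 − F)/F0 = K_A·[Q]ⁿ / (1 + K_A·[Q]ⁿ), bounded in
    [0, 1), which is better conditioned than fitting F directly.  The
    nonlinear fit (lmfit least squares on log10 K_A and n, uniform weights)
    is started from the linearized estimate and repeated over a 5-point
    restart schedule log-spaced around it; the lowest residual sum wins.
    """

    #: log10(K_A) offsets of the restart schedule around the linearized estimate
    RESTART_OFFSETS = (-1.0, -0.5, 0.0, 0.5, 1.0)

    def __init__(self, series: TitrationSeries):
        mask = (series.Q > 0) & (series.F < series.F0)
        if int(mask.sum()) < 4:
            raise ValueError("Hill fit needs at least 4 points with Q > 0 and F < F0")
        self.series = series

    def _linearized(self) -> HillResults:
        s = self.series
        warns = []
        mask = s.Q > 0
        dF = s.F0 - s.F[mask]
        keep = dF > 0
        if not np.all(keep):
            warns.append(f"{int((~keep).sum())} point(s) with F >= F0 excluded from linearized fit")
        x = np.log10(s.Q[mask][keep])
        y = np.log10(dF[keep] / s.F[mask][keep])
        lr = stats.linregress(x, y)
        n = float(lr.slope)
        logKA = float(lr.intercept)
        KA = 10.0**logKA
        KA_se = KA * np.log(10) * float(lr.intercept_stderr)
        r2 = float(lr.rvalue**2)
        return HillResults(KA, KA_se, n, float(lr.stderr), r2, "linearized",
                           s.temperature, int(keep.sum()), s.label, warns)

    def fit(self, method: str = "nonlinear", fix_n: float | None = None) -> HillResults:
        if method == "linearized":
            res = self._linearized()
            if fix_n is not None:
                raise ValueError("fix_n is only supported by the nonlinear method")
            return res
        if method != "nonlinear":
            raise ValueError(f"unknown method {method!r}")
        return self._nonlinear(fix_n)

    def _nonlinear(self, fix_n: float | None) -> HillResults:
        import lmfit

        s = self.series
        lin = self._linearized()
        mask = s.Q > 0
        Q = s.Q[mask]
        y = (s.F0 - s.F[mask]) / s.F0

        def model(pars):
            KA = 10.0 ** pars["logKA"].value
            n = pars["n"].value
            x = KA * Q**n
            return x / (1.0 + x) - y

        logKA0 = np.log10(max(lin.KA, 1e-12))
        n0 = lin.n if fix_n is None else fix_n
        if not np.isfinite(n0) or n0 <= 0:
            n0 = 1.0
        best = None
        for off in self.RESTART_OFFSETS:
            pars = lmfit.Parameters()
            pars.add("logKA", value=logKA0 + off, min=logKA0 - 8, max=logKA0 + 8)
            pars.add("n", value=float(n0), min=1e-3, max=10.0, vary=fix_n is None)
            try:
                out = lmfit.minimize(model, pars, method="leastsq")
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
        if best is None or not best.success:
            diag = "no successful minimization" if best is None else best.message
            raise RuntimeError(f"Hill nonlinear fit failed to converge: {diag}")
        logKA = best.params["logKA"].value
        KA = 10.0**logKA
        nval = best.params["n"].value
        logKA_se = best.params["logKA"].stderr
        KA_se = KA * np.log(10) * logKA_se if logKA_se is not None else float("nan")
        n_se = best.params["n"].stderr
        n_se = float(n_se) if n_se is not None else (0.0 if fix_n is not None else float("nan"))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - best.chisqr / ss_tot if ss_tot > 0 else 1.0
        r2 = float(np.clip(r2, 0.0, 1.0))
        return HillResults(float(KA), float(KA_se), float(nval), n_se, r2, "nonlinear",
                           s.temperature, len(Q), s.label, list(lin.warnings))


def fit_hill(t: TitrationSeries, method: str = "nonlinear", fix_n: float | None = None) -> HillResults:
    """Convenience wrapper: ``HillModel(t).fit(method, fix_n)``."""
    return HillModel(t).fit(method=method, fix_n=fix_n)


# ---------------------------------------------------------------------------
# Mechanism classification and site-marker displacement


@dataclass
class MechanismCall:
    mechanism: str  # "static" | "dynamic" | "indeterminate"
    note: str = ""

    def __str__(self) -> str:  # convenient comparisons / rendering
        return self.mechanism


def classify_quenching_mechanism(fits: Sequence[SternVolmerResults] | Mapping[float, SternVolmerResults],
                                 kq_cutoff: float = KQ_DIFFUSION_LIMIT) -> MechanismCall:
    """Classify the quenching mechanism from the temperature trend of Ksv.

    Static quenching (ground-state complex): Ksv strictly decreases with
    temperature and kq exceeds the diffusion-collision ceiling.  Dynamic
    (collisional) quenching: Ksv strictly increases and kq stays at or
    below the ceiling.  Conflicting evidence (including the combined
    static+dynamic regime) is reported as indeterminate with a note.
    """
    if isinstance(fits, Mapping):
        fits = [fits[T] for T in sorted(fits)]
    else:
        fits = sorted(fits, key=lambda f: f.temperature)
    if len(fits) < 2:
        raise ValueError("mechanism classification needs Stern-Volmer fits at >= 2 temperatures")
    temps = [f.temperature for f in fits]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures")
    ksv = np.array([f.Ksv for f in fits])
    kq = np.array([f.kq for f in fits])
    decreasing = bool(np.all(np.diff(ksv) < 0))
    increasing = bool(np.all(np.diff(ksv) > 0))
    if decreasing and np.all(kq > kq_cutoff):
        return MechanismCall("static", "Ksv decreases with T and kq exceeds the diffusion limit")
    if increasing and np.all(kq <= kq_cutoff):
        return MechanismCall("dynamic", "Ksv increases with T and kq is within the diffusion limit")
    notes = []
    if not (decreasing or increasing):
        notes.append("Ksv is not monotone in temperature (possible combined static+dynamic regime)")
    if decreasing and not np.all(kq > kq_cutoff):
        notes.append("Ksv trend suggests static but kq does not exceed the diffusion limit")
    if increasing and not np.all(kq <= kq_cutoff):
        notes.append("Ksv trend suggests dynamic but kq exceeds the diffusion limit")
    return MechanismCall("indeterminate", "; ".join(notes))


@dataclass
class Displacement:
    ratio: float
    interpretation: str
    n_shift: float

    def __iter__(self):  # unpack as (ratio, interpretation)
        yield self.ratio
        yield self.interpretation


def displacement_ratio(fit_free: HillResults, fit_marker: HillResults,
                       competition_threshold: float = 0.5,
                       retention_threshold: float = 1.0,
                       n_tolerance: float = 0.2) -> Displacement:
    """Compare binding constants with and without a site-marker present.

    ratio = K_A(marker present) / K_A(free).  A drop below
    ``competition_threshold`` with the Hill coefficient unchanged signals
    direct competition for the probed site; retention or increase
    (ratio >= ``retention_threshold``) with n unchanged signals no direct
    competition there; anything else is ambiguous.
    """
    ratio = fit_marker.KA / fit_free.KA
    n_shift = fit_marker.n - fit_free.n
    n_same = abs(n_shift) <= n_tolerance
    if ratio < competition_threshold and n_same:
        interp = "direct competition"
    elif ratio >= retention_threshold and n_same:
        interp = "no direct competition at probed site"
    else:
        interp = "ambiguous"
    return Displacement(float(ratio), interp, float(n_shift))
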