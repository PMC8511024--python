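"""Full-analysis orchestration: quenching → binding → thermodynamics →
FRET → conformation, driven by a YAML config, producing a structured
:class:`AnalysisReport` that serializes to JSON and renders to markdown.

Config layout (every key optional except a titration source)::

    simulate:                  # OR inputs: with CSV paths
      titration: {dH: -27.617, dS: -11.033, hill_n: 1, noise_rel: 0.01, ...}
      spectra_pair: {tail_into_donor: 0.05, ...}
      synchronous: {base_peak: 340, shift: 4, quench_factors: [...], delta_lambda: 60}
      cd: {helix_fraction: 0.6617}
      eem: {}
    inputs:
      titration_csv: path      # columns temperature_K, Q_uM, F [, A_ex, A_em]
      marker_titration_csv: path
      donor_emission_csv: path
      acceptor_epsilon_csv: path
      synchronous_free_csv: path
      synchronous_bound_csv: path
      delta_lambda: 60
      cd_csv: path
      eem_csv: path
    analysis:
      stern_volmer: {tau0: 1.0e-8, constrain_intercept: false}
      hill: {method: nonlinear, fix_n: null}
      fret: {phi_D: 0.15, refractive_index: 1.336, kappa2: [0.475, 0.667],
             efficiency_point_uM: 5}
    seed: 42

Failures in the quenching/binding core abort; failures in the optional
FRET/conformation stages degrade to warnings recorded in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conformation import extract_3d_peaks, helix_content_from_cd, synchronous_shift_analysis
from .fret import fret_analysis
from .quenching import (
    classify_quenching_mechanism,
    displacement_ratio,
    fit_hill,
    fit_stern_volmer,
    read_titration_csv,
)
from .spectra import read_eem_csv, read_spectrum_csv
from .simulate import (
    SimulationConfig,
    simulate_cd_spectrum,
    simulate_eem,
    simulate_spectra_pair,
    simulate_synchronous_set,
    simulate_titration_series,
)
from .thermo import fit_vant_hoff

__all__ = ["AnalysisReport", "run_full_analysis", "write_report"]


@dataclass
class AnalysisReport:
    """Structured results of the full binding analysis."""

    stern_volmer: list = field(default_factory=list)      # per-temperature results
    hill: list = field(default_factory=list)
    mechanism: object = None
    thermo: object = None
    fret: object = None
    shifts: list = field(default_factory=list)
    eem_peaks: list = field(default_factory=list)
    helix_percent: float | None = None
    displacement: object = None
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(obj):
            if obj is None:
                return None
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, float) and not np.isfinite(obj):
                return None
            return obj

        d = {
            "stern_volmer": conv(self.stern_volmer),
            "hill": conv(self.hill),
            "mechanism": conv(self.mechanism),
            "thermo": conv(self.thermo),
            "fret": conv(self.fret),
            "conformation": {
                "synchronous_shifts": conv(self.shifts),
                "eem_peaks": conv(self.eem_peaks),
                "helix_percent": conv(self.helix_percent),
            },
            "displacement": conv(self.displacement),
            "warnings": list(self.warnings),
            "provenance": conv(self.provenance),
        }
        # drop empty optional sections rather than rendering blanks
        if not self.shifts and not self.eem_peaks and self.helix_percent is None:
            d.pop("conformation")
        return {k: v for k, v in d.items() if v not in (None, [], {})}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Binding analysis report", ""]
        if self.stern_volmer:
            lines += ["## Stern-Volmer quenching", "",
                      "| T (K) | Ksv (M⁻¹) | kq (M⁻¹s⁻¹) | r² |",
                      "|---|---|---|---|"]
            for f in self.stern_volmer:
                lines.append(f"| {f.temperature:.0f} | {f.Ksv:.4g} ± {f.Ksv_se:.2g} | "
                             f"{f.kq:.4g} | {f.r2:.4f} |")
            if self.mechanism is not None:
                lines += ["", f"Quenching mechanism: **{self.mechanism.mechanism}** "
                              f"({self.mechanism.note})"]
            lines.append("")
        if self.hill:
            lines += ["## Hill binding and Van't Hoff thermodynamics", "",
                      "| T (K) | K_A (M⁻¹) | n | r² | ΔG° (kJ·mol⁻¹) |",
                      "|---|---|---|---|---|"]
            for f in self.hill:
                dg = ""
                if self.thermo is not None:
                    g = self.thermo.dG_by_T.get(f.temperature)
                    dg = f"{g:.3f}" if g is not None else ""
                lines.append(f"| {f.temperature:.0f} | {f.KA:.4g} ± {f.KA_se:.2g} | "
                             f"{f.n:.3f} | {f.r2:.4f} | {dg} |")
            if self.thermo is not None:
                t = self.thermo
                lines += ["", f"ΔH° = {t.dH:.3f} kJ·mol⁻¹, ΔS° = {t.dS:.3f} J·mol⁻¹·K⁻¹ "
                              f"(r² = {t.r2_vanthoff:.4f}); dominant force: **{t.force_class}**"]
            lines.append("")
        if self.fret is not None:
            f = self.fret
            lines += ["## FRET", "",
                      f"J = {f.J:.4g} M⁻¹·cm⁻¹·nm⁴, E = {f.E:.4f} "
                      f"(Φ_D = {f.phi_D:g}, n = {f.refractive_index:g})", "",
                      "| κ² | R0 (nm) | r (nm) | valid |", "|---|---|---|---|"]
            for k2 in sorted(f.R0_by_kappa2):
                r = f.r_by_kappa2.get(k2)
                lines.append(f"| {k2:g} | {f.R0_by_kappa2[k2]:.2f} | "
                             f"{'' if r is None else format(r, '.2f')} | "
                             f"{f.valid.get(k2, '')} |")
            lines.append("")
        if self.shifts:
            lines += ["## Synchronous fluorescence", ""]
            lines += [f"- {s.summary()}" for s in self.shifts]
            lines.append("")
        if self.eem_peaks:
            lines += ["## 3D fluorescence peaks", "",
                      "| peak | λ_ex (nm) | λ_em (nm) | intensity |", "|---|---|---|---|"]
            for p in self.eem_peaks:
                lines.append(f"| {p.label} | {p.ex:.0f} | {p.em:.0f} | {p.intensity:.4g} |")
            lines.append("")
        if self.helix_percent is not None:
            lines += [f"α-helix content: {self.helix_percent:.2f}%", ""]
        if self.displacement is not None:
            lines += ["## Site-marker displacement", "",
                      f"K_A ratio (marker/free) = {self.displacement.ratio:.3f} → "
                      f"{self.displacement.interpretation}", ""]
        if self.warnings:
            lines += ["## Warnings", ""] + [f"- {w}" for w in self.warnings] + [""]
        return "\n".join(lines)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    return yaml.safe_load(path.read_text()) or {}


def run_full_analysis(config, seed: int | None = None) -> AnalysisReport:
    """Execute the configured stages in fixed order and return the report.

    ``config`` is a YAML file path or an equivalent dict; ``seed`` overrides
    the config's seed for every stochastic stage.
    """
    cfg = _load_config(config)
    sim = cfg.get("simulate") or {}
    inputs = cfg.get("inputs") or {}
    analysis = cfg.get("analysis") or {}
    if seed is None:
        seed = int(cfg.get("seed", 0))
    report = AnalysisReport()
    prov = {"version": __version__, "seed": seed, "config": cfg, "input_hashes": {}}
    report.provenance = prov

    # --- titration source (mandatory core) -------------------------------
    series = None
    truth = None
    if "titration" in sim:
        simcfg = SimulationConfig(**{**sim["titration"], "seed": seed})
        series, truth = simulate_titration_series(simcfg)
        prov["simulated_truth"] = truth
    elif "titration_csv" in inputs:
        path = inputs["titration_csv"]
        series = read_titration_csv(path)
        prov["input_hashes"]["titration_csv"] = _sha256(path)
    has_other_stage = any(k in sim for k in ("spectra_pair", "synchronous", "cd", "eem")) or any(
        k in inputs for k in ("donor_emission_csv", "synchronous_free_csv", "cd_csv", "eem_csv"))
    if series is None and not has_other_stage:
        raise ValueError("no titration source: provide simulate.titration or inputs.titration_csv")

    hill_kw = analysis.get("hill") or {}
    if series is not None:
        temps = [s.temperature for s in series]
        if len(set(temps)) != len(temps):
            raise ValueError("inconsistent/duplicate temperatures across titration series")
        # inner-filter correction where absorbances are attached
        series = [s.corrected() if s.A_ex is not None and s.A_em is not None else s
                  for s in series]

        # --- Stern-Volmer + mechanism (core: abort on failure) -----------
        sv_kw = analysis.get("stern_volmer") or {}
        report.stern_volmer = [
            fit_stern_volmer(s, tau0=float(sv_kw.get("tau0", 1e-8)),
                             constrain_intercept=bool(sv_kw.get("constrain_intercept", False)))
            for s in series
        ]
        for f in report.stern_volmer:
            report.warnings += [f"Stern-Volmer {f.temperature:.0f} K: {w}" for w in f.warnings]
        if len(report.stern_volmer) >= 2:
            report.mechanism = classify_quenching_mechanism(report.stern_volmer)

        # --- Hill + Van't Hoff (core) -------------------------------------
        fix_n = hill_kw.get("fix_n")
        report.hill = [fit_hill(s, method=hill_kw.get("method", "nonlinear"),
                                fix_n=None if fix_n is None else float(fix_n))
                       for s in series]
        if len(report.hill) >= 2:
            report.thermo = fit_vant_hoff({f.temperature: f.KA for f in report.hill})

    # --- site-marker displacement (optional) -----------------------------
    if "marker_titration_csv" in inputs and report.hill:
        try:
            path = inputs["marker_titration_csv"]
            marker = read_titration_csv(path)
            prov["input_hashes"]["marker_titration_csv"] = _sha256(path)
            marker = [m.corrected() if m.A_ex is not None and m.A_em is not None else m
                      for m in marker]
            mfit = fit_hill(marker[-1], method=hill_kw.get("method", "nonlinear"))
            free_at_T = {f.temperature: f for f in report.hill}
            ffit = free_at_T.get(marker[-1].temperature, report.hill[-1])
            report.displacement = displacement_ratio(ffit, mfit)
        except Exception as exc:  # optional stage degrades to a warning
            report.warnings.append(f"displacement stage failed: {exc}")

    # --- FRET (optional) --------------------------------------------------
    fret_kw = analysis.get("fret") or {}
    donor = acceptor = None
    try:
        if "spectra_pair" in sim:
            donor, acceptor = simulate_spectra_pair(**{**sim["spectra_pair"], "seed": seed})
        elif "donor_emission_csv" in inputs and "acceptor_epsilon_csv" in inputs:
            donor = read_spectrum_csv(inputs["donor_emission_csv"], kind="emission")
            acceptor = read_spectrum_csv(inputs["acceptor_epsilon_csv"], kind="absorbance")
            for key in ("donor_emission_csv", "acceptor_epsilon_csv"):
                prov["input_hashes"][key] = _sha256(inputs[key])
        if donor is not None:
            if "efficiency" in fret_kw:
                E = float(fret_kw["efficiency"])
                F0, F = 1.0, 1.0 - E
            elif series is not None:
                q_point = float(fret_kw.get("efficiency_point_uM", 5.0)) * 1e-6
                s = max(series, key=lambda s: s.temperature)
                i = int(np.argmin(np.abs(s.Q - q_point)))
                if s.Q[i] == 0:
                    i = 1
                F, F0 = float(s.F[i]), s.F0
            else:
                raise ValueError("FRET stage needs analysis.fret.efficiency or a titration source")
            report.fret = fret_analysis(
                donor, acceptor, F=F, F0=F0,
                phi_D=float(fret_kw.get("phi_D", 0.15)),
                refractive_index=float(fret_kw.get("refractive_index", 1.336)),
                kappa2=tuple(fret_kw.get("kappa2", (0.475, 0.667))),
            )
    except Exception as exc:
        report.warnings.append(f"FRET stage failed: {exc}")

    # --- conformation (optional) ------------------------------------------
    try:
        if "synchronous" in sim:
            skw = dict(sim["synchronous"])
            dl = skw.pop("delta_lambda", 60.0)
            sset = simulate_synchronous_set(**{**skw, "delta_lambda": dl, "seed": seed})
            report.shifts.append(synchronous_shift_analysis(sset[0], sset[-1], dl))
        elif "synchronous_free_csv" in inputs and "synchronous_bound_csv" in inputs:
            free = read_spectrum_csv(inputs["synchronous_free_csv"], kind="synchronous")
            bound = read_spectrum_csv(inputs["synchronous_bound_csv"], kind="synchronous")
            for key in ("synchronous_free_csv", "synchronous_bound_csv"):
                prov["input_hashes"][key] = _sha256(inputs[key])
            report.shifts.append(synchronous_shift_analysis(
                free, bound, float(inputs.get("delta_lambda", 60.0))))
    except Exception as exc:
        report.warnings.append(f"synchronous stage failed: {exc}")
    try:
        if "eem" in sim:
            eem = simulate_eem(**{**(sim["eem"] or {}), "seed": seed})
            report.eem_peaks = extract_3d_peaks(eem)
        elif "eem_csv" in inputs:
            eem = read_eem_csv(inputs["eem_csv"])
            prov["input_hashes"]["eem_csv"] = _sha256(inputs["eem_csv"])
            report.eem_peaks = extract_3d_peaks(eem)
    except Exception as exc:
        report.warnings.append(f"EEM stage failed: {exc}")
    try:
        if "cd" in sim:
            cd = simulate_cd_spectrum(**sim["cd"])
            report.helix_percent = helix_content_from_cd(cd)
        elif "cd_csv" in inputs:
            cd = read_spectrum_csv(inputs["cd_csv"], kind="cd")
            prov["input_hashes"]["cd_csv"] = _sha256(inputs["cd_csv"])
            report.helix_percent = helix_content_from_cd(cd)
    except Exception as exc:
        report.warnings.append(f"CD stage failed: {exc}")

    return report


def write_report(report: AnalysisReport, path, format: str = "json") -> Path:
    """Serialize the report to ``path`` as JSON or markdown."""
    path = Path(path)
    if format == "json":
        path.write_text(report.to_json() + "\n")
    elif format == "markdown":
        path.write_text(report.to_markdown())
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
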