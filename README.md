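# quenchbind

Analysis toolkit for **fluorescence-quenching titrations of drug–serum-protein
binding**, built around the workflow used to characterize how small aromatic
ligands (here, a quinoline-type compound) associate with serum albumin:

1. **Inner-filter correction** of raw intensities,
   F_cor = F_obs·10^((A_ex+A_em)/2);
2. **Stern–Volmer analysis** — OLS of F₀/F on [Q]: slope K_sv (M⁻¹),
   k_q = K_sv/τ₀ — and classification of the quenching mechanism
   (static vs dynamic) from the temperature trend of K_sv and the magnitude
   of k_q relative to the diffusion limit (2×10¹⁰ M⁻¹s⁻¹);
3. **Hill binding isotherm** (F₀−F)/F₀ = K_A[Q]ⁿ/(1+K_A[Q]ⁿ), fitted
   nonlinearly with linearized log-log starting values, giving the binding
   constant K_A and cooperativity n;
4. **Van't Hoff thermodynamics** — ln K_A = −ΔH°/(RT) + ΔS°/R, with
   ΔG° = ΔH° − TΔS° and Ross–Subramanian sign rules mapping (ΔH°, ΔS°) to
   the dominant non-covalent force;
5. **FRET geometry** — overlap integral J = ∫Fελ⁴dλ/∫Fdλ, Förster radius
   R₀ = 0.211(κ²Φ_D J/n⁴)^{1/6} (Å → nm), efficiency E = 1 − F/F₀ and
   donor–acceptor distance r = R₀((1−E)/E)^{1/6};
6. **Conformational diagnostics** — synchronous-fluorescence shift analysis
   (Δλ = 15 nm Tyr / 60 nm Trp), 3-D excitation–emission-matrix peak
   extraction (Rayleigh ridge, Trp/Tyr and polypeptide bands), UV
   second-derivative spectra, and α-helix content from CD at 208 nm;
7. **Site-marker displacement** comparison of binding constants.

It is written for spectroscopists and cheminformaticians who have titration
tables and spectra from a fluorometer (or want a fully synthetic testbed —
the `simulate` module generates titrations, spectra, EEMs and CD curves with
known ground truth).

## Worked example

```python
from quenchbind import (SimulationConfig, simulate_titration_series,
                        fit_stern_volmer, fit_hill, fit_vant_hoff,
                        classify_quenching_mechanism)

# a 4 µM albumin-like donor titrated with 0-170 µM quencher at three
# temperatures; binding constants lie exactly on a Van't Hoff line
cfg = SimulationConfig(dH=-27.617, dS=-11.033, hill_n=1.0, noise_rel=0.0)
series, truth = simulate_titration_series(cfg)

sv = [fit_stern_volmer(s) for s in series]
print(classify_quenching_mechanism(sv).mechanism)   # static
ka = {s.temperature: fit_hill(s).KA for s in series}
print({T: round(v) for T, v in ka.items()})
# {290.0: 25016, 300.0: 17076, 310.0: 11947}
print(fit_vant_hoff(ka).summary())
```

prints

```
static
{290.0: 25016, 300.0: 17076, 310.0: 11947}
Van't Hoff thermodynamics
-------------------------
ΔH°           -27.617 ± 0.000 kJ·mol⁻¹
ΔS°           -11.033 ± 0.000 J·mol⁻¹·K⁻¹
r²            1.0000   (n = 3)
force class   hbond_vdw
ΔG°(290 K)   -24.417 kJ·mol⁻¹  (spontaneous)
ΔG°(300 K)   -24.307 kJ·mol⁻¹  (spontaneous)
ΔG°(310 K)   -24.197 kJ·mol⁻¹  (spontaneous)
```

i.e. an exothermic, spontaneous association (ΔG° ≈ −24 kJ·mol⁻¹) whose
negative ΔH° and ΔS° indicate hydrogen bonding and van der Waals contacts,
with a moderate binding constant of ~10⁴ M⁻¹ declining as temperature rises
(thermal destabilization of the ground-state complex — static quenching).

The same analysis runs end-to-end from a YAML config on files or simulated
inputs:

```sh
quenchbind run --config examples/full_synthetic.yaml --seed 42 \
    --out report.json --markdown report.md
```

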