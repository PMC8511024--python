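# Full synthetic run: albumin-like donor titrated with a quinoline-type
# quencher at 290/300/310 K, plus FRET spectra, synchronous scans, an
# excitation-emission matrix and a CD curve.  Seed may be overridden on
# the command line.
simulate:
  titration:
    dH: -27.617        # kJ·mol⁻¹
    dS: -11.033        # J·mol⁻¹·K⁻¹
    hill_n: 1.0
    noise_rel: 0.005
  spectra_pair:
    tail_into_donor: 0.05
  synchronous:
    base_peak: 340.0
    shift: 4.0
    quench_factors: [1.0, 0.8, 0.6, 0.4]
    delta_lambda: 60.0
  cd:
    helix_fraction: 0.6617
  eem: {}
analysis:
  hill:
    fix_n: 1.0         # noncooperative convention
  fret:
    phi_D: 0.15
    refractive_index: 1.336
    kappa2: [0.475, 0.667]
    efficiency_point_uM: 5
seed: 42
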