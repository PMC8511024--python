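"""Physical constants and experiment-level defaults shared across the package.

Unit conventions (kept explicit to mirror the mixed bookkeeping of the
underlying experiment): wavelengths in nm, quencher concentrations in M
(input files carry µM and are converted at parse time), ΔH° in kJ·mol⁻¹,
ΔS° in J·mol⁻¹·K⁻¹, ΔG° in kJ·mol⁻¹, Ksv and K_A in M⁻¹, kq in M⁻¹·s⁻¹.
"""

#: Gas constant, J·mol⁻¹·K⁻¹.
R_GAS = 8.314

#: Thermochemical calorie: 1 kcal·mol⁻¹ = 4.184 kJ·mol⁻¹.
KCAL_TO_KJ = 4.184

#: Assumed unquenched fluorophore lifetime (s) when no lifetime
#: spectrometer is available; standard for tryptophan fluorescence.
TAU0_DEFAULT = 1e-8

#: Diffusion-limited collisional quenching ceiling, M⁻¹·s⁻¹.  kq far above
#: this value rules out purely dynamic (collisional) quenching.
KQ_DIFFUSION_LIMIT = 2e10

#: Titration design used throughout: quencher concentrations in µM.
DEFAULT_Q_GRID_UM = (0.0, 5.0, 10.0, 30.0, 50.0, 70.0, 90.0, 110.0, 130.0, 150.0, 170.0)

#: Orientation-factor presets for the Förster radius.
KAPPA2_DYNAMIC = 0.667  # isotropic dynamic averaging of dipole orientations
KAPPA2_STATIC = 0.475   # static random orientation

#: Canonical excitation-emission matrix peak coordinates (ex_nm, em_nm)
#: for serum-albumin-like proteins: B = Trp/Tyr band, C = polypeptide band.
CANONICAL_EEM_PEAKS = {"B": (280.0, 340.0), "C": (236.0, 335.0)}
#: Matching radius (nm) for labelling EEM peaks against the canonical table.
EEM_MATCH_RADIUS_NM = 15.0

#: α-helix estimator anchors for mean residue ellipticity at 208 nm
#: (deg·cm²·dmol⁻¹): MRE208 of pure coil and pure helix.
MRE208_COIL = -4000.0
MRE208_HELIX = -33000.0

#: Bovine serum albumin: residue count and molar mass (g·mol⁻¹) used to
#: convert raw ellipticity to mean residue ellipticity.
BSA_N_RESIDUES = 583
BSA_MOLAR_MASS = 66430.0
BSA_MEAN_RESIDUE_WEIGHT = BSA_MOLAR_MASS / BSA_N_RESIDUES
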