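# Methods

This note records the models implemented in `oligostate`, the conventions
and defaults they use, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## SEC hydrodynamics

**Calibration model.** Both calibration lines are ordinary least squares on
the transformed axes x = √(−log₁₀ K_av), with K_av = (V_e − V_o)/(V_t − V_o):
one line maps x → Mr^(1/3), the other x → R_S. The total volume V_t is a
column constant (2.41 mL for the analytical columns the defaults describe).
The void volume V_o is frequently unreported; when unset it is treated as a
fit parameter, scanned on a grid bounded to [0.3·V_t, 0.6·V_t] (further
restricted below the earliest standard peak) with the inner line refitted at
each candidate and the summed normalised residuals of all available lines
minimised. When standards carry both masses and radii, both lines share the
fitted V_o. Extrapolation beyond the standards' x-range triggers a warning,
not an error; K_av marginally outside [0, 1] (apex-interpolation jitter) is
clamped with a warning.

**Reference radii.** Expected Stokes radii come from the empirical
mass–radius laws for folded globular proteins
(log₁₀ R_S = −0.204 + 0.357 log₁₀ Mr) and unfolded chains
(log₁₀ R_S = −0.551 + 0.493 log₁₀ Mr), with Mr in Da and R_S in Å. Note the
two laws cross near 356 Da; "folded is more compact" only holds above that,
which is every actual protein.

**State calls.** The apparent aggregation number AAN = AMW/monomer mass is
classified with bands at 1.35 / 2.25 / 3.6 (monomer, monomer–dimer mixture,
dimer, higher-order). The bands are configurable; the defaults place the
commonly printed values (1.2; 1.5–2.1; 2.4–2.8; 4.8) in their intended
classes with room on both sides. AAN is reported to one decimal for display
and kept at full precision internally. The default monomer mass is half the
expected fusion-dimer mass (96 kDa → 48 kDa), the only mass such studies
print.

**Unresolved mixtures.** A mixture of similarly populated folded-dimer and
unfolded-monomer species elutes as a single merged peak. Two conventions are
provided. `estimate_rs` + `estimate_dimer_fraction` evaluates the fitted
R_S line at the observed apex and applies the linear-mixing ratio
(R_obs − R_mono)/(R_dim − R_mono) with end-member radii (defaults 44/32 Å).
`mixture_dimer_fraction` instead assumes the apex position moves linearly
between the two pure end-member peaks on the calibration abscissa and
interpolates R_obs between the end-member radii there; this is the
convention under which a 1.50 mL apex between a 1.40 mL dimer peak and a
1.57 mL monomer peak corresponds to ≈40% dimer, and it is what the
acceptance script reports. The two conventions differ by several percentage
points when the calibration points are not perfectly collinear (the fitted
line smooths over the end-member points; the mixture convention honours
them exactly).

**Peak detection.** Local maxima above a relative height threshold (default
5% of the baseline-subtracted maximum), apex refined by three-point
parabolic interpolation. Two Gaussians of common width σ merge into a
single apex only when their separation is ≲2σ; the merged-apex tests use
widths in that regime.

## Structure geometry

**Data model and I/O.** Multi-model coordinate files are read and written
through gemmi; author residue numbering is authoritative and all ranges are
inclusive. All models of an ensemble must share one atom topology; the
first divergent atom is named in the error.

**Helix detection.** Residues whose backbone (φ, ψ) fall in the α-window
(φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°]) are collected into runs of ≥4,
merging across single-residue gaps; a run needs ≥6 Cα to carry an axis.
This dihedral rule is a deliberate stand-in for shift-based secondary
structure assignment, so helix boundaries may differ from shift-derived
ones by a residue or two.

**Axes and angles.** A helix axis is the principal SVD direction of its Cα
cloud, oriented N→C; adequate for 14–17-residue helices (the `fit_rms` of
an ideal helix returns its ~2.3 Å Cα radius). Crossing angles are
orientation-independent: min(θ, 180°−θ) ∈ [0°, 90°]. The protomer docking
angle is the crossing angle between the two chains' hairpin principal axes
(principal direction of all helical Cα of each chain); the axis definition
for "docking" is this module's choice, and other reasonable definitions can
differ by a few degrees. Ensemble statistics are computed per model and
reported as mean ± sd.

**Precision.** `ensemble_rmsd` iteratively superposes all models (Kabsch,
proper rotations enforced) onto their evolving mean until the mean moves
<10⁻⁴ Å, then reports mean ± sd of the per-model RMSD to the mean, for
backbone (N, CA, C, O) or all heavy atoms.

**SASA and interface.** Shrake–Rupley with a deterministic golden-spiral
point set (default 960 points, probe 1.4 Å) and Bondi radii; hydrogens are
excluded by default so NMR models are comparable with heavy-atom
conventions (a flag includes them). The isolated-sphere error at 960 points
is <1%, two-body overlaps agree with a 10⁵-point reference to <2%. Buried
interface area is (SASA_A + SASA_B − SASA_AB)/2 — halved, the per-protomer
convention of interface servers — with the unhalved total also reported.
Per-residue relative exposure divides a residue's in-context SASA by the
SASA of the same residue, in the same conformation, isolated; this
self-reference makes an isolated residue score exactly 1 and avoids
needing an extended-tripeptide reference library (published Gly-X-Gly
tables vary by source; the self-referenced fraction answers the same
"how much of this residue's surface is covered" question).

**Contacts** use heavy-atom criteria: H-bond, donor–acceptor ≤3.5 Å with
antecedent–donor–acceptor angle ≥90°; salt bridge, side-chain N⁺/O⁻ group
atoms of oppositely charged residues (Asp/Glu vs Lys/Arg/His) ≤4.0 Å;
non-polar, side-chain carbon pairs of apolar residues ≤4.5 Å. Peptide-bond
neighbours are excluded; every contact is tagged intra- or inter-protomer.

## ¹⁵N relaxation

**Model.** R₁, R₂ and the heteronuclear NOE follow the standard ¹⁵N
dipolar + CSA expressions with Lipari–Szabo model-free spectral densities
under isotropic tumbling. The physical constants — N–H bond length 1.02 Å,
¹⁵N CSA −160 ppm, CODATA gyromagnetic ratios — live in one frozen
`NMRConstants` object shared by the generator and the estimators, so the
estimators invert the generator by construction; the absolute rates scale
with these constants but the τ_C inferred from R₂/R₁ is insensitive to the
common prefactors.

**τ_C estimation.** Residues are filtered to hetNOE ≥ 0.65 (drops flexible
sites) and R₂ within 1.5·MAD of the retained median (drops
exchange-broadened sites), with a relative floor of 10⁻³·median on the MAD
scale so the filter still operates on noiseless tables. Each retained
residue gives a correlation time from its R₂/R₁ ratio: the closed form
τ_C = √(6R₂/R₁ − 7)/(4πν_N) neglects high-frequency spectral densities and
is biased low by 1–2% in the 5–20 ns range, so by default it seeds a
root-finding solve of the full rigid-rotor ratio (`refine=False` recovers
the plain closed form). The reported value is a 10%-trimmed mean ± sd, with
every rejected residue listed with its reason. No model-free (S², τ_e)
fitting and no anisotropic diffusion — the single-field ratio method
matches the level of analysis the reported 9.9 ± 0.7 ns number represents.

**Structured region and exchange flags.** Structured ranges are maximal
runs (≥5 residues) of hetNOE ≥ 0.65 tolerating single-residue dips.
Exchange-broadened residues exceed the structured-region median R₂ by
>3·MAD (same relative floor). On homogeneous noisy tables the false-flag
rate is the expected tail rate of the MAD rule, not zero.

**Shifts.** Dispersion is max − min of the selected shifts (backbone amide
¹H by default) — translation-invariant in referencing. The helix/coil
classifier smooths Δδ(Cα) − Δδ(Cβ) secondary shifts (Wishart-style
random-coil reference shipped in-package, recorded in output) over a
3-residue window and calls helix on runs of ≥4 at ≥1.4 ppm. NMR-STAR 3.1
input is supported by a minimal reader of the `_Atom_chem_shift` loop;
relaxation tables are CSV (deposition formats for relaxation vary too much
to promise more).

## Equilibrium models

**Dimer melt.** N₂ ⇌ 2U with K = [U]²/[N₂] = 2C_t f_U²/(1 − f_U), van't
Hoff temperature dependence (ΔC_p = 0), and the T_m convention
K(T_m) = C_t, equivalent to f_U(T_m) = ½ at the stated total monomer
concentration — stated explicitly because dimer melts are concentration
dependent (an optional reference concentration separates "where T_m was
measured" from "what concentration is being predicted"). The unique
positive root of the mass-action quadratic is used in closed form. The
observable is a baseline-weighted two-state signal with linear native and
unfolded baselines. Fitting is non-linear least squares initialised from
the terminal 10% of points (baselines), the maximum of the smoothed
derivative (T_m), and its height (ΔH, van't Hoff width rule); data
explained by a single global line (residual <2% of the span) are rejected
as transition-free before fitting. A monomolecular N ⇌ U variant is
available (`coupling="monomer"`); the dimer-coupled form is the default
because unfolding and dissociation are concurrent for this system.

**Sedimentation equilibrium.** Single ideal species:
c(r) = b + c_ref·exp[σ(r² − r_ref²)/2] with σ = M(1 − v̄ρ)ω²/(RT) (cgs
internally so σr² is dimensionless with r in cm). The global fit shares one
molar mass across rotor speeds with per-profile c_ref (log-parameterised
for positivity) and baseline, initialised from a linearised
ln(c − b) vs r²/2 regression; parameter covariance comes from the Jacobian
at the optimum. Partial-specific volume, solvent density, temperature and
rotor speeds are user inputs — the defaults (v̄ = 0.73 mL/g, ρ = 1.0 g/mL,
20 000/28 000 rpm, 293 K) are generic placeholders for simulation, not
measurements, and must be supplied for real-data reanalysis.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given their seed (`numpy.random.default_rng`),
and their noiseless outputs are exact evaluations of the stated closed
forms — this is checked against independent re-implementations in the
tests. Noise is additive Gaussian everywhere, the simplest model consistent
with absorbance/CD detection.

- **Chromatograms** are sums of Gaussians on a volume grid: no tailing,
  fronting, or baseline drift.
- **Hairpin dimers** are backbone-only (N, CA, C, O) ideal helices built by
  chain extension from ideal internal coordinates (φ = −60°, ψ = −45°,
  ω = 180°; ~1.5 Å rise, 3.6 residues/turn), assembled so the two helix
  axes of a protomer cross at the requested angle, and the second protomer
  (a rotated copy) docks at the requested angle at the smallest separation
  satisfying the minimum-gap constraint. There are no side chains and no
  connector loop, so generated interfaces bury far less area than real
  side-chain-packed interfaces — angle and precision recovery are
  meaningful on these fixtures; absolute buried areas are not.
- **Ensemble emulation** (`jitter_ensemble`) offers iid per-atom jitter
  (analytic expectations: per-model RMSD to the mean ≈ σ√3·√(1−1/M)) and a
  "smooth" mode — low-frequency per-residue displacement fields with exact
  per-model RMS — because real conformer ensembles vary collectively;
  iid noise at realistic amplitudes scrambles backbone dihedrals that the
  helix detector needs.
- **Relaxation profiles** use the same spectral densities as the analysis:
  a rigid core (default S² = 0.86), linear S² ramps over flexible termini
  (default 8 residues per end, leaving a 39-residue structured core in the
  default 55-residue construct), optional per-residue exchange terms on R₂
  only. Defaults describe a ~10 ns dimer at 500 MHz.
- **Melts and sedimentation profiles** evaluate exactly the fitted models,
  so recovery tests probe estimator correctness and noise response, not
  model misspecification.

Passing these tests therefore demonstrates that the estimators invert
their own forward models at realistic noise levels — it does not guarantee
robustness to chromatographic asymmetry, anisotropic tumbling, thermal
baselines with curvature, or non-ideal sedimentation, all of which are out
of scope.

## Numerical choices and degenerate inputs

- Least-squares superposition enforces proper rotations (determinant
  correction); collinear point sets raise.
- The void-volume scan uses 2001 grid points; the inner fits are linear, so
  the scan is globally robust within its bounds.
- Peaks at grid edges skip parabolic refinement; the interpolation offset
  is clamped to ±½ grid step.
- `dimer_unfolded_fraction` clips the van't Hoff exponent to ±700 before
  exponentiation and is exact (≤10⁻¹⁰ relative mass-action residual) at
  every returned root.
- SASA neighbour search uses a k-d tree; unknown elements get a
  configurable default radius with a warning rather than an error.

## Known limitations

- The SEC calibration is strictly linear on the stated axes; sigmoidal
  calibration models and >2-species deconvolution are out of scope.
- Helix boundaries from dihedral windows can differ by ±2 residues from
  shift-derived assignments; the docking-angle definition is axis-based
  and convention-dependent at the few-degree level.
- The R₂/R₁ method assumes isotropic tumbling and reports a single global
  τ_C; exchange and anisotropy are handled only by exclusion.
- Buried-area values depend on the radii set and point density at the
  1–2% level; comparisons across software should use matched conventions.
- The four printed radius calibration points used in the examples are not
  perfectly collinear; fitted-line predictions at the end-member volumes
  carry ~2 Å residuals, which is why the mixture convention interpolates
  between the end-member points directly.
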