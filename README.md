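# oligostate

**How a small protein domain proves it is a dimer.** `oligostate` implements,
as a tested and reusable pipeline, the quantitative arguments by which the
oligomeric state and interface of a small α-helical-hairpin homodimer (the
QUA1 dimerization element of STAR-family RNA-binding proteins, studied as a
maltose-binding-protein fusion) are established:

1. **SEC hydrodynamics** — calibrate an analytical size-exclusion column on
   the classical linear axes, Mr<sup>1/3</sup> (or R<sub>S</sub>) versus
   x = √(−log₁₀ K<sub>av</sub>) with K<sub>av</sub> = (V<sub>e</sub> − V<sub>o</sub>)/(V<sub>t</sub> − V<sub>o</sub>);
   convert elution volumes into apparent molecular weights, Stokes radii and
   apparent aggregation numbers (AAN = AMW / monomer mass); classify
   monomer / mixture / dimer / higher-order states; and estimate the dimer
   fraction of unresolved two-state mixtures from the linear-mixing ratio
   (R<sub>S,obs</sub> − R<sub>S,monomer</sub>)/(R<sub>S,dimer</sub> − R<sub>S,monomer</sub>).
   Reference radii come from the empirical laws
   log₁₀R<sub>S</sub> = −0.204 + 0.357·log₁₀Mr (folded, globular) and
   log₁₀R<sub>S</sub> = −0.551 + 0.493·log₁₀Mr (unfolded chain).
2. **Structure geometry** — read multi-model PDB ensembles (gemmi), call
   helices from backbone dihedrals, fit helix axes by SVD, measure
   inter-helix crossing and protomer docking angles, compute ensemble
   coordinate precision (iterative superposition onto the mean), Shrake–Rupley
   SASA, PISA-convention buried interface area, per-residue exposure, and
   typed contacts (H-bonds, salt bridges, non-polar packing).
3. **¹⁵N relaxation** — per-residue R₁/R₂/hetNOE analysis: overall rotational
   correlation time τ<sub>C</sub> from the R₂/R₁ ratio of well-structured
   residues, structured-region delineation from hetNOE, exchange-broadening
   flags (robust R₂ outliers), amide shift dispersion, and a secondary-shift
   (ΔδCα − ΔδCβ) helix/coil classifier.
4. **Equilibrium models** — a two-state dimer-to-unfolded-monomers thermal
   transition, N₂ ⇌ 2U with van't Hoff K(T) and K(T<sub>m</sub>) = C<sub>t</sub>
   (so f<sub>U</sub>(T<sub>m</sub>) = ½ at the stated total monomer
   concentration), and a global single-species sedimentation-equilibrium fit,
   c(r) = b + c<sub>ref</sub>·exp[M(1 − v̄ρ)ω²(r² − r<sub>ref</sub>²)/2RT].
5. **Synthetic data** — deterministic generators for every input class
   (Gaussian elution traces, ideal backbone-only hairpin dimers with
   controllable crossing/docking angles, model-free relaxation profiles with
   flexible termini and exchange sites, two-state melts, exponential radial
   distributions), so every estimator has parameter-recovery tests with known
   ground truth and no downloads.

## Worked example

Calibrate the 2.41 mL analytical column on the fusion-protein peaks and
interpret the mutant elution volumes:

```bash
$ oligostate sec analyze samples.csv --standards standards.csv
sample          ve_ml  kav    amw_kda  rs_angstrom  aan  state                  dimer_fraction
C59S            1.4    0.401  131.0    44           2.7  dimer
C59S/E72G       1.57   0.502  55.0     32           1.1  monomer
C59S/R67A       1.5    0.461  81.0     36           1.7  monomer/dimer mixture  0.37
C59S/R67A/E72G  1.39   0.395  138.0    44           2.9  dimer
C59S/R67A/E72G  1.53   0.478  69.0     34           1.4  monomer/dimer mixture  0.19
C59S/R67E/E72R  1.46   0.437  99.0     39           2.1  monomer/dimer mixture  0.61
```

Reading the table: the cysteine-free fusion elutes as a clean dimer
(AAN 2.7); deleting the interface glutamate (E72G) leaves an unfolded
monomer (AAN 1.1); removing one side of the inter-protomer salt bridge
(R67A) gives a partially dissociated mixture (~40% dimer); swapping the
salt-bridge polarity (R67E/E72R) restores a mostly dimeric population.

The other stages run the same way on synthetic or real inputs:

```bash
$ oligostate simulate relaxation --out relax.csv --seed 1
$ oligostate nmr tauc relax.csv --field 500
tau_c = 9.76 +/- 0.12 ns (32 residues)      # a ~10 ns tumbler: dimer-sized

$ oligostate simulate melt --out melt.csv --seed 1
$ oligostate fit melt melt.csv --ct 20e-6
Tm = 337.90 K (64.7 C), dH = 300 kJ/mol

$ oligostate simulate sedimentation --out sed.csv --seed 1
$ oligostate fit sedeq sed.csv
M = 12.30 +/- 0.01 kDa (2 speeds)           # the folded-dimer mass

$ oligostate simulate hairpin --out dimer.pdb
$ oligostate struct angles dimer.pdb
{"interhelix_deg": [31.0, 0.002], "docking_deg": [85.0, 0.0]}
```

Deposited entries (a wwPDB coordinate ensemble, BMRB assignments) can be
retrieved with the explicit opt-in `oligostate fetch <id> --out <path>`;
no analysis command ever downloads implicitly.

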