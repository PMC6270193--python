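# Methods

## Model

The pipeline implements fragment-based CoMFA for a two-R-site congeneric
series. Its assumptions, in order of appearance:

1. **Decomposition.** Every molecule contains the declared core exactly
   once, and both cut bonds are acyclic single bonds from the core to a
   non-hydrogen substituent atom. The cut sites are *declared* (a core
   pattern with two mapped dummy atoms), never detected automatically.
   For the lupane series the R1 cut severs the exocyclic C-17→C-28 bond
   and the R2 cut the C3—O bond; the oxygen travels with R2, which is
   why acyl substituents read "—OCOCH₃" rather than "—COCH₃". This
   convention is what makes the reference compound decompose into
   R1 = —COOH, R2 = —OH.

2. **Canonical poses.** A fragment's descriptors must be a function of
   its graph only. The pose pipeline guarantees this by (a) canonically
   reordering the fragment graph before any 3-D work, (b) replacing the
   attachment dummy with a carbon cap standing in for the core atom,
   (c) embedding one conformer with seeded ETKDG distance geometry and
   relaxing it with MMFF94 (UFF fallback), (d) setting every acyclic
   rotatable torsion to 180° walking outward from the attachment atom,
   and (e) rigidly canonicalizing the frame: attachment atom at the
   origin, cap direction along +X, azimuth fixed by the
   highest-canonical-rank neighbour placed in the +Y half-plane, mirror
   ambiguity resolved by the sign of the first out-of-plane atom in
   rank order. The original commercial topomer rules are unpublished;
   this rule set is an independent, documented equivalent that provides
   the same *property* (identical fragments → identical fields) without
   reproducing the proprietary descriptor values — which is why the
   original model's q²/r²/F are treated as configuration references, not
   as numeric targets.

3. **Fields.** Steric: Lennard-Jones against an sp³-carbon probe
   (ε = 0.107 kcal/mol, r = 1.70 Å, Lorentz–Berthelot combination with a
   Tripos-style per-element table covering H, C, N, O, S and halogens),
   clamped at +30 kcal/mol. Electrostatic: Coulomb with +1 probe charge,
   distance-dependent dielectric ε = d and prefactor 332.0, clamped at
   ±30. Grid: 2.0 Å spacing, bounding box of all fragments of a label
   plus 4.0 Å padding, origin snapped down to a spacing multiple so the
   lattice is reproducible. Electrostatic values at sterically clamped
   ("inside") points are imputed with the column mean over non-clamped
   compounds to keep the matrix rectangular. All of these are standard
   CoMFA conventions and all are configurable; none is fitted.

4. **Regression.** PLS1 by NIPALS with mean-centering and *no* column
   autoscaling (field columns share physical units; their variance is
   information). Components are chosen by maximizing leave-one-out q²
   over 1..10, ties to the smaller count; each LOO fold re-centers.
   When the requested component count exceeds the rank of the centered
   matrix the fit truncates and flags itself; at full rank the
   predictions coincide with the least-squares fit.

5. **Validation.** r²pred uses the *observed* test activities in SD
   (the sum of squared deviations from the training mean). The
   alternative reading — predicted activities in SD — is exposed as an
   option but is not the default, because only the observed convention
   reproduces the published external-validation value from the published
   table. RMSEP = √(PRESS/n_test). R²m is computed in both axis
   conventions (through-origin regression of predicted on observed and
   the reverse) and both are always reported; published values of this
   statistic are convention-sensitive and the two computed values here
   differ substantially (0.164 vs 0.554 on the packaged table), so no
   single number is privileged. q² uses the plain 1 − PRESS/SS_tot
   scaling.

6. **Interpretation.** Contours are StDev*Coeff (training column
   standard deviation × coefficient) thresholded per
   (fragment, field) block at the 80th/20th percentiles. Favored points
   correspond to the green (steric) / blue (electrostatic) regions of
   conventional maps, disfavored to yellow / red.

## Censoring

Activities reported only as exceeding the highest tested concentration
("IC50 > 100 μM") carry no magnitude information. They are assigned the
policy value pIC50 = 4.0 (the pIC50 of exactly 100 μM); the policy value
and threshold are configurable. The packaged table contains one such
compound, deliberately placed in the test set by the original study to
widen the activity range.

## Synthetic series generator

The generator emulates the *statistical* structure of the real series:
a fixed asymmetric methyl-decalin core with two attachment sites (a
deliberately small stand-in for the lupane skeleton — conformer
embedding of a 30-carbon pentacycle adds cost but no statistical
content; the real lupane core remains available as a configuration),
substituent libraries of 8 (R1: carboxyl/ester/carbamate side chains)
× 6 (R2: O-linked acyl/alkyl groups), 37 compounds drawn without
replacement, activities y = Xw + b + ε with ε ~ N(0, 0.15²) log units,
the weight vector w planted sparsely (two cells per field block, chosen
among high-variance columns with pairwise |correlation| < 0.95 and
alternating signs, magnitudes scaled so the noise-free activities span
pIC50 4.0–5.7), censoring at 100 μM, and a 26/11 train/test split that
spans the activity range (one test compound drawn per activity
stratum). Everything is driven by one mandatory seed; regeneration is
bit-identical.

What the generator does *not* emulate: assay biology (noise is a single
Gaussian; real MTT IC50s have heteroscedastic, correlated errors),
figure-only substituent structures of the published table, conformer
ensembles, and receptor information. Passing recovery tests therefore
demonstrates that the pipeline machinery is correct and identifiable
under its own assumptions — not that the physical field model captures
the true pharmacology of any real series.

## Numerical choices

- Embedding seed default 20130822; any fixed integer works, it only has
  to be shared so identical fragments embed identically.
- Pose tolerances: collinearity threshold 1e-6 Å for the azimuth and
  mirror rules; fragments whose atoms all lie on the open-valence axis
  keep translation+axis alignment only and are flagged.
- NIPALS rank tolerance 1e-10 relative to the centered-matrix scale;
  score norms below it truncate the component sequence.
- A lattice point exactly on an atom center contributes +∞ steric
  energy (clamped) and signed-∞ electrostatic energy (clamped to the
  charge's sign); no division error escapes.
- Degenerate inputs raise typed errors rather than returning NaN:
  constant y (q², r² undefined), zero SD (r²pred), zero-variance pairs
  (R²m), unparameterized elements (fields, charges).
- Reported summaries round to 3 decimals; all internal arithmetic is
  double precision.

## Problem sizes

The default test and reproduction runs use the reference synthetic
conditions (37 compounds, ~2400 descriptor columns, LOO over 26 training
rows, component cap 10) and a 100-seed replication for the recovery
study; fragment poses and field blocks are memoized across seeds since
they are pure functions of (fragment graph, seed, grid). These sizes
were chosen to mirror the study design while keeping a full replication
in the minutes range on one CPU.

## Known limitations

- The canonical-pose rules are an independent reconstruction; absolute
  descriptor values differ from the original commercial implementation,
  so published component-level statistics are not comparable numbers.
- Stereochemistry survives parsing but the pose pipeline embeds from
  the canonical graph; enantiomeric fragments receive mirror-resolved
  (hence identical) poses. Ring pucker is taken as embedded and flagged,
  not canonicalized.
- Substituents present only as drawings in the source table cannot be
  re-derived from it; full-structure runs require user-supplied or
  synthetic structures. The packaged table still supports all
  activity-level statistics.
- Only steric and electrostatic fields are implemented — no H-bond,
  hydrophobic or attractive-steric variants.
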