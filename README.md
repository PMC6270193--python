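# fragqsar

Fragment-based ("topomer"-style) CoMFA 3D-QSAR for congeneric series,
built around a published betulinic acid / betulin anti-tumor SAR study.

## The problem

Betulinic acid (BA) is a pentacyclic lupane triterpenoid with selective
cytotoxicity against tumor cells; betulin (BE), its 28-hydroxyl analog,
is abundant in birch bark but inactive. Medicinal-chemistry series
derivatize the shared skeleton at two sites, C-3 and C-28. Classical
CoMFA needs a whole-molecule alignment; the fragment-based variant
removes that requirement: each molecule is cut into a common core plus
R-group fragments, each fragment gets one *rule-based canonical 3-D
pose*, and steric/electrostatic probe fields sampled on a lattice around
each pose become the regression descriptors. Graph-identical fragments
always produce identical descriptors, so no alignment step exists.

The model is PLS (NIPALS, mean-centering only) of pIC50 on the
concatenated field columns, with the component count chosen by
leave-one-out cross-validation:

- q² = 1 − PRESS/Σ(y−ȳ)² (LOO), training r², F = (r²/m)/((1−r²)/(n−m−1))
- external validation: r²pred = (SD − PRESS)/SD with SD the squared
  deviations of the test activities from the training mean,
  RMSEP = √(PRESS/n_test), and Roy's R²m = r²·(1 − √|r² − r²0|)
- interpretation: StDev*Coeff contours (column standard deviation ×
  PLS coefficient), thresholded at the 80th/20th block percentiles into
  favored/disfavored lattice regions.

The package ships transcriptions of the study's activity tables
(37 compounds, 26 train / 11 test, HT29 cells; plus three prospectively
synthesized BE 28-O-esters) and a synthetic series generator that plants
a known sparse linear model on real field descriptors, so every pipeline
stage is testable with exact ground truth.

## Worked example

```
python examples/01_published_table_validation.py
```

```
training compounds : 26
test compounds     : 11
training mean pIC50: 4.865
PRESS              : 0.44572   (sum of squared test residuals)
RMSEP              : 0.201     (log units; published 0.201)
r2_pred            : 0.676     (published 0.675)
R2m (observed axis): 0.164
R2m (predicted ax.): 0.554
```

The recomputed RMSEP and r²pred agree with the published external
validation of the original model. The two R²m lines are the two axis
conventions of Roy's metric computed from the same printed test pairs;
they bracket how sensitive that statistic is to its convention.

`examples/02_fragment_decomposition.py` cuts BA/BE derivatives at
C-28/C-3 (BA → R1 = —COOH, R2 = —OH, with ester oxygens traveling with
the R2 group), `examples/03_canonical_poses_and_fields.py` shows a
canonical fragment pose and its grid fields, and
`examples/04_synthetic_fit_and_contours.py` runs the full
simulate → fields → PLS → contours loop, printing LOO q², external
r²pred/RMSEP and whether each planted field hotspot reappears in the
fitted contour sets.

A thin CLI wraps the same library calls:

```
fragqsar validate-tables
fragqsar simulate --seed 7 --outdir run
fragqsar fit run/structures.smi run/activities.csv \
    --core "CC12CCCC1C([*:1])CCC2[*:2]" --outdir fit
fragqsar predict fit/model.json run/structures.smi
fragqsar contour fit/model.json --outdir contours
```

## Layout

- `src/fragqsar/activity.py` — pIC50 arithmetic, censoring policy, all
  validation statistics, packaged-table loaders
- `src/fragqsar/fragmentation.py` — SMILES/SDF input, declared-cut-bond
  R-group decomposition, Gasteiger charges
- `src/fragqsar/align.py` — deterministic canonical fragment poses
- `src/fragqsar/fields.py` — Lennard-Jones / Coulomb lattice fields,
  descriptor-matrix assembly, cube export
- `src/fragqsar/pls.py` — NIPALS PLS, LOO CV, StDev*Coeff contours
- `src/fragqsar/synthetic.py` — ground-truth series generator
- `src/fragqsar/cli.py` — the command-line driver
- `docs/methods.md` — model assumptions, parameter choices, limitations
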