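# Methods

## Problem and model

`smopsi` predicts, from sequence-derived information alone, which residues of
a protein bind a small-molecule ligand (ATP, FAD, NAD, ...). The ground truth
is structural: a residue is a *binding residue* when its reference atom lies
strictly within 3.5 Å of any atom of a co-resolved ligand, and nonbinding
otherwise. The predictor is a per-residue binary classifier over sliding
windows of residue features, fitted with gradient-boosted trees on repeated
class-balanced draws.

### Contact labeling

The "central atom" of a residue is taken to be its Cα (`atom_mode =
central_atom`, the default). Because genuine Cα–ligand contacts under 3.5 Å
are rare in real structures, a second interpretation is shipped:
`any_heavy_atom` takes the minimum distance over all heavy atoms of the
residue, which yields a superset of the Cα labels at the same threshold. Both
modes are interpretations of an underdetermined notion, documented as such,
and the comparison is strict (`< 3.5`), never `<=`. Multiple co-resolved
copies of the same ligand code are unioned: a residue contacting any copy is
positive. Waters are always excluded. Residues missing their reference atom
are labeled 0 with a warning by default (configurable to a hard error).

### Features (44 per residue)

| block | columns | content |
|---|---|---|
| PSSM | 0–19 | the residue's row of the L×20 position-specific scoring matrix, in PSI-BLAST column order `ARNDCQEGHILKMFPSTWYV`, raw scores |
| physicochemical | 20–23 | hydrophilicity (Hopp–Woods, AAindex HOPT810101), hydrophobicity (Kyte–Doolittle hydropathy, AAindex KYTJ820101), charge (+1 for R/H/K, −1 for D/E, 0 otherwise), side-chain H-bond donor count (AAindex FAUJ880109) |
| one-hot | 24–43 | residue identity, same alphabet order as the PSSM block |

The hydrophilicity and hydrophobicity sources are deliberately two distinct
AAindex entries; HOPT810101 is a hydrophilicity scale and cannot serve as
both. KYTJ820101 is the package's default hydrophobicity entry and any
AAindex-format file can replace it
(`PhysChemScales.with_hydrophobicity_file`). The FAUJ880109 donor counts are
nonzero for exactly 11 residues (R N D Q E H K S T W Y), consistent with the
standard statement that 11 amino acids hydrogen-bond through their side
chains. PSSM scores are used raw; a logistic squashing `1/(1+e^(−x))` is
available behind `squash_pssm=True` but off by default, since no
normalization is part of the reference protocol.

### Windows

Each residue becomes the center of one window of odd width `w` (default 15,
so a row has 660 values); `(w−1)/2` flanking residues contribute their
44-blocks on each side and positions past a terminus are zero-padded. Zero
padding keeps the row count equal to the chain length and is detectable
downstream (a padded slot's one-hot block sums to 0, a real residue's to 1).
The window label is the center residue's label. The window-width sweep
defaults to the eight odd candidates {3,5,7,9,11,13,15,17}.

### Classifier and cross-validation

Binding residues are typically <5 % of a chain, so training repeats a
downsample: all positives are kept and negatives are drawn uniformly without
replacement to `neg_pos_ratio` × n_pos (default 1.0). One XGBoost classifier
is fitted per draw (default 5 repeats) and prediction averages the per-model
positive-class probabilities. Booster settings are fixed, recorded in every
saved model, and never auto-tuned: 100 trees, learning rate 0.1, max depth 4,
subsample 0.8, histogram method, single-threaded.

Cross-validation is 10-fold and chain-grouped by default: chain ids are
shuffled once (seeded) and split into folds whose chain counts differ by at
most one, so no protein contributes windows to both train and test —
residue-level splitting (available as `cv_grouping="residue"`) is closer to
some published protocols but leaks within-protein information. Test folds
are themselves downsample-balanced before scoring by default, because the
reference per-ligand metrics (recall ≈ 0.93–0.94 across all classes) are only
consistent with evaluation on balanced sets; `eval_on_full=True` scores the
natural class ratio instead, and the chosen mode is recorded in every report.

Thresholded metrics use 0.5 on the ensemble score, with `score >= threshold`
counted positive. AUC is the midrank Mann–Whitney statistic (half credit for
ties), computed from ranks, and is checked in the tests against an O(n²)
pair-counting oracle and an independent library implementation. Ratios with
zero denominators are reported as 0 and flagged. Report averages over ligand
classes are unweighted arithmetic means; display rounding is 3 decimals and
JSON output keeps full precision.

### Importance scoring

Importance is aggregated per feature block (PSSM, the four physicochemical
scalars, one-hot), replicated across all window positions. Two estimators:
mean decrease accuracy (drop in held-out accuracy when the block's columns
are corrupted at prediction time — within-column permutation by default,
which preserves marginals; literal uniform-random substitution behind
`corrupt="random-uniform"`), and normalized impurity importance from a
random forest. Permutation was chosen as the default corruption because it
is the field-standard reading of mean decrease accuracy.

### Statistical tests in the distribution analyses

The per-letter binding/nonbinding composition comparison uses a
two-proportion z-test with Benjamini–Hochberg correction across the 20
letters; the physicochemical property comparison uses the two-sided
Mann–Whitney rank test. These choices are this package's protocol for
"significantly different", stated explicitly because several reasonable
tests exist.

## Synthetic benchmark generator

The generator emulates the statistical structure the method exploits, not
protein physics:

* **Geometry.** Cα atoms sit on a straight 3.8 Å-spaced trace; each planted
  binding residue gets one ligand atom 3.3 Å above its Cα. This makes the
  3.5 Å rule recover the planted labels exactly while every nonbinding Cα is
  ≥ √(3.8² + 3.3²) ≈ 5.03 Å from any ligand atom — a deliberate margin so
  labeling tests are sharp. Only distances matter to the labeler; realism of
  the backbone is a non-goal.
* **PSSM signal.** Scores are normals (mean 0, sd 2) rounded to integers and
  clipped to ±12; rows at binding positions (plus `spatial_extent` flanks)
  are mean-shifted by `signal_strength` on a fixed subset of 8 columns. The
  signal is thereby confined to the PSSM block, which is what makes the
  block-masking and importance-recovery tests meaningful.
* **Composition.** Letters at binding positions are drawn with excess
  probability `composition_bias` from the hydrophilic/charged set
  `RKHDESTNQ`, mimicking the enrichment real binding sites show.

Presets fix the study conditions: `null` (no signal — classifiers must sit
at chance), `weak` (shift 1.0, bias 0.10) and `strong` (shift 4.0, bias
0.40). Defaults elsewhere: 10 % binding fraction, chain lengths 80–160.
Identical configs produce byte-identical bundles, and the generator writes
the exact PSI-BLAST ASCII dialect and PDB fixed-width records the package's
parsers read, so the round trip is executable documentation of the format
assumptions.

What passing on this generator does **not** show: performance on real
proteins. Real PSSMs have position-dependent structure, binding sites
cluster spatially in sequence and 3-D, chains are redundant, and label noise
exists. The synthetic results validate the machinery (labeling, encoding,
balancing, grouping, scoring), not the published biological performance,
which required the sc-PDB corpus and PSI-BLAST searches of NCBI nr.

## Reproducibility and numerics

All randomness descends from one master seed; per-stage and per-fold seeds
are derived as `sha256(tag:seed) mod 2^31`. XGBoost runs single-threaded
with the histogram method, so reruns from a saved manifest produce
byte-identical reports (`report.json` intentionally carries no timestamps;
the manifest does). Ensemble probabilities are single precision, so
reordering models can shift scores by one ulp — tests compare at 1e-6.

Problem sizes used by the shipped checks: the end-to-end preset calibrations
run 200 chains with 10-fold chain-grouped CV; unit-level model tests use
16–50 chains; importance recovery uses 30–40 chains. These sizes were chosen
so the null preset's pooled AUC estimate is stable (±0.01) while a full run
of the suite stays in the minutes range.

## Known limitations

* PDB input only (no mmCIF), first model only, first alternate conformer
  only; nonstandard residues beyond a small substitution table (MSE→M etc.)
  are dropped with a warning.
* The redundancy filter is a greedy longest-first clustering on global
  alignment identity (match 1 / mismatch 0 / gap −1; identity =
  matches / alignment length; ties broken lexicographically by id). It is a
  deterministic, documented substitute for a dedicated culling server, not a
  reimplementation of one.
* `run_pssm_tool` only wraps an external PSI-BLAST-compatible executable;
  profile generation is never exercised in tests — precomputed ASCII PSSM
  files are the supported path.
* Metrics on the balanced evaluation stream (the default) are not comparable
  to natural-ratio metrics; both modes are labeled in output and must not be
  mixed in one table.
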