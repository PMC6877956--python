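# smopsi

Sequence-based prediction and analysis of protein–small-molecule binding
residues.

Knowing which residues of a protein contact a small-molecule ligand (ATP,
FAD, NAD, SAM, ...) matters for understanding protein function and for drug
design, but solving a structure for every complex is expensive. `smopsi`
implements a residue-level classifier that needs only sequence-derived
inputs at prediction time, plus the structural machinery to build training
labels when complexes are available. It is aimed at structural
bioinformaticians who want a transparent, reproducible baseline pipeline:
every stage is a plain library function with a CLI wrapper, and every number
in a report is reachable from a single seed.

## Method

**Labels.** Given a PDB structure with a bound ligand, residue *i* is a
binding residue iff

    min over ligand atoms a of d(ref_i, a) < 3.5 Å

where `ref_i` is the residue's Cα by default (an `any_heavy_atom` mode takes
the minimum over all heavy atoms). The comparison is strict.

**Features.** Each residue is encoded as 44 values: its row of the L×20
position-specific scoring matrix (PSSM, from PSI-BLAST ASCII output), four
physicochemical scalars — Hopp–Woods hydrophilicity (AAindex HOPT810101),
Kyte–Doolittle hydrophobicity (KYTJ820101), charge (+1 R/H/K, −1 D/E),
side-chain H-bond donor count (FAUJ880109) — and a 20-long one-hot identity.
A sliding window of odd width *w* (default 15) concatenates the center
residue's block with (w−1)/2 flanking blocks per side (zero-padded at
termini), giving w×44 = 660 features per training vector.

**Classifier.** Binding residues are a small minority, so training draws
repeated balanced subsets (all positives + an equal random sample of
negatives) and fits one XGBoost model per draw; the ensemble score is the
mean positive-class probability. Evaluation is 10-fold chain-grouped
cross-validation reporting ACC, precision, recall, F1 (harmonic mean) and
AUC (midrank Mann–Whitney).

The package also ships the surrounding analyses — per-letter and
physicochemical distributions of binding vs nonbinding residues, mean
decrease accuracy and random-forest importance per feature block, the
window-width sweep — and a synthetic benchmark generator that plants
controllable signal (contact geometry, PSSM mean shift, composition bias) so
the whole pipeline is testable without downloads. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
from smopsi.synthetic_data import preset_config, generate_bundle
from smopsi.pipeline import featurize_bundle
from smopsi.model import TrainConfig, cross_validate

bundle = generate_bundle(preset_config("strong", seed=42, n_chains=30))
matrix, _, _ = featurize_bundle(bundle)
print(f"{len(matrix)} windows, {matrix.n_positive} binding "
      f"({matrix.n_positive/len(matrix):.1%})")
result = cross_validate(matrix, TrainConfig(random_seed=42, cv_folds=10))
p = result.pooled
print(f"pooled 10-fold CV ({result.grouping}-grouped, {result.eval_mode} eval): "
      f"ACC {p.acc:.3f}  precision {p.precision:.3f}  recall {p.recall:.3f}  "
      f"F1 {p.f1:.3f}  AUC {p.auc:.3f}")
```

prints

```
3530 windows, 354 binding (10.0%)
pooled 10-fold CV (chain-grouped, balanced eval): ACC 0.992  precision 0.992  recall 0.992  F1 0.992  AUC 0.999
```

The bundle is 30 synthetic chains whose binding residues were planted
geometrically (ligand atoms 3.3 Å above their Cα) with a strong PSSM mean
shift; `featurize_bundle` re-derives the labels by actually parsing the PDB
text and applying the 3.5 Å rule, then windows the features. The pooled CV
row says the ensemble separates planted binding from nonbinding windows
nearly perfectly on held-out chains — the expected outcome at this effect
size, and the sanity check that the pipeline neither leaks across chains
(the `null` preset scores AUC ≈ 0.5) nor loses the signal.

The same flow from a shell:

```sh
smopsi simulate --preset strong --n-chains 30 --seed 42 --out bundle/
smopsi featurize --bundle-dir bundle/ --window 15 --out features.npz
smopsi cv --features features.npz --folds 10 --seed 42 --out report.json
smopsi label --pdb bundle/syn0000.pdb --ligand ATP --out labels.tsv
smopsi run --preset strong --n-chains 30 --seed 42 --out run/   # end to end
```

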