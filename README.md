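# ddgcv

Leakage-aware evaluation of protein stability-change (ΔΔG) predictors.

## The problem

Machine-learned predictors of the folding free-energy change upon point
mutation (ΔΔG, kcal/mol; positive = stabilizing here) are routinely scored
by random n-fold cross-validation on mutation collections dominated by
destabilizing records. Two practices interact badly with that design:

1. experimental collections contain many mutations of the same protein,
   often several at the same site, and those records are strongly
   correlated — random folds put them on both sides of the train/test
   boundary (**intra-protein data leakage**);
2. to fix the class imbalance, *hypothetical reverse mutations* (HRMs) are
   added: for a measured mutation A→B, the inverse B→A is assigned
   ΔΔG_BA = −ΔΔG_AB by thermodynamic antisymmetry. Each HRM is a near-twin
   of its forward record, so mixing both into random folds leaks further.

`ddgcv` packages the evaluation experiment that separates these effects:
it encodes mutations with the classic 42-value sequence feature vector
(20 mutation-code values, 20 residue counts in a 19-residue window centred
at the site, temperature, pH), builds the three dataset designs —
**unbalanced** (forward only), **balanced** (a random half replaced by
HRMs), **combined** (forward ∪ HRMs) — and scores a pluggable regressor
(default: RBF-kernel support-vector regression, C = 1, ε = 0.1,
γ = 1/42) under both random k-fold CV and **leave-one-protein-out (LOPO)**
grouped CV, reporting Pearson R, threshold-swept ROC AUC and the
sign-agreement rate Q2 per cell. A synthetic-data module generates
datasets with tunable shared per-site/per-protein effects so every claim
is testable without any download.

It is written for method developers and reviewers in structural
bioinformatics who need to ask: *does this cross-validated score survive
grouped evaluation, and does the model predict reverse mutations at all?*

## Worked example

`examples/03_leakage_demo.py` generates datasets in which mutations at a
shared site carry a common latent effect (the leakage substrate), then
scores the same SVR under both fold schemes:

```
seed 0:  10-fold R = 0.629   LOPO R = 0.309   gap = +0.320
seed 1:  10-fold R = 0.585   LOPO R = 0.201   gap = +0.384
seed 2:  10-fold R = 0.675   LOPO R = 0.331   gap = +0.345
seed 3:  10-fold R = 0.589   LOPO R = 0.189   gap = +0.400
seed 4:  10-fold R = 0.567   LOPO R = 0.190   gap = +0.377

mean inflation of 10-fold over LOPO: +0.365
```

Identical data, identical model — only the fold boundaries differ. The
gap is the leakage; the LOPO column is the honest generalization estimate.

`examples/04_experiment_grid.py` runs the full designs × schemes grid on a
reduced benchmark (32 proteins × 16 mutations) and prints:

```
   variant scheme  subset    n     R   AUC    Q2
unbalanced  kfold forward  512 0.595 0.798 0.771
unbalanced  kfold reverse  512 0.255 0.665 0.367
unbalanced   lopo forward  512 0.233 0.631 0.699
unbalanced   lopo reverse  512 0.317 0.695 0.367
  balanced  kfold forward  256 0.393 0.753 0.660
  balanced  kfold reverse  256 0.527 0.801 0.742
  balanced   lopo forward  256 0.203 0.647 0.578
  balanced   lopo reverse  256 0.409 0.737 0.680
  combined  kfold     all 1024 0.570 0.809 0.725
  combined   lopo     all 1024 0.288 0.662 0.617
```

Read the R column: every k-fold score beats its LOPO counterpart, and the
forward-trained model's reverse predictions collapse (0.595 → 0.255) —
apparently strong CV results that rest on leakage, not on informative
features. The `reverse` rows of the unbalanced design are *counterpart*
evaluations: each fold's model predicts the HRMs of its own held-out
records, keeping the reverse assessment out-of-sample.

The same pipeline runs from the shell on any mutation table + FASTA:

```bash
ddgcv simulate --out scratch/sim --seed 0          # or bring your own data
ddgcv validate --in scratch/sim.tsv --fasta scratch/sim.fasta
ddgcv grid --in scratch/sim.tsv --fasta scratch/sim.fasta \
      --out scratch/grid --seed-folds 11 --seed-balance 12
```

Mutation tables are CSV/TSV with columns
`protein_id, position, wt, mut, ddg, temp, ph` (names configurable,
positions 1-based); sequences come from a FASTA keyed by `protein_id`.

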