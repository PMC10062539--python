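# Methods

## The evaluation design

`ddgcv` measures how much of a stability-change predictor's
cross-validated score is attributable to intra-protein data leakage. The
object under study is not the regressor but the *evaluation protocol*:
the same model family is scored under

* **random k-fold CV** (default k = 10): all records are randomly
  partitioned into k folds of sizes within one of each other; correlated
  records from one protein — in particular several mutations at one site —
  routinely straddle the train/test boundary;
* **leave-one-protein-out (LOPO)**: one fold per protein, so no protein's
  records ever appear on both sides. LOPO removes intra-protein leakage
  only; leakage through sequence similarity *between* proteins is out of
  scope here, so LOPO is a necessary, not sufficient, robustness check.

Three dataset designs are compared. With a forward collection of n
records: **unbalanced** (the n forward records), **balanced** (a random
⌊n/2⌋ of the records kept forward, the rest replaced in place by their
hypothetical reverse mutations), and **combined** (all n forward plus all
n reverses). A reverse record swaps wild-type and incoming residue,
keeps position, protein, temperature and pH, and receives exactly
negated ΔΔG (thermodynamic antisymmetry, ΔΔG_AB = −ΔΔG_BA). Reversal is
an involution, and every reverse carries a `source_id` naming its
forward origin, which is how counterpart evaluation pairs them.

## Features and model

Each record is encoded as 42 values: a 20-vector with −1 at the deleted
residue and +1 at the incoming one (residue order alphabetical by
one-letter code, fixed and documented); 20 counts of each residue type in
a 19-residue window centred at the mutation site, computed on the
record's *starting* sequence (native for forward records, mutated for
reverse ones) and truncated without padding at the termini; and the
experimental temperature (°C) and pH. Two points the classic encoding
leaves ambiguous are exposed as switches with these defaults:

* the window **includes the central site** (`include_center=True`) —
  "centred at the site" most naturally counts the centre, and using the
  starting sequence treats forward and reverse records symmetrically;
* missing temperature/pH values are **rejected** unless median imputation
  is explicitly requested — silent imputation hides data problems.

The default regressor is ε-SVR with an RBF kernel, C = 1, ε = 0.1,
γ = 1/42 (the standard library defaults for this family); any object with
the scikit-learn `fit`/`predict` surface can be substituted. Per fold,
features are standardized with **training-fold statistics only** and a
fresh clone of the regressor is fitted; test-fold means and variances are
never consulted (asserted by a test that plants an extreme outlier in a
held-out fold and checks the training matrix is unchanged).

For forward-only data the harness can additionally predict the reverse
counterpart of every held-out record with that fold's own model
("counterpart" predictions). This keeps the reverse evaluation
out-of-sample per fold and yields exactly n pooled reverse predictions.

## Metrics

* **Pearson R** between predicted and experimental ΔΔG, pooled over all
  held-out predictions (per-fold R is available separately as a
  dispersion diagnostic). Undefined inputs (constant vector, n < 2)
  report NaN with a warning, never a silent 0.
* **ROC AUC** from sweeping a threshold over the predicted ΔΔG against
  the experimental binary class (stabilizing = ΔΔG > 0); equal to the
  Mann–Whitney probability with ties counted ½. Single-class input
  reports NaN with a warning.
* **Q2**, the fraction of records whose predicted sign class matches the
  experimental one; values ≤ 0 (including exact zeros) count as
  non-stabilizing. "Positive means stabilizing" forces a two-class rule
  to place measured-as-zero records somewhere; classing them with the
  majority negative class is the conservative reading, and a switch
  (`neutral="exclude"`) drops them instead.

Grid rows per design: unbalanced — held-out forward predictions and the
pooled counterpart reverses; balanced — held-out predictions split by
direction flag; combined — one pooled row. The resulting table has five
rows per scheme.

## The synthetic generator

The generator emulates the statistical shape of experimental ΔΔG
collections, not their thermodynamics. For each of `n_proteins` random
i.i.d.-uniform sequences it draws mutations whose ΔΔG is

    ΔΔG = w·x + e_site + e_protein + shift + ε

with `x` the 42 features, `w` a weak linear signal (per-block scales
chosen so each block contributes a fraction of a kcal/mol; each 20-block
centred so the signal is identified despite the blocks' constant-sum
structure), `e_site ~ N(0, site_effect_sd²)` shared by every mutation at
a site, `e_protein ~ N(0, protein_effect_sd²)` shared within a protein,
`ε ~ N(0, noise_sd²)` i.i.d., and `shift` either fixed or calibrated by
an empirical quantile so the realized stabilizing fraction hits a target.

Defaults are the benchmark preset: 64 proteins × 32 mutations
(2048 records, the scale of the canonical experimental collection), a
stabilizing-fraction target of 600/2048 ≈ 0.29 (~69 % destabilizing),
site/protein/noise standard deviations of 1.2 / 0.4 / 0.6 kcal/mol
(total ΔΔG spread ≈ 1.5 kcal/mol, typical of experimental collections,
with the shared-site component deliberately dominant over the learnable
signal), temperatures uniform in 20–30 °C and pH in 5–9. Mutation sites
are drawn from a per-protein pool of 8 hotspot positions: experimental
stability studies mutate a handful of positions repeatedly, and this
multiplicity is precisely the substrate of intra-protein leakage — with
sites drawn uniformly over whole sequences, same-site duplication is
rare and the leakage effect shrinks toward zero (setting
`sites_per_protein=None` reproduces that regime).

`composition_standin(seed)` derives from the benchmark preset a dataset
with *exactly* the canonical composition — 2048 mutations from 64
proteins, 600 stabilizing / 31 neutral / 1417 destabilizing — by placing
the positivity threshold between the 600th and 601st largest value and
zeroing the 31 negative records nearest zero. It is synthetic: it shares
the composition and scale of the real collection, nothing else.

What the generator does not emulate: real substitution-type preferences,
structural context, heteroscedastic measurement error, between-protein
sequence similarity (so inter-protein leakage cannot be studied on it),
and any genuine physical relationship between the features and ΔΔG.
Passing tests therefore demonstrate that the *machinery* behaves as
specified and that the leakage mechanism operates as described — not
that any particular real predictor is or is not leaky.

Under this generator the forward model's linear component is
antisymmetric in the mutation-code block but not in the window/condition
blocks, and the latent effects negate under reversal only through the
antisymmetry construction itself. One consequence: the combined design's
k-fold score here exceeds its LOPO score (leakage) but does not rise
above the unbalanced forward k-fold score the way exact-counterpart
memorization can drive it on real data, where the learnable signal is
carried almost entirely by the antisymmetric mutation code.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fold assignment, balanced selection and the generator each take
  their own seed, and every report/output file records them.
* "Half" in the balanced construction is ⌊n/2⌋ kept forward with odd n.
* k-fold partition: a seeded permutation split into k contiguous chunks
  (sizes within 1).
* LOPO fold order is the proteins' first-occurrence order; no seed.
* Reverse-record contexts are derived on demand from the native sequence
  (substituting the record's wild-type residue at the site) rather than
  stored, which keeps the dataset container single-sourced; serialized
  variants optionally write the mutated sequences as a companion FASTA.
* Degenerate metric inputs produce NaN plus a warning; empty training
  folds and mixed-direction inputs to forward-only operations raise.

## Problem sizes

The default test suite and the acceptance script use reduced replicates
of the benchmark: grid orderings on 32 proteins × 16 mutations, the
leakage Monte Carlo on 24 × 16 with 20 seed replicates, noiseless
recovery on 12 × 12, while the acceptance script's grid runs at the full
2048-record scale. These sizes were chosen so the statistical effects
under study are comfortably larger than their sampling error at
single-CPU-minutes cost.

## Known limitations

* No real mutation data ship with the package; the canonical collection
  is represented by a clearly-labelled synthetic stand-in, and absolute
  metric values on real data depend on hyperparameters the classic
  predictors did not publish.
* Inter-protein (similarity-based) leakage is explicitly out of scope.
* The generator's hotspot mechanism is a deliberate simplification of
  how mutation multiplicity arises in curated databases.
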