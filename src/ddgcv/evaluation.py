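"""Cross-validation harness, metrics and the 10-FCV vs LOPO experiment grid.

The question this module answers is evaluative, not predictive: how much of
a stability-change predictor's apparent accuracy survives when correlated
mutations from the same protein are forbidden from straddling the
train/test boundary?  Two fold schemes are provided:

* **random k-fold** (conventional n-FCV) — cases are randomly partitioned
  into k near-equal folds, so mutations from one protein, even repeated
  mutations at one site, routinely land on both sides of a split
  (intra-protein leakage);
* **leave-one-protein-out (LOPO)** — each protein's mutations form one test
  fold, with all other proteins as training data, eliminating intra-protein
  leakage entirely.

The harness is strict about hygiene: features are standardized with
training-fold statistics only, the regressor is refit from scratch per
fold, and every record is predicted exactly once as held-out.  For
forward-only datasets it can additionally predict each held-out record's
hypothetical reverse with the same fitted model (the ``counterpart``
evaluation), which is how a model trained on destabilizing-skewed data is
shown to collapse on reversed mutations.

Metrics follow standard conventions: Pearson R between predicted and
experimental ΔΔG, ROC AUC obtained by sweeping a threshold over the
predicted values against the experimental stabilizing/destabilizing class
(equal to the Mann–Whitney probability with ties counted 1/2), and Q2, the
fraction of cases whose predicted sign class matches the experimental one.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.base import clone
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .data_model import MutationDataset
from .features import EncodedDataset, encode_dataset
from .transforms import (
    DatasetVariant,
    VariantName,
    make_balanced,
    make_combined,
    make_reverse_dataset,
    make_unbalanced,
)

__all__ = [
    "FoldScheme", "FoldAssignment", "assign_kfold", "assign_lopo",
    "default_regressor", "cross_validate", "pearson_r", "roc_auc", "q2",
    "MetricsReport", "evaluate_subsets", "GridResult", "run_experiment_grid",
]


class FoldScheme(str, enum.Enum):
    KFOLD = "kfold"
    LOPO = "lopo"


@dataclass(frozen=True)
class FoldAssignment:
    """A partition of record indices into folds.

    ``fold_of[i]`` is the fold label of record i; labels are 0..k-1 for
    k-fold and protein ids for LOPO.
    """

    scheme: FoldScheme
    fold_of: np.ndarray
    k: int
    seed: int | None = None

    @property
    def labels(self) -> list:
        """Fold labels in deterministic order."""
        seen: dict = {}
        for lab in self.fold_of:
            seen.setdefault(lab, None)
        return list(seen)


def assign_kfold(n: int, k: int, seed: int) -> FoldAssignment:
    """Uniform random partition of n records into k folds of sizes within
    one of each other, reproducible from the seed."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of records n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=object)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        fold_of[chunk] = fold
    return FoldAssignment(FoldScheme.KFOLD, fold_of, k=k, seed=seed)


def assign_lopo(ds: MutationDataset | DatasetVariant) -> FoldAssignment:
    """One fold per protein (grouped CV); deterministic, no seed.

    All of a protein's mutations share a fold, so no protein ever appears
    on both sides of a split.
    """
    dataset = ds.dataset if isinstance(ds, DatasetVariant) else ds
    pids = dataset.protein_ids
    if len(pids) < 2:
        raise ValueError("leave-one-protein-out needs at least 2 proteins")
    fold_of = np.array([rec.protein_id for rec in dataset.records], dtype=object)
    return FoldAssignment(FoldScheme.LOPO, fold_of, k=len(pids))


def default_regressor() -> SVR:
    """Epsilon-SVR with RBF kernel: C=1, epsilon=0.1, gamma=1/n_features —
    the common library defaults for this model family."""
    return SVR(kernel="rbf", C=1.0, epsilon=0.1, gamma="auto")


class EvalTag(str, enum.Enum):
    HELDOUT = "heldout"
    COUNTERPART = "counterpart"


@dataclass(frozen=True)
class PredictionSet:
    """Per-record out-of-sample predictions from one cross-validation run.

    ``frame`` has columns: record_index, observed, predicted, direction,
    protein_id, fold, tag.  ``heldout`` rows cover every record exactly
    once; ``counterpart`` rows (if requested) are the reverse-mutation
    predictions paired 1:1 with held-out forward records.
    """

    frame: pd.DataFrame
    variant: VariantName
    scheme: FoldScheme

    def subset(self, tag: EvalTag | str, direction: str | None = None) -> pd.DataFrame:
        tag = EvalTag(tag)
        sel = self.frame[self.frame["tag"] == tag.value]
        if direction is not None:
            sel = sel[sel["direction"] == direction]
        return sel


def cross_validate(
    variant: DatasetVariant,
    folds: FoldAssignment,
    regressor=None,
    counterparts: bool = False,
    include_center: bool = True,
    encoded: EncodedDataset | None = None,
) -> PredictionSet:
    """Run grouped or random cross-validation around a pluggable regressor.

    For each fold: standardize features with training-fold statistics only,
    fit a fresh clone of the regressor on the training rows, and predict
    the held-out rows.  With ``counterparts=True`` (forward-only variants
    only) each fold's model also predicts the hypothetical reverse of every
    held-out record, keeping the reverse evaluation out-of-sample per fold.

    The regressor is anything with sklearn's ``fit``/``predict`` surface;
    ``None`` means the default RBF support-vector regressor.  ``encoded``
    lets callers pass a precomputed feature matrix (row i ↔ record i).
    """
    ds = variant.dataset
    n = len(ds.records)
    if len(folds.fold_of) != n:
        raise ValueError(
            f"fold assignment covers {len(folds.fold_of)} records, dataset "
            f"has {n}"
        )
    if regressor is None:
        regressor = default_regressor()
    enc = encoded if encoded is not None else encode_dataset(
        ds, include_center=include_center)
    if len(enc) != n:
        raise ValueError("encoded features do not match the dataset size")

    enc_rev = None
    if counterparts:
        rev_ds = make_reverse_dataset(ds)  # rejects non-forward inputs
        enc_rev = encode_dataset(rev_ds, include_center=include_center)

    rows: list[dict] = []
    index = np.arange(n)
    for fold in folds.labels:
        test_mask = folds.fold_of == fold
        train_mask = ~test_mask
        if not train_mask.any():
            raise ValueError(f"fold {fold!r} leaves an empty training set")
        scaler = StandardScaler().fit(enc.X[train_mask])
        model = clone(regressor)
        model.fit(scaler.transform(enc.X[train_mask]), enc.y[train_mask])
        pred = model.predict(scaler.transform(enc.X[test_mask]))
        for i, p in zip(index[test_mask], pred):
            rows.append(
                dict(record_index=int(i), observed=enc.y[i], predicted=float(p),
                     direction=str(enc.directions[i]), protein_id=str(enc.groups[i]),
                     fold=fold, tag=EvalTag.HELDOUT.value)
            )
        if enc_rev is not None:
            pred_rev = model.predict(scaler.transform(enc_rev.X[test_mask]))
            for i, p in zip(index[test_mask], pred_rev):
                rows.append(
                    dict(record_index=int(i), observed=enc_rev.y[i],
                         predicted=float(p), direction="reverse",
                         protein_id=str(enc_rev.groups[i]), fold=fold,
                         tag=EvalTag.COUNTERPART.value)
                )

    frame = pd.DataFrame(rows)
    heldout = frame[frame["tag"] == EvalTag.HELDOUT.value]
    assert sorted(heldout["record_index"]) == list(range(n))
    return PredictionSet(frame=frame, variant=variant.name, scheme=folds.scheme)


# ---------------------------------------------------------------------------
# Metrics

def pearson_r(pred, obs) -> float:
    """Pearson product-moment correlation of predicted vs experimental ΔΔG.

    Undefined (NaN, with a warning) when either side has zero variance or
    fewer than two points — never silently reported as 0.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size < 2 or np.ptp(pred) == 0 or np.ptp(obs) == 0:
        warnings.warn("Pearson R undefined (constant input or n < 2); "
                      "reporting NaN", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(pred, obs).statistic)


def stabilizing_labels(obs, neutral: str = "destab") -> np.ndarray | None:
    """Binary class labels from experimental ΔΔG: 1 = stabilizing (> 0).

    ``neutral`` picks the fate of exact-zero values: ``"destab"`` classes
    them with the non-stabilizing (negative) class, ``"exclude"`` marks
    them for removal (returned label −1).
    """
    obs = np.asarray(obs, dtype=float)
    if neutral == "destab":
        return (obs > 0).astype(int)
    if neutral == "exclude":
        lab = np.where(obs > 0, 1, 0)
        lab[obs == 0] = -1
        return lab
    raise ValueError(f"neutral must be 'destab' or 'exclude', got {neutral!r}")


def roc_auc(pred, labels) -> float:
    """Area under the ROC curve from sweeping a threshold over predictions.

    ``labels`` are binary (1 = stabilizing).  Equals the Mann–Whitney
    probability that a random stabilizing case outscores a random
    destabilizing one, ties counted 1/2.  Undefined (NaN + warning) when
    only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    pred = np.asarray(pred, dtype=float)
    if len(np.unique(labels)) < 2:
        warnings.warn("ROC AUC undefined (single-class input); reporting NaN",
                      stacklevel=2)
        return float("nan")
    return float(skmetrics.roc_auc_score(labels, pred))


def q2(pred, obs, neutral: str = "destab") -> float:
    """Fraction of records whose predicted ΔΔG sign class matches the
    experimental one (value > 0 → stabilizing, value ≤ 0 → destabilizing)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if neutral == "exclude":
        keep = obs != 0
        pred, obs = pred[keep], obs[keep]
    if pred.size == 0:
        warnings.warn("Q2 undefined on empty input; reporting NaN", stacklevel=2)
        return float("nan")
    return float(np.mean((pred > 0) == (obs > 0)))


@dataclass(frozen=True)
class MetricsReport:
    """R / AUC / Q2 for one named prediction subset."""

    subset: str
    n: int
    R: float
    AUC: float
    Q2: float


def _report(name: str, df: pd.DataFrame, neutral: str) -> MetricsReport:
    pred = df["predicted"].to_numpy()
    obs = df["observed"].to_numpy()
    lab = stabilizing_labels(obs, neutral)
    if neutral == "exclude":
        keep = lab >= 0
        auc = roc_auc(pred[keep], lab[keep]) if keep.any() else float("nan")
    else:
        auc = roc_auc(pred, lab)
    return MetricsReport(
        subset=name, n=len(df),
        R=pearson_r(pred, obs), AUC=auc, Q2=q2(pred, obs, neutral),
    )


def evaluate_subsets(ps: PredictionSet, neutral: str = "destab") -> list[MetricsReport]:
    """The per-variant metric subsets of the experiment grid.

    * unbalanced — "forward" = held-out records, "reverse" = counterpart
      reverse predictions;
    * balanced — held-out records split by direction flag;
    * combined — one pooled "all" subset of every held-out record.
    """
    if len(ps.frame) == 0:
        raise ValueError("empty prediction set")
    if ps.variant is VariantName.UNBALANCED:
        out = [_report("forward", ps.subset(EvalTag.HELDOUT), neutral)]
        counter = ps.subset(EvalTag.COUNTERPART)
        if len(counter):
            out.append(_report("reverse", counter, neutral))
        return out
    if ps.variant is VariantName.BALANCED:
        held = ps.subset(EvalTag.HELDOUT)
        return [
            _report("forward", held[held["direction"] == "forward"], neutral),
            _report("reverse", held[held["direction"] == "reverse"], neutral),
        ]
    return [_report("all", ps.subset(EvalTag.HELDOUT), neutral)]


def pearson_r_per_fold(ps: PredictionSet) -> pd.Series:
    """Per-fold Pearson R of held-out predictions (an alternative to the
    default pooled R, for fold-level dispersion diagnostics)."""
    held = ps.subset(EvalTag.HELDOUT)
    return held.groupby("fold").apply(
        lambda g: pearson_r(g["predicted"], g["observed"]),
        include_groups=False,
    )


# ---------------------------------------------------------------------------
# The experiment grid

@dataclass
class GridResult:
    """Full 10-FCV vs LOPO comparison over the three dataset variants.

    ``table`` mirrors the standard report layout: one row per
    (variant, scheme, subset) with n, R, AUC and Q2.  ``predictions`` keeps
    every per-record prediction set for plotting; ``config`` records seeds
    and regressor parameters for reproducibility.
    """

    table: pd.DataFrame
    predictions: dict[tuple[str, str], PredictionSet] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def cell(self, variant: str, scheme: str, subset: str) -> MetricsReport:
        t = self.table
        row = t[(t["variant"] == variant) & (t["scheme"] == scheme)
                & (t["subset"] == subset)]
        if len(row) != 1:
            raise KeyError((variant, scheme, subset))
        r = row.iloc[0]
        return MetricsReport(subset=subset, n=int(r["n"]), R=r["R"],
                             AUC=r["AUC"], Q2=r["Q2"])


def run_experiment_grid(
    forward_ds: MutationDataset,
    fold_seed: int,
    balance_seed: int,
    regressor=None,
    k: int = 10,
    neutral: str = "destab",
    include_center: bool = True,
    variants: tuple[str, ...] = ("unbalanced", "balanced", "combined"),
    schemes: tuple[str, ...] = ("kfold", "lopo"),
) -> GridResult:
    """Evaluate {unbalanced, balanced, combined} × {k-FCV, LOPO}.

    The unbalanced variant additionally gets the counterpart reverse
    evaluation, so its grid rows are forward and reverse; balanced rows
    split held-out predictions by direction; combined is pooled.  All
    stochastic steps (fold assignment, balanced half-selection) take
    explicit seeds recorded in the result.
    """
    if regressor is None:
        regressor = default_regressor()
    builders = {
        "unbalanced": lambda: make_unbalanced(forward_ds),
        "balanced": lambda: make_balanced(forward_ds, seed=balance_seed),
        "combined": lambda: make_combined(forward_ds),
    }
    rows = []
    predictions: dict[tuple[str, str], PredictionSet] = {}
    for vname in variants:
        variant = builders[vname]()
        enc = encode_dataset(variant.dataset, include_center=include_center)
        for sname in schemes:
            if sname == "kfold":
                folds = assign_kfold(len(variant.dataset), k=k, seed=fold_seed)
            else:
                folds = assign_lopo(variant)
            ps = cross_validate(
                variant, folds, regressor=regressor,
                counterparts=(vname == "unbalanced"),
                include_center=include_center, encoded=enc,
            )
            predictions[(vname, sname)] = ps
            for rep in evaluate_subsets(ps, neutral=neutral):
                rows.append(
                    dict(variant=vname, scheme=sname, subset=rep.subset,
                         n=rep.n, R=rep.R, AUC=rep.AUC, Q2=rep.Q2)
                )
    table = pd.DataFrame(rows)
    config = dict(
        fold_seed=fold_seed, balance_seed=balance_seed, k=k, neutral=neutral,
        include_center=include_center,
        regressor=repr(regressor),
    )
    return GridResult(table=table, predictions=predictions, config=config)
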