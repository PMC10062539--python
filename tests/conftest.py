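import numpy as np
import pytest

from ddgcv import (
    MutationDataset,
    MutationRecord,
    ProteinRecord,
)

#: A 20-residue toy sequence containing each canonical residue exactly once.
ALPHABET_SEQ = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def alphabet_protein():
    return ProteinRecord("TOY1", ALPHABET_SEQ)


def make_toy_dataset():
    """Three forward mutations on two small proteins, hand-checkable."""
    proteins = {
        "TOY1": ProteinRecord("TOY1", ALPHABET_SEQ),
        "TOY2": ProteinRecord("TOY2", "MKVLAAGI" * 5),  # length 40
    }
    records = [
        MutationRecord("TOY1", 10, "L", "A", ddg=1.2, temperature=25.0, ph=7.0),
        MutationRecord("TOY1", 2, "C", "S", ddg=-0.5, temperature=25.0, ph=6.5),
        MutationRecord("TOY2", 5, "A", "G", ddg=0.0, temperature=30.0, ph=7.4),
    ]
    return MutationDataset(records=records, proteins=proteins)


@pytest.fixture
def toy_dataset():
    return make_toy_dataset()


@pytest.fixture(scope="session")
def small_synthetic():
    """A small generated dataset shared across tests (8 proteins x 8)."""
    from ddgcv import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(n_proteins=8, mutations_per_protein=8,
                          sequence_length=(40, 80), seed=42)
    ds, truth = generate_dataset(cfg)
    return ds, truth


def brute_force_auc(pred, labels):
    """Independent AUC oracle: exhaustive positive-negative pair counting,
    ties worth 1/2."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = pred[labels == 1]
    neg = pred[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def closed_form_pearson(x, y):
    """Independent Pearson oracle straight from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx * sx) * np.sqrt(
        n * (y * y).sum() - sy * sy
    )
    return num / den
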