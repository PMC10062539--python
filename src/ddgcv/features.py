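"""The 42-value sequence feature vector used by I-Mutant2.0-style predictors.

Each mutation is encoded as:

* 20 mutation-code values, one per residue type in alphabetical one-letter
  order: −1 for the deleted (wild-type) residue, +1 for the incoming residue,
  0 elsewhere;
* 20 window-composition counts: how many residues of each type fall inside a
  19-residue window centred at the mutation site, computed on the record's
  *starting* sequence (native for forward records, mutated for reverse ones)
  and truncated at the sequence termini without padding;
* the experimental temperature (°C) and pH.

The residue ordering within each 20-value block is alphabetical
(``A C D E F G H I K L M N P Q R S T V W Y``) and stable across versions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    CANONICAL_RESIDUES,
    DataModelError,
    MutationDataset,
    MutationRecord,
)

#: Half-width of the composition window: 9 residues either side of the site.
WINDOW_HALF = 9
#: Total feature count: 20 mutation-code + 20 window-composition + temp + pH.
N_FEATURES = 42

_RESIDUE_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}

#: Stable column names for serialized feature matrices.
FEATURE_NAMES = (
    [f"mc_{r}" for r in CANONICAL_RESIDUES]
    + [f"wc_{r}" for r in CANONICAL_RESIDUES]
    + ["temp", "ph"]
)


def residue_index(residue: str) -> int:
    """Index of a canonical residue letter in the documented alphabetical
    order; a bijection onto 0..19."""
    try:
        return _RESIDUE_INDEX[residue]
    except KeyError:
        raise DataModelError(f"non-canonical residue {residue!r}") from None


@dataclass(frozen=True)
class FeatureVector:
    """The 42 predictor values for one mutation record."""

    mutation_code: np.ndarray  # shape (20,), entries in {-1, 0, +1}
    window_composition: np.ndarray  # shape (20,), non-negative counts
    temperature: float
    ph: float

    def to_array(self) -> np.ndarray:
        """Concatenate into the canonical 42-vector (see FEATURE_NAMES)."""
        return np.concatenate(
            [
                self.mutation_code,
                self.window_composition,
                [self.temperature, self.ph],
            ]
        ).astype(float)


def window_bounds(position: int, length: int) -> tuple[int, int]:
    """Inclusive 1-based [start, end] of the composition window after
    truncation at the sequence ends."""
    return max(position - WINDOW_HALF, 1), min(position + WINDOW_HALF, length)


def encode_mutation(
    record: MutationRecord,
    starting_sequence: str,
    include_center: bool = True,
) -> FeatureVector:
    """Encode one mutation given its starting sequence.

    ``starting_sequence`` must carry ``record.wt_residue`` at
    ``record.position`` (the pre-mutation state); a mismatch is an error.
    ``include_center=False`` drops the mutated site itself from the
    composition count — the window definition is ambiguous in the original
    predictor, so both readings are available.
    """
    L = len(starting_sequence)
    if record.position > L:
        raise DataModelError(
            f"position {record.position} beyond sequence length {L}"
        )
    i = record.position - 1
    if starting_sequence[i] != record.wt_residue:
        raise DataModelError(
            f"context mismatch: starting sequence has "
            f"{starting_sequence[i]!r} at position {record.position}, "
            f"record expects {record.wt_residue!r}"
        )

    code = np.zeros(20)
    code[residue_index(record.wt_residue)] = -1.0
    code[residue_index(record.mut_residue)] = 1.0

    lo, hi = window_bounds(record.position, L)
    comp = np.zeros(20)
    for pos in range(lo, hi + 1):
        if not include_center and pos == record.position:
            continue
        comp[residue_index(starting_sequence[pos - 1])] += 1.0

    return FeatureVector(code, comp, record.temperature, record.ph)


@dataclass(frozen=True)
class EncodedDataset:
    """Feature matrix plus the aligned targets and grouping metadata."""

    X: np.ndarray  # (n, 42)
    y: np.ndarray  # (n,) experimental ΔΔG, kcal/mol
    groups: np.ndarray  # (n,) protein ids
    directions: np.ndarray  # (n,) "forward" / "reverse"

    def __len__(self) -> int:
        return self.X.shape[0]


def encode_dataset(
    ds: MutationDataset, include_center: bool = True
) -> EncodedDataset:
    """Encode every record of a dataset, row i ↔ record i.

    Column order is 20 mutation-code, 20 window-composition, temperature,
    pH (:data:`FEATURE_NAMES`).  Reverse records are encoded against their
    mutated starting sequence, derived from the native one.
    """
    n = len(ds.records)
    X = np.empty((n, N_FEATURES))
    y = np.empty(n)
    groups = np.empty(n, dtype=object)
    directions = np.empty(n, dtype=object)
    for i, rec in enumerate(ds.records):
        try:
            fv = encode_mutation(
                rec, ds.starting_sequence(rec), include_center=include_center
            )
        except DataModelError as exc:
            raise DataModelError(f"record {i}: {exc}") from exc
        X[i] = fv.to_array()
        y[i] = rec.ddg
        groups[i] = rec.protein_id
        directions[i] = rec.direction.value
    return EncodedDataset(X, y, groups, directions)


def write_feature_table(enc: EncodedDataset, path) -> None:
    """Write the feature matrix as TSV with the canonical 42-name header,
    plus ddg/protein_id/direction columns for traceability."""
    import pandas as pd

    df = pd.DataFrame(enc.X, columns=FEATURE_NAMES)
    df["ddg"] = enc.y
    df["protein_id"] = enc.groups
    df["direction"] = enc.directions
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_feature_table(path) -> EncodedDataset:
    """Read a feature matrix previously written by :func:`write_feature_table`
    (or produced elsewhere with the same 42-column header), so precomputed
    features can feed the evaluation harness directly."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_NAMES + ["ddg", "protein_id", "direction"]
               if c not in df.columns]
    if missing:
        raise DataModelError(f"feature table missing columns: {missing}")
    return EncodedDataset(
        X=df[FEATURE_NAMES].to_numpy(dtype=float),
        y=df["ddg"].to_numpy(dtype=float),
        groups=df["protein_id"].to_numpy(dtype=object),
        directions=df["direction"].to_numpy(dtype=object),
    )
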