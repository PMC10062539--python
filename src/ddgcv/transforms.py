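"""Construction of the three evaluation dataset variants.

Starting from an all-forward mutation dataset, three variants are built:

* **unbalanced** — the original forward records, dominated by destabilizing
  mutations;
* **balanced** — same size, but a random half of the records is replaced by
  their hypothetical reverse mutations (HRMs), nearly equalizing the
  stabilizing/destabilizing counts;
* **combined** — the union of every forward record and its reverse, twice
  the size and exactly sign-balanced apart from neutrals.

A reverse mutation swaps wild-type and incoming residues, keeps position,
protein, temperature and pH, and negates ΔΔG by thermodynamic antisymmetry:
the free-energy change of mutating A→B is exactly the negative of B→A.
Every reverse record carries a ``source_id`` pointing at its forward origin
so evaluation can pair them up.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .data_model import Direction, MutationDataset, MutationRecord


class VariantName(str, enum.Enum):
    UNBALANCED = "unbalanced"
    BALANCED = "balanced"
    COMBINED = "combined"


@dataclass(frozen=True)
class DatasetVariant:
    """A named dataset variant plus the seed that produced it (if random)."""

    name: VariantName
    dataset: MutationDataset
    seed: int | None = None


def record_key(rec: MutationRecord, index: int) -> str:
    """Stable identifier for a forward record within its dataset: positional
    index plus mutation label, e.g. ``17:1BNI:L10A``."""
    return f"{index}:{rec.protein_id}:{rec.label}"


def make_reverse(rec: MutationRecord, source_id: str) -> MutationRecord:
    """The hypothetical reverse of a forward record.

    Residues swap, ΔΔG negates exactly; position, protein, temperature and
    pH are unchanged (the hypothetical experiment runs at the same
    conditions).  Applying the construction twice restores the original
    record, so the reverse of a reverse is the forward mutation itself.
    """
    if rec.direction is Direction.FORWARD:
        new_dir = Direction.REVERSE
    else:
        new_dir = Direction.FORWARD
    return replace(
        rec,
        wt_residue=rec.mut_residue,
        mut_residue=rec.wt_residue,
        ddg=-rec.ddg,
        direction=new_dir,
        source_id=source_id,
    )


def make_reverse_dataset(ds: MutationDataset) -> MutationDataset:
    """One reverse record per input record, in input order.

    The stabilizing and destabilizing counts of the output are the input's
    swapped; neutral records stay neutral (−0.0 counts as 0).
    """
    _require_all_forward(ds, "make_reverse_dataset")
    records = [
        make_reverse(rec, source_id=record_key(rec, i))
        for i, rec in enumerate(ds.records)
    ]
    return MutationDataset(records=records, proteins=dict(ds.proteins))


def make_unbalanced(ds: MutationDataset) -> DatasetVariant:
    """The original forward-only dataset as a named variant."""
    _require_all_forward(ds, "make_unbalanced")
    return DatasetVariant(VariantName.UNBALANCED,
                          MutationDataset(list(ds.records), dict(ds.proteins)))


def make_balanced(ds: MutationDataset, seed: int) -> DatasetVariant:
    """Replace a random half of the forward records by their reverses.

    ``floor(n/2)`` records (drawn without replacement with the given seed)
    are kept forward; the remaining ``ceil(n/2)`` are replaced in place by
    their reverse counterparts.  Size, protein set and the multiset of
    |ΔΔG| are preserved; the output's stabilizing/destabilizing counts are
    nearly equal when the input is skewed the way experimental data are.
    """
    _require_all_forward(ds, "make_balanced")
    n = len(ds.records)
    if n < 2:
        raise ValueError("balanced construction needs at least 2 records")
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(n, size=n // 2, replace=False).tolist())
    records = [
        rec if i in keep else make_reverse(rec, source_id=record_key(rec, i))
        for i, rec in enumerate(ds.records)
    ]
    return DatasetVariant(
        VariantName.BALANCED,
        MutationDataset(records=records, proteins=dict(ds.proteins)),
        seed=seed,
    )


def make_combined(ds: MutationDataset) -> DatasetVariant:
    """All forward records followed by all their reverses (size 2n)."""
    _require_all_forward(ds, "make_combined")
    rev = make_reverse_dataset(ds)
    return DatasetVariant(
        VariantName.COMBINED,
        MutationDataset(records=list(ds.records) + list(rev.records),
                        proteins=dict(ds.proteins)),
    )


def write_variant(variant: DatasetVariant, table_path, fasta_path=None) -> None:
    """Serialize a variant as a TSV mutation table; if ``fasta_path`` is
    given, also write the mutated starting sequences of its reverse records
    (keyed ``<protein_id>|<reverse label>``) as a companion FASTA."""
    from .data_model import ProteinRecord, write_fasta, write_mutation_table

    write_mutation_table(variant.dataset, table_path)
    if fasta_path is None:
        return
    ds = variant.dataset
    mutated: dict[str, ProteinRecord] = {}
    for rec in ds.records:
        if rec.direction is Direction.REVERSE:
            key = f"{rec.protein_id}|{rec.label}"
            if key not in mutated:
                mutated[key] = ProteinRecord(key, ds.starting_sequence(rec))
    write_fasta(mutated, fasta_path)


def _require_all_forward(ds: MutationDataset, op: str) -> None:
    for i, rec in enumerate(ds.records):
        if rec.direction is not Direction.FORWARD:
            raise ValueError(f"{op} expects an all-forward dataset; record "
                             f"{i} has direction {rec.direction.value!r}")
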