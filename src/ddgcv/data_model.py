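"""Domain types, parsing and validation for point-mutation stability datasets.

The central objects are :class:`ProteinRecord` (an identifier plus amino-acid
sequence), :class:`MutationRecord` (one mutation event with its experimental
ΔΔG, temperature and pH) and :class:`MutationDataset` (an ordered collection
of records plus the sequences they index into).

Conventions, fixed package-wide:

* positions are 1-based indices into the protein sequence, matching mutation
  notation (``L10A`` mutates position 10);
* ΔΔG is in kcal/mol with positive = stabilizing, negative = destabilizing;
* sequences use the 20 canonical uppercase one-letter codes only —
  non-canonical residues are a hard error, never silently masked.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

#: The 20 canonical amino-acid one-letter codes, alphabetical.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


class Direction(str, enum.Enum):
    """Whether a record is an experimental (forward) mutation or a
    hypothetical reverse mutation derived from one by antisymmetry."""

    FORWARD = "forward"
    REVERSE = "reverse"


class DataModelError(ValueError):
    """Base class for dataset parsing/validation failures."""


class ConfigurationError(DataModelError):
    """A required column or option is missing or malformed."""


class RowError(DataModelError):
    """A specific table row could not be parsed; carries the row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence.

    The sequence is the coordinate frame for mutation positions.
    """

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise DataModelError("protein_id must be non-empty")
        if not self.sequence:
            raise DataModelError(f"{self.protein_id}: sequence must be non-empty")
        seq = self.sequence.upper()
        for i, ch in enumerate(seq):
            if ch not in _CANONICAL_SET:
                raise DataModelError(
                    f"{self.protein_id}: non-canonical residue {ch!r} "
                    f"at position {i + 1}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationRecord:
    """One mutation event.

    ``wt_residue`` is the residue present *before* the event in the record's
    starting sequence; ``mut_residue`` the residue after.  For reverse
    records the starting sequence is the mutated protein, so ``wt_residue``
    equals the forward record's incoming residue.
    """

    protein_id: str
    position: int  # 1-based
    wt_residue: str
    mut_residue: str
    ddg: float  # kcal/mol, positive = stabilizing
    temperature: float  # °C
    ph: float
    direction: Direction = Direction.FORWARD
    source_id: str | None = None  # links a reverse record to its forward origin

    def __post_init__(self) -> None:
        for name in ("wt_residue", "mut_residue"):
            r = getattr(self, name)
            if r not in _CANONICAL_SET:
                raise DataModelError(f"{name} {r!r} is not a canonical residue")
        if self.wt_residue == self.mut_residue:
            raise DataModelError(
                f"{self.protein_id} position {self.position}: "
                f"wt and mutant residue are both {self.wt_residue!r}"
            )
        if self.position < 1:
            raise DataModelError(f"position must be >= 1, got {self.position}")
        for name in ("ddg", "temperature", "ph"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DataModelError(f"{name} must be finite, got {v!r}")
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))

    @property
    def label(self) -> str:
        """Mutation in conventional notation, e.g. ``L10A``."""
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


@dataclass
class MutationDataset:
    """An ordered collection of mutation records plus their proteins.

    Duplicate (protein, position, wt, mut) entries are permitted and kept as
    distinct cases: the same substitution measured at different temperature
    or pH is a distinct experiment, and no redundancy reduction is applied.
    """

    records: list[MutationRecord] = field(default_factory=list)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def protein_ids(self) -> list[str]:
        """Distinct protein ids in first-occurrence order over records."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.protein_id, None)
        return list(seen)

    def attach_sequences(self, proteins: Mapping[str, ProteinRecord]) -> None:
        """Register sequences for the records' proteins (merging)."""
        for pid, prot in proteins.items():
            if pid in self.proteins and self.proteins[pid].sequence != prot.sequence:
                raise DataModelError(f"conflicting sequences for protein {pid!r}")
            self.proteins[pid] = prot

    def starting_sequence(self, rec: MutationRecord) -> str:
        """The sequence in which ``rec.wt_residue`` sits at ``rec.position``.

        For forward records this is the native sequence; for reverse records
        it is the native sequence with the original (forward) substitution
        applied, which by construction places ``rec.wt_residue`` at the site.
        """
        prot = self.proteins.get(rec.protein_id)
        if prot is None:
            raise DataModelError(f"no sequence for protein {rec.protein_id!r}")
        seq = prot.sequence
        if rec.position > len(seq):
            raise DataModelError(
                f"{rec.protein_id}: position {rec.position} beyond sequence "
                f"length {len(seq)}"
            )
        i = rec.position - 1
        if rec.direction is Direction.FORWARD:
            if seq[i] != rec.wt_residue:
                raise DataModelError(
                    f"{rec.protein_id} {rec.label}: sequence has {seq[i]!r} "
                    f"at position {rec.position}, expected {rec.wt_residue!r}"
                )
            return seq
        # reverse: native must carry the residue the reverse event restores
        if seq[i] != rec.mut_residue:
            raise DataModelError(
                f"{rec.protein_id} {rec.label} (reverse): native sequence has "
                f"{seq[i]!r} at position {rec.position}, expected "
                f"{rec.mut_residue!r}"
            )
        return seq[:i] + rec.wt_residue + seq[i + 1 :]


# ---------------------------------------------------------------------------
# Table I/O

#: Default column names for mutation tables.
DEFAULT_COLUMNS = {
    "protein_id": "protein_id",
    "position": "position",
    "wt": "wt",
    "mut": "mut",
    "ddg": "ddg",
    "temp": "temp",
    "ph": "ph",
}
_OPTIONAL_COLUMNS = {"direction": "direction", "source_id": "source_id"}


def read_mutation_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
    flip_sign: bool = False,
    impute_missing: bool = False,
) -> MutationDataset:
    """Read a CSV/TSV mutation table into a :class:`MutationDataset`.

    Parameters
    ----------
    path:
        Table with a header row.  The separator is sniffed from the file
        extension (``.tsv`` → tab, otherwise comma) unless ``sep`` is given.
    columns:
        Overrides for the logical→physical column-name mapping; keys as in
        :data:`DEFAULT_COLUMNS`.
    flip_sign:
        Negate ΔΔG on read, for sources using the opposite sign convention
        (negative = stabilizing).
    impute_missing:
        If True, records with missing temperature or pH receive the dataset
        median instead of being rejected.

    Sequences are attached separately (see :func:`read_fasta` and
    :meth:`MutationDataset.attach_sequences`); rows come in as forward
    records unless the table carries a ``direction`` column.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"mutation table not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(DEFAULT_COLUMNS) - set(_OPTIONAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown column keys: {sorted(unknown)}")
        colmap.update(columns)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    for logical, physical in colmap.items():
        if physical not in df.columns:
            raise ConfigurationError(
                f"required column {physical!r} (for {logical}) not in "
                f"{path.name}; available: {list(df.columns)}"
            )

    def _num(row_idx: int, name: str, raw, allow_missing: bool = False) -> float:
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or (
            isinstance(raw, str) and not raw.strip()
        ):
            if allow_missing:
                return math.nan
            raise RowError(row_idx, f"missing value in column {name!r}")
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise RowError(row_idx, f"unparseable number {raw!r} in column {name!r}")

    has_direction = _OPTIONAL_COLUMNS["direction"] in df.columns
    has_source = _OPTIONAL_COLUMNS["source_id"] in df.columns

    rows: list[dict] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        pos_f = _num(idx, colmap["position"], r[colmap["position"]])
        if pos_f != int(pos_f):
            raise RowError(idx, f"position {pos_f!r} is not an integer")
        rows.append(
            dict(
                protein_id=str(r[colmap["protein_id"]]).strip(),
                position=int(pos_f),
                wt=str(r[colmap["wt"]]).strip().upper(),
                mut=str(r[colmap["mut"]]).strip().upper(),
                ddg=_num(idx, colmap["ddg"], r[colmap["ddg"]]),
                temp=_num(idx, colmap["temp"], r[colmap["temp"]], allow_missing=True),
                ph=_num(idx, colmap["ph"], r[colmap["ph"]], allow_missing=True),
                direction=str(r["direction"]).strip() if has_direction else "forward",
                source_id=(
                    str(r["source_id"]).strip()
                    if has_source
                    and isinstance(r.get("source_id"), str)
                    and r["source_id"].strip()
                    else None
                ),
            )
        )

    # missing temperature / pH policy
    missing = [
        i for i, r in enumerate(rows) if math.isnan(r["temp"]) or math.isnan(r["ph"])
    ]
    if missing:
        if not impute_missing:
            raise RowError(
                missing[0],
                "missing temperature or pH (pass impute_missing=True to use "
                "the dataset median)",
            )
        med_t = _median([r["temp"] for r in rows if not math.isnan(r["temp"])])
        med_p = _median([r["ph"] for r in rows if not math.isnan(r["ph"])])
        for i in missing:
            if math.isnan(rows[i]["temp"]):
                rows[i]["temp"] = med_t
            if math.isnan(rows[i]["ph"]):
                rows[i]["ph"] = med_p

    records = []
    for idx, r in enumerate(rows):
        try:
            records.append(
                MutationRecord(
                    protein_id=r["protein_id"],
                    position=r["position"],
                    wt_residue=r["wt"],
                    mut_residue=r["mut"],
                    ddg=-r["ddg"] if flip_sign else r["ddg"],
                    temperature=r["temp"],
                    ph=r["ph"],
                    direction=Direction(r["direction"]),
                    source_id=r["source_id"],
                )
            )
        except DataModelError as exc:
            raise RowError(idx, str(exc)) from exc
    return MutationDataset(records=records)


def _median(values: Sequence[float]) -> float:
    if not values:
        raise DataModelError("cannot impute: no non-missing values in column")
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def write_mutation_table(ds: MutationDataset, path: str | Path) -> None:
    """Write records as TSV with direction and source_id columns.

    Numeric fields are rendered with ``repr`` so a read/write round trip is
    value-exact.
    """
    path = Path(path)
    cols = ["protein_id", "position", "wt", "mut", "ddg", "temp", "ph",
            "direction", "source_id"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in ds.records:
            fh.write(
                "\t".join(
                    [
                        rec.protein_id,
                        str(rec.position),
                        rec.wt_residue,
                        rec.mut_residue,
                        repr(rec.ddg),
                        repr(rec.temperature),
                        repr(rec.ph),
                        rec.direction.value,
                        rec.source_id or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read protein sequences from FASTA, keyed by the header's first token.

    Sequences are uppercased; duplicate ids and non-canonical residues are
    errors.
    """
    path = Path(path)
    proteins: dict[str, ProteinRecord] = {}
    pid: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        nonlocal pid, chunks
        if pid is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise DataModelError(f"FASTA record {pid!r} has an empty sequence")
        bad = sorted(set(seq) - _CANONICAL_SET)
        if bad:
            raise DataModelError(
                f"FASTA record {pid!r} contains non-canonical residue(s) "
                f"{','.join(bad)}"
            )
        proteins[pid] = ProteinRecord(pid, seq)
        pid, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                pid = line[1:].split()[0] if line[1:].split() else ""
                if not pid:
                    raise DataModelError("FASTA header with empty id")
                if pid in proteins:
                    raise DataModelError(f"duplicate FASTA id {pid!r}")
            else:
                if pid is None:
                    raise DataModelError("FASTA sequence data before any header")
                chunks.append(line)
        _flush()
    if not proteins:
        raise DataModelError(f"no FASTA records in {path}")
    return proteins


def write_fasta(proteins: Mapping[str, ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write sequences as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for pid, prot in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(prot.sequence), width):
                fh.write(prot.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Validation and summary

@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    record_index: int
    kind: str  # "missing_sequence" | "position_out_of_range" | "wt_mismatch"
    message: str


def validate_dataset(ds: MutationDataset) -> list[Violation]:
    """Check every record against its protein sequence.

    Returns a (possibly empty) list of violations; never raises for data
    problems.  An empty report means every position is in range and every
    record's wt residue agrees with its starting sequence.
    """
    report: list[Violation] = []
    for i, rec in enumerate(ds.records):
        prot = ds.proteins.get(rec.protein_id)
        if prot is None:
            report.append(
                Violation(i, "missing_sequence",
                          f"no sequence for protein {rec.protein_id!r}")
            )
            continue
        if rec.position > len(prot):
            report.append(
                Violation(
                    i, "position_out_of_range",
                    f"{rec.protein_id} {rec.label}: position {rec.position} > "
                    f"length {len(prot)}",
                )
            )
            continue
        native = prot.sequence[rec.position - 1]
        expected = (
            rec.wt_residue if rec.direction is Direction.FORWARD else rec.mut_residue
        )
        if native != expected:
            report.append(
                Violation(
                    i, "wt_mismatch",
                    f"{rec.protein_id} {rec.label}: sequence has {native!r} at "
                    f"position {rec.position}, expected {expected!r}",
                )
            )
    return report


def summarize(ds: MutationDataset) -> dict[str, int]:
    """Counts of records, proteins and ΔΔG sign classes.

    Stabilizing means ΔΔG > 0, neutral exactly 0, destabilizing < 0; the
    three always partition the records.
    """
    n_stab = sum(1 for r in ds.records if r.ddg > 0)
    n_neut = sum(1 for r in ds.records if r.ddg == 0)
    n_destab = sum(1 for r in ds.records if r.ddg < 0)
    return {
        "n_records": len(ds.records),
        "n_proteins": len(ds.protein_ids),
        "n_stabilizing": n_stab,
        "n_neutral": n_neut,
        "n_destabilizing": n_destab,
    }
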