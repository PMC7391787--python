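"""Protein FASTA input/output and labeled-dataset assembly.

Sequences are validated against the 20-letter amino-acid alphabet.  Labels
are +1 (antioxidant) / -1 (non-antioxidant) throughout the package, matching
the +/-1 vote convention of the stacked classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Cleaning policies for residues outside the standard alphabet.
POLICIES = ("strict", "drop_nonstandard")


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


class SequenceError(ValueError):
    """Raised for invalid amino-acid sequences."""


def clean_sequence(raw: str, policy: str = "drop_nonstandard") -> str:
    """Uppercase ``raw`` and resolve non-standard residues.

    ``strict`` raises on any character outside the 20-letter alphabet;
    ``drop_nonstandard`` removes such characters (B, J, O, U, X, Z, gaps,
    ``*`` ...) before any counting.  An empty result is always an error.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown cleaning policy {policy!r}; expected one of {POLICIES}")
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper()
    bad = [(i, c) for i, c in enumerate(seq) if c not in _AA_SET]
    if bad:
        if policy == "strict":
            i, c = bad[0]
            raise SequenceError(
                f"non-standard character {c!r} at position {i + 1} (strict policy)"
            )
        drop = {c for _, c in bad}
        seq = "".join(c for c in seq if c in _AA_SET)
        logger.warning("dropped %d non-standard residue(s) (%s)", len(bad), "".join(sorted(drop)))
    if not seq:
        raise SequenceError("sequence empty after removing non-standard residues")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One identifier plus a validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid residue(s) {''.join(sorted(bad))!r}; "
                "clean the sequence first"
            )

    @property
    def length(self) -> int:
        """Residue count L."""
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered protein records with parallel +/-1 class labels."""

    records: list[ProteinRecord]
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        bad = {l for l in self.labels if l not in (+1, -1)}
        if bad:
            raise ValueError(f"labels must be +1 or -1, got {sorted(bad)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=[self.labels[i] for i in indices],
        )

    def positives(self) -> "LabeledDataset":
        return self.subset([i for i, l in enumerate(self.labels) if l == +1])

    def negatives(self) -> "LabeledDataset":
        return self.subset([i for i, l in enumerate(self.labels) if l == -1])

    @staticmethod
    def concatenate(parts: Iterable["LabeledDataset"]) -> "LabeledDataset":
        records: list[ProteinRecord] = []
        labels: list[int] = []
        for part in parts:
            records.extend(part.records)
            labels.extend(part.labels)
        return LabeledDataset(records=records, labels=labels)


@dataclass
class DatasetSplit:
    """Stratified train/test partition of a labeled dataset."""

    train: LabeledDataset
    test: LabeledDataset
    fraction: float
    seed: int


def _iter_fasta(path: Path):
    """Parse FASTA with a line-level sanity pass before handing to SeqIO."""
    with open(path) as fh:
        lines = fh.readlines()
    nonblank = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(lines) if ln.strip()]
    if not nonblank:
        raise FastaError(f"{path}: empty FASTA file")
    first_line, first = nonblank[0]
    if not first.startswith(">"):
        raise FastaError(
            f"{path}: line {first_line}: expected FASTA header starting with '>', got {first[:30]!r}"
        )
    yield from SeqIO.parse(str(path), "fasta")


def read_fasta(
    path: str | Path,
    label: int,
    policy: str = "drop_nonstandard",
) -> LabeledDataset:
    """Read one FASTA file whose entries all carry ``label`` (+1 or -1).

    Headers are parsed up to the first whitespace as the record id; sequences
    are uppercased and cleaned per ``policy``.
    """
    if label not in (+1, -1):
        raise ValueError(f"label must be +1 or -1, got {label}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for entry in _iter_fasta(path):
        try:
            seq = clean_sequence(str(entry.seq), policy=policy)
        except SequenceError as exc:
            raise SequenceError(f"record {entry.id!r}: {exc}") from exc
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return LabeledDataset(records=records, labels=[label] * len(records))


def read_fasta_with_labels(
    fasta_path: str | Path,
    label_table: str | Path,
    policy: str = "drop_nonstandard",
) -> LabeledDataset:
    """Read a mixed FASTA plus a two-column TSV (id, label) label table."""
    table = pd.read_csv(label_table, sep="\t", header=None, names=["id", "label"], dtype={"id": str})
    label_map = dict(zip(table["id"], table["label"].astype(int)))
    records: list[ProteinRecord] = []
    labels: list[int] = []
    for entry in _iter_fasta(Path(fasta_path)):
        if entry.id not in label_map:
            raise ValueError(f"record {entry.id!r} missing from label table {label_table}")
        seq = clean_sequence(str(entry.seq), policy=policy)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
        labels.append(label_map[entry.id])
    if not records:
        raise FastaError(f"{fasta_path}: no FASTA records found")
    return LabeledDataset(records=records, labels=labels)


def write_fasta(data: LabeledDataset | Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped)."""
    records = data.records if isinstance(data, LabeledDataset) else list(data)
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def split_dataset(data: LabeledDataset, fraction: float = 0.8, seed: int = 42) -> DatasetSplit:
    """Stratified random train/test split; ``fraction`` goes to train.

    Per-class train proportion is within one record of ``fraction``; the two
    parts are disjoint and exhaustive; membership is reproducible from seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    labels = data.label_array
    for cls in (+1, -1):
        if int(np.sum(labels == cls)) < 2:
            raise ValueError(f"class {cls:+d} has fewer than 2 records; cannot stratify")
    indices = np.arange(len(data))
    train_idx, test_idx = train_test_split(
        indices,
        train_size=fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return DatasetSplit(
        train=data.subset(sorted(train_idx)),
        test=data.subset(sorted(test_idx)),
        fraction=fraction,
        seed=seed,
    )


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Persist split membership as TSV (id, subset, label)."""
    rows = [(r.id, "train", l) for r, l in zip(split.train.records, split.train.labels)]
    rows += [(r.id, "test", l) for r, l in zip(split.test.records, split.test.labels)]
    pd.DataFrame(rows, columns=["id", "subset", "label"]).to_csv(path, sep="\t", index=False)
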