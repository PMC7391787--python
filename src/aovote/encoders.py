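"""Sequence feature encodings.

Two feature families:

* **g-gap dipeptide composition** — for gap ``g``, the frequency of each
  ordered residue pair (a, b) occurring at positions (p, p+g+1), normalized
  by the number of counted pairs, L - g - 1.  The vector always has
  20 x 20 = 400 entries; ``g = 0`` is the ordinary adjacent dipeptide
  composition and larger ``g`` captures longer-range residue correlation.

* **reduced amino-acid composition (RAAC)** — the 20 amino acids are mapped
  onto a smaller alphabet of physicochemical clusters (profiles Op5, Op8,
  Op9, Op11, Op13 with 5/8/9/11/13 groups), and the overlapping n-peptide
  composition is computed over the reduced alphabet: k^n entries, each
  count / (L - n + 1).

Both produce frequency vectors that sum to one whenever the sequence admits
at least one counted k-mer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .io_fasta import AMINO_ACIDS, LabeledDataset, ProteinRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Ordered amino-acid pairs in lexicographic order (the fixed 400-feature order).
PAIR_ORDER = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)


@dataclass(frozen=True)
class GGapSpec:
    """Gap size for the g-gap dipeptide encoder.

    ``g`` is restricted to [0, 9] unless ``allow_extended`` is set, since
    larger gaps push the minimum usable sequence length above g + 2.
    """

    g: int
    allow_extended: bool = False

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError(f"gap must be non-negative, got {self.g}")
        if self.g > 9 and not self.allow_extended:
            raise ValueError(
                f"gap {self.g} outside [0, 9]; pass allow_extended=True to override"
            )

    @property
    def min_length(self) -> int:
        return self.g + 2

    def feature_names(self) -> list[str]:
        return [f"{p[0]}.{p[1]}|g={self.g}" for p in PAIR_ORDER]


@dataclass(frozen=True)
class ClusterProfile:
    """A partition of the 20 amino acids into k physicochemical groups.

    Each group is written as its residues in profile order; the group's first
    letter serves as its representative in reduced sequences (an arbitrary
    but stable internal labeling).  ``optimal_n`` is the peptide order the
    profile is used with by default.
    """

    name: str
    groups: tuple[str, ...]
    optimal_n: int

    def __post_init__(self) -> None:
        letters = "".join(self.groups)
        if sorted(letters) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"profile {self.name}: groups must partition the 20-letter alphabet, "
                f"got {letters!r}"
            )
        if any(not g for g in self.groups):
            raise ValueError(f"profile {self.name}: empty group")
        if self.optimal_n < 1:
            raise ValueError(f"profile {self.name}: optimal_n must be >= 1")

    @property
    def size(self) -> int:
        """Number of groups k (the reduced-alphabet size)."""
        return len(self.groups)

    @property
    def representatives(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.groups)

    @property
    def mapping(self) -> dict[str, str]:
        """Residue -> representative letter."""
        return {aa: g[0] for g in self.groups for aa in g}

    @property
    def index_mapping(self) -> np.ndarray:
        """Residue index (0..19, alphabetical) -> group index."""
        out = np.empty(20, dtype=np.int64)
        for gi, g in enumerate(self.groups):
            for aa in g:
                out[_AA_INDEX[aa]] = gi
        return out

    def dimension(self, n: int | None = None) -> int:
        return self.size ** (self.optimal_n if n is None else n)

    def feature_names(self, n: int | None = None) -> list[str]:
        n = self.optimal_n if n is None else n
        reps = self.representatives
        return [
            "".join(mer) + f"|{self.name}"
            for mer in itertools.product(reps, repeat=n)
        ]


def _profile(name: str, spec: str, optimal_n: int) -> ClusterProfile:
    return ClusterProfile(name=name, groups=tuple(spec.split(";")), optimal_n=optimal_n)


#: Built-in cluster profiles (5, 8, 9, 11 and 13 groups) with their default
#: peptide orders: tripeptides for Op5, dipeptides for the rest.
PROFILES: dict[str, ClusterProfile] = {
    "Op5": _profile("Op5", "G;IVFYW;ALMEQRK;P;NDHSTC", 3),
    "Op8": _profile("Op8", "G;IV;FYW;ALM;EQRK;P;ND;HSTC", 2),
    "Op9": _profile("Op9", "G;IV;FYW;ALM;EQRK;P;ND;HS;TC", 2),
    "Op11": _profile("Op11", "G;IV;FYW;A;LM;EQRK;P;ND;HS;T;C", 2),
    "Op13": _profile("Op13", "G;IV;FYW;A;L;M;E;QRK;P;ND;HS;T;C", 2),
}

#: An encoder specification: either a gap spec or a (profile, n) pair.
EncoderSpec = Union[GGapSpec, tuple[ClusterProfile, int]]


def load_profile(path: str | Path, name: str | None = None, optimal_n: int = 2) -> ClusterProfile:
    """Load a user-supplied profile file: one group of residue letters per line."""
    path = Path(path)
    groups = tuple(
        line.strip().upper() for line in path.read_text().splitlines() if line.strip()
    )
    return ClusterProfile(name=name or path.stem, groups=groups, optimal_n=optimal_n)


@dataclass
class FeatureVector:
    """Named feature values for one sequence; frequencies lie in [0, 1]."""

    names: list[str]
    values: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values length mismatch")


@dataclass
class FeatureMatrix:
    """Rows of named feature vectors aligned with ids and +/-1 labels."""

    ids: list[str]
    labels: np.ndarray
    X: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        n, d = self.X.shape
        if len(self.ids) != n or self.labels.shape[0] != n:
            raise ValueError("ids/labels/X row mismatch")
        if len(self.feature_names) != d:
            raise ValueError("feature_names/X column mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_features(self, names: Iterable[str]) -> "FeatureMatrix":
        names = list(names)
        index = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        cols = [index[f] for f in names]
        return FeatureMatrix(
            ids=list(self.ids),
            labels=self.labels.copy(),
            X=self.X[:, cols].copy(),
            feature_names=names,
        )

    def subset_rows(self, indices: Iterable[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            ids=[self.ids[i] for i in idx],
            labels=self.labels[idx].copy(),
            X=self.X[idx].copy(),
            feature_names=list(self.feature_names),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        df.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
        return FeatureMatrix(
            ids=df["id"].tolist(),
            labels=df["label"].to_numpy(dtype=int),
            X=df.drop(columns=["id", "label"]).to_numpy(dtype=float),
            feature_names=[c for c in df.columns if c not in ("id", "label")],
        )


def _seq_indices(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))


def ggap_composition(record: ProteinRecord, spec: GGapSpec) -> FeatureVector:
    """g-gap dipeptide composition: 400 pair frequencies, counts / (L - g - 1).

    Entry (a, b) counts positions p with sequence[p] = a and
    sequence[p + g + 1] = b.  Requires L > g + 1.
    """
    g = spec.g
    L = record.length
    if L <= g + 1:
        raise ValueError(
            f"record {record.id!r}: length {L} too short for gap g={g} "
            f"(needs L >= {g + 2})"
        )
    idx = _seq_indices(record.sequence)
    pair_codes = idx[: L - g - 1] * 20 + idx[g + 1 :]
    counts = np.bincount(pair_codes, minlength=400).astype(float)
    values = counts / (L - g - 1)
    return FeatureVector(names=spec.feature_names(), values=values, counts=counts)


def reduce_sequence(record: ProteinRecord | str, profile: ClusterProfile) -> str:
    """Map each residue to its group's representative letter (length preserved)."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    mapping = profile.mapping
    try:
        return "".join(mapping[c] for c in seq)
    except KeyError as exc:  # valid profiles cover the alphabet; guard anyway
        raise ValueError(f"residue {exc.args[0]!r} not covered by profile {profile.name}")


def raac_composition(
    record: ProteinRecord,
    profile: ClusterProfile,
    n: int | None = None,
) -> FeatureVector:
    """Reduced n-peptide composition: k^n overlapping n-mer frequencies.

    The sequence is first reduced to the profile's k-letter alphabet; each
    overlapping n-mer count is divided by L - n + 1.  Requires L >= n.
    """
    n = profile.optimal_n if n is None else n
    L = record.length
    if L < n:
        raise ValueError(
            f"record {record.id!r}: length {L} too short for n-peptides with n={n}"
        )
    k = profile.size
    group_idx = profile.index_mapping[_seq_indices(record.sequence)]
    codes = np.zeros(L - n + 1, dtype=np.int64)
    for j in range(n):
        codes = codes * k + group_idx[j : L - n + 1 + j]
    counts = np.bincount(codes, minlength=k**n).astype(float)
    values = counts / (L - n + 1)
    return FeatureVector(names=profile.feature_names(n), values=values, counts=counts)


def encoder_name(spec: EncoderSpec) -> str:
    if isinstance(spec, GGapSpec):
        return f"ggap_g{spec.g}"
    profile, n = spec
    return f"raac_{profile.name}_n{n}"


def encode_record(record: ProteinRecord, spec: EncoderSpec) -> FeatureVector:
    if isinstance(spec, GGapSpec):
        return ggap_composition(record, spec)
    profile, n = spec
    return raac_composition(record, profile, n)


def encode_dataset(data: LabeledDataset, spec: EncoderSpec) -> FeatureMatrix:
    """Encode every record with one encoder spec; row order is preserved.

    Records failing the encoder's length precondition are reported together
    in one error — nothing is silently dropped.
    """
    if isinstance(spec, GGapSpec):
        min_len = spec.min_length
        names = spec.feature_names()
    else:
        profile, n = spec
        min_len = n
        names = profile.feature_names(n)
    offenders = [r.id for r in data.records if r.length < min_len]
    if offenders:
        raise ValueError(
            f"encoder {encoder_name(spec)} requires length >= {min_len}; "
            f"offending records: {offenders}"
        )
    X = np.empty((len(data), len(names)), dtype=float)
    for i, record in enumerate(data.records):
        X[i] = encode_record(record, spec).values
    return FeatureMatrix(ids=data.ids, labels=data.label_array, X=X, feature_names=names)
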