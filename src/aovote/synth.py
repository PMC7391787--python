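"""Synthetic labeled protein datasets with a plantable class signal.

Negatives are i.i.d. residues drawn from a background frequency table
(uniform 1/20 by default, optionally natural abundances).  Positives share
that background but carry a first-order dependence in one chosen feature
channel:

* **g-gap channel** — a set of target ordered residue pairs (a, b); while
  generating a positive sequence left-to-right, whenever the residue at lag
  g+1 behind the current position is some target's ``a``, the emission
  probability of its ``b`` is multiplied by exp(effect) and the position's
  distribution renormalized.

* **RAAC channel** — a set of target reduced n-mers; whenever the previous
  n-1 reduced letters match a target's prefix, every 20-letter residue
  mapping into the target's final group receives the same multiplicative
  boost.

``effect = 0`` makes the boost factor exp(0) = 1, so both classes are drawn
from the identical process.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoders import ClusterProfile, EncoderSpec, GGapSpec, encoder_name
from .io_fasta import AMINO_ACIDS, LabeledDataset, ProteinRecord

#: Approximate natural amino-acid abundances (SwissProt-like), alphabetical.
NATURAL_FREQUENCIES = {
    "A": 0.0826, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0394, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings: class sizes, length range, signal channel/strength."""

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (30, 500)
    effect: float = 0.0
    signal_channel: EncoderSpec = GGapSpec(1)
    n_signal_features: int = 10
    seed: int = 0
    background: str = "uniform"  # "uniform" or "natural"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        if lo < 11:  # shortest length usable by every default encoder (g=9 needs L >= 11)
            raise ValueError(f"length_range lower bound must be >= 11, got {lo}")
        if self.effect < 0:
            raise ValueError(f"effect must be >= 0, got {self.effect}")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        if self.n_signal_features < 1:
            raise ValueError("n_signal_features must be >= 1")
        if self.background not in ("uniform", "natural"):
            raise ValueError(f"unknown background {self.background!r}")


def _background_probs(kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.full(20, 1.0 / 20)
    p = np.array([NATURAL_FREQUENCIES[a] for a in AMINO_ACIDS])
    return p / p.sum()


def _sample_from_cdf(cdf: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(cdf, rng.random(), side="right"))


def _plant_ggap_targets(rng: np.random.Generator, k: int) -> list[tuple[int, int]]:
    """Pick k distinct ordered residue-index pairs."""
    codes = rng.choice(400, size=k, replace=False)
    return [(int(c) // 20, int(c) % 20) for c in codes]


def _plant_raac_targets(rng: np.random.Generator, k: int, n_groups: int, n: int) -> list[tuple[int, ...]]:
    codes = rng.choice(n_groups**n, size=k, replace=False)
    out = []
    for c in codes:
        mer = []
        c = int(c)
        for _ in range(n):
            mer.append(c % n_groups)
            c //= n_groups
        out.append(tuple(reversed(mer)))
    return out


def _generate_negative(rng: np.random.Generator, length: int, bg_cdf: np.ndarray) -> str:
    idx = np.searchsorted(bg_cdf, rng.random(length), side="right")
    return "".join(AMINO_ACIDS[i] for i in idx)


def _generate_positive_ggap(
    rng: np.random.Generator,
    length: int,
    bg: np.ndarray,
    lag: int,
    boost: dict[int, list[int]],
    factor: float,
) -> str:
    # per-conditioning-letter emission CDFs, precomputed once per call set
    idx = np.empty(length, dtype=np.int64)
    bg_cdf = np.cumsum(bg)
    cond_cdfs: dict[int, np.ndarray] = {}
    for a, bs in boost.items():
        w = bg.copy()
        w[bs] *= factor
        cond_cdfs[a] = np.cumsum(w / w.sum())
    for p in range(length):
        if p < lag:
            idx[p] = _sample_from_cdf(bg_cdf, rng)
        else:
            cdf = cond_cdfs.get(int(idx[p - lag]), bg_cdf)
            idx[p] = _sample_from_cdf(cdf, rng)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _generate_positive_raac(
    rng: np.random.Generator,
    length: int,
    bg: np.ndarray,
    profile: ClusterProfile,
    n: int,
    targets: list[tuple[int, ...]],
    factor: float,
) -> str:
    group_of = profile.index_mapping  # residue index -> group index
    bg_cdf = np.cumsum(bg)
    # map reduced (n-1)-prefix -> boosted final groups
    prefix_boost: dict[tuple[int, ...], list[int]] = {}
    for t in targets:
        prefix_boost.setdefault(t[:-1], []).append(t[-1])
    cdf_cache: dict[tuple[int, ...], np.ndarray] = {}
    idx = np.empty(length, dtype=np.int64)
    for p in range(length):
        if p < n - 1:
            idx[p] = _sample_from_cdf(bg_cdf, rng)
            continue
        prefix = tuple(int(group_of[idx[q]]) for q in range(p - n + 1, p))
        if prefix not in prefix_boost:
            idx[p] = _sample_from_cdf(bg_cdf, rng)
            continue
        if prefix not in cdf_cache:
            w = bg.copy()
            for gi in prefix_boost[prefix]:
                w[group_of == gi] *= factor
            cdf_cache[prefix] = np.cumsum(w / w.sum())
        idx[p] = _sample_from_cdf(cdf_cache[prefix], rng)
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate(config: SyntheticConfig) -> tuple[LabeledDataset, dict]:
    """Generate a labeled dataset plus a manifest naming the planted features.

    Manifest keys: ``channel``, ``planted_features`` (names in the encoder's
    feature-name convention), ``effect``, ``seed``, and the class sizes.
    """
    rng = np.random.default_rng(config.seed)
    bg = _background_probs(config.background)
    bg_cdf = np.cumsum(bg)
    factor = float(np.exp(config.effect))
    lo, hi = config.length_range

    channel = config.signal_channel
    if isinstance(channel, GGapSpec):
        targets = _plant_ggap_targets(rng, config.n_signal_features)
        boost: dict[int, list[int]] = {}
        for a, b in targets:
            boost.setdefault(a, []).append(b)
        planted = [f"{AMINO_ACIDS[a]}.{AMINO_ACIDS[b]}|g={channel.g}" for a, b in targets]
    else:
        profile, n = channel
        targets_r = _plant_raac_targets(rng, config.n_signal_features, profile.size, n)
        reps = profile.representatives
        planted = ["".join(reps[g] for g in t) + f"|{profile.name}" for t in targets_r]

    records: list[ProteinRecord] = []
    labels: list[int] = []
    lengths_pos = rng.integers(lo, hi + 1, size=config.n_pos)
    lengths_neg = rng.integers(lo, hi + 1, size=config.n_neg)
    for i, L in enumerate(lengths_pos):
        if isinstance(channel, GGapSpec):
            seq = _generate_positive_ggap(rng, int(L), bg, channel.g + 1, boost, factor)
        else:
            profile, n = channel
            seq = _generate_positive_raac(rng, int(L), bg, profile, n, targets_r, factor)
        records.append(ProteinRecord(id=f"pos_{i:04d}", sequence=seq))
        labels.append(+1)
    for i, L in enumerate(lengths_neg):
        records.append(ProteinRecord(id=f"neg_{i:04d}", sequence=_generate_negative(rng, int(L), bg_cdf)))
        labels.append(-1)

    manifest = {
        "channel": encoder_name(channel),
        "planted_features": planted,
        "effect": config.effect,
        "boost_factor": factor,
        "seed": config.seed,
        "n_pos": config.n_pos,
        "n_neg": config.n_neg,
        "length_range": list(config.length_range),
        "background": config.background,
    }
    return LabeledDataset(records=records, labels=labels), manifest


def generate_complementary(
    n_pos: int,
    n_neg: int,
    channels: list[EncoderSpec],
    effect: float = 2.0,
    length_range: tuple[int, int] = (30, 500),
    n_signal_features: int = 10,
    seed: int = 0,
) -> tuple[LabeledDataset, dict]:
    """Positives split across several signal channels (complementary signal).

    Each positive subpopulation carries signal in a different feature family,
    so no single encoder sees all positives well — the regime in which vote
    stacking should beat any single base model.  Negatives are one shared
    background sample.
    """
    if not channels:
        raise ValueError("need at least one channel")
    per = [n_pos // len(channels)] * len(channels)
    for i in range(n_pos - sum(per)):
        per[i] += 1
    parts: list[LabeledDataset] = []
    manifests = []
    for ci, (channel, np_i) in enumerate(zip(channels, per)):
        cfg = SyntheticConfig(
            n_pos=np_i,
            n_neg=1,  # throwaway; negatives regenerated below
            length_range=length_range,
            effect=effect,
            signal_channel=channel,
            n_signal_features=n_signal_features,
            seed=seed * 1009 + ci,
        )
        ds, man = generate(cfg)
        pos = ds.positives()
        pos = LabeledDataset(
            records=[ProteinRecord(id=f"c{ci}_{r.id}", sequence=r.sequence) for r in pos.records],
            labels=list(pos.labels),
        )
        parts.append(pos)
        manifests.append(man)
    neg_cfg = SyntheticConfig(
        n_pos=1, n_neg=n_neg, length_range=length_range, effect=0.0,
        signal_channel=channels[0], n_signal_features=n_signal_features,
        seed=seed * 1009 + 999,
    )
    neg_ds, _ = generate(neg_cfg)
    parts.append(neg_ds.negatives())
    dataset = LabeledDataset.concatenate(parts)
    manifest = {
        "channels": [m["channel"] for m in manifests],
        "planted_features": {m["channel"]: m["planted_features"] for m in manifests},
        "effect": effect,
        "seed": seed,
        "n_pos": n_pos,
        "n_neg": n_neg,
    }
    return dataset, manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
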