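import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aovote as av

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Write a small FASTA file and return its path."""

    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))
        return path

    return _write


def random_dataset(rng, n_pos=10, n_neg=10, length=(15, 40), prefix=""):
    """Unstructured random dataset over the 20-letter alphabet."""
    records, labels = [], []
    for i in range(n_pos + n_neg):
        L = int(rng.integers(length[0], length[1] + 1))
        seq = "".join(rng.choice(list(av.AMINO_ACIDS), size=L))
        records.append(av.ProteinRecord(id=f"{prefix}s{i:03d}", sequence=seq))
        labels.append(+1 if i < n_pos else -1)
    return av.LabeledDataset(records=records, labels=labels)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


def blob_matrix(rng, n_per_class=10, d=2, sep=6.0):
    """Two well-separated Gaussian blobs as a FeatureMatrix."""
    pos = rng.normal(loc=+sep / 2, scale=0.5, size=(n_per_class, d))
    neg = rng.normal(loc=-sep / 2, scale=0.5, size=(n_per_class, d))
    X = np.vstack([pos, neg])
    labels = np.array([+1] * n_per_class + [-1] * n_per_class)
    return av.FeatureMatrix(
        ids=[f"b{i}" for i in range(2 * n_per_class)],
        labels=labels,
        X=X,
        feature_names=[f"f{j}" for j in range(d)],
    )


@pytest.fixture
def fast_config():
    """Scaled-down run configuration for pipeline tests."""
    return av.RunConfig(
        seed=7,
        c_grid=(0.5, 2.0, 8.0, 32.0, 128.0),
        gamma_grid=tuple(2.0**e for e in range(-7, 3, 2)),
        ifs_max_k=25,
    )
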