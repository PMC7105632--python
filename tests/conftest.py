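import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phagehydro as ph

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_record_fasta(tmp_path):
    p = tmp_path / "two.fasta"
    p.write_text(">p1\nACDE\n>p2\nKKRR\n")
    return p


@pytest.fixture
def small_dataset():
    """Six labelled sequences long enough for every encoder at defaults."""
    rng = np.random.default_rng(7)
    alphabet = list(ph.ALPHABET)
    records = []
    for i in range(6):
        seq = "".join(rng.choice(alphabet, size=40))
        records.append(ph.ProteinRecord(f"s{i}", seq, label=i % 2))
    return ph.Dataset(records)


@pytest.fixture
def random_labelled_matrix():
    """20 samples x 50 features of Gaussian noise with balanced labels."""
    rng = np.random.default_rng(11)
    values = rng.normal(size=(20, 50))
    labels = np.array([0, 1] * 10)
    ids = [f"r{i}" for i in range(20)]
    names = [f"ggdc|f{i:02d}" for i in range(50)]
    return ph.FeatureMatrix(ids, names, values, labels)


@pytest.fixture
def separable_matrix():
    """Two well-separated Gaussian blobs (n=40, d=5)."""
    rng = np.random.default_rng(3)
    pos = rng.normal(loc=4.0, scale=0.5, size=(20, 5))
    neg = rng.normal(loc=-4.0, scale=0.5, size=(20, 5))
    values = np.vstack([pos, neg])
    labels = np.array([1] * 20 + [0] * 20)
    ids = [f"b{i}" for i in range(40)]
    names = [f"ggdc|x{i}" for i in range(5)]
    return ph.FeatureMatrix(ids, names, values, labels)
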