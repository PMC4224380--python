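import numpy as np
import pytest

from nucpos import DnaSequence, EntropyParams, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def params():
    return EntropyParams(q=2.0, standard_length=147)


@pytest.fixture
def random_dna(rng):
    """Factory for random DNA strings (optionally with N)."""

    def make(length, n_frac=0.0):
        bases = np.array(list("ACGT"))
        s = rng.choice(bases, size=length)
        if n_frac > 0:
            mask = rng.random(length) < n_frac
            s[mask] = "N"
        return "".join(s)

    return make


@pytest.fixture
def spec7():
    return SyntheticSpec(seed=7)


@pytest.fixture
def bench_dataset(spec7):
    """Featurized 200+200 synthetic nucleosome-like vs linker-like dataset."""
    from nucpos import LabeledDataset, feature_matrix, gen_linker_like, gen_nucleosomal_like

    nuc = gen_nucleosomal_like(spec7)
    link = gen_linker_like(spec7)
    X = np.vstack([feature_matrix(nuc), feature_matrix(link)])
    y = np.array([1] * len(nuc) + [-1] * len(link))
    return LabeledDataset(X, y, [d.id for d in nuc + link])
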