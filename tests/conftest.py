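import numpy as np
import pytest
from hypothesis import settings

from tnfpred import LabeledDataset, ProteinSequence, SynthConfig, generate_dataset

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset() -> LabeledDataset:
    """The generator at its default study conditions: 18 vs 133, lengths 100-600."""
    return generate_dataset(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """A reduced dataset for fast pipeline mechanics tests (not for effect-size claims)."""
    return generate_dataset(SynthConfig(n_pos=8, n_neg=24, length_range=(60, 120), seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_sequence(seq_id: str, residues: str, label: int | None = None) -> ProteinSequence:
    return ProteinSequence(seq_id, residues, label)
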