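import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def separable_dataset():
    """A small clearly-separable synthetic dataset (matrix pairs + labels)."""
    from dvmppi import SynthConfig, evolution_matrices, pair_stack, synth_pair_dataset

    cfg = SynthConfig(n_proteins=20, n_pos=60, n_neg=60, separation=12.0, seed=7)
    proteins, pairs = synth_pair_dataset(cfg)
    X, y = pair_stack(evolution_matrices(proteins), pairs)
    return proteins, pairs, X, y


def random_score_matrix(rng, length=None, protein_id="p"):
    from dvmppi import AMINO_ACIDS, ScoreMatrix

    length = length or int(rng.integers(50, 120))
    scores = rng.integers(-10, 13, size=(length, 20))
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ScoreMatrix(protein_id=protein_id, scores=scores, residues=residues)
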