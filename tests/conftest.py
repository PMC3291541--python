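import numpy as np
import pytest

from pepself.recognition import (
    RecognitionModel,
    SimilarityRule,
    build_similarity_rule,
)
from pepself.synthetic import make_similarity_matrix, random_peptides


@pytest.fixture(scope="session")
def pmbec_like_rule() -> SimilarityRule:
    """A conservative-substitution rule in the PMBEC regime
    (mean similar-set size ~1.6)."""
    matrix = make_similarity_matrix(1.6, seed=11)
    return build_similarity_rule(matrix, "abs_covariance_gt", 0.05)


@pytest.fixture(scope="session")
def degenerate_model(pmbec_like_rule) -> RecognitionModel:
    return RecognitionModel.degenerate(pmbec_like_rule)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_random_rule(seed: int, p_edge: float = 0.1, alphabet: str | None = None
                     ) -> SimilarityRule:
    """A random symmetric similarity rule (optionally on a sub-alphabet)."""
    from pepself.peptidome import AMINO_ACIDS

    letters = alphabet or AMINO_ACIDS
    rng = np.random.default_rng(seed)
    similar: dict[str, set[str]] = {aa: set() for aa in AMINO_ACIDS}
    for i, a in enumerate(letters):
        for b in letters[i + 1:]:
            if rng.random() < p_edge:
                similar[a].add(b)
                similar[b].add(a)
    return SimilarityRule(
        similar={a: frozenset(s) for a, s in similar.items()},
        provenance=f"random:{seed}",
    )


@pytest.fixture
def random_9mers():
    return random_peptides(200, seed=7)
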