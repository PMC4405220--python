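import numpy as np
import pytest

from holoperm.corpus import (
    SyntheticCorpusSpec,
    generate_synthetic_corpus,
    generate_synthetic_eval_sets,
)
from holoperm.evaluate import read_similarity_tsv, read_synonymy_tsv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_fixture(tmp_path_factory):
    """A seeded planted-synonym corpus with matching evaluation files."""
    root = tmp_path_factory.mktemp("synth")
    spec = SyntheticCorpusSpec(master_seed=3)
    corpus, truth = generate_synthetic_corpus(
        spec, root / "corpus.txt", root / "truth.json"
    )
    synonymy, similarity = generate_synthetic_eval_sets(
        truth, 5, root / "synonymy.tsv", root / "similarity.tsv"
    )
    return {
        "spec": spec,
        "corpus": corpus,
        "truth": truth,
        "synonymy": read_synonymy_tsv(synonymy),
        "similarity": read_similarity_tsv(similarity),
        "synonymy_path": synonymy,
        "similarity_path": similarity,
    }
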