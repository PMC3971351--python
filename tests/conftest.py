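import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pathprints.genesets import GeneSet, GeneSetCollection
from pathprints.pipeline import fingerprint_corpus
from pathprints.synthetic import CorpusDesign, make_corpus

CORPUS_SEED = 7


@pytest.fixture(scope="session")
def corpus():
    """The default synthetic study corpus: 2 platforms, 2 species, 4 classes."""
    return make_corpus(CorpusDesign(seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def corpus_prints(corpus):
    """Fingerprints of every class sample on the shared pathways, plus labels."""
    prints = fingerprint_corpus(corpus)
    labels = corpus.labels.reindex(prints.columns)
    return prints, labels


@pytest.fixture(scope="session")
def small_corpus():
    """A single-platform, single-species corpus for fast unit-level pipeline tests."""
    design = CorpusDesign(
        n_platforms=1,
        genes_per_platform=600,
        platform_gene_overlap=1.0,
        n_pathways=20,
        pathway_size=(8, 12),
        n_classes=2,
        n_informative=12,
        n_samples=6,
        n_background=60,
        species=("human",),
        seed=11,
    )
    return make_corpus(design)


@pytest.fixture
def toy_collection():
    sets = [
        GeneSet("WNT", "KEGG", frozenset({"g1", "g2", "g3"})),
        GeneSet("P53", "Reactome", frozenset({"g2", "g4", "g5", "g6"})),
        GeneSet("EMT", "custom", frozenset({"g7", "g8"})),
    ]
    return GeneSetCollection(sets=sets, species="human")


def random_ternary_prints(rng, n_pathways, n_samples, prefix="s"):
    return pd.DataFrame(
        rng.choice([-1, 0, 1], size=(n_pathways, n_samples)),
        index=[f"PW{i:03d}" for i in range(n_pathways)],
        columns=[f"{prefix}{i}" for i in range(n_samples)],
    )
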