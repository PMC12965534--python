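"""Shared fixtures: a handcrafted micro-corpus plus one simulated corpus with
a classifier trained on it (session-scoped; several modules reuse it)."""

from types import SimpleNamespace

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from rankshift import (
    GeneVocabulary,
    RankEncoder,
    SimulationSpec,
    StateTransformerClassifier,
    ExpressionCorpus,
    simulate_corpus,
)


@pytest.fixture
def tiny_corpus() -> ExpressionCorpus:
    """3 cells x 4 genes, hand-checkable."""
    return ExpressionCorpus(
        gene_ids=np.array(["GA", "GB", "GC", "GD"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        counts=np.array([[5, 3, 0, 2], [0, 1, 0, 0], [4, 0, 0, 6]]),
        condition=np.array(["control", "disease", "control"], dtype=object),
    )


@pytest.fixture
def abc_vocabulary() -> GeneVocabulary:
    """Genes A/B/C/D with fixed normalization factors; tokens A=2..D=5."""
    return GeneVocabulary(["A", "B", "C", "D"], np.array([1.0, 0.25, 0.5, 1.0]))


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    return SimulationSpec(
        n_cells_control=300,
        n_cells_disease=300,
        n_genes=50,
        n_driver_genes=8,
        driver_log2fc=3.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return simulate_corpus(small_spec)


@pytest.fixture(scope="session")
def small_setup(small_corpus):
    """Encoder + fine-tuned classifier on a held-out split of the small corpus."""
    idx = np.arange(small_corpus.n_cells)
    train_idx, test_idx = train_test_split(
        idx, test_size=0.25, random_state=0, stratify=small_corpus.condition
    )
    train = small_corpus.subset_cells(np.sort(train_idx))
    test = small_corpus.subset_cells(np.sort(test_idx))
    encoder = RankEncoder(context_length=48).fit(train)
    enc_train = encoder.transform(train)
    enc_test = encoder.transform(test)
    assert not encoder.dropped_cells_
    model = StateTransformerClassifier(
        vocab_size=encoder.vocabulary_.size,
        context_length=48,
        epochs=6,
        batch_size=32,
        seed=1,
    )
    model.fit(enc_train, train.condition)
    return SimpleNamespace(
        corpus=small_corpus,
        train=train,
        test=test,
        encoder=encoder,
        vocabulary=encoder.vocabulary_,
        enc_train=enc_train,
        enc_test=enc_test,
        model=model,
    )
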