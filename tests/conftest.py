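import pytest

import simtransfer as st


@pytest.fixture(scope="session")
def panel20():
    """The embedded 20-drug panel."""
    return st.fixture_panel()


@pytest.fixture(scope="session")
def fast_config():
    """Classifier settings small enough for per-test training runs."""
    return st.TrainConfig(max_epochs=8, patience=2, n_features=2**13, seed=0)


@pytest.fixture(scope="session")
def coupled_world(fast_config):
    """A small fully coupled synthetic world: drugs, similarity matrix, corpus.

    8 drugs in 4 classes, 150 docs each, coupling 1.0 — same-class drugs have
    identical text distributions, so structural similarity is maximally
    informative about transfer.
    """
    config = st.GeneratorConfig(
        n_drugs=8, n_classes=4, docs_per_drug=150, coupling=1.0, seed=11
    )
    drugs = st.generate_drug_set(config)
    corpus = st.generate_corpus(drugs, config)
    simmat = st.similarity_matrix_from_drugs(drugs)
    return drugs, simmat, corpus


def make_labeled_corpus(counts: dict[str, int], drug: str = "drugA") -> st.Corpus:
    """A deterministic corpus with the given per-label document counts."""
    docs = []
    k = 0
    for label, n in counts.items():
        for _ in range(n):
            docs.append(
                st.Document(
                    doc_id=f"{drug}-{k:04d}",
                    drug_query=drug,
                    text=f"tok{k % 7} {label.replace('/', '_')}_word w{k % 3}",
                    label=label,
                )
            )
            k += 1
    return st.Corpus(tuple(docs))
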