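"""Shared fixtures: small hand-built objects plus the planted-corpus
pipeline (session-scoped because the UMAP fit dominates runtime)."""

import numpy as np
import pytest

from qtykit import ProteinRecord, TMSegment, Topology, apply_qty
from qtykit.synth import (
    SynthSpec,
    make_function_corpus,
    make_helix_bundle_model,
    make_membrane_protein,
    perturb_structure,
)
from qtykit.textspace import (
    FunctionCorpus,
    build_vocabulary,
    embed_umap,
    tfidf_encode,
)


@pytest.fixture
def simple_record():
    return ProteinRecord("P1", "MKKLLVVIFFAGRKQ")


@pytest.fixture
def simple_topology():
    return Topology("P1", (TMSegment(4, 10),))


@pytest.fixture(scope="session")
def synth_protein():
    """One deterministic synthetic membrane protein + topology."""
    return make_membrane_protein(SynthSpec(), seed=3)


@pytest.fixture(scope="session")
def bundle_pair(synth_protein):
    """Native bundle model and a loop-only perturbed copy."""
    record, topo = synth_protein
    native = make_helix_bundle_model(record, topo)
    perturbed = perturb_structure(
        native, sigma=1.0, region="loops", seed=11, topo=topo
    )
    return record, topo, native, perturbed


@pytest.fixture(scope="session")
def planted_corpus():
    """4-class keyword corpus with planted cancer labels (n=200, seed=1)."""
    annotations, truth = make_function_corpus(n_per_class=50, seed=1)
    return annotations, truth


@pytest.fixture(scope="session")
def planted_embedding(planted_corpus):
    """TF-IDF + UMAP embedding of the planted corpus (paper defaults)."""
    annotations, truth = planted_corpus
    corpus = FunctionCorpus.from_annotations(annotations)
    with pytest.warns(UserWarning):  # fewer distinct terms than requested
        vocabulary = build_vocabulary(corpus, 50)
    matrix = tfidf_encode(corpus, vocabulary)
    return embed_umap(matrix, random_state=1)


def random_protein(rng: np.random.Generator, min_len=30, max_len=120):
    """A random sequence with a random valid topology (for properties)."""
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    segments = []
    pos = 1
    while pos + 6 <= n and len(segments) < 5:
        start = pos + int(rng.integers(0, 5))
        end = min(n, start + int(rng.integers(3, 15)))
        if start > n or start > end:
            break
        segments.append(TMSegment(start, end))
        pos = end + 2
    record = ProteinRecord("R", seq)
    topo = Topology("R", tuple(segments))
    return record, topo
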