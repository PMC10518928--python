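"""Function-description encoding, 3D embedding, and association scoring.

Free-text functional descriptions are cleaned (lowercased, PubMed-ID
references and punctuation removed, stopwords dropped), encoded as a
TF-IDF matrix over the top-``max_features`` corpus terms, embedded in 3D
with UMAP, and mined for protein-cancer associations by k-nearest-
neighbor label voting: the association score of protein p with cancer c
is the fraction of p's k nearest embedding neighbors annotated with c.
A high score for a protein not itself carrying the label flags a
candidate novel association.

TF-IDF uses the smoothed-idf + L2 convention of scikit-learn's
TfidfTransformer: weight(d,t) = tf * (ln((1+N)/(1+df)) + 1), rows
L2-normalized. UMAP defaults: n_neighbors=10, n_components=3,
min_dist=0.5, metric='correlation', random_state=16.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .records import AnnotationRecord

#: The max_features grid exposed for vocabulary cut-offs.
MAX_FEATURES_GRID = (50, 100, 150, 200, 250)

UMAP_DEFAULTS = dict(
    n_neighbors=10, n_components=3, min_dist=0.5, metric="correlation",
    random_state=16,
)


def _load_stopwords() -> frozenset[str]:
    text = (
        resources.files("qtykit.data").joinpath("stopwords.txt").read_text()
    )
    return frozenset(w for w in text.split() if w)


STOPWORDS: frozenset[str] = _load_stopwords()

# Parenthesized reference blocks mentioning PubMed, then any remaining
# bare "PubMed ... 1234567" tokens (6-9 digit ids).
_PAREN_PUBMED = re.compile(r"\([^()]*pubmed[^()]*\)", re.IGNORECASE)
_PUBMED_ID = re.compile(r"pubmed[:\s]*\d{6,9}", re.IGNORECASE)
_PUNCT = re.compile(r"[^\w\s]|_")


def clean_text(raw: str, stopwords: frozenset[str] = STOPWORDS) -> list[str]:
    """Clean one description into a token list.

    Lowercase; strip parenthesized PubMed reference blocks and bare
    PubMed-ID patterns; replace punctuation with whitespace; split;
    drop stopwords. Idempotent: cleaning a cleaned, re-joined stream
    changes nothing.
    """
    text = raw.lower()
    text = _PAREN_PUBMED.sub(" ", text)
    text = _PUBMED_ID.sub(" ", text)
    text = _PUNCT.sub(" ", text)
    return [t for t in text.split() if t not in stopwords]


@dataclass(frozen=True)
class FunctionCorpus:
    """Parallel protein ids and cleaned token streams."""

    protein_ids: tuple[str, ...]
    cleaned_texts: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.protein_ids) != len(self.cleaned_texts):
            raise ValueError("ids and texts must be parallel")

    def __len__(self) -> int:
        return len(self.protein_ids)

    @classmethod
    def from_annotations(
        cls, annotations: list[AnnotationRecord]
    ) -> "FunctionCorpus":
        return cls(
            protein_ids=tuple(a.protein_id for a in annotations),
            cleaned_texts=tuple(
                tuple(clean_text(a.function_text)) for a in annotations
            ),
        )


def build_vocabulary(
    corpus: FunctionCorpus, max_features: int
) -> list[str]:
    """Top-``max_features`` terms by total corpus count.

    Ties break alphabetically; deterministic. When the corpus has fewer
    distinct terms than requested, all of them are returned with a
    warning.
    """
    import warnings
    from collections import Counter

    counts: Counter[str] = Counter()
    for tokens in corpus.cleaned_texts:
        counts.update(tokens)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < max_features:
        warnings.warn(
            f"corpus has only {len(ranked)} distinct terms "
            f"(max_features={max_features})",
            stacklevel=2,
        )
    return [term for term, _ in ranked[:max_features]]


def tfidf_encode(
    corpus: FunctionCorpus, vocabulary: list[str]
) -> np.ndarray:
    """Encode the corpus as an N x len(vocabulary) TF-IDF matrix.

    Raw term counts are weighted by TfidfTransformer (smooth_idf, L2
    norm), so every non-empty row has unit L2 norm and a term present in
    all documents has idf factor exactly 1.
    """
    from sklearn.feature_extraction.text import TfidfTransformer

    if not vocabulary:
        raise ValueError("empty vocabulary")
    index = {t: j for j, t in enumerate(vocabulary)}
    counts = np.zeros((len(corpus), len(vocabulary)))
    for i, tokens in enumerate(corpus.cleaned_texts):
        for tok in tokens:
            j = index.get(tok)
            if j is not None:
                counts[i, j] += 1.0
    transformer = TfidfTransformer(norm="l2", smooth_idf=True,
                                   sublinear_tf=False)
    return np.asarray(transformer.fit_transform(counts).todense())


@dataclass(frozen=True)
class Embedding:
    """An N x 3 embedding and the seed that produced it."""

    coordinates: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")


def embed_umap(matrix: np.ndarray, **params) -> Embedding:
    """Embed TF-IDF rows in 3D with UMAP.

    Parameters default to n_neighbors=10, n_components=3, min_dist=0.5,
    metric='correlation', random_state=16; any can be overridden. Output
    is deterministic for a fixed random_state and input.
    """
    import warnings

    import umap

    opts = {**UMAP_DEFAULTS, **params}
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < opts["n_neighbors"] + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {opts['n_neighbors'] + 1} rows, "
            f"got {matrix.shape[0]}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # numba/umap housekeeping warnings
        reducer = umap.UMAP(**opts)
        coords = reducer.fit_transform(matrix)
    return Embedding(
        coordinates=np.asarray(coords, dtype=float),
        seed=int(opts["random_state"]),
        params=opts,
    )


@dataclass(frozen=True)
class AssociationScore:
    protein_id: str
    cancer: str
    score: float
    is_novel: bool


def knn_associations(
    embedding: Embedding | np.ndarray,
    annotations: list[AnnotationRecord],
    k: int = 10,
    threshold: float = 0.6,
) -> list[AssociationScore]:
    """Score protein-cancer associations by k-NN label voting.

    For each protein p and each cancer c in the closed vocabulary
    observed in ``annotations``: score = fraction of the k nearest
    Euclidean neighbors of p (self excluded, distance ties broken by
    index order) labeled c. ``is_novel`` is true when p lacks the label
    and score >= threshold. Output sorted by score descending, then by
    (protein_id, cancer) for determinism.
    """
    coords = (
        embedding.coordinates
        if isinstance(embedding, Embedding)
        else np.asarray(embedding, dtype=float)
    )
    n = coords.shape[0]
    if n != len(annotations):
        raise ValueError("embedding rows and annotations must be parallel")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of rows {n}")
    from scipy.spatial.distance import cdist

    dists = cdist(coords, coords)
    np.fill_diagonal(dists, np.inf)
    # stable argsort: equal distances keep index order
    neighbor_idx = np.argsort(dists, axis=1, kind="stable")[:, :k]

    cancers = sorted({c for a in annotations for c in a.cancers})
    labels = {
        c: np.array([c in a.cancers for a in annotations]) for c in cancers
    }
    out: list[AssociationScore] = []
    for i, ann in enumerate(annotations):
        for c in cancers:
            score = float(labels[c][neighbor_idx[i]].mean())
            already = c in ann.cancers
            out.append(
                AssociationScore(
                    protein_id=ann.protein_id,
                    cancer=c,
                    score=score,
                    is_novel=(not already) and score >= threshold,
                )
            )
    out.sort(key=lambda s: (-s.score, s.protein_id, s.cancer))
    return out


def select_view(
    annotations: list[AnnotationRecord],
    categories: set[str] | None = None,
    cancers: set[str] | None = None,
) -> list[int]:
    """Indices of proteins matching the category AND cancer filters.

    A protein matches when its category is in ``categories`` and its
    cancer set intersects ``cancers``; an empty/None filter means "all".
    Unknown filter labels are errors.
    """
    from .io import CANCER_TYPES, CATEGORIES

    if categories:
        unknown = set(categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
    if cancers:
        unknown = set(cancers) - set(CANCER_TYPES)
        if unknown:
            raise ValueError(f"unknown cancer labels {sorted(unknown)}")
    out = []
    for i, ann in enumerate(annotations):
        if categories and ann.category not in categories:
            continue
        if cancers and not (ann.cancers & set(cancers)):
            continue
        out.append(i)
    return out
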