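"""Latent semantic space construction.

A lemmatized corpus is counted into a sparse term-document matrix,
reweighted with the log-entropy scheme, and factored with a truncated
singular value decomposition.  Term vectors are the rows of ``U @ S`` --
left singular vectors scaled by their singular values -- so dot products
between term vectors approximate the term-term association structure of
the weighted matrix.  New documents are represented by *fold-in*: the
(optionally entropy-weighted) sum of their terms' vectors.

Notation: the space has ``k`` retained dimensions; local weight is
``log(1 + f_td)`` and the global weight of a term is one minus its
normalized entropy over documents, so terms spread evenly across the
corpus are driven toward zero and terms concentrated in few documents
toward one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

__all__ = [
    "Corpus",
    "TermDocMatrix",
    "SemanticSpace",
    "OOVReport",
    "build_term_doc_matrix",
    "log_entropy_weight",
    "train_space",
    "fold_in",
    "cosine",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Corpus:
    """An ordered collection of pre-lemmatized, pre-tokenized documents."""

    documents: list[list[str]]
    doc_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.doc_ids):
            raise ValueError("documents and doc_ids must have equal length")
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise ValueError("doc_ids must be unique")

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def empty_doc_ids(self) -> list[str]:
        """Identifiers of documents with no tokens."""
        return [i for i, d in zip(self.doc_ids, self.documents) if not d]

    @classmethod
    def from_lines(cls, path: str | Path, prefix: str = "doc") -> "Corpus":
        """One document per line; tokens are whitespace-separated lemmas."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        docs = [ln.lower().split() for ln in lines]
        ids = [f"{prefix}{i:06d}" for i in range(len(docs))]
        return cls(docs, ids)

    @classmethod
    def from_dir(cls, path: str | Path) -> "Corpus":
        """One document per ``.txt`` file; file stem becomes the doc id."""
        files = sorted(Path(path).glob("*.txt"))
        docs = [f.read_text(encoding="utf-8").lower().split() for f in files]
        return cls(docs, [f.stem for f in files])

    def to_lines(self, path: str | Path) -> None:
        Path(path).write_text(
            "\n".join(" ".join(d) for d in self.documents) + "\n", encoding="utf-8"
        )


@dataclass
class TermDocMatrix:
    """Sparse term x document count matrix with its vocabulary."""

    counts: sp.csr_matrix
    vocabulary: list[str]
    doc_ids: list[str]
    dropped_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.vocabulary), len(self.doc_ids)):
            raise ValueError("counts shape inconsistent with vocabulary/doc_ids")
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SemanticSpace:
    """A trained latent semantic space (term vectors = rows of U @ S)."""

    term_vectors: np.ndarray          # (n_terms, k)
    singular_values: np.ndarray       # (k,), non-increasing, > 0
    vocabulary: list[str]
    global_weights: np.ndarray        # (n_terms,), entropy weights in [0, 1]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.term_vectors.shape[0] != len(self.vocabulary):
            raise ValueError("term_vectors rows must match vocabulary size")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")
        if np.any(self.singular_values <= 0):
            raise ValueError("singular values must be positive")
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.vocabulary)}

    @property
    def k(self) -> int:
        return self.term_vectors.shape[1]

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def term_vector(self, term: str) -> np.ndarray:
        return self.term_vectors[self._index[term]]

    def term_weight(self, term: str) -> float:
        return float(self.global_weights[self._index[term]])

    # -- persistence: vocabulary text + delimited matrix + JSON sidecar ----

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "vocabulary.txt").write_text(
            "\n".join(self.vocabulary) + "\n", encoding="utf-8"
        )
        np.savetxt(d / "term_vectors.tsv", self.term_vectors,
                   fmt="%.17g", delimiter="\t")
        meta = {
            "k": self.k,
            "singular_values": [float(s) for s in self.singular_values],
            "global_weights": [float(w) for w in self.global_weights],
            "weighting": "log-entropy",
        }
        (d / "space.json").write_text(
            json.dumps(meta, sort_keys=True, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "SemanticSpace":
        d = Path(directory)
        vocab = (d / "vocabulary.txt").read_text(encoding="utf-8").splitlines()
        tv = np.loadtxt(d / "term_vectors.tsv", delimiter="\t", ndmin=2)
        meta = json.loads((d / "space.json").read_text(encoding="utf-8"))
        return cls(tv, np.asarray(meta["singular_values"], dtype=float),
                   vocab, np.asarray(meta["global_weights"], dtype=float))


@dataclass
class OOVReport:
    """Out-of-vocabulary accounting for one folded-in document."""

    n_tokens: int
    n_oov: int
    oov_terms: list[str]

    @property
    def oov_rate(self) -> float:
        return self.n_oov / self.n_tokens if self.n_tokens else 0.0


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def build_term_doc_matrix(corpus: Corpus, min_doc_freq: int = 2) -> TermDocMatrix:
    """Count terms into a sparse term x document matrix.

    Terms occurring in fewer than ``min_doc_freq`` documents are dropped
    and listed in ``dropped_terms``.  Raises if the corpus has no tokens
    at all, or if filtering removes every term.
    """
    if not corpus.documents or all(not d for d in corpus.documents):
        raise ValueError("empty corpus")
    vocab_all = sorted({t for doc in corpus.documents for t in doc})
    index = {t: i for i, t in enumerate(vocab_all)}
    rows, cols, vals = [], [], []
    doc_freq = np.zeros(len(vocab_all), dtype=np.int64)
    for j, doc in enumerate(corpus.documents):
        seen: dict[int, int] = {}
        for tok in doc:
            seen[index[tok]] = seen.get(index[tok], 0) + 1
        for i, c in seen.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
            doc_freq[i] += 1
    keep = doc_freq >= min_doc_freq
    dropped = [t for t, k in zip(vocab_all, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"no term reaches min_doc_freq={min_doc_freq}; vocabulary empty"
        )
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(vocab_all), len(corpus.documents)),
        dtype=np.float64,
    )[keep]
    vocab = [t for t, k in zip(vocab_all, keep) if k]
    return TermDocMatrix(counts, vocab, list(corpus.doc_ids), dropped)


def log_entropy_weight(tdm: TermDocMatrix) -> tuple[sp.csr_matrix, np.ndarray]:
    """Apply log-entropy weighting.

    Entry ``(t, d)`` becomes ``log(1 + f_td) * g_t`` with global weight
    ``g_t = 1 + sum_d p_td log(p_td) / log(n_docs)`` and
    ``p_td = f_td / sum_d f_td``.  ``g_t`` lies in [0, 1]: 1 for a term
    confined to a single document, 0 for a term spread uniformly.
    """
    n_docs = len(tdm.doc_ids)
    if n_docs < 2:
        raise ValueError("log-entropy requires at least 2 documents "
                         "(entropy denominator log(1) = 0)")
    counts = tdm.counts.tocsr()
    row_tot = np.asarray(counts.sum(axis=1)).ravel()
    if (row_tot == 0).any():
        raise ValueError("all-zero term row in counts")
    # entropy over the nonzero entries of each row (p log p -> 0 at p = 0)
    p = (sp.diags(1.0 / row_tot) @ counts).tocsr()
    plogp = p.copy()
    plogp.data = p.data * np.log(p.data)
    entropy = -np.asarray(plogp.sum(axis=1)).ravel()
    global_w = 1.0 - entropy / np.log(n_docs)
    global_w = np.clip(global_w, 0.0, 1.0)
    local = counts.copy()
    local.data = np.log1p(local.data)
    weighted = (sp.diags(global_w) @ local).tocsr()
    return weighted, global_w


def train_space(
    weighted: sp.spmatrix,
    k: int,
    *,
    vocabulary: list[str],
    global_weights: np.ndarray,
    seed: int | None = 0,
) -> SemanticSpace:
    """Truncated SVD of the weighted matrix; keep ``U_k @ S_k`` as term vectors.

    Singular vectors have a deterministic sign convention (the largest-
    magnitude coordinate of each left singular vector is positive), so a
    given matrix and ``k`` always yield bit-identical spaces.
    """
    n_terms, n_docs = weighted.shape
    if k > min(n_terms, n_docs):
        raise ValueError(f"k={k} exceeds min(n_terms, n_docs)="
                         f"{min(n_terms, n_docs)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= min(n_terms, n_docs) - 1:
        # svds requires k < min(shape); fall back to a dense SVD
        u, s, _ = np.linalg.svd(np.asarray(weighted.todense()),
                                full_matrices=False)
        u, s = u[:, :k], s[:k]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(n_terms, n_docs))
        u, s, _ = svds(sp.csr_matrix(weighted, dtype=np.float64), k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]
    if np.any(s <= 0):
        raise ValueError(f"k={k} exceeds the numerical rank of the matrix")
    # deterministic sign: largest |coordinate| of each column positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
    flip[flip == 0] = 1.0
    u = u * flip
    return SemanticSpace(u * s, s, list(vocabulary),
                         np.asarray(global_weights, dtype=float))


def fold_in(
    tokens: list[str],
    space: SemanticSpace,
    weight_terms: bool = False,
    normalize: bool = False,
) -> tuple[np.ndarray, OOVReport]:
    """Project a token sequence into the space as a bag-of-words sum.

    Out-of-vocabulary tokens are skipped and reported.  With
    ``weight_terms`` each term vector is multiplied by its global entropy
    weight before summation.  With ``normalize`` the resulting document
    vector is scaled to unit length (all-zero vectors are left as is).
    """
    vec = np.zeros(space.k)
    oov: list[str] = []
    for tok in tokens:
        if tok in space:
            tv = space.term_vector(tok)
            vec += tv * space.term_weight(tok) if weight_terms else tv
        else:
            oov.append(tok)
    report = OOVReport(len(tokens), len(oov), oov)
    if report.n_tokens and report.n_oov == report.n_tokens:
        warnings.warn("all tokens out of vocabulary; zero vector returned")
    if normalize:
        nrm = np.linalg.norm(vec)
        if nrm > 0:
            vec = vec / nrm
    return vec, report


def cosine(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity; raises on zero-length input."""
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("undefined cosine: zero vector")
    return float(np.dot(v1, v2) / (n1 * n2))
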