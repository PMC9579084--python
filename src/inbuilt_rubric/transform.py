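"""Change of basis: from a latent to a rubric-meaningful semantic space.

The new basis is a p x p matrix (here called the *beta* matrix) whose
leading columns are the rubric's concept vectors -- plus, in the
bifactor variant, one general-knowledge vector -- and whose remaining
columns are standard-basis vectors drawn at random without replacement.
The basis is orthonormalized by modified Gram-Schmidt in column order, a
per-column *fidelity* correlation between the pre- and post-
orthogonalization meaningful vectors gates reliability (0.80 by
default), and the term matrix is rotated into the new basis.  Because
the basis is orthonormal the rotation preserves every norm and pairwise
cosine of the original space.

The general vector follows a bifactor logic: each concept's lemma list
is split into two balanced random subsets, each subset is represented as
a unit vector, a one-factor analysis of the 2k subset vectors (observed
over the p space coordinates) yields loadings, and the general vector is
the normalized loadings-weighted sum of the subset vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import config
from .corpus_space import SemanticSpace
from .rubric import ConceptVector, Rubric
from .psychometrics import minres_loadings

__all__ = [
    "BetaMatrix",
    "GeneralFactorModel",
    "MeaningfulSpace",
    "assemble_beta",
    "estimate_general_vector",
    "assemble_beta_bifactor",
    "gram_schmidt",
    "change_basis",
]

GENERAL_LABEL = "G"


@dataclass
class BetaMatrix:
    """A (possibly orthonormalized) basis for the meaningful space."""

    columns: np.ndarray               # (p, p)
    meaningful_labels: list[str]      # concept names (+ general label)
    k: int                            # number of concept columns
    has_general: bool
    fill_indices: np.ndarray          # standard-basis coordinates used as fill
    seed: int | None
    orthonormal: bool = False
    fidelity: np.ndarray | None = None  # per-meaningful-column correlation

    def __post_init__(self) -> None:
        p = self.columns.shape[0]
        if self.columns.shape != (p, p):
            raise ValueError("beta must be square (p x p)")
        n_meaningful = self.k + int(self.has_general)
        if len(self.meaningful_labels) != n_meaningful:
            raise ValueError("meaningful_labels inconsistent with k/has_general")
        if len(self.fill_indices) != p - n_meaningful:
            raise ValueError("fill must contain p - k(-1) columns")
        if len(set(self.fill_indices.tolist())) != len(self.fill_indices):
            raise ValueError("fill_indices must be distinct")

    @property
    def p(self) -> int:
        return self.columns.shape[0]

    @property
    def n_meaningful(self) -> int:
        return self.k + int(self.has_general)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "beta.tsv", self.columns, fmt="%.17g", delimiter="\t")
        meta = {
            "meaningful_labels": self.meaningful_labels,
            "k": self.k,
            "has_general": self.has_general,
            "fill_indices": [int(i) for i in self.fill_indices],
            "seed": self.seed,
            "orthonormal": self.orthonormal,
            "fidelity": None if self.fidelity is None
            else [float(f) for f in self.fidelity],
        }
        (d / "beta.json").write_text(
            json.dumps(meta, sort_keys=True, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "BetaMatrix":
        d = Path(directory)
        cols = np.loadtxt(d / "beta.tsv", delimiter="\t", ndmin=2)
        m = json.loads((d / "beta.json").read_text(encoding="utf-8"))
        fid = None if m["fidelity"] is None else np.asarray(m["fidelity"])
        return cls(cols, m["meaningful_labels"], m["k"], m["has_general"],
                   np.asarray(m["fill_indices"], dtype=int), m["seed"],
                   m["orthonormal"], fid)


@dataclass
class GeneralFactorModel:
    """One-factor summary of split-descriptor subset vectors."""

    subset_vectors: np.ndarray        # (2k, p) unit rows
    subset_labels: list[str]
    loadings: np.ndarray              # (2k,)
    general_vector: np.ndarray        # (p,), unit norm

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.general_vector) - 1.0) > 1e-10:
            raise ValueError("general vector must be unit norm")
        if not np.all(np.isfinite(self.loadings)):
            raise ValueError("non-finite loadings")


@dataclass
class MeaningfulSpace:
    """Term matrix expressed in the orthonormalized beta basis."""

    term_vectors_rotated: np.ndarray  # (n_terms, p)
    meaningful_labels: list[str]
    k: int
    has_general: bool
    fidelity: np.ndarray
    vocabulary: list[str]
    global_weights: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.term_vectors_rotated.shape[0] != len(self.vocabulary):
            raise ValueError("rotated term matrix rows must match vocabulary")
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.vocabulary)}

    @property
    def p(self) -> int:
        return self.term_vectors_rotated.shape[1]

    @property
    def n_meaningful(self) -> int:
        return self.k + int(self.has_general)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def term_vector(self, term: str) -> np.ndarray:
        return self.term_vectors_rotated[self._index[term]]

    def term_weight(self, term: str) -> float:
        return float(self.global_weights[self._index[term]])

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "vocabulary.txt").write_text(
            "\n".join(self.vocabulary) + "\n", encoding="utf-8")
        np.savetxt(d / "term_vectors.tsv", self.term_vectors_rotated,
                   fmt="%.17g", delimiter="\t")
        meta = {
            "meaningful_labels": self.meaningful_labels,
            "k": self.k,
            "has_general": self.has_general,
            "fidelity": [float(f) for f in self.fidelity],
            "global_weights": [float(w) for w in self.global_weights],
        }
        (d / "mspace.json").write_text(
            json.dumps(meta, sort_keys=True, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "MeaningfulSpace":
        d = Path(directory)
        vocab = (d / "vocabulary.txt").read_text(encoding="utf-8").splitlines()
        tv = np.loadtxt(d / "term_vectors.tsv", delimiter="\t", ndmin=2)
        m = json.loads((d / "mspace.json").read_text(encoding="utf-8"))
        return cls(tv, m["meaningful_labels"], m["k"], m["has_general"],
                   np.asarray(m["fidelity"]), vocab,
                   np.asarray(m["global_weights"]))


# ---------------------------------------------------------------------------
# beta assembly
# ---------------------------------------------------------------------------

def _fill_columns(
    p: int, n_meaningful: int, seed: int | None
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    fill_idx = np.sort(rng.choice(p, size=p - n_meaningful, replace=False))
    fill = np.zeros((p, p - n_meaningful))
    fill[fill_idx, np.arange(p - n_meaningful)] = 1.0
    return fill, fill_idx


def assemble_beta(
    space: SemanticSpace,
    concept_vectors: list[ConceptVector],
    seed: int | None = 0,
) -> BetaMatrix:
    """Classic beta: concept columns then random standard-basis fill.

    The fill coordinates are drawn uniformly at random without
    replacement under ``seed``, so assembly is fully deterministic.
    """
    p = space.k
    k = len(concept_vectors)
    if not 1 <= k < p:
        raise ValueError(f"need 1 <= k < p (k={k}, p={p})")
    for cv in concept_vectors:
        if np.linalg.norm(cv.vector) == 0:
            raise ValueError(f"zero concept vector {cv.concept_name!r}")
    concept_block = np.column_stack([cv.vector for cv in concept_vectors])
    fill, fill_idx = _fill_columns(p, k, seed)
    return BetaMatrix(
        np.hstack([concept_block, fill]),
        [cv.concept_name for cv in concept_vectors],
        k, False, fill_idx, seed,
    )


def estimate_general_vector(
    space: SemanticSpace,
    rubric: Rubric,
    split_seed: int | None = 0,
    source: str = "descriptors",
    strict: bool = False,
) -> GeneralFactorModel:
    """Estimate the general-knowledge vector from split lemma subsets.

    Each concept's usable (in-vocabulary) lemmas are split into two
    balanced random subsets; each subset becomes a unit vector; a
    one-factor analysis over the 2k subset vectors (variables) across
    the p space coordinates (observations) yields loadings; the general
    vector is the normalized loadings-weighted sum of subset vectors.
    """
    rng = np.random.default_rng(split_seed)
    subset_vecs: list[np.ndarray] = []
    labels: list[str] = []
    for concept in rubric.concepts:
        lemmas = (concept.descriptors if source == "descriptors"
                  else concept.fragment_nouns)
        usable = [w for w in lemmas if w in space]
        if len(usable) < 2:
            if strict or len(usable) == 0:
                raise ValueError(
                    f"concept {concept.name!r}: fewer than 2 usable lemmas "
                    "for a 2-way split")
            usable = usable * 2  # duplicate-lexeme fallback
        perm = rng.permutation(len(usable))
        half = len(usable) // 2 + len(usable) % 2
        for s, idx in enumerate((perm[:half], perm[half:])):
            v = np.sum([space.term_vector(usable[i]) for i in idx], axis=0)
            nrm = np.linalg.norm(v)
            if nrm == 0:
                raise ValueError(
                    f"concept {concept.name!r}: degenerate subset vector")
            subset_vecs.append(v / nrm)
            labels.append(f"{concept.name}__{s + 1}")
    X = np.array(subset_vecs)                    # (2k, p)
    R = np.corrcoef(X)
    lam = minres_loadings(R, 1).ravel()
    if not np.all(np.isfinite(lam)) or np.all(np.abs(lam) < 1e-8):
        raise ValueError("degenerate one-factor solution for general vector")
    if np.any(np.abs(lam) > 1.0 + 1e-6):
        raise ValueError(
            f"Heywood case in general-factor fit (max |loading| = "
            f"{np.max(np.abs(lam)):.4f})")
    if lam.sum() < 0:                            # sign convention
        lam = -lam
    g = lam @ X
    nrm = np.linalg.norm(g)
    if nrm == 0:
        raise ValueError("general vector cancelled to zero")
    return GeneralFactorModel(X, labels, lam, g / nrm)


def assemble_beta_bifactor(
    space: SemanticSpace,
    concept_vectors: list[ConceptVector],
    general: GeneralFactorModel,
    position: str = "after_concepts",
    seed: int | None = 0,
) -> BetaMatrix:
    """Bifactor beta: concepts plus one general column; one fewer fill.

    ``position`` places the general column after the concepts (the
    default layout) or first (which residualizes every concept against
    the general vector during orthogonalization, matching bifactor
    semantics most literally).  Both orders are legitimate readings of
    the method and both are exposed.
    """
    p = space.k
    k = len(concept_vectors)
    if not 1 <= k < p - 1:
        raise ValueError(f"need 1 <= k < p-1 for a bifactor basis (k={k}, p={p})")
    for cv in concept_vectors:
        c = float(np.dot(cv.vector, general.general_vector))
        if abs(c) > config.COLLINEARITY_TOL:
            raise ValueError(
                f"general vector collinear with concept {cv.concept_name!r} "
                f"(|cos| = {abs(c):.4f})")
    concept_block = np.column_stack([cv.vector for cv in concept_vectors])
    g = general.general_vector[:, None]
    names = [cv.concept_name for cv in concept_vectors]
    if position == "after_concepts":
        meaningful = np.hstack([concept_block, g])
        labels = names + [GENERAL_LABEL]
    elif position == "general_first":
        meaningful = np.hstack([g, concept_block])
        labels = [GENERAL_LABEL] + names
    else:
        raise ValueError(f"unknown position {position!r}")
    fill, fill_idx = _fill_columns(p, k + 1, seed)
    return BetaMatrix(np.hstack([meaningful, fill]), labels, k, True,
                      fill_idx, seed)


# ---------------------------------------------------------------------------
# orthogonalization and rotation
# ---------------------------------------------------------------------------

def gram_schmidt(
    beta: BetaMatrix,
    fidelity_threshold: float = config.FIDELITY_THRESHOLD,
    strict: bool = False,
) -> BetaMatrix:
    """Modified Gram-Schmidt in column order with the fidelity gate.

    Columns are processed strictly in order (meaningful block first), so
    the first column is unchanged and each later meaningful column loses
    only the variance shared with its predecessors.  Fidelity is the
    uncentered correlation (cosine) between each meaningful column's
    coordinates before and after orthogonalization -- numerically the
    Pearson correlation of the coordinates for the near-mean-zero
    columns of a high-dimensional basis, but still defined when a
    column's coordinates are constant; values below the threshold warn,
    or raise in ``strict`` mode.  A residual collapsing below the
    degeneracy tolerance raises, naming the offending column, so the
    caller can re-seed the fill.
    """
    import warnings

    Q = np.array(beta.columns, dtype=float, copy=True)
    p = Q.shape[0]
    for j in range(p):
        for i in range(j):
            Q[:, j] -= np.dot(Q[:, i], Q[:, j]) * Q[:, i]
        nrm = np.linalg.norm(Q[:, j])
        if nrm < config.GS_DEGENERATE_TOL:
            label = (beta.meaningful_labels[j] if j < beta.n_meaningful
                     else f"fill[{j - beta.n_meaningful}]")
            raise ValueError(
                f"degenerate basis: column {j} ({label}) has residual norm "
                f"{nrm:.2e}; re-seed the standard-basis fill")
        Q[:, j] /= nrm
    fidelity = np.empty(beta.n_meaningful)
    for j in range(beta.n_meaningful):
        a, b = beta.columns[:, j], Q[:, j]
        fidelity[j] = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    low = [(beta.meaningful_labels[j], float(fidelity[j]))
           for j in range(beta.n_meaningful)
           if fidelity[j] < fidelity_threshold]
    if low:
        msg = (f"fidelity below {fidelity_threshold:.2f} for: "
               + ", ".join(f"{n} ({f:.4f})" for n, f in low))
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    return replace(beta, columns=Q, orthonormal=True, fidelity=fidelity)


def change_basis(space: SemanticSpace, ortho_beta: BetaMatrix) -> MeaningfulSpace:
    """Express every term vector in the orthonormalized beta basis.

    Coordinate ``j`` of a term vector ``v`` becomes ``<beta_j, v>``.  An
    orthonormal basis makes this a pure rotation: the original semantic
    distances (norms and pairwise cosines) remain, which is verified
    here against the rotation tolerance.
    """
    Q = ortho_beta.columns
    if not ortho_beta.orthonormal or \
            np.max(np.abs(Q.T @ Q - np.eye(Q.shape[0]))) > config.GS_ORTHO_TOL:
        raise ValueError("beta basis is not orthonormal; run gram_schmidt first")
    if space.k != ortho_beta.p:
        raise ValueError("beta dimensionality does not match the space")
    rotated = space.term_vectors @ Q
    return MeaningfulSpace(
        rotated,
        list(ortho_beta.meaningful_labels),
        ortho_beta.k,
        ortho_beta.has_general,
        np.array(ortho_beta.fidelity),
        list(space.vocabulary),
        np.array(space.global_weights),
    )
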