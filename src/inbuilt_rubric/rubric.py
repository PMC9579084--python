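"""Assessment rubrics and concept vectors.

A rubric is an ordered set of named concepts, each carrying a small set
of expert-chosen *lexical descriptors* and/or a (typically larger) list
of nouns harvested from a fragment of the instructional text.  A concept
vector is the unit-normalized sum of the term vectors of its lemmas:
normalization happens once, after summation, so frequent/strong terms
contribute proportionally to their raw vector length unless
``prenormalize_terms`` is requested.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus_space import SemanticSpace, cosine

__all__ = [
    "Concept",
    "Rubric",
    "ConceptVector",
    "concept_vector_from_descriptors",
    "concept_vector_from_fragment",
    "build_concept_vectors",
    "neighborhood_check",
    "load_rubric",
    "save_rubric",
]

#: Rule-of-thumb number of descriptors that usually suffices per concept;
#: deviations trigger a lint warning, never an error.
RECOMMENDED_DESCRIPTORS = 3


@dataclass
class Concept:
    name: str
    descriptors: list[str] = field(default_factory=list)
    fragment_nouns: list[str] = field(default_factory=list)
    max_score: float = 2.0

    def __post_init__(self) -> None:
        if not self.descriptors and not self.fragment_nouns:
            raise ValueError(
                f"concept {self.name!r}: needs descriptors or fragment_nouns"
            )
        self.descriptors = [w.lower() for w in self.descriptors]
        self.fragment_nouns = [w.lower() for w in self.fragment_nouns]
        if self.max_score < 0:
            raise ValueError(f"concept {self.name!r}: negative max_score")


@dataclass
class Rubric:
    concepts: list[Concept]
    text_id: str = "text"

    def __post_init__(self) -> None:
        if not self.concepts:
            raise ValueError("rubric needs at least one concept")
        names = [c.name for c in self.concepts]
        if len(set(names)) != len(names):
            raise ValueError("concept names must be unique")
        for c in self.concepts:
            if c.descriptors and len(c.descriptors) != RECOMMENDED_DESCRIPTORS:
                warnings.warn(
                    f"concept {c.name!r} has {len(c.descriptors)} descriptors; "
                    f"{RECOMMENDED_DESCRIPTORS} per concept is usually enough"
                )

    @property
    def concept_names(self) -> list[str]:
        return [c.name for c in self.concepts]

    def __len__(self) -> int:
        return len(self.concepts)


@dataclass
class ConceptVector:
    """Unit-norm vector representation of one rubric concept."""

    concept_name: str
    vector: np.ndarray
    source: str                  # "descriptors" | "fragment_nouns"
    n_terms_used: int
    oov_terms: list[str]

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.vector) - 1.0) > 1e-10:
            raise ValueError(f"concept {self.concept_name!r}: vector not unit norm")
        if self.n_terms_used < 1:
            raise ValueError(f"concept {self.concept_name!r}: no terms used")


def _sum_vector(
    space: SemanticSpace,
    name: str,
    lemmas: list[str],
    source: str,
    prenormalize_terms: bool,
    strict: bool,
) -> ConceptVector:
    used = 0
    oov: list[str] = []
    vec = np.zeros(space.k)
    for lemma in lemmas:
        if lemma in space:
            tv = space.term_vector(lemma)
            if prenormalize_terms:
                tv = tv / np.linalg.norm(tv)
            vec += tv
            used += 1
        else:
            oov.append(lemma)
    if oov:
        msg = f"concept {name!r}: out-of-vocabulary lemmas {sorted(set(oov))}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " (dropped)")
    if used == 0:
        raise ValueError(f"concept {name!r}: every lemma is out of vocabulary")
    nrm = np.linalg.norm(vec)
    if nrm == 0:
        raise ValueError(f"concept {name!r}: term vectors cancel to zero")
    return ConceptVector(name, vec / nrm, source, used, oov)


def concept_vector_from_descriptors(
    space: SemanticSpace,
    concept: Concept,
    prenormalize_terms: bool = False,
    strict: bool = False,
) -> ConceptVector:
    """Concept vector from the curated descriptor list."""
    if not concept.descriptors:
        raise ValueError(f"concept {concept.name!r}: no descriptors")
    return _sum_vector(space, concept.name, concept.descriptors,
                       "descriptors", prenormalize_terms, strict)


def concept_vector_from_fragment(
    space: SemanticSpace,
    concept: Concept,
    prenormalize_terms: bool = False,
    strict: bool = False,
    unique: bool = False,
) -> ConceptVector:
    """Concept vector from fragment nouns.

    Identical construction to the descriptor variant over a (typically
    larger) noun list.  By default a noun repeated in the fragment
    contributes once per occurrence (multiset sum); ``unique`` collapses
    repeats to a set (first-occurrence order preserved).
    """
    if not concept.fragment_nouns:
        raise ValueError(f"concept {concept.name!r}: no fragment nouns")
    nouns = concept.fragment_nouns
    if unique:
        nouns = list(dict.fromkeys(nouns))
    return _sum_vector(space, concept.name, nouns,
                       "fragment_nouns", prenormalize_terms, strict)


def build_concept_vectors(
    space: SemanticSpace,
    rubric: Rubric,
    source: str = "descriptors",
    **kwargs,
) -> list[ConceptVector]:
    """Concept vectors for every rubric concept from the chosen source."""
    if source == "descriptors":
        return [concept_vector_from_descriptors(space, c, **kwargs)
                for c in rubric.concepts]
    if source == "fragment_nouns":
        return [concept_vector_from_fragment(space, c, **kwargs)
                for c in rubric.concepts]
    raise ValueError(f"unknown source {source!r}")


def neighborhood_check(
    space: SemanticSpace, cv: ConceptVector, n: int = 10
) -> list[tuple[str, float]]:
    """Top-``n`` vocabulary terms by cosine to the concept vector.

    Inspecting a concept vector's semantic neighborhood is the standard
    sanity check on descriptor quality: its nearest terms should belong
    to the concept's own topic.  Ties break lexicographically.
    """
    norms = np.linalg.norm(space.term_vectors, axis=1)
    ok = norms > 0
    cos = np.zeros(len(space.vocabulary))
    cos[ok] = (space.term_vectors[ok] @ cv.vector) / norms[ok]
    ranked = sorted(zip(space.vocabulary, cos), key=lambda p: (-p[1], p[0]))
    return [(t, float(c)) for t, c in ranked[:n]]


# ---------------------------------------------------------------------------
# rubric files (YAML or JSON)
# ---------------------------------------------------------------------------

def load_rubric(path: str | Path) -> Rubric:
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    concepts = [
        Concept(
            name=c["name"],
            descriptors=list(c.get("descriptors", [])),
            fragment_nouns=list(c.get("fragment_nouns", [])),
            max_score=float(c.get("max_score", 2.0)),
        )
        for c in data["concepts"]
    ]
    return Rubric(concepts, text_id=data.get("text_id", "text"))


def save_rubric(rubric: Rubric, path: str | Path) -> None:
    data = {
        "text_id": rubric.text_id,
        "concepts": [
            {
                "name": c.name,
                "max_score": c.max_score,
                "descriptors": c.descriptors,
                "fragment_nouns": c.fragment_nouns,
            }
            for c in rubric.concepts
        ],
    }
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(data, indent=1, sort_keys=True), encoding="utf-8")
    else:
        p.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
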