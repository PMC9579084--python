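"""Seeded synthetic data: topic corpora, rubrics, summaries and raters.

The generative model is intentionally simple and fully documented so
every downstream test is reproducible: documents are multinomial draws
from per-topic word distributions with a mild power-law (Zipf-like)
profile, an optional shared vocabulary pool plants a general-knowledge
component across topics, summaries mix topic vocabularies according to
known coverage weights, and simulated raters discretize noisy monotone
transforms of the true coverage onto the rubric's 0..max score scale.
Rater noise is calibrated so the between-rater correlation of the
*discretized* scores hits a target reliability: the pre-discretization
correlation is solved numerically from bivariate-normal cell
probabilities rather than by a linear attenuation formula (which cannot
reach high reliabilities on a 3-point scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import brentq

from .corpus_space import Corpus
from .rubric import Concept, Rubric
from .scoring import RatingTable

__all__ = [
    "TopicModelSpec",
    "SummarySpec",
    "RaterSpec",
    "TopicTruth",
    "generate_topic_corpus",
    "generate_rubric_from_topics",
    "generate_summaries",
    "generate_ratings",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class TopicModelSpec:
    """Planted-topic corpus: k disjoint topic vocabularies (+ shared pool)."""

    n_topics: int = 5
    words_per_topic: int = 40
    shared_vocab_fraction: float = 0.0   # P(token from the shared pool)
    #: P(token from a random *other* topic): documents are mixtures
    #: dominated by their own topic, as in real expository paragraphs.
    #: Without any cross-topic co-occurrence the term vectors of
    #: different topics would be exactly orthogonal and no common
    #: variance would exist for a general factor to summarize.
    topic_mixing: float = 0.10
    docs_per_topic: int = 200
    doc_length: tuple[int, int] = (60, 120)   # uniform inclusive bounds
    zipf_exponent: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_vocab_fraction <= 1.0:
            raise ValueError("shared_vocab_fraction must be in [0, 1]")
        if not 0.0 <= self.topic_mixing < 1.0 or \
                self.topic_mixing + self.shared_vocab_fraction >= 1.0:
            raise ValueError("topic_mixing must be in [0, 1) and leave room "
                             "for the dominant topic")
        if min(self.n_topics, self.words_per_topic, self.docs_per_topic) < 1:
            raise ValueError("all counts must be positive")
        if self.doc_length[0] < 1 or self.doc_length[1] < self.doc_length[0]:
            raise ValueError("infeasible doc_length bounds")


@dataclass
class SummarySpec:
    """Summaries with known per-concept coverage weights."""

    n_summaries: int = 200
    coverage_weights: np.ndarray | None = None  # (n_summaries, k) simplex rows
    length: tuple[int, int] = (40, 80)
    noise_word_rate: float = 0.10
    dirichlet_alpha: float = 2.0
    #: Beta parameters of the per-summary total topical mass ("quality"):
    #: all concept coverages are scaled by one draw, planting the positive
    #: manifold real summary ratings exhibit (better students cover more of
    #: everything).
    quality_beta: tuple[float, float] = (2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_summaries < 1:
            raise ValueError("n_summaries must be positive")
        if not 0.0 <= self.noise_word_rate < 1.0:
            raise ValueError("noise_word_rate must be in [0, 1)")
        if self.length[0] < 1 or self.length[1] < self.length[0]:
            raise ValueError("infeasible length bounds")
        if self.coverage_weights is not None:
            w = np.asarray(self.coverage_weights, dtype=float)
            if (w < 0).any() or (w.sum(axis=1) > 1.0 + 1e-9).any():
                raise ValueError("coverage weights must be nonnegative with "
                                 "row sums <= 1")


@dataclass
class RaterSpec:
    """Simulated raters with a target reliability on the rubric scale."""

    n_raters: int = 2
    reliability: float | list[float] = 0.8
    scale_max: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        rel = np.atleast_1d(np.asarray(self.reliability, dtype=float))
        if ((rel <= 0) | (rel > 1)).any():
            raise ValueError("reliability must be in (0, 1]")
        if self.scale_max < 1:
            raise ValueError("scale_max must be >= 1")

    def reliabilities(self) -> np.ndarray:
        rel = np.atleast_1d(np.asarray(self.reliability, dtype=float))
        if rel.size == 1:
            rel = np.repeat(rel, self.n_raters)
        if rel.size != self.n_raters:
            raise ValueError("reliability list must match n_raters")
        return rel


@dataclass
class TopicTruth:
    """Ground truth attached to a generated corpus."""

    topic_words: list[list[str]]          # per-topic exclusive vocabulary
    shared_words: list[str]
    topic_of_doc: list[int]
    topic_term_counts: list[dict[str, int]] = field(default_factory=list)

    @property
    def n_topics(self) -> int:
        return len(self.topic_words)

    @property
    def vocabulary(self) -> list[str]:
        return [w for tw in self.topic_words for w in tw] + self.shared_words

    def concept_names(self) -> list[str]:
        return [f"concept_{t + 1}" for t in range(self.n_topics)]


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def generate_topic_corpus(spec: TopicModelSpec) -> tuple[Corpus, TopicTruth]:
    """Sample a corpus of single-topic documents (plus shared vocabulary).

    Each document belongs to one topic; each token comes from the shared
    pool with probability ``shared_vocab_fraction`` and otherwise from
    the document's own topic vocabulary, both with a power-law word
    profile.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    topic_words = [
        [f"t{t + 1}_w{i + 1}" for i in range(spec.words_per_topic)]
        for t in range(spec.n_topics)
    ]
    n_shared = spec.words_per_topic if spec.shared_vocab_fraction > 0 else 0
    shared = [f"shared_w{i + 1}" for i in range(n_shared)]
    w_topic = _zipf_weights(spec.words_per_topic, spec.zipf_exponent)
    w_shared = _zipf_weights(n_shared, spec.zipf_exponent) if n_shared else None

    docs: list[list[str]] = []
    ids: list[str] = []
    topic_of_doc: list[int] = []
    counts = [dict.fromkeys(tw, 0) for tw in topic_words]
    others = [[u for u in range(spec.n_topics) if u != t]
              for t in range(spec.n_topics)]
    for t in range(spec.n_topics):
        for d in range(spec.docs_per_topic):
            length = int(rng.integers(spec.doc_length[0],
                                      spec.doc_length[1] + 1))
            p_shared = spec.shared_vocab_fraction if n_shared else 0.0
            n_sh, n_mix = rng.multinomial(
                length, [p_shared, spec.topic_mixing,
                         1.0 - p_shared - spec.topic_mixing])[:2]
            toks = list(rng.choice(topic_words[t],
                                   size=length - n_sh - n_mix, p=w_topic))
            for u in rng.choice(others[t], size=n_mix) if n_mix else []:
                toks.append(str(rng.choice(topic_words[u], p=w_topic)))
            if n_sh:
                toks += list(rng.choice(shared, size=n_sh, p=w_shared))
            rng.shuffle(toks)
            for tok in toks:
                if tok in counts[t]:
                    counts[t][tok] += 1
            docs.append(toks)
            ids.append(f"t{t + 1}_d{d + 1}")
            topic_of_doc.append(t)
    truth = TopicTruth(topic_words, shared, topic_of_doc, counts)
    return Corpus(docs, ids), truth


def generate_rubric_from_topics(
    truth: TopicTruth,
    n_descriptors: int = 3,
    fragment_length: int = 12,
) -> Rubric:
    """Rubric whose concepts are the planted topics.

    Descriptors are each topic's ``n_descriptors`` most frequent
    topic-exclusive words; fragment nouns are a larger slice of the same
    frequency ranking (the whole topic vocabulary if ``fragment_length``
    exceeds it), mimicking noun lists harvested from an instructional-
    text fragment.
    """
    concepts = []
    for t, name in enumerate(truth.concept_names()):
        exclusive = truth.topic_words[t]
        if len(exclusive) < n_descriptors:
            raise ValueError(
                f"topic {t + 1} has {len(exclusive)} exclusive words; "
                f"cannot pick {n_descriptors} descriptors")
        cnt = truth.topic_term_counts[t]
        ranked = sorted(exclusive, key=lambda w: (-cnt.get(w, 0), w))
        concepts.append(Concept(
            name=name,
            descriptors=ranked[:n_descriptors],
            fragment_nouns=ranked[:min(fragment_length, len(ranked))],
        ))
    return Rubric(concepts, text_id="synthetic")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def generate_summaries(
    spec: SummarySpec, truth: TopicTruth
) -> tuple[Corpus, pd.DataFrame]:
    """Summaries with known concept coverage.

    Each summary's tokens are a multinomial draw over its concepts
    (proportional to the coverage weights) plus off-topic noise drawn
    uniformly from the full vocabulary; the coverage matrix used for
    generation is returned for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    k = truth.n_topics
    if spec.coverage_weights is not None:
        W = np.asarray(spec.coverage_weights, dtype=float)
        if W.shape != (spec.n_summaries, k):
            raise ValueError(f"coverage_weights must be "
                             f"({spec.n_summaries}, {k})")
    else:
        shares = rng.dirichlet(np.full(k, spec.dirichlet_alpha),
                               size=spec.n_summaries)
        quality = rng.beta(*spec.quality_beta, size=spec.n_summaries)
        W = shares * (quality * (1.0 - spec.noise_word_rate))[:, None]
    w_topic = _zipf_weights(len(truth.topic_words[0]), 0.8)
    vocab = truth.vocabulary
    docs: list[list[str]] = []
    ids: list[str] = []
    for s in range(spec.n_summaries):
        length = int(rng.integers(spec.length[0], spec.length[1] + 1))
        probs = np.append(W[s], 1.0 - W[s].sum())
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        comp = rng.multinomial(length, probs)
        toks: list[str] = []
        for t in range(k):
            if comp[t]:
                toks += list(rng.choice(truth.topic_words[t], size=comp[t],
                                        p=w_topic))
        if comp[k]:
            toks += list(rng.choice(vocab, size=comp[k]))
        rng.shuffle(toks)
        docs.append(toks)
        ids.append(f"s{s + 1}")
    coverage = pd.DataFrame(W, index=pd.Index(ids, name="doc_id"),
                            columns=truth.concept_names())
    return Corpus(docs, ids), coverage


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------

def _equal_prob_thresholds(n_categories: int) -> np.ndarray:
    return st.norm.ppf(np.arange(1, n_categories) / n_categories)


def _discretized_corr(r: float, thresholds: np.ndarray) -> float:
    """Correlation of two equal-probability discretizations of a
    standard bivariate normal with latent correlation ``r``."""
    m = len(thresholds) + 1
    edges = np.concatenate([[-10.0], thresholds, [10.0]])
    mvn = st.multivariate_normal(mean=[0.0, 0.0],
                                 cov=[[1.0, r], [r, 1.0]],
                                 allow_singular=True)
    cdf = np.array([[mvn.cdf([edges[i], edges[j]]) for j in range(m + 1)]
                    for i in range(m + 1)])
    cell = (cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1])
    vals = np.arange(m, dtype=float)
    mean = vals.mean()
    var = np.mean(vals ** 2) - mean ** 2
    e_xy = float(vals @ cell @ vals)
    return (e_xy - mean ** 2) / var


def _latent_corr_for(target: float, n_categories: int) -> float:
    """Pre-discretization correlation achieving the target discretized
    correlation (solved numerically; monotone in the latent r)."""
    thr = _equal_prob_thresholds(n_categories)
    f = lambda r: _discretized_corr(r, thr) - target
    if f(1.0 - 1e-9) < 0:
        return 1.0 - 1e-9
    return brentq(f, 1e-9, 1.0 - 1e-9, xtol=1e-6)


def generate_ratings(
    coverage: pd.DataFrame, spec: RaterSpec
) -> RatingTable:
    """Simulate human ratings of known-coverage summaries.

    Per concept, the true coverage is rank-normalized to a latent
    standard-normal score; each rater observes a correlated noisy copy
    and bins it into ``scale_max + 1`` equal-probability categories.
    Noise is calibrated so the discretized between-rater correlation
    targets the requested reliability; reliability 1 means no noise and
    identical rater columns.
    """
    rng = np.random.default_rng(spec.seed)
    rel = spec.reliabilities()
    n_cat = spec.scale_max + 1
    thresholds = _equal_prob_thresholds(n_cat)
    n = len(coverage)
    # per-rater latent weight a_r: corr(rater i, rater j) = sqrt(a_i a_j)
    a = np.empty(spec.n_raters)
    for j, rho in enumerate(rel):
        a[j] = 1.0 if rho >= 1.0 else _latent_corr_for(rho, n_cat)
    rows = []
    for concept in coverage.columns:
        x = coverage[concept].to_numpy(dtype=float)
        # rank-normalize (monotone in true coverage; ties broken stably)
        order = np.argsort(x, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        z = st.norm.ppf(ranks / (n + 1))
        for j in range(spec.n_raters):
            if rel[j] >= 1.0:
                y = z
            else:
                y = np.sqrt(a[j]) * z + np.sqrt(1.0 - a[j]) * \
                    rng.standard_normal(n)
            score = np.digitize(y, thresholds)
            for doc_id, s in zip(coverage.index, score):
                rows.append((doc_id, f"rater{j + 1}", concept, int(s)))
    long = pd.DataFrame(rows, columns=["doc_id", "rater_id", "concept",
                                       "score"])
    max_scores = {c: float(spec.scale_max) for c in coverage.columns}
    return RatingTable(long, max_scores)
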