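"""Shared synthetic-study fixtures.

Everything is generated programmatically under fixed seeds; the bundle
is session-scoped because training even a small semantic space is the
most expensive step the module tests share.
"""

from dataclasses import dataclass

import numpy as np
import pytest

import inbuilt_rubric as ir


@dataclass
class StudyBundle:
    corpus: ir.Corpus
    truth: ir.TopicTruth
    space: ir.SemanticSpace
    rubric: ir.Rubric
    concept_vectors: list
    summaries: ir.Corpus
    coverage: "object"
    ratings: ir.RatingTable


def _build_bundle(shared: float, seed: int, k: int = 25,
                  n_topics: int = 4, docs_per_topic: int = 80,
                  n_summaries: int = 150) -> StudyBundle:
    corpus, truth = ir.generate_topic_corpus(ir.TopicModelSpec(
        n_topics=n_topics, words_per_topic=30, docs_per_topic=docs_per_topic,
        shared_vocab_fraction=shared, seed=seed))
    tdm = ir.build_term_doc_matrix(corpus, 2)
    weighted, gw = ir.log_entropy_weight(tdm)
    space = ir.train_space(weighted, k, vocabulary=tdm.vocabulary,
                           global_weights=gw, seed=seed)
    rubric = ir.generate_rubric_from_topics(truth)
    cvs = ir.build_concept_vectors(space, rubric)
    summaries, coverage = ir.generate_summaries(
        ir.SummarySpec(n_summaries=n_summaries, seed=seed + 1), truth)
    ratings = ir.generate_ratings(coverage, ir.RaterSpec(seed=seed + 2))
    return StudyBundle(corpus, truth, space, rubric, cvs, summaries,
                       coverage, ratings)


@pytest.fixture(scope="session")
def study() -> StudyBundle:
    """Small planted-topic study with a shared-vocabulary component."""
    return _build_bundle(shared=0.2, seed=11)


@pytest.fixture(scope="session")
def study_disjoint() -> StudyBundle:
    """Study with fully disjoint topics (no shared pool, no mixing)."""
    corpus, truth = ir.generate_topic_corpus(ir.TopicModelSpec(
        n_topics=3, words_per_topic=30, docs_per_topic=60,
        shared_vocab_fraction=0.0, topic_mixing=0.0, seed=7))
    tdm = ir.build_term_doc_matrix(corpus, 2)
    weighted, gw = ir.log_entropy_weight(tdm)
    space = ir.train_space(weighted, 15, vocabulary=tdm.vocabulary,
                           global_weights=gw, seed=7)
    rubric = ir.generate_rubric_from_topics(truth)
    cvs = ir.build_concept_vectors(space, rubric)
    summaries, coverage = ir.generate_summaries(
        ir.SummarySpec(n_summaries=80, seed=8), truth)
    ratings = ir.generate_ratings(coverage, ir.RaterSpec(seed=9))
    return StudyBundle(corpus, truth, space, rubric, cvs, summaries,
                       coverage, ratings)


@pytest.fixture(scope="session")
def mspace(study) -> ir.MeaningfulSpace:
    """Classic meaningful space over the shared-component study."""
    beta = ir.assemble_beta(study.space, study.concept_vectors, seed=11)
    return ir.change_basis(study.space, ir.gram_schmidt(beta))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
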