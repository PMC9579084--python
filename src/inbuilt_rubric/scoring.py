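"""Scoring constructed responses in a meaningful space, plus the
end-to-end pipeline.

A document folded into the rotated space has one coordinate per basis
column; the leading coordinates -- the concept dimensions and, in the
bifactor variant, the general dimension -- are its scores.  Raw
coordinates may be negative and are not floored or rescaled: downstream
validation consumes them as-is.  Score columns are named
``score__<concept>`` (``score__G`` for the general dimension).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import config as cfg
from .corpus_space import (Corpus, OOVReport, build_term_doc_matrix,
                           log_entropy_weight, train_space)
from .rubric import Rubric, build_concept_vectors, load_rubric
from .transform import (MeaningfulSpace, assemble_beta, assemble_beta_bifactor,
                        change_basis, estimate_general_vector, gram_schmidt)

__all__ = [
    "ScoreTable",
    "RatingTable",
    "score_document",
    "score_corpus",
    "run_pipeline",
]

SCORE_PREFIX = "score__"


@dataclass
class ScoreTable:
    """Documents x meaningful-dimension coordinates with OOV accounting."""

    scores: pd.DataFrame              # index doc_id, columns score__<label>
    oov_rate: pd.Series
    flagged: pd.Series                # True when the row is unreliable
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("non-finite scores")

    @property
    def doc_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def labels(self) -> list[str]:
        return [c[len(SCORE_PREFIX):] for c in self.scores.columns]

    def to_csv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out["oov_rate"] = self.oov_rate
        out["flagged"] = self.flagged.astype(int)
        out.to_csv(path, index_label="doc_id", float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, meta: dict | None = None) -> "ScoreTable":
        df = pd.read_csv(path, index_col="doc_id")
        oov = df.pop("oov_rate")
        flagged = df.pop("flagged").astype(bool)
        return cls(df, oov, flagged, meta or {})


@dataclass
class RatingTable:
    """Human ratings in long format: (doc_id, rater_id, concept, score)."""

    long: pd.DataFrame
    max_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"doc_id", "rater_id", "concept", "score"}
        if not required.issubset(self.long.columns):
            raise ValueError(f"rating table needs columns {sorted(required)}")
        per_rater = self.long.groupby("rater_id")["concept"].apply(
            lambda s: tuple(sorted(set(s))))
        if per_rater.nunique() > 1:
            raise ValueError("raters must rate the same set of concepts")
        for concept, mx in self.max_scores.items():
            sub = self.long.loc[self.long.concept == concept, "score"]
            if ((sub < 0) | (sub > mx)).any():
                raise ValueError(
                    f"scores for {concept!r} outside [0, {mx}]")

    @property
    def doc_ids(self) -> list[str]:
        return list(pd.unique(self.long["doc_id"]))

    @property
    def rater_ids(self) -> list[str]:
        return list(pd.unique(self.long["rater_id"]))

    @property
    def concepts(self) -> list[str]:
        return list(pd.unique(self.long["concept"]))

    def to_wide(self) -> pd.DataFrame:
        """Pivot to doc_id x `<rater>__<concept>` columns."""
        wide = self.long.pivot_table(
            index="doc_id", columns=["rater_id", "concept"],
            values="score", aggfunc="first")
        wide.columns = [f"{r}__{c}" for r, c in wide.columns]
        return wide.loc[self.doc_ids]

    def rater_matrix(self, concept: str) -> pd.DataFrame:
        """Targets x raters matrix for one concept (for reliability)."""
        sub = self.long[self.long.concept == concept]
        return sub.pivot_table(index="doc_id", columns="rater_id",
                               values="score", aggfunc="first")

    def totals(self) -> pd.DataFrame:
        """Per-document rubric total score, one column per rater."""
        return self.long.pivot_table(index="doc_id", columns="rater_id",
                                     values="score", aggfunc="sum")

    def mean_ratings(self) -> pd.DataFrame:
        """Doc x concept ratings averaged over raters."""
        return self.long.pivot_table(index="doc_id", columns="concept",
                                     values="score", aggfunc="mean")

    def to_csv(self, path: str | Path) -> None:
        self.long.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path,
                 max_scores: dict[str, float] | None = None) -> "RatingTable":
        return cls(pd.read_csv(path), max_scores or {})


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_document(
    mspace: MeaningfulSpace,
    tokens: list[str],
    normalize: bool = False,
    weight_terms: bool = False,
) -> tuple[np.ndarray, OOVReport]:
    """Project one document and read off the meaningful coordinates.

    The document vector is the bag-of-words sum of rotated term vectors
    (projection is linear, so concatenating two documents adds their
    score vectors unless ``normalize`` is on).  All-OOV documents score
    zero on every dimension.
    """
    vec = np.zeros(mspace.p)
    oov: list[str] = []
    for tok in tokens:
        if tok in mspace:
            tv = mspace.term_vector(tok)
            vec += tv * mspace.term_weight(tok) if weight_terms else tv
        else:
            oov.append(tok)
    if normalize:
        nrm = np.linalg.norm(vec)
        if nrm > 0:
            vec = vec / nrm
    return vec[: mspace.n_meaningful], OOVReport(len(tokens), len(oov), oov)


def score_corpus(
    mspace: MeaningfulSpace,
    corpus: Corpus,
    normalize: bool = False,
    weight_terms: bool = False,
    oov_flag_threshold: float = cfg.OOV_FLAG_THRESHOLD,
) -> ScoreTable:
    """Score every document; rows keep the corpus order.

    Rows whose OOV rate exceeds the threshold (or that are empty) are
    flagged as unreliable but never dropped.
    """
    rows = []
    oov_rates = []
    flags = []
    for tokens in corpus.documents:
        s, rep = score_document(mspace, tokens, normalize, weight_terms)
        rows.append(s)
        oov_rates.append(rep.oov_rate)
        flags.append(rep.n_tokens == 0 or rep.oov_rate > oov_flag_threshold)
    cols = [SCORE_PREFIX + lab for lab in mspace.meaningful_labels]
    scores = pd.DataFrame(np.array(rows), index=pd.Index(corpus.doc_ids,
                                                         name="doc_id"),
                          columns=cols)
    meta = {"normalize": normalize, "weight_terms": weight_terms,
            "labels": list(mspace.meaningful_labels)}
    return ScoreTable(scores, pd.Series(oov_rates, index=scores.index),
                      pd.Series(flags, index=scores.index), meta)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = {
    "corpus": str, "rubric": str, "documents": str, "out_dir": str,
    "k": int, "seed": int,
}
_OPTIONAL_KEYS = {
    "variant": ("classic", "bifactor"),
    "source": ("descriptors", "fragment_nouns"),
    "general_position": ("after_concepts", "general_first"),
    "normalize": (True, False),
    "weight_terms": (True, False),
    "strict_fidelity": (True, False),
    "min_doc_freq": None,
    "ratings": None,
}
_DEFAULTS = {
    "variant": "classic", "source": "descriptors",
    "general_position": "after_concepts", "normalize": False,
    "weight_terms": False, "strict_fidelity": False,
    "min_doc_freq": cfg.MIN_DOC_FREQ_DEFAULT, "ratings": None,
}


def _validate_config(raw: dict) -> dict:
    conf = dict(_DEFAULTS)
    errors = []
    for key, typ in _REQUIRED_KEYS.items():
        if key not in raw:
            errors.append(f"config.{key}: required")
        elif not isinstance(raw[key], typ):
            errors.append(f"config.{key}: expected {typ.__name__}, "
                          f"got {type(raw[key]).__name__}")
    for key, val in raw.items():
        if key in _REQUIRED_KEYS:
            conf[key] = val
        elif key in _OPTIONAL_KEYS:
            allowed = _OPTIONAL_KEYS[key]
            if allowed is not None and val not in allowed:
                errors.append(f"config.{key}: {val!r} not in {allowed}")
            conf[key] = val
        else:
            errors.append(f"config.{key}: unknown field")
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    return conf


def run_pipeline(config: dict | str | Path) -> dict:
    """Train, transform, score and (optionally) validate; write artifacts.

    ``config`` is a dict or a YAML file path.  Every artifact is written
    deterministically (fixed float formats, sorted JSON keys, no
    timestamps), so identical configs and seeds reproduce byte-identical
    outputs.  Returns the artifact paths plus the validation report.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
    conf = _validate_config(config)
    out = Path(conf["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    corpus = Corpus.from_lines(conf["corpus"])
    rubric = load_rubric(conf["rubric"])
    tdm = build_term_doc_matrix(corpus, conf["min_doc_freq"])
    weighted, gw = log_entropy_weight(tdm)
    space = train_space(weighted, conf["k"], vocabulary=tdm.vocabulary,
                        global_weights=gw, seed=conf["seed"])
    space.save(out / "space")

    cvs = build_concept_vectors(space, rubric, source=conf["source"])
    if conf["variant"] == "bifactor":
        general = estimate_general_vector(space, rubric,
                                          split_seed=conf["seed"],
                                          source=conf["source"])
        beta = assemble_beta_bifactor(space, cvs, general,
                                      position=conf["general_position"],
                                      seed=conf["seed"])
    else:
        beta = assemble_beta(space, cvs, seed=conf["seed"])
    ortho = gram_schmidt(beta, strict=conf["strict_fidelity"])
    ortho.save(out / "beta")
    mspace = change_basis(space, ortho)
    mspace.save(out / "mspace")

    docs = Corpus.from_lines(conf["documents"], prefix="summary")
    table = score_corpus(mspace, docs, normalize=conf["normalize"],
                         weight_terms=conf["weight_terms"])
    table.meta.update(variant=conf["variant"], source=conf["source"])
    table.to_csv(out / "scores.csv")

    report: dict = {}
    if conf["ratings"]:
        ratings = RatingTable.from_csv(conf["ratings"])
        report = validation_report(table, ratings, seed=conf["seed"])
        (out / "validation.json").write_text(
            json.dumps(report, sort_keys=True, indent=1), encoding="utf-8")

    # the output location is not part of the scientific configuration:
    # identical analyses written to different directories must produce
    # identical artifacts
    conf_prov = {k: v for k, v in conf.items() if k != "out_dir"}
    canonical = json.dumps(conf_prov, sort_keys=True).encode()
    provenance = {
        "config": conf_prov,
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "package": "inbuilt-rubric 0.1.0",
        "fidelity": [float(f) for f in ortho.fidelity],
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=1), encoding="utf-8")
    return {"out_dir": str(out), "validation": report,
            "fidelity": [float(f) for f in ortho.fidelity]}


def validation_report(table: ScoreTable, ratings: RatingTable,
                      seed: int = 0) -> dict:
    """Run the validation battery on a score table and human ratings.

    Inter-rater reliability per concept and for rubric totals, parallel
    analysis and EFA of the human ratings, standardized-beta regressions
    of each human concept on all computational scores, and the full
    cross-loading structural model with its convergent paths.
    """
    from . import psychometrics as psy

    # a plain one-document-per-line summaries file carries no ids; when
    # the two tables share no doc_ids but have equal length, align rows
    # positionally (scores and ratings both follow the file order)
    if not set(table.doc_ids) & set(ratings.doc_ids):
        if len(table.doc_ids) != len(ratings.doc_ids):
            raise ValueError("score and rating tables share no doc_ids and "
                             "differ in length; cannot align")
        warnings.warn("score and rating tables share no doc_ids; aligning "
                      "rows positionally")
        scores = table.scores.copy()
        scores.index = pd.Index(ratings.doc_ids, name="doc_id")
        table = ScoreTable(scores, table.oov_rate.set_axis(scores.index),
                           table.flagged.set_axis(scores.index), table.meta)

    report: dict = {"icc": {}, "regressions": {}}
    for concept in ratings.concepts:
        try:
            r = psy.icc_two_way_mixed(ratings.rater_matrix(concept))
            report["icc"][concept] = round(r.icc, 6)
        except ValueError as e:
            report["icc"][concept] = f"undefined ({e})"
    try:
        report["icc"]["total"] = round(
            psy.icc_two_way_mixed(ratings.totals()).icc, 6)
    except ValueError as e:
        report["icc"]["total"] = f"undefined ({e})"

    wide = ratings.to_wide()
    try:
        pa = psy.parallel_analysis(wide.to_numpy(), seed=seed)
        report["parallel_analysis"] = {
            "n_factors": pa.n_factors_retained,
            "n_components": pa.n_components_retained,
        }
        n_fac = max(pa.n_factors_retained, 1)
    except ValueError as e:
        report["parallel_analysis"] = f"undefined ({e})"
        n_fac = len(ratings.concepts)
    n_fac = min(n_fac, wide.shape[1] - 1)
    try:
        ef = psy.efa(wide, n_fac)
        report["efa"] = {"n_factors": n_fac, "rmsea": round(ef.rmsea, 6),
                         "tli": round(ef.tli, 6), "rmsr": round(ef.rmsr, 6)}
    except Exception as e:                     # EFA may fail on tiny inputs
        warnings.warn(f"EFA failed: {e}")
        report["efa"] = None

    mean_hr = ratings.mean_ratings().loc[table.doc_ids]
    for concept in ratings.concepts:
        try:
            row = psy.standardized_regression(mean_hr[concept], table.scores)
            report["regressions"][concept] = {
                "beta": {k: round(v, 6) for k, v in row["beta"].items()},
                "r2": round(row["r2"], 6),
            }
        except ValueError as e:
            report["regressions"][concept] = f"undefined ({e})"

    try:
        structure = "bifactor" if table.meta.get("labels") and \
            "G" in table.meta["labels"] else "classic"
        sem = psy.fit_sem_crossloading(table, ratings, structure=structure,
                                       standard_errors=False)
        report["sem"] = {
            "structure": structure,
            "chi2": round(sem.fit.chi2, 4), "df": sem.fit.df,
            "cfi": round(sem.fit.cfi, 6), "tli": round(sem.fit.tli, 6),
            "rmsea": round(sem.fit.rmsea, 6), "srmr": round(sem.fit.srmr, 6),
            "convergent_paths": sem.convergent_paths,
        }
    except Exception as e:
        warnings.warn(f"SEM failed: {e}")
        report["sem"] = None
    return report
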