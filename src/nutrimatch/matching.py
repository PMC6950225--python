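"""Nutrient-profile, text, and fused similarity matching between two
food-composition databases.

Three similarity kinds are computed between every query food and every
target food:

* ``nutrient_pcc`` — (optionally weighted) Pearson correlation across the
  shared nutrient panel of the two records;
* ``text_cosine`` — cosine similarity of TF-IDF vectors over character
  n-grams of the food descriptions, with the first comma-separated chunk
  of each description repeated to reflect its greater importance;
* ``combined`` — the element-wise product of the two.

The top-k targets per query (default k = 5) are returned with the target's
lactose value transferred, so a nutrient absent from the query database can
be read off its best matches.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .data import FoodDatabase, IntegrityError, MatchEntry, MatchResult, NutrientSchema

logger = logging.getLogger(__name__)

__all__ = [
    "WeightVector",
    "SimilarityMatrix",
    "preprocess_description",
    "repeat_first_chunk",
    "DescriptionVectorizer",
    "cosine_similarity_matrix",
    "pearson_similarity_matrix",
    "combine_similarity",
    "top_k_matches",
    "FoodMatcher",
    "match_databases",
]


@dataclass
class WeightVector:
    """Non-negative per-nutrient weights for the Pearson similarity.

    Typically the absolute values of bounded-LASSO or bounded-Ridge
    regression coefficients; uniform weights reduce to the ordinary PCC.
    """

    values: np.ndarray
    origin: str = "user"  # {"uniform", "lasso", "ridge", "user"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("weights must be >= 0")
        if not np.any(self.values > 0):
            raise ValueError("at least one weight must be > 0")

    @classmethod
    def uniform(cls, schema: NutrientSchema) -> "WeightVector":
        return cls(values=np.ones(len(schema)), origin="uniform")

    @classmethod
    def from_coefficients(cls, coef, origin: str = "user") -> "WeightVector":
        """Weights as |coefficients| of a fitted linear model."""
        return cls(values=np.abs(np.asarray(coef, dtype=float)), origin=origin)


@dataclass
class SimilarityMatrix:
    """Queries-by-targets similarity scores; NaN marks undefined entries."""

    kind: str  # {"nutrient_pcc", "text_cosine", "combined"}
    query_ids: list[str]
    target_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_ids), len(self.target_ids)):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"({len(self.query_ids)}, {len(self.target_ids)}) ids"
            )

    @property
    def undefined_mask(self) -> np.ndarray:
        return np.isnan(self.values)


# ---------------------------------------------------------------------------
# text pipeline


def repeat_first_chunk(description: str, repeats: int) -> str:
    """Prepend ``repeats`` extra copies of the first comma-separated chunk."""
    chunks = description.split(",")
    if repeats <= 0 or not chunks or not chunks[0].strip():
        return description
    return ",".join([chunks[0]] * repeats + chunks)


def preprocess_description(
    description: str, chunk_repeats: int = 1, ngram_length: int = 3
) -> list[str]:
    """Tokenize a comma-structured food description into character n-grams.

    The description is split on commas; ``chunk_repeats`` extra copies of
    the first chunk are prepended (the first phrase carries the food
    identity).  Text is lowercased, punctuation is stripped from word
    boundaries (token-internal characters are kept), and each
    whitespace-delimited word is expanded into its within-word character
    n-grams; words shorter than ``ngram_length`` are emitted whole.
    N-grams never span whitespace.
    """
    if ngram_length < 1:
        raise ValueError("ngram_length must be >= 1")
    chunks = description.split(",")
    if chunks and chunks[0].strip():
        chunks = [chunks[0]] * chunk_repeats + chunks
    tokens: list[str] = []
    for word in " ".join(chunks).lower().split():
        word = word.strip(string.punctuation)
        if not word:
            continue
        if len(word) < ngram_length:
            tokens.append(word)
        else:
            tokens.extend(
                word[i : i + ngram_length]
                for i in range(len(word) - ngram_length + 1)
            )
    return tokens


class DescriptionVectorizer(TransformerMixin, BaseEstimator):
    """TF-IDF vectorizer over character n-grams of food descriptions.

    Variant: smoothed idf ``ln((1 + N)/(1 + df)) + 1`` with raw term counts
    and L2-normalized document vectors.  The vocabulary is corpus-dependent,
    so query and target descriptions must be vectorized by one fitted
    instance (fit on the joint corpus).
    """

    def __init__(self, chunk_repeats: int = 1, ngram_length: int = 3):
        self.chunk_repeats = chunk_repeats
        self.ngram_length = ngram_length

    def _analyze(self, doc: str) -> list[str]:
        return preprocess_description(doc, self.chunk_repeats, self.ngram_length)

    def fit(self, corpus: list[str], y=None) -> "DescriptionVectorizer":
        if len(corpus) == 0:
            raise ValueError("corpus must be non-empty")
        self.vectorizer_ = TfidfVectorizer(
            analyzer=self._analyze, norm="l2", smooth_idf=True, sublinear_tf=False
        )
        try:
            self.vectorizer_.fit(corpus)
        except ValueError as exc:  # only empty descriptions
            raise ValueError(
                "corpus yields no vocabulary (all descriptions empty?)"
            ) from exc
        self.vocabulary_ = self.vectorizer_.vocabulary_
        self.idf_ = self.vectorizer_.idf_
        return self

    def transform(self, docs: list[str]):
        return self.vectorizer_.transform(docs)


def cosine_similarity_matrix(
    query_vectors,
    target_vectors,
    query_ids: list[str],
    target_ids: list[str],
) -> SimilarityMatrix:
    """Cosine similarity between two sets of document vectors.

    Both sets must come from the same fitted vectorizer.  An all-zero
    vector (empty description) has similarity 0 to everything.
    """
    if query_vectors.shape[1] != target_vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: {query_vectors.shape[1]} vs "
            f"{target_vectors.shape[1]}"
        )
    values = _sk_cosine(query_vectors, target_vectors)
    return SimilarityMatrix(
        kind="text_cosine",
        query_ids=list(query_ids),
        target_ids=list(target_ids),
        values=np.clip(values, 0.0, 1.0),
    )


# ---------------------------------------------------------------------------
# nutrient pipeline


def _weighted_pearson(X: np.ndarray, Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All-pairs weighted Pearson correlation between rows of X and rows of Y.

    With weights w normalized to sum 1: m(x) = sum(w x),
    cov(x, y) = sum(w (x - m(x)) (y - m(y))), r = cov / sqrt(var var).
    Entries with zero weighted variance on either side are NaN (undefined).
    """
    w = w / w.sum()
    Xc = X - (X @ w)[:, None]
    Yc = Y - (Y @ w)[:, None]
    var_x = (Xc**2) @ w
    var_y = (Yc**2) @ w
    cov = (Xc * w) @ Yc.T
    # a constant vector has zero weighted variance; catastrophic cancellation
    # can leave a tiny positive residue, hence the relative tolerance
    tol_x = 1e-13 * ((X**2) @ w)
    tol_y = 1e-13 * ((Y**2) @ w)
    bad_x = var_x <= tol_x
    bad_y = var_y <= tol_y
    denom = np.sqrt(np.outer(np.where(bad_x, 1.0, var_x), np.where(bad_y, 1.0, var_y)))
    r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    r[bad_x, :] = np.nan
    r[:, bad_y] = np.nan
    return r


def pearson_similarity_matrix(
    query_db: FoodDatabase,
    target_db: FoodDatabase,
    weights: WeightVector | None = None,
) -> SimilarityMatrix:
    """Weighted Pearson correlation of nutrient profiles, all pairs.

    Each entry correlates the two per-100 g nutrient vectors across the
    shared panel.  Uniform (or omitted) weights give the ordinary PCC.
    A record whose nutrient vector is constant has no defined correlation;
    its entries are NaN and rank below every defined score.
    """
    if query_db.schema.names != target_db.schema.names:
        raise ValueError("query and target databases must share one nutrient schema")
    if weights is None:
        weights = WeightVector.uniform(query_db.schema)
    w = np.asarray(weights.values, dtype=float)
    if w.shape != (len(query_db.schema),):
        raise ValueError(
            f"weight vector length {w.shape} does not match schema "
            f"length {len(query_db.schema)}"
        )
    values = _weighted_pearson(
        query_db.nutrient_matrix(), target_db.nutrient_matrix(), w
    )
    return SimilarityMatrix(
        kind="nutrient_pcc",
        query_ids=query_db.ids,
        target_ids=target_db.ids,
        values=values,
    )


def combine_similarity(
    nutrient: SimilarityMatrix, text: SimilarityMatrix
) -> SimilarityMatrix:
    """Element-wise product of the nutrient-PCC and text-cosine matrices.

    Undefined nutrient entries stay undefined; a zero in either factor
    forces zero; negative combined scores are allowed and rank low.
    """
    if nutrient.kind != "nutrient_pcc" or text.kind != "text_cosine":
        raise ValueError("expected a nutrient_pcc and a text_cosine matrix")
    if (
        nutrient.query_ids != text.query_ids
        or nutrient.target_ids != text.target_ids
    ):
        raise ValueError("similarity matrices must share id orderings")
    return SimilarityMatrix(
        kind="combined",
        query_ids=nutrient.query_ids,
        target_ids=nutrient.target_ids,
        values=nutrient.values * text.values,
    )


def top_k_matches(
    sim: SimilarityMatrix, target_db: FoodDatabase, k: int = 5
) -> list[MatchResult]:
    """Per query, the k targets with the highest defined scores, descending.

    Ties are broken by target-table order (stable sort).  Undefined (NaN)
    entries are excluded; a query whose entries are all undefined yields an
    empty ranked list with a logged warning.  The target's lactose value is
    copied onto each match.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    results: list[MatchResult] = []
    for i, qid in enumerate(sim.query_ids):
        row = sim.values[i]
        defined = np.flatnonzero(~np.isnan(row))
        if defined.size == 0:
            logger.warning("query %s: all similarities undefined; no matches", qid)
            results.append(MatchResult(query_id=qid, ranked=[]))
            continue
        order = defined[np.argsort(-row[defined], kind="stable")][:k]
        ranked = []
        for j in order:
            rec = target_db.records[j]
            ranked.append(
                MatchEntry(
                    target_id=rec.food_id,
                    score=float(row[j]),
                    lactose_g=float("nan") if rec.lactose_g is None else rec.lactose_g,
                    description=rec.description,
                )
            )
        results.append(MatchResult(query_id=qid, ranked=ranked))
    return results


# ---------------------------------------------------------------------------
# estimator facade


class FoodMatcher(BaseEstimator):
    """Top-k food matcher against a fixed target database.

    Parameters
    ----------
    mode : {"nutrient", "nutrient_text"}
        Nutrient-only PCC matching, or PCC fused with TF-IDF text cosine.
    weights : WeightVector or None
        Per-nutrient weights for the PCC factor only (text is never
        weighted); None means uniform.
    k : int
        Matches returned per query.
    chunk_repeats, ngram_length : int
        Text-preprocessing settings (see :func:`preprocess_description`).
    symmetric_text : bool
        Whether target descriptions get the same first-chunk repetition as
        query descriptions.

    Nutrient-only results are independent of which other queries are in the
    batch; nutrient+text results depend on the joint corpus (the vectorizer
    is re-fit on query plus target descriptions at match time) but are
    deterministic for a fixed corpus.
    """

    def __init__(
        self,
        mode: str = "nutrient_text",
        weights: WeightVector | None = None,
        k: int = 5,
        chunk_repeats: int = 1,
        ngram_length: int = 3,
        symmetric_text: bool = True,
    ):
        self.mode = mode
        self.weights = weights
        self.k = k
        self.chunk_repeats = chunk_repeats
        self.ngram_length = ngram_length
        self.symmetric_text = symmetric_text

    def fit(self, target_db: FoodDatabase, y=None) -> "FoodMatcher":
        if self.mode not in ("nutrient", "nutrient_text"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.target_db_ = target_db
        return self

    def similarity(self, query_db: FoodDatabase) -> SimilarityMatrix:
        """The similarity matrix the ranking is based on."""
        nutrient = pearson_similarity_matrix(query_db, self.target_db_, self.weights)
        if self.mode == "nutrient":
            return nutrient
        q_docs = query_db.descriptions
        t_docs = self.target_db_.descriptions
        if self.symmetric_text:
            vec = DescriptionVectorizer(
                chunk_repeats=self.chunk_repeats, ngram_length=self.ngram_length
            )
            vec.fit(q_docs + t_docs)
            Q, T = vec.transform(q_docs), vec.transform(t_docs)
        else:
            # repetition applied to query descriptions only, as a document
            # preprocessing step in front of one shared vectorizer
            q_rep = [repeat_first_chunk(d, self.chunk_repeats) for d in q_docs]
            vec = DescriptionVectorizer(
                chunk_repeats=0, ngram_length=self.ngram_length
            )
            vec.fit(q_rep + t_docs)
            Q, T = vec.transform(q_rep), vec.transform(t_docs)
        text = cosine_similarity_matrix(Q, T, query_db.ids, self.target_db_.ids)
        self.vectorizer_ = vec
        return combine_similarity(nutrient, text)

    def match(self, query_db: FoodDatabase) -> list[MatchResult]:
        return top_k_matches(self.similarity(query_db), self.target_db_, self.k)


def match_databases(
    query_db: FoodDatabase,
    target_db: FoodDatabase,
    mode: str = "nutrient_text",
    weights: WeightVector | None = None,
    k: int = 5,
    chunk_repeats: int = 1,
    ngram_length: int = 3,
) -> list[MatchResult]:
    """One-shot convenience wrapper around :class:`FoodMatcher`."""
    matcher = FoodMatcher(
        mode=mode,
        weights=weights,
        k=k,
        chunk_repeats=chunk_repeats,
        ngram_length=ngram_length,
    )
    return matcher.fit(target_db).match(query_db)
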