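import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from nutrimatch.data import FoodDatabase, FoodRecord
from nutrimatch.matching import (
    DescriptionVectorizer,
    FoodMatcher,
    SimilarityMatrix,
    WeightVector,
    combine_similarity,
    cosine_similarity_matrix,
    pearson_similarity_matrix,
    preprocess_description,
    repeat_first_chunk,
    top_k_matches,
)

from conftest import make_db


# ---------------------------------------------------------------------------
# description preprocessing


def test_burger_three_grams():
    assert preprocess_description("burger", chunk_repeats=0) == [
        "bur", "urg", "rge", "ger"
    ]


def test_empty_description_gives_no_tokens():
    assert preprocess_description("", chunk_repeats=1) == []


def test_first_chunk_repetition_doubles_head_tokens():
    tokens = Counter(preprocess_description("Milk, whole", chunk_repeats=1))
    assert tokens == Counter(
        {"mil": 2, "ilk": 2, "who": 1, "hol": 1, "ole": 1}
    )


def test_short_words_emitted_whole_and_case_punctuation_folded():
    assert preprocess_description("An EGG!", chunk_repeats=0) == ["an", "egg"]


def test_ngrams_never_span_whitespace():
    tokens = preprocess_description("ab cd", chunk_repeats=0, ngram_length=3)
    assert tokens == ["ab", "cd"]


def test_repeat_first_chunk_is_equivalent_preprocessing():
    desc = "Milk, whole, with vitamin D"
    assert preprocess_description(desc, 2) == preprocess_description(
        repeat_first_chunk(desc, 2), 0
    )


# ---------------------------------------------------------------------------
# TF-IDF


def _tfidf_oracle(corpus, chunk_repeats=1, ngram_length=3):
    """Independent dict-based TF-IDF: idf = ln((1+N)/(1+df)) + 1, raw
    counts, L2 normalization."""
    token_lists = [
        preprocess_description(d, chunk_repeats, ngram_length) for d in corpus
    ]
    vocab = sorted({t for toks in token_lists for t in toks})
    N = len(corpus)
    df = {t: sum(t in toks for toks in token_lists) for t in vocab}
    idf = {t: math.log((1 + N) / (1 + df[t])) + 1.0 for t in vocab}
    vectors = []
    for toks in token_lists:
        counts = Counter(toks)
        v = np.array([counts[t] * idf[t] for t in vocab])
        norm = np.linalg.norm(v)
        vectors.append(v / norm if norm > 0 else v)
    return vocab, idf, np.array(vectors)


def test_tfidf_matches_hand_computation_on_toy_corpus():
    corpus = ["Milk, whole", "Milk, chocolate", "Lettuce, raw"]
    vec = DescriptionVectorizer().fit(corpus)
    vocab, idf, V = _tfidf_oracle(corpus)
    assert sorted(vec.vocabulary_) == vocab
    got = vec.transform(corpus).toarray()
    # re-order columns to the oracle's sorted vocabulary
    order = [vec.vocabulary_[t] for t in vocab]
    np.testing.assert_allclose(got[:, order], V, atol=1e-12)
    for t in vocab:
        assert vec.idf_[vec.vocabulary_[t]] == pytest.approx(idf[t], rel=1e-12)


def test_token_in_every_document_has_idf_one():
    corpus = ["mil", "mil x", "mil y"]
    vec = DescriptionVectorizer(chunk_repeats=0).fit(corpus)
    assert vec.idf_[vec.vocabulary_["mil"]] == pytest.approx(1.0)


def test_single_document_corpus_uniform_idf_and_unit_norm():
    vec = DescriptionVectorizer().fit(["Milk, whole"])
    assert np.allclose(vec.idf_, vec.idf_[0])
    v = vec.transform(["Milk, whole"]).toarray()[0]
    assert np.linalg.norm(v) == pytest.approx(1.0)


def test_identical_descriptions_have_identical_vectors():
    vec = DescriptionVectorizer().fit(["Milk, whole", "Lettuce, raw"])
    a, b = vec.transform(["Milk, whole", "Milk, whole"]).toarray()
    np.testing.assert_array_equal(a, b)


def test_corpus_of_empty_descriptions_is_an_error():
    with pytest.raises(ValueError, match="vocabulary|empty"):
        DescriptionVectorizer().fit(["", "  "])


# ---------------------------------------------------------------------------
# cosine similarity


def test_cosine_identical_and_disjoint():
    vec = DescriptionVectorizer().fit(["Milk, whole", "xyzq"])
    Q = vec.transform(["Milk, whole", "xyzq"])
    sim = cosine_similarity_matrix(Q, Q, ["a", "b"], ["a", "b"])
    assert sim.values[0, 0] == pytest.approx(1.0)
    assert sim.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_cosine_matches_double_loop_oracle(rng):
    Q = rng.random((5, 8))
    T = rng.random((4, 8))
    sim = cosine_similarity_matrix(Q, T, list("abcde"), list("wxyz"))
    for i in range(5):
        for j in range(4):
            expected = Q[i] @ T[j] / (np.linalg.norm(Q[i]) * np.linalg.norm(T[j]))
            assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_cosine_dimension_mismatch_errors(rng):
    with pytest.raises(ValueError, match="mismatch"):
        cosine_similarity_matrix(rng.random((2, 3)), rng.random((2, 4)), ["a", "b"], ["c", "d"])


# ---------------------------------------------------------------------------
# weighted Pearson


def test_identical_vector_gives_r_one(tiny_schema):
    q = make_db(tiny_schema, [("q", "x", [1.0, 5.0, 2.0])])
    t = make_db(tiny_schema, [("t", "x", [1.0, 5.0, 2.0])], source="target_db")
    sim = pearson_similarity_matrix(q, t)
    assert sim.values[0, 0] == pytest.approx(1.0)


def test_perfect_anticorrelation(tiny_schema):
    x = np.array([1.0, 5.0, 2.0])
    q = make_db(tiny_schema, [("q", "x", x)])
    t = make_db(tiny_schema, [("t", "x", 10.0 - x)], source="target_db")
    sim = pearson_similarity_matrix(q, t)
    assert sim.values[0, 0] == pytest.approx(-1.0)


def test_uniform_weights_reduce_to_plain_pcc(rng, tiny_schema):
    # 62-long vectors need a wide schema; use 20 pairs on a 10-nutrient panel
    from nutrimatch.data import NutrientSchema

    schema = NutrientSchema(names=tuple(f"N{i}" for i in range(10)))
    Q = rng.random((20, 10)) * 100
    T = rng.random((20, 10)) * 100
    qdb = make_db(schema, [(f"q{i}", "x", Q[i]) for i in range(20)])
    tdb = make_db(schema, [(f"t{i}", "x", T[i]) for i in range(20)], source="target_db")
    sim = pearson_similarity_matrix(qdb, tdb)
    for i in range(20):
        for j in range(20):
            expected = stats.pearsonr(Q[i], T[j]).statistic
            assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_weighted_pearson_matches_direct_formula_oracle(rng):
    from nutrimatch.data import NutrientSchema

    schema = NutrientSchema(names=tuple(f"N{i}" for i in range(8)))
    Q = rng.random((6, 8)) * 10
    T = rng.random((5, 8)) * 10
    w = rng.random(8) + 0.1
    qdb = make_db(schema, [(f"q{i}", "x", Q[i]) for i in range(6)])
    tdb = make_db(schema, [(f"t{i}", "x", T[i]) for i in range(5)], source="target_db")
    sim = pearson_similarity_matrix(qdb, tdb, WeightVector(values=w))
    wn = w / w.sum()
    for i in range(6):
        for j in range(5):
            mx, my = wn @ Q[i], wn @ T[j]
            cov = wn @ ((Q[i] - mx) * (T[j] - my))
            vx = wn @ (Q[i] - mx) ** 2
            vy = wn @ (T[j] - my) ** 2
            assert sim.values[i, j] == pytest.approx(
                cov / math.sqrt(vx * vy), abs=1e-12
            )


def test_constant_vector_is_undefined_and_ranks_last(tiny_schema):
    q = make_db(tiny_schema, [("q", "x", [5.0, 5.0, 5.0])])
    t = make_db(
        tiny_schema,
        [("t1", "x", [1.0, 2.0, 3.0]), ("t2", "x", [3.0, 1.0, 9.0])],
        source="target_db",
        lactose=[0.0, 0.0],
    )
    sim = pearson_similarity_matrix(q, t)
    assert np.isnan(sim.values).all()
    results = top_k_matches(sim, t, k=2)
    assert results[0].ranked == []


def test_affine_rescaling_per_nutrient_leaves_pcc_unchanged(rng, tiny_schema):
    from nutrimatch.data import NutrientSchema

    schema = NutrientSchema(names=tuple(f"N{i}" for i in range(6)))
    Q = rng.random((4, 6)) * 50
    T = rng.random((3, 6)) * 50
    scale = rng.random(6) * 5 + 0.5
    qdb = make_db(schema, [(f"q{i}", "x", Q[i]) for i in range(4)])
    tdb = make_db(schema, [(f"t{i}", "x", T[i]) for i in range(3)], source="target_db")
    qdb2 = make_db(schema, [(f"q{i}", "x", Q[i] * scale) for i in range(4)])
    tdb2 = make_db(schema, [(f"t{i}", "x", T[i] * scale) for i in range(3)], source="target_db")
    s1 = pearson_similarity_matrix(qdb, tdb)
    s2 = pearson_similarity_matrix(qdb2, tdb2)
    # correlation across nutrients is NOT invariant to per-nutrient scaling
    # in general; it IS invariant when both sides share a common positive
    # affine transform applied to whole vectors
    a, b = 3.7, 11.0
    qdb3 = make_db(schema, [(f"q{i}", "x", a * Q[i] + b) for i in range(4)])
    tdb3 = make_db(schema, [(f"t{i}", "x", a * T[i] + b) for i in range(3)], source="target_db")
    s3 = pearson_similarity_matrix(qdb3, tdb3)
    np.testing.assert_allclose(s3.values, s1.values, atol=1e-10)
    assert s1.values.shape == s2.values.shape


# ---------------------------------------------------------------------------
# fusion and ranking


def _sim(kind, values, qids=None, tids=None):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(
        kind=kind,
        query_ids=qids or [f"q{i}" for i in range(values.shape[0])],
        target_ids=tids or [f"t{j}" for j in range(values.shape[1])],
        values=values,
    )


@pytest.mark.parametrize(
    "n, t, expected",
    [(0.8, 0.5, 0.4), (0.9, 0.0, 0.0), (-0.2, 0.5, -0.1)],
)
def test_combine_is_elementwise_product(n, t, expected):
    combined = combine_similarity(
        _sim("nutrient_pcc", [[n]]), _sim("text_cosine", [[t]])
    )
    assert combined.values[0, 0] == pytest.approx(expected)
    assert combined.kind == "combined"


def test_combine_preserves_undefined_and_checks_ids():
    combined = combine_similarity(
        _sim("nutrient_pcc", [[np.nan, 0.5]]), _sim("text_cosine", [[0.9, 0.5]])
    )
    assert np.isnan(combined.values[0, 0]) and combined.values[0, 1] == 0.25
    with pytest.raises(ValueError, match="id"):
        combine_similarity(
            _sim("nutrient_pcc", [[0.5]], tids=["t0"]),
            _sim("text_cosine", [[0.5]], tids=["other"]),
        )


def test_top_k_tie_broken_by_target_order(tiny_schema):
    tdb = make_db(
        tiny_schema,
        [(f"t{j}", "x", [1.0, 2.0, float(j + 1)]) for j in range(4)],
        source="target_db",
        lactose=[0.0, 1.0, 2.0, 3.0],
    )
    sim = _sim("nutrient_pcc", [[0.9, 0.2, 0.9, 0.5]], qids=["q"], tids=tdb.ids)
    res = top_k_matches(sim, tdb, k=2)
    assert [e.target_id for e in res[0].ranked] == ["t0", "t2"]


def test_top_k_with_fewer_targets_than_k(tiny_schema):
    tdb = make_db(
        tiny_schema,
        [(f"t{j}", "x", [1.0, 2.0, float(j + 1)]) for j in range(3)],
        source="target_db",
        lactose=[0.0, 1.0, 2.0],
    )
    sim = _sim("nutrient_pcc", [[0.1, 0.5, 0.3]], qids=["q"], tids=tdb.ids)
    res = top_k_matches(sim, tdb, k=5)
    assert [e.target_id for e in res[0].ranked] == ["t1", "t2", "t0"]
    assert [e.lactose_g for e in res[0].ranked] == [1.0, 2.0, 0.0]


def test_top_k_matches_full_sort_oracle(rng, tiny_schema):
    tdb = make_db(
        tiny_schema,
        [(f"t{j:02d}", "x", [1.0, 2.0, float(j + 1)]) for j in range(50)],
        source="target_db",
        lactose=list(range(50)),
    )
    values = rng.random((10, 50))
    sim = _sim("combined", values, tids=tdb.ids)
    res = top_k_matches(sim, tdb, k=5)
    for i, r in enumerate(res):
        expected = [tdb.ids[j] for j in np.argsort(-values[i], kind="stable")[:5]]
        assert [e.target_id for e in r.ranked] == expected
        assert all(
            a.score >= b.score for a, b in zip(r.ranked, r.ranked[1:])
        )


# ---------------------------------------------------------------------------
# matcher-level invariants


def _paired_dbs(rng, n=12):
    from nutrimatch.data import NutrientSchema

    schema = NutrientSchema(names=tuple(f"N{i}" for i in range(10)))
    Q = rng.random((n, 10)) * 100
    heads = ["Milk", "Rice", "Apple", "Cheese"]
    qrows = [
        (f"q{i}", f"{heads[i % 4]}, variant {i}", Q[i]) for i in range(n)
    ]
    trows = [
        (f"t{i}", f"{heads[i % 4]}, variant {i}", Q[i] * (1 + 0.01 * rng.standard_normal(10)))
        for i in range(n)
    ]
    qdb = make_db(schema, qrows)
    tdb = make_db(schema, trows, source="target_db", lactose=[float(i) for i in range(n)])
    return qdb, tdb


def test_nutrient_only_results_are_batch_independent(rng):
    qdb, tdb = _paired_dbs(rng)
    full = FoodMatcher(mode="nutrient").fit(tdb).match(qdb)
    sub_db = FoodDatabase(schema=qdb.schema, records=[qdb.records[3]], source="query_db")
    solo = FoodMatcher(mode="nutrient").fit(tdb).match(sub_db)
    assert [e.target_id for e in solo[0].ranked] == [
        e.target_id for e in full[3].ranked
    ]
    assert [e.score for e in solo[0].ranked] == pytest.approx(
        [e.score for e in full[3].ranked], rel=1e-12
    )


def test_nutrient_text_deterministic_for_fixed_corpus(rng):
    qdb, tdb = _paired_dbs(rng)
    r1 = FoodMatcher(mode="nutrient_text").fit(tdb).match(qdb)
    r2 = FoodMatcher(mode="nutrient_text").fit(tdb).match(qdb)
    for a, b in zip(r1, r2):
        assert [e.target_id for e in a.ranked] == [e.target_id for e in b.ranked]
        assert [e.score for e in a.ranked] == [e.score for e in b.ranked]


def test_permuting_targets_permutes_columns_consistently(rng):
    qdb, tdb = _paired_dbs(rng)
    perm = rng.permutation(len(tdb))
    tdb_perm = FoodDatabase(
        schema=tdb.schema, records=[tdb.records[j] for j in perm], source="target_db"
    )
    s1 = pearson_similarity_matrix(qdb, tdb)
    s2 = pearson_similarity_matrix(qdb, tdb_perm)
    np.testing.assert_allclose(s2.values, s1.values[:, perm], atol=1e-12)
    r1 = top_k_matches(s1, tdb, k=3)
    r2 = top_k_matches(s2, tdb_perm, k=3)
    for a, b in zip(r1, r2):
        assert [e.target_id for e in a.ranked] == [e.target_id for e in b.ranked]
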