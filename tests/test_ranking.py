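"""BM25 / PL2 term weights against closed-form oracles, and retrieval."""

import math

import numpy as np
import pytest

from patentsearch.index import CollectionStats, IndexConfig, build_index
from patentsearch.ranking import (
    EmptyQueryError,
    OutOfVocabularyError,
    Query,
    RankingParams,
    bm25_term_weight,
    pl2_term_weight,
    retrieve,
    score_document_bruteforce,
)

BM25 = RankingParams(model="BM25")
PL2 = RankingParams(model="PL2")


def _stats(N=10, avdl=100.0):
    return CollectionStats(N=N, avdl=avdl)


class TestBM25:
    def test_matches_direct_formula_evaluation(self):
        # independent oracle: idf * (k1+1)*tf / (k1*((1-b)+b*dl/avdl)+tf)
        stats = _stats(N=10, avdl=50.0)
        expected = math.log(8.5 / 2.5) * (2.2 * 3) / (1.2 * 1.0 + 3)
        got = bm25_term_weight(tf=3, df=2, dl=50.0, stats=stats, params=BM25)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.9231, abs=5e-5)

    def test_idf_floor_zeroes_common_terms(self):
        stats = _stats(N=2, avdl=10.0)
        assert bm25_term_weight(tf=5, df=1, dl=10.0, stats=stats, params=BM25) == 0.0
        stats = _stats(N=10, avdl=10.0)
        assert bm25_term_weight(tf=5, df=9, dl=10.0, stats=stats, params=BM25) == 0.0

    def test_monotone_in_tf_and_saturating(self):
        stats = _stats(N=100, avdl=20.0)
        weights = [
            bm25_term_weight(tf, df=5, dl=20.0, stats=stats, params=BM25)
            for tf in range(1, 200)
        ]
        assert all(b > a for a, b in zip(weights, weights[1:]))
        idf = math.log((100 - 5 + 0.5) / 5.5)
        bound = idf * (BM25.k1 + 1)
        assert all(w < bound for w in weights)
        assert weights[-1] > 0.95 * bound

    def test_non_increasing_in_df(self):
        stats = _stats(N=100, avdl=20.0)
        weights = [
            bm25_term_weight(tf=2, df=df, dl=20.0, stats=stats, params=BM25)
            for df in range(1, 100)
        ]
        assert all(b <= a for a, b in zip(weights, weights[1:]))

    def test_invalid_inputs_rejected(self):
        stats = _stats(N=10, avdl=20.0)
        with pytest.raises(ValueError):
            bm25_term_weight(tf=0, df=2, dl=20.0, stats=stats, params=BM25)
        with pytest.raises(ValueError):
            bm25_term_weight(tf=1, df=11, dl=20.0, stats=stats, params=BM25)


class TestPL2:
    def test_matches_direct_formula_evaluation(self):
        # tfn=2 (dl=avdl, c=1), lambda=0.04
        stats = _stats(N=100, avdl=30.0)
        lam = 4 / 100
        tfn = 2.0
        expected = (1 / (tfn + 1)) * (
            tfn * math.log2(tfn / lam)
            + (lam + 1 / (12 * tfn) - tfn) * math.log2(math.e)
            + 0.5 * math.log2(2 * math.pi * tfn)
        )
        got = pl2_term_weight(tf=2, cf=4, dl=30.0, stats=stats, params=PL2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(3.4486, abs=5e-5)

    def test_tfn_equals_tf_at_avdl_with_unit_c(self):
        # at dl=avdl and c=1 the normalization is log2(2)=1, so the score
        # reduces to the un-normalized Poisson form with tfn=tf
        stats = _stats(N=1000, avdl=80.0)
        for tf in (1, 2, 7):
            lam = 5 / 1000
            tfn = float(tf)
            expected = (1 / (tfn + 1)) * (
                tfn * math.log2(tfn / lam)
                + (lam + 1 / (12 * tfn) - tfn) * math.log2(math.e)
                + 0.5 * math.log2(2 * math.pi * tfn)
            )
            assert pl2_term_weight(tf, cf=5, dl=80.0, stats=stats, params=PL2) == pytest.approx(
                expected, rel=1e-12
            )

    def test_longer_documents_score_lower(self):
        stats = _stats(N=100, avdl=50.0)
        weights = [
            pl2_term_weight(tf=3, cf=10, dl=dl, stats=stats, params=PL2)
            for dl in (10.0, 50.0, 200.0, 1000.0)
        ]
        assert all(b < a for a, b in zip(weights, weights[1:]))

    def test_rarer_terms_weigh_more_below_the_poisson_mode(self):
        # for lambda <= tfn the contribution decreases as the term gets more
        # common in the collection (rarer = more informative); no floor or
        # clamp is applied to the formula value
        stats = _stats(N=1000, avdl=40.0)
        weights = [
            pl2_term_weight(tf=3, cf=cf, dl=40.0, stats=stats, params=PL2)
            for cf in (1, 10, 100, 1000, 2500)
        ]
        assert all(b < a for a, b in zip(weights, weights[1:]))


class TestRetrieve:
    def test_unique_term_ranks_its_document_first(self, synth_corpus, synth_index):
        # pick a term occurring in exactly one document
        term = next(t for t, p in synth_index.postings.items() if len(p) == 1)
        doc_id = synth_index.postings[term][0][0]
        out = retrieve(synth_index, Query(terms={term: 1}), BM25)
        assert out.items[0][0] == doc_id

    def test_cutoff_k(self, synth_index):
        term = max(synth_index.postings, key=lambda t: synth_index.stats.df[t])
        params = RankingParams(model="BM25", k=1)
        out = retrieve(synth_index, Query(terms={term: 1}), params)
        assert len(out) <= 1

    def test_empty_vs_oov_queries_distinguished(self, synth_index):
        with pytest.raises(EmptyQueryError):
            retrieve(synth_index, Query(terms={}), BM25)
        with pytest.raises(OutOfVocabularyError):
            retrieve(synth_index, Query(terms={"zzzznotaterm": 1}), BM25)

    def test_results_strictly_sorted_with_id_tiebreak(self, synth_index):
        term = max(synth_index.postings, key=lambda t: synth_index.stats.df[t])
        out = retrieve(synth_index, Query(terms={term: 2}), BM25)
        for (d1, s1), (d2, s2) in zip(out.items, out.items[1:]):
            assert s1 > s2 or (s1 == s2 and d1 < d2)
        assert len(set(out.doc_ids())) == len(out)

    def test_deterministic(self, synth_index):
        terms = dict.fromkeys(list(synth_index.postings)[:20], 1)
        a = retrieve(synth_index, Query(terms=terms), PL2)
        b = retrieve(synth_index, Query(terms=terms), PL2)
        assert a.items == b.items

    @pytest.mark.parametrize("params", [BM25, PL2], ids=["bm25", "pl2"])
    def test_scores_match_bruteforce_oracle(self, synth_index, params):
        rng = np.random.default_rng(11)
        vocab = sorted(synth_index.postings)
        for _ in range(10):
            n_terms = int(rng.integers(1, 8))
            picks = rng.choice(len(vocab), size=n_terms, replace=False)
            query = Query(terms={vocab[i]: int(rng.integers(1, 4)) for i in picks})
            out = retrieve(synth_index, query, params)
            for doc_id, score in out.items:
                oracle = score_document_bruteforce(query, doc_id, synth_index, params)
                assert score == pytest.approx(oracle, rel=1e-9)

    def test_bruteforce_unknown_document_errors(self, synth_index):
        with pytest.raises(KeyError):
            score_document_bruteforce(Query(terms={"x": 1}), "NOPE", synth_index, BM25)

    def test_absent_term_contributes_zero(self, synth_index):
        doc_id = next(iter(synth_index.doc_lengths))
        q = Query(terms={"zzzznotaterm": 1})
        assert score_document_bruteforce(q, doc_id, synth_index, BM25) == 0.0
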