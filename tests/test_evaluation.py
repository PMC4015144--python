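"""Retrieval metrics against definition oracles; sign-flip randomization test."""

import itertools

import numpy as np
import pytest

from patentsearch.evaluation import (
    average_precision,
    evaluate_run,
    paired_randomization_test,
    precision_at_1,
    reciprocal_rank,
)
from patentsearch.ranking import RankedResultList


def _ranked(doc_ids):
    n = len(doc_ids)
    return RankedResultList("Q", [(d, float(n - i)) for i, d in enumerate(doc_ids)])


def _ranked_with_relevant_at(positions, length=120):
    """Ranked list with relevant docs at the given 1-based positions."""
    docs = [f"N{i:04d}" for i in range(length)]
    for j, pos in enumerate(positions):
        docs[pos - 1] = f"REL{j}"
    return _ranked(docs), {f"REL{j}" for j in range(len(positions))}


class TestReciprocalRank:
    def test_definition(self):
        ranked, rel = _ranked_with_relevant_at([4])
        assert reciprocal_rank(ranked, rel) == 0.25
        ranked, rel = _ranked_with_relevant_at([1])
        assert reciprocal_rank(ranked, rel) == 1.0

    def test_no_relevant_retrieved(self):
        assert reciprocal_rank(_ranked(["A", "B"]), {"Z"}) == 0.0

    def test_cutoff_hides_deep_hits(self):
        ranked, rel = _ranked_with_relevant_at([50])
        assert reciprocal_rank(ranked, rel, cutoff=10) == 0.0


class TestAveragePrecision:
    def test_two_relevant_deep_positions(self):
        # a prior-art topic whose two relevant patents sit deep in the list
        ranked, rel = _ranked_with_relevant_at([39, 97])
        assert average_precision(ranked, rel) == pytest.approx(
            (1 / 39 + 2 / 97) / 2
        )
        assert 100 * average_precision(ranked, rel) == pytest.approx(2.31, abs=0.005)

    def test_two_relevant_boosted_to_top(self):
        ranked, rel = _ranked_with_relevant_at([2, 3])
        assert average_precision(ranked, rel) == pytest.approx((1 / 2 + 2 / 3) / 2)
        assert 100 * average_precision(ranked, rel) == pytest.approx(58.33, abs=0.005)

    def test_perfect_ranking_is_one(self):
        ranked, rel = _ranked_with_relevant_at([1, 2, 3])
        assert average_precision(ranked, rel) == 1.0

    def test_empty_relevant_set_rejected(self):
        with pytest.raises(ValueError):
            average_precision(_ranked(["A"]), set())

    def test_unretrieved_relevant_contribute_zero(self):
        ranked, _ = _ranked_with_relevant_at([1])
        assert average_precision(ranked, {"REL0", "NEVER"}) == pytest.approx(0.5)


def _oracle_metrics(doc_ids, relevant, cutoff):
    """Exhaustive-definition oracle: walk every position and apply the
    textbook definitions directly."""
    rr = 0.0
    for i, d in enumerate(doc_ids[:cutoff]):
        if d in relevant:
            rr = 1.0 / (i + 1)
            break
    ap_sum = 0.0
    for i, d in enumerate(doc_ids[:cutoff]):
        if d in relevant:
            n_rel_upto = sum(1 for x in doc_ids[: i + 1] if x in relevant)
            ap_sum += n_rel_upto / (i + 1)
    ap = ap_sum / len(relevant) if relevant else None
    p1 = 1.0 if doc_ids[:1] and doc_ids[0] in relevant else 0.0
    return rr, ap, p1


def test_metrics_agree_with_exhaustive_oracle_on_random_cases():
    rng = np.random.default_rng(1234)
    pool = [f"D{i}" for i in range(30)]
    for _ in range(1000):
        n = int(rng.integers(1, 21))
        docs = list(rng.choice(pool, size=n, replace=False))
        n_rel = int(rng.integers(1, 6))
        relevant = set(rng.choice(pool, size=n_rel, replace=False))
        cutoff = int(rng.integers(1, 25))
        ranked = _ranked(docs)
        rr_o, ap_o, p1_o = _oracle_metrics(docs, relevant, cutoff)
        assert reciprocal_rank(ranked, relevant, cutoff) == pytest.approx(rr_o)
        assert average_precision(ranked, relevant, cutoff) == pytest.approx(ap_o)
        assert precision_at_1(ranked, relevant) == pytest.approx(p1_o)


def test_ap_equals_rr_for_single_relevant():
    rng = np.random.default_rng(7)
    pool = [f"D{i}" for i in range(40)]
    for _ in range(200):
        n = int(rng.integers(1, 30))
        docs = list(rng.choice(pool, size=n, replace=False))
        relevant = {str(rng.choice(pool))}
        ranked = _ranked(docs)
        assert average_precision(ranked, relevant) == reciprocal_rank(ranked, relevant)


class TestEvaluateRun:
    def test_single_topic_perfect(self):
        runs = {"Q1": _ranked(["R", "X"])}
        report = evaluate_run(runs, {"Q1": {"R"}})
        assert report.p0 == report.map == report.p_at_1 == 1.0
        assert report.n_topics == 1

    def test_mean_over_topics(self):
        ranked_a, rel_a = _ranked_with_relevant_at([2])
        ranked_b, rel_b = _ranked_with_relevant_at([4])
        runs = {"Q1": ranked_a, "Q2": ranked_b}
        report = evaluate_run(runs, {"Q1": rel_a, "Q2": rel_b})
        assert report.p0 == pytest.approx((0.5 + 0.25) / 2)

    def test_empty_qrels_topic_excluded_but_counted(self):
        runs = {"Q1": _ranked(["R"]), "Q2": _ranked(["X"])}
        report = evaluate_run(runs, {"Q1": {"R"}, "Q2": set()})
        assert report.n_topics == 1 and report.n_excluded == 1
        assert report.p0 == 1.0

    def test_topic_missing_from_qrels_errors(self):
        with pytest.raises(ValueError, match="Q9"):
            evaluate_run({"Q9": _ranked(["A"])}, {})

    def test_known_item_map_equals_p0(self, synth_corpus, synth_index):
        from patentsearch.bench import build_known_item_benchmark
        from patentsearch.pipeline import run_search

        topics, qrels = build_known_item_benchmark(synth_corpus, n_topics=30, seed=2)
        runs = run_search(synth_index, synth_corpus, topics)
        report = evaluate_run(runs, qrels)
        assert report.map == pytest.approx(report.p0)
        for m in report.per_topic.values():
            assert m["ap"] == m["rr"]


class TestPairedRandomizationTest:
    def test_all_zero_differences_give_p_one(self):
        assert paired_randomization_test([0.3, 0.4], [0.3, 0.4]) == 1.0

    def test_five_equal_positive_deltas_exact(self):
        a = [1.0] * 5
        b = [0.0] * 5
        assert paired_randomization_test(a, b) == pytest.approx(2 / 32)

    def test_n_one_gives_p_one(self):
        assert paired_randomization_test([0.9], [0.1]) == 1.0

    def test_exact_matches_independent_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.normal(size=8)
            a = list(d)
            b = [0.0] * 8
            obs = abs(d.mean())
            count = sum(
                1
                for signs in itertools.product([1, -1], repeat=8)
                if abs(np.mean(d * np.array(signs))) >= obs - 1e-12
            )
            assert paired_randomization_test(a, b) == pytest.approx(count / 256)

    def test_monte_carlo_agrees_with_exact_within_3_se(self):
        # n=21 exceeds the exact-enumeration threshold, so the implementation
        # takes the Monte-Carlo path; an independent full enumeration of all
        # 2^21 sign patterns provides the reference p-value
        rng = np.random.default_rng(9)
        d = rng.normal(0.2, 1.0, size=21)
        a, b = list(d), [0.0] * 21
        n_perm = 20000
        p_mc = paired_randomization_test(a, b, n_permutations=n_perm, seed=3)
        p_ref = _exact_p(d)
        se = np.sqrt(p_ref * (1 - p_ref) / n_perm)
        assert abs(p_mc - p_ref) <= 3 * se + 2 / n_perm

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_randomization_test([1.0], [1.0, 2.0])


def _exact_p(d):
    """Independent exact enumeration (supports n up to ~25 via numpy bits)."""
    n = d.size
    obs = abs(d.mean())
    masks = np.arange(1 << n, dtype=np.uint64)
    count = 0
    chunk = 1 << 16
    for start in range(0, 1 << n, chunk):
        m = masks[start : start + chunk]
        bits = (m[:, None] >> np.arange(n, dtype=np.uint64)) & 1
        stats = np.abs(((1.0 - 2.0 * bits) * d).mean(axis=1))
        count += int(np.sum(stats >= obs - 1e-12))
    return count / (1 << n)
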