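"""Retrieval metrics and paired significance testing.

Metrics use 1-based ranks internally.  P0 (top-precision) is the mean
reciprocal rank over topics; MAP is the mean of non-interpolated average
precision computed over the top ``cutoff`` (default 1000) results.  For a
topic with a single relevant document, AP equals RR exactly, which is why
the known-item benchmark reports only P0.

Significance between two tunings is assessed with a two-sided paired
sign-flip randomization test on the mean per-topic difference: exact
enumeration of all 2^n sign assignments when n <= 20, otherwise seeded
Monte Carlo with the observed assignment always counted (so p >= 1/(B+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bench import Qrels
from .ranking import RankedResultList

__all__ = [
    "EvalReport",
    "reciprocal_rank",
    "average_precision",
    "precision_at_1",
    "evaluate_run",
    "paired_randomization_test",
]


@dataclass
class EvalReport:
    """Per-topic and mean retrieval metrics for one run."""

    per_topic: dict[str, dict[str, float]] = field(default_factory=dict)
    p0: float = 0.0  # mean reciprocal rank
    map: float = 0.0  # mean average precision
    p_at_1: float = 0.0
    n_topics: int = 0
    n_excluded: int = 0  # topics with empty qrels, left out of the means
    cutoff: int = 1000

    def metric_vector(self, metric: str) -> list[float]:
        """Per-topic values of one metric, in topic order (for paired tests)."""
        return [m[metric] for m in self.per_topic.values()]


def reciprocal_rank(
    ranked: RankedResultList, relevant: set[str], cutoff: int = 1000
) -> float:
    """1/r for the first relevant document at 1-based rank r <= cutoff, else 0."""
    for pos, (doc_id, _) in enumerate(ranked.items[:cutoff], start=1):
        if doc_id in relevant:
            return 1.0 / pos
    return 0.0


def average_precision(
    ranked: RankedResultList, relevant: set[str], cutoff: int = 1000
) -> float:
    """Non-interpolated AP over the top ``cutoff`` results.

    AP = (1/R) * sum over relevant docs retrieved at 1-based positions
    p <= cutoff of (relevant seen up to p)/p; unretrieved relevant documents
    contribute zero.  Raises on an empty relevant set (the topic must be
    excluded upstream).
    """
    if not relevant:
        raise ValueError("average precision is undefined for an empty relevant set")
    hits = 0
    total = 0.0
    for pos, (doc_id, _) in enumerate(ranked.items[:cutoff], start=1):
        if doc_id in relevant:
            hits += 1
            total += hits / pos
    return total / len(relevant)


def precision_at_1(ranked: RankedResultList, relevant: set[str]) -> float:
    if not ranked.items:
        return 0.0
    return 1.0 if ranked.items[0][0] in relevant else 0.0


def evaluate_run(
    runs: dict[str, RankedResultList], qrels: Qrels, cutoff: int = 1000
) -> EvalReport:
    """Evaluate a run against qrels; topics with empty qrels are excluded
    from the means (AP is undefined there) but counted in ``n_excluded``."""
    report = EvalReport(cutoff=cutoff)
    for qid, ranked in runs.items():
        if qid not in qrels:
            raise ValueError(f"run topic {qid} missing from qrels")
        relevant = qrels[qid]
        if not relevant:
            report.n_excluded += 1
            continue
        report.per_topic[qid] = {
            "rr": reciprocal_rank(ranked, relevant, cutoff),
            "ap": average_precision(ranked, relevant, cutoff),
            "p1": precision_at_1(ranked, relevant),
        }
    report.n_topics = len(report.per_topic)
    if report.n_topics:
        report.p0 = float(np.mean(report.metric_vector("rr")))
        report.map = float(np.mean(report.metric_vector("ap")))
        report.p_at_1 = float(np.mean(report.metric_vector("p1")))
    return report


def paired_randomization_test(
    per_topic_a: list[float],
    per_topic_b: list[float],
    n_permutations: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided paired sign-flip randomization p-value on the mean difference.

    Exact (all 2^n sign patterns) for n <= 20; otherwise seeded Monte Carlo
    including the observed assignment.  All-zero differences give p = 1.
    """
    a = np.asarray(per_topic_a, dtype=float)
    b = np.asarray(per_topic_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("metric vectors must be 1-D, non-empty and the same length")
    d = a - b
    n = d.size
    observed = abs(d.mean())
    tol = 1e-12 * max(1.0, observed)
    if n <= 20:
        # exact enumeration of all sign assignments, in vectorized chunks
        total = 1 << n
        count = 0
        bit_positions = np.arange(n, dtype=np.uint32)
        chunk_size = 1 << 16
        for start in range(0, total, chunk_size):
            masks = np.arange(start, min(start + chunk_size, total), dtype=np.uint32)
            bits = (masks[:, None] >> bit_positions) & 1
            signs = 1.0 - 2.0 * bits
            stats = np.abs((signs * d).mean(axis=1))
            count += int(np.sum(stats >= observed - tol))
        return count / total
    rng = np.random.default_rng(seed)
    flips = rng.choice([1.0, -1.0], size=(n_permutations, n))
    stats = np.abs((flips * d).mean(axis=1))
    count = int(np.sum(stats >= observed - tol))
    return (count + 1) / (n_permutations + 1)
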