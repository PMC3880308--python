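"""Scoring ranked rule lists against a ground-truth set of category links.

The ground truth is a set of unordered cross-hierarchy category pairs (a
partial gold-standard mapping); a directed rule matches when its unordered
item pair is in the truth set, so the two directions of a rule can never be
double-counted.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .mining import Item, Rule, pair_key

__all__ = [
    "GroundTruth",
    "EvalReport",
    "f1_at_k",
    "best_possible_f1",
    "median_abs_support",
    "rule_set_intersection",
]


@dataclass
class GroundTruth:
    """Unordered true category pairs, each a pair of (ontology, category)."""

    pairs: set

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[Item, Item]]) -> "GroundTruth":
        return cls({pair_key(Item(*a), Item(*b)) for a, b in pairs})

    def __len__(self) -> int:
        return len(self.pairs)

    def matches(self, rule: Rule) -> bool:
        return rule.pair in self.pairs


@dataclass
class EvalReport:
    """Collected comparison statistics for one or more ranked rule lists."""

    k: int = 0
    true_found_at_k: int = 0
    f1_at_k: float = 0.0
    best_possible: tuple[int, int, float] = (0, 0, 0.0)
    median_abs_support: dict = field(default_factory=dict)
    intersections: dict = field(default_factory=dict)


def _f1(true_found: int, k: int, n_truth: int) -> float:
    if k == 0 or n_truth == 0 or true_found == 0:
        return 0.0
    precision = true_found / k
    recall = true_found / n_truth
    return 100.0 * 2 * precision * recall / (precision + recall)


def f1_at_k(ranked: Sequence[Rule], truth: GroundTruth, k: int) -> tuple[int, float]:
    """True rules among the top ``k`` and the corresponding F-1 in percent.

    Precision is taken over the k retained rules and recall over the full
    truth set; by convention k is often set to the truth-set size, making
    precision and recall coincide.
    """
    if not truth.pairs:
        raise ValueError("empty ground truth")
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranking length {len(ranked)}")
    true_found = sum(1 for r in ranked[:k] if truth.matches(r))
    return true_found, _f1(true_found, k, len(truth))


def best_possible_f1(ranked: Sequence[Rule], truth: GroundTruth) -> tuple[int, int, float]:
    """Best F-1 over all prefixes of the ranking.

    Equivalent to iteratively dropping the lowest-ranked rule and
    re-scoring: returns ``(prefix size, true rules found, F-1 %)`` for the
    prefix maximizing F-1, preferring the smaller prefix on ties.
    """
    if not truth.pairs:
        raise ValueError("empty ground truth")
    n_truth = len(truth)
    best = (0, 0, 0.0)
    true_found = 0
    for k, rule in enumerate(ranked, start=1):
        if truth.matches(rule):
            true_found += 1
        f1 = _f1(true_found, k, n_truth)
        if f1 > best[2] + 1e-12:
            best = (k, true_found, f1)
    return best


def median_abs_support(rules: Sequence[Rule]) -> float:
    """Median co-occurrence count of a rule subset (midpoint on even sizes)."""
    if not rules:
        raise ValueError("empty rule subset")
    return statistics.median(r.n_ab for r in rules)


def rule_set_intersection(
    ranked_a: Sequence[Rule], ranked_b: Sequence[Rule], top_n: int = 500
) -> int:
    """Common unordered pairs among the top ``top_n`` of two rankings.

    A list shorter than ``top_n`` contributes its full length.
    """
    pairs_a = {r.pair for r in ranked_a[:top_n]}
    pairs_b = {r.pair for r in ranked_b[:top_n]}
    return len(pairs_a & pairs_b)
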