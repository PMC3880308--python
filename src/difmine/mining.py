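"""Pairwise co-occurrence counting and candidate rule generation.

Rules here are pairwise generalized association rules: one item from each
(or the same) hierarchy, mined with a minimum absolute support of a single
co-occurrence so that rare associations survive to the ranking stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, NamedTuple, Optional, Sequence

from .annotations import AnnotationStore
from .ontology import Ontology

__all__ = [
    "Item",
    "SupportTable",
    "Rule",
    "count_pair_supports",
    "generate_rules",
    "rank_rules",
    "direction_select",
]


class Item(NamedTuple):
    """A category addressed as (ontology_id, category_id)."""

    ontology: str
    category: str


def pair_key(a: Item, b: Item) -> tuple[Item, Item]:
    """Canonical unordered key for an item pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class SupportTable:
    """Absolute counts behind every measure: n(a), n(b), n(a,b) and N."""

    N: int
    item_counts: dict[Item, int]
    pair_counts: dict[tuple[Item, Item], int]

    def item_count(self, item: Item) -> int:
        return self.item_counts.get(item, 0)

    def pair_count(self, a: Item, b: Item) -> int:
        return self.pair_counts.get(pair_key(a, b), 0)


@dataclass
class Rule:
    """A directed category pair with its counts and computed scores."""

    antecedent: Item
    consequent: Item
    n_ab: int
    n_a: int
    n_b: int
    N: int
    measures: dict = field(default_factory=dict)
    expectation: Optional[float] = None
    flags: set = field(default_factory=set)

    @property
    def pair(self) -> tuple[Item, Item]:
        return pair_key(self.antecedent, self.consequent)

    @property
    def confidence(self) -> float:
        return self.n_ab / self.n_a

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Rule({self.antecedent.category} -> {self.consequent.category}, "
            f"n_ab={self.n_ab})"
        )


def count_pair_supports(
    store: AnnotationStore,
    scope: Sequence[str],
    min_abs_support: int = 1,
) -> SupportTable:
    """Count item and pair supports over the transaction set.

    ``scope`` is either two ontology ids (cross-hierarchy mining: one item
    from each) or one (intra-hierarchy mining: both items from it).  Item
    counts cover every category of the scope hierarchies that appears in any
    transaction, so parent counts needed by expectation computation are
    always available.  Pairs co-occurring in fewer than ``min_abs_support``
    transactions are discarded.
    """
    if not store.closed:
        raise ValueError("count_pair_supports requires an ancestor-closed store")
    if len(scope) not in (1, 2):
        raise ValueError("scope must name one or two ontologies")
    if min_abs_support < 1:
        raise ValueError("min_abs_support must be >= 1")

    item_counts: Counter = Counter()
    pair_counts: Counter = Counter()
    cross = len(scope) == 2 and scope[0] != scope[1]
    for _, per_ont in store.iter_labelled(list(dict.fromkeys(scope))):
        for ont, labels in per_ont.items():
            for cat in labels:
                item_counts[Item(ont, cat)] += 1
        if cross:
            left = per_ont.get(scope[0], ())
            right = per_ont.get(scope[1], ())
            for ca, cb in product(left, right):
                pair_counts[pair_key(Item(scope[0], ca), Item(scope[1], cb))] += 1
        else:
            labels = sorted(per_ont.get(scope[0], ()))
            for ca, cb in combinations(labels, 2):
                pair_counts[pair_key(Item(scope[0], ca), Item(scope[0], cb))] += 1
    retained = {k: v for k, v in pair_counts.items() if v >= min_abs_support}
    return SupportTable(N=store.N, item_counts=dict(item_counts), pair_counts=retained)


def generate_rules(
    supports: SupportTable,
    ontologies: Optional[Sequence[Ontology]] = None,
) -> list[Rule]:
    """Emit both directed rules for every retained pair.

    Inside one hierarchy a child→ancestor rule is tautological after
    ancestor closure (its confidence is 1 by construction); such rules are
    flagged ``"hierarchical"`` rather than dropped, so each pruning method
    can treat them the way it prescribes.  Cross-hierarchy rules are flagged
    ``"cross_ontology"``.
    """
    by_id = {o.ontology_id: o for o in ontologies} if ontologies else {}
    rules = []
    for (a, b), n_ab in sorted(supports.pair_counts.items()):
        n_a = supports.item_count(a)
        n_b = supports.item_count(b)
        for ant, cons, n_ant, n_cons in ((a, b, n_a, n_b), (b, a, n_b, n_a)):
            flags = set()
            if ant.ontology != cons.ontology:
                flags.add("cross_ontology")
            elif ant.ontology in by_id:
                o = by_id[ant.ontology]
                if cons.category in o.ancestors(ant.category):
                    flags.add("hierarchical")
            rules.append(
                Rule(
                    antecedent=ant,
                    consequent=cons,
                    n_ab=n_ab,
                    n_a=n_ant,
                    n_b=n_cons,
                    N=supports.N,
                    flags=flags,
                )
            )
    return rules


def rank_rules(rules: Iterable[Rule], measure: str, descending: bool = True) -> list[Rule]:
    """Deterministic total order: measure value, then n_ab, then lexicographic.

    The measure value must already be attached to every rule.  Ties on the
    value are broken by absolute support (higher first), then by the
    (antecedent, consequent) item pair so the order is stable across runs.
    """
    rules = list(rules)
    for r in rules:
        if measure not in r.measures:
            raise ValueError(f"rule {r!r} lacks measure {measure!r}")
    sign = -1.0 if descending else 1.0

    def key(r: Rule):
        return (sign * r.measures[measure], -r.n_ab, r.antecedent, r.consequent)

    return sorted(rules, key=key)


def direction_select(ranked: Sequence[Rule]) -> list[Rule]:
    """Keep only the better-ranked direction of each unordered pair."""
    seen: set[tuple[Item, Item]] = set()
    out = []
    for r in ranked:
        if r.pair in seen:
            continue
        seen.add(r.pair)
        out.append(r)
    return out
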