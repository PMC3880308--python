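"""Comparator rule-pruning frameworks: GRP and GRL.

GRP (Generalized Rule Pruning, Srikant-style) keeps a specialized rule only
when its actual support or confidence exceeds the value expected from its
parent rule by an interest factor R; rules between root categories are
always kept.  GRL (GO Relationship Learning, Faria-style) filters by
minimum absolute support, confidence and *agreement* — confidence computed
over distinct annotation label-sets instead of objects — and then applies
Specific Structure Pruning (SSP): drop rules whose items are four or fewer
edges apart, whose items have more than ten descendants, or that are
generalizations (ancestor rules) of another retained rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .measures import support_expectation
from .mining import Item, Rule, SupportTable, rank_rules
from .ontology import Ontology

__all__ = [
    "GrpConfig",
    "GrlConfig",
    "grp_prune",
    "agreement",
    "ssp_filter",
    "grl_filter",
    "ancestor_rule_removal",
]


@dataclass
class GrpConfig:
    """Interest factor R >= 1 and which expectation tests to apply."""

    interest_factor: float = 1.1
    tests: tuple[str, ...] = ("support", "confidence")

    def __post_init__(self):
        if self.interest_factor < 1:
            raise ValueError("interest factor R must be >= 1")
        bad = set(self.tests) - {"support", "confidence"}
        if bad:
            raise ValueError(f"unknown GRP tests: {bad}")


@dataclass
class GrlConfig:
    """GRL thresholds: absolute support, confidence, agreement, SSP switch."""

    min_abs_support: int = 10
    min_cnf: float = 0.8
    min_agr: float = 0.8
    ssp_enabled: bool = True
    cross_ontology: bool = True

    def __post_init__(self):
        if not (0 <= self.min_cnf <= 1 and 0 <= self.min_agr <= 1):
            raise ValueError("min_cnf and min_agr must lie in [0,1]")


def grp_prune(
    rules: Iterable[Rule],
    supports: SupportTable,
    ontologies: Sequence[Ontology],
    cfg: Optional[GrpConfig] = None,
    expectation_mode: str = "both_sides_min",
) -> list[Rule]:
    """Srikant-style expected-value pruning; survivors ranked by confidence.

    A rule survives when both of its items are roots (root rules are always
    interesting to GRP), or when its actual support or confidence reaches R
    times the value expected from its parent rule.  The expected confidence
    is the expected co-occurrence count divided by n(a).
    """
    cfg = cfg or GrpConfig()
    by_id = {o.ontology_id: o for o in ontologies}
    survivors = []
    for rule in rules:
        a_root = by_id[rule.antecedent.ontology].is_root(rule.antecedent.category)
        b_root = by_id[rule.consequent.ontology].is_root(rule.consequent.category)
        if a_root and b_root:
            keep = True
        else:
            exp_count = support_expectation(
                rule, ontologies, supports, mode=expectation_mode
            )
            keep = False
            if "support" in cfg.tests and rule.n_ab >= cfg.interest_factor * exp_count:
                keep = True
            if (
                not keep
                and "confidence" in cfg.tests
                and rule.confidence >= cfg.interest_factor * (exp_count / rule.n_a)
            ):
                keep = True
        if keep:
            rule.measures.setdefault("Cnf", rule.confidence)
            survivors.append(rule)
    return rank_rules(survivors, "Cnf")


def agreement(rule: Rule, combos: Counter) -> float:
    """Confidence over distinct label-sets instead of objects.

    ``combos`` maps each distinct closed label-set (frozenset of
    ``(ontology_id, category_id)`` items) to its object multiplicity, as
    produced by :func:`difmine.annotations.unique_combinations`; each set
    counts once regardless of multiplicity.
    """
    a = tuple(rule.antecedent)
    b = tuple(rule.consequent)
    with_a = sum(1 for combo in combos if a in combo)
    if with_a == 0:
        raise ValueError(f"no label combination contains {rule.antecedent}")
    with_both = sum(1 for combo in combos if a in combo and b in combo)
    return with_both / with_a


def ssp_filter(
    rules: Iterable[Rule],
    ontologies: Sequence[Ontology],
    cross_ontology: bool = False,
    annotated_items: Optional[set] = None,
) -> list[Rule]:
    """Specific Structure Pruning.

    Intra-hierarchy mode removes (1) rules whose items are connected by four
    or fewer undirected edges, (2) rules where either item has more than ten
    descendants, and (3) ancestor rules — a rule both of whose items are
    (weak) ancestors of another retained rule's corresponding items.  When
    the two items come from different hierarchies no edge path exists, so
    cross-hierarchy mode applies only the descendant limit.

    ``annotated_items`` restricts the descendant count to categories that
    actually occur in the data (the annotated sub-ontology); by default the
    full hierarchy is counted.
    """
    by_id = {o.ontology_id: o for o in ontologies}
    annotated_by_ont: dict[str, set[str]] = {}
    if annotated_items is not None:
        for it in annotated_items:
            annotated_by_ont.setdefault(it[0], set()).add(it[1])

    def desc_count(item: Item) -> int:
        descs = by_id[item.ontology].descendants(item.category)
        if annotated_items is not None:
            descs = descs & annotated_by_ont.get(item.ontology, set())
        return len(descs)

    kept = []
    for rule in rules:
        if desc_count(rule.antecedent) > 10 or desc_count(rule.consequent) > 10:
            continue
        if not cross_ontology and rule.antecedent.ontology == rule.consequent.ontology:
            dist = by_id[rule.antecedent.ontology].edge_distance(
                rule.antecedent.category, rule.consequent.category
            )
            if dist is not None and dist <= 4:
                continue
        kept.append(rule)
    if not cross_ontology:
        kept = ancestor_rule_removal(kept, ontologies)
    return kept


def ancestor_rule_removal(rules: Iterable[Rule], ontologies: Sequence[Ontology]) -> list[Rule]:
    """Drop generalizations: keep only the most specific version of a rule.

    A rule a→b is removed when another retained rule a'→b' exists with a'
    a (weak) descendant of a and b' a (weak) descendant of b, at least one
    strictly.  Rules are processed from most specific (deepest item pair) to
    most general so the outcome is order-independent.
    """
    by_id = {o.ontology_id: o for o in ontologies}

    def depth(rule: Rule) -> int:
        return by_id[rule.antecedent.ontology].depth(rule.antecedent.category) + by_id[
            rule.consequent.ontology
        ].depth(rule.consequent.category)

    def weak_ancestor(general: Item, specific: Item) -> bool:
        if general.ontology != specific.ontology:
            return False
        if general.category == specific.category:
            return True
        return general.category in by_id[specific.ontology].ancestors(specific.category)

    ordered = sorted(rules, key=lambda r: (-depth(r), r.antecedent, r.consequent))
    kept: list[Rule] = []
    for rule in ordered:
        specialized = any(
            (k.antecedent, k.consequent) != (rule.antecedent, rule.consequent)
            and weak_ancestor(rule.antecedent, k.antecedent)
            and weak_ancestor(rule.consequent, k.consequent)
            for k in kept
        )
        if not specialized:
            kept.append(rule)
    return kept


def grl_filter(
    rules: Iterable[Rule],
    supports: SupportTable,
    combos: Counter,
    ontologies: Sequence[Ontology],
    cfg: Optional[GrlConfig] = None,
) -> list[Rule]:
    """GRL: threshold filtering plus SSP, survivors ranked by confidence."""
    cfg = cfg or GrlConfig()
    passed = []
    for rule in rules:
        if rule.n_ab < cfg.min_abs_support:
            continue
        if rule.confidence < cfg.min_cnf:
            continue
        if agreement(rule, combos) < cfg.min_agr:
            continue
        rule.measures.setdefault("Cnf", rule.confidence)
        passed.append(rule)
    if cfg.ssp_enabled:
        passed = ssp_filter(
            passed,
            ontologies,
            cross_ontology=cfg.cross_ontology,
            annotated_items=set(supports.item_counts),
        )
    return rank_rules(passed, "Cnf")
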