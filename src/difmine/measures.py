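"""Interestingness measures for pairwise rules, including the hierarchy-aware
*Interestingness by Difference* class.

Classical measures score a rule a→b from the 2×2 contingency of the item
counts n(a), n(b), the co-occurrence count n(a,b) and the transaction count
N.  The null-invariant subset (Jaccard, cosine, all-confidence, Kulczynski,
confidence) ignores transactions containing neither item, which is what
makes them usable for rare rules.

The Dif class compares a rule's actual measure value M with the value E
expected from its *parent* rule under the proportional-distribution
assumption: if the child's transactions were spread over the consequent the
same way its parent's are, the co-occurrence count would be
``n(pa(a),b) · n(a) / n(pa(a))``.  E is the base measure re-evaluated at
that expected count, and ``Dif = M·(M−E)``: positive when a rule beats what
the hierarchy already implies, negative when a parent or sibling carries the
association.  Root–root rules, having no parents, fall back to the
independence expectation ``n(a)·n(b)/N``.  In a DAG the smallest expectation
over all parents is kept.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

from .mining import Item, Rule, SupportTable
from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "DIF_BASE",
    "ALL_MEASURE_IDS",
    "needs_N",
    "compute_measure",
    "support_expectation",
    "dif_measure",
    "annotate_measures",
]


def _sup(n_ab, n_a, n_b, N):
    return n_ab / N


def _cnf(n_ab, n_a, n_b, N):
    return n_ab / n_a


def _cos(n_ab, n_a, n_b, N):
    return n_ab / math.sqrt(n_a * n_b)


def _acnf(n_ab, n_a, n_b, N):
    return n_ab / max(n_a, n_b)


def _kulc(n_ab, n_a, n_b, N):
    return 0.5 * (n_ab / n_a + n_ab / n_b)


def _lift(n_ab, n_a, n_b, N):
    return N * n_ab / (n_a * n_b)


def _bf(n_ab, n_a, n_b, N):
    # Bayes factor: confidence over the confidence among non-a transactions,
    # Cnf / P(b|¬a).  n_ab = n_b means b never occurs without a: +inf.
    # n_a = N (a in every transaction) leaves no ¬a transactions: also +inf.
    if n_b == n_ab or N == n_a:
        return math.inf
    return (n_ab / n_a) / ((n_b - n_ab) / (N - n_a))


def _ccnf(n_ab, n_a, n_b, N):
    return n_ab / n_a - n_b / N


def _phi(n_ab, n_a, n_b, N):
    p_ab, p_a, p_b = n_ab / N, n_a / N, n_b / N
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        logger.warning("phi undefined for marginal probability 0 or 1; returning 0")
        return 0.0
    return (p_ab - p_a * p_b) / math.sqrt(p_a * p_b * (1 - p_a) * (1 - p_b))


def _jac(n_ab, n_a, n_b, N):
    return n_ab / (n_a + n_b - n_ab)


#: measure id -> (function, needs N)
MEASURES = {
    "Sup": (_sup, True),
    "Cnf": (_cnf, False),
    "Cos": (_cos, False),
    "ACnf": (_acnf, False),
    "Kulc": (_kulc, False),
    "Lift": (_lift, True),
    "BF": (_bf, True),
    "CCnf": (_ccnf, True),
    "Phi": (_phi, True),
    "Jac": (_jac, False),
}

#: Dif measure id -> base measure id (base must have range [0,1])
DIF_BASE = {"JacDif": "Jac", "CosDif": "Cos"}

ALL_MEASURE_IDS = tuple(MEASURES) + tuple(DIF_BASE)


def needs_N(measure_id: str) -> bool:
    if measure_id in DIF_BASE:
        measure_id = DIF_BASE[measure_id]
    return MEASURES[measure_id][1]


def compute_measure(
    measure_id: str,
    n_ab: float,
    n_a: float,
    n_b: float,
    N: Optional[float] = None,
    clamp_phi: bool = False,
) -> float:
    """Evaluate one classical measure from the rule's counts.

    ``n_ab`` may be fractional (expectation re-evaluation passes expected
    counts through the same formulas).  ``clamp_phi`` maps negative φ values
    to 0 for strict [0,1]-range conformance; the default keeps the signed
    coefficient.
    """
    if measure_id not in MEASURES:
        raise ValueError(f"unknown measure {measure_id!r}")
    func, wants_n = MEASURES[measure_id]
    if n_a <= 0 or n_b <= 0:
        raise ValueError("item counts must be positive")
    if n_ab < 0:
        raise ValueError("co-occurrence count must be non-negative")
    if wants_n:
        if N is None:
            raise ValueError(f"measure {measure_id!r} needs the transaction count N")
        if N < max(n_a, n_b):
            raise ValueError("N must be at least max(n_a, n_b)")
    value = func(n_ab, n_a, n_b, N)
    if measure_id == "Phi" and clamp_phi and value < 0:
        value = 0.0
    return value


def support_expectation(
    rule: Rule,
    ontologies: Sequence[Ontology],
    supports: SupportTable,
    mode: str = "both_sides_min",
) -> float:
    """Expected co-occurrence count of a rule given its parent rules.

    For each parent ``pa`` of the antecedent ``a`` (when ``a`` is not a
    root) the candidate expectation is ``n(pa,b) · n(a) / n(pa)`` — the
    parent rule's support shared out proportionally to the child's item
    support.  ``mode="both_sides_min"`` adds the mirror-image candidates
    from the consequent's parents; the minimum over all candidates is
    returned (the DAG convention).  ``mode="antecedent_only"`` restricts to
    antecedent-side parents.  When no side offers a parent (a root–root
    rule) the independence expectation ``n(a)·n(b)/N`` is used instead.
    """
    if mode not in ("both_sides_min", "antecedent_only"):
        raise ValueError(f"unknown expectation mode {mode!r}")
    by_id = {o.ontology_id: o for o in ontologies}
    a, b = rule.antecedent, rule.consequent
    oa, ob = by_id[a.ontology], by_id[b.ontology]

    sides = [(a, oa, b)]
    if mode == "both_sides_min":
        sides.append((b, ob, a))

    candidates: list[float] = []
    for child, ontology, other in sides:
        if ontology.is_root(child.category):
            continue
        n_child = supports.item_count(child)
        for parent in sorted(ontology.parents(child.category)):
            p_item = Item(child.ontology, parent)
            n_parent = supports.item_count(p_item)
            if n_parent <= 0:
                raise ValueError(
                    f"parent {parent!r} of {child.category!r} has no support count"
                )
            n_pair = supports.pair_count(p_item, other)
            candidates.append(n_pair * n_child / n_parent)

    if candidates:
        return min(candidates)
    if oa.is_root(a.category) and (mode == "antecedent_only" or ob.is_root(b.category)):
        return rule.n_a * rule.n_b / rule.N
    raise ValueError(
        f"no expectation candidate for rule {a.category!r} -> {b.category!r}: "
        "non-root item without usable parents"
    )


def dif_measure(
    base_measure: str,
    rule: Rule,
    expected_count: float,
    form: str = "product",
) -> float:
    """Interestingness by Difference for a [0,1]-range base measure.

    The actual value M and the expected value E (the base measure with the
    co-occurrence count replaced by ``expected_count``) are combined as
    ``M·(M−E)`` by default; ``form="plain"`` yields the raw difference
    ``M−E``.  Negative values mark rules already implied — or out-performed
    — by their parent rule.
    """
    if base_measure not in MEASURES:
        raise ValueError(f"unknown base measure {base_measure!r}")
    if form not in ("product", "plain"):
        raise ValueError(f"unknown Dif form {form!r}")
    m = compute_measure(base_measure, rule.n_ab, rule.n_a, rule.n_b, rule.N)
    e = compute_measure(base_measure, expected_count, rule.n_a, rule.n_b, rule.N)
    if not (0.0 <= e <= 1.0 + 1e-9):
        raise ValueError(
            f"expected value {e:.4f} of {base_measure} outside [0,1]: inconsistent counts"
        )
    return m * (m - e) if form == "product" else m - e


def annotate_measures(
    rules: Iterable[Rule],
    measures: Sequence[str],
    supports: SupportTable,
    ontologies: Sequence[Ontology] = (),
    expectation_mode: str = "both_sides_min",
    dif_form: str = "product",
    clamp_phi: bool = False,
) -> list[Rule]:
    """Attach the requested measure values to every rule (in place).

    Dif measures trigger the expectation computation; the expected count is
    stored on ``rule.expectation`` for reporting.
    """
    rules = list(rules)
    unknown = [m for m in measures if m not in MEASURES and m not in DIF_BASE]
    if unknown:
        raise ValueError(f"unknown measures: {unknown}")
    wants_dif = [m for m in measures if m in DIF_BASE]
    if any(needs_N(m) for m in measures) and supports.N == 0:
        raise ValueError("transaction count N is zero")
    for rule in rules:
        for m in measures:
            if m in MEASURES:
                rule.measures[m] = compute_measure(
                    m, rule.n_ab, rule.n_a, rule.n_b, rule.N, clamp_phi=clamp_phi
                )
        if wants_dif:
            exp = support_expectation(rule, ontologies, supports, mode=expectation_mode)
            rule.expectation = exp
            for m in wants_dif:
                rule.measures[m] = dif_measure(DIF_BASE[m], rule, exp, form=dif_form)
    return rules
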