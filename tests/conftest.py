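from types import SimpleNamespace

import pytest

import difmine as dm
from difmine.datasets import retail_example
from difmine.ontology import Category, Ontology


@pytest.fixture
def diamond():
    """A <- B, A <- C, B <- D, C <- D: the minimal multi-parent hierarchy."""
    return Ontology(
        "dia",
        [Category("A"), Category("B"), Category("C"), Category("D")],
        {"B": {"A"}, "C": {"A"}, "D": {"B", "C"}},
    )


@pytest.fixture(scope="session")
def retail():
    """Clothing/footwear worked example: hierarchies, closed store, supports."""
    clothes, footwear, store = retail_example()
    closed = dm.ancestor_closure(store, [clothes, footwear])
    supports = dm.count_pair_supports(closed, ["clothes", "footwear"])
    rules = dm.generate_rules(supports, [clothes, footwear])
    return SimpleNamespace(
        clothes=clothes,
        footwear=footwear,
        store=store,
        closed=closed,
        supports=supports,
        rules=rules,
    )


@pytest.fixture(scope="session")
def bench():
    """Default synthetic benchmark (seed 42) run through the full pipeline."""
    cfg = dm.SynthConfig()
    o1 = dm.generate_ontology(cfg, "O1")
    o2 = dm.generate_ontology(cfg, "O2")
    data = dm.generate_annotations(cfg, o1, o2)
    closed = dm.ancestor_closure(data.store, [o1, o2])
    supports = dm.count_pair_supports(closed, ["O1", "O2"])
    rules = dm.generate_rules(supports, [o1, o2])
    rules = dm.annotate_measures(rules, ["Jac", "JacDif"], supports, [o1, o2])
    ranked = dm.direction_select(dm.rank_rules(rules, "JacDif"))
    return SimpleNamespace(
        cfg=cfg, o1=o1, o2=o2, data=data, closed=closed,
        supports=supports, rules=rules, ranked=ranked,
    )


def make_rule(ant, cons, n_ab, n_a, n_b, N, **measures):
    """Shorthand for a rule between items given as (ontology, category)."""
    return dm.Rule(
        antecedent=dm.Item(*ant),
        consequent=dm.Item(*cons),
        n_ab=n_ab,
        n_a=n_a,
        n_b=n_b,
        N=N,
        measures=dict(measures),
    )
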