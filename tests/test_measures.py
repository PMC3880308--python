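import math

import pytest
from hypothesis import given, settings, strategies as st

import difmine as dm
from difmine.measures import DIF_BASE, MEASURES, compute_measure, dif_measure, support_expectation
from difmine.mining import Item, Rule

from conftest import make_rule


class TestClassicalMeasures:
    @pytest.mark.parametrize(
        "measure, args, expected",
        [
            ("Jac", (15, 90, 30, None), 15 / 105),
            ("Kulc", (10, 15, 30, None), 0.5),
            ("ACnf", (10, 15, 30, None), 1 / 3),
            ("Cos", (10, 15, 30, None), 10 / math.sqrt(450)),
            ("Lift", (15, 90, 30, 1000), 1000 * 15 / 2700),
            ("BF", (15, 90, 30, 1000), (15 / 90) / (15 / 910)),
            ("Sup", (15, 90, 30, 1000), 0.015),
            ("Cnf", (15, 90, 30, None), 15 / 90),
            ("CCnf", (15, 90, 30, 1000), 15 / 90 - 0.03),
        ],
    )
    def test_exact_values(self, measure, args, expected):
        assert compute_measure(measure, *args) == pytest.approx(expected, abs=1e-12)

    def test_phi_from_contingency_table(self):
        # brute-force from the 2x2 table: n11=15, n10=75, n01=15, n00=895
        n11, n10, n01, n00 = 15, 75, 15, 895
        num = n11 * n00 - n10 * n01
        den = math.sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
        assert compute_measure("Phi", 15, 90, 30, 1000) == pytest.approx(num / den)
        assert compute_measure("Phi", 15, 90, 30, 1000) == pytest.approx(0.25195, abs=5e-6)

    @pytest.mark.parametrize(
        "n_ab, n_a, n_b, expected", [(0, 9, 5, 0.0), (7, 7, 7, 1.0)]
    )
    def test_jaccard_boundaries(self, n_ab, n_a, n_b, expected):
        assert compute_measure("Jac", n_ab, n_a, n_b) == expected

    def test_bf_infinite_when_b_never_without_a(self):
        assert compute_measure("BF", 5, 10, 5, 100) == math.inf

    def test_phi_degenerate_marginal_is_zero(self, caplog):
        assert compute_measure("Phi", 5, 100, 5, 100) == 0.0

    def test_phi_clamp_option(self):
        # negatively dependent items: signed phi < 0, clamped version is 0
        signed = compute_measure("Phi", 0, 50, 50, 100)
        assert signed < 0
        assert compute_measure("Phi", 0, 50, 50, 100, clamp_phi=True) == 0.0

    def test_needs_N_enforced(self):
        with pytest.raises(ValueError, match="needs the transaction count"):
            compute_measure("Lift", 1, 2, 3)


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_measure_ranges(data):
    N = data.draw(st.integers(2, 10_000))
    n_a = data.draw(st.integers(1, N))
    n_b = data.draw(st.integers(1, N))
    n_ab = data.draw(st.integers(0, min(n_a, n_b)))
    for m in ("Jac", "Cos", "ACnf", "Sup", "Cnf", "Kulc"):
        v = compute_measure(m, n_ab, n_a, n_b, N)
        assert 0.0 <= v <= 1.0 + 1e-12
    # CCnf reaches -1 exactly when n_ab=0 and b fills every transaction
    assert -1.0 <= compute_measure("CCnf", n_ab, n_a, n_b, N) < 1.0
    assert compute_measure("Lift", n_ab, n_a, n_b, N) >= 0.0
    if N > n_a:
        assert compute_measure("BF", n_ab, n_a, n_b, N) >= 0.0


@settings(max_examples=100, deadline=None)
@given(st.data())
def test_monotone_in_co_occurrence(data):
    N = data.draw(st.integers(4, 1000))
    n_a = data.draw(st.integers(2, N))
    n_b = data.draw(st.integers(2, N))
    hi = data.draw(st.integers(1, min(n_a, n_b)))
    lo = data.draw(st.integers(0, hi - 1))
    for m in MEASURES:
        v_lo = compute_measure(m, lo, n_a, n_b, N)
        v_hi = compute_measure(m, hi, n_a, n_b, N)
        assert v_hi >= v_lo - 1e-12


NULL_INVARIANT = ("Jac", "Cos", "ACnf", "Kulc", "Cnf")
NULL_SENSITIVE = ("Sup", "Lift", "CCnf", "Phi")


def test_null_transaction_invariance():
    """Adding transactions containing neither item must not move the
    null-invariant measures at all, and must move all the others."""
    n_ab, n_a, n_b, N = 15, 90, 30, 1000
    N2 = N + 10_000
    for m in NULL_INVARIANT:
        assert compute_measure(m, n_ab, n_a, n_b, N) == compute_measure(m, n_ab, n_a, n_b, N2)
    for m in NULL_SENSITIVE:
        assert compute_measure(m, n_ab, n_a, n_b, N) != compute_measure(m, n_ab, n_a, n_b, N2)


def test_phi_converges_to_cosine():
    """With the item counts fixed, φ approaches the cosine as N grows —
    the asymptotically null-invariant behaviour."""
    n_ab, n_a, n_b = 15, 90, 30
    cos = compute_measure("Cos", n_ab, n_a, n_b)
    gaps = [
        abs(compute_measure("Phi", n_ab, n_a, n_b, N) - cos)
        for N in (10**3, 10**4, 10**5, 10**6)
    ]
    assert gaps == sorted(gaps, reverse=True)
    assert gaps[-1] < 1e-3
    assert compute_measure("Phi", n_ab, n_a, n_b, 10**6) == pytest.approx(0.2886405, abs=1e-6)


class TestSupportExpectation:
    def rule(self, retail, ant, n_ab, n_a):
        return make_rule(("clothes", ant), ("footwear", "Hiking Boots"), n_ab, n_a, 30, 1000)

    def test_antecedent_only_worked_values(self, retail):
        onts = [retail.clothes, retail.footwear]
        r3 = self.rule(retail, "Jackets", 15, 90)
        r4 = self.rule(retail, "Travel Pants", 10, 15)
        assert support_expectation(r3, onts, retail.supports, "antecedent_only") == pytest.approx(18.0)
        assert support_expectation(r4, onts, retail.supports, "antecedent_only") == pytest.approx(3.0)

    def test_both_roots_independence(self, retail):
        onts = [retail.clothes, retail.footwear]
        r = make_rule(("clothes", "Clothes"), ("footwear", "Hiking Boots"), 30, 150, 30, 1000)
        assert support_expectation(r, onts, retail.supports) == pytest.approx(4.5)

    def test_dag_minimum_over_parents(self):
        # b has two parents with different parent-rule strengths: keep the min
        from difmine.annotations import AnnotationStore
        from difmine.ontology import Category, Ontology

        o1 = Ontology(
            "L",
            [Category("r"), Category("p"), Category("q"), Category("c")],
            {"p": {"r"}, "q": {"r"}, "c": {"p", "q"}},
        )
        o2 = Ontology("R", [Category("y")], {})
        store = AnnotationStore()
        for i in range(8):  # c (and its parents) with y
            store.add(f"a{i}", "L", {"c"})
            store.add(f"a{i}", "R", {"y"})
        for i in range(12):  # q-only transactions, no y: weakens q->y
            store.add(f"b{i}", "L", {"q"})
        closed = dm.ancestor_closure(store, [o1, o2])
        sup = dm.count_pair_supports(closed, ["L", "R"])
        r = make_rule(("L", "c"), ("R", "y"), 8, 8, 8, 20)
        # candidates: via p: 8*8/8 = 8 ; via q: 8*8/20 = 3.2
        assert support_expectation(r, [o1, o2], sup, "antecedent_only") == pytest.approx(3.2)

    def test_zero_parent_rule_support_gives_zero(self, retail):
        onts = [retail.clothes, retail.footwear]
        # a hypothetical consequent never co-occurring with the parent
        sup = retail.supports
        r = make_rule(("clothes", "Jackets"), ("footwear", "Hiking Boots"), 0, 90, 30, 1000)
        # remove the parent pair count by querying a fresh table
        table = dm.SupportTable(N=sup.N, item_counts=dict(sup.item_counts), pair_counts={})
        assert support_expectation(r, onts, table, "antecedent_only") == 0.0


class TestDifMeasure:
    @pytest.mark.parametrize(
        "base, n_ab, n_a, exp_count, expected",
        [
            ("Jac", 15, 90, 18.0, -0.004802),   # frequent specialized rule: penalized
            ("Jac", 10, 15, 3.0, 0.061224),     # rare unexpected rule: rewarded
            ("Cos", 15, 90, 18.0, -0.016667),
        ],
    )
    def test_product_form_values(self, base, n_ab, n_a, exp_count, expected):
        r = make_rule(("c", "x"), ("f", "y"), n_ab, n_a, 30, 1000)
        assert dif_measure(base, r, exp_count) == pytest.approx(expected, abs=1e-6)

    def test_expectation_met_exactly_gives_zero(self):
        r = make_rule(("c", "x"), ("f", "y"), 20, 100, 30, 1000)
        assert dif_measure("Jac", r, 20.0) == pytest.approx(0.0)

    def test_plain_form(self):
        r = make_rule(("c", "x"), ("f", "y"), 15, 90, 30, 1000)
        m = 15 / 105
        e = 18 / (90 + 30 - 18)
        assert dif_measure("Jac", r, 18.0, form="plain") == pytest.approx(m - e)

    def test_negative_iff_actual_below_expected_and_bounded_by_m(self):
        r = make_rule(("c", "x"), ("f", "y"), 15, 90, 30, 1000)
        m = compute_measure("Jac", 15, 90, 30)
        for exp_count in (0.0, 5.0, 15.0, 25.0):
            d = dif_measure("Jac", r, exp_count)
            e = compute_measure("Jac", exp_count, 90, 30)
            assert (d < 0) == (m < e)
            assert d <= m + 1e-12

    @pytest.mark.parametrize("bad_expected", [15.0, 50.0])
    def test_inconsistent_expected_count_errors(self, bad_expected):
        # expected counts pushing the expected Jaccard above 1 (or through
        # a non-positive denominator) can only come from inconsistent counts
        r = make_rule(("c", "x"), ("f", "y"), 5, 10, 10, 100)
        with pytest.raises(ValueError, match="inconsistent"):
            dif_measure("Jac", r, bad_expected)

    def test_proportional_child_has_zero_dif(self, retail):
        """A child whose transactions follow the parent's distribution
        exactly (Outerwear vs Clothes) is fully expected: Dif = 0."""
        onts = [retail.clothes, retail.footwear]
        rules = dm.annotate_measures(
            list(retail.rules), ["Jac", "JacDif"], retail.supports, onts,
            expectation_mode="antecedent_only",
        )
        ow = next(
            r for r in rules
            if r.antecedent.category == "Outerwear" and r.consequent.ontology == "footwear"
        )
        assert ow.expectation == pytest.approx(20.0)
        assert ow.measures["JacDif"] == pytest.approx(0.0, abs=1e-12)


class TestAnnotateMeasures:
    def test_requested_measures_attached(self, retail):
        onts = [retail.clothes, retail.footwear]
        rules = dm.annotate_measures(
            list(retail.rules), ["Jac", "JacDif"], retail.supports, onts
        )
        for r in rules:
            assert set(r.measures) >= {"Jac", "JacDif"}
            assert r.expectation is not None

    def test_empty_measure_list_is_identity(self, retail):
        rules = dm.annotate_measures(list(retail.rules), [], retail.supports)
        assert all(r.expectation is None for r in rules if not r.measures)

    def test_zero_N_rejected(self):
        table = dm.SupportTable(N=0, item_counts={}, pair_counts={})
        with pytest.raises(ValueError, match="zero"):
            dm.annotate_measures([], ["Sup"], table)

    def test_unknown_measure_rejected(self, retail):
        with pytest.raises(ValueError, match="unknown measures"):
            dm.annotate_measures([], ["Bogus"], retail.supports)
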