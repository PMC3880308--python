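# Methods

## Problem setting

`difmine` mines **pairwise generalized association rules** between the
categories of one or two rooted hierarchies (ontologies). A *transaction*
is one annotated object — a protein with its GO terms, a Wikipedia entry
with its taxonomy labels — viewed as the set of categories assigned to it.
A rule `a → b` connects a category `a` of one hierarchy with a category `b`
of the other (or of the same one), and is scored from the absolute counts
`n(a)`, `n(b)`, `n(a,b)` and the transaction count `N`.

Two properties of curated annotation data drive every design choice:

1. **Annotations are hierarchical.** An object annotated with a category
   implicitly belongs to all its ancestors, so every label set is expanded
   by *ancestor closure* before counting. This makes parent counts always
   at least as large as child counts and creates systematic, uninteresting
   child→ancestor rules (confidence 1 by construction), which the miner
   flags rather than silently drops.
2. **The interesting rules are rare.** Specific categories are infrequent,
   so mining runs with a minimum absolute support of **one** co-occurrence
   and relies on ranking, not support thresholds, to surface signal.

## Interestingness measures

The classical measures are computed from the 2×2 contingency table
(`P_x = n(x)/N`):

| id | formula | range |
|----|---------|-------|
| Sup | n(a,b)/N | [0,1] |
| Cnf | n(a,b)/n(a) | [0,1] |
| Cos | n(a,b)/√(n(a)·n(b)) | [0,1] |
| ACnf | n(a,b)/max(n(a),n(b)) | [0,1] |
| Kulc | ½(n(a,b)/n(a) + n(a,b)/n(b)) | [0,1] |
| Lift | N·n(a,b)/(n(a)·n(b)) | [0,∞) |
| BF | (n(a,b)/n(a)) / ((n(b)−n(a,b))/(N−n(a))) | [0,∞] |
| CCnf | n(a,b)/n(a) − n(b)/N | [−1,1) |
| Phi | (P_ab − P_a·P_b)/√(P_a·P_b·(1−P_a)(1−P_b)) | [−1,1] |
| Jac | n(a,b)/(n(a)+n(b)−n(a,b)) | [0,1] |

Jac, Cos, ACnf, Kulc and Cnf are **null-transaction invariant**: appending
transactions containing neither item leaves them bit-identical, the
property that makes them usable for rare rules. Sup, Lift, CCnf and Phi
are not — though Phi converges to Cos as `N → ∞` with the item counts held
fixed (the test suite checks a monotone gap below 10⁻³ at N = 10⁶).

Numerical edge cases: BF returns `+inf` when `n(a,b) = n(b)` (b never
occurs without a) or `N = n(a)`; the infinity sorts above every finite
value in rankings. Phi returns 0 with a logged warning when a marginal
probability is 0 or 1. Phi is signed by default; `clamp_phi=True` maps
negative values to 0 for strict [0,1]-range conformance.

## Interestingness by Difference

For a [0,1]-range base measure `M` (here Jaccard and cosine), the
hierarchy-aware score compares the actual value with the value **expected
from the rule's parent rule**:

```
SupExp(a→b) = n(pa(a), b) · n(a) / n(pa(a))        (a not a root)
SupExp(a→b) = n(a) · n(b) / N                      (a and b both roots)
```

i.e. the parent rule's co-occurrence count shared out in proportion to the
child's share of the parent's support; root–root rules, having no parents,
fall back to the independence product. In a DAG the **minimum** expectation
over all parents is kept. The default mode (`both_sides_min`) also
considers the consequent's parents and takes the overall minimum;
`antecedent_only` restricts to the antecedent side (the mode used in the
worked example below, where the consequent hierarchy is a single node).

The expected measure value `E` is the base measure re-evaluated with
`n(a,b)` replaced by the expected count, and the score is

```
Dif = M · (M − E)
```

Positive when the rule is *stronger than the hierarchy already implies*,
negative when a parent or sibling carries the association, zero when the
child exactly follows the parent's distribution (the built-in retail
example's Outerwear rule demonstrates this identity). The multiplicative
form weights the difference by the rule's own strength, so a strong rule
that beats its expectation outranks a weak one with the same margin; a
plain difference `M − E` is available via `dif_form="plain"`. An expected
`E` outside [0,1] can only arise from mutually inconsistent counts and is
rejected.

### Worked example

Clothing hierarchy Clothes→{Outerwear→Jackets, Travel Pants}, one footwear
category, N = 1000, supports Clothes 150 / Outerwear 100 / Jackets 90 /
Travel Pants 15 / Hiking Boots 30, rule supports 30/20/15/10. Then, in
antecedent-only mode:

* Jackets → Hiking Boots: SupExp = 20·90/100 = 18 > 15 actual;
  M = 0.1429, E = 0.1765, **JacDif = −0.0048** — frequent but *expected*,
  penalized.
* Travel Pants → Hiking Boots: SupExp = 20·15/100 = 3 < 10 actual;
  M = 0.2857, E = 0.0714, **JacDif = +0.0612** — rare but *unexpected*,
  rewarded.

`difmine.datasets.retail_example()` reconstructs exactly this transaction
set; the acceptance script recomputes both values through the full
pipeline.

## Comparator pruning methods

**GRP** (Srikant-style generalized rule pruning): a specialized rule
survives only if its actual support or confidence reaches `R ×` the value
expected from its parent rule (same expectation machinery as above;
expected confidence = expected count / n(a)); rules between root
categories always survive. Default `R = 1.1`, the canonical setting in the
pruning literature; the package treats it as fully configurable and no
test depends on its exact value.

**GRL** (Faria-style filtering): keep rules with absolute support ≥ 10,
confidence ≥ 0.8 and *agreement* ≥ 0.8 — agreement being confidence
computed over **distinct closed label-sets** rather than objects, which
damps the weight of heavily duplicated annotation profiles — then apply
**Specific Structure Pruning (SSP)**: remove rules whose items are ≤ 4
undirected edges apart, whose items have more than 10 descendants, and
*ancestor rules* (generalizations of another retained rule). Between two
disjoint hierarchies no edge path exists, so cross-hierarchy runs apply
only the descendant limit. The descendant limit is counted over the
annotated sub-ontology when the caller supplies the annotated item set
(the default inside `grl_filter`), over the full hierarchy otherwise.
Ancestor-rule removal processes rules from the deepest item pair upward,
which makes the outcome independent of input order.

The structural bias this creates is the point of the comparison: GRL's
support threshold makes it *provably blind* to rules with fewer than 10
co-occurrences, exactly the rare regime Dif ranking targets.

## DAG-to-tree conversion

For workflows requiring single-parent hierarchies, every placement of a
multi-parent node under a distinct parent copy becomes its own node
(`D@B`, `D@C`), with the subtree below duplicated recursively; a
provenance map links copies back to originals, annotation loading resolves
an original id onto all its copies, and collapsing by provenance recovers
the original category set exactly.

## Synthetic benchmark

The generator builds the statistical structure the method assumes, not a
replica of any real corpus:

| parameter | default | meaning |
|-----------|---------|---------|
| depth / branching | 4 / 3 | tree shape; +1 child with prob. `branch_jitter`=0.3 → ≈120 leaves |
| dag_fraction | 0.0 | share of nodes given a second parent |
| n_objects | 2000 | transactions |
| n_planted_links | 20 | one-to-one leaf links across hierarchies |
| p_link | 0.9 | P(linked partner co-annotated) |
| rare_fraction | 0.3 | share of links capped below support 10 |
| noise_rate | 0.05 | P(extra random leaf per hierarchy per object) |

Objects are annotated at the **leaves** (mirroring real usage, where
specific categories are infrequent relative to their ancestors) and closed
upward. Rare links draw a cap uniformly in 4..9 and stop co-annotating
once it is reached; their endpoints are excluded from the noise pool, so a
rare link's absolute support is below 10 by construction. On the default
benchmark (seed 42) the JacDif ranking places 19 of the 20 planted pairs —
including 5 of the 6 rare ones — in the top 40 after direction selection,
while GRL at its default support threshold recovers none of the rare
links. These numbers are recomputed, never stored, by the test suite and
the acceptance script.

What the generator does **not** emulate: realistic label multiplicity
(real corpora annotate many leaves per object), correlated noise,
many-to-many true links, obsolete-term churn, and evidence-code structure.
Passing the recovery test therefore shows the ranking separates planted
signal from uniform noise under leaf-biased closure — not that it matches
any particular corpus's precision.

## Evaluation protocol

Ground truth is a set of **unordered** category pairs, so the two
directions of a rule cannot be double-counted; rankings are
direction-selected (only the better-ranked direction of each pair kept,
ties broken toward the lexicographically smaller direction) before
scoring. Reported statistics: F-1 at `k` (by default `k` = truth size, so
precision = recall), best-possible F-1 (maximum over all ranking prefixes,
ties toward the smaller prefix — equivalent to iteratively removing the
bottom rule), median absolute support (robust to single high-support true
rules), and top-`n` intersection counts between methods (a list shorter
than `n` contributes its full length). Ranking ties are broken by absolute
support, then lexicographically, making every ordering deterministic.

## Problem sizes and determinism

The default benchmark (2000 objects, ≈120-leaf hierarchies, ≈7–8k candidate
pairs) runs the full pipeline in well under a second, so the whole test
suite and the acceptance script are dominated by interpreter startup. All
randomness flows through a single `numpy` generator seeded from
`SynthConfig.seed` (hierarchies additionally mix in the ontology id so the
two trees differ in shape); the same seed yields byte-identical output
files.

## Known limitations

* Only `is_a` edges are honored when loading OBO files; other relationship
  types (e.g. `part_of`) are ignored by default since propagation
  semantics differ per relation.
* Mining is strictly pairwise; no itemsets of size > 2.
* The both-sides expectation takes the minimum over single-side parent
  candidates; a joint generalization over antecedent *and* consequent in
  one term is not implemented.
* GRL here is a faithful re-implementation of the published procedure, not
  a byte-level reproduction of any specific historical run.
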