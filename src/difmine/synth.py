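"""Synthetic benchmark generator: two hierarchies with planted cross-links.

Emulates the structure the mining method assumes: two rooted hierarchies
(optionally DAGs), objects annotated at the leaves (specific categories are
rare, their ancestors frequent — the usage pattern of curated annotation
databases), a set of planted one-to-one links between leaves of the two
hierarchies, and annotation noise.  A configurable share of the planted
links is forced to be *rare* — absolute co-occurrence support below 10 —
which is exactly the regime where support-threshold methods go blind.

Default parameters define the reference benchmark used throughout the test
suite: two depth-4 branching-3 trees (81 leaves each), 2000 objects, 20
planted links at link strength 0.9, noise rate 0.05 and 30% of links rare.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .annotations import AnnotationStore
from .evaluation import GroundTruth
from .mining import Item
from .ontology import Category, Ontology

__all__ = ["SynthConfig", "PlantedLink", "SyntheticDataset", "generate_ontology", "generate_annotations"]


@dataclass
class SynthConfig:
    """Benchmark parameters; fixed seed ⇒ byte-identical output."""

    seed: int = 42
    depth: int = 4                #: levels below the root in each hierarchy
    branching: int = 3            #: base number of children per internal node
    branch_jitter: float = 0.3    #: P(one extra child); 0.3 at depth 4 gives ~120 leaves
    dag_fraction: float = 0.0     #: share of non-root nodes given a 2nd parent
    n_objects: int = 2000
    n_planted_links: int = 20
    p_link: float = 0.9           #: P(linked partner co-annotated)
    rare_fraction: float = 0.3    #: share of links capped below support 10
    noise_rate: float = 0.05      #: P(extra random leaf per hierarchy)
    rare_max_support: int = 9     #: hard cap on a rare link's co-occurrence

    def __post_init__(self):
        for name in ("branch_jitter", "dag_fraction", "p_link", "rare_fraction", "noise_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.depth < 1 or self.branching < 1 or self.n_objects < 1:
            raise ValueError("depth, branching and n_objects must be >= 1")


class PlantedLink(NamedTuple):
    source: str       #: leaf of the first hierarchy
    target: str       #: leaf of the second hierarchy
    rare: bool
    cap: Optional[int]  #: co-occurrence cap for rare links, else None


class SyntheticDataset(NamedTuple):
    store: AnnotationStore    #: unclosed annotation store
    truth: GroundTruth
    links: tuple              #: the PlantedLink records, rare ones first


def generate_ontology(
    cfg: SynthConfig, ontology_id: str, rng: Optional[np.random.Generator] = None
) -> Ontology:
    """Build one rooted hierarchy of the configured depth and branching.

    Node ids encode the path from the root (``"O1:R.2.0.1"``), so the same
    seed always yields the same edge set; distinct ontology ids get distinct
    random streams, so the two hierarchies of a benchmark differ in shape.
    Each internal node gets ``branching`` children plus one more with
    probability ``branch_jitter``.  With ``dag_fraction > 0`` the stated
    share of non-root nodes receives one extra parent drawn from the level
    above, keeping the graph acyclic by construction.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, *ontology_id.encode()])
    root = f"{ontology_id}:R"
    levels: list[list[str]] = [[root]]
    parent_edges: dict[str, set[str]] = {}
    for _ in range(cfg.depth):
        nxt = []
        for parent in levels[-1]:
            width = cfg.branching + (1 if rng.random() < cfg.branch_jitter else 0)
            for i in range(width):
                child = f"{parent}.{i}"
                parent_edges[child] = {parent}
                nxt.append(child)
        levels.append(nxt)
    if cfg.dag_fraction > 0:
        for level_idx in range(1, len(levels)):
            pool = levels[level_idx - 1]
            if len(pool) < 2:
                continue
            for node in levels[level_idx]:
                if rng.random() < cfg.dag_fraction:
                    (first,) = parent_edges[node]
                    extra = pool[int(rng.integers(len(pool)))]
                    if extra != first:
                        parent_edges[node].add(extra)
    cats = [Category(id=root)] + [
        Category(id=n) for lvl in levels[1:] for n in lvl
    ]
    return Ontology(ontology_id, cats, parent_edges)


def _leaves(o: Ontology) -> list[str]:
    return sorted(n for n in o.nodes() if not o.children(n))


def generate_annotations(
    cfg: SynthConfig, o1: Ontology, o2: Ontology
) -> SyntheticDataset:
    """Draw objects, plant the cross-hierarchy links and add noise.

    Each object gets one uniform leaf of the first hierarchy.  If that leaf
    is a planted source, with probability ``p_link`` the object also gets
    the linked leaf of the second hierarchy, otherwise a random one.  Rare
    links stop co-annotating once their cap (< 10) is reached, and their
    endpoints are excluded from the noise pool, so a rare link's absolute
    support provably stays below 10.  The returned store is not yet
    ancestor-closed; the ground truth is the set of planted leaf pairs.
    """
    rng = np.random.default_rng(cfg.seed)
    leaves1, leaves2 = _leaves(o1), _leaves(o2)
    if cfg.n_planted_links > min(len(leaves1), len(leaves2)):
        raise ValueError(
            f"cannot plant {cfg.n_planted_links} links into hierarchies with "
            f"{len(leaves1)} and {len(leaves2)} leaves"
        )
    src = rng.choice(len(leaves1), size=cfg.n_planted_links, replace=False)
    dst = rng.choice(len(leaves2), size=cfg.n_planted_links, replace=False)
    n_rare = round(cfg.rare_fraction * cfg.n_planted_links)
    links = []
    for idx in range(cfg.n_planted_links):
        rare = idx < n_rare
        cap = int(rng.integers(4, cfg.rare_max_support + 1)) if rare else None
        links.append(PlantedLink(leaves1[src[idx]], leaves2[dst[idx]], rare, cap))
    partner = {l.source: l for l in links}
    rare_leaves1 = {l.source for l in links if l.rare}
    rare_leaves2 = {l.target for l in links if l.rare}
    noise1 = [x for x in leaves1 if x not in rare_leaves1]
    noise2 = [x for x in leaves2 if x not in rare_leaves2]

    store = AnnotationStore()
    co_count: dict[str, int] = {l.source: 0 for l in links}
    for i in range(cfg.n_objects):
        obj = f"obj{i:05d}"
        leaf1 = leaves1[int(rng.integers(len(leaves1)))]
        link = partner.get(leaf1)
        leaf2 = None
        if link is not None:
            capped = link.rare and co_count[leaf1] >= link.cap
            if not capped and rng.random() < cfg.p_link:
                leaf2 = link.target
            elif capped:
                # draw any other leaf so the rare pair cannot exceed its cap
                while leaf2 is None or leaf2 == link.target:
                    leaf2 = leaves2[int(rng.integers(len(leaves2)))]
        if leaf2 is None:
            leaf2 = leaves2[int(rng.integers(len(leaves2)))]
        if link is not None and leaf2 == link.target:
            co_count[leaf1] += 1
        labels1, labels2 = {leaf1}, {leaf2}
        if rng.random() < cfg.noise_rate:
            labels1.add(noise1[int(rng.integers(len(noise1)))])
        if rng.random() < cfg.noise_rate:
            labels2.add(noise2[int(rng.integers(len(noise2)))])
        store.add(obj, o1.ontology_id, labels1)
        store.add(obj, o2.ontology_id, labels2)

    truth = GroundTruth.from_pairs(
        ((Item(o1.ontology_id, l.source), Item(o2.ontology_id, l.target)) for l in links)
    )
    return SyntheticDataset(store=store, truth=truth, links=tuple(links))
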