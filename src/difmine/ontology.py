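"""Rooted category hierarchies (DAGs or trees) and their structural queries.

A hierarchy is a rooted directed acyclic graph of categories connected by
``is_a`` edges.  Every other stage of the pipeline — annotation closure,
expectation computation, structure-based pruning — reduces to ancestor,
descendant and distance queries answered here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, TextIO, Union

import networkx as nx
import obonet

__all__ = [
    "Category",
    "Ontology",
    "CycleError",
    "load_hierarchy",
    "dag_to_tree",
]


class CycleError(ValueError):
    """Raised when a hierarchy definition contains a cycle."""


@dataclass(frozen=True)
class Category:
    """A single category (term) of a hierarchy."""

    id: str
    name: str = ""
    obsolete: bool = False


class Ontology:
    """A rooted hierarchy of categories.

    Parameters
    ----------
    ontology_id
        Identifier used to address this hierarchy in annotation tables.
    categories
        All categories, including obsolete ones.  Obsolete categories carry
        no edges and do not take part in any structural query.
    parent_edges
        Mapping from a category id to the ids of its direct parents
        (``is_a`` targets).  Roots are the non-obsolete categories with no
        parents.
    provenance
        For hierarchies produced by :func:`dag_to_tree`: mapping from each
        node id (including duplicated copies like ``"D@B"``) back to the
        original category id.  Empty for hierarchies loaded from source.
    """

    def __init__(
        self,
        ontology_id: str,
        categories: Iterable[Category],
        parent_edges: Mapping[str, Iterable[str]],
        provenance: Optional[Mapping[str, str]] = None,
    ):
        self.ontology_id = ontology_id
        cat_list = list(categories)
        self.categories: dict[str, Category] = {c.id: c for c in cat_list}
        if len(self.categories) < len(cat_list):
            raise ValueError(f"duplicate category ids in ontology {ontology_id!r}")

        # child -> parent digraph over non-obsolete categories only
        g = nx.DiGraph()
        for cid, cat in self.categories.items():
            if not cat.obsolete:
                g.add_node(cid)
        for child, parents in parent_edges.items():
            if child not in self.categories:
                raise ValueError(f"edge references unknown category {child!r}")
            if self.categories[child].obsolete:
                continue
            for parent in parents:
                if parent not in self.categories:
                    raise ValueError(f"unknown parent id {parent!r} (child {child!r})")
                if self.categories[parent].obsolete:
                    continue
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(f"hierarchy contains a cycle through {cycle[0][0]!r}")
        self._graph = g
        self.roots: set[str] = {n for n in g.nodes if g.out_degree(n) == 0}
        self.provenance: dict[str, str] = dict(provenance or {})
        # original id -> copies, for annotation transfer onto tree copies
        self._copies: dict[str, list[str]] = {}
        for copy_id, orig in self.provenance.items():
            self._copies.setdefault(orig, []).append(copy_id)

    # -- basic introspection ------------------------------------------------

    def __contains__(self, category_id: str) -> bool:
        return category_id in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Ontology({self.ontology_id!r}, {len(self)} categories, "
            f"{len(self.roots)} roots)"
        )

    @property
    def graph(self) -> nx.DiGraph:
        """Child→parent digraph over non-obsolete categories."""
        return self._graph

    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    def parents(self, category_id: str) -> set[str]:
        self._check(category_id)
        return set(self._graph.successors(category_id))

    def children(self, category_id: str) -> set[str]:
        self._check(category_id)
        return set(self._graph.predecessors(category_id))

    def is_root(self, category_id: str) -> bool:
        return category_id in self.roots

    def resolve(self, category_id: str) -> set[str]:
        """Map a (possibly original) id onto the nodes representing it.

        On an ontology produced by :func:`dag_to_tree` an original
        multi-parent category is represented by several copies; annotations
        against the original id apply to every copy.
        """
        if category_id in self._graph:
            return {category_id}
        if category_id in self._copies:
            return set(self._copies[category_id])
        raise KeyError(f"unknown category {category_id!r} in {self.ontology_id!r}")

    # -- structural queries -------------------------------------------------

    def _check(self, category_id: str) -> None:
        if category_id not in self._graph:
            raise KeyError(f"unknown category {category_id!r} in {self.ontology_id!r}")

    def ancestors(self, category_id: str) -> set[str]:
        """All categories strictly above ``category_id`` (transitive)."""
        self._check(category_id)
        return nx.descendants(self._graph, category_id)

    def descendants(self, category_id: str) -> set[str]:
        """All categories strictly below ``category_id`` (transitive)."""
        self._check(category_id)
        return nx.ancestors(self._graph, category_id)

    def descendant_count(self, category_id: str) -> int:
        return len(self.descendants(category_id))

    def depth(self, category_id: str) -> int:
        """Longest path length from ``category_id`` up to any root."""
        self._check(category_id)
        return self._depth_memo(category_id)

    def _depth_memo(self, cid: str) -> int:
        cache = self.__dict__.setdefault("_depth_cache", {})
        if cid in cache:
            return cache[cid]
        parents = self.parents(cid)
        d = 0 if not parents else 1 + max(self._depth_memo(p) for p in parents)
        cache[cid] = d
        return d

    def edge_distance(self, a: str, b: str) -> Optional[int]:
        """Shortest undirected path length between ``a`` and ``b``.

        Returns ``None`` when the two categories lie in different connected
        components (a valid outcome, not an error).
        """
        self._check(a)
        self._check(b)
        if a == b:
            return 0
        try:
            return nx.shortest_path_length(self._graph.to_undirected(as_view=True), a, b)
        except nx.NetworkXNoPath:
            return None


# -- loading ------------------------------------------------------------------


def load_hierarchy(
    source: Union[str, TextIO],
    format: str = "obo",
    ontology_id: Optional[str] = None,
) -> Ontology:
    """Load a hierarchy from an OBO file or a child/parent edge table.

    Only ``is_a`` relationships are honoured in OBO input; obsolete terms
    are kept as categories but stripped of all edges.
    """
    if format == "obo":
        return _load_obo(source, ontology_id)
    if format == "edge-table":
        return _load_edge_table(source, ontology_id)
    raise ValueError(f"unknown hierarchy format {format!r}")


def _load_obo(source: Union[str, TextIO], ontology_id: Optional[str]) -> Ontology:
    graph = obonet.read_obo(source, ignore_obsolete=False)
    categories = []
    parent_edges: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        categories.append(Category(id=node, name=data.get("name", ""), obsolete=obsolete))
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        parent_edges.setdefault(child, set()).add(parent)
    oid = ontology_id or str(graph.graph.get("ontology", "ontology"))
    return Ontology(oid, categories, parent_edges)


def _load_edge_table(source: Union[str, TextIO], ontology_id: Optional[str]) -> Ontology:
    if isinstance(source, str):
        fh: TextIO = open(source)
        close = True
    else:
        fh, close = source, False
    try:
        parent_edges: dict[str, set[str]] = {}
        seen: set[str] = set()
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two columns, got {len(parts)}")
            child, parent = parts
            if lineno == 1 and {child.lower(), parent.lower()} == {"child", "parent"}:
                continue  # optional header
            seen.add(child)
            seen.add(parent)
            parent_edges.setdefault(child, set()).add(parent)
        categories = [Category(id=c) for c in sorted(seen)]
        return Ontology(ontology_id or "ontology", categories, parent_edges)
    finally:
        if close:
            fh.close()


# -- DAG to tree conversion ----------------------------------------------------


def dag_to_tree(o: Ontology) -> Ontology:
    """Duplicate multi-parent nodes so every category has exactly one parent.

    Each placement of a node under a distinct parent copy becomes its own
    node; when more than one placement exists the copies are named
    ``"<origid>@<parent-copy-id>"``.  The subtree below a duplicated node is
    duplicated with it.  The returned ontology carries a provenance map from
    every node back to its original id, so collapsing copies recovers the
    original category set.
    """
    order = list(nx.topological_sort(o.graph.reverse(copy=False)))  # roots first
    copies: dict[str, list[str]] = {}
    tree_parent: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for node in order:
        parents = sorted(o.parents(node))
        if not parents:
            copies[node] = [node]
            provenance[node] = node
            continue
        placements = [(p, cp) for p in parents for cp in copies[p]]
        node_copies = []
        for _, parent_copy in placements:
            cid = node if len(placements) == 1 else f"{node}@{parent_copy}"
            tree_parent[cid] = parent_copy
            provenance[cid] = node
            node_copies.append(cid)
        copies[node] = node_copies
    cats = []
    for cid, orig in provenance.items():
        base = o.categories[orig]
        cats.append(Category(id=cid, name=base.name, obsolete=False))
    # obsolete categories pass through untouched (no edges to duplicate)
    for cat in o.categories.values():
        if cat.obsolete:
            cats.append(cat)
    edges = {c: {p} for c, p in tree_parent.items()}
    return Ontology(o.ontology_id, cats, edges, provenance=provenance)
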