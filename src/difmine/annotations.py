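"""The transaction database: objects annotated with hierarchy categories.

Each object (a protein, a Wikipedia entry, ...) is one transaction whose
items are the categories annotated to it across one or two hierarchies.
Preprocessing mirrors curated-annotation practice: evidence-code filtering
(e.g. dropping IEA, "inferred from electronic annotation") and ancestor
closure — an object annotated with a category implicitly belongs to all of
that category's ancestors.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence, TextIO, Union

from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = ["AnnotationStore", "load_annotations", "ancestor_closure", "unique_combinations"]


class AnnotationStore:
    """Object → per-ontology category-set mapping; the transaction set.

    ``N`` (the total transaction count used by relative supports) is the
    number of objects in the store, including objects that carry labels in
    only one — or neither — of the hierarchies of a given mining run.
    """

    def __init__(self, objects: Optional[Iterable[str]] = None):
        self.objects: set[str] = set(objects or ())
        self._labels: dict[tuple[str, str], set[str]] = {}
        self.closed: bool = False
        self.dropped_unknown: int = 0
        self.dropped_evidence: int = 0

    @property
    def N(self) -> int:
        return len(self.objects)

    def ontology_ids(self) -> set[str]:
        return {ont for (_, ont) in self._labels}

    def add(self, object_id: str, ontology_id: str, category_ids: Iterable[str]) -> None:
        self.objects.add(object_id)
        self._labels.setdefault((object_id, ontology_id), set()).update(category_ids)

    def labels(self, object_id: str, ontology_id: str) -> set[str]:
        return self._labels.get((object_id, ontology_id), set())

    def iter_labelled(self, ontology_ids: Sequence[str]):
        """Yield (object_id, {ontology_id: labels}) for objects with >=1 label."""
        for obj in sorted(self.objects):
            per_ont = {
                ont: self._labels[(obj, ont)]
                for ont in ontology_ids
                if (obj, ont) in self._labels and self._labels[(obj, ont)]
            }
            if per_ont:
                yield obj, per_ont

    def copy(self) -> "AnnotationStore":
        out = AnnotationStore(self.objects)
        out._labels = {k: set(v) for k, v in self._labels.items()}
        out.closed = self.closed
        out.dropped_unknown = self.dropped_unknown
        out.dropped_evidence = self.dropped_evidence
        return out


def _resolve_ontology(ontologies: Sequence[Ontology], category_id: str) -> Optional[Ontology]:
    for o in ontologies:
        try:
            o.resolve(category_id)
            return o
        except KeyError:
            continue
    return None


def load_annotations(
    source: Union[str, TextIO],
    format: str,
    ontologies: Sequence[Ontology],
    exclude_evidence: Iterable[str] = (),
) -> AnnotationStore:
    """Read annotation records from a TSV or GAF-like stream.

    TSV columns: ``object_id<TAB>ontology_id<TAB>category_id[<TAB>evidence]``.
    GAF-like input uses the GAF 2.x column positions: object id in column 2,
    category id in column 5, evidence code in column 7; the ontology is
    inferred by looking the category up in the supplied hierarchies.

    Records whose evidence code is excluded, or whose category id is unknown
    to every supplied hierarchy, are dropped (unknown-category drops are
    counted and logged).  A malformed line is logged and skipped; if every
    line is malformed the input is rejected.
    """
    if format not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation format {format!r}")
    excl = set(exclude_evidence)
    by_id = {o.ontology_id: o for o in ontologies}
    if isinstance(source, str):
        fh: TextIO = open(source)
        close = True
    else:
        fh, close = source, False
    store = AnnotationStore()
    n_lines = n_bad = 0
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            n_lines += 1
            parts = line.split("\t")
            try:
                if format == "tsv":
                    if len(parts) < 3:
                        raise ValueError("need >=3 columns")
                    obj, ont_id, cat = parts[0], parts[1], parts[2]
                    evidence = parts[3] if len(parts) > 3 else ""
                    ontology = by_id.get(ont_id)
                    if ontology is None:
                        raise ValueError(f"unknown ontology {ont_id!r}")
                else:  # gaf
                    if len(parts) < 7:
                        raise ValueError("need >=7 columns")
                    obj, cat, evidence = parts[1], parts[4], parts[6]
                    ontology = _resolve_ontology(ontologies, cat)
            except ValueError as exc:
                n_bad += 1
                logger.warning("skipping malformed line %d: %s", lineno, exc)
                continue
            if evidence and evidence in excl:
                store.dropped_evidence += 1
                continue
            if ontology is None:
                store.dropped_unknown += 1
                continue
            try:
                node_ids = ontology.resolve(cat)
            except KeyError:
                store.dropped_unknown += 1
                continue
            store.add(obj, ontology.ontology_id, node_ids)
        if n_lines and n_bad == n_lines:
            raise ValueError("all annotation lines were malformed")
    finally:
        if close:
            fh.close()
    if store.dropped_unknown:
        logger.info("dropped %d records with unknown categories", store.dropped_unknown)
    return store


def ancestor_closure(store: AnnotationStore, ontologies: Sequence[Ontology]) -> AnnotationStore:
    """Expand every label set with all ancestors of its categories.

    Idempotent; returns a new closed store and leaves the input untouched.
    """
    by_id = {o.ontology_id: o for o in ontologies}
    out = store.copy()
    anc_cache: dict[tuple[str, str], set[str]] = {}
    for (obj, ont_id), labels in out._labels.items():
        ontology = by_id.get(ont_id)
        if ontology is None:
            raise KeyError(f"no hierarchy supplied for ontology {ont_id!r}")
        expanded = set(labels)
        for cat in labels:
            key = (ont_id, cat)
            if key not in anc_cache:
                anc_cache[key] = ontology.ancestors(cat)
            expanded |= anc_cache[key]
        labels.clear()
        labels.update(expanded)
    out.closed = True
    return out


def unique_combinations(
    store: AnnotationStore, ontology_ids: Sequence[str]
) -> Counter:
    """Distinct closed label-sets (restricted to the given hierarchies).

    Returns a :class:`collections.Counter` mapping each distinct label set —
    a frozenset of ``(ontology_id, category_id)`` items — to the number of
    objects sharing it.  Objects with no label in the chosen hierarchies do
    not contribute.  This is the "unique combinations" basis on which the
    agreement statistic is computed.
    """
    if not store.closed:
        raise ValueError("unique_combinations requires a closed store")
    combos: Counter = Counter()
    for _, per_ont in store.iter_labelled(ontology_ids):
        items = frozenset(
            (ont, cat) for ont, labels in per_ont.items() for cat in labels
        )
        combos[items] += 1
    return combos
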