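"""Small built-in example datasets, constructed programmatically.

``retail_example`` is the classic clothing/footwear teaching example for
hierarchical expectation: a three-level clothing hierarchy whose categories
co-occur with a single footwear category, with item supports chosen so that
a frequent specialized rule (Jackets → Hiking Boots) *underperforms* its
parent rule while a rare one (Travel Pants → Hiking Boots) outperforms it.
"""

from __future__ import annotations

from .annotations import AnnotationStore
from .ontology import Category, Ontology

__all__ = ["retail_example"]


def retail_example() -> tuple[Ontology, Ontology, AnnotationStore]:
    """The clothing/footwear example transaction set.

    1000 transactions.  Item supports after ancestor closure:
    Clothes 150, Outerwear 100, Jackets 90, Travel Pants 15, Hiking Boots 30;
    pair supports with Hiking Boots: Clothes 30, Outerwear 20, Jackets 15,
    Travel Pants 10.  Returns the two hierarchies and the (unclosed) store.
    """
    clothes = Ontology(
        "clothes",
        [
            Category("Clothes"),
            Category("Outerwear"),
            Category("Jackets"),
            Category("Travel Pants"),
        ],
        {
            "Outerwear": {"Clothes"},
            "Jackets": {"Outerwear"},
            "Travel Pants": {"Clothes"},
        },
    )
    footwear = Ontology("footwear", [Category("Hiking Boots")], {})

    # group composition: (count, clothes labels, has hiking boots)
    groups = [
        (15, {"Jackets"}, True),
        (75, {"Jackets"}, False),
        (5, {"Outerwear"}, True),
        (5, {"Outerwear"}, False),
        (10, {"Travel Pants"}, True),
        (5, {"Travel Pants"}, False),
        (35, {"Clothes"}, False),
        (850, set(), False),
    ]
    store = AnnotationStore()
    i = 0
    for count, labels, boots in groups:
        for _ in range(count):
            obj = f"t{i:04d}"
            store.objects.add(obj)
            if labels:
                store.add(obj, "clothes", labels)
            if boots:
                store.add(obj, "footwear", {"Hiking Boots"})
            i += 1
    return clothes, footwear, store
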