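"""Reading and writing the tool's delimited text formats.

Everything is tab-separated plain text with a stable column order, so rule
tables and reports diff cleanly between runs.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

from .evaluation import GroundTruth
from .mining import Item, Rule

__all__ = ["rules_to_frame", "write_rules", "read_rules", "load_ground_truth", "write_ground_truth"]

_BASE_COLUMNS = [
    "rule_id",
    "antecedent_ontology",
    "antecedent",
    "consequent_ontology",
    "consequent",
    "n_ab",
    "n_a",
    "n_b",
    "N",
]


def rules_to_frame(
    rules: Sequence[Rule],
    measures: Optional[Sequence[str]] = None,
    precision: Optional[int] = 3,
) -> pd.DataFrame:
    """Tabulate rules; measure values rounded unless ``precision`` is None."""
    if measures is None:
        seen: dict[str, None] = {}
        for r in rules:
            for m in r.measures:
                seen.setdefault(m)
        measures = list(seen)
    rows = []
    for i, r in enumerate(rules, start=1):
        row = {
            "rule_id": i,
            "antecedent_ontology": r.antecedent.ontology,
            "antecedent": r.antecedent.category,
            "consequent_ontology": r.consequent.ontology,
            "consequent": r.consequent.category,
            "n_ab": r.n_ab,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "N": r.N,
        }
        for m in measures:
            v = r.measures.get(m)
            row[m] = round(v, precision) if (v is not None and precision is not None) else v
        row["expectation"] = (
            round(r.expectation, precision)
            if (r.expectation is not None and precision is not None)
            else r.expectation
        )
        row["flags"] = ",".join(sorted(r.flags))
        rows.append(row)
    return pd.DataFrame(rows, columns=_BASE_COLUMNS + list(measures) + ["expectation", "flags"])


def write_rules(
    rules: Sequence[Rule],
    path: Union[str, TextIO],
    measures: Optional[Sequence[str]] = None,
    precision: Optional[int] = 3,
) -> None:
    rules_to_frame(rules, measures, precision).to_csv(path, sep="\t", index=False)


def read_rules(path: Union[str, TextIO]) -> list[Rule]:
    df = pd.read_csv(path, sep="\t")
    measure_cols = [c for c in df.columns if c not in _BASE_COLUMNS + ["expectation", "flags"]]
    rules = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        rules.append(
            Rule(
                antecedent=Item(str(d["antecedent_ontology"]), str(d["antecedent"])),
                consequent=Item(str(d["consequent_ontology"]), str(d["consequent"])),
                n_ab=int(d["n_ab"]),
                n_a=int(d["n_a"]),
                n_b=int(d["n_b"]),
                N=int(d["N"]),
                measures={
                    m: float(d[m]) for m in measure_cols if pd.notna(d[m])
                },
                expectation=float(d["expectation"]) if pd.notna(d["expectation"]) else None,
                flags=set(str(d["flags"]).split(",")) if pd.notna(d["flags"]) and d["flags"] else set(),
            )
        )
    return rules


def load_ground_truth(
    path: Union[str, TextIO], ontology_a: str, ontology_b: str
) -> GroundTruth:
    """Two-column delimited text, one unordered category pair per line.

    Column 1 is read against ``ontology_a``, column 2 against ``ontology_b``.
    """
    if isinstance(path, str):
        fh: TextIO = open(path)
        close = True
    else:
        fh, close = path, False
    pairs = []
    try:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"expected two columns in ground-truth line {line!r}")
            pairs.append((Item(ontology_a, parts[0]), Item(ontology_b, parts[1])))
    finally:
        if close:
            fh.close()
    return GroundTruth.from_pairs(pairs)


def write_ground_truth(truth: GroundTruth, path: str, ontology_a: str) -> None:
    """Write pairs with the ``ontology_a`` member in the first column."""
    with open(path, "w") as fh:
        for pair in sorted(truth.pairs):
            first = next(i for i in pair if i.ontology == ontology_a)
            second = next(i for i in pair if i is not first)
            fh.write(f"{first.category}\t{second.category}\n")
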