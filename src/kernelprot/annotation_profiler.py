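"""Functional category tallies (GO biological process / cellular component /
molecular function, and COG) per tissue.

Counting is flat multi-membership: a protein carrying k categories in a
namespace contributes to k tallies.  No GO DAG propagation is performed —
the input map is taken as an already-sliced flat classification, so counts
do not depend on any ontology release.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .quant_io import NAMESPACES, AnnotationMap

UNANNOTATED = "__unannotated__"


@dataclass(frozen=True)
class CategoryTally:
    namespace: str
    category: str
    pericarp_count: int
    endosperm_count: int


def tally(
    amap: AnnotationMap,
    protein_sets: Mapping[str, set[str]],
    namespace: str,
    top: int | None = None,
) -> list[CategoryTally]:
    """Per-category protein counts for each tissue, sorted by total descending.

    ``protein_sets`` maps tissue name -> protein id set (the caller chooses
    whether that is all identified proteins or DEPs only).  Proteins with no
    annotation in the namespace are tallied under the ``__unannotated__``
    bucket.  Equal totals break ties lexicographically by category label.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    tissues = list(protein_sets)
    counts: dict[str, dict[str, int]] = {}
    for tissue in tissues:
        for pid in protein_sets[tissue]:
            cats = amap.categories(pid, namespace)
            if not cats:
                cats = {UNANNOTATED}
            for cat in cats:
                counts.setdefault(cat, {t: 0 for t in tissues})[tissue] += 1
    tallies = [
        CategoryTally(
            namespace=namespace,
            category=cat,
            pericarp_count=c.get("pericarp", 0),
            endosperm_count=c.get("endosperm", 0),
        )
        for cat, c in counts.items()
    ]
    tallies.sort(key=lambda t: (-(t.pericarp_count + t.endosperm_count), t.category))
    return tallies[:top] if top is not None else tallies


def tissue_exclusive_categories(
    amap: AnnotationMap,
    protein_sets: Mapping[str, set[str]],
    namespace: str,
) -> dict[str, dict[str, set[str]]]:
    """Categories present in exactly one tissue, with witnessing protein ids.

    Returns tissue -> {category -> protein ids carrying it in that tissue}.
    """
    per_tissue: dict[str, dict[str, set[str]]] = {}
    for tissue, pids in protein_sets.items():
        cats: dict[str, set[str]] = {}
        for pid in pids:
            for cat in amap.categories(pid, namespace):
                cats.setdefault(cat, set()).add(pid)
        per_tissue[tissue] = cats
    out: dict[str, dict[str, set[str]]] = {t: {} for t in protein_sets}
    for tissue, cats in per_tissue.items():
        others = set().union(
            *(set(c) for t, c in per_tissue.items() if t != tissue)
        ) if len(per_tissue) > 1 else set()
        for cat, pids in cats.items():
            if cat not in others:
                out[tissue][cat] = pids
    return out


def tally_table(tallies: Iterable[CategoryTally]):
    """Tallies as a pandas DataFrame for export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "namespace": t.namespace,
                "category": t.category,
                "pericarp": t.pericarp_count,
                "endosperm": t.endosperm_count,
            }
            for t in tallies
        ],
        columns=["namespace", "category", "pericarp", "endosperm"],
    )
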