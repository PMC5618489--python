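"""KEGG-orthology interaction-network integration.

Strongly regulated proteins (consensus ratio >= min_fold or <= 1/min_fold at
any stage; default 5) seed a typed graph.  Each seed protein is mapped
protein -> gene model -> KEGG orthology (KO) id, KOs are linked to pathways
through an offline two-column link table (the flat format of the KEGG REST
``link`` endpoint), and the network is expanded by pathway co-membership:

* first-degree interactors share >= 1 pathway with a seed KO;
* second-degree interactors share >= 1 pathway with a first-degree KO but
  with no seed (shortest-hop labeling keeps the roles a partition).

"Interaction" here is operationalized as KO co-membership in a KEGG
pathway — the integration uses no physical protein-protein-interaction
database, only pathway linking.  Exports are Cytoscape-compatible SIF and
GraphML plus a node-attribute TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .dep_analysis import DepCall
from .quant_io import OrthologMap, PathwayLinkTable

ROLES = ("stage", "dep", "first_degree", "second_degree", "ortholog_annotation")


@dataclass(frozen=True)
class NetworkConfig:
    min_fold: float = 5.0
    max_degree: int = 2
    include_stage_nodes: bool = True

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if self.max_degree not in (1, 2):
            raise ValueError("max_degree must be 1 or 2")


@dataclass
class NetworkSummary:
    n_dep: int
    n_first: int
    n_second: int
    n_pathways: int

    @property
    def n_total_interactors(self) -> int:
        return self.n_first + self.n_second


def filter_candidates(
    consensus_ratios: Mapping[str, Mapping[int, float]], config: NetworkConfig
) -> set[str]:
    """Seed set: proteins whose ratio crosses the two-sided min_fold at any stage."""
    lo = 1.0 / config.min_fold
    kept = set()
    for pid, per_stage in consensus_ratios.items():
        for ratio in per_stage.values():
            if ratio <= 0:
                raise ValueError(f"non-positive ratio for {pid}")
            if ratio >= config.min_fold or ratio <= lo:
                kept.add(pid)
                break
    return kept


def strip_protein_suffix(protein_id: str) -> str:
    """Drop a trailing protein-isoform suffix like ``_P01`` to get the gene model."""
    if "_P" in protein_id:
        stem, _, tail = protein_id.rpartition("_P")
        if tail.isdigit():
            return stem
    return protein_id


def map_orthology(
    seeds: Iterable[str], omap: OrthologMap
) -> tuple[dict[str, str], list[str]]:
    """protein -> KO for each seed; seeds without a KO go to the unmapped list."""
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for pid in sorted(set(seeds)):
        gene = omap.protein_to_gene.get(pid)
        if gene is None:
            gene = strip_protein_suffix(pid)
            gene = omap.protein_to_gene.get(gene, gene)
        ko = omap.gene_to_ko.get(gene)
        if ko is None:
            unmapped.append(pid)
        else:
            mapped[pid] = ko
    return mapped, unmapped


def _proteins_by_ko(proteome_ko: Mapping[str, str]) -> dict[str, set[str]]:
    by_ko: dict[str, set[str]] = {}
    for pid, ko in proteome_ko.items():
        by_ko.setdefault(ko, set()).add(pid)
    return by_ko


@dataclass
class Expansion:
    first_degree: set[str]
    second_degree: set[str]
    #: node -> pathway ids witnessing its attachment
    witness: dict[str, set[str]] = field(default_factory=dict)
    #: seed proteins whose KO belongs to no pathway
    isolated_seeds: list[str] = field(default_factory=list)


def expand_interactions(
    seed_kos: Mapping[str, str],
    links: PathwayLinkTable,
    proteome_ko: Mapping[str, str],
    max_degree: int = 2,
) -> Expansion:
    """Depth-limited pathway co-membership expansion around the seed KOs.

    Equivalent to a breadth-first search of depth ``max_degree`` on the KO
    co-membership graph, mapped back to proteins through ``proteome_ko``.
    """
    ko_pathways: dict[str, set[str]] = {}
    for ko, pw in links.pairs:
        ko_pathways.setdefault(ko, set()).add(pw)
    by_ko = _proteins_by_ko(proteome_ko)

    seed_proteins = set(seed_kos)
    seed_ko_set = set(seed_kos.values())
    isolated = sorted(
        pid for pid, ko in seed_kos.items() if not ko_pathways.get(ko)
    )

    witness: dict[str, set[str]] = {}

    def co_members(kos: set[str]) -> tuple[set[str], dict[str, set[str]]]:
        """KOs sharing >= 1 pathway with the given set, with witness pathways."""
        hit: dict[str, set[str]] = {}
        pathways = set().union(*(ko_pathways.get(k, set()) for k in kos)) if kos else set()
        for pw in pathways:
            for ko in links.members_of(pw):
                hit.setdefault(ko, set()).add(pw)
        return set(hit), hit

    # a KO co-occurs with itself in any pathway that contains it, so a
    # non-seed protein carrying a seed KO counts as first-degree
    first_kos_all, w1 = co_members(seed_ko_set)
    first_proteins = (
        set().union(*(by_ko.get(k, set()) for k in first_kos_all))
        if first_kos_all
        else set()
    )
    first_proteins -= seed_proteins
    for pid in first_proteins:
        witness[pid] = set(w1[proteome_ko[pid]])

    second_proteins: set[str] = set()
    if max_degree >= 2 and first_kos_all:
        second_kos_all, w2 = co_members(first_kos_all)
        second_kos = second_kos_all - seed_ko_set - first_kos_all
        second_proteins = (
            set().union(*(by_ko.get(k, set()) for k in second_kos)) if second_kos else set()
        )
        second_proteins -= seed_proteins | first_proteins
        for pid in second_proteins:
            witness[pid] = set(w2[proteome_ko[pid]])

    return Expansion(
        first_degree=first_proteins,
        second_degree=second_proteins,
        witness=witness,
        isolated_seeds=isolated,
    )


def build_network(
    seeds: Iterable[str],
    expansion: Expansion,
    stage_attribution: Mapping[str, Sequence[int]],
    proteome_ko: Mapping[str, str],
    links: PathwayLinkTable,
    annotations: Mapping[str, str] | None = None,
    include_stage_nodes: bool = True,
    stages: Sequence[int] | None = None,
) -> nx.Graph:
    """Assemble the typed graph: stage, DEP, interactor and annotation nodes.

    ``stage_attribution`` maps each seed protein to the stages at which it is
    differential; dep-interactor and interactor-interactor edges carry the
    witnessing pathway ids.
    """
    ko_pathways: dict[str, set[str]] = {}
    for ko, pw in links.pairs:
        ko_pathways.setdefault(ko, set()).add(pw)

    g = nx.Graph()
    seeds = sorted(set(seeds))
    for pid in seeds:
        ko = proteome_ko.get(pid, "")
        g.add_node(
            pid, role="dep", ko=ko, pathways=sorted(ko_pathways.get(ko, set()))
        )
    for pid in sorted(expansion.first_degree):
        ko = proteome_ko.get(pid, "")
        g.add_node(pid, role="first_degree", ko=ko, pathways=sorted(expansion.witness.get(pid, set())))
    for pid in sorted(expansion.second_degree):
        ko = proteome_ko.get(pid, "")
        g.add_node(pid, role="second_degree", ko=ko, pathways=sorted(expansion.witness.get(pid, set())))

    if include_stage_nodes:
        for stage in stages or ():
            g.add_node(f"stage:{stage}DAP", role="stage", stage=stage)
        for pid in seeds:
            for stage in stage_attribution.get(pid, ()):
                node = f"stage:{stage}DAP"
                if node not in g:
                    g.add_node(node, role="stage", stage=stage)
                g.add_edge(node, pid, type="stage-dep")

    # dep-interactor edges where a pathway is shared
    for pid in sorted(expansion.first_degree):
        pw_first = expansion.witness.get(pid, set())
        for seed in seeds:
            shared = pw_first & ko_pathways.get(proteome_ko.get(seed, ""), set())
            if shared:
                g.add_edge(seed, pid, type="dep-interactor", pathways=sorted(shared))
    # interactor-interactor edges (first <-> second via shared pathway)
    for pid in sorted(expansion.second_degree):
        pw_second = expansion.witness.get(pid, set())
        for fid in sorted(expansion.first_degree):
            ko_f = proteome_ko.get(fid, "")
            shared = pw_second & ko_pathways.get(ko_f, set())
            if shared:
                g.add_edge(fid, pid, type="interactor-interactor", pathways=sorted(shared))

    if annotations:
        for pid, label in sorted(annotations.items()):
            if pid in g:
                node = f"annot:{label}"
                if node not in g:
                    g.add_node(node, role="ortholog_annotation", label=label)
                g.add_edge(pid, node, type="node-annotation")
    return g


def summarize(g: nx.Graph) -> NetworkSummary:
    """Counts by node role plus the distinct witnessing pathway count."""
    roles = nx.get_node_attributes(g, "role")
    pathways: set[str] = set()
    for _, data in g.nodes(data=True):
        pathways.update(data.get("pathways", ()))
    return NetworkSummary(
        n_dep=sum(1 for r in roles.values() if r == "dep"),
        n_first=sum(1 for r in roles.values() if r == "first_degree"),
        n_second=sum(1 for r in roles.values() if r == "second_degree"),
        n_pathways=len(pathways),
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def write_sif(g: nx.Graph, path) -> None:
    """One interaction per line: source <tab> edge-type <tab> target."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data.get('type', 'interacts')}\t{v}\n")


def write_graphml(g: nx.Graph, path) -> None:
    # GraphML attributes must be scalars; serialize pathway lists
    h = g.copy()
    for _, data in h.nodes(data=True):
        if "pathways" in data:
            data["pathways"] = "|".join(data["pathways"])
    for _, _, data in h.edges(data=True):
        if "pathways" in data:
            data["pathways"] = "|".join(data["pathways"])
    nx.write_graphml(h, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, data in g.nodes(data=True):
        d = dict(data)
        if "pathways" in d:
            d["pathways"] = d["pathways"].split("|") if d["pathways"] else []
        out.add_node(n, **d)
    for u, v, data in g.edges(data=True):
        d = dict(data)
        if "pathways" in d:
            d["pathways"] = d["pathways"].split("|") if d["pathways"] else []
        out.add_edge(u, v, **d)
    return out


def write_node_attributes(g: nx.Graph, path) -> None:
    import pandas as pd

    rows = [
        {
            "node": n,
            "role": d.get("role", ""),
            "stage": d.get("stage", ""),
            "ko": d.get("ko", ""),
            "pathways": "|".join(d.get("pathways", ())),
        }
        for n, d in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["node", "role", "stage", "ko", "pathways"]).to_csv(
        path, sep="\t", index=False
    )
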