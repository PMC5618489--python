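#!/usr/bin/env python
"""Build the per-tissue KEGG-orthology interaction networks.

Seeds each network with proteins changing at least 5-fold (either
direction) at any stage, maps seeds protein -> gene model -> KO, links KOs
to pathways through the offline link table, expands first- and
second-degree interactors by pathway co-membership, and exports SIF,
GraphML and node-attribute tables under results/.
"""

import json
from pathlib import Path

from kernelprot import network_integration as ni
from kernelprot.dep_analysis import consensus_calls
from kernelprot.network_integration import NetworkConfig
from kernelprot.quant_io import (
    StageDesign,
    read_ortholog_map,
    read_pathway_links,
    read_quant_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = StageDesign()
    records = read_quant_table(ROOT / "sim" / "quant.tsv")
    calls, _ = consensus_calls(records, design)
    omap = read_ortholog_map(ROOT / "sim" / "ortholog_map.tsv")
    links = read_pathway_links(ROOT / "sim" / "pathway_links.tsv", strict=False)
    proteome_ko = {
        pid: omap.gene_to_ko[g]
        for pid, g in omap.protein_to_gene.items()
        if g in omap.gene_to_ko
    }
    cfg = NetworkConfig()
    summaries = {}
    for tissue in ("pericarp", "endosperm"):
        ratios, stage_attr = {}, {}
        for c in calls:
            if c.tissue != tissue:
                continue
            ratios.setdefault(c.protein_id, {})[c.stage] = c.ratio
            if c.verdict != "none":
                stage_attr.setdefault(c.protein_id, []).append(c.stage)
        seeds = ni.filter_candidates(ratios, cfg)
        seed_kos, unmapped = ni.map_orthology(seeds, omap)
        exp = ni.expand_interactions(seed_kos, links, proteome_ko, cfg.max_degree)
        g = ni.build_network(
            seed_kos, exp, stage_attr, proteome_ko, links, stages=design.stages
        )
        ni.write_sif(g, ROOT / f"network_{tissue}.sif")
        ni.write_graphml(g, ROOT / f"network_{tissue}.graphml")
        ni.write_node_attributes(g, ROOT / f"network_{tissue}_nodes.tsv")
        s = ni.summarize(g)
        summaries[tissue] = {
            "n_dep": s.n_dep,
            "n_first_degree": s.n_first,
            "n_second_degree": s.n_second,
            "n_total_interactors": s.n_total_interactors,
            "n_pathways": s.n_pathways,
            "n_unmapped_seeds": len(unmapped),
        }
        print(
            f"{tissue}: {s.n_dep} seed DEPs, {s.n_first} first-degree and "
            f"{s.n_second} second-degree interactors "
            f"({s.n_total_interactors} total) across {s.n_pathways} pathways"
        )
    (ROOT / "network_summaries.json").write_text(json.dumps(summaries, indent=2))


if __name__ == "__main__":
    main()
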