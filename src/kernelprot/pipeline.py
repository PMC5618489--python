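"""End-to-end orchestration: quant -> DEP calls -> patterns -> annotation ->
network, with a run report mirroring the identification-summary layout
(per-stage counts per tissue, totals, non-redundant counts).

Every protein dropped at any stage is logged with a machine-readable reason
code; the report's arithmetic identities (per-tissue total = sum of stage
counts, Venn inclusion-exclusion) hold by construction and are asserted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_profiler, network_integration, pattern_clustering
from .dep_analysis import (
    DepCall,
    DepThresholds,
    assess_concordance,
    consensus_calls,
    count_updown,
    mrna_fold_changes,
    partition_stages,
    partition_tissues,
)
from .network_integration import NetworkConfig
from .pattern_clustering import TemporalProfile, classify_pattern, summarize_patterns
from .quant_io import (
    StageDesign,
    read_annotation_map,
    read_ct_table,
    read_ortholog_map,
    read_pathway_links,
    read_quant_table,
)


@dataclass
class RunConfig:
    quant_table: str
    out_dir: str
    annotation_map: str | None = None
    ortholog_map: str | None = None
    pathway_links: str | None = None
    ct_table: str | None = None
    thresholds: DepThresholds = field(default_factory=DepThresholds)
    pattern_tolerance: float = pattern_clustering.DEFAULT_TOLERANCE
    network: NetworkConfig = field(default_factory=NetworkConfig)
    concordance_cutoff: float = 0.5
    strict_ko: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        thresholds = DepThresholds(**raw.pop("thresholds", {}))
        network = NetworkConfig(**raw.pop("network", {}))
        return cls(thresholds=thresholds, network=network, **raw)

    def validate(self) -> None:
        for name in ("quant_table", "annotation_map", "ortholog_map",
                     "pathway_links", "ct_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")


@dataclass
class RunResult:
    calls: list[DepCall]
    summary_table: pd.DataFrame
    report: dict
    dropped: dict[str, str]


def _stage_presence(
    calls: list[DepCall], tissue: str
) -> dict[int, set[str]]:
    sets: dict[int, set[str]] = {}
    for c in calls:
        if c.tissue == tissue:
            sets.setdefault(c.stage, set()).add(c.protein_id)
    return sets


def identification_summary(
    calls: list[DepCall], design: StageDesign, tissues: tuple[str, str] = ("pericarp", "endosperm")
) -> pd.DataFrame:
    """Identification-count table: per-stage counts, stage-sum total, and
    non-redundant (distinct) count per tissue, plus Total/Nonredundance rows.
    """
    rows = {}
    for tissue in tissues:
        presence = _stage_presence(calls, tissue)
        stage_counts = [len(presence.get(s, set())) for s in design.stages]
        distinct = set().union(*presence.values()) if presence else set()
        rows[tissue] = stage_counts + [sum(stage_counts), len(distinct)]
    total_row = [sum(rows[t][i] for t in tissues) for i in range(len(design.stages) + 1)]
    all_by_stage = [
        set().union(
            *(_stage_presence(calls, t).get(s, set()) for t in tissues)
        )
        for s in design.stages
    ]
    union_all = set().union(*all_by_stage) if all_by_stage else set()
    total_row.append(len(union_all))
    nonred_row = [len(s) for s in all_by_stage] + [len(union_all), len(union_all)]
    cols = [f"{s} DAP" for s in design.stages] + ["Total", "Nonredundance"]
    df = pd.DataFrame(
        [rows[tissues[0]], rows[tissues[1]], total_row, nonred_row],
        index=[tissues[0], tissues[1], "Total", "Nonredundance"],
        columns=cols,
    )
    return df


def temporal_profiles(
    calls: list[DepCall], design: StageDesign
) -> list[TemporalProfile]:
    """Consensus log2-ratio profiles for proteins quantified at every stage."""
    by_pt: dict[tuple[str, str], dict[int, float]] = {}
    for c in calls:
        by_pt.setdefault((c.protein_id, c.tissue), {})[c.stage] = c.ratio
    profiles = []
    for (pid, tissue), ratios in sorted(by_pt.items()):
        if set(ratios) == set(design.stages):
            profiles.append(
                TemporalProfile(
                    protein_id=pid,
                    tissue=tissue,
                    stages=tuple(design.stages),
                    log2_values=tuple(
                        float(np.log2(ratios[s])) for s in design.stages
                    ),
                )
            )
    return profiles


def run_all(config: RunConfig, design: StageDesign | None = None) -> RunResult:
    """Execute the full pipeline and write report files under ``out_dir``."""
    config.validate()
    design = design or StageDesign()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    # --- quantification + DEP calling ---
    records = read_quant_table(config.quant_table)
    calls, dropped = consensus_calls(records, design, config.thresholds)
    calls_df = pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "tissue": c.tissue,
                "stage": c.stage,
                "ratio": c.ratio,
                "verdict": c.verdict,
                "replicate_support": c.replicate_support,
            }
            for c in calls
        ]
    )
    calls_df.to_csv(out / "dep_calls.tsv", sep="\t", index=False, float_format="%.6g")
    if dropped:
        pd.DataFrame(
            [{"protein_id": k, "reason": "control_invalid:" + v} for k, v in sorted(dropped.items())]
        ).to_csv(out / "dropped.tsv", sep="\t", index=False)

    summary = identification_summary(calls, design)
    summary.to_csv(out / "identification_summary.tsv", sep="\t")
    # arithmetic identities of the report
    for tissue in ("pericarp", "endosperm"):
        assert summary.loc[tissue, "Total"] == sum(
            summary.loc[tissue, f"{s} DAP"] for s in design.stages
        )

    tissue_sets = {
        t: {c.protein_id for c in calls if c.tissue == t}
        for t in ("pericarp", "endosperm")
    }
    venn = partition_tissues(tissue_sets["pericarp"], tissue_sets["endosperm"])
    assert (
        len(venn.a_specific) + len(venn.b_specific) + len(venn.shared)
        == len(tissue_sets["pericarp"] | tissue_sets["endosperm"])
    )
    report["venn"] = {
        "pericarp_specific": len(venn.a_specific),
        "endosperm_specific": len(venn.b_specific),
        "shared": len(venn.shared),
        "union": venn.union_size,
    }
    report["stage_partition"] = {}
    for tissue in ("pericarp", "endosperm"):
        presence = _stage_presence(calls, tissue)
        if len(presence) >= 2:
            common, specific = partition_stages(presence)
            report["stage_partition"][tissue] = {
                "common_all_stages": len(common),
                "stage_specific": {str(s): len(v) for s, v in sorted(specific.items())},
            }
        ud = count_updown(calls, tissue)
        report.setdefault("updown", {})[tissue] = {
            "up_per_stage": {str(s): n for s, n in ud.up_per_stage.items()},
            "down_per_stage": {str(s): n for s, n in ud.down_per_stage.items()},
            "exclusive_up_per_stage": {
                str(s): n for s, n in ud.exclusive_up_per_stage.items()
            },
            "always_up": len(ud.always_up),
        }

    # --- temporal patterns ---
    profiles = temporal_profiles(calls, design)
    assignments = [
        classify_pattern(p, tolerance=config.pattern_tolerance) for p in profiles
    ]
    pd.DataFrame(
        [
            {"protein_id": a.protein_id, "tissue": a.tissue, "pattern": a.pattern}
            for a in assignments
        ]
    ).to_csv(out / "patterns.tsv", sep="\t", index=False)
    report["patterns"] = summarize_patterns(assignments)

    # --- annotation tallies ---
    if config.annotation_map:
        amap = read_annotation_map(config.annotation_map)
        tally_frames = []
        for ns in ("GO-BP", "GO-CC", "GO-MF", "COG"):
            tallies = annotation_profiler.tally(amap, tissue_sets, ns)
            tally_frames.append(annotation_profiler.tally_table(tallies))
        pd.concat(tally_frames, ignore_index=True).to_csv(
            out / "category_tallies.tsv", sep="\t", index=False
        )

    # --- interaction networks, per tissue independently ---
    if config.ortholog_map and config.pathway_links:
        omap = read_ortholog_map(config.ortholog_map)
        links = read_pathway_links(config.pathway_links, strict=config.strict_ko)
        proteome_ko = {
            pid: omap.gene_to_ko[gene]
            for pid, gene in omap.protein_to_gene.items()
            if gene in omap.gene_to_ko
        }
        report["network"] = {}
        for tissue in ("pericarp", "endosperm"):
            ratios: dict[str, dict[int, float]] = {}
            stage_attr: dict[str, list[int]] = {}
            for c in calls:
                if c.tissue != tissue:
                    continue
                ratios.setdefault(c.protein_id, {})[c.stage] = c.ratio
                if c.verdict != "none":
                    stage_attr.setdefault(c.protein_id, []).append(c.stage)
            seeds = network_integration.filter_candidates(ratios, config.network)
            seed_kos, unmapped = network_integration.map_orthology(seeds, omap)
            expansion = network_integration.expand_interactions(
                seed_kos, links, proteome_ko, config.network.max_degree
            )
            g = network_integration.build_network(
                seed_kos,
                expansion,
                stage_attr,
                proteome_ko,
                links,
                include_stage_nodes=config.network.include_stage_nodes,
                stages=design.stages,
            )
            network_integration.write_sif(g, out / f"network_{tissue}.sif")
            network_integration.write_graphml(g, out / f"network_{tissue}.graphml")
            network_integration.write_node_attributes(
                g, out / f"network_{tissue}_nodes.tsv"
            )
            s = network_integration.summarize(g)
            report["network"][tissue] = {
                "n_dep": s.n_dep,
                "n_first_degree": s.n_first,
                "n_second_degree": s.n_second,
                "n_total_interactors": s.n_total_interactors,
                "n_pathways": s.n_pathways,
                "n_seed_candidates": len(seeds),
                "n_unmapped_seeds": len(unmapped),
            }

    # --- mRNA-protein concordance ---
    if config.ct_table:
        ct_rows = read_ct_table(config.ct_table)
        by_pt = {
            (c.protein_id, c.tissue): {} for c in calls
        }
        for c in calls:
            by_pt[(c.protein_id, c.tissue)][c.stage] = c.ratio
        genes = sorted({(r.gene_id, r.tissue) for r in ct_rows})
        conc = []
        for gene, tissue in genes:
            stages = sorted({r.stage for r in ct_rows if r.gene_id == gene and r.tissue == tissue})
            mrna = mrna_fold_changes(ct_rows, gene, tissue, calibrator_stage=stages[0])
            # match protein profile by gene model prefix
            match = [
                prof
                for (pid, tis), prof in by_pt.items()
                if tis == tissue and pid.startswith(gene)
            ]
            if not match:
                continue
            res = assess_concordance(
                match[0], mrna, gene_id=gene, tissue=tissue,
                cutoff=config.concordance_cutoff,
            )
            conc.append(
                {
                    "gene_id": gene,
                    "tissue": tissue,
                    "correlation": res.correlation,
                    "verdict": res.verdict,
                }
            )
        pd.DataFrame(conc).to_csv(out / "concordance.tsv", sep="\t", index=False)
        report["concordance"] = {
            "n_genes": len(conc),
            "n_concordant": sum(1 for c in conc if c["verdict"] == "concordant"),
            "n_discordant": sum(1 for c in conc if c["verdict"] == "discordant"),
        }

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return RunResult(calls=calls, summary_table=summary, report=report, dropped=dropped)
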