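"""Synthetic-data generator with planted ground truth.

Emulates the modeled experimental design — two tissues (pericarp,
endosperm) x four stages (10/20/33/46 DAP) x two biological replicates on an
8-plex reporter layout — so that every pipeline stage is testable without
raw MS data.

Each protein is planted with:

* a tissue membership (shared, pericarp-specific, or endosperm-specific);
* a temporal pattern (P1 monotone up, P2 up-down, P3 down-up, P4 monotone
  down, or flat/unclassified) realized as a fixed unit shape scaled by an
  amplitude in log2-ratio space;
* an amplitude class: differential proteins draw their maximal fold change
  from ``dep_fold_range``; background proteins stay inside the calling
  thresholds (max fold 1.4, safely within 0.67-1.5).

Reporter intensities follow the multiplicative model standard for
reporter-ion quantification: control-channel intensity is log-normal, and
each stage channel is ``control x planted_ratio x exp(eps)`` with
``eps ~ Normal(0, sigma^2)`` drawn independently per replicate — so the
geometric-mean replicate consensus is exact in expectation.  Missing values
are injected on stage channels (never the control) at the configured rate.

All generators are deterministic under (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .quant_io import (
    AnnotationMap,
    CtRow,
    OrthologMap,
    PathwayLinkTable,
    QuantRecord,
    StageDesign,
    Tissue,
)

# unit-amplitude log2 shapes over the four stages.  Values are +-1 at the
# extreme stages and +-0.25 in the interior so that, at any differential
# amplitude >= 1 log2 unit, extreme stages sit far (>= 4 sd at sigma=0.1,
# two replicates) from the 1.5/0.67 calling thresholds; consecutive steps
# are >= 0.5 shape units so amplitudes >= 0.2 clear the default 0.1
# classification tolerance
PATTERN_SHAPES: dict[str, tuple[float, ...]] = {
    "P1_up": (-1.0, -0.25, 0.25, 1.0),
    "P2_up_down": (-0.25, 1.0, 0.25, -1.0),
    "P3_down_up": (0.25, -1.0, -0.25, 1.0),
    "P4_down": (1.0, 0.25, -0.25, -1.0),
    "unclassified": (0.0, 0.0, 0.0, 0.0),
}

#: log2-amplitude bounds for background (non-differential) proteins:
#: max fold 2**0.35 = 1.27, >= 2 consensus noise sd inside the 0.67/1.5
#: calling window at the default sigma
BACKGROUND_AMPLITUDE = (0.2, 0.35)


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the modeled experiment: two replicates, four stages,
    log-normal reporter noise, a modest differential fraction with fold
    changes spanning the 2-8x range (which includes the >= 5-fold network
    seeds), and a small KO/pathway bipartite database.
    """

    n_proteins: int = 500
    frac_pericarp_specific: float = 0.15
    frac_endosperm_specific: float = 0.10
    dep_fraction: float = 0.2
    dep_fold_range: tuple[float, float] = (2.0, 8.0)
    pattern_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "P1_up": 0.30,
            "P2_up_down": 0.10,
            "P3_down_up": 0.10,
            "P4_down": 0.30,
            "unclassified": 0.20,
        }
    )
    noise_sigma: float = 0.1
    n_replicates: int = 2
    missing_rate: float = 0.0
    n_kos: int = 400
    n_pathways: int = 80
    membership_density: float = 0.008
    control_intensity_mean_log: float = np.log(1000.0)
    control_intensity_sigma_log: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SimConfigError("n_proteins must be >= 1")
        if self.noise_sigma < 0:
            raise SimConfigError("noise_sigma must be >= 0")
        fr = self.frac_pericarp_specific + self.frac_endosperm_specific
        if not (0 <= fr <= 1):
            raise SimConfigError("tissue-specific fractions must sum to <= 1")
        if not (0 <= self.dep_fraction <= 1):
            raise SimConfigError("dep_fraction must be in [0, 1]")
        if abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("pattern_mix must sum to 1")
        if not (0 <= self.missing_rate < 1):
            raise SimConfigError("missing_rate must be in [0, 1)")
        if not (0 < self.membership_density <= 1):
            raise SimConfigError("membership_density must be in (0, 1]")
        if self.dep_fold_range[0] < 1.5:
            raise SimConfigError("dep fold changes must be callable (>= 1.5)")


@dataclass
class ProteinTruth:
    protein_id: str
    tissue: str
    tissue_class: str  # "shared" | "pericarp_specific" | "endosperm_specific"
    pattern: str
    is_dep: bool
    ratio_profile: dict[int, float]
    verdicts: dict[int, str]
    ko: str | None = None


@dataclass
class GroundTruth:
    """Planted truth, keyed by (protein_id, tissue)."""

    proteins: dict[tuple[str, str], ProteinTruth] = field(default_factory=dict)

    def for_tissue(self, tissue: str) -> dict[str, ProteinTruth]:
        return {
            pid: t for (pid, tis), t in self.proteins.items() if tis == tissue
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pid, tissue), t in sorted(self.proteins.items()):
            row = {
                "protein_id": pid,
                "tissue": tissue,
                "tissue_class": t.tissue_class,
                "pattern": t.pattern,
                "is_dep": t.is_dep,
                "ko": t.ko or "",
            }
            for stage, r in t.ratio_profile.items():
                row[f"ratio_{stage}"] = r
                row[f"verdict_{stage}"] = t.verdicts[stage]
            rows.append(row)
        return pd.DataFrame(rows)


def _planted_verdict(ratio: float, up: float = 1.5, down: float = 0.67) -> str:
    # intentionally a plain threshold comparison, independent of dep_analysis
    if ratio >= up:
        return "up"
    if ratio <= down:
        return "down"
    return "none"


def simulate_quant(
    config: SimConfig, design: StageDesign | None = None
) -> tuple[list[QuantRecord], GroundTruth]:
    """Generate quantification records plus the planted ground truth."""
    design = design or StageDesign()
    rng = np.random.default_rng(config.seed)
    patterns = list(config.pattern_mix)
    probs = np.array([config.pattern_mix[p] for p in patterns])

    records: list[QuantRecord] = []
    truth = GroundTruth()
    tissues = [Tissue.PERICARP.value, Tissue.ENDOSPERM.value]

    for i in range(config.n_proteins):
        pid = f"SIMZM{i:05d}_P01"
        u = rng.random()
        if u < config.frac_pericarp_specific:
            tissue_class, present = "pericarp_specific", [tissues[0]]
        elif u < config.frac_pericarp_specific + config.frac_endosperm_specific:
            tissue_class, present = "endosperm_specific", [tissues[1]]
        else:
            tissue_class, present = "shared", tissues

        for tissue in present:
            pattern = str(rng.choice(patterns, p=probs))
            is_dep = pattern != "unclassified" and rng.random() < config.dep_fraction
            if pattern == "unclassified":
                amplitude = 0.0
            elif is_dep:
                lo, hi = config.dep_fold_range
                amplitude = float(rng.uniform(np.log2(lo), np.log2(hi)))
            else:
                amplitude = float(rng.uniform(*BACKGROUND_AMPLITUDE))
            shape = PATTERN_SHAPES[pattern]
            log2_profile = {
                stage: shape[j] * amplitude for j, stage in enumerate(design.stages)
            }
            ratio_profile = {s: float(2.0**v) for s, v in log2_profile.items()}
            verdicts = {s: _planted_verdict(r) for s, r in ratio_profile.items()}
            truth.proteins[(pid, tissue)] = ProteinTruth(
                protein_id=pid,
                tissue=tissue,
                tissue_class=tissue_class,
                pattern=pattern,
                is_dep=is_dep,
                ratio_profile=ratio_profile,
                verdicts=verdicts,
            )
            for rep in range(1, config.n_replicates + 1):
                control = float(
                    np.exp(
                        rng.normal(
                            config.control_intensity_mean_log,
                            config.control_intensity_sigma_log,
                        )
                    )
                )
                intensities = {design.control_channel: control}
                for stage in design.stages:
                    if config.missing_rate and rng.random() < config.missing_rate:
                        continue
                    eps = (
                        rng.normal(0.0, config.noise_sigma)
                        if config.noise_sigma > 0
                        else 0.0
                    )
                    ch = design.channel(tissue, stage)
                    intensities[ch] = control * ratio_profile[stage] * float(np.exp(eps))
                records.append(
                    QuantRecord(
                        protein_id=pid,
                        tissue=tissue,
                        replicate=rep,
                        intensities=intensities,
                    )
                )
    return records, truth


def simulate_pathway_db(
    config: SimConfig, truth: GroundTruth
) -> tuple[OrthologMap, PathwayLinkTable]:
    """Miniature KO/pathway bipartite database plus protein->gene->KO map.

    Every protein gets a gene model (its id minus the isoform suffix) and a
    KO drawn uniformly from the synthetic KO universe; membership pairs are
    sampled at ``membership_density``, and every KO carried by a planted
    network seed (a differential protein whose fold reaches 5) is guaranteed
    at least one pathway so no seed is structurally silent.  The KO
    assignment is recorded back into the truth.
    """
    if config.n_kos < 1 or config.n_pathways < 1:
        raise SimConfigError("n_kos and n_pathways must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    kos = [f"K9{j:04d}" for j in range(config.n_kos)]
    pathways = [f"path:sim{j:05d}" for j in range(config.n_pathways)]

    omap = OrthologMap()
    protein_ids = sorted({pid for pid, _ in truth.proteins})
    for pid in protein_ids:
        gene = pid.rsplit("_P", 1)[0]
        omap.protein_to_gene[pid] = gene
        ko = str(rng.choice(kos))
        omap.gene_to_ko[gene] = ko
    for t in truth.proteins.values():
        t.ko = omap.gene_to_ko[omap.protein_to_gene[t.protein_id]]

    table = PathwayLinkTable()
    for ko in kos:
        for pw in pathways:
            if rng.random() < config.membership_density:
                table.pairs.add((ko, pw))

    seed_kos = {
        t.ko
        for t in truth.proteins.values()
        if t.is_dep
        and any(r >= 5.0 or r <= 0.2 for r in t.ratio_profile.values())
    }
    for ko in sorted(k for k in seed_kos if k):
        if not table.pathways_of(ko):
            table.pairs.add((ko, str(rng.choice(pathways))))
    return omap, table


#: small flat category pools in the style of GO slices / COG classes
ANNOTATION_POOLS: dict[str, tuple[str, ...]] = {
    "GO-BP": (
        "metabolic process",
        "cellular process",
        "localization",
        "response to stimulus",
        "biological regulation",
    ),
    "GO-CC": ("cell part", "organelle", "membrane", "macromolecular complex"),
    "GO-MF": ("binding", "catalytic activity", "transporter activity"),
    "COG": (
        "Energy production and conversion",
        "Carbohydrate transport and metabolism",
        "Amino acid transport and metabolism",
        "Posttranslational modification, protein turnover, chaperones",
        "Translation, ribosomal structure and biogenesis",
        "Cell wall/membrane/envelope biogenesis",
        "Lipid transport and metabolism",
        "Signal transduction mechanisms",
    ),
}


def simulate_annotations(
    config: SimConfig,
    truth: GroundTruth,
    n_exclusive_per_tissue: int = 2,
    annotation_rate: float = 0.9,
) -> AnnotationMap:
    """Flat GO/COG annotation maps with planted tissue-exclusive categories.

    Each protein is annotated (with probability ``annotation_rate``) with
    1-2 categories per namespace; additionally, ``n_exclusive_per_tissue``
    categories per tissue (named ``only_<tissue>_<k>``) are planted
    exclusively on tissue-specific proteins, so the category-exclusivity
    report has known positives.  Deterministic under seed.
    """
    rng = np.random.default_rng(config.seed + 3)
    amap = AnnotationMap()
    protein_ids = sorted({pid for pid, _ in truth.proteins})
    for pid in protein_ids:
        if rng.random() > annotation_rate:
            continue
        for ns, pool in ANNOTATION_POOLS.items():
            k = int(rng.integers(1, 3))
            for cat in rng.choice(pool, size=min(k, len(pool)), replace=False):
                amap.add(pid, ns, str(cat))
    for tissue, label in (
        (Tissue.PERICARP.value, "pericarp_specific"),
        (Tissue.ENDOSPERM.value, "endosperm_specific"),
    ):
        specific = sorted(
            pid
            for (pid, tis), t in truth.proteins.items()
            if tis == tissue and t.tissue_class == label
        )
        for k in range(n_exclusive_per_tissue):
            if not specific:
                break
            pid = specific[k % len(specific)]
            amap.add(pid, "COG", f"only_{tissue}_{k}")
    return amap


def simulate_ct(
    config: SimConfig,
    truth: GroundTruth,
    genes: list[tuple[str, str]] | None = None,
    discordant: set[str] | None = None,
    n_technical_replicates: int = 3,
    ct_noise_sd: float = 0.0,
) -> list[CtRow]:
    """qPCR Ct tables consistent (or deliberately discordant) with the truth.

    For each requested (protein_id, tissue), the mRNA log2 profile equals
    the planted protein log2 profile (concordant) or its negation (genes in
    ``discordant``).  Ct values invert the 2^-ddCt relation with the first
    stage as calibrator: the target Ct decreases by one cycle per planted
    log2 unit, around a reference gene at a constant 20 cycles.
    """
    rng = np.random.default_rng(config.seed + 2)
    if genes is None:
        genes = sorted(truth.proteins)[:4]
    discordant = discordant or set()
    rows: list[CtRow] = []
    for pid, tissue in genes:
        t = truth.proteins[(pid, tissue)]
        gene = pid.rsplit("_P", 1)[0]
        sign = -1.0 if pid in discordant or gene in discordant else 1.0
        stages = sorted(t.ratio_profile)
        base = float(np.log2(t.ratio_profile[stages[0]]))
        for stage in stages:
            log2_fold = sign * (float(np.log2(t.ratio_profile[stage])) - base)
            for rep in range(1, n_technical_replicates + 1):
                noise_t = rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                noise_r = rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    CtRow(
                        gene_id=gene,
                        tissue=tissue,
                        stage=stage,
                        ct_target=25.0 - log2_fold + float(noise_t),
                        ct_reference=20.0 + float(noise_r),
                        replicate=rep,
                    )
                )
    return rows
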