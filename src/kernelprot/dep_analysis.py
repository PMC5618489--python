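"""Differential-expression calling and tissue/stage specificity analysis.

Reporter ratios are formed against the common control channel, replicates
are merged by geometric mean (ratios are multiplicative), and a protein is
called up- or down-regulated at a stage when its consensus ratio crosses the
inclusive thresholds (defaults 1.5 up, 0.67 down).  Tissue and stage
specificity are plain set partitions; mRNA-protein concordance compares a
protein's temporal ratio profile with qPCR-derived 2^-ddCt fold changes by
rank correlation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .quant_io import CtRow, QuantRecord, StageDesign


class QuantificationError(ValueError):
    """Control channel absent/zero or other per-protein ratio failure."""

    def __init__(self, protein_id: str, reason: str):
        self.protein_id = protein_id
        self.reason = reason
        super().__init__(f"{protein_id}: {reason}")


@dataclass(frozen=True)
class DepThresholds:
    """Ratio cutoffs for differential calls.

    up/down are the per-stage DEP thresholds (inclusive); network_min_fold is
    the stricter two-sided cutoff used to seed interaction networks.
    """

    up: float = 1.5
    down: float = 0.67
    network_min_fold: float = 5.0

    def __post_init__(self) -> None:
        if not (self.down <= 1.0 <= self.up):
            raise ValueError("require down <= 1 <= up")
        if self.network_min_fold < self.up:
            raise ValueError("network_min_fold must be >= up threshold")


@dataclass(frozen=True)
class DepCall:
    protein_id: str
    tissue: str
    stage: int
    ratio: float
    verdict: str  # "up" | "down" | "none"
    replicate_support: int = 1


@dataclass
class VennPartition:
    """Two-set partition: tissue-specific sets and the shared intersection."""

    a_specific: set[str]
    b_specific: set[str]
    shared: set[str]

    @property
    def union_size(self) -> int:
        return len(self.a_specific) + len(self.b_specific) + len(self.shared)


@dataclass
class ConcordanceResult:
    gene_id: str
    tissue: str
    mrna_fold: dict[int, float]
    protein_ratio: dict[int, float]
    correlation: float | None
    verdict: str  # "concordant" | "discordant" | "undefined"


def compute_ratios(
    record: QuantRecord, design: StageDesign
) -> dict[int, float]:
    """Stage -> (stage-channel intensity / control intensity) for one record.

    Stages whose channel is absent from the record are omitted.  A missing
    or zero control raises :class:`QuantificationError`.
    """
    control = record.intensities.get(design.control_channel)
    if control is None:
        raise QuantificationError(record.protein_id, "control channel absent")
    if control == 0:
        raise QuantificationError(record.protein_id, "control intensity is zero")
    out: dict[int, float] = {}
    for stage in design.stages:
        ch = design.channel(record.tissue, stage)
        v = record.intensities.get(ch)
        if v is not None:
            out[stage] = v / control
    return out


def merge_replicates(
    replicate_ratios: Sequence[float], policy: str = "geometric"
) -> tuple[float, int]:
    """Consensus ratio across replicates plus the support count.

    Default policy is the geometric mean; "arithmetic" is available.  A
    protein is considered replicate-confirmed only when support == 2 (seen
    in both biological replicates).
    """
    ratios = [r for r in replicate_ratios if r is not None]
    if not ratios:
        raise ValueError("no replicate ratios to merge")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if policy == "geometric":
        if len(ratios) == 1:
            consensus = float(ratios[0])
        else:
            consensus = float(np.exp(np.mean(np.log(ratios))))
    elif policy == "arithmetic":
        consensus = float(np.mean(ratios))
    else:
        raise ValueError(f"unknown merge policy {policy!r}")
    return consensus, len(ratios)


def call_dep(ratio: float, thresholds: DepThresholds = DepThresholds()) -> str:
    """Map a positive consensus ratio to 'up' / 'down' / 'none' (boundaries inclusive)."""
    if ratio <= 0 or not math.isfinite(ratio):
        raise ValueError(f"ratio must be a positive finite number, got {ratio}")
    if ratio >= thresholds.up:
        return "up"
    if ratio <= thresholds.down:
        return "down"
    return "none"


def consensus_calls(
    records: Iterable[QuantRecord],
    design: StageDesign,
    thresholds: DepThresholds = DepThresholds(),
    policy: str = "geometric",
) -> tuple[list[DepCall], dict[str, str]]:
    """Full per-tissue pipeline: ratios per replicate -> merge -> verdicts.

    Returns the calls plus a map of dropped protein ids to a reason code
    (no protein is silently discarded).
    """
    per_key: dict[tuple[str, str, int], list[float]] = defaultdict(list)
    dropped: dict[str, str] = {}
    for rec in records:
        try:
            ratios = compute_ratios(rec, design)
        except QuantificationError as e:
            dropped[rec.protein_id] = e.reason
            continue
        for stage, ratio in ratios.items():
            per_key[(rec.protein_id, rec.tissue, stage)].append(ratio)
    calls = []
    for (pid, tissue, stage), ratios in sorted(per_key.items()):
        consensus, support = merge_replicates(ratios, policy=policy)
        calls.append(
            DepCall(
                protein_id=pid,
                tissue=tissue,
                stage=stage,
                ratio=consensus,
                verdict=call_dep(consensus, thresholds),
                replicate_support=support,
            )
        )
    return calls, dropped


def partition_tissues(set_a: set[str], set_b: set[str]) -> VennPartition:
    """Venn partition of two protein id sets (specific/specific/shared)."""
    return VennPartition(
        a_specific=set_a - set_b, b_specific=set_b - set_a, shared=set_a & set_b
    )


def partition_stages(
    stage_sets: Mapping[int, set[str]],
) -> tuple[set[str], dict[int, set[str]]]:
    """Common set (in every stage) and per-stage exclusive sets (in exactly one)."""
    if len(stage_sets) < 2:
        raise ValueError("need at least two stage sets")
    sets = list(stage_sets.values())
    common = set.intersection(*sets)
    specific: dict[int, set[str]] = {}
    for stage, s in stage_sets.items():
        others = set.union(*(o for st, o in stage_sets.items() if st != stage))
        specific[stage] = s - others
    return common, specific


@dataclass
class UpDownSummary:
    up_per_stage: dict[int, int] = field(default_factory=dict)
    down_per_stage: dict[int, int] = field(default_factory=dict)
    exclusive_up_per_stage: dict[int, int] = field(default_factory=dict)
    always_up: set[str] = field(default_factory=set)
    always_down: set[str] = field(default_factory=set)


def count_updown(calls: Iterable[DepCall], tissue: str) -> UpDownSummary:
    """Per-stage up/down tallies plus stage-exclusive and always-up sets.

    "Stage-exclusive up" means up at that stage and not up at any other
    stage; "always up" means up at every stage at which the protein was
    quantified in this tissue (requiring all stages present).
    """
    by_protein: dict[str, dict[int, str]] = defaultdict(dict)
    stages: set[int] = set()
    for c in calls:
        if c.tissue != tissue:
            continue
        by_protein[c.protein_id][c.stage] = c.verdict
        stages.add(c.stage)
    out = UpDownSummary(
        up_per_stage={s: 0 for s in sorted(stages)},
        down_per_stage={s: 0 for s in sorted(stages)},
        exclusive_up_per_stage={s: 0 for s in sorted(stages)},
    )
    for pid, verdicts in by_protein.items():
        ups = {s for s, v in verdicts.items() if v == "up"}
        downs = {s for s, v in verdicts.items() if v == "down"}
        for s in ups:
            out.up_per_stage[s] += 1
        for s in downs:
            out.down_per_stage[s] += 1
        if len(ups) == 1:
            out.exclusive_up_per_stage[next(iter(ups))] += 1
        if stages and ups == stages and len(verdicts) == len(stages):
            out.always_up.add(pid)
        if stages and downs == stages and len(verdicts) == len(stages):
            out.always_down.add(pid)
    return out


def ddct_fold(
    ct_target_sample: float,
    ct_reference_sample: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target,sample - Ct_ref,sample) - (Ct_target,cal - Ct_ref,cal).
    """
    ddct = (ct_target_sample - ct_reference_sample) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return float(2.0 ** (-ddct))


def mrna_fold_changes(
    ct_rows: Sequence[CtRow], gene_id: str, tissue: str, calibrator_stage: int
) -> dict[int, float]:
    """Per-stage 2^-ddCt fold changes relative to the calibrator stage.

    Technical replicates are averaged on the Ct scale before the ddCt step.
    """
    mean_ct: dict[int, tuple[float, float]] = {}
    grouped: dict[int, list[CtRow]] = defaultdict(list)
    for r in ct_rows:
        if r.gene_id == gene_id and r.tissue == tissue:
            grouped[r.stage].append(r)
    for stage, rows in grouped.items():
        mean_ct[stage] = (
            float(np.mean([r.ct_target for r in rows])),
            float(np.mean([r.ct_reference for r in rows])),
        )
    if calibrator_stage not in mean_ct:
        raise ValueError(f"calibrator stage {calibrator_stage} missing for {gene_id}")
    cal_t, cal_r = mean_ct[calibrator_stage]
    return {
        stage: ddct_fold(ct_t, ct_r, cal_t, cal_r)
        for stage, (ct_t, ct_r) in sorted(mean_ct.items())
    }


def assess_concordance(
    protein_profile: Mapping[int, float],
    mrna_profile: Mapping[int, float],
    gene_id: str = "",
    tissue: str = "",
    cutoff: float = 0.5,
) -> ConcordanceResult:
    """Rank-correlate temporal protein and mRNA profiles over shared stages.

    Verdict is "concordant" iff Spearman rho >= cutoff.  Fewer than three
    shared stages yields an undefined result (no verdict), as does a
    constant profile (rank correlation undefined).
    """
    shared = sorted(set(protein_profile) & set(mrna_profile))
    if len(shared) < 3:
        return ConcordanceResult(
            gene_id, tissue, dict(mrna_profile), dict(protein_profile), None, "undefined"
        )
    p = [protein_profile[s] for s in shared]
    m = [mrna_profile[s] for s in shared]
    if len(set(p)) == 1 or len(set(m)) == 1:
        rho = None
        verdict = "undefined"
    else:
        rho = float(stats.spearmanr(p, m).statistic)
        verdict = "concordant" if rho >= cutoff else "discordant"
    return ConcordanceResult(
        gene_id, tissue, dict(mrna_profile), dict(protein_profile), rho, verdict
    )
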