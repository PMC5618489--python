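#!/usr/bin/env python
"""Quantify reporter ratios and call differential expression.

Reads results/sim/quant.tsv, merges replicates by geometric mean, applies
the 1.5 / 0.67 thresholds per stage, and writes the call table plus the
identification-summary table (per-stage counts, totals, non-redundant
counts per tissue) and Venn/up-down tallies under results/.
"""

import json
from pathlib import Path

import pandas as pd

from kernelprot.dep_analysis import (
    consensus_calls,
    count_updown,
    partition_stages,
    partition_tissues,
)
from kernelprot.pipeline import _stage_presence, identification_summary
from kernelprot.quant_io import StageDesign, read_quant_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = StageDesign()
    records = read_quant_table(ROOT / "sim" / "quant.tsv")
    calls, dropped = consensus_calls(records, design)
    pd.DataFrame(
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
    ).to_csv(ROOT / "dep_calls.tsv", sep="\t", index=False, float_format="%.6g")

    summary = identification_summary(calls, design)
    summary.to_csv(ROOT / "identification_summary.tsv", sep="\t")
    print("identification summary:")
    print(summary.to_string())

    sets = {
        t: {c.protein_id for c in calls if c.tissue == t}
        for t in ("pericarp", "endosperm")
    }
    venn = partition_tissues(sets["pericarp"], sets["endosperm"])
    print(
        f"\nVenn: {len(venn.a_specific)} pericarp-specific, "
        f"{len(venn.b_specific)} endosperm-specific, {len(venn.shared)} shared "
        f"({venn.union_size} total)"
    )

    report = {"venn": {
        "pericarp_specific": len(venn.a_specific),
        "endosperm_specific": len(venn.b_specific),
        "shared": len(venn.shared),
    }}
    for tissue in ("pericarp", "endosperm"):
        presence = _stage_presence(calls, tissue)
        common, specific = partition_stages(presence)
        ud = count_updown(calls, tissue)
        print(
            f"{tissue}: {len(common)} proteins at all stages; "
            f"stage-exclusive up counts "
            f"{[ud.exclusive_up_per_stage[s] for s in design.stages]}; "
            f"{len(ud.always_up)} up at every stage"
        )
        report[tissue] = {
            "common_all_stages": len(common),
            "up_per_stage": ud.up_per_stage,
            "down_per_stage": ud.down_per_stage,
            "exclusive_up_per_stage": ud.exclusive_up_per_stage,
            "always_up": len(ud.always_up),
        }
    (ROOT / "dep_summary.json").write_text(json.dumps(report, indent=2, default=int))
    if dropped:
        print(f"dropped {len(dropped)} proteins with invalid control channel")


if __name__ == "__main__":
    main()
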