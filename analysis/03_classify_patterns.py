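#!/usr/bin/env python
"""Classify temporal expression patterns and cluster the profiles.

Builds log2 consensus-ratio trajectories for every protein quantified at
all four stages, assigns each to one of the four developmental trend
patterns (monotone up, up-down, down-up, monotone down) or unclassified,
and writes per-tissue pattern counts plus an average-linkage clustering of
the profiles (uncentered Pearson distance) for ordering/export.
"""

import json
from pathlib import Path

import pandas as pd

from kernelprot.dep_analysis import consensus_calls
from kernelprot.pattern_clustering import classify_pattern, hier_cluster, summarize_patterns
from kernelprot.pipeline import temporal_profiles
from kernelprot.quant_io import StageDesign, read_quant_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = StageDesign()
    records = read_quant_table(ROOT / "sim" / "quant.tsv")
    calls, _ = consensus_calls(records, design)
    profiles = temporal_profiles(calls, design)
    assignments = [classify_pattern(p) for p in profiles]
    pd.DataFrame(
        [
            {"protein_id": a.protein_id, "tissue": a.tissue, "pattern": a.pattern}
            for a in assignments
        ]
    ).to_csv(ROOT / "patterns.tsv", sep="\t", index=False)

    counts = summarize_patterns(assignments)
    (ROOT / "pattern_counts.json").write_text(json.dumps(counts, indent=2))
    for tissue, c in counts.items():
        print(
            f"{tissue}: P1 {c['P1_up']}, P2 {c['P2_up_down']}, "
            f"P3 {c['P3_down_up']}, P4 {c['P4_down']}, "
            f"unclassified {c['unclassified']}"
        )

    for tissue in counts:
        tp = [p for p in profiles if p.tissue == tissue]
        res = hier_cluster(tp, k=4)
        labels = pd.DataFrame(
            {"protein_id": res.kept_ids, "cluster": res.flat_labels}
        )
        labels.to_csv(ROOT / f"clusters_{tissue}.tsv", sep="\t", index=False)
        print(
            f"{tissue}: clustered {len(res.kept_ids)} profiles into "
            f"{labels['cluster'].nunique()} groups "
            f"({len(res.excluded)} excluded as degenerate)"
        )


if __name__ == "__main__":
    main()
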