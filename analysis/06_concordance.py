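#!/usr/bin/env python
"""Compare mRNA and protein temporal profiles for the qPCR genes.

Computes 2^-ddCt fold changes per stage from the Ct table (first stage as
calibrator), rank-correlates them with the protein consensus-ratio
profiles, and reports each gene as concordant or discordant.
"""

from pathlib import Path

import pandas as pd

from kernelprot.dep_analysis import (
    assess_concordance,
    consensus_calls,
    mrna_fold_changes,
)
from kernelprot.quant_io import StageDesign, read_ct_table, read_quant_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = StageDesign()
    records = read_quant_table(ROOT / "sim" / "quant.tsv")
    calls, _ = consensus_calls(records, design)
    profiles = {}
    for c in calls:
        profiles.setdefault((c.protein_id, c.tissue), {})[c.stage] = c.ratio
    ct_rows = read_ct_table(ROOT / "sim" / "ct.tsv")

    rows = []
    for gene, tissue in sorted({(r.gene_id, r.tissue) for r in ct_rows}):
        stages = sorted({r.stage for r in ct_rows if r.gene_id == gene and r.tissue == tissue})
        mrna = mrna_fold_changes(ct_rows, gene, tissue, calibrator_stage=stages[0])
        protein = next(
            (prof for (pid, tis), prof in profiles.items()
             if tis == tissue and pid.startswith(gene)),
            None,
        )
        if protein is None:
            continue
        res = assess_concordance(protein, mrna, gene_id=gene, tissue=tissue)
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "correlation": res.correlation,
                "verdict": res.verdict,
            }
        )
        corr = "n/a" if res.correlation is None else f"{res.correlation:+.2f}"
        print(f"{gene} ({tissue}): rho={corr} -> {res.verdict}")
    pd.DataFrame(rows).to_csv(ROOT / "concordance.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
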