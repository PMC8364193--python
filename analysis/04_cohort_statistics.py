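#!/usr/bin/env python
"""Cohort-level statistics over the screened synthetic cohort.

Reports (i) the fraction of marker-positive samples, (ii) the Mann-Whitney
association between marker presence and the metabolite level, and (iii)
gene/transcript concordance, writing tidy tables under results/stats/.
The comparison against ground truth shows what the screen recovered.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from markerscreen.stats import (
    associate_presence_with_metabolite,
    gene_transcript_concordance,
    prevalence,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "stats"


def main() -> None:
    table = pd.read_csv(ROOT / "cohort_table.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "cohort" / "truth.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)

    prev = prevalence(table)
    prev.to_csv(OUT / "prevalence.tsv", sep="\t", index=False)
    print("prevalence:")
    print(prev.to_string(index=False))

    assoc = associate_presence_with_metabolite(table, "gbb")
    assoc.to_csv(OUT / "association.tsv", sep="\t", index=False)
    r = assoc.iloc[0]
    print(f"\nmetabolite association: U={r.U:.0f}, p={r.p_two_sided:.4f}, "
          f"median gbb {r.median_positive:.1f} (gene+) vs {r.median_negative:.1f} (gene-)")

    conc = gene_transcript_concordance(table)
    pd.DataFrame([conc.__dict__]).to_csv(OUT / "concordance.tsv", sep="\t", index=False)
    print(f"\ntranscript positivity: {conc.frac_transcript_pos_given_gene_pos:.2f} "
          f"among gene-positive, "
          f"{conc.frac_transcript_pos_given_gene_neg:.2f} among gene-negative")

    merged = table.merge(truth, on="sample_id")
    agree = (merged["gene_present"] == (merged["marker_copies"] > 0)).mean()
    print(f"\npresence calls agree with ground truth for {agree:.0%} of samples")


if __name__ == "__main__":
    main()
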