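#!/usr/bin/env python
"""Simulate a small synthetic cohort of paired gut metagenome /
metatranscriptome samples with known marker content.

Half the samples come from communities that carry the marker gene (a few
copies per 200 genomes), half from marker-free communities; every community
also carries decoy homologs in the 50-65% identity band. Marker-positive
samples draw their metabolite level one log-SD lower. Outputs under
results/cohort/: per-sample FASTQ, the marker and decoy-pool FASTA, the
metabolite table, and the ground truth.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from markerscreen.seq import write_fasta
from markerscreen.simulate import CommunitySpec, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
N_SAMPLES = 16
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = [
        CommunitySpec(
            n_genomes=200, genome_length_bp=20_000,
            marker_carriage_rate=0.02 if i % 2 else 0.0,
            decoy_carriage_rate=0.1, n_reads=30_000,
            metabolite_effect_size=1.0, seed=0,
        )
        for i in range(N_SAMPLES)
    ]
    cohort = simulate_cohort(specs, seed=SEED, n_transcript_reads=10_000)
    rows = []
    for sample in cohort.samples:
        sample.metagenome.to_fastq(OUT / f"{sample.sample_id}.meta.fastq")
        sample.transcriptome.to_fastq(OUT / f"{sample.sample_id}.txn.fastq")
        rows.append({
            "sample_id": sample.sample_id,
            "reads_path": str(OUT / f"{sample.sample_id}.meta.fastq"),
            "transcript_reads_path": str(OUT / f"{sample.sample_id}.txn.fastq"),
            "ags_bp": sample.community.genome_length_bp,
        })
    # all samples share one marker; pool decoy proteins across samples
    write_fasta([cohort.samples[0].community.marker_protein], OUT / "marker.faa")
    decoys = {d.id: d for s in cohort.samples for d in s.community.decoy_proteins}
    write_fasta(decoys.values(), OUT / "decoy_pool.faa")
    pd.DataFrame(rows).to_csv(OUT / "samples.tsv", sep="\t", index=False)
    cohort.metabolites.to_csv(OUT / "metabolites.tsv", sep="\t", index=False)
    cohort.truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    n_pos = int((cohort.truth["marker_copies"] > 0).sum())
    print(f"simulated {N_SAMPLES} paired samples; {n_pos} truly carry the marker")
    print(f"wrote {OUT}/samples.tsv, metabolites.tsv, truth.tsv")


if __name__ == "__main__":
    main()
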