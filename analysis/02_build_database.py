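#!/usr/bin/env python
"""Build the marker + negative-control (decoy) protein database for the
simulated cohort.

Takes the marker and the decoy candidate pool written by 01_simulate_cohort
and applies the three construction steps (exclude homologs >70% identity,
cluster the remainder at 50%, add back the 50-70% near-homolog band).
Writes the database FASTA files and a per-sequence manifest.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from markerscreen.markerdb import build_negative_control
from markerscreen.seq import read_fasta, write_fasta

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"
OUT = Path(__file__).resolve().parents[1] / "results" / "db"


def main() -> None:
    markers = read_fasta(COHORT / "marker.faa")
    pool = read_fasta(COHORT / "decoy_pool.faa")
    db, manifest = build_negative_control(markers, pool, band=(50.0, 70.0))
    OUT.mkdir(parents=True, exist_ok=True)
    write_fasta(db.markers, OUT / "markers.faa")
    write_fasta(db.decoys, OUT / "decoys.faa")
    manifest.to_csv(OUT / "db_manifest.tsv", sep="\t", index=False)
    db.validate()
    print(f"{len(db.markers)} marker(s), {len(db.decoys)} decoys "
          f"(from a pool of {len(pool)}); invariant holds: no decoy is a homolog")
    print(manifest.to_string(index=False))


if __name__ == "__main__":
    main()
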