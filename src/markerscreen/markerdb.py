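"""Marker and negative-control (decoy) protein database construction.

The decoy database absorbs reads that originate from non-marker homologs:
under the competitive classification rule a read is only counted for the
marker when its best marker hit is at least as good as its best decoy hit.
Decoys are drawn from a candidate pool in three steps:

1. drop every pool sequence that is itself a marker homolog (> the homolog
   identity cutoff to any marker);
2. cluster the remainder at a lower identity threshold and keep one
   representative per cluster;
3. additionally keep every pool sequence in the near-homolog identity band
   (above the band floor, at or below the homolog cutoff), because those
   are the sequences most likely to steal reads.

The decoy set is the deduplicated union of (2) and (3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .align import global_identity
from .seq import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_HOMOLOG_CUTOFF = 70.0
DEFAULT_CLUSTER_THRESHOLD = 50.0
DEFAULT_BAND = (50.0, 70.0)


@dataclass
class MarkerDatabase:
    """Marker proteins plus their competitive decoy set."""

    markers: list[SequenceRecord]
    decoys: list[SequenceRecord]
    homolog_identity_cutoff: float = DEFAULT_HOMOLOG_CUTOFF

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("a MarkerDatabase needs at least one marker")
        if not 0 < self.homolog_identity_cutoff <= 100:
            raise ValueError("homolog cutoff must lie in (0, 100]")
        ids = [r.id for r in self.markers] + [r.id for r in self.decoys]
        if len(set(ids)) != len(ids):
            raise ValueError("marker and decoy ids must be disjoint and unique")

    def validate(self) -> None:
        """Check the decoy invariant (no decoy is a marker homolog). O(m*d)."""
        for decoy in self.decoys:
            if is_homolog(decoy, self.markers, self.homolog_identity_cutoff):
                raise ValueError(f"decoy {decoy.id!r} is a marker homolog")

    def effective_gene_length_kb(self) -> float:
        """Length-weighted mean marker coding-sequence length in kb.

        Weighting each marker by its own length gives the expected gene
        length of the marker a uniformly chosen marker residue belongs to;
        used as the database-level gene length in RPKM.
        """
        lengths = [3 * len(m.seq) for m in self.markers]
        return sum(length * length for length in lengths) / sum(lengths) / 1000.0


@dataclass
class ClusterResult:
    """Greedy identity clustering outcome."""

    representatives: list[str]
    membership: dict[str, str]
    threshold: float


def cluster_by_identity(seqs: list[SequenceRecord], threshold_pct: float) -> ClusterResult:
    """Greedy incremental clustering by global percent identity.

    Sequences are processed longest-first (ties broken lexicographically by
    id); each joins the first existing representative it matches at
    >= ``threshold_pct`` global identity, else founds a new cluster.
    Deterministic given the input set.
    """
    if not seqs:
        raise ValueError("cluster_by_identity requires a nonempty input")
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    ordered = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    reps: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for rec in ordered:
        for rep in reps:
            if global_identity(rec, rep) >= threshold_pct:
                membership[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            membership[rec.id] = rec.id
    return ClusterResult([r.id for r in reps], membership, threshold_pct)


def is_homolog(
    candidate: SequenceRecord,
    markers: list[SequenceRecord],
    cutoff_pct: float = DEFAULT_HOMOLOG_CUTOFF,
) -> bool:
    """True iff the candidate exceeds the cutoff (strictly) to any marker."""
    if not markers:
        raise ValueError("markers must be nonempty")
    return max(global_identity(candidate, m) for m in markers) > cutoff_pct


def build_negative_control(
    markers: list[SequenceRecord],
    candidate_pool: list[SequenceRecord],
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BAND,
    reference_marker_id: str | None = None,
) -> tuple[MarkerDatabase, pd.DataFrame]:
    """Build the decoy set from a candidate pool and return (database, manifest).

    ``band`` is the near-homolog identity interval (lo, hi], with ``hi``
    equal to the homolog cutoff. When ``reference_marker_id`` is given,
    identities are computed against that single marker instead of the
    maximum over all markers.

    The manifest has one row per input sequence (markers and pool members)
    with its role, max identity to the markers, and — for pool members that
    were clustered away — the decoy representative absorbing them.
    """
    if not candidate_pool:
        logger.warning("empty candidate pool: decoy set is empty; "
                       "classification degenerates to the identity cutoff alone")
    lo, hi = band
    if not 0 < lo < hi <= 100:
        raise ValueError("band must satisfy 0 < lo < hi <= 100")
    refs = markers
    if reference_marker_id is not None:
        refs = [m for m in markers if m.id == reference_marker_id]
        if not refs:
            raise ValueError(f"reference marker {reference_marker_id!r} not found")

    max_ident = {
        rec.id: (max(global_identity(rec, m) for m in refs) if refs else 0.0)
        for rec in candidate_pool
    }
    # step 1: exclude marker homologs
    remainder = [rec for rec in candidate_pool if max_ident[rec.id] <= hi]
    rows = []
    for m in markers:
        rows.append({"id": m.id, "role": "marker", "max_identity_to_marker": 100.0,
                     "representative": m.id, "duplicate_of": ""})
    for rec in candidate_pool:
        if max_ident[rec.id] > hi:
            rows.append({"id": rec.id, "role": "excluded_homolog",
                         "max_identity_to_marker": max_ident[rec.id],
                         "representative": "", "duplicate_of": ""})

    decoys: list[SequenceRecord] = []
    if remainder:
        # step 2: cluster representatives
        clusters = cluster_by_identity(remainder, cluster_threshold)
        by_id = {rec.id: rec for rec in remainder}
        selected: dict[str, str] = {}  # id -> provenance step
        for rep_id in clusters.representatives:
            selected[rep_id] = "cluster_representative"
        # step 3: band members
        for rec in remainder:
            if lo < max_ident[rec.id] <= hi and rec.id not in selected:
                selected[rec.id] = "identity_band"
        # dedup by exact sequence, first-selected wins (representatives first)
        seen_seq: dict[str, str] = {}
        order = [rid for rid in selected if selected[rid] == "cluster_representative"]
        order += [rid for rid in selected if selected[rid] == "identity_band"]
        dup_of: dict[str, str] = {}
        for rid in order:
            seq = by_id[rid].seq
            if seq in seen_seq:
                dup_of[rid] = seen_seq[seq]
            else:
                seen_seq[seq] = rid
                decoys.append(by_id[rid])
        kept = {d.id for d in decoys}
        for rec in remainder:
            if rec.id in kept:
                role = f"decoy_{selected[rec.id]}"
                rep = rec.id
            elif rec.id in dup_of:
                role = "decoy_duplicate"
                rep = dup_of[rec.id]
            else:
                role = "clustered"
                rep = clusters.membership[rec.id]
            rows.append({"id": rec.id, "role": role,
                         "max_identity_to_marker": max_ident[rec.id],
                         "representative": rep,
                         "duplicate_of": dup_of.get(rec.id, "")})
    else:
        if candidate_pool:
            logger.warning("all pool sequences are marker homologs: decoy set is empty")

    db = MarkerDatabase(markers=list(markers), decoys=decoys,
                        homolog_identity_cutoff=hi)
    manifest = pd.DataFrame(rows, columns=["id", "role", "max_identity_to_marker",
                                           "representative", "duplicate_of"])
    return db, manifest
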