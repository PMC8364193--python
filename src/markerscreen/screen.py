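"""Competitive translated-read classification and contig screening.

Every read is translated in all six frames and searched against the marker
and decoy protein databases. Hits are kept when their E-value is below the
cutoff and their percent identity is above the reporting floor; the best hit
per database is the one with the highest identity (ties broken by raw score,
then by subject id). A read is a positive marker observation iff

* its best marker identity exceeds the positive cutoff (default >70%), and
* no decoy hit beats it: best marker identity >= best decoy identity.

A read is one observation: however many markers it hits, it contributes at
most one positive count. Metatranscriptome reads go through the identical
procedure; only the downstream interpretation differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, DEFAULT_MATRIX, AlignmentHit, EvalueParams, local_align
from .kmer import DEFAULT_SEED_K, KmerIndex, matrix_codes, membership_table
from .markerdb import MarkerDatabase
from .seq import (
    INT_TO_AA,
    SequenceRecord,
    encode_dna,
    iter_fastq,
    read_fasta,
    translate_frames_matrix,
    translate_six_frames,
)

logger = logging.getLogger(__name__)

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class SearchParams:
    """Filters and scoring for the translated search."""

    evalue_cutoff: float = 1e-4
    report_identity_floor_pct: float = 50.0
    positive_identity_cutoff_pct: float = 70.0
    matrix_name: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    seed_k: int = DEFAULT_SEED_K
    use_seed: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.report_identity_floor_pct <= self.positive_identity_cutoff_pct <= 100:
            raise ValueError("require 0 < floor <= positive cutoff <= 100")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue cutoff must be positive")


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    best_marker_hit: AlignmentHit | None
    best_decoy_hit: AlignmentHit | None
    positive: bool
    flag: str = ""


@dataclass
class SampleScreenResult:
    """Per-sample tally of the translated search."""

    sample_id: str
    total_reads: int
    positive_reads: int
    positives: list[ReadClassification] = field(default_factory=list)


@dataclass(frozen=True)
class GenomicHit:
    """A protein-query hit on a translated contig segment."""

    contig_id: str
    strand: str
    frame: int
    contig_span: tuple[int, int]
    query_id: str
    identity_pct: float
    evalue: float
    at_contig_end: bool


class _CompiledDB:
    """Seeding indexes and E-value sizes for one database + parameter set."""

    def __init__(self, db: MarkerDatabase, params: SearchParams):
        self.db = db
        self.params = params
        self.marker_index = KmerIndex(db.markers, params.seed_k)
        self.decoy_index = KmerIndex(db.decoys, params.seed_k) if db.decoys else None
        self.n_marker = max(self.marker_index.total_residues, 1)
        self.n_decoy = max(sum(len(d.seq) for d in db.decoys), 1)
        if self.decoy_index is not None and self.decoy_index.sorted_codes.size:
            self.all_codes = np.union1d(self.marker_index.sorted_codes,
                                        self.decoy_index.sorted_codes)
        else:
            self.all_codes = self.marker_index.sorted_codes
        self.lookup = membership_table(self.all_codes, params.seed_k)


def _compiled(db: MarkerDatabase, params: SearchParams) -> _CompiledDB:
    cache = getattr(db, "_compiled_cache", None)
    key = (params.matrix_name, params.gap_open, params.gap_extend, params.seed_k)
    if cache is None:
        cache = {}
        db._compiled_cache = cache
    if key not in cache:
        cache[key] = _CompiledDB(db, params)
    return cache[key]


def _segments(peptide: str, min_len: int) -> list[tuple[int, str]]:
    """Stop-free segments of a translated frame, with their offsets."""
    out = []
    pos = 0
    for part in peptide.split("*"):
        if len(part) >= min_len:
            out.append((pos, part))
        pos += len(part) + 1
    return out


def _best_hits_for_frames(
    read_id: str,
    frames: Sequence[tuple[int, str]],
    proteins: list[SequenceRecord],
    index: KmerIndex | None,
    n_db: int,
    params: SearchParams,
    min_segment: int,
) -> AlignmentHit | None:
    """Best filtered hit of any frame segment against one database."""
    best: AlignmentHit | None = None
    for frame_no, peptide in frames:
        for offset, segment in _segments(peptide, min_segment):
            if params.use_seed and index is not None:
                subject_ids = sorted(index.subjects_for(segment))
                if not subject_ids:
                    continue
            else:
                subject_ids = range(len(proteins))
            seg_rec = SequenceRecord._trusted(read_id, segment)
            for si in subject_ids:
                subject = proteins[si]
                hit = local_align(
                    seg_rec,
                    subject,
                    matrix_name=params.matrix_name,
                    gap_open=params.gap_open,
                    gap_extend=params.gap_extend,
                    evalue_params=EvalueParams(m=max(len(segment), 1), n=n_db),
                    frame=frame_no,
                    max_evalue=params.evalue_cutoff,
                )
                if hit is None:
                    continue
                if hit.identity_pct <= params.report_identity_floor_pct:
                    continue
                hit = replace(
                    hit,
                    aligned_query_span=(
                        hit.aligned_query_span[0] + offset,
                        hit.aligned_query_span[1] + offset,
                    ),
                )
                if best is None or _hit_key(hit) > _hit_key(best):
                    best = hit
    return best


def _hit_key(hit: AlignmentHit) -> tuple:
    # highest identity wins; ties by raw score, then earliest subject id
    return (hit.identity_pct, hit.raw_score, _NegStr(hit.subject_id))


class _NegStr(str):
    """Orders lexicographically *descending* inside a max-comparison key."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def _classify_frames(
    read_id: str,
    frames: Sequence[tuple[int, str]],
    compiled: "_CompiledDB",
    params: SearchParams,
) -> ReadClassification:
    db = compiled.db
    min_seg = params.seed_k if params.use_seed else 1
    best_marker = _best_hits_for_frames(
        read_id, frames, db.markers, compiled.marker_index, compiled.n_marker, params, min_seg
    )
    best_decoy = _best_hits_for_frames(
        read_id, frames, db.decoys, compiled.decoy_index, compiled.n_decoy, params, min_seg
    )
    positive = (
        best_marker is not None
        and best_marker.identity_pct > params.positive_identity_cutoff_pct
        and (best_decoy is None or best_marker.identity_pct >= best_decoy.identity_pct)
    )
    return ReadClassification(read_id, best_marker, best_decoy, positive)


def classify_read(
    read: SequenceRecord, db: MarkerDatabase, params: SearchParams = SearchParams()
) -> ReadClassification:
    """Apply the competitive positivity rule to one nucleotide read."""
    min_nt = 3 * params.seed_k if params.use_seed else 3
    if len(read.seq) < min_nt:
        return ReadClassification(read.id, None, None, False, flag="too_short")
    compiled = _compiled(db, params)
    frames = [(no, f.seq) for no, f in zip(FRAME_ORDER, translate_six_frames(read))]
    return _classify_frames(read.id, frames, compiled, params)


# ---------------------------------------------------------------------------
# Sample-level screening
# ---------------------------------------------------------------------------

_CHUNK = 200_000


def _iter_read_chunks(reads, chunk: int):
    """Yield (ids, matrix uint8 padded with N, lengths) chunks from any source."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        if path.suffix in (".fastq", ".fq"):
            reads = iter_fastq(path)
        else:
            reads = iter(read_fasta(path, alphabet="dna"))
    if hasattr(reads, "matrix"):  # a simulated ReadSet
        mat, ids = reads.matrix, reads.ids
        lengths = np.full(mat.shape[0], mat.shape[1], dtype=np.int64)
        for lo in range(0, mat.shape[0], chunk):
            hi = min(lo + chunk, mat.shape[0])
            yield list(ids[lo:hi]), mat[lo:hi], lengths[lo:hi]
        return
    batch: list[SequenceRecord] = []
    it = iter(reads)
    while True:
        batch = []
        for rec in it:
            batch.append(rec)
            if len(batch) >= chunk:
                break
        if not batch:
            return
        lengths = np.array([len(r.seq) for r in batch], dtype=np.int64)
        width = int(lengths.max())
        mat = np.full((len(batch), width), 4, dtype=np.uint8)
        for i, rec in enumerate(batch):
            mat[i, : lengths[i]] = encode_dna(rec.seq)
        yield [r.id for r in batch], mat, lengths


def screen_sample(
    reads,
    db: MarkerDatabase,
    params: SearchParams = SearchParams(),
    sample_id: str = "sample",
) -> SampleScreenResult:
    """Classify every read of a sample and tally positives.

    ``reads`` may be a FASTQ/FASTA path, an iterable of nucleotide
    :class:`SequenceRecord`, or a simulated read set. Reads are bulk
    pre-filtered by exact k-mer seeding against the combined marker+decoy
    word set (a superset of any read the seeded classifier could call
    positive), then candidates get the full per-read classification.
    """
    compiled = _compiled(db, params)
    total = 0
    min_nt = 3 * params.seed_k if params.use_seed else 3
    positives: list[ReadClassification] = []
    for ids, mat, lengths in _iter_read_chunks(reads, _CHUNK):
        total += len(ids)
        frame_mats = translate_frames_matrix(mat, lengths)
        if params.use_seed:
            # per-frame seed masks: a frame sharing no word with the combined
            # marker+decoy vocabulary can yield no hit for either database,
            # so only seeded frames need the full classification
            frame_hits = []
            for frame_mat in frame_mats:
                codes = matrix_codes(frame_mat, params.seed_k)
                if not codes.size:
                    frame_hits.append(np.zeros(len(ids), dtype=bool))
                elif compiled.lookup is not None:
                    frame_hits.append(compiled.lookup[codes].any(axis=1))
                else:
                    flat = codes.ravel()
                    pos = np.searchsorted(compiled.all_codes, flat)
                    pos[pos == compiled.all_codes.size] = 0
                    hit = (compiled.all_codes[pos] == flat).reshape(codes.shape)
                    frame_hits.append(hit.any(axis=1))
            candidate = np.logical_or.reduce(frame_hits)
            idx = np.nonzero(candidate)[0]
        else:
            frame_hits = None
            idx = np.arange(len(ids))
        for i in idx:
            if lengths[i] < min_nt:
                continue
            frames = []
            for f, (frame_no, frame_mat) in enumerate(zip(FRAME_ORDER, frame_mats)):
                if frame_hits is not None and not frame_hits[f][i]:
                    continue
                off = abs(frame_no) - 1
                ncod = (int(lengths[i]) - off) // 3
                if ncod <= 0:
                    continue
                frames.append((frame_no, INT_TO_AA[frame_mat[i, :ncod]].tobytes().decode()))
            cls = _classify_frames(ids[i], frames, compiled, params)
            if cls.positive:
                positives.append(cls)
    if total == 0:
        logger.warning("sample %s has zero reads; downstream RPKM is undefined", sample_id)
    return SampleScreenResult(sample_id, total, len(positives), positives)


def classifications_to_frame(result: SampleScreenResult) -> pd.DataFrame:
    """Tidy per-positive-read table for TSV export."""
    rows = []
    for cls in result.positives:
        mk, dc = cls.best_marker_hit, cls.best_decoy_hit
        rows.append({
            "read_id": cls.read_id,
            "marker_id": mk.subject_id if mk else "",
            "marker_identity_pct": mk.identity_pct if mk else np.nan,
            "marker_evalue": mk.evalue if mk else np.nan,
            "decoy_id": dc.subject_id if dc else "",
            "decoy_identity_pct": dc.identity_pct if dc else np.nan,
            "positive": cls.positive,
        })
    return pd.DataFrame(rows, columns=["read_id", "marker_id", "marker_identity_pct",
                                       "marker_evalue", "decoy_id",
                                       "decoy_identity_pct", "positive"])


# ---------------------------------------------------------------------------
# Contig / genome screening
# ---------------------------------------------------------------------------

def screen_contigs(
    contigs: list[SequenceRecord],
    queries: list[SequenceRecord],
    params: SearchParams = SearchParams(),
    min_identity_pct: float | None = None,
) -> list[GenomicHit]:
    """Search protein queries against all six translated frames of contigs.

    Stop-delimited segments of each frame are aligned against queries that
    share a seed word; hits passing the E-value cutoff and identity floor are
    reported with their nucleotide span mapped back from peptide coordinates.
    Pass ``min_identity_pct=70`` to keep homolog calls only.
    """
    index = KmerIndex(queries, params.seed_k) if params.use_seed else None
    n_db = max(sum(len(c.seq) for c in contigs) // 3, 1)
    floor = params.report_identity_floor_pct if min_identity_pct is None else min_identity_pct
    hits: list[GenomicHit] = []
    for contig in contigs:
        if contig.alphabet != "dna":
            raise ValueError(f"contig {contig.id!r} must be nucleotide")
        length = len(contig.seq)
        frames = translate_six_frames(contig)
        for frame_no, frame in zip(FRAME_ORDER, frames):
            off = abs(frame_no) - 1
            for seg_off, segment in _segments(frame.seq, params.seed_k if params.use_seed else 1):
                if params.use_seed and index is not None:
                    q_ids = sorted(index.subjects_for(segment))
                else:
                    q_ids = range(len(queries))
                seg_rec = SequenceRecord(f"{contig.id}|{frame_no}|{seg_off}", segment, "protein")
                for qi in q_ids:
                    query = queries[qi]
                    hit = local_align(
                        query,
                        seg_rec,
                        matrix_name=params.matrix_name,
                        gap_open=params.gap_open,
                        gap_extend=params.gap_extend,
                        evalue_params=EvalueParams(m=len(query.seq), n=n_db),
                        frame=frame_no,
                    )
                    if hit is None or hit.evalue >= params.evalue_cutoff:
                        continue
                    if hit.identity_pct <= floor:
                        continue
                    ps, pe = hit.aligned_subject_span
                    ps += seg_off
                    pe += seg_off
                    if frame_no > 0:
                        span = (off + 3 * ps, off + 3 * pe)
                        strand = "+"
                    else:
                        span = (length - (off + 3 * pe), length - (off + 3 * ps))
                        strand = "-"
                    hits.append(GenomicHit(
                        contig_id=contig.id,
                        strand=strand,
                        frame=frame_no,
                        contig_span=span,
                        query_id=query.id,
                        identity_pct=hit.identity_pct,
                        evalue=hit.evalue,
                        at_contig_end=span[0] < 3 or span[1] > length - 3,
                    ))
    return hits


def genomic_hits_to_frame(hits: list[GenomicHit]) -> pd.DataFrame:
    rows = [{
        "contig_id": h.contig_id, "strand": h.strand, "frame": h.frame,
        "start": h.contig_span[0], "end": h.contig_span[1],
        "start_1based": h.contig_span[0] + 1,
        "query_id": h.query_id, "identity_pct": h.identity_pct,
        "evalue": h.evalue, "at_contig_end": h.at_contig_end,
    } for h in hits]
    return pd.DataFrame(rows, columns=["contig_id", "strand", "frame", "start", "end",
                                       "start_1based", "query_id", "identity_pct",
                                       "evalue", "at_contig_end"])


def detect_cluster_context(
    hits: list[GenomicHit],
    gene_annotations: pd.DataFrame,
    window_bp: int = 10_000,
    known_contigs: set[str] | None = None,
) -> pd.DataFrame:
    """Annotated genes within ``window_bp`` of each hit, on the same contig.

    ``gene_annotations`` needs columns contig_id, start, end, strand, name
    (0-based half-open). Neighbors are sorted by absolute offset from the
    hit. Raises if an annotation names a contig outside ``known_contigs``
    (defaulting to the contigs carrying hits plus those in the annotations).
    """
    required = {"contig_id", "start", "end", "strand", "name"}
    missing = required - set(gene_annotations.columns)
    if missing:
        raise ValueError(f"annotations missing columns {sorted(missing)}")
    if known_contigs is not None:
        unknown = set(gene_annotations["contig_id"]) - set(known_contigs)
        if unknown:
            raise KeyError(f"annotations reference unknown contigs {sorted(unknown)}")
    rows = []
    for h in hits:
        sub = gene_annotations[gene_annotations["contig_id"] == h.contig_id]
        hs, he = h.contig_span
        for _, g in sub.iterrows():
            # gap between the hit span and the gene span (0 if they overlap)
            if g["end"] <= hs:
                gap = hs - g["end"]
                offset = g["start"] - hs
            elif g["start"] >= he:
                gap = g["start"] - he
                offset = g["start"] - he
            else:
                gap = 0
                offset = g["start"] - hs
            if gap <= window_bp:
                rows.append({
                    "contig_id": h.contig_id, "hit_query": h.query_id,
                    "hit_start": hs, "hit_end": he,
                    "hit_at_contig_end": h.at_contig_end,
                    "neighbor": g["name"], "neighbor_strand": g["strand"],
                    "offset_bp": offset,
                })
    frame = pd.DataFrame(rows, columns=["contig_id", "hit_query", "hit_start", "hit_end",
                                        "hit_at_contig_end", "neighbor",
                                        "neighbor_strand", "offset_bp"])
    return frame.sort_values(["contig_id", "hit_start", "offset_bp"],
                             key=lambda s: s.abs() if s.name == "offset_bp" else s,
                             ignore_index=True)
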