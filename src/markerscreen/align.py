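"""Protein pairwise alignment and Karlin–Altschul E-values.

Local (Smith–Waterman) and global (Needleman–Wunsch) alignment with affine
gap penalties are delegated to Biopython's ``PairwiseAligner``; this module
owns the percent-identity convention and the E-value model.

Percent identity is computed over alignment *columns*: matches divided by
(matches + mismatches + gap columns), so gaps count against identity. For
local alignments only the locally aligned region (including its internal
gaps) contributes columns; for global alignments terminal gaps count too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seq import SequenceRecord

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

#: published gapped-BLOSUM62 Karlin–Altschul constants
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267


class MatrixConfigError(ValueError):
    """Unknown substitution matrix name."""


@dataclass(frozen=True)
class EvalueParams:
    """Karlin–Altschul parameters: E = K * m * n * exp(-lambda * S).

    ``m`` is the effective query length and ``n`` the effective database
    length, both in residues.
    """

    K: float = DEFAULT_K
    lam: float = DEFAULT_LAMBDA
    m: int = 1
    n: int = 1

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be positive")
        if self.m < 1 or self.n < 1:
            raise ValueError("effective lengths must be >= 1")


def evalue_for(hit_score: float, params: EvalueParams) -> float:
    """Expected number of chance hits at score >= hit_score."""
    return params.K * params.m * params.n * math.exp(-params.lam * hit_score)


@dataclass(frozen=True)
class AlignmentHit:
    """One local protein alignment between a query and a subject."""

    query_id: str
    subject_id: str
    raw_score: float
    identity_pct: float
    aligned_query_span: tuple[int, int]
    aligned_subject_span: tuple[int, int]
    evalue: float
    frame: int = 0


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise MatrixConfigError(f"unknown substitution matrix {matrix_name!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(gap_open + gap_extend)  # first gap residue costs open+extend
    aligner.extend_gap_score = -gap_extend
    return aligner


def _column_counts(aln) -> tuple[int, int]:
    """(identities, columns incl. gap columns) of one Biopython alignment."""
    counts = aln.counts()
    gaps = counts.left_gaps + counts.internal_gaps + counts.right_gaps
    columns = counts.identities + counts.mismatches + gaps
    return counts.identities, columns


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    matrix_name: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    evalue_params: EvalueParams | None = None,
    frame: int = 0,
    max_evalue: float | None = None,
) -> AlignmentHit | None:
    """Optimal Smith–Waterman local alignment; ``None`` if no positive score.

    The reported identity covers alignment columns of the local region,
    counting internal gaps as mismatches. E-value defaults to
    ``EvalueParams(m=len(query), n=len(subject))`` unless supplied. When
    ``max_evalue`` is given, alignments whose E-value (a function of the
    optimal score alone) fails the cutoff return ``None`` without a
    traceback — the hot path when screening millions of reads.
    """
    if query.alphabet != "protein" or subject.alphabet != "protein":
        raise ValueError("local_align requires protein records")
    if gap_open < gap_extend or gap_extend < 0:
        raise ValueError("require gap_open >= gap_extend >= 0")
    aligner = _aligner(matrix_name, gap_open, gap_extend, "local")
    score = aligner.score(query.seq, subject.seq)
    if score <= 0:
        return None
    params = evalue_params or EvalueParams(m=len(query.seq), n=len(subject.seq))
    if max_evalue is not None and evalue_for(float(score), params) >= max_evalue:
        return None
    aln = next(iter(aligner.align(query.seq, subject.seq)))
    identities, columns = _column_counts(aln)
    blocks_q, blocks_s = aln.aligned
    qspan = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    sspan = (int(blocks_s[0][0]), int(blocks_s[-1][1]))
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=float(score),
        identity_pct=100.0 * identities / columns,
        aligned_query_span=qspan,
        aligned_subject_span=sspan,
        evalue=evalue_for(float(score), params),
        frame=frame,
    )


def global_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix_name: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Percent identity of the optimal global alignment of two proteins.

    All columns, including terminal gaps, enter the denominator, so e.g. a
    4-mer against its own 8-mer tandem duplication scores 50%. Symmetric in
    its arguments.
    """
    if not a.seq or not b.seq:
        raise ValueError("global_identity requires nonempty sequences")
    if a.alphabet != "protein" or b.alphabet != "protein":
        raise ValueError("global_identity requires protein records")
    if b.seq < a.seq:  # canonical order: co-optimal tracebacks cannot break symmetry
        a, b = b, a
    aligner = _aligner(matrix_name, gap_open, gap_extend, "global")
    aln = next(iter(aligner.align(a.seq, b.seq)))
    identities, columns = _column_counts(aln)
    return 100.0 * identities / columns
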