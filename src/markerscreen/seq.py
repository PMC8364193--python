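"""Sequence records, FASTA/FASTQ I/O, and six-frame translation.

Conventions used throughout the package:

* coordinates are 0-based half-open; 1-based numbers appear only in
  human-readable report columns;
* the protein alphabet is the 20 standard residues plus ``X`` (unknown)
  and ``*`` (stop, produced by translation only);
* the nucleotide alphabet is ``ACGT`` plus ``N`` (any base).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET_FULL = PROTEIN_ALPHABET + "XBZJUO*"
DNA_ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codon -> amino acid, standard genetic code, stops as '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


class AlphabetError(ValueError):
    """Sequence contains characters outside its declared alphabet."""


class EmptyPeptideError(ValueError):
    """A nucleotide sequence is too short to yield a single codon."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with a declared alphabet.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    seq : str
        Residues, upper-case. ``N`` (dna) and ``X`` (protein) are allowed
        ambiguity codes.
    alphabet : str
        ``"protein"`` or ``"dna"``.
    description : str
        Free-text provenance, may be empty.
    """

    id: str
    seq: str
    alphabet: str = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = set(PROTEIN_ALPHABET_FULL if self.alphabet == "protein" else DNA_ALPHABET)
        bad = set(self.seq) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} not in {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def _trusted(cls, id: str, seq: str, alphabet: str = "protein") -> "SequenceRecord":
        """Internal constructor skipping alphabet validation (hot loops only)."""
        rec = object.__new__(cls)
        object.__setattr__(rec, "id", id)
        object.__setattr__(rec, "seq", seq)
        object.__setattr__(rec, "alphabet", alphabet)
        object.__setattr__(rec, "description", "")
        return rec


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a nucleotide string in frame +1, standard code.

    Trailing bases not filling a codon are dropped; stop codons render as
    ``'*'``; any codon containing ``N`` renders as ``'X'``.
    """
    n = len(nt) - len(nt) % 3
    out = []
    for i in range(0, n, 3):
        codon = nt[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def translate_six_frames(read: SequenceRecord) -> list[SequenceRecord]:
    """All six translation frames of a nucleotide record.

    Returns frames in the order +1, +2, +3, -1, -2, -3, where frame -k is
    frame +k of the reverse complement. Raises
    :class:`EmptyPeptideError` for reads shorter than one codon.
    """
    if read.alphabet != "dna":
        raise AlphabetError(f"translate_six_frames requires dna input, got {read.alphabet}")
    if len(read.seq) < 3:
        raise EmptyPeptideError(f"read {read.id!r} shorter than one codon")
    rc = reverse_complement(read.seq)
    frames = []
    for label, src in (("+", read.seq), ("-", rc)):
        for off in range(3):
            pep = translate(src[off:])
            frame = int(f"{label}{off + 1}")
            frames.append(
                SequenceRecord(
                    id=f"{read.id}|frame{label}{off + 1}",
                    seq=pep if pep else "*",  # frames +3/-3 of 3-4 nt reads are empty
                    alphabet="protein",
                    description=f"frame={frame}",
                )
            )
    return frames


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path | io.TextIOBase, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file (wrapped lines allowed) into records."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path)
        close = True
    else:
        handle = path
    records: list[SequenceRecord] = []
    try:
        name: str | None = None
        desc = ""
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks).upper(), alphabet, desc))
                head = line[1:].split(None, 1)
                name = head[0] if head else ""
                desc = head[1] if len(head) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line.strip())
        if name is not None:
            records.append(SequenceRecord(name, "".join(chunks).upper(), alphabet, desc))
    finally:
        if close:
            handle.close()
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in FASTA input")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Iterate 4-line FASTQ records; qualities are parsed but discarded."""
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not head.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {head!r}")
            if len(qual) != len(seq):
                raise ValueError(f"quality length mismatch for {head!r}")
            rid = head[1:].split()[0]
            yield SequenceRecord(rid, seq.upper(), "dna")


def write_fastq(
    ids: Iterable[str], seqs: Iterable[str], path: str | Path, quality_char: str = "I"
) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Integer encodings shared by the vectorized screening and simulation paths
# ---------------------------------------------------------------------------

#: nucleotide byte -> small int (A,C,G,T,N -> 0..4; anything else -> 4)
NT_TO_INT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    NT_TO_INT[ord(_c)] = _i
INT_TO_NT = np.frombuffer(b"ACGTN", dtype=np.uint8)
#: reverse complement on the integer code (N -> N)
RC_INT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

#: amino-acid byte -> small int over PROTEIN_ALPHABET + X(20) + *(21)
AA_TO_INT = np.full(256, 20, dtype=np.uint8)  # unknowns collapse to X
for _i, _c in enumerate(PROTEIN_ALPHABET):
    AA_TO_INT[ord(_c)] = _i
AA_TO_INT[ord("X")] = 20
AA_TO_INT[ord("*")] = 21
INT_TO_AA = np.frombuffer((PROTEIN_ALPHABET + "X*").encode(), dtype=np.uint8)

#: codon index (16a+4b+c over ACGT ints) -> amino-acid int; 64 = "has N" -> X
CODON_INT_TO_AA = np.empty(65, dtype=np.uint8)
for _a in range(4):
    for _b in range(4):
        for _c2 in range(4):
            codon = "ACGT"[_a] + "ACGT"[_b] + "ACGT"[_c2]
            CODON_INT_TO_AA[16 * _a + 4 * _b + _c2] = AA_TO_INT[ord(CODON_TABLE[codon])]
CODON_INT_TO_AA[64] = 20  # X


def encode_dna(seq: str) -> np.ndarray:
    return NT_TO_INT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_dna(arr: np.ndarray) -> str:
    return INT_TO_NT[arr].tobytes().decode()


def translate_frames_matrix(reads: np.ndarray, lengths: np.ndarray) -> list[np.ndarray]:
    """Translate a padded read matrix in all six frames, vectorized.

    Parameters
    ----------
    reads : uint8 array, shape (n, max_len)
        Nucleotide integer codes, padded with 4 (``N``) beyond each read's
        length so padding translates to ``X`` and can never seed a match.
    lengths : int array, shape (n,)
        True read lengths (used by callers for coordinate mapping).

    Returns
    -------
    list of six uint8 matrices of amino-acid integer codes, frames in the
    order +1, +2, +3, -1, -2, -3.
    """
    n, width = reads.shape
    rc = RC_INT[reads[:, ::-1]]
    # reverse complement of the *unpadded* read: shift the pad back to the right
    if width > 1:
        pad = width - lengths
        rows = np.nonzero(pad > 0)[0]
        if rows.size:
            shifted = np.full_like(rc, 4)
            for r in rows:  # few distinct lengths in practice; cheap
                p = pad[r]
                shifted[r, : width - p] = rc[r, p:]
            rc[rows] = shifted[rows]
    out = []
    for src in (reads, rc):
        for off in range(3):
            ncod = (width - off) // 3
            if ncod == 0:
                out.append(np.full((n, 1), 21, dtype=np.uint8))
                continue
            cod = src[:, off : off + 3 * ncod].reshape(n, ncod, 3).astype(np.int16)
            has_n = (cod >= 4).any(axis=2)
            idx = 16 * cod[:, :, 0] + 4 * cod[:, :, 1] + cod[:, :, 2]
            idx[has_n] = 64
            out.append(CODON_INT_TO_AA[idx])
    return out
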