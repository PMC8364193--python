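"""Exact k-mer seeding index over protein databases.

A full Smith–Waterman of every read frame against every database protein is
wasteful: almost all reads in a metagenome share no exact peptide word with
a small marker/decoy database. The index stores every k-residue word (base-32
packed into an int64) of the database proteins; a translated frame is only
aligned against subjects it shares at least one word with.

Words containing ``X`` or ``*`` are never indexed, and because every residue
code is < 32 the packing is injective — a frame word containing an ambiguous
residue can never collide with an indexed word.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .seq import AA_TO_INT, SequenceRecord

DEFAULT_SEED_K = 5

_POW32 = 32 ** np.arange(12, dtype=np.int64)
_AA_TABLE = bytes(AA_TO_INT)  # byte -> residue code, for str.translate


def peptide_codes(aa_ints: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer codes of one peptide given as int codes (1-D)."""
    n = aa_ints.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    a = aa_ints.astype(np.int64)
    for j in range(k):
        out += a[j : j + n] * _POW32[j]
    return out


def matrix_codes(aa_ints: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer codes row-wise for a peptide matrix (n, L) -> (n, L-k+1)."""
    n, width = aa_ints.shape
    ncols = width - k + 1
    if ncols <= 0:
        return np.empty((n, 0), dtype=np.int64)
    out = np.zeros((n, ncols), dtype=np.int64)
    a = aa_ints.astype(np.int64)
    for j in range(k):
        out += a[:, j : j + ncols] * _POW32[j]
    return out


class KmerIndex:
    """Word index of a protein collection for seeded search."""

    def __init__(self, proteins: list[SequenceRecord], k: int = DEFAULT_SEED_K):
        if not 1 <= k <= 12:
            raise ValueError("k must lie in [1, 12]")
        self.k = k
        self.proteins = list(proteins)
        self.total_residues = sum(len(p.seq) for p in proteins)
        by_code: dict[int, set[int]] = defaultdict(set)
        for idx, prot in enumerate(proteins):
            ints = AA_TO_INT[np.frombuffer(prot.seq.encode(), dtype=np.uint8)]
            codes = peptide_codes(ints, k)
            valid = codes[
                np.all(
                    np.lib.stride_tricks.sliding_window_view(ints, k) < 20, axis=1
                )
            ]
            for code in valid.tolist():
                by_code[code].add(idx)
        self.by_code: dict[int, frozenset[int]] = {c: frozenset(s) for c, s in by_code.items()}
        self.sorted_codes = np.array(sorted(self.by_code), dtype=np.int64)

    def subjects_for(self, peptide: str) -> set[int]:
        """Indices of proteins sharing at least one exact k-mer with peptide."""
        k = self.k
        if len(peptide) < k:
            return set()
        ints = peptide.encode().translate(_AA_TABLE)
        code = 0
        for j in range(k):
            code += ints[j] << (5 * j)
        top = 5 * (k - 1)
        hits: set[int] = set()
        by_code = self.by_code
        subj = by_code.get(code)
        if subj:
            hits.update(subj)
        for i in range(len(peptide) - k):
            code = ((code - ints[i]) >> 5) + (ints[i + k] << top)
            subj = by_code.get(code)
            if subj:
                hits.update(subj)
        return hits

    def any_match(self, codes: np.ndarray) -> np.ndarray:
        """Boolean row mask: does any code in the row occur in the index?"""
        if codes.size == 0 or self.sorted_codes.size == 0:
            return np.zeros(codes.shape[0], dtype=bool)
        flat = codes.ravel()
        pos = np.searchsorted(self.sorted_codes, flat)
        pos[pos == self.sorted_codes.size] = 0
        hit = self.sorted_codes[pos] == flat
        return hit.reshape(codes.shape).any(axis=1)


def membership_table(codes: np.ndarray, k: int) -> np.ndarray | None:
    """Dense boolean lookup over the packed code domain (32**k), or ``None``
    when the domain is too large to tabulate (k > 5)."""
    domain = 32**k
    if domain > 1 << 26:
        return None
    table = np.zeros(domain, dtype=bool)
    if codes.size:
        table[codes] = True
    return table
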