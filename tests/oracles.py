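"""Independent reference implementations used only by the tests.

These deliberately avoid the package's alignment/classification code paths:
pure-Python dynamic programming, literal rule application, and complete
permutation enumeration, so they can serve as oracles for the optimized
implementations.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, exp

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def sw_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal local alignment score, affine gaps (first gap residue costs
    open+extend), three-matrix Gotoh DP."""
    la, lb = len(a), len(b)
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]  # gap in b (a consumed)
    Y = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]  # gap in a
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            sub = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + sub, X[i - 1][j - 1] + sub, Y[i - 1][j - 1] + sub)
            best = max(best, M[i][j])
    return best


def sw_align(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0):
    """(score, identity_pct) of one optimal local alignment, with traceback.

    Identity is matches / alignment columns (gap columns count).
    """
    la, lb = len(a), len(b)
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            sub = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + sub, X[i - 1][j - 1] + sub, Y[i - 1][j - 1] + sub)
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best <= 0:
        return 0.0, None
    # traceback from (bi, bj) in M until a zero cell
    i, j, state = bi, bj, "M"
    matches = columns = 0
    while True:
        if state == "M":
            if M[i][j] == 0:
                break
            sub = _BLOSUM62[a[i - 1]][b[j - 1]]
            columns += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = M[i][j] - sub
            if prev == M[i - 1][j - 1]:
                state = "M"
            elif prev == X[i - 1][j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
            if state == "M" and M[i][j] == 0:
                break
        elif state == "X":
            columns += 1
            if X[i][j] == X[i - 1][j] - gap_extend:
                state = "X"
            else:
                state = "M"
            i -= 1
        else:
            columns += 1
            if Y[i][j] == Y[i][j - 1] - gap_extend:
                state = "Y"
            else:
                state = "M"
            j -= 1
    return best, 100.0 * matches / columns


def six_frames(nt: str) -> list[tuple[int, str]]:
    """Six-frame translation via Biopython, frames +1..+3, -1..-3."""
    out = []
    rc = str(Seq(nt).reverse_complement())
    for sign, src in ((1, nt), (-1, rc)):
        for off in range(3):
            sub = src[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            out.append((sign * (off + 1), pep))
    return out


def classify_oracle(read_nt, markers, decoys, evalue_cutoff=1e-4, floor=50.0,
                    positive_cutoff=70.0, K=0.041, lam=0.267):
    """Literal competitive rule via seedless all-pairs pure-Python alignment.

    Returns (positive, best_marker_identity, best_decoy_identity), identities
    None when no filtered hit.
    """

    def best_identity(proteins):
        n_db = max(sum(len(p) for p in proteins), 1)
        best = None
        for _, pep in six_frames(read_nt):
            for segment in pep.split("*"):
                if not segment:
                    continue
                for prot in proteins:
                    score, ident = sw_align(segment, prot)
                    if ident is None:
                        continue
                    ev = K * len(segment) * n_db * exp(-lam * score)
                    if ev >= evalue_cutoff or ident <= floor:
                        continue
                    if best is None or ident > best:
                        best = ident
        return best

    bm = best_identity(markers)
    bd = best_identity(decoys)
    positive = bm is not None and bm > positive_cutoff and (bd is None or bm >= bd)
    return positive, bm, bd


def mann_whitney_exact_oracle(a, b):
    """Two-sided exact Mann–Whitney p by enumerating group assignments of the
    pooled observations (doubled smaller tail, capped at 1)."""
    pooled = sorted(list(a) + list(b))
    n1 = len(a)

    def u_of(subset):
        # U = sum over pairs (x in group1, y in group2) of 1[x > y] + 0.5 ties
        g1 = [pooled[i] for i in subset]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in set(subset)]
        u = 0.0
        for x in g1:
            for y in g2:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = 0.0
    for x in a:
        for y in b:
            u_obs += 1.0 if x > y else (0.5 if x == y else 0.0)
    us = [u_of(s) for s in combinations(range(len(pooled)), n1)]
    total = comb(len(pooled), n1)
    lower = sum(1 for u in us if u <= u_obs + 1e-9)
    upper = sum(1 for u in us if u >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper) / total)
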