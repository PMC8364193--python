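"""Cohort-level prevalence, concordance, and nonparametric association.

The cohort table is a tidy pandas DataFrame, one row per sample, with the
columns

    sample_id, cohort, group, gene_present, transcript_present, abundance,
    <metabolite columns, e.g. gbb, carnitine, butyrate>

``transcript_present`` and metabolite columns may be missing (NaN). Group
comparisons use the Mann–Whitney U test: an exact two-sided p-value by
complete enumeration for small tie-free samples, otherwise the normal
approximation with tie and continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Mann–Whitney U outcome for one two-group comparison.

    ``statistic`` is U of the first group; ``p_two_sided`` is doubled-tail
    (exact path) or tie/continuity-corrected normal (approximation path).
    """

    statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2)


def mann_whitney_u(values_a, values_b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact null distribution by complete enumeration of rank splits when
    n1 + n2 <= 12 and the pooled data are tie-free (two-sided p = doubled
    smaller tail, capped at 1); otherwise normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size

    if n1 + n2 <= EXACT_MAX_N and tie_free:
        # enumerate which pooled ranks go to group 1; all C(N, n1) splits
        # are equally likely under H0
        total = comb(n1 + n2, n1)
        us = np.array([
            sum(split) - n1 * (n1 + 1) / 2
            for split in combinations(range(1, n1 + n2 + 1), n1)
        ])
        lower = int((us <= u).sum())
        upper = int((us >= u).sum())
        p = min(1.0, 2.0 * min(lower, upper) / total)
        return TestResult(u, n1, n2, p, "exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return TestResult(u, n1, n2, 1.0, "normal-approximation-with-tie-correction")
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult(u, n1, n2, p, "normal-approximation-with-tie-correction")


def prevalence(
    table: pd.DataFrame, by: str = "cohort", presence_col: str = "gene_present"
) -> pd.DataFrame:
    """Fraction of samples positive and negative per group.

    Rows with a missing presence call are excluded; empty groups are dropped
    with a warning.
    """
    rows = []
    for group, sub in table.groupby(by, dropna=False):
        calls = sub[presence_col].dropna()
        if calls.empty:
            logger.warning("group %r has no presence calls; excluded", group)
            continue
        n = len(calls)
        pos = int(calls.astype(bool).sum())
        rows.append({by: group, "n": n, "n_positive": pos,
                     "fraction_positive": pos / n,
                     "fraction_negative": (n - pos) / n})
    return pd.DataFrame(rows, columns=[by, "n", "n_positive",
                                       "fraction_positive", "fraction_negative"])


def associate_presence_with_metabolite(
    table: pd.DataFrame,
    metabolite_name: str,
    stratify_by: str | None = None,
    presence_col: str = "gene_present",
) -> pd.DataFrame:
    """Mann–Whitney comparison of metabolite levels, gene-positive vs -negative.

    One row per stratum with group sizes, U, two-sided p, and the group
    medians and means. Missing metabolite values are dropped pairwise;
    strata with fewer than two usable samples in either group are skipped
    with a warning.
    """
    if metabolite_name not in table.columns:
        raise KeyError(f"no metabolite column {metabolite_name!r}")
    strata = [("all", table)] if stratify_by is None else list(table.groupby(stratify_by))
    rows = []
    for name, sub in strata:
        usable = sub.dropna(subset=[metabolite_name, presence_col])
        pos = usable.loc[usable[presence_col].astype(bool), metabolite_name].to_numpy()
        neg = usable.loc[~usable[presence_col].astype(bool), metabolite_name].to_numpy()
        if pos.size < 2 or neg.size < 2:
            logger.warning("stratum %r skipped: <2 usable samples in a group", name)
            continue
        res = mann_whitney_u(pos, neg)
        rows.append({
            "stratum": name, "metabolite": metabolite_name,
            "n_positive": res.n1, "n_negative": res.n2,
            "U": res.statistic, "p_two_sided": res.p_two_sided,
            "method": res.method,
            "median_positive": float(np.median(pos)),
            "median_negative": float(np.median(neg)),
            "mean_positive": float(np.mean(pos)),
            "mean_negative": float(np.mean(neg)),
        })
    return pd.DataFrame(rows, columns=["stratum", "metabolite", "n_positive", "n_negative",
                                       "U", "p_two_sided", "method", "median_positive",
                                       "median_negative", "mean_positive", "mean_negative"])


@dataclass(frozen=True)
class ConcordanceResult:
    """2x2 gene-presence x transcript-presence tally and conditional rates."""

    n_gene_pos_transcript_pos: int
    n_gene_pos_transcript_neg: int
    n_gene_neg_transcript_pos: int
    n_gene_neg_transcript_neg: int
    frac_transcript_pos_given_gene_pos: float | None
    frac_transcript_pos_given_gene_neg: float | None


def gene_transcript_concordance(table: pd.DataFrame) -> ConcordanceResult:
    """Transcript positivity conditioned on gene presence.

    Fractions are None when the conditioning group is empty. Raises when no
    sample has a transcript call.
    """
    usable = table.dropna(subset=["gene_present", "transcript_present"])
    if usable.empty:
        raise ValueError("no samples with both gene and transcript calls")
    g = usable["gene_present"].astype(bool)
    t = usable["transcript_present"].astype(bool)
    a = int((g & t).sum())
    b_ = int((g & ~t).sum())
    c = int((~g & t).sum())
    d = int((~g & ~t).sum())
    return ConcordanceResult(
        a, b_, c, d,
        a / (a + b_) if (a + b_) else None,
        c / (c + d) if (c + d) else None,
    )


def load_cohort_table(path) -> pd.DataFrame:
    """Read a cohort TSV; enforces unique sample ids."""
    table = pd.read_csv(path, sep="\t")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in cohort table")
    return table
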