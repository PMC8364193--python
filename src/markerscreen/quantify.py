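"""RPKM and genome-size-normalized marker abundance.

Positive read counts are converted to RPKM (reads per kilobase of gene per
million sample reads) and then to genes per microbial genome by multiplying
with the sample's average genome size (AGS, in bp):

    RPKM      = (positive / total) * 1e6 / gene_length_kb
    abundance = RPKM * AGS * 1e-9        [marker genes per genome]

Both steps are exactly linear in the positive-read count. AGS estimation is
an upstream input (one value per sample, in base pairs), not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .screen import SampleScreenResult


class UndefinedQuantificationError(ValueError):
    """Raised when a sample has zero total reads (RPKM undefined)."""


@dataclass(frozen=True)
class SampleQuantification:
    sample_id: str
    total_reads: int
    positive_reads: int
    gene_length_kb: float
    ags_bp: float
    rpkm: float
    abundance: float
    present: bool


def rpkm(positive_reads: int, total_reads: int, gene_length_kb: float) -> float:
    if total_reads < 1:
        raise UndefinedQuantificationError("RPKM undefined for zero total reads")
    if gene_length_kb <= 0:
        raise ValueError("gene length must be positive")
    return (positive_reads / total_reads) * 1e6 / gene_length_kb


def abundance(rpkm_value: float, ags_bp: float) -> float:
    """Marker genes per microbial genome."""
    if ags_bp <= 0:
        raise ValueError("average genome size must be positive")
    return rpkm_value * ags_bp * 1e-9


def quantify_sample(
    screen: SampleScreenResult,
    ags_bp: float,
    gene_length_kb: float,
    presence_min_reads: int = 1,
) -> SampleQuantification:
    """Assemble per-sample quantification from a screening tally.

    Presence defaults to >= 1 positive read; the threshold is exposed for
    sensitivity analyses.
    """
    r = rpkm(screen.positive_reads, screen.total_reads, gene_length_kb)
    return SampleQuantification(
        sample_id=screen.sample_id,
        total_reads=screen.total_reads,
        positive_reads=screen.positive_reads,
        gene_length_kb=gene_length_kb,
        ags_bp=ags_bp,
        rpkm=r,
        abundance=abundance(r, ags_bp),
        present=screen.positive_reads >= presence_min_reads,
    )
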