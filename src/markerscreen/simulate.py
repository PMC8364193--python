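"""Synthetic gut communities, short reads, transcriptomes, metabolites.

The generator emulates the statistical setting the screening pipeline is
built for: large mixed communities of bacterial genomes in which a small
minority carry a single copy of the marker gene (true abundance down to
1e-3 genes per genome), confounded by decoy genes whose proteins sit in a
50–70% identity band below the marker, sequenced as short substitution-error
reads. Paired transcriptomes over-sample the marker ("induced" expression),
and the metabolite the marker enzyme consumes is stochastically lower in
marker-positive samples.

Background sequence is uniform random sense codons — a deliberately
low-homology background, so false seeding is rare and every positive call
traces to a planted gene. All randomness flows from one integer seed; the
same spec and seed reproduce byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import global_identity
from .seq import (
    AA_TO_INT,
    NT_TO_INT,
    PROTEIN_ALPHABET,
    RC_INT,
    SequenceRecord,
    decode_dna,
    write_fastq,
)
from Bio.Data.CodonTable import standard_dna_table

# sense codons per amino acid, deterministic order, for reverse translation
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_SENSE_CODONS = np.array(
    [[NT_TO_INT[ord(c)] for c in codon] for codon in sorted(standard_dna_table.forward_table)],
    dtype=np.uint8,
)

DEFAULT_MARKER_LENGTH_AA = 400


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth parameters of one simulated community sample.

    Defaults describe the reference condition the pipeline is validated
    under: 5,000 genomes of 50 kb, a 400-residue marker (1.2 kb gene)
    carried by one genome in a thousand, decoy homologs at 50–65% identity
    carried by 5% of genomes, and 2 million 150-nt reads with 0.5%
    substitution error.
    """

    n_genomes: int = 5000
    genome_length_bp: int = 50_000
    marker_protein: SequenceRecord | None = None
    marker_carriage_rate: float = 1e-3
    decoy_identity_band: tuple[float, float] = (50.0, 65.0)
    decoy_carriage_rate: float = 0.05
    n_decoy_variants: int = 5
    decoy_proteins: tuple[SequenceRecord, ...] | None = None  # override generation
    read_length_nt: int = 150
    substitution_error_rate: float = 0.005
    n_reads: int = 2_000_000
    expression_multiplier_marker: float = 100.0
    metabolite_effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.marker_carriage_rate <= 1:
            raise ValueError("marker carriage rate must lie in [0, 1]")
        if not 0 <= self.decoy_carriage_rate <= 1:
            raise ValueError("decoy carriage rate must lie in [0, 1]")
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution error rate must lie in [0, 1)")
        lo, hi = self.decoy_identity_band
        if not 0 < lo < hi < 100:
            raise ValueError("decoy identity band must lie inside (0, 100)")
        if self.read_length_nt > self.genome_length_bp:
            raise ValueError("reads cannot be longer than genomes")


@dataclass
class GroundTruth:
    """Planted structure of one community."""

    marker_copies: np.ndarray  # per-genome counts
    marker_spans: np.ndarray  # (k, 2) global nt coords, sorted
    decoy_spans: np.ndarray  # (k, 2) global nt coords, sorted
    decoy_variant_ids: list[str]

    @property
    def true_genes_per_genome(self) -> float:
        return float(self.marker_copies.sum()) / len(self.marker_copies)


@dataclass
class Community:
    """A simulated community held as one concatenated integer array."""

    seq: np.ndarray  # uint8 codes, length n_genomes * genome_length_bp
    n_genomes: int
    genome_length_bp: int
    truth: GroundTruth
    marker_protein: SequenceRecord = None  # type: ignore[assignment]
    decoy_proteins: list[SequenceRecord] = field(default_factory=list)

    def genome_records(self) -> list[SequenceRecord]:
        L = self.genome_length_bp
        return [
            SequenceRecord(f"genome{g:05d}", decode_dna(self.seq[g * L : (g + 1) * L]), "dna")
            for g in range(self.n_genomes)
        ]

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        L = self.genome_length_bp
        with open(path, "w") as fh:
            for g in range(self.n_genomes):
                fh.write(f">genome{g:05d}\n")
                s = decode_dna(self.seq[g * L : (g + 1) * L])
                for i in range(0, L, width):
                    fh.write(s[i : i + width] + "\n")


@dataclass
class ReadSet:
    """Fixed-length reads as an integer matrix plus per-read origin tags.

    ``origin`` is 0 for background, 1 for marker-overlapping, 2 for
    decoy-overlapping (overlap of at least one codon with a planted gene).
    """

    ids: list[str]
    matrix: np.ndarray  # uint8 (n_reads, read_length)
    origin: np.ndarray  # int8 (n_reads,)

    ORIGIN_BACKGROUND = 0
    ORIGIN_MARKER = 1
    ORIGIN_DECOY = 2

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def sequences(self) -> list[str]:
        return [decode_dna(row) for row in self.matrix]

    def to_fastq(self, path: str | Path) -> None:
        write_fastq(self.ids, self.sequences(), path)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(PROTEIN_ALPHABET))[rng.integers(0, 20, length)])


def reverse_translate(protein: str, rng: np.random.Generator) -> np.ndarray:
    """Coding sequence (no stop codon) with random synonymous codons."""
    out = np.empty(3 * len(protein), dtype=np.uint8)
    for i, aa in enumerate(protein):
        codons = _CODONS_BY_AA[aa]
        codon = codons[rng.integers(0, len(codons))]
        out[3 * i : 3 * i + 3] = [NT_TO_INT[ord(c)] for c in codon]
    return out


def mutate_to_identity(
    protein: SequenceRecord, target_identity_pct: float, seed: int, tolerance: float = 2.0
) -> SequenceRecord:
    """Substitution-only variant at a target global identity (±tolerance).

    Residues at uniformly random positions are replaced by one of the 19
    alternatives (no indels) until the measured global identity lands within
    the band. Deterministic given the seed. Raises if the target cannot be
    reached within a bounded number of adjustment rounds (short proteins at
    very low targets).
    """
    if not 0 < target_identity_pct <= 100:
        raise ValueError("target identity must lie in (0, 100]")
    if target_identity_pct >= 100:
        return protein
    rng = np.random.default_rng(seed)
    length = len(protein.seq)
    aa = np.array(list(protein.seq))
    orig = aa.copy()
    n_mut = int(round(length * (1 - target_identity_pct / 100.0)))
    alphabet = np.array(list(PROTEIN_ALPHABET))
    mutated = rng.choice(length, size=min(n_mut, length), replace=False).tolist()
    untouched = [i for i in range(length) if i not in set(mutated)]
    rng.shuffle(untouched)

    def substitute(i: int) -> None:
        choices = alphabet[alphabet != orig[i]]
        aa[i] = choices[rng.integers(0, len(choices))]

    for i in mutated:
        substitute(i)
    variant = SequenceRecord(f"{protein.id}|id{target_identity_pct:g}", "".join(aa), "protein")
    for _ in range(4 * length):
        ident = global_identity(variant, protein)
        if abs(ident - target_identity_pct) <= tolerance:
            return variant
        if ident > target_identity_pct:
            if not untouched:
                break
            i = untouched.pop()
            mutated.append(i)
            substitute(i)
        else:
            if not mutated:
                break
            i = mutated.pop()
            untouched.append(i)
            aa[i] = orig[i]
        variant = SequenceRecord(variant.id, "".join(aa), "protein")
    raise ValueError(
        f"could not reach {target_identity_pct}% identity ±{tolerance} on {length} residues"
    )


def _place_genes(
    rng: np.random.Generator,
    seq: np.ndarray,
    genome_idx: np.ndarray,
    gene: np.ndarray | list[np.ndarray],
    genome_length: int,
    occupied: dict[int, list[tuple[int, int]]],
) -> np.ndarray:
    """Write one gene copy into each listed genome at a random free position."""
    spans = []
    for j, g in enumerate(genome_idx):
        cds = gene[j] if isinstance(gene, list) else gene
        glen = len(cds)
        for _ in range(100):
            start = int(rng.integers(0, genome_length - glen + 1))
            span = (start, start + glen)
            if all(span[1] <= s or span[0] >= e for s, e in occupied.get(int(g), [])):
                break
        else:
            raise ValueError("could not place gene without overlap")
        occupied.setdefault(int(g), []).append(span)
        lo = int(g) * genome_length + start
        seq[lo : lo + glen] = cds
        spans.append((lo, lo + glen))
    return np.array(sorted(spans), dtype=np.int64).reshape(-1, 2)


def make_decoy_proteins(spec: CommunitySpec, marker: SequenceRecord, seed: int) -> list[SequenceRecord]:
    """Distinct decoy variants with targets spread across the identity band."""
    lo, hi = spec.decoy_identity_band
    targets = np.linspace(lo + 1, hi - 1, spec.n_decoy_variants)
    return [
        SequenceRecord(
            f"decoy{v:02d}",
            mutate_to_identity(marker, float(t), seed=seed + 101 + v).seq,
            "protein",
            description=f"target_identity={t:.1f}",
        )
        for v, t in enumerate(targets)
    ]


def simulate_community(spec: CommunitySpec) -> Community:
    """Generate one community and its ground truth.

    Each genome is random sense codons; with probability
    ``marker_carriage_rate`` it carries one copy of the marker coding
    sequence at a random position, and with probability
    ``decoy_carriage_rate`` one decoy gene (variant chosen uniformly).
    """
    rng = np.random.default_rng(spec.seed)
    marker = spec.marker_protein or SequenceRecord(
        "marker", random_protein(DEFAULT_MARKER_LENGTH_AA, np.random.default_rng(spec.seed + 7)),
        "protein", description="synthetic marker protein",
    )
    if 3 * len(marker.seq) > spec.genome_length_bp:
        raise ValueError("marker gene longer than a genome")

    total = spec.n_genomes * spec.genome_length_bp
    n_codons = -(-total // 3)
    codon_ids = rng.integers(0, len(_SENSE_CODONS), n_codons)
    seq = _SENSE_CODONS[codon_ids].reshape(-1)[:total].copy()

    marker_cds = reverse_translate(marker.seq, rng)
    decoy_proteins = (list(spec.decoy_proteins) if spec.decoy_proteins is not None
                      else make_decoy_proteins(spec, marker, spec.seed))
    decoy_cds = [reverse_translate(p.seq, rng) for p in decoy_proteins]

    carriers = np.nonzero(rng.random(spec.n_genomes) < spec.marker_carriage_rate)[0]
    decoy_carriers = np.nonzero(rng.random(spec.n_genomes) < spec.decoy_carriage_rate)[0]
    decoy_choice = rng.integers(0, max(spec.n_decoy_variants, 1), len(decoy_carriers))

    occupied: dict[int, list[tuple[int, int]]] = {}
    marker_spans = _place_genes(rng, seq, carriers, marker_cds,
                                spec.genome_length_bp, occupied)
    decoy_spans = _place_genes(rng, seq, decoy_carriers,
                               [decoy_cds[c] for c in decoy_choice],
                               spec.genome_length_bp, occupied)

    copies = np.zeros(spec.n_genomes, dtype=np.int64)
    copies[carriers] = 1
    truth = GroundTruth(copies, marker_spans, decoy_spans,
                        [p.id for p in decoy_proteins])
    return Community(seq, spec.n_genomes, spec.genome_length_bp, truth,
                     marker_protein=marker, decoy_proteins=decoy_proteins)


def _tag_origin(starts: np.ndarray, read_len: int, spans: np.ndarray, min_overlap: int = 3) -> np.ndarray:
    """Boolean mask: read [s, s+len) overlaps some span by >= min_overlap nt."""
    if spans.size == 0:
        return np.zeros(len(starts), dtype=bool)
    s0 = spans[:, 0]
    hit = np.zeros(len(starts), dtype=bool)
    for j in (np.searchsorted(s0, starts, side="right") - 1,
              np.searchsorted(s0, starts, side="right")):
        jc = np.clip(j, 0, len(s0) - 1)
        ov = np.minimum(spans[jc, 1], starts + read_len) - np.maximum(spans[jc, 0], starts)
        hit |= ov >= min_overlap
    return hit


def simulate_reads(
    community: Community,
    spec: CommunitySpec,
    seed: int | None = None,
    n_reads: int | None = None,
    transcriptome: bool = False,
    sample_tag: str = "r",
) -> ReadSet:
    """Draw substitution-error short reads from a community.

    Metagenome mode: read start positions are uniform over the community
    (genomes are equal-length, so this is length-weighted), strands uniform,
    and reads never cross a genome boundary. Transcriptome mode re-weights
    marker regions by ``expression_multiplier_marker``: with the
    corresponding probability a read starts inside a marker gene span.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    n = spec.n_reads if n_reads is None else n_reads
    if n < 1:
        raise ValueError("n_reads must be >= 1")
    rl = spec.read_length_nt
    L = community.genome_length_bp
    truth = community.truth

    genome = rng.integers(0, community.n_genomes, n)
    offset = rng.integers(0, L - rl + 1, n)
    starts = genome * L + offset

    if transcriptome and truth.marker_spans.size:
        glen = int(truth.marker_spans[0, 1] - truth.marker_spans[0, 0])
        k = truth.marker_spans.shape[0]
        w_marker = k * glen * spec.expression_multiplier_marker
        p = w_marker / (community.n_genomes * L + k * glen * (spec.expression_multiplier_marker - 1))
        from_marker = rng.random(n) < p
        idx = np.nonzero(from_marker)[0]
        if idx.size:
            span_pick = rng.integers(0, k, idx.size)
            within = rng.integers(0, max(glen - rl, 1), idx.size)
            starts[idx] = truth.marker_spans[span_pick, 0] + within

    strand = rng.integers(0, 2, n)
    matrix = np.empty((n, rl), dtype=np.uint8)
    chunk = 200_000
    offsets = np.arange(rl, dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        matrix[lo:hi] = community.seq[starts[lo:hi, None] + offsets]
    minus = np.nonzero(strand == 1)[0]
    if minus.size:
        matrix[minus] = RC_INT[matrix[minus, ::-1]]

    n_err = rng.binomial(n * rl, spec.substitution_error_rate)
    if n_err:
        pos = rng.integers(0, n * rl, n_err)
        shift = rng.integers(1, 4, n_err).astype(np.uint8)
        flat = matrix.reshape(-1)
        flat[pos] = (flat[pos] + shift) % 4

    origin = np.zeros(n, dtype=np.int8)
    origin[_tag_origin(starts, rl, truth.decoy_spans)] = ReadSet.ORIGIN_DECOY
    origin[_tag_origin(starts, rl, truth.marker_spans)] = ReadSet.ORIGIN_MARKER
    ids = [f"{sample_tag}{i:07d}" for i in range(n)]
    return ReadSet(ids, matrix, origin)


def draw_metabolites(
    presence: np.ndarray,
    effect_size: float,
    rng: np.random.Generator,
    baseline_log_mean: float = np.log(50.0),
    log_sd: float = 1.0,
) -> np.ndarray:
    """Log-normal metabolite levels, shifted down for marker-positive samples.

    ``effect_size`` is the downward location shift in units of the log-scale
    standard deviation. Baseline defaults put the median near 50 (arbitrary
    concentration units) with a one-log-unit spread.
    """
    presence = np.asarray(presence, dtype=bool)
    mu = baseline_log_mean - effect_size * log_sd * presence
    return np.exp(rng.normal(mu, log_sd))


@dataclass
class CohortSample:
    sample_id: str
    community: Community
    metagenome: ReadSet
    transcriptome: ReadSet


@dataclass
class SimulatedCohort:
    samples: list[CohortSample]
    metabolites: pd.DataFrame  # sample_id, gbb
    truth: pd.DataFrame  # sample_id, marker_copies, true_genes_per_genome


def simulate_cohort(
    specs: Sequence[CommunitySpec],
    seed: int = 0,
    n_transcript_reads: int | None = None,
) -> SimulatedCohort:
    """Simulate a cohort of paired metagenome/metatranscriptome samples.

    Each sample gets its own community from its spec (re-seeded from the
    cohort seed), metagenome reads, transcriptome reads (marker regions
    re-weighted by the expression multiplier), and a metabolite level drawn
    lower — by the spec's effect size — when the sample truly carries the
    marker.
    """
    if len(specs) < 2:
        raise ValueError("a cohort needs at least two samples")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs) + 1)
    # one marker gene family per cohort: samples without an explicit marker
    # protein all screen against the same cohort-level marker
    shared_marker = specs[0].marker_protein or SequenceRecord(
        "marker", random_protein(DEFAULT_MARKER_LENGTH_AA, np.random.default_rng(seed + 7)),
        "protein", description="synthetic cohort marker",
    )
    # the near-homolog (decoy) gene family is likewise shared across the
    # cohort: real negative-control neighbors exist in many samples
    shared_decoys = specs[0].decoy_proteins or tuple(
        make_decoy_proteins(specs[0], shared_marker, seed + 13))
    samples: list[CohortSample] = []
    truth_rows = []
    for i, (spec, ss) in enumerate(zip(specs, children[:-1])):
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        spec_i = replace(spec, seed=sub_seed,
                         marker_protein=spec.marker_protein or shared_marker,
                         decoy_proteins=spec.decoy_proteins or shared_decoys)
        community = simulate_community(spec_i)
        meta = simulate_reads(community, spec_i, seed=sub_seed + 1, sample_tag=f"S{i}_m")
        txn = simulate_reads(
            community, spec_i, seed=sub_seed + 2, transcriptome=True,
            n_reads=n_transcript_reads, sample_tag=f"S{i}_t",
        )
        sid = f"S{i:03d}"
        samples.append(CohortSample(sid, community, meta, txn))
        truth_rows.append({
            "sample_id": sid,
            "marker_copies": int(community.truth.marker_copies.sum()),
            "true_genes_per_genome": community.truth.true_genes_per_genome,
        })
    truth = pd.DataFrame(truth_rows)
    rng = np.random.default_rng(children[-1].generate_state(1)[0] % (2**31 - 1))
    presence = truth["marker_copies"].to_numpy() > 0
    gbb = draw_metabolites(presence, specs[0].metabolite_effect_size, rng)
    metabolites = pd.DataFrame({"sample_id": truth["sample_id"], "gbb": gbb})
    return SimulatedCohort(samples, metabolites, truth)
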