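# Methods

## The screening problem

A single marker gene (here called *bbuA*-type: the gene for the
TMA-eliminating γ-butyrobetaine-utilizing enzyme of anaerobic gut bacteria)
is to be detected and quantified in shotgun metagenomes and
metatranscriptomes where the carrying organisms may make up as little as
one cell in a thousand. Naive translated search over-counts, because reads
from related but functionally different genes (e.g. carnitine oxygenase
homologs at 50–70% amino-acid identity) also align to the marker above any
practical identity threshold on short reads. The pipeline therefore screens
reads *competitively* against two databases — the marker proteins and a
negative-control ("decoy") set of near-homologs — and only counts a read
when the marker explains it at least as well as any decoy.

## Pipeline

### 1. Database construction (`markerdb`)

Given marker proteins and a candidate pool of related sequences, the decoy
set is built in three steps: (i) discard pool sequences that are themselves
marker homologs (global identity strictly above the 70% homolog cutoff);
(ii) cluster the remainder at 50% identity and keep one representative per
cluster; (iii) add back every pool sequence in the (50%, 70%] near-homolog
band, since those are the sequences most likely to absorb reads. The decoy
set is the union of (ii) and (iii), deduplicated by exact sequence
(first-kept wins; duplicates are flagged in the manifest). Clustering is
greedy and deterministic: sequences are processed longest-first (ties by
id), joining the first representative at or above the threshold. This
stands in for an external cluster database; it preserves the property that
matters here (every member is within the threshold of its representative)
without reproducing any particular tool's algorithm.

Band membership uses the maximum identity over all markers by default; a
single-reference flag restricts it to one named marker.

### 2. Translated read classification (`sequence_core`, `read_screen`)

Each read is translated in six frames (standard code, stops as `*`,
`N` codons as `X`); stop-free segments of each frame are aligned
Smith–Waterman (affine gaps, BLOSUM62, gap open 11 / extend 1) against
database proteins. Alignments never cross a stop. Percent identity is
computed over alignment columns — gaps count as mismatches — matching the
convention of the standard translated-search tools. E-values use the
Karlin–Altschul form `E = K·m·n·exp(−λS)` with the published gapped
BLOSUM62 constants `K = 0.041`, `λ = 0.267`, `m` the translated segment
length and `n` the residue count of the searched database. Hits are kept
when `E < 1e-4` and identity > 50%.

A read is a **positive marker observation** iff its best marker hit (ranked
by identity, ties by raw score then subject id) has identity > 70% *and* is
at least as good as its best decoy hit (`marker identity >= decoy
identity`; the tie goes to the marker). Each read counts at most once, no
matter how many markers it hits. Metatranscriptome reads are classified
identically; only the interpretation (expression rather than gene presence)
differs downstream. Reads shorter than one seed word are flagged
`too_short` and counted negative rather than raising.

Two consequences of ranking by identity are worth knowing:

* a read that covers a stretch where a decoy is *locally identical* to the
  marker can produce a short 100%-identity marker hit that ties the (long,
  also ~100%) decoy hit, and by the tie rule is counted positive. Such
  reads are genuinely ambiguous — they come from sequence shared verbatim
  by marker and homolog — and the rule counts them for the marker by
  design. With the default synthetic decoys (uniform random substitutions)
  these events are rare (identical runs long enough to pass the E-value
  filter occur a few times per thousand decoy reads at 60% identity);
* the E-value filter, not the identity floor, is what rejects short chance
  hits, and it scales with database size: against a very small database a
  ~12-residue exact submatch can pass `E < 1e-4`.

**Seeded acceleration.** Aligning every read against every protein is
wasteful, so a candidate read must share an exact amino-acid 5-mer with a
database protein before any alignment is attempted (word size
configurable). Bulk screening vectorizes this: reads are translated
frame-wise as integer matrices, 5-mers are packed base-32 into integers and
tested against a dense lookup table of database words; only candidate reads
get the full per-read classification, and only against subjects sharing a
word with the specific translated segment. The seeded path is tested for
agreement with seedless classification and with an independent pure-Python
dynamic-programming oracle. The alignment itself (and a raw-score E-value
rejection before any traceback) keeps per-candidate cost low; a 2-million-
read sample screens in roughly two minutes on one CPU.

### 3. Quantification (`quantify`)

Positive reads convert to abundance via

    RPKM      = (positive reads / total reads) × 10^6 / gene length [kb]
    abundance = RPKM × AGS × 10^-9   [marker genes per microbial genome]

with AGS the sample's average genome size in bp (an upstream input, one
value per sample). The chain is exactly linear in the positive count, and
on a one-genome community with one marker copy it returns exactly 1
gene/genome — the unit check that fixes the interpretation of the RPKM
formula. With several markers the database-level gene length defaults to
the length-weighted mean marker length; per-read best-hit lengths are
deliberately not used, so the estimate stays a simple rescaled count.
Presence defaults to >= 1 positive read (threshold configurable).

*Known bias.* Reads that only partially overlap a gene are still
detectable once ~35 nt of coding overlap remain, so the effective target
is slightly longer than the gene and the estimator overshoots by up to
`read_length / gene_length` (about +8% at 150 nt / 1.2 kb in practice).
The printed equations do not correct for this, so neither does the
implementation; the recovery tests bound the deviation by this ceiling
plus sampling error.

### 4. Cohort statistics (`cohort_stats`)

Prevalence is the fraction of positive samples per group. Metabolite
association compares metabolite levels between gene-positive and
gene-negative samples with a two-sided Mann–Whitney U test: exact null
distribution by complete enumeration of rank splits when `n1+n2 <= 12`
and the data are tie-free (two-sided p = doubled smaller tail, capped at
1), otherwise the normal approximation with tie correction and 0.5
continuity correction. Group medians and means are reported alongside.
Gene/transcript concordance is the 2×2 tally of gene presence versus
transcript presence with the two conditional transcript-positive rates.
Missing values are dropped pairwise, never imputed; strata with fewer than
two usable samples per group are skipped with a warning. No
multiple-testing correction is applied to these comparisons.

## The synthetic-data generator (`synthetic_data`)

The generator's reference condition mirrors the regime the screen must
work in: 5,000 genomes of 50 kb each; a 400-residue marker (1.2 kb gene)
carried, one copy, by each genome independently with probability 10^-3;
five decoy protein variants at 50–65% global identity to the marker
(substitution-only mutants, verified by realignment, ±2 points), carried by
5% of genomes; 2×10^6 reads of 150 nt with 0.5% substitution error,
uniform starts and strands, never crossing genome boundaries. Background
sequence is uniform random sense codons, a deliberately low-homology
background: every positive call is attributable to a planted gene.
Transcriptome samples re-weight marker regions by an expression multiplier
(default 100, "induced" expression), which at sparse metagenome depth
produces the gene-negative/transcript-positive samples seen in real
paired data. Metabolite levels are log-normal (log-scale SD 1, baseline
median 50 in arbitrary concentration units), with marker-positive samples
shifted down by the effect size (default 1) in log-SD units. In cohorts,
the marker and the decoy family are shared across samples — as real
near-homolog families are — so the cohort-level decoy database actually
contains the homologs planted in every sample; per-sample decoy families
would understate decoy coverage and admit avoidable false positives.

What the generator does **not** emulate: realistic taxon abundance
distributions (genomes are equal-length and uniform), platform error
profiles or indels (substitution-only keeps reading frames intact),
paired-end structure, and real protein family architecture (decoys are
random mutants, not structurally constrained homologs; real conserved
domains would produce *more* marker/decoy-identical stretches, i.e. more
ambiguous reads, than uniform mutants do). Passing tests therefore
demonstrate the pipeline's internal correctness and statistical behaviour
under its stated model, not performance on any particular real cohort.

## Numerical and design choices

* Coordinates 0-based half-open internally; 1-based only in report columns.
* Global identity counts terminal gaps in the denominator and is made
  exactly symmetric by canonicalizing the argument order before alignment
  (co-optimal tracebacks can otherwise differ between orders).
* Best-hit ties break by raw score, then lexicographically smallest
  subject id — fully deterministic outputs.
* `mutate_to_identity` substitutes at uniformly random positions and
  adjusts (add/remove substitutions) until measured global identity is
  within ±2 points of the target; it raises after bounded attempts for
  unreachable targets (very low targets on very short proteins).
* All randomness flows from integer seeds through `numpy` generators; the
  same spec and seed reproduce byte-identical FASTQ.
* Problem sizes in the test suite are chosen so the full suite exercises
  the reference condition (five 2-million-read samples) while smaller
  invariant checks run on hundreds of genomes; the analysis scripts use a
  16-sample cohort at 30,000 reads per sample.

## Limitations

* E-values use fixed published constants rather than sequence-composition
  corrections; against very small databases short exact submatches can
  pass the cutoff (see above).
* The screen does not model paired-end reads (mates are independent
  observations) and performs no taxonomic attribution.
* AGS estimation is out of scope; abundance quality is bounded by the
  quality of the supplied AGS values.
* The greedy clustering is order-dependent by construction (longest-first,
  documented); it is not a reproduction of any external cluster database.
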