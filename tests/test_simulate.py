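import numpy as np
import pytest

from markerscreen.align import global_identity
from markerscreen.markerdb import build_negative_control
from markerscreen.screen import classify_read
from markerscreen.seq import SequenceRecord, decode_dna
from markerscreen.simulate import (
    CommunitySpec,
    ReadSet,
    draw_metabolites,
    mutate_to_identity,
    simulate_cohort,
    simulate_community,
    simulate_reads,
)

from .conftest import make_protein

SMALL = dict(n_genomes=50, genome_length_bp=9000, marker_carriage_rate=0.3,
             decoy_carriage_rate=0.2, n_reads=2000, read_length_nt=150)


class TestMutateToIdentity:
    def test_target_100_unchanged(self, rng):
        p = make_protein(rng, 50)
        assert mutate_to_identity(p, 100, seed=1).seq == p.seq

    @pytest.mark.parametrize("target", [40, 60, 80])
    def test_lands_in_band(self, rng, target):
        p = make_protein(rng, 200)
        v = mutate_to_identity(p, target, seed=7)
        assert abs(global_identity(v, p) - target) <= 2.0

    def test_deterministic(self, rng):
        p = make_protein(rng, 120)
        assert mutate_to_identity(p, 55, seed=3).seq == mutate_to_identity(p, 55, seed=3).seq

    def test_unreachable_target_raises(self, rng):
        p = make_protein(rng, 6)
        with pytest.raises(ValueError):
            mutate_to_identity(p, 10, seed=1)


class TestSimulateCommunity:
    def test_zero_carriage_no_markers(self):
        spec = CommunitySpec(**{**SMALL, "marker_carriage_rate": 0.0}, seed=1)
        com = simulate_community(spec)
        assert com.truth.marker_copies.sum() == 0
        assert com.truth.true_genes_per_genome == 0.0
        assert com.truth.marker_spans.size == 0

    def test_full_carriage_one_copy_each(self):
        spec = CommunitySpec(**{**SMALL, "marker_carriage_rate": 1.0}, seed=1)
        com = simulate_community(spec)
        assert com.truth.true_genes_per_genome == 1.0
        assert len(com.truth.marker_spans) == spec.n_genomes

    def test_carriage_matches_seeded_binomial_scale(self):
        spec = CommunitySpec(n_genomes=5000, genome_length_bp=6000,
                             marker_carriage_rate=0.001, decoy_carriage_rate=0.0,
                             n_reads=10, seed=11)
        com = simulate_community(spec)
        planted = int(com.truth.marker_copies.sum())
        # Binomial(5000, 0.001): mean 5, sd ~2.2; seeded draw must be plausible
        assert 0 <= planted <= 15
        assert com.truth.true_genes_per_genome == planted / 5000

    def test_planted_marker_sequence_is_in_genome(self, rng):
        spec = CommunitySpec(**{**SMALL, "marker_carriage_rate": 1.0}, seed=2)
        com = simulate_community(spec)
        lo, hi = com.truth.marker_spans[0]
        nt = decode_dna(com.seq[lo:hi])
        from markerscreen.seq import translate

        assert translate(nt) == com.marker_protein.seq

    def test_decoy_proteins_inside_band(self):
        spec = CommunitySpec(**SMALL, seed=3)
        com = simulate_community(spec)
        lo, hi = spec.decoy_identity_band
        for decoy in com.decoy_proteins:
            ident = global_identity(decoy, com.marker_protein)
            assert lo - 2 <= ident <= hi + 2

    def test_marker_longer_than_genome_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_community(CommunitySpec(
                n_genomes=2, genome_length_bp=600,
                marker_protein=make_protein(rng, 400), n_reads=10, read_length_nt=100))


class TestSimulateReads:
    def test_read_count_and_shape(self):
        spec = CommunitySpec(**SMALL, seed=4)
        reads = simulate_reads(simulate_community(spec), spec)
        assert len(reads) == spec.n_reads
        assert reads.matrix.shape == (2000, 150)

    def test_errorfree_marker_read_classifies_positive(self):
        spec = CommunitySpec(**{**SMALL, "substitution_error_rate": 0.0}, seed=5)
        com = simulate_community(spec)
        reads = simulate_reads(com, spec)
        db, _ = build_negative_control([com.marker_protein], com.decoy_proteins,
                                       band=(50.0, 70.0))
        # a read fully inside a marker gene (>=50 codons of overlap)
        idx = None
        for i in np.nonzero(reads.origin == ReadSet.ORIGIN_MARKER)[0]:
            cls = classify_read(
                SequenceRecord(reads.ids[i], decode_dna(reads.matrix[i]), "dna"), db)
            if cls.best_marker_hit and cls.best_marker_hit.identity_pct == 100.0:
                idx = i
                break
        assert idx is not None
        assert cls.positive

    def test_marker_origin_fraction_matches_length_weighting(self):
        spec = CommunitySpec(n_genomes=100, genome_length_bp=20_000,
                             marker_carriage_rate=0.5, decoy_carriage_rate=0.0,
                             n_reads=50_000, seed=6)
        com = simulate_community(spec)
        reads = simulate_reads(com, spec)
        copies = int(com.truth.marker_copies.sum())
        gene_nt = 3 * len(com.marker_protein.seq)
        # expected fraction of reads overlapping a marker by >=3 nt
        window = gene_nt + spec.read_length_nt - 1 - 4  # start positions, >=3nt overlap
        p = copies * window / (100 * (20_000 - spec.read_length_nt + 1))
        got = int((reads.origin == ReadSet.ORIGIN_MARKER).sum())
        sd = np.sqrt(spec.n_reads * p * (1 - p))
        assert abs(got - spec.n_reads * p) <= 3 * sd

    def test_byte_identical_fastq_under_fixed_seed(self, tmp_path):
        spec = CommunitySpec(**SMALL, seed=7)
        for name in ("a", "b"):
            com = simulate_community(spec)
            simulate_reads(com, spec).to_fastq(tmp_path / f"{name}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()


class TestMetabolitesAndCohort:
    def test_zero_effect_single_distribution(self):
        rng = np.random.default_rng(0)
        presence = np.array([True] * 500 + [False] * 500)
        vals = draw_metabolites(presence, 0.0, rng)
        from markerscreen.stats import mann_whitney_u

        assert mann_whitney_u(vals[:500], vals[500:]).p_two_sided > 0.01

    def test_effect_shifts_positive_group_down(self):
        rng = np.random.default_rng(1)
        presence = np.array([True] * 400 + [False] * 400)
        vals = draw_metabolites(presence, 1.0, rng)
        assert np.median(vals[:400]) < np.median(vals[400:])

    def test_cohort_structure_and_metabolite_association(self):
        specs = [CommunitySpec(n_genomes=30, genome_length_bp=6000,
                               marker_carriage_rate=0.5 if i % 2 else 0.0,
                               decoy_carriage_rate=0.0, n_reads=50,
                               metabolite_effect_size=2.0, seed=0)
                 for i in range(16)]
        cohort = simulate_cohort(specs, seed=9)
        assert len(cohort.samples) == 16
        assert set(cohort.metabolites.columns) == {"sample_id", "gbb"}
        present = cohort.truth["marker_copies"] > 0
        # forced carriage pattern: roughly half the samples are positive
        assert 2 <= present.sum() <= 14

    def test_high_expression_low_depth_gives_gene_neg_transcript_pos(self):
        """Sparse metagenome depth with induced expression yields samples
        that are transcript-positive but gene-negative."""
        spec = CommunitySpec(n_genomes=50, genome_length_bp=50_000,
                             marker_carriage_rate=0.2, decoy_carriage_rate=0.0,
                             n_reads=20, expression_multiplier_marker=100.0,
                             substitution_error_rate=0.0, seed=12)
        com = simulate_community(spec)
        # expected marker reads: metagenome 20 * (10*1200)/(2.5e6) ~ 0.1 << 1
        meta = simulate_reads(com, spec, seed=1)
        txn = simulate_reads(com, spec, seed=2, transcriptome=True, n_reads=100)
        assert (meta.origin == ReadSet.ORIGIN_MARKER).sum() == 0
        # expectation ~0.33 * 100 marker-origin transcript reads; >=5 is ~6 sd below
        assert (txn.origin == ReadSet.ORIGIN_MARKER).sum() >= 5

    def test_cohort_needs_two_samples(self):
        with pytest.raises(ValueError):
            simulate_cohort([CommunitySpec(**SMALL)], seed=1)
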