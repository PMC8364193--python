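import numpy as np
import pandas as pd
import pytest

from markerscreen.markerdb import MarkerDatabase
from markerscreen.screen import (
    SearchParams,
    classify_read,
    detect_cluster_context,
    screen_contigs,
    screen_sample,
)
from markerscreen.seq import SequenceRecord, reverse_complement

from .conftest import cds_of, make_protein, mutate_nt
from .oracles import classify_oracle


def substituted(seq: str, n_sub: int, rng, avoid: set[int] = frozenset()) -> str:
    """Protein with n_sub residues replaced (positions disjoint from avoid)."""
    from markerscreen.seq import PROTEIN_ALPHABET

    positions = [i for i in range(len(seq)) if i not in avoid]
    picked = rng.choice(len(positions), size=n_sub, replace=False)
    out = list(seq)
    for p in picked:
        i = positions[p]
        choices = [c for c in PROTEIN_ALPHABET if c != seq[i]]
        out[i] = choices[int(rng.integers(0, 19))]
    return "".join(out)


_ENDS_40 = {0, 1, 2, 37, 38, 39}  # keep ends intact so local alignment spans all 40 columns


@pytest.fixture
def controlled(rng):
    """A query peptide with marker at 80% and decoy at 75% identity to it."""
    query = make_protein(rng, 40, "query")
    marker = SequenceRecord("marker", substituted(query.seq, 8, rng, avoid=_ENDS_40), "protein")
    decoy = SequenceRecord("decoy", substituted(query.seq, 10, rng, avoid=_ENDS_40), "protein")
    read = SequenceRecord("read", cds_of(query, rng), "dna")
    return query, marker, decoy, read


class TestCompetitiveRule:
    def test_marker_beats_weaker_decoy(self, controlled):
        _, marker, decoy, read = controlled
        db = MarkerDatabase([marker], [decoy])
        cls = classify_read(read, db)
        assert cls.best_marker_hit.identity_pct == pytest.approx(80.0)
        assert cls.best_decoy_hit.identity_pct == pytest.approx(75.0)
        assert cls.positive

    def test_tie_goes_to_marker(self, rng):
        query = make_protein(rng, 40, "query")
        marker = SequenceRecord(
            "marker", substituted(query.seq, 8, rng, avoid=set(range(20)) | _ENDS_40), "protein")
        decoy = SequenceRecord(
            "decoy", substituted(query.seq, 8, rng, avoid=set(range(20, 40)) | _ENDS_40), "protein")
        read = SequenceRecord("read", cds_of(query, rng), "dna")
        cls = classify_read(read, MarkerDatabase([marker], [decoy]))
        assert cls.best_marker_hit.identity_pct == pytest.approx(cls.best_decoy_hit.identity_pct)
        assert cls.positive

    def test_below_identity_cutoff_negative_even_without_decoy(self, rng):
        query = make_protein(rng, 100, "query")
        marker = SequenceRecord("marker", substituted(query.seq, 31, rng), "protein")
        read = SequenceRecord("read", cds_of(query, rng), "dna")
        cls = classify_read(read, MarkerDatabase([marker], []))
        assert cls.best_marker_hit is not None
        assert cls.best_marker_hit.identity_pct == pytest.approx(69.0)
        assert not cls.positive

    def test_stronger_decoy_wins(self, rng):
        query = make_protein(rng, 40, "query")
        marker = SequenceRecord("marker", substituted(query.seq, 10, rng), "protein")
        read = SequenceRecord("read", cds_of(query, rng), "dna")
        decoy = SequenceRecord("decoy", query.seq, "protein")  # exact
        cls = classify_read(read, MarkerDatabase([marker], [decoy]))
        assert not cls.positive

    def test_too_short_read_flagged_not_raised(self, rng, controlled):
        _, marker, decoy, _ = controlled
        db = MarkerDatabase([marker], [decoy])
        cls = classify_read(SequenceRecord("tiny", "ATGGCAGCA", "dna"), db)
        assert cls.flag == "too_short"
        assert not cls.positive


def toy_database(rng):
    markers = [make_protein(rng, 40, f"m{i}") for i in range(3)]
    decoys = []
    for i, m in enumerate(markers):
        n_sub = int(rng.integers(10, 20))  # 50-75% identity to its marker
        decoys.append(SequenceRecord(f"d{i}", substituted(m.seq, n_sub, rng), "protein"))
    decoys.append(make_protein(rng, 35, "d_bg"))
    return MarkerDatabase(markers, decoys)


def toy_reads(db, rng, n_per_source=3, error=0.03):
    reads = []
    sources = db.markers + db.decoys
    for rec in sources:
        cds = cds_of(rec, rng)
        for j in range(n_per_source):
            start = int(rng.integers(0, len(cds) - 60 + 1))
            nt = mutate_nt(cds[start : start + 60], error, rng)
            if rng.random() < 0.5:
                nt = reverse_complement(nt)
            reads.append(SequenceRecord(f"{rec.id}_r{j}", nt, "dna"))
    for j in range(6):
        reads.append(SequenceRecord(
            f"bg_r{j}", "".join("ACGT"[i] for i in rng.integers(0, 4, 60)), "dna"))
    return reads


class TestOracleEquivalence:
    def test_classification_matches_literal_rule(self, rng):
        """Seeded classification agrees with seedless pure-Python rule
        application on randomized 60-nt reads against a toy database."""
        db = toy_database(rng)
        reads = toy_reads(db, rng)
        markers = [m.seq for m in db.markers]
        decoys = [d.seq for d in db.decoys]
        for read in reads:
            got = classify_read(read, db)
            want_pos, want_bm, _ = classify_oracle(read.seq, markers, decoys)
            assert got.positive == want_pos, read.id
            if want_bm is not None and got.best_marker_hit is not None:
                assert got.best_marker_hit.identity_pct == pytest.approx(want_bm)

    def test_seeded_equals_seedless_classification(self, rng):
        db = toy_database(rng)
        reads = toy_reads(db, rng, error=0.02)
        seeded = SearchParams(use_seed=True)
        seedless = SearchParams(use_seed=False)
        for read in reads:
            assert classify_read(read, db, seeded).positive == \
                classify_read(read, db, seedless).positive


class TestScreenSample:
    def test_zero_reads(self, rng, caplog):
        db = toy_database(rng)
        with caplog.at_level("WARNING"):
            res = screen_sample([], db, sample_id="empty")
        assert (res.total_reads, res.positive_reads) == (0, 0)

    def test_verbatim_marker_reads_all_positive(self, rng):
        db = toy_database(rng)
        reads = []
        for m in db.markers:
            cds = cds_of(m, rng)
            for s in range(0, len(cds) - 60, 17):
                reads.append(SequenceRecord(f"{m.id}_{s}", cds[s : s + 60], "dna"))
        res = screen_sample(reads, db)
        assert res.positive_reads == res.total_reads == len(reads)

    def test_decoy_reads_never_positive(self, rng):
        db = toy_database(rng)
        reads = []
        for d in db.decoys:
            cds = cds_of(d, rng)
            for s in range(0, len(cds) - 60, 11):
                reads.append(SequenceRecord(f"{d.id}_{s}", cds[s : s + 60], "dna"))
        res = screen_sample(reads, db)
        assert res.positive_reads == 0

    def test_bulk_path_matches_per_read_classification(self, rng):
        db = toy_database(rng)
        reads = toy_reads(db, rng, error=0.05)
        res = screen_sample(reads, db)
        expected = {r.id for r in reads if classify_read(r, db).positive}
        assert {c.read_id for c in res.positives} == expected

    def test_raising_cutoff_never_increases_positives(self, rng):
        db = toy_database(rng)
        reads = toy_reads(db, rng, error=0.08)
        counts = []
        for cutoff in (60.0, 70.0, 80.0, 90.0):
            params = SearchParams(positive_identity_cutoff_pct=cutoff)
            counts.append(screen_sample(reads, db, params).positive_reads)
        assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_adding_decoys_never_increases_positives(self, rng):
        full = toy_database(rng)
        reads = toy_reads(full, rng, error=0.05)
        bare = MarkerDatabase(full.markers, [])
        partial = MarkerDatabase(full.markers, full.decoys[:1])
        n_bare = screen_sample(reads, bare).positive_reads
        n_partial = screen_sample(reads, partial).positive_reads
        n_full = screen_sample(reads, full).positive_reads
        assert n_bare >= n_partial >= n_full


class TestScreenContigs:
    def build_contig(self, rng, query, lead=300, tail=300):
        cds = cds_of(query, rng)
        bg = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        return bg(lead) + cds + bg(tail), lead, lead + len(cds)

    def test_exact_gene_recovered_with_full_span(self, rng):
        query = make_protein(rng, 60, "q")
        contig_seq, start, end = self.build_contig(rng, query)
        contig = SequenceRecord("c1", contig_seq, "dna")
        hits = [h for h in screen_contigs([contig], [query]) if h.identity_pct > 99]
        assert len(hits) == 1
        assert hits[0].contig_span == (start, end)
        assert hits[0].strand == "+"
        assert not hits[0].at_contig_end

    def test_reverse_strand_gene_recovered(self, rng):
        query = make_protein(rng, 60, "q")
        contig_seq, start, end = self.build_contig(rng, query)
        rc = SequenceRecord("c1rc", reverse_complement(contig_seq), "dna")
        hits = [h for h in screen_contigs([rc], [query]) if h.identity_pct > 99]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        L = len(contig_seq)
        assert hits[0].contig_span == (L - end, L - start)

    def test_random_contig_no_hits(self, rng):
        query = make_protein(rng, 60, "q")
        contig = SequenceRecord(
            "bg", "".join("ACGT"[i] for i in rng.integers(0, 4, 2000)), "dna")
        assert screen_contigs([contig], [query]) == []

    def test_truncated_gene_flagged_at_contig_end(self, rng):
        query = make_protein(rng, 60, "q")
        cds = cds_of(query, rng)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        contig = SequenceRecord("trunc", cds[90:] + bg, "dna")  # starts mid-gene
        hits = screen_contigs([contig], [query])
        assert hits and hits[0].at_contig_end
        assert hits[0].contig_span[0] == 0

    def test_recovers_all_planted_genes(self, rng):
        """>=99% recovery of planted full-length genes at zero mutation."""
        queries = [make_protein(rng, 50, f"q{i}") for i in range(10)]
        contigs = []
        expected = set()
        for i, q in enumerate(queries):
            seq, s, e = self.build_contig(rng, q, lead=200, tail=200)
            contigs.append(SequenceRecord(f"c{i}", seq, "dna"))
            expected.add((f"c{i}", q.id))
        hits = screen_contigs(contigs, queries, min_identity_pct=70.0)
        found = {(h.contig_id, h.query_id) for h in hits if h.identity_pct > 99}
        assert expected <= found


class TestClusterContext:
    def hit(self, contig="c1", span=(5000, 5600)):
        from markerscreen.screen import GenomicHit

        return GenomicHit(contig, "+", 1, span, "q", 100.0, 1e-30, False)

    def annotations(self, rows):
        return pd.DataFrame(rows, columns=["contig_id", "start", "end", "strand", "name"])

    def test_no_neighbors_empty(self):
        ann = self.annotations([])
        assert detect_cluster_context([self.hit()], ann).empty

    def test_neighbors_within_window_sorted_by_offset(self):
        rows = [("c1", 5700 + 900 * i, 6200 + 900 * i, "+", f"g{i}") for i in range(6)]
        report = detect_cluster_context([self.hit()], self.annotations(rows), window_bp=6000)
        assert list(report["neighbor"]) == [f"g{i}" for i in range(6)]
        assert report["offset_bp"].is_monotonic_increasing

    def test_neighbor_beyond_window_excluded(self):
        rows = [("c1", 20_000, 20_500, "+", "far")]
        report = detect_cluster_context([self.hit()], self.annotations(rows), window_bp=10_000)
        assert report.empty

    def test_unknown_contig_rejected(self):
        rows = [("ghost", 100, 200, "+", "g")]
        with pytest.raises(KeyError):
            detect_cluster_context([self.hit()], self.annotations(rows),
                                   known_contigs={"c1"})
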