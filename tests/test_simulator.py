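"""Simulator: variant construction rules, benchmark assembly, read simulation."""

import numpy as np
import pytest

from ectvar.errors import SimulationInfeasibleError
from ectvar.genome import (
    AnnotationIndex,
    GenomicInterval,
    SequenceStore,
    Transcript,
    reverse_complement,
    transcript_sequence,
)
from ectvar.simulate import (
    INDEL_SIZE,
    SPLICE_SIZE,
    ReadSimParams,
    VariantType,
    build_benchmark,
    make_fusion,
    make_splice_variant,
    make_tsv,
    select_eligible_transcripts,
    simulate_reads,
    tx_segments,
)
from ectvar.synth import generate_synthetic_genome


class TestEligibility:
    def test_overlapping_gene_excluded(self):
        iv = lambda s, e: GenomicInterval("c", s, e)
        txs = [
            Transcript("a", "gA", (iv(0, 100), iv(200, 300), iv(400, 500))),
            # gB overlaps gA
            Transcript("b", "gB", (iv(450, 550), iv(600, 700), iv(800, 900))),
            # gC is clean
            Transcript("c", "gC", (iv(2000, 2100), iv(2200, 2300), iv(2400, 2500))),
        ]
        idx = AnnotationIndex(txs)
        assert [t.id for t in select_eligible_transcripts(idx)] == ["c"]

    def test_two_exon_transcript_excluded(self):
        iv = lambda s, e: GenomicInterval("c", s, e)
        txs = [
            Transcript("a", "gA", (iv(0, 100), iv(200, 300))),
            Transcript("b", "gB", (iv(1000, 1100), iv(1200, 1300), iv(1400, 1500))),
        ]
        assert [t.id for t in select_eligible_transcripts(AnnotationIndex(txs))] == ["b"]

    def test_clean_four_exon_genes_all_eligible(self):
        _, idx = generate_synthetic_genome(100, exons_per_gene_range=(4, 4), seed=2)
        assert len(select_eligible_transcripts(idx)) == 100


@pytest.fixture(scope="module")
def sim_genome():
    return generate_synthetic_genome(40, seed=21)


def _two_txs(index):
    elig = select_eligible_transcripts(index)
    return elig[0], elig[1]


class TestFusions:
    def test_canonical_fusion_sequence_oracle(self, sim_genome):
        store, idx = sim_genome
        tx_a, tx_b = _two_txs(idx)
        rng = np.random.default_rng(0)
        t = make_fusion(VariantType.FUSION_CANONICAL, tx_a, tx_b, store, idx, rng)
        a = tx_segments(tx_a)[:2]
        b = tx_segments(tx_b)[-2:]
        expect = "".join(
            store.fetch(x.chrom, x.start, x.end)
            if x.strand == "+"
            else reverse_complement(store.fetch(x.chrom, x.start, x.end))
            for x in a + b
        )
        assert t.variant_sequence == expect
        assert t.genes == (tx_a.gene_id, tx_b.gene_id)

    def test_fusion_insertion_size_range(self, sim_genome):
        store, idx = sim_genome
        tx_a, tx_b = _two_txs(idx)
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = make_fusion(VariantType.FUSION_INSERTION, tx_a, tx_b, store, idx, rng)
            assert INDEL_SIZE[0] <= t.size_bp <= INDEL_SIZE[1]
            wt_len = sum(s.length for s in tx_segments(tx_a)[:2] + tx_segments(tx_b)[-2:])
            assert len(t.variant_sequence) == wt_len + t.size_bp

    def test_same_gene_partner_rejected(self, sim_genome):
        store, idx = sim_genome
        tx_a, _ = _two_txs(idx)
        with pytest.raises(ValueError):
            make_fusion(
                VariantType.FUSION_CANONICAL, tx_a, tx_a, store, idx,
                np.random.default_rng(0),
            )

    def test_unpartnered_fusion_locus_outside_genes(self, sim_genome):
        store, idx = sim_genome
        from ectvar.synth import intergenic_tail

        tx_a, _ = _two_txs(idx)
        tail = intergenic_tail(idx, store, tx_a.chrom)
        t = make_fusion(
            VariantType.FUSION_UNPARTNERED, tx_a, tail, store, idx,
            np.random.default_rng(2),
        )
        assert t.genes == (tx_a.gene_id,)
        for bp in t.breakpoints[1:]:
            assert not idx.genes_overlapping(bp.chrom, bp.start, bp.end)


class TestTSVs:
    def test_deletion_length_arithmetic(self, sim_genome):
        store, idx = sim_genome
        tx = select_eligible_transcripts(idx)[3]
        t = make_tsv(VariantType.DEL, tx, store, np.random.default_rng(3))
        assert len(t.variant_sequence) == tx.length - t.size_bp

    def test_itd_duplicates_segment_adjacently(self, sim_genome):
        store, idx = sim_genome
        tx = select_eligible_transcripts(idx)[4]
        t = make_tsv(VariantType.ITD, tx, store, np.random.default_rng(4))
        dup = t.breakpoints[0]
        dup_seq = store.fetch_interval(dup)
        assert (dup_seq + dup_seq) in t.variant_sequence
        assert len(t.variant_sequence) == tx.length + t.size_bp

    def test_ptd_sequence_oracle(self, sim_genome):
        store, idx = sim_genome
        tx = select_eligible_transcripts(idx)[5]
        t = make_tsv(VariantType.PTD, tx, store, np.random.default_rng(5))
        exons = [store.fetch_interval(GenomicInterval(b.chrom, b.start, b.end, b.strand))
                 for b in tx_segments(tx)]
        wt = transcript_sequence(tx, store)
        # the duplicated run is recorded in the breakpoints: rebuild manually
        run = [store.fetch_interval(bp) for bp in t.breakpoints]
        joined = "".join(run)
        start = wt.find(joined)
        assert start >= 0
        expect = wt[: start + len(joined)] + joined + wt[start + len(joined):]
        assert t.variant_sequence == expect

    def test_inversion_reverse_complements_run(self, sim_genome):
        store, idx = sim_genome
        tx = select_eligible_transcripts(idx)[6]
        t = make_tsv(VariantType.INV, tx, store, np.random.default_rng(6))
        wt = transcript_sequence(tx, store)
        assert len(t.variant_sequence) == len(wt)
        assert t.variant_sequence != wt
        inverted = reverse_complement(
            "".join(store.fetch_interval(bp) for bp in t.breakpoints)
        )
        assert inverted in t.variant_sequence


class TestSpliceVariants:
    def _toy_with_intron(self, i1_len):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        store = SequenceStore({"c": seq})
        e1 = GenomicInterval("c", 0, 100)
        e2 = GenomicInterval("c", 100 + i1_len, 200 + i1_len)
        tx = Transcript("t", "g", (e1, e2))
        return store, AnnotationIndex([tx]), tx

    def test_retained_intron_length_boundary(self):
        store, idx, tx = self._toy_with_intron(31)
        t = make_splice_variant(VariantType.RI, tx, idx, store, np.random.default_rng(0))
        assert t.size_bp == 31
        store, idx, tx = self._toy_with_intron(30)
        with pytest.raises(SimulationInfeasibleError):
            make_splice_variant(VariantType.RI, tx, idx, store, np.random.default_rng(0))

    def test_novel_exon_block_overlaps_no_reference_exon(self, sim_genome):
        store, idx = sim_genome
        for i in range(8, 14):
            tx = select_eligible_transcripts(idx)[i]
            t = make_splice_variant(VariantType.NE, tx, idx, store, np.random.default_rng(i))
            block = t.breakpoints[0]
            assert idx.exons_overlapping(block.chrom, block.start, block.end) == []

    def test_nj_resamples_annotated_junctions(self):
        # a 3-exon transcript whose only skippable pair is already joined by
        # an annotated junction of a second isoform -> infeasible
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        store = SequenceStore({"c": seq})
        iv = lambda s, e: GenomicInterval("c", s, e)
        tx = Transcript("t1", "g", (iv(0, 100), iv(500, 600), iv(1000, 1100)))
        iso = Transcript("t2", "g", (iv(0, 100), iv(1000, 1100)))
        idx = AnnotationIndex([tx, iso])
        with pytest.raises(SimulationInfeasibleError):
            make_splice_variant(VariantType.NJ, tx, idx, store, np.random.default_rng(0))

    def test_skipped_exon_drops_intervening_exons(self, sim_genome):
        store, idx = sim_genome
        tx = select_eligible_transcripts(idx)[15]
        t = make_splice_variant(VariantType.NJ, tx, idx, store, np.random.default_rng(1))
        assert len(t.variant_sequence) < tx.length
        # sequence is a concatenation of a prefix and suffix of the wild type
        wt = transcript_sequence(tx, store)
        assert t.variant_sequence[:50] == wt[:50]
        assert t.variant_sequence[-50:] == wt[-50:]


class TestSizeRangeConservation:
    def test_sizes_within_vocabulary_over_many_draws(self, sim_genome):
        store, idx = sim_genome
        elig = select_eligible_transcripts(idx)
        rng = np.random.default_rng(77)
        checked = 0
        for rep in range(170):
            tx = elig[int(rng.integers(0, len(elig)))]
            for vt in (VariantType.INS, VariantType.DEL, VariantType.ITD):
                t = make_tsv(vt, tx, store, rng)
                assert INDEL_SIZE[0] <= t.size_bp <= INDEL_SIZE[1]
                checked += 1
            for vt in (VariantType.EE, VariantType.NE):
                t = make_splice_variant(vt, tx, idx, store, rng)
                assert SPLICE_SIZE[0] <= t.size_bp <= SPLICE_SIZE[1]
                checked += 1
            t = make_splice_variant(VariantType.TRUNC, tx, idx, store, rng)
            assert 2 * SPLICE_SIZE[0] <= t.size_bp <= 2 * SPLICE_SIZE[1]
            for bp in t.breakpoints:
                assert SPLICE_SIZE[0] <= bp.length <= SPLICE_SIZE[1]
            checked += 1
        assert checked >= 1000


class TestBenchmark:
    def test_one_per_type_gives_fifteen_truths(self, sim_genome):
        store, idx = sim_genome
        sample = build_benchmark(idx, store, 1, 5, seed=0)
        assert len(sample.truth) == 15
        assert len({t.vtype for t in sample.truth}) == 15
        # 2 sequences per variant (variant + wild type) plus background
        assert len(sample.case_reference) == 2 * 15 + 5

    def test_heterozygous_design(self, sim_genome):
        store, idx = sim_genome
        sample = build_benchmark(idx, store, 1, 5, seed=1)
        case_ids = [sid for sid, _ in sample.case_reference]
        for t in sample.truth:
            assert case_ids.count(t.variant_id) == 1
            assert case_ids.count(t.source_transcripts[0]) == 1

    def test_control_purity(self, sim_genome):
        store, idx = sim_genome
        sample = build_benchmark(idx, store, 1, 5, seed=2)
        control_seqs = [s for _, s in sample.control_reference]
        for t in sample.truth:
            assert all(t.variant_sequence not in s for s in control_seqs)

    def test_background_identical_in_both_references(self, sim_genome):
        store, idx = sim_genome
        sample = build_benchmark(idx, store, 1, 8, seed=3)
        case = dict(sample.case_reference)
        control = dict(sample.control_reference)
        assert len(sample.background_ids) == 8
        for bid in sample.background_ids:
            assert case[bid] == control[bid]

    def test_insufficient_genes_reports_shortfall(self, sim_genome):
        store, idx = sim_genome
        with pytest.raises(SimulationInfeasibleError, match="shortfall"):
            build_benchmark(idx, store, 10, 100, seed=0)


class TestReadSimulation:
    def test_pair_count_matches_coverage_arithmetic(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        n = simulate_reads(
            [("s", seq)],
            ReadSimParams(coverage=50, error_rate=0, seed=0),
            str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"),
        )
        assert abs(n - 750) <= 1

    def test_error_free_reads_are_exact_substrings(self, tmp_path):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        simulate_reads(
            [("s", seq)],
            ReadSimParams(coverage=5, error_rate=0, seed=1),
            str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"),
        )
        import pysam

        with pysam.FastxFile(str(tmp_path / "r1.fq")) as fh:
            for rec in fh:
                assert rec.sequence in seq
        with pysam.FastxFile(str(tmp_path / "r2.fq")) as fh:
            for rec in fh:
                assert reverse_complement(rec.sequence) in seq

    def test_deterministic_fastq_bytes(self, tmp_path):
        rng = np.random.default_rng(3)
        ref = [("s", "".join("ACGT"[i] for i in rng.integers(0, 4, 2000)))]
        outs = []
        for run in (1, 2):
            p1, p2 = tmp_path / f"a{run}.fq", tmp_path / f"b{run}.fq"
            simulate_reads(ref, ReadSimParams(coverage=10, seed=9), str(p1), str(p2))
            outs.append(p1.read_bytes() + p2.read_bytes())
        assert outs[0] == outs[1]

    def test_short_sequence_skipped_with_warning(self, tmp_path):
        with pytest.warns(UserWarning, match="shorter than fragment"):
            n = simulate_reads(
                [("short", "ACGT" * 20)],
                ReadSimParams(coverage=50, seed=0),
                str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"),
            )
        assert n == 0
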