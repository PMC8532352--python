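"""Annotation: CIGAR walking, candidate detection, classification, VAF."""

import numpy as np
import pytest

from ectvar.annotate import (
    AlignmentRecord,
    AnnotationParams,
    VariantClass,
    check_motif,
    detect_raw_variants,
    estimate_vaf,
    filter_alignments,
    load_alignments,
    refine_and_classify,
    write_results,
    VariantCall,
)
from ectvar.genome import GenomicInterval, SequenceStore
from ectvar.quant import ECCountTable, build_index_from_records, match_ecs

NO_MOTIF = AnnotationParams(motif_check=False)


def _sam(tmp_path, rows, lengths={"chrT": 5000, "chrU": 5000}):
    path = tmp_path / "t.sam"
    header = "".join(f"@SQ\tSN:{c}\tLN:{l}\n" for c, l in lengths.items())
    body = ""
    for name, flag, chrom, pos1, cigar in rows:
        body += f"{name}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
    path.write_text(header + body)
    return str(path)


class TestLoadAlignments:
    def test_simple_match_converts_to_zero_based(self, tmp_path):
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 1, "100M")]))
        r = recs["c1"][0]
        assert r.pos == 0
        assert r.match_intervals() == [(0, 100)]

    def test_spliced_cigar_yields_two_blocks(self, tmp_path):
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 1, "50M1000N50M")]))
        r = recs["c1"][0]
        assert r.match_intervals() == [(0, 50), (1050, 1100)]

    def test_supplementary_grouped_across_chromosomes(self, tmp_path):
        recs = load_alignments(
            _sam(
                tmp_path,
                [("c1", 0, "chrT", 1, "60M40S"), ("c1", 2048, "chrU", 11, "60S40M")],
            )
        )
        assert len(recs["c1"]) == 2
        assert {r.chrom for r in recs["c1"]} == {"chrT", "chrU"}

    def test_cigar_contig_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="CIGAR length"):
            AlignmentRecord("c", "chrT", "+", 0, [("M", 50)], False, contig_length=60)

    def test_reverse_record_query_span_flipped(self):
        r = AlignmentRecord(
            "c", "chrT", "-", 0, [("S", 30), ("M", 60), ("S", 10)], False, 100
        )
        assert r.query_span == (10, 70)


class TestFilterAlignments:
    def test_fraction_boundary(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # 59 of 200 bp aligned (29.5%) over an exon -> discarded
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 101, "59M141S")]))
        assert not filter_alignments(recs["c1"], idx)

    def test_intergenic_alignment_discarded(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 3501, "100M")]))
        assert not filter_alignments(recs["c1"], idx)

    def test_both_thresholds_met_over_exon(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 101, "40M60S")]))
        assert filter_alignments(recs["c1"], idx)


class TestDetectRawVariants:
    def test_deletion_candidate_from_gap(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # inside geneA exon2 [500, 650)
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 501, "40M10D40M")]))
        cands = detect_raw_variants(recs["c1"], idx, NO_MOTIF)
        dels = [c for c in cands if c.kind == "del"]
        assert len(dels) == 1 and dels[0].size == 10
        assert (dels[0].start, dels[0].end) == (540, 550)

    def test_small_gap_below_threshold_ignored(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 501, "40M6D40M")]))
        assert [c for c in detect_raw_variants(recs["c1"], idx, NO_MOTIF) if c.kind == "del"] == []

    def test_clip_threshold_boundary(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 101, "80M20S")]))
        assert [c.kind for c in detect_raw_variants(recs["c1"], idx, NO_MOTIF)] == ["clip"]
        recs = load_alignments(_sam(tmp_path, [("c2", 0, "chrT", 101, "80M19S")]))
        assert detect_raw_variants(recs["c2"], idx, NO_MOTIF) == []

    def test_annotated_junction_produces_no_candidate(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # geneA junction (200, 500) is annotated
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 101, "100M300N150M")]))
        assert detect_raw_variants(recs["c1"], idx, NO_MOTIF) == []

    def test_novel_junction_candidate(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # junction (200, 1000) skips exon 2: novel
        recs = load_alignments(_sam(tmp_path, [("c1", 0, "chrT", 101, "100M800N100M")]))
        cands = detect_raw_variants(recs["c1"], idx, NO_MOTIF)
        assert [c.kind for c in cands] == ["junction"]
        assert cands[0].junction == (200, 1000)

    def test_raising_thresholds_never_adds_candidates(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        rows = [
            ("c1", 0, "chrT", 501, "40M10D30M8I40M22S"),
            ("c2", 0, "chrT", 101, "100M800N100M"),
        ]
        recs = load_alignments(_sam(tmp_path, rows))
        counts = []
        for gap_min, clip_min in [(7, 20), (9, 25), (11, 40), (60, 80)]:
            p = AnnotationParams(gap_min=gap_min, clip_min=clip_min, motif_check=False)
            n = sum(len(detect_raw_variants(r, idx, p)) for r in recs.values())
            counts.append(n)
        assert counts == sorted(counts, reverse=True)


class TestCheckMotif:
    @pytest.fixture()
    def motif_store(self):
        seq = list("A" * 100)
        # intron [10, 50): GT..AG ; intron [60, 90): GA..AG
        seq[10:12] = "GT"; seq[48:50] = "AG"
        seq[60:62] = "GA"; seq[88:90] = "AG"
        return SequenceStore({"m": "".join(seq)})

    def test_canonical_valid_at_zero_tolerance(self, motif_store):
        assert check_motif(("m", 10, 50), motif_store, tolerance=0)

    def test_invalid_dinucleotides(self, motif_store):
        assert not check_motif(("m", 20, 40), motif_store, tolerance=0)  # AA..AA

    def test_one_mismatch_allowed_with_tolerance(self, motif_store):
        assert not check_motif(("m", 60, 90), motif_store, tolerance=0)
        assert check_motif(("m", 60, 90), motif_store, tolerance=1)

    def test_minus_strand_motif_accepted(self):
        seq = list("A" * 60)
        seq[10:12] = "CT"; seq[38:40] = "AC"  # GT..AG after reverse complement
        store = SequenceStore({"m": "".join(seq)})
        assert check_motif(("m", 10, 40), store, tolerance=0)


class TestRefineAndClassify:
    def _classify(self, tmp_path, idx, rows, params=NO_MOTIF, store=None):
        recs = load_alignments(_sam(tmp_path, rows))
        calls = []
        for cid, rlist in recs.items():
            cands = detect_raw_variants(rlist, idx, params)
            calls.extend(refine_and_classify(cid, rlist, cands, idx, store, params))
        return calls

    def test_extended_exon_needs_novel_junction(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # exon2 extended by 60 bp, then a novel junction to exon3
        calls = self._classify(
            tmp_path, idx, [("c1", 0, "chrT", 101, "100M300N210M290N100M")]
        )
        assert [c.vclass for c in calls] == [VariantClass.NOVEL_EXTENDED_EXON]
        assert calls[0].loci[0] == GenomicInterval("chrT", 650, 710)
        # same block without any junction: no call
        calls = self._classify(tmp_path, idx, [("c2", 0, "chrT", 501, "210M")])
        assert calls == []

    def test_retained_intron_between_flanking_exons(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # contiguous alignment across exon2-intron-exon3
        calls = self._classify(tmp_path, idx, [("c1", 0, "chrT", 501, "600M")])
        assert [c.vclass for c in calls] == [VariantClass.RETAINED_INTRON]
        # the A.1 intron is [650, 1000) but [900, 1000) is exonic in A.2,
        # so the unannotated retained block is [650, 900)
        assert calls[0].size_bp == 250
        assert calls[0].loci[0] == GenomicInterval("chrT", 650, 900)

    def test_exon_skip_is_novel_exon_junction(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        calls = self._classify(tmp_path, idx, [("c1", 0, "chrT", 101, "100M800N100M")])
        assert [c.vclass for c in calls] == [VariantClass.NOVEL_EXON_JUNCTION]
        assert calls[0].junction == (200, 1000)

    def test_truncated_exon_is_novel_exon_junction(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # junction leaves exon2 40 bp early (donor at 610 inside [500,650))
        # and enters A.2's exon [900,1100) 100 bp late: truncation size is
        # the larger of the two ends
        calls = self._classify(tmp_path, idx, [("c1", 0, "chrT", 501, "110M390N100M")])
        assert [c.vclass for c in calls] == [VariantClass.NOVEL_EXON_JUNCTION]
        assert calls[0].size_bp == 100

    def test_fusion_gene_plus_intergenic(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        calls = self._classify(
            tmp_path, idx,
            [("c1", 0, "chrT", 101, "100M100S"),
             ("c1", 2048, "chrT", 3501, "100S100M")],
        )
        assert [c.vclass for c in calls] == [VariantClass.FUSION]
        assert calls[0].genes == ("geneA", "intergenic")

    def test_fusion_two_genes(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        calls = self._classify(
            tmp_path, idx,
            [("c1", 0, "chrT", 101, "100M100S"),
             ("c1", 2048, "chrT", 2001, "100S100M")],
        )
        assert [c.vclass for c in calls] == [VariantClass.FUSION]
        assert calls[0].genes == ("geneA", "geneB")

    def test_strand_discordant_records_are_rearrangement(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        calls = self._classify(
            tmp_path, idx,
            [("c1", 0, "chrT", 101, "100M100S"),
             ("c1", 2064, "chrT", 501, "100M100S")],
        )
        assert [c.vclass for c in calls] == [VariantClass.INTRAGENIC_REARRANGEMENT]

    def test_reference_identical_contig_yields_no_calls(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        # exact A.1 structure: all junctions annotated, no indels or clips
        calls = self._classify(
            tmp_path, idx, [("c1", 0, "chrT", 101, "100M300N150M350N100M")]
        )
        assert calls == []

    def test_insertion_passes_through(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        calls = self._classify(tmp_path, idx, [("c1", 0, "chrT", 501, "40M12I40M")])
        assert [c.vclass for c in calls] == [VariantClass.INSERTION]
        assert calls[0].size_bp == 12

    def test_unexplained_clip_is_unknown(self, tmp_path, toy_annotation):
        _, idx = toy_annotation
        calls = self._classify(tmp_path, idx, [("c1", 0, "chrT", 101, "100M60S")])
        assert [c.vclass for c in calls] == [VariantClass.UNKNOWN]

    def test_motif_gating_of_novel_exons(self, tmp_path, toy_annotation):
        store, idx = toy_annotation
        # force invalid motifs at the novel junction (AAs on both ends)
        chrom = list(store["chrT"])
        chrom[710:712] = "AA"; chrom[998:1000] = "AA"
        bad = SequenceStore({"chrT": "".join(chrom)})
        rows = [("c1", 0, "chrT", 101, "100M300N210M290N100M")]
        strict = AnnotationParams(motif_check=True, motif_tolerance=0)
        assert self._classify(tmp_path, idx, rows, strict, bad) == []
        relaxed = NO_MOTIF
        assert len(self._classify(tmp_path, idx, rows, relaxed, bad)) == 1


class TestVAF:
    def _setup(self):
        rng = np.random.default_rng(0)
        mk = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        kidx = build_index_from_records(
            [("contig1", mk(80))], [("A.1", mk(80)), ("A.2", mk(80))], 31
        )
        return kidx

    def _matrix(self, rows):
        counts = {ec: c for ec, c in rows.items() if c > 0}
        t = ECCountTable("case", counts, n_assigned=sum(counts.values()))
        return match_ecs([t], "case")

    def _call(self):
        return VariantCall(
            "contig1", VariantClass.DELETION, ("geneA",),
            (GenomicInterval("chrT", 500, 510),),
        )

    def test_balanced_counts_give_half(self, toy_annotation):
        _, idx = toy_annotation
        kidx = self._setup()
        m = self._matrix({("contig1",): 50, ("A.1",): 50})
        assert estimate_vaf(self._call(), m, idx, kidx) == pytest.approx(0.5)

    def test_no_wildtype_evidence_gives_one(self, toy_annotation):
        _, idx = toy_annotation
        kidx = self._setup()
        m = self._matrix({("contig1",): 30, ("A.1", "contig1"): 100})
        assert estimate_vaf(self._call(), m, idx, kidx) == pytest.approx(1.0)

    def test_missing_when_no_informative_counts(self, toy_annotation):
        _, idx = toy_annotation
        kidx = self._setup()
        m = self._matrix({("A.1", "contig1"): 100})
        assert estimate_vaf(self._call(), m, idx, kidx) is None

    def test_heterozygous_simulation_indel_vaf_near_half(self, mini_benchmark):
        vafs = [
            c.vaf
            for c in mini_benchmark.pipeline.calls
            if c.vaf is not None
            and (c.contig_id.startswith("ins_") or c.contig_id.startswith("del_"))
        ]
        assert len(vafs) >= 4
        assert 0.35 <= float(np.median(vafs)) <= 0.65


class TestWriteResults:
    def test_empty_call_list_writes_header_only(self, tmp_path):
        path = tmp_path / "v.tsv"
        write_results([], str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("contig_id")

    def test_duplicate_calls_deduplicated(self, tmp_path):
        call = VariantCall(
            "c1", VariantClass.DELETION, ("geneA",),
            (GenomicInterval("chrT", 10, 20),), size_bp=10,
        )
        df = write_results([call, call], str(tmp_path / "v.tsv"))
        assert len(df) == 1
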