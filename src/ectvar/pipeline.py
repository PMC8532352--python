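"""Pipeline orchestration: quantify -> match -> novel-EC filter -> DE ->
annotate, plus the simulated-benchmark driver and ground-truth ("perfect")
contig/alignment generation.

The pipeline consumes one case sample and N >= 0 controls. Contigs come
from an external assembler (or from the simulator's truth records), spliced
genome alignments come from an external aligner (or are derived from truth
breakpoints). With zero controls the DE test is skipped and novel ECs are
selected on the case CPM filter alone.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import pysam

from .annotate import AnnotationParams, VariantCall, annotate_contigs, write_results
from .diffexp import (
    DEParams,
    DEResult,
    de_results_table,
    filter_low_expression,
    run_de,
    select_significant_contigs,
)
from .errors import ConfigurationError
from .evaluate import EvaluationReport, evaluate
from .genome import (
    AnnotationIndex,
    SequenceStore,
    read_fasta_records,
    read_gtf,
    reverse_complement,
    write_gtf,
    write_records_fasta,
    write_transcriptome_fasta,
)
from .quant import (
    DEFAULT_K,
    ECCountTable,
    build_index_from_records,
    count_ecs,
    filter_novel_ecs,
    match_ecs,
)
from .simulate import (
    InsSeq,
    ReadSimParams,
    RefBlock,
    SimulatedSample,
    VariantTruth,
    build_benchmark,
    genes_required,
    simulate_reads,
    write_truth_tsv,
)
from .synth import generate_synthetic_genome

logger = logging.getLogger("ectvar")

# gaps longer than this break an alignment chain into separate records
CHAIN_GAP_MAX = 200_000
# genomic gaps up to this size, contained within one exon, align as deletions
DELETION_GAP_MAX = 50


@dataclass
class PipelineConfig:
    """Run configuration; all defaults are the pipeline's defaults."""

    k: int = DEFAULT_K
    min_contig_len: int = 150
    dispersion: float = 0.1
    cpm_min: float = 0.1
    fdr_max: float = 0.05
    logfc_min: float = 2.0
    prior_count: float = 0.5
    gap_min: int = 7
    clip_min: int = 20
    block_min: int = 20
    min_aligned_bp: int = 30
    min_aligned_frac: float = 0.3
    motif_check: bool = True
    motif_tolerance: int = 1
    seed: int = 0

    def de_params(self) -> DEParams:
        return DEParams(
            dispersion=self.dispersion,
            cpm_min=self.cpm_min,
            fdr_max=self.fdr_max,
            logfc_min=self.logfc_min,
            prior_count=self.prior_count,
        )

    def annotation_params(self) -> AnnotationParams:
        return AnnotationParams(
            gap_min=self.gap_min,
            clip_min=self.clip_min,
            block_min=self.block_min,
            min_aligned_bp=self.min_aligned_bp,
            min_aligned_frac=self.min_aligned_frac,
            motif_check=self.motif_check,
            motif_tolerance=self.motif_tolerance,
        )

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        kwargs: Dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ConfigurationError(f"unknown config key {key!r}")
                cur = getattr(defaults, key)
                if isinstance(cur, bool):
                    kwargs[key] = val.strip().lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = type(cur)(val.strip())
        return cls(**kwargs)


@dataclass
class PipelineResult:
    calls: List[VariantCall]
    de_results: Optional[List[DEResult]]
    retained_contigs: Set[str]
    summary: Dict[str, int]
    variants_path: Optional[str] = None
    de_path: Optional[str] = None


def run_pipeline(
    case_fastqs: Sequence[str],
    control_fastqs_list: Sequence[Sequence[str]],
    contigs: Union[str, Sequence[Tuple[str, str]]],
    ref_tx: Union[str, Sequence[Tuple[str, str]]],
    genome: Union[str, SequenceStore, None],
    gtf: Union[str, AnnotationIndex],
    sam_path: str,
    config: PipelineConfig = PipelineConfig(),
    outdir: Optional[str] = None,
) -> PipelineResult:
    """Run quantification, differential expression and annotation.

    ``contigs``/``ref_tx`` may be FASTA paths or in-memory (id, seq)
    records; ``genome``/``gtf`` may be paths or already-loaded objects.
    Writes ``variants.tsv`` and ``de.tsv`` into ``outdir`` when given.
    """
    index = gtf if isinstance(gtf, AnnotationIndex) else read_gtf(gtf)
    if genome is None:
        store: Optional[SequenceStore] = None
    elif isinstance(genome, SequenceStore):
        store = genome
    else:
        store = SequenceStore.from_fasta(genome)
    if store is None and config.motif_check:
        raise ConfigurationError("motif checking requires a genome sequence")

    contig_records = (
        read_fasta_records(contigs) if isinstance(contigs, str) else list(contigs)
    )
    n_contigs_in = len(contig_records)
    contig_records = [
        (cid, seq) for cid, seq in contig_records if len(seq) >= config.min_contig_len
    ]
    ref_records = read_fasta_records(ref_tx) if isinstance(ref_tx, str) else list(ref_tx)

    kidx = build_index_from_records(contig_records, ref_records, config.k)
    logger.info("indexed %d contigs + %d reference transcripts (%d k-mers)",
                len(contig_records), len(ref_records), kidx.n_kmers)

    tables: List[ECCountTable] = [count_ecs(case_fastqs, kidx, "case")]
    for i, fq in enumerate(control_fastqs_list):
        tables.append(count_ecs(fq, kidx, f"control{i + 1}"))
    for t in tables:
        logger.info("sample %s: %d assigned / %d unassigned read ends",
                    t.sample_id, t.n_assigned, t.n_unassigned)

    matched = match_ecs(tables, "case")
    novel = filter_novel_ecs(matched, kidx)
    de_params = config.de_params()
    filtered = filter_low_expression(novel, de_params)
    logger.info("ECs: %d matched, %d novel, %d past CPM filter",
                matched.n_ecs, novel.n_ecs, filtered.n_ecs)

    controls_present = len(control_fastqs_list) > 0
    de_results: Optional[List[DEResult]] = None
    if controls_present:
        de_results = run_de(filtered, de_params)
        retained = select_significant_contigs(de_results, filtered, de_params, True)
        n_significant = sum(r.significant for r in de_results)
    else:
        retained = select_significant_contigs(None, novel, de_params, False)
        n_significant = len(filtered.ec_list)
    contig_ids = {cid for cid, _ in contig_records}
    retained &= contig_ids
    logger.info("%d significant ECs -> %d retained contigs", n_significant, len(retained))

    de_stats: Dict[str, Tuple[float, float, float]] = {}
    if de_results is not None:
        for r in de_results:
            if not r.significant:
                continue
            for member in r.ec:
                prev = de_stats.get(member)
                if prev is None or r.case_cpm > prev[2]:
                    de_stats[member] = (r.logfc, r.fdr, r.case_cpm)

    calls = annotate_contigs(
        sam_path,
        index,
        store,
        retained,
        config.annotation_params(),
        matrix=matched,
        kmer_index=kidx,
        de_stats=de_stats,
    )
    summary = {
        "n_contigs_in": n_contigs_in,
        "n_contigs_after_length_filter": len(contig_records),
        "n_ecs_matched": matched.n_ecs,
        "n_ecs_novel": novel.n_ecs,
        "n_ecs_cpm_pass": filtered.n_ecs,
        "n_ecs_significant": n_significant,
        "n_retained_contigs": len(retained),
        "n_calls": len(calls),
    }
    logger.info("pipeline summary: %s", summary)

    variants_path = de_path = None
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        variants_path = os.path.join(outdir, "variants.tsv")
        write_results(calls, variants_path)
        if de_results is not None:
            de_path = os.path.join(outdir, "de.tsv")
            de_results_table(de_results).to_csv(de_path, sep="\t", index=False)
    return PipelineResult(
        calls=calls,
        de_results=de_results,
        retained_contigs=retained,
        summary=summary,
        variants_path=variants_path,
        de_path=de_path,
    )


# -- ground-truth contigs and alignments -----------------------------------


def perfect_contigs(truth: Sequence[VariantTruth]) -> List[Tuple[str, str]]:
    """One contig per variant: the exact variant transcript sequence."""
    return [(t.variant_id, t.variant_sequence) for t in truth]


def _close_run(run: List[Tuple[object, int, int]]) -> List[Tuple[object, int, int]]:
    while run and isinstance(run[-1][0], InsSeq):
        run.pop()
    return run


def _segment_runs(truth: VariantTruth) -> List[List[Tuple[object, int, int]]]:
    """Split segments into maximal collinear runs with query offsets."""
    runs: List[List[Tuple[object, int, int]]] = []
    cur: List[Tuple[object, int, int]] = []
    qpos = 0
    last_block: Optional[RefBlock] = None
    for seg in truth.segments:
        qs, qe = qpos, qpos + seg.length
        qpos = qe
        if isinstance(seg, InsSeq):
            if cur:
                cur.append((seg, qs, qe))
            continue
        ok = False
        if last_block is not None and cur:
            if seg.chrom == last_block.chrom and seg.strand == last_block.strand:
                if seg.strand == "+":
                    gap = seg.start - last_block.end
                else:
                    gap = last_block.start - seg.end
                ok = 0 <= gap <= CHAIN_GAP_MAX
        if ok:
            cur.append((seg, qs, qe))
        else:
            if cur:
                runs.append(_close_run(cur))
            cur = [(seg, qs, qe)]
        last_block = seg
    if cur:
        runs.append(_close_run(cur))
    return [r for r in runs if r]


def _gap_op(index: AnnotationIndex, chrom: str, start: int, end: int) -> int:
    """2 (D) for small intra-exon gaps, 3 (N) for everything else."""
    gap = end - start
    if gap <= DELETION_GAP_MAX:
        for a, b, _ in index.exons_overlapping(chrom, start, end):
            if a <= start and end <= b:
                return 2
    return 3


def write_truth_sam(
    truth: Sequence[VariantTruth],
    store: SequenceStore,
    index: AnnotationIndex,
    path: str,
) -> None:
    """Ground-truth spliced alignments of the variant contigs.

    Each maximal collinear segment run becomes one SAM record (the longest
    run is primary, the rest supplementary); within a run, genomic gaps
    become D or N and non-templated inserts become I. Inserts at run
    boundaries stay soft-clipped, as a spliced aligner would leave them.
    """
    chroms = sorted(store.names())
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": store.length(c)} for c in chroms],
    }
    chrom_id = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for t in sorted(truth, key=lambda x: x.variant_id):
            runs = _segment_runs(t)
            if not runs:
                continue
            L = len(t.variant_sequence)
            order = sorted(
                range(len(runs)),
                key=lambda i: -sum(
                    s.length for s, _, _ in runs[i] if isinstance(s, RefBlock)
                ),
            )
            for rank, ri in enumerate(order):
                run = runs[ri]
                strand = next(
                    s.strand for s, _, _ in run if isinstance(s, RefBlock)
                )
                qs, qe = run[0][1], run[-1][2]
                items = run if strand == "+" else list(reversed(run))
                cig: List[Tuple[int, int]] = []
                prev: Optional[RefBlock] = None
                for seg, _, _ in items:
                    if isinstance(seg, InsSeq):
                        cig.append((1, seg.length))
                        continue
                    if prev is not None:
                        gap = seg.start - prev.end
                        if gap > 0:
                            cig.append((_gap_op(index, seg.chrom, prev.end, seg.start), gap))
                    cig.append((0, seg.length))
                    prev = seg
                if strand == "+":
                    lead, tail = qs, L - qe
                    seq = t.variant_sequence
                else:
                    lead, tail = L - qe, qs
                    seq = reverse_complement(t.variant_sequence)
                full_cig = (
                    ([(4, lead)] if lead else []) + cig + ([(4, tail)] if tail else [])
                )
                rec = pysam.AlignedSegment()
                rec.query_name = t.variant_id
                rec.flag = (16 if strand == "-" else 0) | (2048 if rank > 0 else 0)
                rec.reference_id = chrom_id[items[0][0].chrom]
                rec.reference_start = items[0][0].start
                rec.mapping_quality = 60
                rec.cigartuples = full_cig
                rec.query_sequence = seq
                out.write(rec)


# -- benchmark driver ------------------------------------------------------


@dataclass
class BenchmarkResult:
    report: EvaluationReport
    pipeline: PipelineResult
    sample: SimulatedSample
    outdir: str


def run_simulated_benchmark(
    n_per_type: int,
    n_background: int,
    coverage: float,
    seed: int,
    outdir: str,
    error_rate: float = 0.001,
    config: Optional[PipelineConfig] = None,
    n_controls: int = 1,
    write_reference_files: bool = False,
) -> BenchmarkResult:
    """End-to-end benchmark: simulate, quantify, test, annotate, evaluate.

    Variant transcripts are sequenced at ``coverage`` alongside their
    wild-type partners at the same depth (heterozygous design); background
    genes and the control sample run at twice ``coverage`` so every gene
    carries the same total expression in both samples. Ground-truth contigs
    and alignments stand in for the assembly and alignment stages, and
    motif checking is off because simulated junctions carry no splice
    motifs.
    """
    os.makedirs(outdir, exist_ok=True)
    if config is None:
        config = PipelineConfig(motif_check=False, seed=seed)

    n_genes = genes_required(n_per_type, n_background) + 20
    store, index = generate_synthetic_genome(n_genes, seed=_sub_seed(seed, 1))
    sample = build_benchmark(index, store, n_per_type, n_background,
                             seed=_sub_seed(seed, 2))

    case1 = os.path.join(outdir, "case_R1.fastq")
    case2 = os.path.join(outdir, "case_R2.fastq")
    cov_map = {vid: coverage for vid, _ in sample.case_reference}
    for bid in sample.background_ids:
        cov_map[bid] = 2 * coverage
    simulate_reads(
        sample.case_reference,
        ReadSimParams(coverage=coverage, error_rate=error_rate,
                      seed=_sub_seed(seed, 3)),
        case1, case2, coverage_by_id=cov_map,
    )
    control_fastqs = []
    for ci in range(n_controls):
        c1 = os.path.join(outdir, f"control{ci + 1}_R1.fastq")
        c2 = os.path.join(outdir, f"control{ci + 1}_R2.fastq")
        simulate_reads(
            sample.control_reference,
            ReadSimParams(coverage=2 * coverage, error_rate=error_rate,
                          seed=_sub_seed(seed, 4 + ci)),
            c1, c2,
        )
        control_fastqs.append([c1, c2])

    contigs = perfect_contigs(sample.truth)
    contigs_path = os.path.join(outdir, "contigs.fasta")
    write_records_fasta(contigs, contigs_path)
    sam_path = os.path.join(outdir, "contigs.sam")
    write_truth_sam(sample.truth, store, index, sam_path)
    write_truth_tsv(sample.truth, os.path.join(outdir, "truth.tsv"))
    if write_reference_files:
        store.write_fasta(os.path.join(outdir, "genome.fasta"))
        write_gtf(index, os.path.join(outdir, "annotation.gtf"))
        write_transcriptome_fasta(index, store, os.path.join(outdir, "ref_tx.fasta"))

    ref_records = [
        (tid, _spliced(index, store, tid)) for tid in sorted(index.transcript_map)
    ]
    result = run_pipeline(
        [case1, case2],
        control_fastqs,
        contigs_path,
        ref_records,
        store,
        index,
        sam_path,
        config=config,
        outdir=outdir,
    )
    report = evaluate(result.calls, sample.truth, index, sample.background_genes)
    return BenchmarkResult(report=report, pipeline=result, sample=sample, outdir=outdir)


def _spliced(index: AnnotationIndex, store: SequenceStore, tid: str) -> str:
    from .genome import transcript_sequence

    return transcript_sequence(index.transcript_map[tid], store)


def _sub_seed(seed: int, stage: int) -> int:
    return (seed * 1_000_003 + stage) % (2**31 - 1)
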