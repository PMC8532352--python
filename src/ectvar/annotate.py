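"""Contig annotation: classify retained contigs from spliced genome
alignments against the reference annotation, and estimate VAF.

A contig retained by the differential-expression step is examined through
its SAM records (primary plus supplementaries, from any spliced aligner).
Raw evidence is collected first — insertions/deletions of >= 7 bp, soft or
hard clips of >= 20 bp, splice junctions absent from the reference, and
aligned blocks of >= 20 bp outside every reference exon — and then
consolidated into variant calls:

* novel blocks flanked by a novel junction become novel/extended exons
  (requiring a valid donor or acceptor motif unless motif checking is off);
* novel blocks contiguous with exons on both sides and contained in an
  intron become retained introns;
* novel junctions truncating an exon end by >= 20 bp, or joining annotated
  exon boundaries, become novel exon junctions;
* contigs whose aligned segments hit two genes, or a gene plus a locus
  outside every gene, become fusions; segments within one gene that
  overlap, run out of transcriptional order, or disagree in strand become
  intra-genic rearrangements;
* clips not explained by another aligned segment of the same contig are
  reported as class "unknown".

A single contig may yield several calls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd
import pysam

from .genome import AnnotationIndex, GenomicInterval, SequenceStore
from .quant import KmerIndex, MatchedECMatrix

_QUERY_OPS = {"M", "I", "S", "=", "X"}
_REF_OPS = {"M", "D", "N", "=", "X"}
_OP_NAMES = "MIDNSHP=X"

INTERGENIC = "intergenic"


class VariantClass(str, enum.Enum):
    FUSION = "fusion"
    INTRAGENIC_REARRANGEMENT = "intragenic_rearrangement"
    DELETION = "deletion"
    INSERTION = "insertion"
    NOVEL_EXTENDED_EXON = "novel_extended_exon"
    NOVEL_EXON_JUNCTION = "novel_exon_junction"
    RETAINED_INTRON = "retained_intron"
    UNKNOWN = "unknown"


@dataclass
class AnnotationParams:
    gap_min: int = 7
    clip_min: int = 20
    block_min: int = 20
    trunc_min: int = 20
    min_aligned_bp: int = 30
    min_aligned_frac: float = 0.3
    motif_check: bool = True
    motif_tolerance: int = 1


@dataclass
class AlignmentRecord:
    """One SAM record of a contig, with 0-based leftmost position.

    ``query_span`` is the aligned query interval in the *original* contig
    orientation (reverse-strand records are flipped back).
    """

    contig_id: str
    chrom: str
    strand: str
    pos: int
    cigar: List[Tuple[str, int]]
    is_supplementary: bool
    contig_length: int
    query_span: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        qlen = sum(l for op, l in self.cigar if op in _QUERY_OPS or op == "H")
        if qlen != self.contig_length:
            raise ValueError(
                f"{self.contig_id}: CIGAR length {qlen} != contig length "
                f"{self.contig_length}"
            )
        for op, l in self.cigar:
            if op in ("N", "D") and l <= 0:
                raise ValueError(f"{self.contig_id}: non-positive {op} length")
        qs = 0
        for op, l in self.cigar:
            if op in ("S", "H"):
                qs += l
            else:
                break
        qe = self.contig_length
        for op, l in reversed(self.cigar):
            if op in ("S", "H"):
                qe -= l
            else:
                break
        if self.strand == "-":
            qs, qe = self.contig_length - qe, self.contig_length - qs
        self.query_span = (qs, qe)

    def aligned_bases(self) -> int:
        return sum(l for op, l in self.cigar if op in ("M", "=", "X"))

    def match_intervals(self) -> List[Tuple[int, int]]:
        """Maximal reference intervals of M/=/X runs, merged across I."""
        out: List[Tuple[int, int]] = []
        ref = self.pos
        cur: Optional[List[int]] = None
        for op, l in self.cigar:
            if op in ("M", "=", "X"):
                if cur is not None and cur[1] == ref:
                    cur[1] = ref + l
                else:
                    if cur is not None:
                        out.append((cur[0], cur[1]))
                    cur = [ref, ref + l]
                ref += l
            elif op in ("D", "N"):
                ref += l
        if cur is not None:
            out.append((cur[0], cur[1]))
        return out

    def ref_span(self) -> Tuple[int, int]:
        iv = self.match_intervals()
        return (iv[0][0], iv[-1][1])


def load_alignments(sam_path: str) -> Dict[str, List[AlignmentRecord]]:
    """Group SAM records by contig. Unmapped records are dropped."""
    out: Dict[str, List[AlignmentRecord]] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            cig = [(_OP_NAMES[op], l) for op, l in rec.cigartuples]
            qlen = sum(l for op, l in cig if op in _QUERY_OPS or op == "H")
            record = AlignmentRecord(
                contig_id=rec.query_name,
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                pos=rec.reference_start,
                cigar=cig,
                is_supplementary=rec.is_supplementary,
                contig_length=qlen,
            )
            out.setdefault(rec.query_name, []).append(record)
    return out


def filter_alignments(
    records: Sequence[AlignmentRecord],
    index: AnnotationIndex,
    params: AnnotationParams = AnnotationParams(),
) -> bool:
    """Retention rule for one contig's records.

    Kept when total aligned bases reach both the absolute (30 bp) and
    fractional (30%) thresholds and at least one aligned block overlaps a
    reference exon.
    """
    if not records:
        return False
    total = sum(r.aligned_bases() for r in records)
    clen = records[0].contig_length
    if total < params.min_aligned_bp or total < params.min_aligned_frac * clen:
        return False
    for r in records:
        for s, e in r.match_intervals():
            if index.exons_overlapping(r.chrom, s, e):
                return True
    return False


# -- raw candidates --------------------------------------------------------


@dataclass
class Candidate:
    kind: str  # ins | del | clip | junction | novel_block
    chrom: str
    start: int
    end: int
    size: int = 0
    junction: Optional[Tuple[int, int]] = None
    query_interval: Optional[Tuple[int, int]] = None
    # novel-block flank descriptors: 'contiguous', 'junction:<l>:<r>', 'edge'
    left_flank: str = ""
    right_flank: str = ""
    record: Optional[AlignmentRecord] = None


def detect_raw_variants(
    records: Sequence[AlignmentRecord],
    index: AnnotationIndex,
    params: AnnotationParams = AnnotationParams(),
) -> List[Candidate]:
    """Collect raw variant evidence from a contig's alignment records."""
    cands: List[Candidate] = []
    for rec in records:
        cands.extend(_scan_record(rec, index, params))
    return cands


def _scan_record(
    rec: AlignmentRecord, index: AnnotationIndex, params: AnnotationParams
) -> List[Candidate]:
    cands: List[Candidate] = []
    ref = rec.pos
    qpos = 0  # stored-orientation query position
    clen = rec.contig_length

    def orig_interval(qs: int, qe: int) -> Tuple[int, int]:
        if rec.strand == "-":
            return (clen - qe, clen - qs)
        return (qs, qe)

    for i, (op, l) in enumerate(rec.cigar):
        if op in ("M", "=", "X"):
            ref += l
            qpos += l
        elif op == "I":
            if l >= params.gap_min:
                cands.append(
                    Candidate(
                        "ins", rec.chrom, max(0, ref - 1), ref + 1, size=l,
                        query_interval=orig_interval(qpos, qpos + l), record=rec,
                    )
                )
            qpos += l
        elif op == "D":
            if l >= params.gap_min:
                cands.append(
                    Candidate("del", rec.chrom, ref, ref + l, size=l, record=rec)
                )
            ref += l
        elif op == "N":
            left, right = ref, ref + l
            if not index.has_junction(rec.chrom, left, right):
                cands.append(
                    Candidate(
                        "junction", rec.chrom, left, right,
                        junction=(left, right), record=rec,
                    )
                )
            ref += l
        elif op in ("S", "H"):
            if l >= params.clip_min:
                at_start = i == 0 or all(o in ("S", "H") for o, _ in rec.cigar[:i])
                bp = rec.pos if at_start else ref
                cands.append(
                    Candidate(
                        "clip", rec.chrom, max(0, bp - 1), bp + 1, size=l,
                        query_interval=orig_interval(qpos, qpos + l), record=rec,
                    )
                )
            qpos += l

    cands.extend(_novel_blocks(rec, index, params))
    return cands


def _novel_blocks(
    rec: AlignmentRecord, index: AnnotationIndex, params: AnnotationParams
) -> List[Candidate]:
    """Aligned sub-blocks outside every reference exon, with flank context."""
    out: List[Candidate] = []
    intervals = rec.match_intervals()
    # event on each side of every interval, for flank classification
    side_events: List[Tuple[str, str]] = []
    ref = rec.pos
    tags: List[str] = []
    for op, l in rec.cigar:
        if op in ("M", "=", "X"):
            ref += l
        elif op == "N":
            tags.append(f"junction:{ref}:{ref + l}")
            ref += l
        elif op == "D":
            tags.append(f"del:{ref}:{ref + l}")
            ref += l
    # pair interval boundaries with N/D tags by coordinate
    tag_at: Dict[int, str] = {}
    for t in tags:
        _, l, r = t.split(":")
        tag_at[int(l)] = t  # event starting at this ref coordinate
    for s, e in intervals:
        left = tag_at_end(tag_at, s)
        right = tag_at.get(e, "edge")
        side_events.append((left, right))
    for (s, e), (lev, rev) in zip(intervals, side_events):
        covered = _exon_cover(index, rec.chrom, s, e)
        for a, b in _uncovered_runs(s, e, covered):
            if b - a < params.block_min:
                continue
            left_flank = "contiguous" if a > s else lev
            right_flank = "contiguous" if b < e else rev
            out.append(
                Candidate(
                    "novel_block", rec.chrom, a, b, size=b - a,
                    left_flank=left_flank, right_flank=right_flank, record=rec,
                )
            )
    return out


def tag_at_end(tag_at: Dict[int, str], start: int) -> str:
    """Event whose reference interval ends exactly at ``start``."""
    for t in tag_at.values():
        _, l, r = t.split(":")
        if int(r) == start:
            return t
    return "edge"


def _exon_cover(index: AnnotationIndex, chrom: str, s: int, e: int) -> List[Tuple[int, int]]:
    hits = sorted((max(s, a), min(e, b)) for a, b, _ in index.exons_overlapping(chrom, s, e))
    merged: List[Tuple[int, int]] = []
    for a, b in hits:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _uncovered_runs(s: int, e: int, covered: List[Tuple[int, int]]):
    pos = s
    for a, b in covered:
        if a > pos:
            yield (pos, a)
        pos = max(pos, b)
    if pos < e:
        yield (pos, e)


# -- motif checking --------------------------------------------------------

_DONOR = ("GT", "CT")
_ACCEPTOR = ("AG", "AC")


def _min_hamming(dinuc: str, options: Sequence[str]) -> int:
    return min(sum(a != b for a, b in zip(dinuc, o)) for o in options)


def check_motif(
    junction: Tuple[str, int, int],
    store: SequenceStore,
    tolerance: int = 1,
) -> bool:
    """Valid splice motif at a junction (chrom, donor_end, acceptor_start).

    The intron must begin with GT or CT and end with AG or AC on the
    genomic forward strand — this set covers canonical GT..AG introns on
    both gene strands. Up to ``tolerance`` mismatches are allowed per end.
    """
    chrom, left, right = junction
    start2 = store.fetch(chrom, left, left + 2)
    end2 = store.fetch(chrom, right - 2, right)
    return (
        _min_hamming(start2, _DONOR) <= tolerance
        and _min_hamming(end2, _ACCEPTOR) <= tolerance
    )


def _motif_ok_one_end(
    junction: Tuple[str, int, int], store: SequenceStore, tolerance: int
) -> bool:
    """Valid donor OR acceptor (either end suffices)."""
    chrom, left, right = junction
    start2 = store.fetch(chrom, left, left + 2)
    end2 = store.fetch(chrom, right - 2, right)
    return (
        _min_hamming(start2, _DONOR) <= tolerance
        or _min_hamming(end2, _ACCEPTOR) <= tolerance
    )


# -- calls -----------------------------------------------------------------


@dataclass
class VariantCall:
    contig_id: str
    vclass: VariantClass
    genes: Tuple[str, ...]
    loci: Tuple[GenomicInterval, ...]
    size_bp: Optional[int] = None
    junction: Optional[Tuple[int, int]] = None
    motif_valid: Optional[bool] = None
    vaf: Optional[float] = None
    de_logfc: Optional[float] = None
    de_fdr: Optional[float] = None
    case_cpm: Optional[float] = None


def _genes_at(index: AnnotationIndex, chrom: str, s: int, e: int) -> Tuple[str, ...]:
    return tuple(sorted(index.genes_overlapping(chrom, s, e)))


def refine_and_classify(
    contig_id: str,
    records: Sequence[AlignmentRecord],
    candidates: Sequence[Candidate],
    index: AnnotationIndex,
    store: Optional[SequenceStore],
    params: AnnotationParams = AnnotationParams(),
) -> List[VariantCall]:
    """Consolidate raw candidates into classified variant calls."""
    calls: List[VariantCall] = []
    junction_cands = [c for c in candidates if c.kind == "junction"]
    block_cands = [c for c in candidates if c.kind == "novel_block"]
    clip_cands = [c for c in candidates if c.kind == "clip"]

    # --- gene-level segment analysis: fusions / rearrangements ------------
    gene_hits: Dict[str, Tuple[int, int, str]] = {}
    intergenic_loci: List[Tuple[str, int, int]] = []
    for rec in records:
        for s, e in rec.match_intervals():
            genes = index.genes_overlapping(rec.chrom, s, e)
            for g in genes:
                if g in gene_hits:
                    cs, ce, cc = gene_hits[g]
                    gene_hits[g] = (min(cs, s), max(ce, e), cc)
                else:
                    gene_hits[g] = (s, e, rec.chrom)
            if not genes and e - s >= params.block_min:
                intergenic_loci.append((rec.chrom, s, e))

    inter_gene_junctions = set()
    for c in junction_cands:
        gl = index.genes_overlapping(c.chrom, c.start, c.start + 1)
        gr = index.genes_overlapping(c.chrom, c.end - 1, c.end)
        if gl and gr and not (gl & gr):
            inter_gene_junctions.add(id(c))

    fusion_called = False
    genes = sorted(gene_hits)
    if len(genes) >= 2:
        g1, g2 = genes[0], genes[1]
        loci = tuple(
            GenomicInterval(gene_hits[g][2], gene_hits[g][0], gene_hits[g][1])
            for g in (g1, g2)
        )
        calls.append(
            VariantCall(contig_id, VariantClass.FUSION, (g1, g2), loci)
        )
        fusion_called = True
    elif len(genes) == 1 and intergenic_loci:
        g = genes[0]
        ic, is_, ie = intergenic_loci[0]
        loci = (
            GenomicInterval(gene_hits[g][2], gene_hits[g][0], gene_hits[g][1]),
            GenomicInterval(ic, is_, ie),
        )
        calls.append(
            VariantCall(contig_id, VariantClass.FUSION, (g, INTERGENIC), loci)
        )
        fusion_called = True
    elif len(genes) == 1 and len(records) > 1:
        if _is_rearranged(records):
            g = genes[0]
            loci = (GenomicInterval(gene_hits[g][2], gene_hits[g][0], gene_hits[g][1]),)
            calls.append(
                VariantCall(
                    contig_id, VariantClass.INTRAGENIC_REARRANGEMENT, (g,), loci
                )
            )

    # --- novel blocks: extended/novel exons and retained introns ----------
    consumed_junctions: Set[Tuple[int, int]] = set()
    for c in block_cands:
        if not index.genes_overlapping(c.chrom, c.start, c.end):
            continue  # intergenic blocks are fusion evidence, handled above
        flanks = (c.left_flank, c.right_flank)
        novel_j = [
            f for f in flanks if f.startswith("junction:") and _flank_is_novel(f, c.chrom, index)
        ]
        if novel_j:
            if params.motif_check and store is not None:
                ok = any(
                    _motif_ok_one_end(_flank_junction(c.chrom, f), store, params.motif_tolerance)
                    for f in novel_j
                )
                if not ok:
                    continue
                motif: Optional[bool] = True
            else:
                motif = None
            jl, jr = _flank_junction(c.chrom, novel_j[0])[1:]
            for f in novel_j:
                consumed_junctions.add(_flank_junction(c.chrom, f)[1:])
            calls.append(
                VariantCall(
                    contig_id,
                    VariantClass.NOVEL_EXTENDED_EXON,
                    _genes_at(index, c.chrom, c.start, c.end),
                    (GenomicInterval(c.chrom, c.start, c.end),),
                    size_bp=c.size,
                    junction=(jl, jr),
                    motif_valid=motif,
                )
            )
        elif flanks[0] == "contiguous" and flanks[1] == "contiguous":
            if index.intron_contains(c.chrom, c.start, c.end):
                calls.append(
                    VariantCall(
                        contig_id,
                        VariantClass.RETAINED_INTRON,
                        _genes_at(index, c.chrom, c.start, c.end),
                        (GenomicInterval(c.chrom, c.start, c.end),),
                        size_bp=c.size,
                    )
                )
        # blocks with an edge or deletion flank and no novel junction are
        # unsupported extended/novel exons: discarded

    # --- novel junctions: truncations and exon-boundary joins -------------
    for c in junction_cands:
        if id(c) in inter_gene_junctions:
            continue  # the fusion junction itself
        jl, jr = c.junction
        if (jl, jr) in consumed_junctions:
            continue  # already explains a novel/extended exon
        left_annot = index.is_exon_end(c.chrom, jl)
        right_annot = index.is_exon_start(c.chrom, jr)
        trunc = _truncation(index, c.chrom, jl, jr, params.trunc_min)
        if (left_annot and right_annot) or trunc:
            motif: Optional[bool] = None
            if params.motif_check and store is not None:
                motif = check_motif((c.chrom, jl, jr), store, params.motif_tolerance)
                if not motif:
                    continue  # novel junctions require valid splice sites
            calls.append(
                VariantCall(
                    contig_id,
                    VariantClass.NOVEL_EXON_JUNCTION,
                    _genes_at(index, c.chrom, jl, jr),
                    (GenomicInterval(c.chrom, max(0, jl - 1), jr + 1),),
                    size_bp=trunc if trunc else None,
                    junction=(jl, jr),
                    motif_valid=motif,
                )
            )

    # --- indels ------------------------------------------------------------
    for c in candidates:
        if c.kind == "ins":
            calls.append(
                VariantCall(
                    contig_id, VariantClass.INSERTION,
                    _genes_at(index, c.chrom, c.start, c.end),
                    (GenomicInterval(c.chrom, c.start, c.end),),
                    size_bp=c.size,
                )
            )
        elif c.kind == "del":
            motif = None
            if params.motif_check and store is not None:
                # a deletion with valid motifs at both ends may be a novel intron
                motif = check_motif((c.chrom, c.start, c.end), store, params.motif_tolerance)
            calls.append(
                VariantCall(
                    contig_id, VariantClass.DELETION,
                    _genes_at(index, c.chrom, c.start, c.end),
                    (GenomicInterval(c.chrom, c.start, c.end),),
                    size_bp=c.size,
                    motif_valid=motif,
                )
            )

    # --- unexplained clips -------------------------------------------------
    for c in clip_cands:
        if c.query_interval is None:
            continue
        if _clip_explained(c, records):
            continue
        calls.append(
            VariantCall(
                contig_id, VariantClass.UNKNOWN,
                _genes_at(index, c.chrom, c.start, c.end),
                (GenomicInterval(c.chrom, c.start, c.end),),
                size_bp=c.size,
            )
        )
    return calls


def _flank_junction(chrom: str, flank: str) -> Tuple[str, int, int]:
    _, l, r = flank.split(":")
    return (chrom, int(l), int(r))


def _flank_is_novel(flank: str, chrom: str, index: AnnotationIndex) -> bool:
    _, l, r = flank.split(":")
    return not index.has_junction(chrom, int(l), int(r))


def _truncation(
    index: AnnotationIndex, chrom: str, jl: int, jr: int, trunc_min: int
) -> int:
    """Largest exon-end truncation (bp) implied by a junction, 0 if none."""
    best = 0
    for a, b, _ in index.exons_overlapping(chrom, jl, jl + 1):
        if a < jl < b and b - jl >= trunc_min:
            best = max(best, b - jl)
    for a, b, _ in index.exons_overlapping(chrom, jr - 1, jr):
        if a < jr < b and jr - a >= trunc_min:
            best = max(best, jr - a)
    return best


def _is_rearranged(records: Sequence[AlignmentRecord]) -> bool:
    """Overlapping ref spans, strand discordance, or query/reference order
    mismatch among a contig's records on one chromosome."""
    if len({r.strand for r in records}) > 1:
        return True
    spans = [r.ref_span() for r in records]
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            if records[i].chrom == records[j].chrom:
                a, b = spans[i], spans[j]
                if a[0] < b[1] and b[0] < a[1]:
                    return True  # duplication: reference overlap
    order_q = sorted(range(len(records)), key=lambda i: records[i].query_span[0])
    fwd = records[0].strand == "+"
    refs = [spans[i][0] for i in order_q]
    expected = sorted(refs) if fwd else sorted(refs, reverse=True)
    return refs != expected


def _clip_explained(c: Candidate, records: Sequence[AlignmentRecord]) -> bool:
    qs, qe = c.query_interval
    if qe <= qs:
        return True
    covered = 0
    pieces = [
        r.query_span for r in records if r is not c.record
    ]
    for a, b in pieces:
        covered += max(0, min(qe, b) - max(qs, a))
    return covered >= 0.5 * (qe - qs)


# -- VAF -------------------------------------------------------------------


def estimate_vaf(
    call: VariantCall,
    matrix: MatchedECMatrix,
    index: AnnotationIndex,
    kmer_index: KmerIndex,
) -> Optional[float]:
    """Expressed variant allele frequency from case EC counts.

    U = case counts of contig-only ECs containing this call's contig;
    W = case counts of ECs containing a reference transcript of the call's
    gene(s) and no contig. Returns U / (U + W), or None when U + W = 0.
    """
    gene_tx: Set[str] = set()
    for g in call.genes:
        gene_tx.update(index.gene_transcripts.get(g, ()))
    catalog = kmer_index.id_catalog
    case = matrix.matrix[:, matrix.case_index]
    u = 0
    w = 0
    for i, ec in enumerate(matrix.ec_list):
        is_contig = [catalog[m][0] if m in catalog else False for m in ec]
        if all(is_contig):
            if call.contig_id in ec:
                u += int(case[i])
        elif not any(is_contig):
            if gene_tx.intersection(ec):
                w += int(case[i])
    if u + w == 0:
        return None
    return u / (u + w)


# -- orchestration ---------------------------------------------------------


def annotate_contigs(
    sam_path: str,
    index: AnnotationIndex,
    store: Optional[SequenceStore],
    retained_contigs: Set[str],
    params: AnnotationParams = AnnotationParams(),
    matrix: Optional[MatchedECMatrix] = None,
    kmer_index: Optional[KmerIndex] = None,
    de_stats: Optional[Dict[str, Tuple[float, float, float]]] = None,
) -> List[VariantCall]:
    """Full annotation pass: load, filter, detect, classify, estimate VAF."""
    grouped = load_alignments(sam_path)
    calls: List[VariantCall] = []
    for contig_id in sorted(retained_contigs):
        records = grouped.get(contig_id)
        if not records:
            continue
        if not filter_alignments(records, index, params):
            continue
        cands = detect_raw_variants(records, index, params)
        contig_calls = refine_and_classify(
            contig_id, records, cands, index, store, params
        )
        for call in contig_calls:
            if matrix is not None and kmer_index is not None:
                call.vaf = estimate_vaf(call, matrix, index, kmer_index)
            if de_stats and contig_id in de_stats:
                call.de_logfc, call.de_fdr, call.case_cpm = de_stats[contig_id]
        calls.extend(contig_calls)
    return calls


def write_results(calls: Sequence[VariantCall], path: str) -> pd.DataFrame:
    """Deterministic, deduplicated variant table."""
    rows = []
    for c in calls:
        loc = c.loci[0]
        rows.append(
            {
                "contig_id": c.contig_id,
                "class": c.vclass.value,
                "genes": ",".join(c.genes),
                "chrom": loc.chrom,
                "start": loc.start,
                "end": loc.end,
                "size_bp": "" if c.size_bp is None else c.size_bp,
                "junction": "" if c.junction is None else f"{c.junction[0]}-{c.junction[1]}",
                "motif_valid": "" if c.motif_valid is None else str(c.motif_valid),
                "vaf": "" if c.vaf is None else round(c.vaf, 4),
                "logFC": "" if c.de_logfc is None else round(c.de_logfc, 4),
                "FDR": "" if c.de_fdr is None else f"{c.de_fdr:.3g}",
                "case_cpm": "" if c.case_cpm is None else round(c.case_cpm, 4),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig_id", "class", "genes", "chrom", "start", "end", "size_bp",
            "junction", "motif_valid", "vaf", "logFC", "FDR", "case_cpm",
        ],
    )
    if len(df):
        df = df.drop_duplicates().sort_values(
            ["contig_id", "chrom", "start", "class"], kind="mergesort"
        )
    df.to_csv(path, sep="\t", index=False)
    return df
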