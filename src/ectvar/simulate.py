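"""Benchmark simulator for 15 classes of transcribed variant.

Variants are built by editing eligible reference transcripts: five fusion
subtypes (canonical, extended exon, novel exon, boundary insertion,
unpartnered), five transcribed structural variants (insertion, deletion,
ITD, PTD, inversion) and five novel splice variants (extended exon, novel
exon, truncated exons, skipped exon / novel junction, retained intron).

Each variant transcript is represented as an ordered list of *segments* in
transcription order — genomic blocks (with strand) and non-templated
inserts — from which both the variant nucleotide sequence and a
ground-truth spliced alignment can be derived. The case sample is
heterozygous: every variant sequence is paired with its unaltered wild-type
transcript; controls carry wild-type sequence only.

Splicing motifs are deliberately not enforced at simulated variant
junctions, so benchmark runs are expected to disable motif checking.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import SimulationInfeasibleError
from .genome import (
    AnnotationIndex,
    GenomicInterval,
    SequenceStore,
    Transcript,
    reverse_complement,
)
from .synth import intergenic_tail

# size vocabularies (bp)
INDEL_SIZE = (7, 49)        # insertion / deletion / ITD edits
SPLICE_SIZE = (30, 199)     # extensions, novel exons, truncations, gaps
MIN_EDGE_DIST = 10          # indel endpoints must sit this far inside an exon
MIN_RETAINED_INTRON = 30    # retained introns must exceed this length
_MAX_TRIES = 50


class VariantCategory(str, enum.Enum):
    FUSION = "fusion"
    TSV = "tsv"
    NSV = "nsv"


class VariantType(str, enum.Enum):
    """The 15 simulated variant classes (5 fusion / 5 TSV / 5 NSV)."""

    FUSION_CANONICAL = "fusion_canonical"
    FUSION_EXTENDED_EXON = "fusion_extended_exon"
    FUSION_NOVEL_EXON = "fusion_novel_exon"
    FUSION_INSERTION = "fusion_insertion"
    FUSION_UNPARTNERED = "fusion_unpartnered"
    INS = "ins"
    DEL = "del"
    ITD = "itd"
    PTD = "ptd"
    INV = "inv"
    EE = "ee"
    NE = "ne"
    TRUNC = "trunc"
    NJ = "nj"
    RI = "ri"

    @property
    def category(self) -> VariantCategory:
        if self.value.startswith("fusion"):
            return VariantCategory.FUSION
        if self in (VariantType.INS, VariantType.DEL, VariantType.ITD,
                    VariantType.PTD, VariantType.INV):
            return VariantCategory.TSV
        return VariantCategory.NSV


FUSION_TYPES = tuple(t for t in VariantType if t.category is VariantCategory.FUSION)
TSV_TYPES = tuple(t for t in VariantType if t.category is VariantCategory.TSV)
NSV_TYPES = tuple(t for t in VariantType if t.category is VariantCategory.NSV)

# Plausible output classes per simulated type, used for the
# classification-consistency metric. Hybrid fusion subtypes genuinely carry a
# novel exon (or a non-templated insert) in addition to the gene join, so
# those output classes are accepted for them as well.
EXPECTED_CLASSES: Dict[VariantType, frozenset] = {
    VariantType.FUSION_CANONICAL: frozenset({"fusion", "unknown"}),
    VariantType.FUSION_EXTENDED_EXON: frozenset({"fusion", "unknown", "novel_extended_exon"}),
    VariantType.FUSION_NOVEL_EXON: frozenset({"fusion", "unknown", "novel_extended_exon"}),
    VariantType.FUSION_INSERTION: frozenset({"fusion", "unknown", "insertion"}),
    VariantType.FUSION_UNPARTNERED: frozenset({"fusion", "unknown"}),
    VariantType.INS: frozenset({"insertion"}),
    VariantType.DEL: frozenset({"deletion"}),
    VariantType.ITD: frozenset({"insertion", "unknown", "intragenic_rearrangement"}),
    VariantType.PTD: frozenset({"intragenic_rearrangement", "unknown"}),
    VariantType.INV: frozenset({"intragenic_rearrangement", "unknown"}),
    VariantType.EE: frozenset({"novel_extended_exon"}),
    VariantType.NE: frozenset({"novel_extended_exon"}),
    VariantType.TRUNC: frozenset({"novel_exon_junction"}),
    VariantType.NJ: frozenset({"novel_exon_junction"}),
    VariantType.RI: frozenset({"retained_intron"}),
}


@dataclass(frozen=True)
class RefBlock:
    """A genomic block of a variant transcript, in transcription order.

    ``strand`` gives the orientation of this block *as transcribed*:
    '+' blocks contribute genome[start:end], '-' blocks its reverse
    complement.
    """

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsSeq:
    """A non-templated insert in a variant transcript."""

    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


Segment = Union[RefBlock, InsSeq]


@dataclass
class VariantTruth:
    """Ground truth for one simulated variant."""

    variant_id: str
    vtype: VariantType
    source_transcripts: Tuple[str, ...]
    genes: Tuple[str, ...]
    size_bp: Optional[int]
    breakpoints: Tuple[GenomicInterval, ...]
    segments: Tuple[Segment, ...]
    variant_sequence: str
    expected_classes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.variant_sequence:
            raise ValueError(f"{self.variant_id}: empty variant sequence")
        if not self.expected_classes:
            self.expected_classes = EXPECTED_CLASSES[self.vtype]


@dataclass
class SimulatedSample:
    """Case/control references plus the truth table for one benchmark."""

    case_reference: List[Tuple[str, str]]
    control_reference: List[Tuple[str, str]]
    truth: List[VariantTruth]
    background_genes: Tuple[str, ...] = ()
    background_ids: Tuple[str, ...] = ()
    wildtype_ids: Tuple[str, ...] = ()


@dataclass
class ReadSimParams:
    """Paired-end read simulation parameters."""

    read_len: int = 100
    fragment_len: int = 300
    coverage: float = 50.0
    error_rate: float = 0.001
    fragment_jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len > self.fragment_len:
            raise ValueError("read_len must not exceed fragment_len")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0 <= self.error_rate < 0.05):
            raise ValueError("error_rate must be in [0, 0.05)")


# -- segment helpers -------------------------------------------------------


def tx_segments(tx: Transcript) -> List[RefBlock]:
    """Wild-type transcript as blocks in transcription order."""
    return [
        RefBlock(e.chrom, e.start, e.end, tx.strand)
        for e in tx.exons_transcription_order()
    ]


def segments_sequence(segments: Sequence[Segment], store: SequenceStore) -> str:
    parts = []
    for seg in segments:
        if isinstance(seg, InsSeq):
            parts.append(seg.seq)
        else:
            s = store.fetch(seg.chrom, seg.start, seg.end)
            parts.append(s if seg.strand == "+" else reverse_complement(s))
    return "".join(parts)


def _downstream_intron(tx: Transcript, order_idx: int) -> Optional[GenomicInterval]:
    """Intron immediately downstream (in transcription order) of exon ``order_idx``."""
    exons = tx.exons_transcription_order()
    if order_idx >= len(exons) - 1:
        return None
    cur, nxt = exons[order_idx], exons[order_idx + 1]
    if tx.strand == "+":
        return GenomicInterval(tx.chrom, cur.end, nxt.start, "+")
    return GenomicInterval(tx.chrom, nxt.end, cur.start, "-")


def _intron_slice_downstream(intron: GenomicInterval, offset: int, length: int) -> RefBlock:
    """Block ``offset`` bp into the intron from its transcription-start side."""
    if intron.strand == "+":
        return RefBlock(intron.chrom, intron.start + offset,
                        intron.start + offset + length, "+")
    return RefBlock(intron.chrom, intron.end - offset - length,
                    intron.end - offset, "-")


def _block_interval(b: RefBlock) -> GenomicInterval:
    return GenomicInterval(b.chrom, b.start, b.end, b.strand)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# -- eligibility -----------------------------------------------------------


def select_eligible_transcripts(index: AnnotationIndex) -> List[Transcript]:
    """Transcripts usable for simulation.

    A transcript is eligible when its gene overlaps no other gene and it has
    at least 3 exons. Deterministic order (sorted by transcript id).
    """
    overlapping = set()
    gene_items = sorted(index.gene_extents.items())
    for gid, iv in gene_items:
        others = index.genes_overlapping(iv.chrom, iv.start, iv.end) - {gid}
        if others:
            overlapping.add(gid)
    out = [
        tx
        for tid, tx in sorted(index.transcript_map.items())
        if tx.gene_id not in overlapping and tx.n_exons >= 3
    ]
    if not out:
        raise SimulationInfeasibleError("no eligible transcripts in annotation")
    return out


# -- fusion construction ---------------------------------------------------


def make_fusion(
    subtype: VariantType,
    tx_a: Transcript,
    tx_b_or_locus: Union[Transcript, GenomicInterval],
    store: SequenceStore,
    index: AnnotationIndex,
    rng: np.random.Generator,
    variant_id: str = "fusion",
) -> VariantTruth:
    """Fusion of the first two exons of ``tx_a`` with the last two exons of a
    partner transcript (or, for unpartnered fusions, with a cryptic two-exon
    block taken from the intergenic locus)."""
    if subtype not in FUSION_TYPES:
        raise ValueError(f"{subtype} is not a fusion subtype")
    a_blocks = tx_segments(tx_a)[:2]
    head_end = a_blocks[-1]

    mid: List[Segment] = []
    size_bp: Optional[int] = None
    breakpoints: List[GenomicInterval] = []

    if subtype is VariantType.FUSION_UNPARTNERED:
        locus = tx_b_or_locus
        if not isinstance(locus, GenomicInterval):
            raise ValueError("unpartnered fusion requires an intergenic locus")
        if index.genes_overlapping(locus.chrom, locus.start, locus.end):
            raise ValueError("unpartnered fusion locus overlaps a gene")
        for _ in range(_MAX_TRIES):
            e1 = int(rng.integers(SPLICE_SIZE[0], SPLICE_SIZE[1] + 1))
            e2 = int(rng.integers(SPLICE_SIZE[0], SPLICE_SIZE[1] + 1))
            gap = int(rng.integers(200, 501))
            if locus.length >= e1 + gap + e2:
                break
        else:
            raise SimulationInfeasibleError("intergenic locus too small")
        off = int(rng.integers(0, locus.length - (e1 + gap + e2) + 1))
        c1 = RefBlock(locus.chrom, locus.start + off, locus.start + off + e1, "+")
        c2 = RefBlock(locus.chrom, c1.end + gap, c1.end + gap + e2, "+")
        tail: List[Segment] = [c1, c2]
        genes = (tx_a.gene_id,)
        txs = (tx_a.id,)
        breakpoints = [_block_interval(c1), _block_interval(c2)]
    else:
        tx_b = tx_b_or_locus
        if not isinstance(tx_b, Transcript):
            raise ValueError("partnered fusion requires a partner transcript")
        if tx_b.gene_id == tx_a.gene_id:
            raise ValueError("fusion partners must come from different genes")
        tail = list(tx_segments(tx_b)[-2:])
        genes = (tx_a.gene_id, tx_b.gene_id)
        txs = (tx_a.id, tx_b.id)
        breakpoints = [_block_interval(tail[0])]

        if subtype is VariantType.FUSION_EXTENDED_EXON:
            intron = _downstream_intron(tx_a, 1)
            if intron is None:
                raise SimulationInfeasibleError(f"{tx_a.id}: no intron after exon 2")
            size_bp = int(rng.integers(SPLICE_SIZE[0], SPLICE_SIZE[1] + 1))
            if intron.length < size_bp + 60:
                raise SimulationInfeasibleError(f"{tx_a.id}: intron too short")
            ext = _intron_slice_downstream(intron, 0, size_bp)
            # extend the second exon of tx_a in place
            if ext.strand == "+":
                a_blocks[-1] = RefBlock(head_end.chrom, head_end.start, ext.end, "+")
            else:
                a_blocks[-1] = RefBlock(head_end.chrom, ext.start, head_end.end, "-")
            breakpoints.insert(0, _block_interval(ext))
        elif subtype is VariantType.FUSION_NOVEL_EXON:
            intron = _downstream_intron(tx_a, 1)
            if intron is None:
                raise SimulationInfeasibleError(f"{tx_a.id}: no intron after exon 2")
            gap = int(rng.integers(SPLICE_SIZE[0], SPLICE_SIZE[1] + 1))
            size_bp = int(rng.integers(SPLICE_SIZE[0], SPLICE_SIZE[1] + 1))
            if intron.length < gap + size_bp + 60:
                raise SimulationInfeasibleError(f"{tx_a.id}: intron too short")
            block = _intron_slice_downstream(intron, gap, size_bp)
            mid.append(block)
            breakpoints.insert(0, _block_interval(block))
        elif subtype is VariantType.FUSION_INSERTION:
            size_bp = int(rng.integers(INDEL_SIZE[0], INDEL_SIZE[1] + 1))
            mid.append(InsSeq(_random_seq(rng, size_bp)))

    segments = tuple(a_blocks + mid + tail)
    breakpoints.insert(0, _block_interval(head_end))
    return VariantTruth(
        variant_id=variant_id,
        vtype=subtype,
        source_transcripts=txs,
        genes=genes,
        size_bp=size_bp,
        breakpoints=tuple(breakpoints),
        segments=segments,
        variant_sequence=segments_sequence(segments, store),
    )


# -- transcribed structural variants ---------------------------------------


def _pick_exon_for_edit(tx: Transcript, rng: np.random.Generator, need: int) -> int:
    """Index (transcription order) of a random exon long enough for an edit
    needing ``need`` bp between the 10 bp edge margins."""
    exons = tx.exons_transcription_order()
    order = list(rng.permutation(len(exons)))
    for i in order:
        if exons[i].length >= need + 2 * MIN_EDGE_DIST:
            return int(i)
    raise SimulationInfeasibleError(f"{tx.id}: no exon fits a {need} bp edit")


def _split_block(b: RefBlock, at: int) -> Tuple[RefBlock, RefBlock]:
    """Split a block ``at`` bp into its transcribed sequence."""
    if b.strand == "+":
        return (RefBlock(b.chrom, b.start, b.start + at, "+"),
                RefBlock(b.chrom, b.start + at, b.end, "+"))
    return (RefBlock(b.chrom, b.end - at, b.end, "-"),
            RefBlock(b.chrom, b.start, b.end - at, "-"))


def _sub_block(b: RefBlock, frm: int, to: int) -> RefBlock:
    """Sub-block covering transcribed offsets [frm, to) of ``b``."""
    if b.strand == "+":
        return RefBlock(b.chrom, b.start + frm, b.start + to, "+")
    return RefBlock(b.chrom, b.end - to, b.end - frm, "-")


def make_tsv(
    subtype: VariantType,
    tx: Transcript,
    store: SequenceStore,
    rng: np.random.Generator,
    variant_id: str = "tsv",
) -> VariantTruth:
    """Insertion, deletion or ITD within one exon (7-49 bp, endpoints at
    least 10 bp inside the exon), or PTD/inversion of 1-3 whole exons."""
    if subtype not in TSV_TYPES:
        raise ValueError(f"{subtype} is not a TSV subtype")
    blocks: List[Segment] = list(tx_segments(tx))
    breakpoints: List[GenomicInterval] = []

    if subtype in (VariantType.INS, VariantType.DEL, VariantType.ITD):
        size = int(rng.integers(INDEL_SIZE[0], INDEL_SIZE[1] + 1))
        need = size if subtype is VariantType.DEL else 0
        ei = _pick_exon_for_edit(tx, rng, need)
        exon: RefBlock = blocks[ei]  # type: ignore[assignment]
        if subtype is VariantType.INS:
            at = int(rng.integers(MIN_EDGE_DIST, exon.length - MIN_EDGE_DIST + 1))
            left, right = _split_block(exon, at)
            blocks[ei : ei + 1] = [left, InsSeq(_random_seq(rng, size)), right]
            bp = left.end if exon.strand == "+" else left.start
            breakpoints = [GenomicInterval(exon.chrom, bp - 1, bp + 1)]
        elif subtype is VariantType.DEL:
            a = int(rng.integers(MIN_EDGE_DIST, exon.length - size - MIN_EDGE_DIST + 1))
            left = _sub_block(exon, 0, a)
            gone = _sub_block(exon, a, a + size)
            right = _sub_block(exon, a + size, exon.length)
            blocks[ei : ei + 1] = [left, right]
            breakpoints = [_block_interval(gone)]
        else:  # ITD: duplicate [a, a+size) in tandem; the second copy is an
            # insert because an optimal alignment places it as one
            a = int(rng.integers(MIN_EDGE_DIST, exon.length - size - MIN_EDGE_DIST + 1))
            dup = _sub_block(exon, a, a + size)
            dup_seq = store.fetch(dup.chrom, dup.start, dup.end)
            if dup.strand == "-":
                dup_seq = reverse_complement(dup_seq)
            left = _sub_block(exon, 0, a + size)
            right = _sub_block(exon, a + size, exon.length)
            blocks[ei : ei + 1] = [left, InsSeq(dup_seq), right]
            breakpoints = [_block_interval(dup)]
        size_bp = size
    else:  # PTD / INV over 1-3 consecutive exons
        n = tx.n_exons
        k = int(rng.integers(1, min(3, n - 1) + 1))
        start = int(rng.integers(0, n - k + 1))
        run = blocks[start : start + k]
        if subtype is VariantType.PTD:
            blocks[start + k : start + k] = list(run)
        else:  # inversion: reverse order and flip strand of the run in place
            flipped = [
                RefBlock(b.chrom, b.start, b.end, "-" if b.strand == "+" else "+")
                for b in reversed(run)  # type: ignore[union-attr]
            ]
            blocks[start : start + k] = flipped
        size_bp = sum(b.length for b in run)  # type: ignore[union-attr]
        breakpoints = [_block_interval(b) for b in run]  # type: ignore[arg-type]

    segments = tuple(blocks)
    return VariantTruth(
        variant_id=variant_id,
        vtype=subtype,
        source_transcripts=(tx.id,),
        genes=(tx.gene_id,),
        size_bp=size_bp,
        breakpoints=tuple(breakpoints),
        segments=segments,
        variant_sequence=segments_sequence(segments, store),
    )


# -- novel splice variants -------------------------------------------------


def make_splice_variant(
    subtype: VariantType,
    tx: Transcript,
    index: AnnotationIndex,
    store: SequenceStore,
    rng: np.random.Generator,
    variant_id: str = "nsv",
) -> VariantTruth:
    """Extended/novel/truncated exons, skipped exons and retained introns."""
    if subtype not in NSV_TYPES:
        raise ValueError(f"{subtype} is not an NSV subtype")
    blocks = list(tx_segments(tx))
    n = len(blocks)
    breakpoints: List[GenomicInterval] = []
    size_bp: Optional[int] = None

    if subtype in (VariantType.EE, VariantType.NE):
        candidates = list(rng.permutation(n - 1))
        chosen = None
        for oi in candidates:
            intron = _downstream_intron(tx, int(oi))
            size = int(rng.integers(SPLICE_SIZE[0], SPLICE_SIZE[1] + 1))
            gap = int(rng.integers(SPLICE_SIZE[0], SPLICE_SIZE[1] + 1)) if subtype is VariantType.NE else 0
            # keep a >50 bp remainder so the downstream junction still looks
            # like an intron rather than a small deletion
            if intron is None or intron.length < gap + size + 60:
                continue
            block = _intron_slice_downstream(intron, gap, size)
            hits = index.exons_overlapping(block.chrom, block.start, block.end)
            if hits:
                continue  # would overlap an annotated exon
            chosen = (int(oi), block, size)
            break
        if chosen is None:
            raise SimulationInfeasibleError(f"{tx.id}: no intron fits {subtype.value}")
        oi, block, size = chosen
        exon: RefBlock = blocks[oi]  # type: ignore[assignment]
        if subtype is VariantType.EE:
            if exon.strand == "+":
                blocks[oi] = RefBlock(exon.chrom, exon.start, block.end, "+")
            else:
                blocks[oi] = RefBlock(exon.chrom, block.start, exon.end, "-")
        else:
            blocks.insert(oi + 1, block)
        size_bp = size
        breakpoints = [_block_interval(block)]
    elif subtype is VariantType.NJ:
        pairs = [(i, j) for i in range(n) for j in range(i + 2, n)]
        rng.shuffle(pairs)
        chosen = None
        for i, j in pairs:
            a: RefBlock = blocks[i]  # type: ignore[assignment]
            b: RefBlock = blocks[j]  # type: ignore[assignment]
            left, right = (a.end, b.start) if a.strand == "+" else (b.end, a.start)
            if index.has_junction(a.chrom, left, right):
                continue  # already an annotated junction; resample
            chosen = (i, j, left, right)
            break
        if chosen is None:
            raise SimulationInfeasibleError(f"{tx.id}: all exon pairs already joined")
        i, j, left, right = chosen
        del blocks[i + 1 : j]
        breakpoints = [GenomicInterval(tx.chrom, left, right)]
    elif subtype is VariantType.TRUNC:
        i = int(rng.integers(0, n - 1))
        a: RefBlock = blocks[i]  # type: ignore[assignment]
        b: RefBlock = blocks[i + 1]  # type: ignore[assignment]
        t1 = int(rng.integers(SPLICE_SIZE[0], min(SPLICE_SIZE[1], a.length - 20) + 1))
        t2 = int(rng.integers(SPLICE_SIZE[0], min(SPLICE_SIZE[1], b.length - 20) + 1))
        blocks[i] = _sub_block(a, 0, a.length - t1)
        blocks[i + 1] = _sub_block(b, t2, b.length)
        size_bp = t1 + t2
        breakpoints = [
            _block_interval(_sub_block(a, a.length - t1, a.length)),
            _block_interval(_sub_block(b, 0, t2)),
        ]
    else:  # retained intron
        introns = [
            (oi, _downstream_intron(tx, oi))
            for oi in range(n - 1)
        ]
        introns = [(oi, iv) for oi, iv in introns if iv is not None and iv.length > MIN_RETAINED_INTRON]
        if not introns:
            raise SimulationInfeasibleError(f"{tx.id}: no intron > {MIN_RETAINED_INTRON} bp")
        oi, intron = introns[int(rng.integers(0, len(introns)))]
        a = blocks[oi]
        b = blocks[oi + 1]
        merged = (
            RefBlock(a.chrom, a.start, b.end, "+")
            if a.strand == "+"
            else RefBlock(a.chrom, b.start, a.end, "-")
        )
        blocks[oi : oi + 2] = [merged]
        size_bp = intron.length
        breakpoints = [GenomicInterval(intron.chrom, intron.start, intron.end)]

    segments = tuple(blocks)
    return VariantTruth(
        variant_id=variant_id,
        vtype=subtype,
        source_transcripts=(tx.id,),
        genes=(tx.gene_id,),
        size_bp=size_bp,
        breakpoints=tuple(breakpoints),
        segments=segments,
        variant_sequence=segments_sequence(segments, store),
    )


# -- benchmark assembly ----------------------------------------------------

# genes consumed per variant of each type
_GENES_PER_VARIANT = {
    t: (1 if t is VariantType.FUSION_UNPARTNERED else 2)
    if t.category is VariantCategory.FUSION
    else 1
    for t in VariantType
}


def genes_required(counts_per_type: int, n_background: int) -> int:
    per_unit = sum(_GENES_PER_VARIANT.values())
    return counts_per_type * per_unit + n_background


def build_benchmark(
    index: AnnotationIndex,
    store: SequenceStore,
    counts_per_type: int,
    n_background: int,
    seed: int = 0,
) -> SimulatedSample:
    """Construct the full benchmark: ``counts_per_type`` variants of each of
    the 15 types plus unaltered background genes.

    Every variant gene contributes its variant sequence and the unaltered
    wild-type transcript to the case reference (heterozygous design); the
    control reference holds wild-type sequence only, for all source
    transcripts, plus the same background genes.
    """
    rng = np.random.default_rng(seed)
    eligible = select_eligible_transcripts(index)
    pool = list(eligible)
    rng.shuffle(pool)
    need = genes_required(counts_per_type, n_background)
    if len(pool) < need:
        raise SimulationInfeasibleError(
            f"need {need} eligible genes, have {len(pool)} "
            f"(shortfall {need - len(pool)})"
        )

    # intergenic loci for unpartnered fusions come from chromosome tails
    tails = []
    for chrom in sorted(store.names()):
        try:
            tails.append(intergenic_tail(index, store, chrom))
        except Exception:
            continue
    if not tails:
        raise SimulationInfeasibleError("no intergenic tail available")

    truths: List[VariantTruth] = []
    pos = 0

    def take() -> Transcript:
        nonlocal pos
        tx = pool[pos]
        pos += 1
        return tx

    for vtype in VariantType:
        for i in range(counts_per_type):
            vid = f"{vtype.value}_{i:04d}"
            for attempt in range(_MAX_TRIES):
                try:
                    if vtype.category is VariantCategory.FUSION:
                        tx_a = take()
                        if vtype is VariantType.FUSION_UNPARTNERED:
                            tail = tails[int(rng.integers(0, len(tails)))]
                            truth = make_fusion(vtype, tx_a, tail, store, index, rng, vid)
                        else:
                            truth = make_fusion(vtype, tx_a, take(), store, index, rng, vid)
                    elif vtype.category is VariantCategory.TSV:
                        truth = make_tsv(vtype, take(), store, rng, vid)
                    else:
                        truth = make_splice_variant(vtype, take(), index, store, rng, vid)
                    truths.append(truth)
                    break
                except SimulationInfeasibleError:
                    if pos >= len(pool) or attempt == _MAX_TRIES - 1:
                        raise
    background = [take() for _ in range(n_background)]

    case_reference: List[Tuple[str, str]] = []
    control_reference: List[Tuple[str, str]] = []
    wt_ids = []
    control_seen = set()
    for truth in truths:
        case_reference.append((truth.variant_id, truth.variant_sequence))
        primary = index.transcript_map[truth.source_transcripts[0]]
        wt_seq = segments_sequence(tx_segments(primary), store)
        case_reference.append((primary.id, wt_seq))
        wt_ids.append(primary.id)
        for tid in truth.source_transcripts:
            if tid not in control_seen:
                control_seen.add(tid)
                tx = index.transcript_map[tid]
                control_reference.append(
                    (tid, segments_sequence(tx_segments(tx), store))
                )
    bg_ids = []
    for tx in background:
        seq = segments_sequence(tx_segments(tx), store)
        case_reference.append((tx.id, seq))
        control_reference.append((tx.id, seq))
        bg_ids.append(tx.id)

    return SimulatedSample(
        case_reference=case_reference,
        control_reference=control_reference,
        truth=truths,
        background_genes=tuple(tx.gene_id for tx in background),
        background_ids=tuple(bg_ids),
        wildtype_ids=tuple(wt_ids),
    )


# -- read simulation -------------------------------------------------------


def simulate_reads(
    reference: Sequence[Tuple[str, str]],
    params: ReadSimParams,
    out1: str,
    out2: str,
    coverage_by_id: Optional[Dict[str, float]] = None,
) -> int:
    """Simulate paired-end reads over each reference sequence.

    Fragments of fixed length are sampled uniformly along each sequence to
    reach the per-sequence target coverage; mate 1 is the fragment 5' end,
    mate 2 the reverse complement of its 3' end. Independent per-base
    substitution errors are applied at ``params.error_rate`` and a constant
    quality string is emitted. Deterministic given ``params.seed``. Returns
    the number of read pairs written.
    """
    rng = np.random.default_rng(params.seed)
    rl, fl = params.read_len, params.fragment_len
    qual = "I" * rl
    n_pairs_total = 0
    with open(out1, "w") as fh1, open(out2, "w") as fh2:
        for sid, seq in reference:
            cov = params.coverage if coverage_by_id is None else coverage_by_id.get(sid, params.coverage)
            L = len(seq)
            if L < fl:
                warnings.warn(
                    f"sequence {sid!r} shorter than fragment length ({L} < {fl}); skipped"
                )
                continue
            n_pairs = int(round(L * cov / (2 * rl)))
            if n_pairs == 0:
                continue
            if params.fragment_jitter:
                fls = fl + rng.integers(
                    -params.fragment_jitter, params.fragment_jitter + 1, n_pairs
                )
                fls = np.clip(fls, rl, L)
            else:
                fls = np.full(n_pairs, fl)
            starts = rng.integers(0, L - fls + 1)
            r1 = [seq[s : s + rl] for s in starts]
            r2 = [
                reverse_complement(seq[s + f - rl : s + f])
                for s, f in zip(starts, fls)
            ]
            if params.error_rate > 0:
                _apply_errors(r1, params.error_rate, rng)
                _apply_errors(r2, params.error_rate, rng)
            lines1 = []
            lines2 = []
            for i in range(n_pairs):
                name = f"{sid}|{n_pairs_total + i}"
                lines1.append(f"@{name}/1\n{r1[i]}\n+\n{qual}")
                lines2.append(f"@{name}/2\n{r2[i]}\n+\n{qual}")
            fh1.write("\n".join(lines1) + "\n")
            fh2.write("\n".join(lines2) + "\n")
            n_pairs_total += n_pairs
    return n_pairs_total


def _apply_errors(reads: List[str], rate: float, rng: np.random.Generator) -> None:
    """In-place substitution errors at the given per-base rate."""
    if not reads:
        return
    rl = len(reads[0])
    total = len(reads) * rl
    k = rng.binomial(total, rate)
    if k == 0:
        return
    flat = rng.integers(0, total, k)
    subs = rng.integers(1, 4, k)  # offset into the 3 alternative bases
    by_read: Dict[int, List[Tuple[int, int]]] = {}
    for f, s in zip(flat.tolist(), subs.tolist()):
        by_read.setdefault(f // rl, []).append((f % rl, s))
    for ri, muts in by_read.items():
        b = bytearray(reads[ri], "ascii")
        for pos, s in muts:
            if pos >= len(b):
                continue
            cur = "ACGT".find(chr(b[pos]))
            if cur < 0:
                continue
            b[pos] = ord("ACGT"[(cur + s) % 4])
        reads[ri] = b.decode("ascii")


# -- truth table I/O -------------------------------------------------------


def write_truth_tsv(truths: Sequence[VariantTruth], path: str) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "variant_id": t.variant_id,
                "vtype": t.vtype.value,
                "genes": ",".join(t.genes),
                "transcripts": ",".join(t.source_transcripts),
                "size_bp": "" if t.size_bp is None else t.size_bp,
                "breakpoints": ";".join(
                    f"{b.chrom}:{b.start}-{b.end}" for b in t.breakpoints
                ),
                "expected_classes": ",".join(sorted(t.expected_classes)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> List[VariantTruth]:
    """Load a truth table written by :func:`write_truth_tsv`.

    Segment/sequence information is not round-tripped; records loaded this
    way support evaluation but not alignment regeneration.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        bps = []
        for part in str(r["breakpoints"]).split(";"):
            if not part:
                continue
            chrom, rest = part.rsplit(":", 1)
            s, e = rest.split("-")
            bps.append(GenomicInterval(chrom, int(s), int(e)))
        out.append(
            VariantTruth(
                variant_id=r["variant_id"],
                vtype=VariantType(r["vtype"]),
                source_transcripts=tuple(r["transcripts"].split(",")),
                genes=tuple(r["genes"].split(",")),
                size_bp=int(r["size_bp"]) if r["size_bp"] else None,
                breakpoints=tuple(bps),
                segments=(),
                variant_sequence="N",  # placeholder; not stored in the TSV
                expected_classes=frozenset(r["expected_classes"].split(",")),
            )
        )
    return out
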