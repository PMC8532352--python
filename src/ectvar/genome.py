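"""Genome/transcriptome data model and standard-format I/O.

All coordinates inside the package are 0-based half-open. Conversion to and
from 1-based inclusive coordinates happens only in the GTF/SAM readers and
writers. Minus-strand transcripts store their exons in genomic order;
transcription order is derived where needed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import BoundsError, GTFParseError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_VALID_BASES = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # compact locus notation used in output tables
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class Transcript:
    """A multi-exon transcript.

    ``exons`` are non-overlapping, sorted by genomic start, and all share one
    chromosome and strand. For minus-strand transcripts the first exon in
    transcription order is the genomically last one.
    """

    id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id} mixes chromosomes/strands")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"transcript {self.id} exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id} has overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_transcription_order(self) -> Tuple[GenomicInterval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns(self) -> Tuple[GenomicInterval, ...]:
        """Introns in genomic order (empty for single-exon transcripts)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def junctions(self) -> Tuple[Tuple[str, int, int, str], ...]:
        """(chrom, left_exon_end, right_exon_start, strand) for consecutive exons."""
        return tuple(
            (self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )


class SequenceStore:
    """In-memory chromosome sequences (uppercase A/C/G/T/N)."""

    def __init__(self, sequences: Optional[Dict[str, str]] = None):
        self._seqs: Dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        seq = seq.upper()
        if _VALID_BASES.search(seq):
            warnings.warn(
                f"sequence {name!r} contains non-ACGTN characters; mapping to N"
            )
            seq = _VALID_BASES.sub("N", seq)
        self._seqs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self):
        return iter(self._seqs)

    def names(self) -> List[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise BoundsError(f"interval {chrom}:{start}-{end} outside sequence")
        return seq[start:end]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        """Sequence of ``iv`` on its own strand (reverse-complemented for '-')."""
        seq = self.fetch(iv.chrom, iv.start, iv.end)
        return seq if iv.strand == "+" else reverse_complement(seq)

    @classmethod
    def from_fasta(cls, path: str) -> "SequenceStore":
        store = cls()
        for rec in SeqIO.parse(path, "fasta"):
            store.add(rec.id, str(rec.seq))
        return store

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in sorted(self._seqs):
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


class AnnotationIndex:
    """Exon/junction/gene lookup built from a set of transcripts.

    This is the "reference" against which novelty is defined: splice
    junctions absent from ``junction_set`` are novel, aligned blocks outside
    ``exon_lookup`` are novel blocks, and loci outside every entry of
    ``gene_extents`` are intergenic.
    """

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcript_map: Dict[str, Transcript] = {}
        self.junction_set: Set[Tuple[str, int, int, str]] = set()
        self.exon_lookup: Dict[str, IntervalTree] = {}
        self.gene_extents: Dict[str, GenomicInterval] = {}
        self._gene_tree: Dict[str, IntervalTree] = {}
        self._junctions_unstranded: Set[Tuple[str, int, int]] = set()
        self._exon_starts: Dict[str, Set[int]] = {}
        self._exon_ends: Dict[str, Set[int]] = {}
        self.gene_transcripts: Dict[str, List[str]] = {}

        gene_bounds: Dict[str, List] = {}
        for tx in transcripts:
            if tx.id in self.transcript_map:
                raise ValueError(f"duplicate transcript id {tx.id!r}")
            self.transcript_map[tx.id] = tx
            self.gene_transcripts.setdefault(tx.gene_id, []).append(tx.id)
            self.junction_set.update(tx.junctions())
            tree = self.exon_lookup.setdefault(tx.chrom, IntervalTree())
            starts = self._exon_starts.setdefault(tx.chrom, set())
            ends = self._exon_ends.setdefault(tx.chrom, set())
            for i, e in enumerate(tx.exons):
                tree.addi(e.start, e.end, (tx.id, i))
                starts.add(e.start)
                ends.add(e.end)
            b = gene_bounds.setdefault(
                tx.gene_id, [tx.chrom, tx.span.start, tx.span.end, tx.strand]
            )
            if b[0] != tx.chrom:
                raise ValueError(f"gene {tx.gene_id} spans chromosomes")
            b[1] = min(b[1], tx.span.start)
            b[2] = max(b[2], tx.span.end)

        for gid, (chrom, start, end, strand) in gene_bounds.items():
            iv = GenomicInterval(chrom, start, end, strand)
            self.gene_extents[gid] = iv
            self._gene_tree.setdefault(chrom, IntervalTree()).addi(start, end, gid)
        self._junctions_unstranded = {
            (c, l, r) for (c, l, r, _s) in self.junction_set
        }

    # -- queries -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AnnotationIndex)
            and self.transcript_map == other.transcript_map
        )

    def transcripts(self) -> List[Transcript]:
        return list(self.transcript_map.values())

    def exons_overlapping(self, chrom: str, start: int, end: int):
        """All (start, end, (tx_id, exon_idx)) exon hits over [start, end)."""
        tree = self.exon_lookup.get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end)]

    def transcripts_at_point(self, chrom: str, pos: int) -> Set[str]:
        tree = self.exon_lookup.get(chrom)
        if tree is None:
            return set()
        return {iv.data[0] for iv in tree.at(pos)}

    def genes_overlapping(self, chrom: str, start: int, end: int) -> Set[str]:
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def has_junction(self, chrom: str, left: int, right: int) -> bool:
        """Strand-agnostic annotated-junction membership."""
        return (chrom, left, right) in self._junctions_unstranded

    def is_exon_start(self, chrom: str, pos: int) -> bool:
        return pos in self._exon_starts.get(chrom, ())

    def is_exon_end(self, chrom: str, pos: int) -> bool:
        return pos in self._exon_ends.get(chrom, ())

    def intron_contains(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies inside an intron of some transcript."""
        for gid in self.genes_overlapping(chrom, start, end):
            for tid in self.gene_transcripts[gid]:
                for intr in self.transcript_map[tid].introns():
                    if intr.start <= start and end <= intr.end:
                        return True
        return False

    def validate_bounds(self, store: SequenceStore) -> None:
        for tx in self.transcript_map.values():
            if tx.chrom not in store:
                raise BoundsError(f"transcript {tx.id}: unknown chrom {tx.chrom}")
            if tx.span.end > store.length(tx.chrom):
                raise BoundsError(
                    f"transcript {tx.id} extends past end of {tx.chrom}"
                )


def transcript_sequence(tx: Transcript, store: SequenceStore) -> str:
    """Spliced transcript sequence in transcription (5'->3') order.

    Exon sequences are concatenated in genomic order and the result is
    reverse-complemented as a whole for minus-strand transcripts.
    """
    genomic = "".join(store.fetch(tx.chrom, e.start, e.end) for e in tx.exons)
    return genomic if tx.strand == "+" else reverse_complement(genomic)


# -- GTF I/O ---------------------------------------------------------------


def read_gtf(path: str, sequence_store: Optional[SequenceStore] = None) -> AnnotationIndex:
    """Parse exon features of a GTF into an :class:`AnnotationIndex`.

    GTF 1-based inclusive coordinates are converted to 0-based half-open at
    parse time. Exon features must carry ``gene_id`` and ``transcript_id``
    attributes.
    """
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils internal failures
        raise GTFParseError(f"failed to parse GTF {path!r}: {exc}") from exc

    by_tx: Dict[str, List[GenomicInterval]] = {}
    tx_gene: Dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        tx_ids = feat.attributes.get("transcript_id")
        if not gene_ids or not tx_ids:
            raise GTFParseError(
                f"exon feature missing gene_id/transcript_id: {str(feat)!r}"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        by_tx.setdefault(tx_ids[0], []).append(iv)
        tx_gene[tx_ids[0]] = gene_ids[0]

    transcripts = [
        Transcript(tid, tx_gene[tid], tuple(sorted(ivs, key=lambda e: e.start)))
        for tid, ivs in by_tx.items()
    ]
    index = AnnotationIndex(transcripts)
    if sequence_store is not None:
        index.validate_bounds(sequence_store)
    return index


def write_gtf(index: AnnotationIndex, path: str, source: str = "ectvar") -> None:
    """Write exon features, sorted, in 1-based inclusive GTF coordinates."""
    lines = []
    for tid in sorted(index.transcript_map):
        tx = index.transcript_map[tid]
        for e in tx.exons:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.id}";'
            lines.append(
                "\t".join(
                    [
                        e.chrom,
                        source,
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        e.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    lines.sort(key=lambda ln: (ln.split("\t")[0], int(ln.split("\t")[3])))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_transcriptome_fasta(
    index: AnnotationIndex, store: SequenceStore, path: str, width: int = 80
) -> None:
    """Spliced sequence of every transcript, sorted by id (deterministic)."""
    with open(path, "w") as fh:
        for tid in sorted(index.transcript_map):
            seq = transcript_sequence(index.transcript_map[tid], store)
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_records_fasta(records: Sequence[Tuple[str, str]], path: str, width: int = 80) -> None:
    """Write (id, sequence) records as FASTA in the given order."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_records(path: str) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
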