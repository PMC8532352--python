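"""Synthetic genome generator.

Produces a random genome with non-overlapping multi-exon genes laid out
sequentially on one or more chromosomes, plus a matching annotation. Every
intron carries canonical GT..AG splice dinucleotides on the transcribed
strand so motif checks can pass, and every chromosome ends in a long
gene-free tail that provides intergenic sequence for unpartnered-fusion
simulation.

Defaults are chosen so that every simulated variant transcript stays at
least one fragment length (300 bp) long: with >=4 exons of >=150 bp, even a
skipped-exon variant that drops all internal exons retains >=300 bp.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .errors import ConfigurationError
from .genome import AnnotationIndex, GenomicInterval, SequenceStore, Transcript

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq_array(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def generate_synthetic_genome(
    n_genes: int,
    exons_per_gene_range: Tuple[int, int] = (4, 8),
    exon_len_range: Tuple[int, int] = (150, 300),
    intron_len_range: Tuple[int, int] = (500, 1200),
    intergenic_gap: int = 2000,
    genes_per_chrom: int = 250,
    chrom_tail: int = 60_000,
    seed: int = 0,
) -> Tuple[SequenceStore, AnnotationIndex]:
    """Generate a deterministic random genome and its annotation.

    Genes are pairwise non-overlapping with at least ``intergenic_gap`` bp
    between consecutive gene extents. One transcript per gene. Returns the
    sequence store and annotation index; use :func:`ectvar.genome.write_gtf`
    and :meth:`SequenceStore.write_fasta` to materialise files.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    for name, (lo, hi) in {
        "exons_per_gene_range": exons_per_gene_range,
        "exon_len_range": exon_len_range,
        "intron_len_range": intron_len_range,
    }.items():
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"infeasible {name}: {(lo, hi)}")
    if exons_per_gene_range[0] < 3:
        raise ConfigurationError("genes need >= 3 exons to be usable for simulation")
    if intron_len_range[0] < 4:
        raise ConfigurationError("introns must fit their splice dinucleotides")
    if intergenic_gap < 1:
        raise ConfigurationError("intergenic_gap must be positive")

    rng = np.random.default_rng(seed)
    chrom_seqs: Dict[str, np.ndarray] = {}
    transcripts = []

    n_chroms = (n_genes + genes_per_chrom - 1) // genes_per_chrom
    gene_no = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        parts = []
        pos = 0
        parts.append(_random_seq_array(rng, intergenic_gap))
        pos += intergenic_gap
        genes_here = min(genes_per_chrom, n_genes - gene_no)
        for _ in range(genes_here):
            gene_no += 1
            gid = f"G{gene_no:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
            exon_lens = rng.integers(
                exon_len_range[0], exon_len_range[1] + 1, n_exons
            )
            intron_lens = rng.integers(
                intron_len_range[0], intron_len_range[1] + 1, n_exons - 1
            )
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            body = _random_seq_array(rng, gene_len)
            exons = []
            off = 0
            for i in range(n_exons):
                exons.append(
                    GenomicInterval(chrom, pos + off, pos + off + int(exon_lens[i]), strand)
                )
                off += int(exon_lens[i])
                if i < n_exons - 1:
                    ilen = int(intron_lens[i])
                    # canonical splice motif on the transcribed strand:
                    # + genes read GT..AG; - genes read GT..AG after revcomp,
                    # which is CT..AC on the genomic forward strand.
                    if strand == "+":
                        body[off : off + 2] = np.frombuffer(b"GT", dtype=np.uint8)
                        body[off + ilen - 2 : off + ilen] = np.frombuffer(b"AG", dtype=np.uint8)
                    else:
                        body[off : off + 2] = np.frombuffer(b"CT", dtype=np.uint8)
                        body[off + ilen - 2 : off + ilen] = np.frombuffer(b"AC", dtype=np.uint8)
                    off += ilen
            parts.append(body)
            pos += gene_len
            parts.append(_random_seq_array(rng, intergenic_gap))
            pos += intergenic_gap
            transcripts.append(Transcript(f"{gid}.1", gid, tuple(exons)))
        parts.append(_random_seq_array(rng, chrom_tail))
        chrom_seqs[chrom] = np.concatenate(parts)

    store = SequenceStore(
        {c: arr.tobytes().decode("ascii") for c, arr in chrom_seqs.items()}
    )
    index = AnnotationIndex(transcripts)
    return store, index


def intergenic_tail(index: AnnotationIndex, store: SequenceStore, chrom: str,
                    margin: int = 10_000) -> GenomicInterval:
    """The gene-free region at the end of ``chrom``, ``margin`` bp clear of genes."""
    last_gene_end = max(
        (iv.end for iv in index.gene_extents.values() if iv.chrom == chrom),
        default=0,
    )
    start = last_gene_end + margin
    end = store.length(chrom)
    if start >= end:
        raise ConfigurationError(f"no intergenic tail on {chrom}")
    return GenomicInterval(chrom, start, end)
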