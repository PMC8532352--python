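"""K-mer pseudo-alignment into equivalence classes.

Assembled contigs are merged with the reference transcriptome into a single
canonical k-mer index (each k-mer is stored as the lexicographic minimum of
itself and its reverse complement, so assignment is orientation-agnostic,
as in conventional pseudo-aligners). Each read end is assigned
independently (single-end semantics, so short contigs are counted
correctly) to the equivalence class (EC) of sequences compatible with it:
the intersection of the id-sets of the read's k-mers that are present in
the index. Absent k-mers are skipped so that sequencing errors do not
destroy the assignment, but at least ``min_frac`` of a read's k-mers must
be present for the read to be assigned at all.

EC counts are matched across samples by membership, and the novel-EC filter
keeps only ECs composed entirely of contigs — the substrate for the
one-vs-rest differential expression step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

DEFAULT_K = 31
DEFAULT_MIN_FRAC = 0.5

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes (2 bits/base) of all valid k-mers of ``seq``.

    K-mers containing non-ACGT characters are dropped. Returns an int64
    array; order follows position in the sequence.
    """
    a = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = a.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(a, k)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ weights
    valid = (win >= 0).all(axis=1)
    return codes[valid]


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-symmetric) k-mer codes: min(code, revcomp code)."""
    a = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = a.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(a, k)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ weights
    rev = (3 - win) @ weights[::-1]
    valid = (win >= 0).all(axis=1)
    return np.minimum(fwd, rev)[valid]


@dataclass
class KmerIndex:
    """Canonical k-mer -> id-set lookup over contigs plus reference
    transcripts."""

    k: int
    table: Dict[int, Tuple[str, ...]]
    id_catalog: Dict[str, Tuple[bool, int]]  # id -> (is_contig, length)

    def is_contig(self, seq_id: str) -> bool:
        return self.id_catalog[seq_id][0]

    @property
    def n_kmers(self) -> int:
        return len(self.table)


def build_index_from_records(
    contigs: Sequence[Tuple[str, str]],
    reference: Sequence[Tuple[str, str]],
    k: int = DEFAULT_K,
) -> KmerIndex:
    """Index every k-mer of every contig and reference transcript.

    Sequence ids must be unique across both collections. Sequences shorter
    than ``k`` are skipped with a warning-free tally (they can never be
    matched).
    """
    if not (11 <= k <= 63) or k % 2 == 0:
        raise ValueError("k must be odd and in [11, 63]")
    catalog: Dict[str, Tuple[bool, int]] = {}
    raw: Dict[int, set] = {}
    for records, is_contig in ((contigs, True), (reference, False)):
        for sid, seq in records:
            if sid in catalog:
                raise ValueError(f"duplicate sequence id {sid!r}")
            catalog[sid] = (is_contig, len(seq))
            if len(seq) < k:
                continue
            for code in canonical_kmer_codes(seq, k).tolist():
                s = raw.get(code)
                if s is None:
                    raw[code] = {sid}
                else:
                    s.add(sid)
    # freeze to interned tuples so identical ECs share one object
    intern: Dict[Tuple[str, ...], Tuple[str, ...]] = {}
    table: Dict[int, Tuple[str, ...]] = {}
    for code, ids in raw.items():
        t = tuple(sorted(ids))
        t = intern.setdefault(t, t)
        table[code] = t
    return KmerIndex(k=k, table=table, id_catalog=catalog)


def build_index(contig_fasta: str, reference_fasta: str, k: int = DEFAULT_K) -> KmerIndex:
    from .genome import read_fasta_records

    return build_index_from_records(
        read_fasta_records(contig_fasta), read_fasta_records(reference_fasta), k
    )


def _orientation_ec(
    codes: List[int], table: Dict[int, Tuple[str, ...]]
) -> Tuple[int, Optional[Tuple[str, ...]]]:
    """(number of present k-mers, intersected EC or None)."""
    get = table.get
    vals = []
    for c in codes:
        v = get(c)
        if v is not None:
            vals.append(v)
    if not vals:
        return 0, None
    first = vals[0]
    for v in vals:
        if v is not first:
            break
    else:
        return len(vals), first
    s = set(first)
    for v in vals:
        if v is not first:
            s.intersection_update(v)
            if not s:
                return len(vals), None
    return len(vals), tuple(sorted(s))


def assign_read(
    read_sequence: str,
    index: KmerIndex,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> Optional[Tuple[str, ...]]:
    """Assign one read end to an equivalence class, or None if unassignable.

    Canonical k-mers make the assignment orientation-agnostic: a read and
    its reverse complement receive the same EC. The read is assigned when
    at least ``min_frac`` of its k-mers are present in the index and the
    intersection of their id-sets is non-empty.
    """
    k = index.k
    if len(read_sequence) < k:
        return None
    return _assign_fast(read_sequence, k, index.table, min_frac)


@dataclass
class ECCountTable:
    """Per-sample EC counts. ``library_size`` is the number of assigned read
    ends, computed before any filtering."""

    sample_id: str
    counts: Dict[Tuple[str, ...], int]
    n_assigned: int = 0
    n_unassigned: int = 0

    @property
    def library_size(self) -> int:
        return self.n_assigned


def count_ecs(
    fastq_paths: Sequence[str],
    index: KmerIndex,
    sample_id: str,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> ECCountTable:
    """Count ECs over one sample's FASTQ file(s).

    Mates are assigned independently (each file is just a stream of read
    ends). Malformed FASTQ raises with the failing record number.
    """
    counts: Dict[Tuple[str, ...], int] = {}
    n_assigned = 0
    n_unassigned = 0
    k = index.k
    table = index.table
    intern: Dict[Tuple[str, ...], Tuple[str, ...]] = {}
    for path in fastq_paths:
        rec_no = 0
        try:
            with pysam.FastxFile(path) as fh:
                for entry in fh:
                    rec_no += 1
                    seq = entry.sequence
                    if seq is None or len(seq) < k:
                        n_unassigned += 1
                        continue
                    ec = _assign_fast(seq, k, table, DEFAULT_MIN_FRAC if min_frac is None else min_frac)
                    if ec is None:
                        n_unassigned += 1
                    else:
                        if len(ec) > 1:
                            ec = intern.setdefault(ec, ec)
                        counts[ec] = counts.get(ec, 0) + 1
                        n_assigned += 1
        except OSError as exc:
            raise ValueError(f"malformed FASTQ {path!r} at record {rec_no + 1}: {exc}")
    return ECCountTable(
        sample_id=sample_id,
        counts=counts,
        n_assigned=n_assigned,
        n_unassigned=n_unassigned,
    )


def _assign_fast(
    seq: str, k: int, table: Dict[int, Tuple[str, ...]], min_frac: float
) -> Optional[Tuple[str, ...]]:
    codes = canonical_kmer_codes(seq, k)
    n_present, ec = _orientation_ec(codes.tolist(), table)
    if ec is None or n_present < min_frac * (len(seq) - k + 1):
        return None
    return ec


@dataclass
class MatchedECMatrix:
    """EC x sample count matrix with per-sample library sizes."""

    ec_list: List[Tuple[str, ...]]
    matrix: np.ndarray  # shape (n_ecs, n_samples), int64
    sample_ids: List[str]
    library_sizes: np.ndarray  # shape (n_samples,)
    case_index: int

    @property
    def n_ecs(self) -> int:
        return len(self.ec_list)

    def case_counts(self) -> np.ndarray:
        return self.matrix[:, self.case_index]

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.matrix, columns=self.sample_ids)
        df.insert(0, "ec_members", [",".join(ec) for ec in self.ec_list])
        with open(path, "w") as fh:
            fh.write("# case_sample=" + self.sample_ids[self.case_index] + "\n")
            fh.write(
                "# library_sizes="
                + ",".join(str(int(x)) for x in self.library_sizes)
                + "\n"
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "MatchedECMatrix":
        with open(path) as fh:
            case_line = fh.readline().strip()
            lib_line = fh.readline().strip()
            df = pd.read_csv(fh, sep="\t")
        case_sample = case_line.split("=", 1)[1]
        libs = np.array([int(x) for x in lib_line.split("=", 1)[1].split(",")])
        sample_ids = list(df.columns[1:])
        ecs = [tuple(m.split(",")) for m in df["ec_members"]]
        return cls(
            ec_list=ecs,
            matrix=df[sample_ids].to_numpy(dtype=np.int64),
            sample_ids=sample_ids,
            library_sizes=libs,
            case_index=sample_ids.index(case_sample),
        )


def match_ecs(tables: Sequence[ECCountTable], case_sample_id: str) -> MatchedECMatrix:
    """Match ECs across samples by membership.

    An EC with identical membership in two samples occupies a single row;
    counts are zero where a sample never observed the EC.
    """
    if not tables:
        raise ValueError("need at least one EC table")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    if case_sample_id not in ids:
        raise ValueError(f"case sample {case_sample_id!r} not among tables")
    all_ecs = sorted(set().union(*(t.counts.keys() for t in tables)))
    ec_row = {ec: i for i, ec in enumerate(all_ecs)}
    mat = np.zeros((len(all_ecs), len(tables)), dtype=np.int64)
    for j, t in enumerate(tables):
        for ec, c in t.counts.items():
            mat[ec_row[ec], j] = c
    return MatchedECMatrix(
        ec_list=all_ecs,
        matrix=mat,
        sample_ids=ids,
        library_sizes=np.array([t.library_size for t in tables], dtype=np.int64),
        case_index=ids.index(case_sample_id),
    )


def filter_novel_ecs(matrix: MatchedECMatrix, index: KmerIndex) -> MatchedECMatrix:
    """Keep only ECs whose every member is a contig (novel ECs).

    Library sizes are left untouched: they were computed before filtering
    and stay on the pre-filter scale.
    """
    catalog = index.id_catalog
    keep = []
    for i, ec in enumerate(matrix.ec_list):
        for m in ec:
            if m not in catalog:
                raise ValueError(f"EC member {m!r} missing from index catalog")
        if all(catalog[m][0] for m in ec):
            keep.append(i)
    return MatchedECMatrix(
        ec_list=[matrix.ec_list[i] for i in keep],
        matrix=matrix.matrix[keep, :] if keep else np.zeros((0, len(matrix.sample_ids)), dtype=np.int64),
        sample_ids=list(matrix.sample_ids),
        library_sizes=matrix.library_sizes.copy(),
        case_index=matrix.case_index,
    )
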