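"""Paired-end amplicon read QC and OTU table construction.

Implements the read-processing rules used throughout the pipeline:
quality truncation at the first base with Q <= 2, ungapped overlap
merging with a 50 bp minimum, a length > 399 bp / expected-error <= 0.5
keep rule, exact dereplication with singleton discard, greedy 97%
centroid clustering (UPARSE-style, chimera detection is a no-op hook)
and global-alignment read mapping back onto centroids.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import edlib
import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import OtuTable

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass
class FastqRead:
    """A single read: bases over {A,C,G,T,N} and per-base Phred scores."""

    id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass
class MergedRead:
    id: str
    bases: str
    quals: np.ndarray
    overlap_len: int

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass
class UniqueSeq:
    sequence: str
    size: int


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------- FASTQ IO


def read_fastq(path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            FastqRead(
                id=rec.id,
                bases=str(rec.seq),
                quals=np.array(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ------------------------------------------------------------- quality QC


def truncate_at_quality(read: FastqRead, qmax: int = 2) -> FastqRead:
    """Truncate at the first base whose Q value is <= ``qmax``.

    Returns the prefix ending just before that base; the whole read if
    no base triggers. The result may be empty.
    """
    hits = np.nonzero(read.quals <= qmax)[0]
    if hits.size == 0:
        return read
    cut = int(hits[0])
    return FastqRead(id=read.id, bases=read.bases[:cut], quals=read.quals[:cut])


def expected_error(quals) -> float:
    """Expected number of errors: sum of 10^(-Q/10) over bases."""
    quals = np.asarray(quals, dtype=float)
    if quals.size and quals.min() < 0:
        raise ValueError("Phred scores must be non-negative")
    return float(np.sum(10.0 ** (-quals / 10.0)))


def merge_pair(
    fwd: FastqRead,
    rev: FastqRead,
    min_overlap: int = 50,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge a read pair by ungapped overlap of fwd and revcomp(rev).

    Among offsets whose overlap mismatch fraction is within
    ``max_mismatch_frac``, the one maximising the number of matching
    positions is chosen (ties prefer the longer overlap, then the
    leftmost offset); a long but essentially random overlap can never
    outvote the true one this way. The merge succeeds only if a
    feasible offset exists and its overlap is at least ``min_overlap``.
    In the overlap the base with the higher Q is kept along with its Q;
    ties keep the forward base.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(fwd) == 0 or len(rev) == 0:
        return None
    r_bases = reverse_complement(rev.bases)
    r_quals = rev.quals[::-1]
    f = np.frombuffer(fwd.bases.encode(), dtype=np.uint8)
    r = np.frombuffer(r_bases.encode(), dtype=np.uint8)
    m, n = len(f), len(r)

    best = None  # (matches, overlap, -offset)
    best_parts = None
    for s in range(-(n - 1), m):
        lo_f, hi_f = max(0, s), min(m, s + n)
        if hi_f <= lo_f:
            continue
        seg_f = f[lo_f:hi_f]
        seg_r = r[lo_f - s : hi_f - s]
        matches = int((seg_f == seg_r).sum())
        overlap = hi_f - lo_f
        if (overlap - matches) / overlap > max_mismatch_frac:
            continue
        key = (matches, overlap, -s)
        if best is None or key > best:
            best = key
            best_parts = (s, overlap, matches)
    if best_parts is None:
        return None
    s, overlap, matches = best_parts
    if overlap < min_overlap:
        return None

    lo = min(0, s)
    hi = max(m, s + n)
    out_b = np.zeros(hi - lo, dtype=np.uint8)
    out_q = np.full(hi - lo, -1, dtype=np.int64)
    # forward read occupies [0, m); reverse occupies [s, s+n)
    out_b[-lo : -lo + m] = f
    out_q[-lo : -lo + m] = fwd.quals
    r_slice = slice(s - lo, s - lo + n)
    r_region_q = out_q[r_slice]
    take_rev = r_quals > r_region_q  # strict: ties keep forward base
    out_b[r_slice] = np.where(take_rev, r, out_b[r_slice])
    out_q[r_slice] = np.where(take_rev, r_quals, r_region_q)
    return MergedRead(
        id=fwd.id,
        bases=out_b.tobytes().decode(),
        quals=out_q,
        overlap_len=overlap,
    )


def qc_filter_reads(merged, min_len: int = 400, max_ee: float = 0.5):
    """Keep merged reads with length >= ``min_len`` and EE <= ``max_ee``."""
    return [
        r
        for r in merged
        if len(r) >= min_len and expected_error(r.quals) <= max_ee
    ]


def process_pairs(
    fwd_reads,
    rev_reads,
    qmax: int = 2,
    min_overlap: int = 50,
    max_mismatch_frac: float = 0.1,
    min_len: int = 400,
    max_ee: float = 0.5,
):
    """Run truncation, merging and the length/EE filter on read pairs.

    Returns the passing merged reads plus a per-read-id pass/fail map
    (a pair fails if truncation empties a mate, merging fails, or the
    merged read fails the length/EE rule).
    """
    passing = []
    decisions: dict[str, bool] = {}
    for fwd, rev in zip(fwd_reads, rev_reads, strict=True):
        f = truncate_at_quality(fwd, qmax=qmax)
        r = truncate_at_quality(rev, qmax=qmax)
        merged = merge_pair(
            f, r, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac
        )
        ok = False
        if merged is not None:
            ok = (
                len(merged) >= min_len
                and expected_error(merged.quals) <= max_ee
            )
        decisions[fwd.id] = ok
        if ok:
            passing.append(merged)
    return passing, decisions


# --------------------------------------------- dereplication and clustering


def _sequence_of(read) -> str:
    return read if isinstance(read, str) else read.bases


def dereplicate(reads) -> list[UniqueSeq]:
    """Group identical sequences, discard singletons, sort by abundance.

    Ties in abundance are broken by lexicographic sequence order so the
    output is deterministic.
    """
    counts = Counter(_sequence_of(r) for r in reads)
    uniques = [
        UniqueSeq(sequence=s, size=c) for s, c in counts.items() if c >= 2
    ]
    uniques.sort(key=lambda u: (-u.size, u.sequence))
    return uniques


def remove_chimeras(uniques: list[UniqueSeq]) -> list[UniqueSeq]:
    """Chimera-removal hook; intentionally a no-op pass-through."""
    return uniques


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=-1.0,
    open_gap_score=-2.0,
    extend_gap_score=-0.5,
)


def _screened_identity(a: str, b: str, threshold: float) -> float:
    """Identity, short-circuited when it provably falls below ``threshold``.

    Any global alignment with edit distance d has at most C - d matches
    over C >= max(len) columns, so identity <= 1 - d/(len(a) + len(b));
    when that bound is already under the threshold the exact aligner is
    skipped and the bound returned (only its sub-threshold status is
    ever used by callers).
    """
    if a == b:
        return 1.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    bound = 1.0 - d / (len(a) + len(b))
    if bound < threshold:
        return bound
    return global_identity(a, b)


def global_identity(a: str, b: str) -> float:
    """Pairwise identity: matches / alignment columns, terminal gaps excluded."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    start = 0
    end = len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(1 for x, y in zip(s1[start:end], s2[start:end]) if x == y)
    return matches / (end - start)


def cluster_otus(
    uniques: list[UniqueSeq], identity: float = 0.97
) -> list[UniqueSeq]:
    """Greedy centroid clustering of abundance-sorted unique sequences.

    Scanning in order, each sequence joins the first existing centroid
    with global identity >= ``identity``; otherwise it founds a new
    centroid. Returned centroids carry the summed member abundance.
    """
    centroids: list[UniqueSeq] = []
    for u in uniques:
        placed = False
        for c in centroids:
            if _screened_identity(u.sequence, c.sequence, identity) >= identity:
                c.size += u.size
                placed = True
                break
        if not placed:
            centroids.append(UniqueSeq(sequence=u.sequence, size=u.size))
    return centroids


def map_reads(
    reads,
    centroids,
    identity: float = 0.97,
    sample_id: str = "sample",
    group: str = "unknown",
    day: int = 0,
    subject: str | None = None,
) -> OtuTable:
    """Assign reads to their best-identity centroid at a 97% cutoff.

    Reads below the cutoff against every centroid are dropped. Identity
    ties go to the more abundant centroid, then to the earlier one.
    Returns a single-sample OtuTable with centroids as OTU columns.
    """
    if not centroids:
        raise ValueError("centroids must be non-empty")
    cents = [
        c if isinstance(c, UniqueSeq) else UniqueSeq(sequence=c, size=0)
        for c in centroids
    ]
    counts = np.zeros(len(cents), dtype=np.int64)
    for read in reads:
        seq = _sequence_of(read)
        best_key = None
        best_idx = None
        for i, c in enumerate(cents):
            ident = _screened_identity(seq, c.sequence, identity)
            key = (ident, c.size, -i)
            if best_key is None or key > best_key:
                best_key, best_idx = key, i
        if best_key[0] >= identity:
            counts[best_idx] += 1
    otu_ids = [f"OTU{i + 1:03d}" for i in range(len(cents))]
    counts_df = pd.DataFrame(
        [counts], index=[sample_id], columns=otu_ids
    )
    metadata = pd.DataFrame(
        {
            "group": [group],
            "day": [day],
            "subject": [subject or sample_id],
        },
        index=[sample_id],
    )
    return OtuTable(counts=counts_df, metadata=metadata)
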