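"""Merge 3'-overlapping paired-end reads into high-quality consensus
fragments, removing adapter read-through.

For a pair with reads of length R drawn from an insert of length L:
the two mates overlap over ``min(R, L) - max(0, L - R)`` bases; when
L < R both reads run through the insert into the adapter.  The merger scans
candidate insert lengths, scores each by matches-minus-mismatches over the
overlapping insert region, and accepts the best candidate when the overlap
is long enough and clean enough.  Consensus bases where the mates agree get
the summed phred quality (capped at 93); at disagreements the higher-quality
base wins with quality |q1 - q2|.  Bases 3' of the insert end (adapter
read-through) are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .codons import reverse_complement

QUALITY_CAP = 93
DEFAULT_MIN_OVERLAP = 25
DEFAULT_MAX_MISMATCH_FRACTION = 0.05


@dataclass
class ReadPair:
    id: str
    read1: str
    qual1: list[int]
    read2: str
    qual2: list[int]

    def __post_init__(self):
        if len(self.read1) != len(self.qual1) or len(self.read2) != len(self.qual2):
            raise ValueError(f"read/quality length mismatch in pair {self.id}")


@dataclass
class MergedRead:
    id: str
    sequence: str
    quality: list[int]
    overlap_length: int
    source: str


@dataclass
class MergeStats:
    n_pairs: int
    n_merged: int
    fraction_merged: float
    mean_merged_length: float
    mean_merged_phred: float
    mean_unmerged_phred: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


def _overlap_coords(L: int, r1_len: int, r2_len: int):
    """Insert positions covered by both mates for insert length L."""
    lo = max(0, L - r2_len)
    hi = min(r1_len, L)
    return lo, hi


def merge_read_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> MergedRead | None:
    """Merge one pair, or return None ("unmerged").

    Read 2 is reverse-complemented, then every candidate insert length is
    scored by matches-minus-mismatches over the overlap; the best candidate
    is accepted iff overlap >= min_overlap and its mismatch fraction (N
    counts as mismatch) is <= max_mismatch_fraction.  Ties are broken toward
    the longer overlap, then toward the shorter insert (the full
    read-through interpretation).
    """
    r1, r2 = pair.read1, pair.read2
    if not r1 or not r2:
        return None
    rc2 = reverse_complement(r2)
    q2r = pair.qual2[::-1]
    len1, len2 = len(r1), len(r2)
    a1 = np.frombuffer(r1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    n_code = ord("N")
    best = None  # key=(score, overlap, -L)
    for L in range(min_overlap, len1 + len2 - min_overlap + 1):
        lo, hi = _overlap_coords(L, len1, len2)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        off = L - len2  # insert position p sits at rc2 index p - off
        s1 = a1[lo:hi]
        s2 = a2[lo - off : hi - off]
        matches = int(np.count_nonzero((s1 == s2) & (s1 != n_code)))
        mismatches = overlap - matches
        key = (matches - mismatches, overlap, -L)
        if best is None or key > best[0]:
            best = (key, L, overlap, mismatches)
    if best is None:
        return None
    _, L, overlap, mismatches = best
    if mismatches / overlap > max_mismatch_fraction:
        return None
    if best[0][0] <= 0:  # an all-N or all-mismatch overlap is no evidence
        return None

    off = L - len(r2)
    seq = []
    qual = []
    for p in range(L):
        in1 = p < len(r1)
        in2 = 0 <= p - off < len(rc2)
        if in1 and in2:
            a, qa = r1[p], pair.qual1[p]
            b, qb = rc2[p - off], q2r[p - off]
            if a == "N":
                qa = 0
            if b == "N":
                qb = 0
            if a == b:
                seq.append(a)
                qual.append(min(qa + qb, QUALITY_CAP))
            elif qa >= qb:
                seq.append(a)
                qual.append(qa - qb)
            else:
                seq.append(b)
                qual.append(qb - qa)
        elif in1:
            seq.append(r1[p])
            qual.append(pair.qual1[p])
        else:
            seq.append(rc2[p - off])
            qual.append(q2r[p - off])
    return MergedRead(
        id=pair.id,
        sequence="".join(seq),
        quality=qual,
        overlap_length=overlap,
        source=pair.id,
    )


def merge_set(
    pairs,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
):
    """Merge an iterable of ReadPairs.

    Returns (merged, unmerged, MergeStats); unmerged pairs are passed through
    unchanged for optional downstream use.
    """
    merged: list[MergedRead] = []
    unmerged: list[ReadPair] = []
    for pair in pairs:
        m = merge_read_pair(pair, min_overlap, max_mismatch_fraction)
        if m is None:
            unmerged.append(pair)
        else:
            merged.append(m)
    n = len(merged) + len(unmerged)
    merged_bases = sum(len(m.quality) for m in merged)
    unmerged_bases = sum(len(p.qual1) + len(p.qual2) for p in unmerged)
    stats = MergeStats(
        n_pairs=n,
        n_merged=len(merged),
        fraction_merged=len(merged) / n if n else 0.0,
        mean_merged_length=(
            sum(len(m.sequence) for m in merged) / len(merged) if merged else 0.0
        ),
        mean_merged_phred=(
            sum(sum(m.quality) for m in merged) / merged_bases if merged_bases else 0.0
        ),
        mean_unmerged_phred=(
            sum(sum(p.qual1) + sum(p.qual2) for p in unmerged) / unmerged_bases
            if unmerged_bases
            else 0.0
        ),
    )
    return merged, unmerged, stats


# ---------------------------------------------------------------------------
# FASTQ IO
# ---------------------------------------------------------------------------


def read_paired_fastq(path_r1, path_r2) -> list[ReadPair]:
    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(path_r1), "fastq"), SeqIO.parse(str(path_r2), "fastq")
    ):
        pairs.append(
            ReadPair(
                id=rec1.id.removesuffix("/1"),
                read1=str(rec1.seq).upper(),
                qual1=list(rec1.letter_annotations["phred_quality"]),
                read2=str(rec2.seq).upper(),
                qual2=list(rec2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def read_interleaved_fastq(path) -> list[ReadPair]:
    records = list(SeqIO.parse(str(path), "fastq"))
    if len(records) % 2:
        raise ValueError("interleaved FASTQ has an odd number of records")
    pairs = []
    for rec1, rec2 in zip(records[0::2], records[1::2]):
        pairs.append(
            ReadPair(
                id=rec1.id.removesuffix("/1"),
                read1=str(rec1.seq).upper(),
                qual1=list(rec1.letter_annotations["phred_quality"]),
                read2=str(rec2.seq).upper(),
                qual2=list(rec2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_merged_fastq(merged, path) -> None:
    with open(path, "w") as fh:
        for m in merged:
            q = "".join(chr(min(v, QUALITY_CAP) + 33) for v in m.quality)
            fh.write(f"@{m.id}\n{m.sequence}\n+\n{q}\n")


def read_merged_fastq(path) -> list[MergedRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            MergedRead(
                id=rec.description,
                sequence=str(rec.seq).upper(),
                quality=list(rec.letter_annotations["phred_quality"]),
                overlap_length=0,
                source=rec.description,
            )
        )
    return out


def write_unmerged_fastq(unmerged, path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in unmerged:
            f1.write(
                f"@{p.id}/1\n{p.read1}\n+\n"
                + "".join(chr(min(q, QUALITY_CAP) + 33) for q in p.qual1)
                + "\n"
            )
            f2.write(
                f"@{p.id}/2\n{p.read2}\n+\n"
                + "".join(chr(min(q, QUALITY_CAP) + 33) for q in p.qual2)
                + "\n"
            )
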