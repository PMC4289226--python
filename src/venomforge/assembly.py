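"""Transcript assembly and curation.

Two assembly routes over merged reads — greedy exact-overlap seed extension
and reference-guided majority-vote consensus — followed by duplicate
collapsing, single-linkage clustering of toxin coding sequences at <1%
nucleotide divergence, chimera screening (coverage evenness + mosaic
parent-matching), and keyword-based toxin annotation with cluster-aware
names (class abbreviation, cluster number, lower-case member letter,
e.g. ``3FTx-9a``).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codons import is_valid_cds, reverse_complement, translate_cds

EXTENSION_SAFETY_CAP = 30_000  # longest expected venom transcript ~5 kb
CHIMERA_WINDOW = 100  # nt, coverage-evenness sliding window
MOSAIC_WINDOW = 60  # nt, parent-assignment window
EVENNESS_CUTOFF = 0.1
MOSAIC_SEGMENT_IDENTITY = 0.95

_MEMBER_LETTERS = "abcdefghijklmnopqrstuvwxyz"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    id: str
    sequence: str
    cds_span: tuple[int, int]  # 0-based half-open
    class_label: str = "nontoxin"
    cluster_id: str | None = None
    provenance: str = ""
    abundance: float = 0.0

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_span[0] : self.cds_span[1]]

    def validate(self) -> None:
        cds = self.cds
        if not is_valid_cds(cds):
            raise ValueError(f"transcript {self.id}: CDS is not complete/valid")

    @property
    def protein(self) -> str:
        return translate_cds(self.cds)[:-1]


@dataclass
class ToxinCluster:
    name: str  # CLASS-number, e.g. SVMPIII-2
    members: list[str]  # member transcript names, letter-suffixed
    representative: str
    member_sources: dict[str, str] = field(default_factory=dict)


@dataclass
class ChimeraVerdict:
    transcript_id: str
    is_chimera: bool
    parents: list[tuple[str, tuple[int, int]]]
    evenness: float
    breakpoint: int | None


@dataclass
class ReferenceProtein:
    id: str
    sequence: str
    description: str
    class_label: str


# ---------------------------------------------------------------------------
# Greedy seed extension
# ---------------------------------------------------------------------------


def _read_seq_qual(read):
    if hasattr(read, "sequence"):
        return read.sequence, getattr(read, "quality", None)
    return read, None


def _extend_right(contig: str, index, min_overlap: int) -> str | None:
    """One extension step at the 3' end; returns the new contig or None."""
    best_added = 0
    best_read = None
    c = len(contig)
    max_o = min(c, index["max_len"])
    for o in range(min_overlap, max_o + 1):
        key = contig[c - o : c - o + min_overlap]
        for read in index["by_prefix"].get(key, ()):
            if len(read) <= o:
                continue
            if read[:o] == contig[c - o :]:
                added = len(read) - o
                if added > best_added or (
                    added == best_added and best_read is not None and read < best_read
                ):
                    best_added = added
                    best_read = read
    if best_read is None or best_added == 0:
        return None
    return contig + best_read[-best_added:]


def extend_seed(
    seed: str,
    reads,
    min_overlap: int = 100,
    min_phred: int = 30,
    safety_cap: int = EXTENSION_SAFETY_CAP,
) -> str:
    """Greedy bidirectional exact-overlap extension of a seed sequence.

    A read may extend the contig only if it overlaps a contig end by at
    least `min_overlap` exactly matching bases and every base of the read
    has phred >= `min_phred`.  Each step appends the eligible read that adds
    the most new bases; extension stops when no read qualifies or the
    contig exceeds the safety cap.  The seed always remains an exact
    substring of the output.
    """
    if len(seed) < min_overlap:
        raise ValueError(
            f"seed length {len(seed)} is below the minimum overlap {min_overlap}"
        )
    pool = []
    for r in reads:
        seq, qual = _read_seq_qual(r)
        if qual is not None and any(q < min_phred for q in qual):
            continue
        if len(seq) < min_overlap:
            continue
        pool.append(seq)
        pool.append(reverse_complement(seq))
    index = {"by_prefix": defaultdict(list), "max_len": 0}
    for seq in pool:
        index["by_prefix"][seq[:min_overlap]].append(seq)
        index["max_len"] = max(index["max_len"], len(seq))

    contig = seed
    while len(contig) < safety_cap:
        grown = False
        nxt = _extend_right(contig, index, min_overlap)
        if nxt is not None:
            contig = nxt
            grown = True
        # left end: extend the reverse complement rightward
        rc = reverse_complement(contig)
        nxt = _extend_right(rc, index, min_overlap)
        if nxt is not None:
            contig = reverse_complement(nxt)
            grown = True
        if not grown:
            break
    return contig


# ---------------------------------------------------------------------------
# Reference-guided consensus
# ---------------------------------------------------------------------------


def _kmer_index(references, k: int):
    # every reference position is indexed so that query k-mers sampled at
    # stride k are guaranteed to hit regardless of alignment offset
    index = defaultdict(set)
    for ri, ref in enumerate(references):
        seq = ref.sequence
        for i in range(0, max(1, len(seq) - k + 1)):
            index[seq[i : i + k]].add(ri)
    return index


def _align_read(read_seq: str, ref_seq: str):
    """Infix alignment; returns (identity, start, end) on the reference."""
    res = edlib.align(read_seq, ref_seq, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return 0.0, 0, 0
    identity = 1.0 - res["editDistance"] / len(read_seq)
    start, end = res["locations"][0]
    return identity, start, end + 1


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pileup(read_seq: str, ref_seq: str, start: int, counts: np.ndarray) -> None:
    """Add one read's bases to the per-position base-count matrix using the
    edlib alignment path (substitution-dominated data; indel columns are
    consumed without votes)."""
    res = edlib.align(
        read_seq, ref_seq[start : start + len(read_seq) + 8], mode="HW", task="path"
    )
    loc = res["locations"][0]
    rpos = start + loc[0]
    qpos = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        if op in "=XM":
            for j in range(n):
                base = read_seq[qpos + j]
                if base in _BASE_IDX and rpos + j < counts.shape[0]:
                    counts[rpos + j, _BASE_IDX[base]] += 1
            qpos += n
            rpos += n
        elif op == "I":
            qpos += n
        elif op == "D":
            rpos += n


def reference_consensus(
    reads,
    references: list[Transcript],
    min_identity: float = 0.85,
    min_coverage: int = 5,
    k: int = 21,
) -> list[Transcript]:
    """Reference-guided majority-vote consensus assembly.

    Reads are assigned to the reference they match best (k-mer-seeded,
    identity >= `min_identity` over the read, forward or reverse strand);
    a consensus is kept only if depth >= `min_coverage` at every CDS
    position, and UTR flanks with depth < `min_coverage` are trimmed.
    """
    for ref in references:
        if ref.cds_span is None:
            raise ValueError(f"reference {ref.id} lacks a CDS span")
    index = _kmer_index(references, k)
    counts = [np.zeros((len(r.sequence), 4), dtype=np.int32) for r in references]
    for read in reads:
        seq, _ = _read_seq_qual(read)
        candidates = set()
        for strand_seq in (seq, reverse_complement(seq)):
            for i in range(0, max(1, len(strand_seq) - k + 1), k):
                candidates |= index.get(strand_seq[i : i + k], set())
        best = None
        for ri in candidates:
            for strand_seq in (seq, reverse_complement(seq)):
                ident, start, _ = _align_read(strand_seq, references[ri].sequence)
                if ident >= min_identity and (best is None or ident > best[0]):
                    best = (ident, ri, strand_seq, start)
        if best is not None:
            _, ri, strand_seq, start = best
            _pileup(strand_seq, references[ri].sequence, start, counts[ri])

    out: list[Transcript] = []
    for ref, cnt in zip(references, counts):
        depth = cnt.sum(axis=1)
        lo, hi = ref.cds_span
        if (depth[lo:hi] < min_coverage).any():
            continue
        consensus = np.array(list(ref.sequence))
        covered = depth > 0
        consensus[covered] = np.array(list("ACGT"))[cnt.argmax(axis=1)[covered]]
        # trim low-coverage UTR flanks
        left = 0
        while left < lo and depth[left] < min_coverage:
            left += 1
        right = len(consensus)
        while right > hi and depth[right - 1] < min_coverage:
            right -= 1
        out.append(
            Transcript(
                id=ref.id,
                sequence="".join(consensus[left:right]),
                cds_span=(lo - left, hi - left),
                class_label=ref.class_label,
                cluster_id=ref.cluster_id,
                provenance="reference_consensus",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def deduplicate(transcripts: list[Transcript]) -> list[Transcript]:
    """Collapse exact-duplicate CDSs and CDSs contained verbatim inside a
    longer transcript, keeping the longest sequence; output is in stable id
    order."""
    ranked = sorted(transcripts, key=lambda t: (-len(t.sequence), t.id))
    kept: list[Transcript] = []
    for t in ranked:
        if any(t.cds in other.sequence for other in kept):
            continue
        kept.append(t)
    return sorted(kept, key=lambda t: t.id)


# ---------------------------------------------------------------------------
# Clustering at <1% CDS divergence
# ---------------------------------------------------------------------------

_nuc_aligner = Align.PairwiseAligner()
_nuc_aligner.mode = "global"
_nuc_aligner.match_score = 1
_nuc_aligner.mismatch_score = -1
_nuc_aligner.open_gap_score = -3
_nuc_aligner.extend_gap_score = -1


def pairwise_divergence(a: str, b: str) -> float:
    """Mismatches / aligned non-gap columns of a global pairwise alignment."""
    if a == b:
        return 0.0
    alignment = _nuc_aligner.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    mism = total = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        total += 1
        mism += x != y
    return mism / total if total else 1.0


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def cluster_toxins(
    transcripts: list[Transcript], threshold: float = 0.01
) -> list[ToxinCluster]:
    """Single-linkage clustering of CDSs at divergence strictly < threshold.

    Clusters are numbered per class by descending total abundance (input
    order when abundances are absent); members are lettered a, b, c... by
    descending abundance.  Singleton clusters get no member letter, matching
    the naming scheme used in the expression tables.
    """
    if not transcripts:
        return []
    n = len(transcripts)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_divergence(transcripts[i].cds, transcripts[j].cds) < threshold:
                uf.union(i, j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[uf.find(i)].append(i)

    def total_abundance(idxs):
        return sum(transcripts[i].abundance for i in idxs)

    ordered = sorted(
        groups.values(),
        key=lambda idxs: (-total_abundance(idxs), min(idxs)),
    )
    per_class_counter: Counter = Counter()
    clusters: list[ToxinCluster] = []
    for idxs in ordered:
        classes = Counter(transcripts[i].class_label for i in idxs)
        class_label = classes.most_common(1)[0][0]
        per_class_counter[class_label] += 1
        name = f"{class_label}-{per_class_counter[class_label]}"
        members_sorted = sorted(
            idxs, key=lambda i: (-transcripts[i].abundance, transcripts[i].id)
        )
        member_names = []
        sources = {}
        for rank, i in enumerate(members_sorted):
            suffix = _MEMBER_LETTERS[rank] if len(members_sorted) > 1 else ""
            member_names.append(name + suffix)
            sources[name + suffix] = transcripts[i].id
        clusters.append(
            ToxinCluster(
                name=name,
                members=member_names,
                representative=member_names[0],
                member_sources=sources,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Chimera screening
# ---------------------------------------------------------------------------


def _mosaic_scan(candidate: Transcript, toxin_db: list[Transcript], window: int):
    """Best single-breakpoint two-parent partition of the candidate.

    Returns (found, parents, breakpoint) where each segment matches its
    parent over >= MOSAIC_SEGMENT_IDENTITY of its length and the parents
    are distinct.
    """
    seq = candidate.sequence
    others = [t for t in toxin_db if t.id != candidate.id]
    if len(others) < 2 or len(seq) < 2 * window:
        return False, [], None

    def seg_identity(segment: str, parent: Transcript) -> float:
        ident, _, _ = _align_read(segment, parent.sequence)
        return ident

    n_windows = len(seq) // window
    best = None
    for b in range(1, n_windows):
        bp = b * window
        left, right = seq[:bp], seq[bp:]
        left_best = max(others, key=lambda p: seg_identity(left, p))
        right_best = max(others, key=lambda p: seg_identity(right, p))
        if left_best.id == right_best.id:
            continue
        li = seg_identity(left, left_best)
        ri = seg_identity(right, right_best)
        if li >= MOSAIC_SEGMENT_IDENTITY and ri >= MOSAIC_SEGMENT_IDENTITY:
            score = li + ri
            if best is None or score > best[0]:
                best = (score, left_best.id, right_best.id, bp)
    if best is None:
        return False, [], None
    _, pa, pb, bp = best
    return True, [(pa, (0, bp)), (pb, (bp, len(seq)))], bp


def coverage_evenness(depth: np.ndarray, window: int = CHIMERA_WINDOW) -> float:
    """min sliding-window mean depth / overall median depth.

    Windows overlapping the first/last window-length of the sequence are
    ignored when the sequence is long enough: coverage always ramps down at
    transcript ends and that taper is not evidence of chimerism.
    """
    med = float(np.median(depth))
    if med <= 0:
        return 0.0
    if len(depth) <= 3 * window:
        return float(depth.mean()) / med
    interior = depth[window : len(depth) - window]
    csum = np.concatenate([[0.0], np.cumsum(interior)])
    win_means = (csum[window:] - csum[:-window]) / window
    return float(win_means.min()) / med


def detect_chimeras(
    candidates: list[Transcript],
    reads,
    toxin_db: list[Transcript],
    remap_identity: float = 0.98,
) -> list[ChimeraVerdict]:
    """Screen candidate transcripts for chimerism.

    Test (a): remap reads at high stringency and flag extremely uneven
    coverage (evenness statistic U < 0.1).  Test (b): look for a single
    breakpoint splitting the candidate into two segments each matching a
    distinct database parent almost exactly.  A candidate is called a
    chimera only when a two-parent partition exists; uneven coverage alone
    (test a) is corroborating evidence, and low-but-even coverage never
    triggers a call.
    """
    read_seqs = [_read_seq_qual(r)[0] for r in reads]
    verdicts = []
    for cand in candidates:
        window = MOSAIC_WINDOW if len(cand.sequence) >= MOSAIC_WINDOW else max(
            1, len(cand.sequence) // 2
        )
        depth = np.zeros(len(cand.sequence))
        if len(cand.sequence) >= CHIMERA_WINDOW:
            for seq in read_seqs:
                for strand_seq in (seq, reverse_complement(seq)):
                    ident, start, end = _align_read(strand_seq, cand.sequence)
                    if ident >= remap_identity:
                        depth[start:end] += 1
                        break
            u_stat = coverage_evenness(depth)
        else:
            u_stat = 1.0
        mosaic_found, parents, breakpoint = _mosaic_scan(cand, toxin_db, window)
        is_chimera = mosaic_found and (
            u_stat < EVENNESS_CUTOFF or _segments_cover(parents, len(cand.sequence))
        )
        verdicts.append(
            ChimeraVerdict(
                transcript_id=cand.id,
                is_chimera=is_chimera,
                parents=parents if is_chimera else [],
                evenness=u_stat,
                breakpoint=breakpoint if is_chimera else None,
            )
        )
    return verdicts


def _segments_cover(parents, length: int, min_fraction: float = 0.9) -> bool:
    covered = sum(hi - lo for _, (lo, hi) in parents)
    return covered >= min_fraction * length


# ---------------------------------------------------------------------------
# Annotation and naming
# ---------------------------------------------------------------------------

_prot_aligner = Align.PairwiseAligner()
_prot_aligner.mode = "local"
_prot_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_prot_aligner.open_gap_score = -11
_prot_aligner.extend_gap_score = -1

DEFAULT_TOXIN_KEYWORDS = (
    "toxin",
    "metalloproteinase",
    "three-finger",
    "three finger",
    "crisp",
    "cysteine-rich secretory",
    "lectin",
    "phospholipase",
    "kunitz",
    "natriuretic",
    "waprin",
    "ficolin",
    "venom",
    "acetylcholinesterase",
    "hyaluronidase",
    "vespryn",
)


def annotate_and_name(
    transcripts: list[Transcript],
    toxin_reference_proteins: list[ReferenceProtein],
    keyword_list=DEFAULT_TOXIN_KEYWORDS,
    score_threshold: float = 60.0,
    cluster_threshold: float = 0.01,
) -> tuple[list[Transcript], list[ToxinCluster]]:
    """Assign toxin classes by protein alignment against a class-labeled
    toxin reference, then cluster toxins and emit cluster-aware names.

    A transcript is a toxin iff its best local-alignment hit scores at least
    `score_threshold` and that reference's description contains a keyword;
    everything else is "nontoxin" and keeps its id.
    """
    keywords = [k.lower() for k in keyword_list]
    annotated: list[Transcript] = []
    for t in transcripts:
        prot = t.protein
        best = None
        for ref in toxin_reference_proteins:
            try:
                score = _prot_aligner.score(prot, ref.sequence)
            except ValueError:
                continue
            if best is None or score > best[0]:
                best = (score, ref)
        label = "nontoxin"
        if best is not None and best[0] >= score_threshold:
            if any(k in best[1].description.lower() for k in keywords):
                label = best[1].class_label
        annotated.append(
            Transcript(
                id=t.id,
                sequence=t.sequence,
                cds_span=t.cds_span,
                class_label=label,
                cluster_id=None,
                provenance=t.provenance,
                abundance=t.abundance,
            )
        )

    toxins = [t for t in annotated if t.class_label != "nontoxin"]
    clusters = cluster_toxins(toxins, threshold=cluster_threshold)
    rename: dict[str, tuple[str, str]] = {}
    for cl in clusters:
        for member_name, source_id in cl.member_sources.items():
            rename[source_id] = (member_name, cl.name)
    out = []
    for t in annotated:
        if t.id in rename:
            new_id, cluster_name = rename[t.id]
            t.id = new_id
            t.cluster_id = cluster_name
        out.append(t)
    return out, clusters
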