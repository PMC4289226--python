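"""Transcript-abundance estimation from merged reads mapped to CDS-only
databases, reported at a fixed 10-million-mapped-read scale.

Every read is assigned to the coding sequence it matches best (identity at
least ``min_identity`` over the read); ties across clusters are broken
uniformly at random with a recorded seed, and reads tying only within one
cluster count once for that cluster.  Abundance rows mirror the expression
tables: cluster, cluster size, CDS length, median per-position coverage,
percentage of toxin-mapped reads and percentage of all mapped reads.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import SeqIO

from .codons import reverse_complement

MAPPED_READ_SCALE = 10_000_000


@dataclass
class CdsEntry:
    name: str
    sequence: str
    cluster: str
    class_label: str
    member: str


@dataclass
class MappingResult:
    cluster_counts: dict[str, int]
    depths: dict[str, np.ndarray]  # per-cluster, over representative CDS
    cluster_meta: dict[str, dict]
    n_mapped: int
    n_reads: int
    seed: int

    @property
    def scale(self) -> float:
        return MAPPED_READ_SCALE / self.n_mapped if self.n_mapped else 0.0


@dataclass
class ExpressionRecord:
    rank: int
    cluster_name: str
    cluster_size: int
    cds_length: int
    median_coverage: float
    pct_toxin_reads: float
    pct_total_reads: float


def parse_cds_fasta(path) -> list[CdsEntry]:
    """Header grammar: ``>name|cluster=SVMPIII-2|class=SVMPIII|member=a``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split("|")[1:] if "=" in kv
        )
        name = rec.description.split("|")[0].split()[0]
        entries.append(
            CdsEntry(
                name=name,
                sequence=str(rec.seq).upper(),
                cluster=fields.get("cluster", name),
                class_label=fields.get("class", "nontoxin"),
                member=fields.get("member", "a"),
            )
        )
    return entries


def _identity(read: str, target: str) -> tuple[float, int, int, int]:
    """(identity, target start, target end, aligned span) for a full-read
    infix alignment."""
    res = edlib.align(read, target, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return 0.0, 0, 0, 0
    start, end = res["locations"][0]
    return 1.0 - res["editDistance"] / len(read), start, end + 1, len(read)


MIN_END_OVERLAP = 30


def _end_overlap(
    read: str, target: str, min_identity: float
) -> tuple[float, int, int, int]:
    """Best ungapped overlap of a read hanging off either end of the target.

    Identity is computed over the aligned span only, so reads running from
    the coding sequence into untranslated flanks still map on their
    CDS-overlapping portion.  The longest span meeting `min_identity` wins;
    spans below the threshold are reported only as a fallback.
    """
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    best = (0.0, 0, 0, 0)
    max_o = min(len(r), len(t))
    for o in range(MIN_END_OVERLAP, max_o + 1):
        for ident, start, end in (
            (float(np.count_nonzero(r[-o:] == t[:o])) / o, 0, o),
            (float(np.count_nonzero(r[:o] == t[-o:])) / o, len(t) - o, len(t)),
        ):
            qualifies = ident >= min_identity
            best_qualifies = best[0] >= min_identity
            key = (qualifies, o if qualifies else 0, ident)
            best_key = (best_qualifies, best[3] if best_qualifies else 0, best[0])
            if key > best_key:
                best = (ident, start, end, o)
    return best


def map_reads_to_cds(
    merged_reads,
    cds_db: list[CdsEntry],
    min_identity: float = 0.95,
    seed: int = 0,
    k: int = 21,
) -> MappingResult:
    """Assign each merged read to its best-identity CDS.

    Candidate CDSs are pre-filtered with a k-mer index; identity is computed
    over the full read via infix alignment on both strands.  Reads whose
    best identity falls below `min_identity` stay unmapped.
    """
    if not cds_db:
        raise ValueError("empty CDS database")
    rng = np.random.default_rng(seed)
    index: dict[str, set[int]] = defaultdict(set)
    for i, e in enumerate(cds_db):
        for j in range(0, max(1, len(e.sequence) - k + 1)):
            index[e.sequence[j : j + k]].add(i)

    clusters: dict[str, list[int]] = defaultdict(list)
    for i, e in enumerate(cds_db):
        clusters[e.cluster].append(i)
    rep_of_cluster = {
        cl: min(idxs, key=lambda i: cds_db[i].member) for cl, idxs in clusters.items()
    }
    counts: dict[str, int] = defaultdict(int)
    depths = {
        cl: np.zeros(len(cds_db[rep].sequence)) for cl, rep in rep_of_cluster.items()
    }

    n_mapped = 0
    n_reads = 0
    for read in merged_reads:
        seq = read.sequence if hasattr(read, "sequence") else read
        n_reads += 1
        candidates: set[int] = set()
        for strand_seq in (seq, reverse_complement(seq)):
            for j in range(0, max(1, len(strand_seq) - k + 1), k):
                candidates |= index.get(strand_seq[j : j + k], set())
        best_key = (0.0, 0)
        hits: list[tuple[int, int, int]] = []  # (entry, start, end)
        for ci in candidates:
            for strand_seq in (seq, reverse_complement(seq)):
                ident, start, end, span = _identity(
                    strand_seq, cds_db[ci].sequence
                )
                if ident < min_identity:
                    ident, start, end, span = _end_overlap(
                        strand_seq, cds_db[ci].sequence, min_identity
                    )
                if ident < min_identity:
                    continue
                tied = abs(ident - best_key[0]) <= 1e-12
                if (ident > best_key[0] + 1e-12) or (tied and span > best_key[1]):
                    best_key = (ident, span)
                    hits = [(ci, start, end)]
                elif tied and span == best_key[1]:
                    hits.append((ci, start, end))
        if not hits:
            continue
        tied_clusters = sorted({cds_db[ci].cluster for ci, _, _ in hits})
        chosen_cluster = (
            tied_clusters[0]
            if len(tied_clusters) == 1
            else tied_clusters[int(rng.integers(0, len(tied_clusters)))]
        )
        n_mapped += 1
        counts[chosen_cluster] += 1
        ci, start, end = next(
            h for h in hits if cds_db[h[0]].cluster == chosen_cluster
        )
        d = depths[chosen_cluster]
        d[start : min(end, len(d))] += 1

    meta = {
        cl: {
            "cluster_size": len(idxs),
            "cds_length": len(cds_db[rep_of_cluster[cl]].sequence),
            "class_label": cds_db[rep_of_cluster[cl]].class_label,
            "representative": cds_db[rep_of_cluster[cl]].name,
        }
        for cl, idxs in clusters.items()
    }
    return MappingResult(
        cluster_counts=dict(counts),
        depths=depths,
        cluster_meta=meta,
        n_mapped=n_mapped,
        n_reads=n_reads,
        seed=seed,
    )


def abundance_table(result: MappingResult) -> list[ExpressionRecord]:
    """Expression-table rows for toxin clusters, ranked by % toxin reads.

    pct_total_reads = cluster reads / all mapped reads x 100;
    pct_toxin_reads = cluster reads / toxin-mapped reads x 100;
    median_coverage = median scaled per-position depth over the CDS.
    """
    if result.n_mapped == 0:
        warnings.warn("no mapped reads; abundance table is empty")
        return []
    toxin_clusters = [
        cl
        for cl in result.cluster_counts
        if result.cluster_meta[cl]["class_label"] != "nontoxin"
    ]
    toxin_total = sum(result.cluster_counts[cl] for cl in toxin_clusters)
    rows = []
    for cl in toxin_clusters:
        n = result.cluster_counts[cl]
        meta = result.cluster_meta[cl]
        member_suffix = "a" if meta["cluster_size"] > 1 else ""
        rows.append(
            ExpressionRecord(
                rank=0,
                cluster_name=cl + member_suffix,
                cluster_size=meta["cluster_size"],
                cds_length=meta["cds_length"],
                median_coverage=float(np.median(result.depths[cl]) * result.scale),
                pct_toxin_reads=100.0 * n / toxin_total if toxin_total else 0.0,
                pct_total_reads=100.0 * n / result.n_mapped,
            )
        )
    rows.sort(key=lambda r: -r.pct_toxin_reads)
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


def class_summary(
    table: list[ExpressionRecord], class_of_cluster: dict[str, str] | None = None
):
    """Per-class totals over an expression table.

    Returns (per_class, toxin_total_pct) where per_class maps class label ->
    dict(pct_toxin_reads, pct_total_reads, n_clusters) and toxin_total_pct is
    the summed % of all mapped reads on toxin clusters.
    """
    per_class: dict[str, dict] = {}
    toxin_total = 0.0
    for row in table:
        if class_of_cluster is None:
            label = class_of_label(row.cluster_name)
        else:
            label = class_of_cluster.get(row.cluster_name)
            if label is None:
                warnings.warn(f"unknown class for cluster {row.cluster_name}")
                label = "other"
        entry = per_class.setdefault(
            label, {"pct_toxin_reads": 0.0, "pct_total_reads": 0.0, "n_clusters": 0}
        )
        entry["pct_toxin_reads"] += row.pct_toxin_reads
        entry["pct_total_reads"] += row.pct_total_reads
        entry["n_clusters"] += 1
        toxin_total += row.pct_total_reads
    return per_class, toxin_total


def class_of_label(cluster_name: str) -> str:
    """Toxin class of a cluster/member name, e.g. 'SVMPIII-2a' -> 'SVMPIII'."""
    return cluster_name.split("-")[0]


def write_abundance_tsv(table: list[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "Rank\tCluster name\tCluster size\tCDS length\t"
            "Median coverage\t% Toxin reads\t% Total reads\n"
        )
        for r in table:
            fh.write(
                f"{r.rank}\t{r.cluster_name}\t{r.cluster_size}\t{r.cds_length}\t"
                f"{r.median_coverage:.0f}\t{r.pct_toxin_reads:.3f}\t"
                f"{r.pct_total_reads:.3f}\n"
            )
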