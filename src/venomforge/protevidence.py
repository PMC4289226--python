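"""Proteomic cross-validation of transcripts.

Builds mature-protein search databases with reversed-sequence decoys,
digests proteins in silico (trypsin, one missed cleavage), maps report
peptides back to database entries, applies the acceptance filters
(>=3 matched peptides, >=20% sequence coverage, score above the best
decoy — a 0% false-positive rule by construction), groups accepted
identifications by shared unique peptides, and cross-references confirmed
proteins against toxin transcript clusters.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

DECOY_SUFFIX = "|decoy"


@dataclass
class SearchDatabase:
    entries: dict[str, str]  # protein id -> mature sequence
    decoys: dict[str, str]
    internal_standard: tuple[str, str] | None = None

    def all_entries(self) -> dict[str, str]:
        out = dict(self.entries)
        out.update(self.decoys)
        if self.internal_standard:
            out[self.internal_standard[0]] = self.internal_standard[1]
        return out


@dataclass
class ProteinIdentification:
    protein_id: str
    score: float
    peptide_matches: int
    pct_coverage: float
    peptides: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    group_id: int | None = None

    @property
    def is_decoy(self) -> bool:
        return self.protein_id.endswith(DECOY_SUFFIX)


# ---------------------------------------------------------------------------
# Database construction
# ---------------------------------------------------------------------------


def build_search_db(
    transcripts,
    signal_annotations: dict[str, tuple[int, int]] | None = None,
    internal_standard: tuple[str, str] | None = None,
) -> SearchDatabase:
    """Translate transcripts, strip annotated signal peptides, add decoys.

    `transcripts` yields objects with ``id`` and a protein (``protein`` attr,
    ``mature_protein()`` method, or a (id, protein) tuple).  Signal
    annotations give the 1-based inclusive codon span of the signal peptide;
    the mature protein starts right after the span.  Each entry gets a
    reversed-sequence decoy with a flagged id.
    """
    signal_annotations = signal_annotations or {}
    entries: dict[str, str] = {}
    for t in transcripts:
        if isinstance(t, tuple):
            tid, prot = t
        elif hasattr(t, "protein"):
            tid, prot = t.id, t.protein
        else:
            tid, prot = t.id, t.mature_protein()
        if tid in signal_annotations:
            lo, hi = signal_annotations[tid]
            if not (1 <= lo <= hi <= len(prot)):
                raise ValueError(
                    f"signal-peptide span {lo}-{hi} outside protein {tid}"
                )
            prot = prot[hi:]
        entries[tid] = prot
    decoys = {tid + DECOY_SUFFIX: seq[::-1] for tid, seq in entries.items()}
    return SearchDatabase(
        entries=entries, decoys=decoys, internal_standard=internal_standard
    )


# ---------------------------------------------------------------------------
# In-silico tryptic digestion
# ---------------------------------------------------------------------------


def tryptic_digest(
    protein: str, max_missed_cleavages: int = 1, min_length: int = 6
) -> list[tuple[str, tuple[int, int]]]:
    """Tryptic peptides with 0-based half-open spans.

    Cleaves C-terminal to K/R except when the next residue is P; emits every
    fragment with at most `max_missed_cleavages` internal cleavage sites and
    length >= `min_length` (the length filter is applied last).
    """
    if not protein:
        raise ValueError("empty protein")
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(cuts))):
            lo, hi = cuts[i], cuts[j]
            if hi - lo >= min_length:
                peptides.append((protein[lo:hi], (lo, hi)))
    return peptides


# ---------------------------------------------------------------------------
# Peptide mapping
# ---------------------------------------------------------------------------

_MOD_ANNOTATION = re.compile(r"[\(\[][^\)\]]*[\)\]]|[^A-Z]")


def strip_modifications(peptide: str) -> str:
    """Drop modification annotations, keeping the plain residue sequence."""
    return _MOD_ANNOTATION.sub("", peptide)


def _canon(seq: str, il_equiv: bool) -> str:
    return seq.replace("I", "L") if il_equiv else seq


def map_peptides(
    report_rows,
    db: SearchDatabase,
    leucine_isoleucine_equivalent: bool = True,
) -> tuple[list[ProteinIdentification], list[str]]:
    """Map report peptides onto database entries and build identifications.

    Each report row has protein/score/peptide keys.  A peptide maps to every
    database entry containing it (I and L collapsed by default, since they
    are mass-indistinguishable); coverage is the union of mapped spans.
    Returns (identifications in report order, orphan peptides that map
    nowhere).
    """
    il = leucine_isoleucine_equivalent
    all_entries = db.all_entries()
    canon_entries = {pid: _canon(seq, il) for pid, seq in all_entries.items()}

    peptide_rows: dict[str, list[dict]] = defaultdict(list)
    order: list[str] = []
    for row in report_rows:
        pid = row["protein"]
        if pid not in peptide_rows:
            order.append(pid)
        peptide_rows[pid].append(row)

    orphans: list[str] = []
    mapped_cache: dict[str, dict[str, list[tuple[int, int]]]] = {}

    def spans_of(peptide: str) -> dict[str, list[tuple[int, int]]]:
        if peptide not in mapped_cache:
            cp = _canon(strip_modifications(peptide), il)
            hits: dict[str, list[tuple[int, int]]] = {}
            for pid, seq in canon_entries.items():
                start = seq.find(cp)
                spans = []
                while start != -1:
                    spans.append((start, start + len(cp)))
                    start = seq.find(cp, start + 1)
                if spans:
                    hits[pid] = spans
            mapped_cache[peptide] = hits
        return mapped_cache[peptide]

    idents: list[ProteinIdentification] = []
    for pid in order:
        rows = peptide_rows[pid]
        score = max(float(r["score"]) for r in rows)
        peptides: list[tuple[str, tuple[int, int]]] = []
        covered: set[int] = set()
        seen: set[str] = set()
        for r in rows:
            pep = str(r["peptide"])
            if pep in seen:
                continue
            seen.add(pep)
            hits = spans_of(pep)
            if not hits:
                orphans.append(pep)
                continue
            if pid in hits:
                span = hits[pid][0]
                peptides.append((pep, span))
                covered.update(range(*span))
        length = len(all_entries.get(pid, "")) or 1
        idents.append(
            ProteinIdentification(
                protein_id=pid,
                score=score,
                peptide_matches=len(peptides),
                pct_coverage=100.0 * len(covered) / length,
                peptides=peptides,
            )
        )
    return idents, orphans


def peptide_map_over(
    idents: list[ProteinIdentification],
) -> dict[str, set[str]]:
    """peptide sequence -> set of identification ids containing it."""
    S: dict[str, set[str]] = defaultdict(set)
    for ident in idents:
        for pep, _ in ident.peptides:
            S[pep].add(ident.protein_id)
    return S


# ---------------------------------------------------------------------------
# Acceptance filters
# ---------------------------------------------------------------------------


def accept_identifications(
    idents: list[ProteinIdentification],
    decoy_scores=None,
    min_peptides: int = 3,
    min_coverage: float = 20.0,
) -> list[ProteinIdentification]:
    """Keep identifications with >= min_peptides matched peptides,
    >= min_coverage % sequence coverage, and a score strictly above the
    highest-scoring decoy (no decoy -> -inf, so the score rule is vacuous).
    Decoy identifications themselves are never accepted."""
    if decoy_scores is None:
        decoy_scores = [i.score for i in idents if i.is_decoy]
    decoy_max = max(decoy_scores, default=float("-inf"))
    return [
        i
        for i in idents
        if not i.is_decoy
        and i.peptide_matches >= min_peptides
        and i.pct_coverage >= min_coverage
        and i.score > decoy_max
    ]


# ---------------------------------------------------------------------------
# Grouping by shared unique peptides
# ---------------------------------------------------------------------------


def group_identifications(
    accepted: list[ProteinIdentification],
) -> list[ProteinIdentification]:
    """Assign shared-unique-peptide group numbers.

    Peptides are processed from most to least specific (ascending size of
    their mapped entry set); a peptide whose entries are all still
    unclaimed founds a group of exactly those entries; peptides touching an
    already-claimed entry are shared evidence and found nothing.  Entries
    never claimed by any group-founding peptide have no distinguishing
    peptide and get no group number.  Groups are numbered consecutively
    from 1 in table order.
    """
    S = peptide_map_over(accepted)
    by_id = {i.protein_id: i for i in accepted}
    claimed: dict[str, int] = {}
    groups: list[set[str]] = []
    for pep in sorted(S, key=lambda p: (len(S[p]), p)):
        members = S[pep]
        if any(m in claimed for m in members):
            continue
        gid = len(groups)
        groups.append(set(members))
        for m in members:
            claimed[m] = gid

    # number groups consecutively in table (input) order
    numbering: dict[int, int] = {}
    for ident in accepted:
        gid = claimed.get(ident.protein_id)
        if gid is not None and gid not in numbering:
            numbering[gid] = len(numbering) + 1
        ident.group_id = numbering.get(gid) if gid is not None else None
    return accepted


# ---------------------------------------------------------------------------
# Cross-reference against toxin clusters
# ---------------------------------------------------------------------------

_NAME_GRAMMAR = re.compile(r"^(?P<cluster>[A-Za-z0-9_]+(?:-\d+)?)(?P<member>[a-z]?)$")


def cluster_of_protein(protein_id: str) -> str | None:
    """Strip the member letter: 'SVMPIII-2b' -> 'SVMPIII-2'; 'Fused' -> 'Fused'."""
    m = _NAME_GRAMMAR.match(protein_id)
    return m.group("cluster") if m else None


@dataclass
class CrossReference:
    n_confirmed: int
    n_total: int
    fraction: float
    confirmed: list[str]


def cross_reference(accepted, toxin_clusters) -> CrossReference:
    """Which toxin clusters have >= 1 accepted identification.

    `accepted` yields identifications (or plain protein ids); a cluster is
    confirmed iff at least one accepted id, member letter stripped, names
    it.  Ids outside the naming grammar or outside the cluster list are
    excluded (nontoxins and contaminants in the report do not count).
    """
    cluster_names = [
        c if isinstance(c, str) else c.name for c in toxin_clusters
    ]
    cluster_set = {cluster_of_protein(c) or c for c in cluster_names}
    confirmed: set[str] = set()
    for item in accepted:
        pid = item if isinstance(item, str) else item.protein_id
        cl = cluster_of_protein(pid)
        if cl is None:
            warnings.warn(f"id {pid!r} does not match the naming grammar; skipped")
            continue
        if cl in cluster_set:
            confirmed.add(cl)
    n_total = len(cluster_set)
    return CrossReference(
        n_confirmed=len(confirmed),
        n_total=n_total,
        fraction=len(confirmed) / n_total if n_total else 0.0,
        confirmed=sorted(confirmed),
    )


def write_identifications_tsv(idents: list[ProteinIdentification], path) -> None:
    with open(path, "w") as fh:
        fh.write("Transcript name\tScore\tPeptide matches\t% Seq. coverage\tGroup\n")
        for i in idents:
            group = "" if i.group_id is None else str(i.group_id)
            fh.write(
                f"{i.protein_id}\t{i.score:.2f}\t{i.peptide_matches}\t"
                f"{i.pct_coverage:.2f}\t{group}\n"
            )
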