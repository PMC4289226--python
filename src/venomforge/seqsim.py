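"""Two-species synthetic venom-gland data with known ground truth.

Generates paired transcriptomes for two diverged species, each containing
toxin gene families (clusters of near-identical paralogs/alleles at <1% CDS
divergence) and nontoxins, with strongly toxin-biased expression; 151-nt
paired-end reads with 3'-overlapping inserts, adapter read-through,
per-cycle quality scores and low-level chimeric/unspliced contamination;
and peptide-identification reports with target and decoy protein scores.

Every stochastic step is driven by a numpy Generator seeded from the config,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .codons import (
    CODON_INDEX,
    GENETIC_CODE,
    SENSE_CODONS,
    codon_change_type,
    is_transition,
    is_valid_cds,
    reverse_complement,
    single_nucleotide_neighbors,
    translate_cds,
)

TRUTH_SEPARATOR = "|truth|"

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToxinFamilySpec:
    """One toxin class: `n_clusters` loci, `cluster_size` members each.

    `omega` is the nonsynonymous/synonymous rate ratio used when the family
    diverges between the two species; venom toxins are simulated with
    omega > 1 by default (diversifying selection), nontoxins with omega << 1.
    """

    class_label: str
    n_clusters: int
    cluster_size: int
    omega: float
    n_codons: int = 120


@dataclass(frozen=True)
class ExpressionModel:
    """Log-normal expression weights, rescaled to a fixed toxin fraction."""

    toxin_mu: float = 0.0
    toxin_sigma: float = 1.5
    nontoxin_mu: float = 0.0
    nontoxin_sigma: float = 1.5
    toxin_fraction: float = 0.362


@dataclass(frozen=True)
class ScoreModel:
    """Protein-score distributions for targets and decoys (PLGS-like)."""

    target_loc: float = 5000.0
    target_scale: float = 1500.0
    decoy_loc: float = 150.0
    decoy_scale: float = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_nontoxins: int = 60
    toxin_families: tuple[ToxinFamilySpec, ...] = (
        ToxinFamilySpec("3FTx", 4, 3, 2.5, n_codons=100),
        ToxinFamilySpec("SVMPIII", 3, 2, 2.0, n_codons=200),
        ToxinFamilySpec("CRISP", 1, 2, 1.8, n_codons=160),
        ToxinFamilySpec("CTL", 2, 1, 1.5, n_codons=110),
    )
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    nontoxin_omega: float = 0.10
    kappa: float = 2.5
    divergence_time: float = 0.15
    read_length: int = 151
    insert_mean: float = 150.0
    insert_sd: float = 30.0
    error_rate: float = 0.001
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    quality_slope: float = 0.02  # mean phred lost per cycle
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    chimera_rate: float = 0.002
    unspliced_rate: float = 0.002
    n_read_pairs: int = 10000
    species: tuple[str, str] = ("speciesA", "speciesB")

    def validate(self) -> None:
        for name in ("error_rate", "chimera_rate", "unspliced_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.expression.toxin_fraction <= 1.0:
            raise ValueError("toxin_fraction outside [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.n_read_pairs < 0:
            raise ValueError("n_read_pairs must be >= 0")
        if self.n_nontoxins < 0:
            raise ValueError("n_nontoxins must be >= 0")
        if set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must be an A/C/G/T string")
        for fam in self.toxin_families:
            if fam.omega <= 0:
                raise ValueError(f"omega must be > 0 in family {fam.class_label}")
            if fam.cluster_size < 1 or fam.n_clusters < 1:
                raise ValueError(
                    f"family {fam.class_label}: n_clusters and cluster_size "
                    "must be >= 1"
                )
            if fam.n_codons < 25:
                raise ValueError("toxin CDSs need >= 25 codons (signal peptide)")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class TranscriptTruth:
    id: str
    cds: str
    utr5: str
    utr3: str
    class_label: str  # toxin class or "nontoxin"
    cluster_id: str | None
    expression_weight: float
    signal_peptide_span: tuple[int, int] | None = None  # 1-based codons, incl.

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def is_toxin(self) -> bool:
        return self.class_label != "nontoxin"

    def mature_protein(self) -> str:
        aa = translate_cds(self.cds)[:-1]
        if self.signal_peptide_span is not None:
            aa = aa[self.signal_peptide_span[1] :]
        return aa


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    transcripts: dict[str, list[TranscriptTruth]]
    ortholog_map: list[tuple[str, str]]
    site_omega_map: dict[tuple[str, str], float]

    def by_id(self, species: str) -> dict[str, TranscriptTruth]:
        return {t.id: t for t in self.transcripts[species]}

    def toxin_fraction(self, species: str) -> float:
        return sum(
            t.expression_weight for t in self.transcripts[species] if t.is_toxin
        )

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "transcripts": {
                sp: [dataclasses.asdict(t) for t in ts]
                for sp, ts in self.transcripts.items()
            },
            "ortholog_map": self.ortholog_map,
            "site_omega_map": {
                f"{a}::{b}": w for (a, b), w in self.site_omega_map.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Codon-level evolution (GY94-style, uniform codon frequencies)
# ---------------------------------------------------------------------------


def _site_rates(codon: str, omega: float, kappa: float):
    """(neighbors, rates) for one sense codon; stop moves have rate 0."""
    neighbors = []
    rates = []
    for pos, base, nb in single_nucleotide_neighbors(codon):
        if GENETIC_CODE[nb] == "*":
            continue
        r = kappa if is_transition(codon[pos], base) else 1.0
        if GENETIC_CODE[nb] != GENETIC_CODE[codon]:
            r *= omega
        neighbors.append(nb)
        rates.append(r)
    return neighbors, np.asarray(rates)


def _mean_rate(omega: float, kappa: float) -> float:
    """Expected leaving rate under the uniform stationary distribution."""
    total = 0.0
    for codon in SENSE_CODONS:
        _, rates = _site_rates(codon, omega, kappa)
        total += rates.sum()
    return total / len(SENSE_CODONS)


def _evolve_codon(
    codon: str,
    t: float,
    scale: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
    events: dict[str, int],
) -> str:
    """Gillespie simulation of one codon site along a branch of length t."""
    clock = 0.0
    current = codon
    while True:
        neighbors, rates = _site_rates(current, omega, kappa)
        total = rates.sum() * scale
        clock += rng.exponential(1.0 / total)
        if clock >= t:
            return current
        nxt = neighbors[rng.choice(len(neighbors), p=rates / rates.sum())]
        events[codon_change_type(current, nxt)] += 1
        current = nxt


def evolve_codon_string(
    codons: list[str],
    t: float,
    omega: float | np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[list[str], dict[str, int]]:
    """Evolve a list of sense codons along one branch of length t
    (expected substitutions per codon site). Returns descendant codons and
    realized synonymous/nonsynonymous event counts."""
    omegas = np.broadcast_to(np.asarray(omega, dtype=float), (len(codons),))
    events = {"syn": 0, "nonsyn": 0}
    if t <= 0:
        return list(codons), events
    # one global clock: branch length t is the expected number of
    # substitutions per codon site averaged over the site-omega mixture,
    # so high-omega sites evolve faster, not just differently
    uniq, counts = np.unique(omegas, return_counts=True)
    mean_rates = {float(w): _mean_rate(float(w), kappa) for w in uniq}
    mu_bar = float(
        sum(mean_rates[float(w)] * c for w, c in zip(uniq, counts)) / len(omegas)
    )
    scale = 1.0 / mu_bar
    out = []
    for codon, w in zip(codons, omegas):
        out.append(_evolve_codon(codon, t, scale, float(w), kappa, rng, events))
    return out, events


def evolve_codon_sequences(
    ancestor: str,
    omega: float | np.ndarray,
    kappa: float,
    t: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str, dict[str, int]]:
    """Evolve a valid CDS into two descendants along independent branches of
    length t/2 each (total expected divergence t substitutions/codon site).

    The start codon and terminal stop are held fixed so descendants remain
    valid CDSs; no internal stops can arise because stop codons are outside
    the simulated state space. Returns (descendant1, descendant2, events)
    where events counts realized syn/nonsyn substitutions over both branches.
    """
    if not is_valid_cds(ancestor):
        raise ValueError("ancestor is not a valid CDS")
    rng = np.random.default_rng(rng)
    codons = [ancestor[i : i + 3] for i in range(3, len(ancestor) - 3, 3)]
    if np.ndim(omega) and len(np.atleast_1d(omega)) == len(ancestor) // 3:
        omega = np.atleast_1d(omega)[1:-1]  # align with internal codons
    d1, e1 = evolve_codon_string(codons, t / 2.0, omega, kappa, rng)
    d2, e2 = evolve_codon_string(codons, t / 2.0, omega, kappa, rng)
    events = {k: e1[k] + e2[k] for k in e1}
    stop = ancestor[-3:]
    return (
        "ATG" + "".join(d1) + stop,
        "ATG" + "".join(d2) + stop,
        events,
    )


def simulate_codon_alignment(
    tree,
    n_codons: int,
    omega: float | np.ndarray,
    kappa: float,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Evolve sense codons down a dendropy tree (edge lengths in expected
    substitutions/codon site); returns {taxon label: CDS-like codon string}.

    Used to benchmark the site-model fits against known site-class structure.
    """
    rng = np.random.default_rng(rng)
    root_codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    states = {id(tree.seed_node): root_codons}
    result: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child_state, _ = evolve_codon_string(parent_state, t, omega, kappa, rng)
        states[id(node)] = child_state
        if node.is_leaf():
            result[node.taxon.label] = "".join(child_state)
    return result


# ---------------------------------------------------------------------------
# Transcriptome construction
# ---------------------------------------------------------------------------

_MEMBER_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _sprinkle_substitutions(
    cds: str, n_subs: int, rng: np.random.Generator
) -> str:
    """Apply n_subs random point substitutions to internal codons without
    creating stops or touching the start/stop codons."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    placed = 0
    while placed < n_subs:
        idx = int(rng.integers(1, len(codons) - 1))
        options = [
            nb
            for _, _, nb in single_nucleotide_neighbors(codons[idx])
            if GENETIC_CODE[nb] != "*"
        ]
        codons[idx] = options[int(rng.integers(0, len(options)))]
        placed += 1
    return "".join(codons)


def simulate_transcriptomes(config: SimulationConfig) -> SyntheticTruth:
    """Build the two-species ground-truth transcriptome set.

    Toxin clusters diverge from a family ancestor; within-cluster members
    carry <1% sprinkled substitutions; orthologs across species diverge by
    `divergence_time` expected substitutions per codon site under the codon
    model (toxins with the family omega, nontoxins with `nontoxin_omega`).
    Expression weights are log-normal, rescaled per species so the toxin
    share of transcription equals the configured target.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sp_a, sp_b = config.species
    transcripts: dict[str, list[TranscriptTruth]] = {sp_a: [], sp_b: []}
    ortholog_map: list[tuple[str, str]] = []
    site_omega_map: dict[tuple[str, str], float] = {}

    def add_pair(
        name, cds_a, cds_b, class_label, cluster, omega, signal=None,
        register_ortholog=True,
    ):
        for sp, cds in ((sp_a, cds_a), (sp_b, cds_b)):
            transcripts[sp].append(
                TranscriptTruth(
                    id=name,
                    cds=cds,
                    utr5=_random_utr(rng, 30, 80),
                    utr3=_random_utr(rng, 40, 120),
                    class_label=class_label,
                    cluster_id=cluster,
                    expression_weight=0.0,
                    signal_peptide_span=signal,
                )
            )
        if register_ortholog:
            ortholog_map.append((name, name))
            site_omega_map[(name, name)] = omega

    # Nontoxins: independent loci, purifying selection.
    for i in range(config.n_nontoxins):
        n_codons = int(rng.integers(100, 400))
        anc = _random_cds(rng, n_codons)
        a, b, _ = evolve_codon_sequences(
            anc, config.nontoxin_omega, config.kappa, config.divergence_time, rng
        )
        add_pair(f"NT-{i + 1:04d}", a, b, "nontoxin", None, config.nontoxin_omega)

    # Toxin families: clusters of near-identical members, shared ancestry.
    for fam in config.toxin_families:
        fam_anc = _random_cds(rng, fam.n_codons)
        for k in range(1, fam.n_clusters + 1):
            cluster_name = f"{fam.class_label}-{k}"
            # separate this cluster from its siblings: ~4% within-species
            n_sep = max(4, int(0.04 * len(fam_anc)))
            cluster_anc = _sprinkle_substitutions(fam_anc, n_sep, rng)
            anc_a, anc_b, _ = evolve_codon_sequences(
                cluster_anc, fam.omega, config.kappa, config.divergence_time, rng
            )
            # members: <1% pairwise divergence by construction
            n_within = max(1, int(0.004 * len(cluster_anc)))
            for m in range(fam.cluster_size):
                letter = _MEMBER_LETTERS[m] if fam.cluster_size > 1 else ""
                name = cluster_name + letter
                cds_a = anc_a if m == 0 else _sprinkle_substitutions(anc_a, n_within, rng)
                cds_b = anc_b if m == 0 else _sprinkle_substitutions(anc_b, n_within, rng)
                # members beyond the representative model post-speciation
                # alleles, so only the representative is an ortholog pair
                add_pair(
                    name, cds_a, cds_b, fam.class_label, cluster_name, fam.omega,
                    signal=(1, 20), register_ortholog=(m == 0),
                )

    # Expression weights.
    expr = config.expression
    for sp in (sp_a, sp_b):
        ts = transcripts[sp]
        toxins = [t for t in ts if t.is_toxin]
        nontoxins = [t for t in ts if not t.is_toxin]
        w_tox = rng.lognormal(expr.toxin_mu, expr.toxin_sigma, len(toxins))
        w_non = rng.lognormal(expr.nontoxin_mu, expr.nontoxin_sigma, len(nontoxins))
        tox_target = expr.toxin_fraction if toxins else 0.0
        non_target = 1.0 - tox_target if nontoxins else 0.0
        if toxins:
            w_tox *= tox_target / w_tox.sum()
        if nontoxins:
            w_non *= non_target / w_non.sum()
        total = (w_tox.sum() if toxins else 0.0) + (w_non.sum() if nontoxins else 0.0)
        for t, w in zip(toxins, w_tox):
            t.expression_weight = float(w / total)
        for t, w in zip(nontoxins, w_non):
            t.expression_weight = float(w / total)

    return SyntheticTruth(config, transcripts, ortholog_map, site_omega_map)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReadPair:
    id: str
    read1: str
    qual1: list[int]
    read2: str
    qual2: list[int]
    source_id: str  # transcript of origin ("X+Y" for chimeras)
    insert_start: int
    insert_length: int
    kind: str  # normal | chimera | unspliced


def _draw_qualities(n, cfg: SimulationConfig, rng) -> list[int]:
    cycles = np.arange(n)
    q = rng.normal(cfg.quality_mean - cfg.quality_slope * cycles, cfg.quality_sd)
    return [int(v) for v in np.clip(np.rint(q), 2, 41)]


def _apply_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_reads(
    truth: SyntheticTruth,
    config: SimulationConfig,
    species: str | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[SimulatedReadPair]:
    """Draw `n_read_pairs` paired 3'-overlapping reads from the transcriptome.

    Inserts are sampled per transcript proportionally to expression weight;
    when the insert is shorter than the read length the adapter is read
    through and appended; a `chimera_rate` fraction of inserts are
    single-breakpoint fusions of two transcripts and an `unspliced_rate`
    fraction carry a retained random intron.
    """
    config.validate()
    species = species or config.species[0]
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    else:
        rng = np.random.default_rng(rng)
    ts = truth.transcripts[species]
    if not ts:
        return []
    weights = np.array([t.expression_weight for t in ts])
    weights = weights / weights.sum()
    R = config.read_length
    pairs: list[SimulatedReadPair] = []
    for i in range(config.n_read_pairs):
        u = rng.random()
        if u < config.chimera_rate and len(ts) >= 2:
            ia, ib = rng.choice(len(ts), size=2, replace=False, p=weights)
            sa, sb = ts[ia].sequence, ts[ib].sequence
            bp_a = int(rng.integers(1, len(sa)))
            bp_b = int(rng.integers(0, len(sb) - 1))
            template = sa[:bp_a] + sb[bp_b:]
            src, kind = f"{ts[ia].id}+{ts[ib].id}", "chimera"
        elif u < config.chimera_rate + config.unspliced_rate:
            idx = int(rng.choice(len(ts), p=weights))
            t = ts[idx]
            intron = _random_utr(rng, 120, 200)
            pos = len(t.utr5) + 3 * int(rng.integers(1, len(t.cds) // 3))
            template = t.sequence[:pos] + intron + t.sequence[pos:]
            src, kind = t.id, "unspliced"
        else:
            idx = int(rng.choice(len(ts), p=weights))
            template, src, kind = ts[idx].sequence, ts[idx].id, "normal"
        L = int(np.clip(rng.normal(config.insert_mean, config.insert_sd), 40, None))
        L = min(L, len(template))
        start = int(rng.integers(0, len(template) - L + 1))
        frag = template[start : start + L]
        r1 = (frag + config.adapter * (R // max(len(config.adapter), 1) + 2))[:R] \
            if config.adapter else frag[:R]
        r2_core = reverse_complement(frag)
        r2 = (r2_core + config.adapter * (R // max(len(config.adapter), 1) + 2))[:R] \
            if config.adapter else r2_core[:R]
        r1 = _apply_errors(r1, config.error_rate, rng)
        r2 = _apply_errors(r2, config.error_rate, rng)
        rid = (
            f"sim{i}{TRUTH_SEPARATOR}src={src};start={start};ilen={L};kind={kind}"
        )
        pairs.append(
            SimulatedReadPair(
                id=rid,
                read1=r1,
                qual1=_draw_qualities(len(r1), config, rng),
                read2=r2,
                qual2=_draw_qualities(len(r2), config, rng),
                source_id=src,
                insert_start=start,
                insert_length=L,
                kind=kind,
            )
        )
    return pairs


def strip_truth(read_id: str) -> str:
    """Remove the ground-truth provenance suffix for blind runs."""
    return read_id.split(TRUTH_SEPARATOR, 1)[0]


# ---------------------------------------------------------------------------
# Peptide-identification report simulation
# ---------------------------------------------------------------------------


def simulate_id_report(
    truth: SyntheticTruth,
    detectability: float | dict[str, float] = 0.5,
    score_model: ScoreModel | None = None,
    seed: int | None = None,
    species: str | None = None,
    peptide_detect_prob: float = 0.7,
    decoy_hit_rate: float = 0.1,
):
    """Emulate a protein-identification search report.

    Returns (rows, present_ids) where rows is a list of dicts with keys
    protein/score/peptide/peptide_score (one row per matched peptide) and
    present_ids is the set of proteins genuinely present in the sample.
    Decoy rows carry a ``|decoy`` id suffix and the decoy score distribution.
    """
    from .protevidence import tryptic_digest  # deferred: avoid import cycle

    score_model = score_model or ScoreModel()
    species = species or truth.config.species[0]
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.config.seed if seed is None else seed, 2])
    )
    rows: list[dict] = []
    present: set[str] = set()
    for t in truth.transcripts[species]:
        prot = t.mature_protein()
        if not prot:
            continue
        det = (
            detectability.get(t.id, 0.0)
            if isinstance(detectability, dict)
            else detectability
        )
        if not 0.0 <= det <= 1.0:
            raise ValueError("detectability outside [0, 1]")
        if rng.random() < det:
            peptides = [p for p, _ in tryptic_digest(prot)]
            hit = [p for p in peptides if rng.random() < peptide_detect_prob]
            if not hit:
                hit = [peptides[int(rng.integers(0, len(peptides)))]]
            present.add(t.id)
            score = float(
                max(1.0, rng.normal(score_model.target_loc, score_model.target_scale))
            )
            for pep in hit:
                rows.append(
                    {
                        "protein": t.id,
                        "score": round(score, 2),
                        "peptide": pep,
                        "peptide_score": round(float(rng.normal(score / 10, 5)), 2),
                    }
                )
        # decoy: reversed mature protein, decoy score distribution
        if rng.random() < decoy_hit_rate:
            decoy_peps = [p for p, _ in tryptic_digest(prot[::-1])]
            if decoy_peps:
                n_hit = int(rng.integers(1, min(3, len(decoy_peps)) + 1))
                picks = rng.choice(len(decoy_peps), size=n_hit, replace=False)
                score = float(
                    max(1.0, rng.normal(score_model.decoy_loc, score_model.decoy_scale))
                )
                for j in picks:
                    rows.append(
                        {
                            "protein": t.id + "|decoy",
                            "score": round(score, 2),
                            "peptide": decoy_peps[int(j)],
                            "peptide_score": round(
                                float(rng.normal(score / 10, 5)), 2
                            ),
                        }
                    )
    return rows, present


# ---------------------------------------------------------------------------
# Writers (plain-text standard formats)
# ---------------------------------------------------------------------------


def write_transcript_fasta(truth: SyntheticTruth, species: str, path) -> None:
    """FASTA with the documented header grammar used downstream."""
    with open(path, "w") as fh:
        for t in truth.transcripts[species]:
            member = t.id[len(t.cluster_id) :] if t.cluster_id else ""
            fh.write(
                f">{t.id}|cluster={t.cluster_id or t.id}"
                f"|class={t.class_label}|member={member or 'a'}\n{t.sequence}\n"
            )


def write_cds_fasta(truth: SyntheticTruth, species: str, path) -> None:
    with open(path, "w") as fh:
        for t in truth.transcripts[species]:
            member = t.id[len(t.cluster_id) :] if t.cluster_id else ""
            fh.write(
                f">{t.id}|cluster={t.cluster_id or t.id}"
                f"|class={t.class_label}|member={member or 'a'}\n{t.cds}\n"
            )


def write_paired_fastq(pairs, path_r1, path_r2, blind: bool = False) -> None:
    """4-line FASTQ, phred+33."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            rid = strip_truth(p.id) if blind else p.id
            q1 = "".join(chr(q + 33) for q in p.qual1)
            q2 = "".join(chr(q + 33) for q in p.qual2)
            f1.write(f"@{rid}/1\n{p.read1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{p.read2}\n+\n{q2}\n")


def write_id_report(rows, path) -> None:
    """TSV report: protein, score, peptide, peptide_score."""
    with open(path, "w") as fh:
        fh.write("protein\tscore\tpeptide\tpeptide_score\n")
        for r in rows:
            fh.write(
                f"{r['protein']}\t{r['score']}\t{r['peptide']}\t{r['peptide_score']}\n"
            )
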