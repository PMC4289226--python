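"""Molecular-evolution analyses: ortholog detection, pairwise dN/dS,
nontoxin null distributions with outlier calls, and codon site-model
likelihood ratio tests.

Pairwise rates come in two flavors: counting (Nei-Gojobori 1986 with
pathway averaging and Jukes-Cantor correction; the default because it has
an exact brute-force oracle) and maximum likelihood under a GY94 codon
model with F3x4 frequencies (the mode matching published codeml practice).
Site models M0, M1a (nearly neutral), M2a (positive selection), M7 (beta)
and M8 (beta plus selection) are fit by Felsenstein pruning over the
61-sense-codon state space on a user-supplied or neighbor-joining tree;
nested pairs are compared with chi-square (df=2) likelihood ratio tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import optimize, special, stats

from .codons import (
    CODON_INDEX,
    GENETIC_CODE,
    N_SENSE,
    SENSE_CODONS,
    is_transition,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    cds_a: str  # codon-aligned, gap columns removed
    cds_b: str
    gapped_positions: int
    is_toxin: bool = False


@dataclass
class PairwiseRates:
    dn: float | None
    ds: float | None
    omega: float | None  # None when dS == 0 or a rate is undefined
    method: str  # "counting" | "ML"
    reason: str = ""


@dataclass
class RateNullSummary:
    thresholds: dict[str, float]  # 95th percentiles of nontoxin dN/dS/omega
    toxin_exceed_counts: dict[str, int]
    wilcoxon_p: dict[str, float | None]
    n_toxin: dict[str, int]
    n_nontoxin: dict[str, int]
    n_undefined_omega: int


@dataclass
class SiteModelFit:
    model: str
    lnl: float  # log-likelihood (negative number)
    p: tuple[float, ...]  # site-class proportions
    w: tuple[float, ...]  # site-class omega values
    kappa: float
    tree_scale: float
    branch_lengths: dict[str, float] = field(default_factory=dict)
    codon_freqs: np.ndarray | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def neg_lnl(self) -> float:
        return -self.lnl


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# Reciprocal-best-hit orthologs
# ---------------------------------------------------------------------------

_prot_aligner = Align.PairwiseAligner()
_prot_aligner.mode = "local"
_prot_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_prot_aligner.open_gap_score = -11
_prot_aligner.extend_gap_score = -1

# Karlin-Altschul parameters for gapped BLOSUM62 with 11/1 gap costs
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def rbh_orthologs(
    proteins_a: dict[str, str],
    proteins_b: dict[str, str],
    evalue_cutoff: float = 1e-4,
    exclude: set[str] | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two proteomes.

    All-vs-all local alignment with BLOSUM62; the raw score is converted to
    an E-value with the classical extreme-value formula scaled by the search
    space.  A pair is kept iff each member is the other's best-scoring hit
    and both E-values fall below the cutoff.  `exclude` drops entries (e.g.
    mitochondrially encoded proteins) before searching.
    """
    exclude = exclude or set()
    A = {k: v for k, v in proteins_a.items() if k not in exclude and v}
    B = {k: v for k, v in proteins_b.items() if k not in exclude and v}
    if not A or not B:
        return []
    db_len_b = sum(len(v) for v in B.values())
    db_len_a = sum(len(v) for v in A.values())

    def best_hits(queries, targets, db_len):
        best = {}
        for qid, qseq in queries.items():
            top = None
            for tid, tseq in targets.items():
                try:
                    score = _prot_aligner.score(qseq, tseq)
                except ValueError:
                    continue
                if top is None or score > top[0] or (
                    score == top[0] and tid < top[1]
                ):
                    top = (score, tid)
            if top is not None and _evalue(top[0], len(qseq), db_len) < evalue_cutoff:
                best[qid] = top[1]
        return best

    fwd = best_hits(A, B, db_len_b)
    rev = best_hits(B, A, db_len_a)
    return sorted(
        (a, b) for a, b in fwd.items() if rev.get(b) == a
    )


# ---------------------------------------------------------------------------
# Codon-aware pairwise alignment
# ---------------------------------------------------------------------------

_global_prot_aligner = Align.PairwiseAligner()
_global_prot_aligner.mode = "global"
_global_prot_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_global_prot_aligner.open_gap_score = -10
_global_prot_aligner.extend_gap_score = -0.5


def _translate_no_stop(cds: str) -> str:
    aa = "".join(
        GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3)
    )
    return aa[:-1] if aa.endswith("*") else aa


def codon_align(
    cds_a: str,
    cds_b: str,
    max_gapped_positions: int = 24,
    id_a: str = "A",
    id_b: str = "B",
    is_toxin: bool = False,
) -> OrthologPair | None:
    """Codon-aware pairwise alignment via global protein alignment.

    Gapped nucleotide positions are counted over the coding sequences; the
    pair is excluded (None) when the count exceeds `max_gapped_positions`.
    Gapped codon columns are removed before any rate estimation.
    """
    for cds in (cds_a, cds_b):
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
    aa_a, aa_b = _translate_no_stop(cds_a), _translate_no_stop(cds_b)
    alignment = _global_prot_aligner.align(aa_a, aa_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    gapped_nt = 3 * sum((x == "-") or (y == "-") for x, y in zip(row_a, row_b))
    if gapped_nt > max_gapped_positions:
        return None
    out_a, out_b = [], []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    # drop stop-containing columns (terminal stops, by construction)
    cols = [
        (a, b)
        for a, b in zip(out_a, out_b)
        if GENETIC_CODE.get(a) not in (None, "*") and GENETIC_CODE.get(b) not in (None, "*")
    ]
    return OrthologPair(
        id_a=id_a,
        id_b=id_b,
        cds_a="".join(a for a, _ in cols),
        cds_b="".join(b for _, b in cols),
        gapped_positions=gapped_nt,
        is_toxin=is_toxin,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986 counting
# ---------------------------------------------------------------------------


def _ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes one site split by the fraction of its three
    possible changes that are synonymous; changes creating stop codons count
    as nonsynonymous opportunity.
    """
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        n_syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[alt] == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


def _ng86_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts between two codons.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are discarded (all pathways are used if every
    one hits a stop).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        steps = []
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                via_stop = True
            steps.append(
                "syn" if GENETIC_CODE[cur] == GENETIC_CODE[nxt] else "nonsyn"
            )
            cur = nxt
        paths.append((via_stop, steps))
    valid = [steps for via, steps in paths if not via]
    if not valid:
        valid = [steps for _, steps in paths]
    syn = sum(s.count("syn") for s in valid) / len(valid)
    nonsyn = sum(s.count("nonsyn") for s in valid) / len(valid)
    return syn, nonsyn


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        return None
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd): averaged site counts and pathway-averaged difference
    counts over an aligned gap-free codon pair."""
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise ValueError("sequences must be an aligned, gap-free codon pair")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            continue  # stop codons are not sites
        sa, na = _ng86_site_counts(ca)
        sb, nb = _ng86_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _ng86_path_counts(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def ng86_rates(cds_a: str, cds_b: str) -> PairwiseRates:
    """Nei-Gojobori (1986) dN and dS with Jukes-Cantor correction."""
    S, N, Sd, Nd = ng86_counts(cds_a, cds_b)
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    if ds is None or dn is None:
        return PairwiseRates(
            dn=dn, ds=ds, omega=None, method="counting",
            reason="corrected proportion >= 0.75",
        )
    omega = None if ds == 0.0 else dn / ds
    return PairwiseRates(dn=dn, ds=ds, omega=omega, method="counting")


# ---------------------------------------------------------------------------
# GY94 codon model machinery
# ---------------------------------------------------------------------------

_PAIR_INFO: list[tuple[int, int, bool, bool]] = []
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i >= _j:
            continue
        _d = [k for k in range(3) if _ci[k] != _cj[k]]
        if len(_d) != 1:
            continue
        _k = _d[0]
        _PAIR_INFO.append(
            (
                _i,
                _j,
                is_transition(_ci[_k], _cj[_k]),
                GENETIC_CODE[_ci] != GENETIC_CODE[_cj],
            )
        )
_PAIR_I = np.array([p[0] for p in _PAIR_INFO])
_PAIR_J = np.array([p[1] for p in _PAIR_INFO])
_PAIR_TS = np.array([p[2] for p in _PAIR_INFO])
_PAIR_NONSYN = np.array([p[3] for p in _PAIR_INFO])


def f3x4_frequencies(sequences) -> np.ndarray:
    """F3x4 codon frequencies (position-specific nucleotide compositions)."""
    counts = np.ones((3, 4))  # pseudocount guards empty positions
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in sequences:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            for pos in range(3):
                b = seq[i + pos]
                if b in base_idx:
                    counts[pos, base_idx[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, base_idx[c[0]]] * freqs[1, base_idx[c[1]]] * freqs[2, base_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized GY94 rate matrix over the 61 sense codons."""
    Q = np.zeros((N_SENSE, N_SENSE))
    rate = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_NONSYN, omega, 1.0)
    Q[_PAIR_I, _PAIR_J] = rate * pi[_PAIR_J]
    Q[_PAIR_J, _PAIR_I] = rate * pi[_PAIR_I]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _eig_reversible(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible Q via symmetrization."""
    sq = np.sqrt(pi)
    A = (Q * sq[:, None]) / sq[None, :]
    lam, U = np.linalg.eigh((A + A.T) / 2.0)
    left = U.T * sq[None, :]
    right = U / sq[:, None]
    return lam, right, left


def _transition_matrices(lam, right, left, ts):
    """P(t) for each t in ts from a cached eigendecomposition."""
    expd = np.exp(np.outer(ts, lam))  # (nb, 61)
    return (right[None, :, :] * expd[:, None, :]) @ left


def expected_rates(kappa: float, omega: float, pi: np.ndarray):
    """(synonymous, nonsynonymous) expected flux per unit time per codon."""
    rate = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_NONSYN, omega, 1.0)
    flux = rate * (pi[_PAIR_I] * pi[_PAIR_J] * 2.0)
    syn = float(flux[~_PAIR_NONSYN].sum())
    nonsyn = float(flux[_PAIR_NONSYN].sum())
    return syn, nonsyn


# ---------------------------------------------------------------------------
# Pairwise maximum likelihood (two-sequence GY94)
# ---------------------------------------------------------------------------


def _codon_indices(cds: str) -> np.ndarray:
    idx = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in CODON_INDEX:
            raise ValueError(f"non-sense codon {codon!r} in alignment")
        idx.append(CODON_INDEX[codon])
    return np.array(idx)


def pairwise_loglik(
    cds_a: str, cds_b: str, t: float, kappa: float, omega: float,
    pi: np.ndarray | None = None,
) -> float:
    """Two-sequence GY94 log-likelihood at the given parameters
    (t in expected substitutions per codon site)."""
    pi = f3x4_frequencies([cds_a, cds_b]) if pi is None else pi
    Q = gy94_rate_matrix(kappa, omega, pi)
    mu = -float(np.dot(pi, np.diag(Q)))
    lam, right, left = _eig_reversible(Q / mu, pi)
    P = _transition_matrices(lam, right, left, np.array([max(t, 1e-9)]))[0]
    ia, ib = _codon_indices(cds_a), _codon_indices(cds_b)
    vals = pi[ia] * np.clip(P[ia, ib], 1e-300, None)
    return float(np.log(vals).sum())


def ml_rates(
    cds_a: str, cds_b: str, pi: np.ndarray | None = None
) -> PairwiseRates:
    """Pairwise dN/dS by maximizing the two-sequence GY94 likelihood over
    divergence t, transition/transversion ratio kappa, and omega; codon
    frequencies default to F3x4 from the pair but may be supplied."""
    if pi is None:
        pi = f3x4_frequencies([cds_a, cds_b])
    if cds_a == cds_b:
        return PairwiseRates(dn=0.0, ds=0.0, omega=None, method="ML",
                             reason="identical sequences")

    def nll(x):
        t, kappa, omega = np.exp(x)
        return -pairwise_loglik(cds_a, cds_b, t, kappa, omega, pi)

    best = None
    for w0 in (0.2, 1.0):
        res = optimize.minimize(
            nll,
            x0=np.log([0.3, 2.0, w0]),
            method="L-BFGS-B",
            bounds=[(-8, 3), (-3, 3), (-7, 4)],
        )
        if best is None or res.fun < best.fun:
            best = res
    t, kappa, omega = np.exp(best.x)
    # convert to per-site rates: substitution flux split by site opportunity
    rho_s, rho_n = expected_rates(kappa, omega, pi)
    total = rho_s + rho_n
    rho_s0, rho_n0 = expected_rates(kappa, 1.0, pi)
    sigma_s = rho_s0 / (rho_s0 + rho_n0)  # neutral synonymous opportunity
    syn_sites = 3.0 * sigma_s
    nonsyn_sites = 3.0 - syn_sites
    subs = t  # Q normalized to one substitution per codon per unit t
    ds = subs * (rho_s / total) / syn_sites
    dn = subs * (rho_n / total) / nonsyn_sites
    omega_out = None if ds == 0 else dn / ds
    return PairwiseRates(dn=float(dn), ds=float(ds), omega=omega_out, method="ML")


def pairwise_rates(
    pair: OrthologPair, method: str = "counting", pi: np.ndarray | None = None
) -> PairwiseRates:
    """dN, dS and omega for a gap-free codon-aligned ortholog pair."""
    if method == "counting":
        return ng86_rates(pair.cds_a, pair.cds_b)
    if method == "ML":
        return ml_rates(pair.cds_a, pair.cds_b, pi=pi)
    raise ValueError("method must be 'counting' or 'ML'")


# ---------------------------------------------------------------------------
# Null-distribution outlier analysis
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> float | None:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration of the rank distribution when the smaller sample
    has at most 20 values and there are no ties; otherwise the normal
    approximation with tie correction.  None when either sample has fewer
    than 2 values.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        return None
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 20 and no_ties) else "asymptotic"
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def rate_outlier_analysis(
    toxin_rates: list[PairwiseRates],
    nontoxin_rates: list[PairwiseRates],
    q: float = 0.95,
) -> RateNullSummary:
    """Empirical null thresholds from nontoxins and toxin outlier counts.

    Thresholds are the linear-interpolation q-quantiles of the nontoxin dN,
    dS and omega distributions; toxin pairs exceeding each threshold are
    counted, and the two distributions are compared with two-sided Wilcoxon
    rank-sum tests.  Pairs with undefined omega are dropped from the omega
    statistic (their count is reported).
    """
    if not nontoxin_rates:
        raise ValueError("nontoxin set must be non-empty")

    def values(rates, attr):
        return np.array(
            [getattr(r, attr) for r in rates if getattr(r, attr) is not None]
        )

    thresholds: dict[str, float] = {}
    exceed: dict[str, int] = {}
    pvals: dict[str, float | None] = {}
    n_tox: dict[str, int] = {}
    n_non: dict[str, int] = {}
    for attr, label in (("dn", "dN"), ("ds", "dS"), ("omega", "omega")):
        nx = values(nontoxin_rates, attr)
        tx = values(toxin_rates, attr)
        n_tox[label], n_non[label] = len(tx), len(nx)
        thr = float(np.quantile(nx, q)) if len(nx) else float("nan")
        thresholds[label] = thr
        exceed[label] = int((tx > thr).sum())
        pvals[label] = wilcoxon_rank_sum(tx, nx) if len(tx) >= 2 and len(nx) >= 2 else None
    n_undef = sum(r.omega is None for r in toxin_rates) + sum(
        r.omega is None for r in nontoxin_rates
    )
    return RateNullSummary(
        thresholds=thresholds,
        toxin_exceed_counts=exceed,
        wilcoxon_p=pvals,
        n_toxin=n_tox,
        n_nontoxin=n_non,
        n_undefined_omega=n_undef,
    )


# ---------------------------------------------------------------------------
# Neighbor joining on HKY ML distances
# ---------------------------------------------------------------------------

_NUC_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _hky_distance(seq_a: str, seq_b: str) -> float:
    """ML distance between two nucleotide sequences under HKY."""
    pairs = [
        (a, b) for a, b in zip(seq_a, seq_b) if a in _NUC_IDX and b in _NUC_IDX
    ]
    if not pairs:
        return 0.0
    counts = np.zeros((4, 4))
    for a, b in pairs:
        counts[_NUC_IDX[a], _NUC_IDX[b]] += 1
    if np.trace(counts) == counts.sum():
        return 0.0
    base = counts.sum(axis=0) + counts.sum(axis=1)
    pi = base / base.sum()
    pi = np.clip(pi, 1e-6, None)
    pi /= pi.sum()

    def nll(x):
        t, kappa = np.exp(x)
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                ts = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
                Q[i, j] = pi[j] * (kappa if ts else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        lam, right, left = _eig_reversible(Q / mu, pi)
        P = _transition_matrices(lam, right, left, np.array([t]))[0]
        lik = pi[:, None] * np.clip(P, 1e-300, None)
        return -float((counts * np.log(lik)).sum())

    res = optimize.minimize(
        nll, x0=np.log([0.1, 2.0]), method="L-BFGS-B", bounds=[(-9, 3), (-3, 3)]
    )
    return float(np.exp(res.x[0]))


def nj_tree(sequences: dict[str, str]) -> str:
    """Neighbor-joining newick tree from pairwise HKY ML distances.

    Negative branch lengths are clamped to zero; the tree is unrooted.
    """
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    ids = sorted(sequences)
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _hky_distance(sequences[ids[i]], sequences[ids[j]])
    tree = skbio_nj(DistanceMatrix(dm, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Site models by pruning
# ---------------------------------------------------------------------------


def _beta_category_means(p: float, q: float, K: int) -> np.ndarray:
    """Means of K equal-probability categories of Beta(p, q)."""
    edges = stats.beta.ppf(np.linspace(0, 1, K + 1), p, q)
    upper = special.betainc(p + 1, q, edges[1:])
    lower = special.betainc(p + 1, q, edges[:-1])
    means = (upper - lower) * K * p / (p + q)
    return np.clip(means, 1e-8, 1.0 - 1e-8)


class _CodonData:
    """Site-pattern-compressed alignment bound to a dendropy tree."""

    def __init__(self, alignment: dict[str, str], tree: dendropy.Tree):
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        missing = set(taxa) - set(alignment)
        if missing:
            raise ValueError(f"alignment lacks taxa: {sorted(missing)}")
        mats = np.stack([_codon_indices(alignment[t]) for t in taxa])
        patterns, inverse, counts = np.unique(
            mats.T, axis=0, return_inverse=True, return_counts=True
        )
        self.taxa = taxa
        self.patterns = patterns.T  # (ntaxa, npat)
        self.weights = counts.astype(float)
        self.tree = tree
        self.postorder = list(tree.postorder_node_iter())
        self.node_index = {id(n): i for i, n in enumerate(self.postorder)}
        self.leaf_row = {t: i for i, t in enumerate(taxa)}
        self.rel_lengths = np.array(
            [
                (n.edge.length or 0.0)
                for n in self.postorder
                if n.parent_node is not None
            ]
        )

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())


def _prune_loglik(data: _CodonData, pi, class_probs, class_omegas, kappa, scale):
    """Mixture log-likelihood by Felsenstein pruning with per-node scaling."""
    npat = data.patterns.shape[1]
    branch_ts = np.clip(data.rel_lengths * scale, 1e-9, None)
    active = [(p_k, w_k) for p_k, w_k in zip(class_probs, class_omegas) if p_k > 0]
    if not active:
        return -np.inf
    ncls = len(active)
    # mixture-average normalization: one clock shared by all site classes
    Qs = [gy94_rate_matrix(kappa, w_k, pi) for _, w_k in active]
    mus = [-float(np.dot(pi, np.diag(Q))) for Q in Qs]
    mu_bar = sum(p_k * mu for (p_k, _), mu in zip(active, mus))
    mu_bar /= sum(p_k for p_k, _ in active)
    # batched P(t): (ncls, nbranch, 61, 61)
    P = np.empty((ncls, len(branch_ts), N_SENSE, N_SENSE))
    for c, Q in enumerate(Qs):
        lam, right, left = _eig_reversible(Q / mu_bar, pi)
        P[c] = _transition_matrices(lam, right, left, branch_ts)
    branch_index = {}
    bi = 0
    for node in data.postorder:
        if node.parent_node is not None:
            branch_index[id(node)] = bi
            bi += 1
    partial: dict[int, np.ndarray] = {}
    log_scalers = np.zeros(npat)
    for node in data.postorder:
        if node.is_leaf():
            continue  # tip partials are one-hot; handled at the parent
        L = np.ones((ncls, npat, N_SENSE))
        for child in node.child_nodes():
            Pc = P[:, branch_index[id(child)]]  # (ncls, 61, 61)
            if child.is_leaf():
                states = data.patterns[data.leaf_row[child.taxon.label]]
                L *= Pc[:, :, states].transpose(0, 2, 1)
            else:
                L *= partial.pop(id(child)) @ Pc.transpose(0, 2, 1)
        mx = L.max(axis=(0, 2))
        mx = np.where(mx > 0, mx, 1.0)
        L /= mx[None, :, None]
        log_scalers += np.log(mx)
        partial[id(node)] = L
    root_L = np.clip(partial[id(data.tree.seed_node)] @ pi, 1e-300, None)
    log_p = np.log([p_k for p_k, _ in active])
    site_loglik = special.logsumexp(np.log(root_L) + log_p[:, None], axis=0)
    return float(np.dot(data.weights, site_loglik + log_scalers))


def _model_spec(model: str, K: int):
    """Parameter layout per model: names, bounds, deterministic starts."""
    if model == "M0":
        names = ["kappa", "scale", "omega"]
        bounds = [(0.05, 30.0), (1e-4, 200.0), (1e-6, 50.0)]
        starts = [[2.0, 1.0, w] for w in (0.1, 0.5, 2.0)]
    elif model == "M1a":
        names = ["kappa", "scale", "p0", "w0"]
        bounds = [(0.05, 30.0), (1e-4, 200.0), (1e-6, 1 - 1e-6), (1e-6, 1.0)]
        starts = [[2.0, 1.0, 0.7, w] for w in (0.1, 0.5, 0.9)]
    elif model == "M2a":
        names = ["kappa", "scale", "f0", "f1", "w0", "w2"]
        bounds = [
            (0.05, 30.0),
            (1e-4, 200.0),
            (1e-6, 1 - 1e-6),
            (1e-6, 1 - 1e-6),
            (1e-6, 1.0),
            (1.0, 99.0),
        ]
        starts = [
            [2.0, 1.0, 0.6, 0.7, 0.1, w2] for w2 in (1.5, 3.0, 8.0)
        ]
    elif model == "M7":
        names = ["kappa", "scale", "bp", "bq"]
        bounds = [(0.05, 30.0), (1e-4, 200.0), (0.005, 99.0), (0.005, 99.0)]
        starts = [[2.0, 1.0, p, q] for p, q in ((0.5, 2.0), (1.0, 1.0), (2.0, 0.5))]
    elif model == "M8":
        names = ["kappa", "scale", "bp", "bq", "p0", "ws"]
        bounds = [
            (0.05, 30.0),
            (1e-4, 200.0),
            (0.005, 99.0),
            (0.005, 99.0),
            (1e-6, 1 - 1e-6),
            (1.0, 99.0),
        ]
        starts = [
            [2.0, 1.0, 0.5, 2.0, 0.9, w] for w in (1.5, 3.0, 8.0)
        ]
    else:
        raise ValueError(f"unknown model {model!r}")
    return names, bounds, starts


def _classes_from_params(model: str, x, K: int):
    if model == "M0":
        kappa, scale, w = x
        return kappa, scale, np.array([1.0]), np.array([w])
    if model == "M1a":
        kappa, scale, p0, w0 = x
        return kappa, scale, np.array([p0, 1 - p0]), np.array([w0, 1.0])
    if model == "M2a":
        kappa, scale, f0, f1, w0, w2 = x
        p0 = f0
        p1 = (1 - f0) * f1
        p2 = 1 - p0 - p1
        return (
            kappa,
            scale,
            np.array([p0, p1, p2]),
            np.array([w0, 1.0, w2]),
        )
    if model == "M7":
        kappa, scale, bp, bq = x
        return (
            kappa,
            scale,
            np.full(K, 1.0 / K),
            _beta_category_means(bp, bq, K),
        )
    if model == "M8":
        kappa, scale, bp, bq, p0, ws = x
        probs = np.concatenate([np.full(K, p0 / K), [1 - p0]])
        omegas = np.concatenate([_beta_category_means(bp, bq, K), [ws]])
        return kappa, scale, probs, omegas
    raise ValueError(model)


def fit_site_model(
    alignment: dict[str, str],
    tree: str | dendropy.Tree,
    model: str,
    K: int = 10,
    pi: np.ndarray | None = None,
    max_iter: int = 500,
    fixed: dict[str, float] | None = None,
    warm_start: "SiteModelFit | None" = None,
) -> SiteModelFit:
    """Fit a codon site model by maximum likelihood.

    The likelihood is computed by pruning over the 61 sense codons with a
    GY94 rate matrix and F3x4 frequencies estimated from the data; the
    site-class mixture is integrated per site (the M7 beta is discretized
    into K equal-probability categories at category means).  The input
    tree fixes topology and relative branch lengths; a global scale on
    those lengths is optimized jointly with the model parameters by bounded
    quasi-Newton from three deterministic starts.  `fixed` pins named
    parameters (e.g. forcing the positive-selection class weight to zero to
    recover the nested null).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    data = _CodonData(alignment, tree)
    pi = f3x4_frequencies(alignment.values()) if pi is None else pi
    names, bounds, starts = _model_spec(model, K)
    fixed = fixed or {}
    if not fixed and model in ("M2a", "M8"):
        # warm-start the alternative from its nested null so the fitted
        # lnL can never fall below it (up to optimizer tolerance); reuse a
        # caller-supplied null fit, otherwise fit it here
        null_model = "M1a" if model == "M2a" else "M7"
        if warm_start is not None and warm_start.model == null_model:
            null_fit = warm_start
        else:
            null_fit = fit_site_model(
                alignment, tree, null_model, K=K, pi=pi, max_iter=max_iter
            )
        e = null_fit.extra
        if model == "M2a":
            starts = starts + [
                [e["kappa"], e["scale"], e["p0"], 1.0 - 1e-6, e["w0"], 2.0]
            ]
        else:
            starts = starts + [
                [e["kappa"], e["scale"], e["bp"], e["bq"], 1.0 - 1e-6, 2.0]
            ]
    free_idx = [i for i, n in enumerate(names) if n not in fixed]

    def unpack(z):
        x = np.empty(len(names))
        for i, n in enumerate(names):
            x[i] = fixed[n] if n in fixed else z[free_idx.index(i)]
        return x

    def nll(z):
        kappa, scale, probs, omegas = _classes_from_params(model, unpack(z), K)
        if probs.min() < -1e-9:
            return 1e12
        return -_prune_loglik(data, pi, probs, omegas, kappa, scale)

    free_bounds = [bounds[i] for i in free_idx]
    # two-stage schedule: short deterministic runs from every start, then a
    # full optimization continued from the most promising one
    probes = []
    for start in starts:
        z0 = np.array([start[i] for i in free_idx])
        res = optimize.minimize(
            nll,
            z0,
            method="L-BFGS-B",
            bounds=free_bounds,
            options={"maxiter": 25, "ftol": 1e-8},
        )
        probes.append(res)
    probes.sort(key=lambda r: r.fun)
    best = optimize.minimize(
        nll,
        probes[0].x,
        method="L-BFGS-B",
        bounds=free_bounds,
        options={"maxiter": max_iter, "ftol": 1e-9},
    )
    if probes[0].fun < best.fun:
        best = probes[0]
    converged = True
    if not best.success and "ITERATIONS" in str(best.message).upper():
        converged = False
        warnings.warn(f"{model} fit did not converge; best lnL kept")
    x = unpack(best.x)
    kappa, scale, probs, omegas = _classes_from_params(model, x, K)
    branch_lengths = {}
    for node in data.postorder:
        if node.parent_node is not None:
            label = (
                node.taxon.label
                if node.is_leaf()
                else f"node{data.node_index[id(node)]}"
            )
            branch_lengths[label] = float((node.edge.length or 0.0) * scale)
    return SiteModelFit(
        model=model,
        lnl=-float(best.fun),
        p=tuple(float(v) for v in probs),
        w=tuple(float(v) for v in omegas),
        kappa=float(kappa),
        tree_scale=float(scale),
        branch_lengths=branch_lengths,
        codon_freqs=pi,
        converged=converged,
        extra={name: float(v) for name, v in zip(names, x)},
    )


# ---------------------------------------------------------------------------
# Likelihood ratio test
# ---------------------------------------------------------------------------


def lrt_pvalue(neg_lnl_null: float, neg_lnl_alt: float, df: int = 2) -> LRTResult:
    """Chi-square LRT from -lnL values as conventionally printed.

    statistic = 2 (lnL_alt - lnL_null) = 2 (neg_lnl_null - neg_lnl_alt);
    p is the upper chi-square tail (for df=2 exactly exp(-statistic/2)).
    A negative statistic (null above alternative) is clamped to zero with a
    warning.
    """
    statistic = 2.0 * (neg_lnl_null - neg_lnl_alt)
    if statistic < 0:
        warnings.warn("negative LRT statistic clamped to 0")
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic=statistic, df=df, p=p)
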