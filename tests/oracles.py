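"""Independent brute-force oracles used only by the test suite.

These are written against the published definitions directly (and against
Biopython's codon table rather than the package's own genetic-code module)
so that they stay independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
from math import comb

from Bio.Data.CodonTable import standard_dna_table

_FORWARD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _FORWARD[_stop] = "*"


def _aa(codon: str) -> str:
    return _FORWARD[codon]


def ng86_site_counts_oracle(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts for one codon;
    changes to stop codons count as nonsynonymous opportunity."""
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) != "*" and _aa(mutant) == _aa(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def ng86_diff_counts_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between two
    codons; pathways through stop codons are dropped unless all pathways
    pass through a stop."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(positions):
        current = c1
        syn = nonsyn = 0
        hit_stop = False
        for pos in order:
            mutant = current[:pos] + c2[pos] + current[pos + 1 :]
            if _aa(mutant) == "*":
                hit_stop = True
            if _aa(mutant) == _aa(current):
                syn += 1
            else:
                nonsyn += 1
            current = mutant
        all_paths.append((hit_stop, syn, nonsyn))
    usable = [(s, n) for stop, s, n in all_paths if not stop]
    if not usable:
        usable = [(s, n) for _, s, n in all_paths]
    return (
        sum(s for s, _ in usable) / len(usable),
        sum(n for _, n in usable) / len(usable),
    )


def ng86_counts_oracle(seq1: str, seq2: str):
    """(S, N, Sd, Nd) over an aligned codon pair, brute force; codon
    columns containing a stop codon are not sites."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if _aa(c1) == "*" or _aa(c2) == "*":
            continue
        s1, n1 = ng86_site_counts_oracle(c1)
        s2, n2 = ng86_site_counts_oracle(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = ng86_diff_counts_oracle(c1, c2)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def wilcoxon_two_sided_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by full enumeration of all assignments
    of the pooled values to the two groups (assumes no ties)."""
    pooled = sorted(x) + sorted(y)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n, m = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    total = comb(n + m, n)
    count_le = count_ge = 0
    for combo in itertools.combinations(range(n + m), n):
        u = sum(ranks[pooled[i]] for i in combo) - n * (n + 1) / 2
        if u <= u_obs:
            count_le += 1
        if u >= u_obs:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return min(p, 1.0)
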