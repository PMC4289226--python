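"""Genetic-code utilities shared by the simulator and the selection analyses.

Standard nuclear genetic code; the 61 sense codons form the state space of
every codon model in this package (stop codons are excluded from rate
matrices and never introduced by the simulator).
"""

from __future__ import annotations

import itertools

NUCLEOTIDES = "TCAG"

GENETIC_CODE: dict[str, str] = {}
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_n1, _n2, _n3) in enumerate(
    itertools.product(NUCLEOTIDES, NUCLEOTIDES, NUCLEOTIDES)
):
    GENETIC_CODE[_n1 + _n2 + _n3] = _AA[_i]

STOP_CODONS = tuple(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS = tuple(c for c, a in GENETIC_CODE.items() if a != "*")
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T point change."""
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def translate_cds(cds: str) -> str:
    """Translate a CDS, including any terminal stop as '*'."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def is_valid_cds(cds: str) -> bool:
    """ATG start, terminal stop, no internal stop, length % 3 == 0."""
    if len(cds) % 3 or len(cds) < 6 or not cds.startswith("ATG"):
        return False
    aa = translate_cds(cds)
    return aa[-1] == "*" and "*" not in aa[:-1]


def single_nucleotide_neighbors(codon: str):
    """Yield (position, new_base, neighbor_codon) for the 9 point changes."""
    for pos in range(3):
        for base in "ACGT":
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1 :]


def codon_change_type(c1: str, c2: str) -> str | None:
    """'syn'/'nonsyn' for a single-nucleotide sense-codon change, else None."""
    if c1 == c2:
        return None
    diffs = sum(a != b for a, b in zip(c1, c2))
    if diffs != 1 or GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
        return None
    return "syn" if GENETIC_CODE[c1] == GENETIC_CODE[c2] else "nonsyn"
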