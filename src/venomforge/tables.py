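"""Loaders for the published study tables shipped with the package.

These are the printed venom-gland expression tables, whole-venom protein
identification tables, and codon site-model fits for the two rear-fanged
snakes (Brown Treesnake, *Boiga irregularis*, and Desert Night Snake,
*Hypsiglena* sp.).  They serve as fixed reference inputs for the
table-level consistency analyses: class-level expression summaries,
likelihood-ratio-test arithmetic, and proteomic cross-referencing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quant import ExpressionRecord

SPECIES_KEYS = ("boiga", "hypsiglena")


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("venomforge.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_toxin_expression(species: str) -> list[ExpressionRecord]:
    """Published toxin-cluster expression table for one species."""
    if species not in SPECIES_KEYS:
        raise ValueError(f"species must be one of {SPECIES_KEYS}")
    df = _load(f"{species}_toxin_expression.tsv")
    return [
        ExpressionRecord(
            rank=int(r.rank),
            cluster_name=str(r.cluster_name),
            cluster_size=int(r.cluster_size),
            cds_length=int(r.cds_length),
            median_coverage=float(r.median_coverage),
            pct_toxin_reads=float(r.pct_toxin_reads),
            pct_total_reads=float(r.pct_total_reads),
        )
        for r in df.itertuples()
    ]


def load_protein_identifications(species: str) -> pd.DataFrame:
    """Published whole-venom protein identification table (score, peptide
    matches, % sequence coverage, shared-unique-peptide group; group is NaN
    for entries lacking a distinguishing peptide)."""
    if species not in SPECIES_KEYS:
        raise ValueError(f"species must be one of {SPECIES_KEYS}")
    return _load(f"{species}_protein_ids.tsv")


def load_site_model_fits() -> pd.DataFrame:
    """Published -lnL pairs for the nested codon site-model comparisons
    (nearly-neutral vs positive-selection, and beta vs beta-plus-selection)
    on the six toxin alignments, with the printed p-values."""
    return _load("site_model_fits.tsv")
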