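"""Bundled reference data: a published pharmacogene CNV cohort summary.

A survey of 123 healthy donors from Bogotá, Colombia, typed all 14 genes
of the default panel by MLPA and published per-gene genotype and allele
frequencies (as percentages at one decimal).  Those tables are embedded
here as a ready-made input for cohort summarization, for reconstructing
integer genotype counts, and as realistic allele frequencies for the
simulator.

Only per-gene marginals were published; the joint per-individual
genotypes were not, so quantities that need them (category percentages,
carrier-group fractions) cannot be reproduced from this table — genes
can only be recombined under an independence assumption.
"""

from __future__ import annotations

import pandas as pd

from .simulate import AlleleFreqSpec, apportion

__all__ = [
    "COHORT_N",
    "COHORT_GENES",
    "cohort_genotype_percent",
    "cohort_allele_percent",
    "cohort_genotype_counts",
    "cohort_allele_freq_specs",
]

#: Size of the published cohort.
COHORT_N = 123

#: Gene order of the published frequency tables.
COHORT_GENES = (
    "GSTM1",
    "GSTP1",
    "GSTT1",
    "CYP1A1",
    "CYP1A2",
    "CYP1B1",
    "CYP2A6",
    "CYP2B6",
    "CYP2C9",
    "CYP2C19",
    "CYP2D6",
    "CYP2E1",
    "CYP3A4",
    "CYP3A5",
)

# Genotype frequencies (%) per gene over the 123 donors.
_GENOTYPE_PERCENT = {
    "Del/Wt": (5.7, 0.8, 15.4, 0.8, 0.0, 0.8, 4.1, 0.0, 0.8, 0.8, 3.3, 0.0, 0.8, 0.0),
    "Del/Del": (44.7, 0.0, 19.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "Dup/Wt": (1.6, 0.0, 2.4, 0.0, 0.0, 0.0, 0.8, 0.8, 0.8, 0.0, 10.6, 3.3, 0.0, 0.8),
    "Dup/Dup": (14.6, 0.0, 16.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.4, 0.0, 0.0, 0.0),
    "Wt/Wt": (33.3, 99.2, 46.3, 99.2, 100.0, 99.2, 95.1, 99.2, 98.4, 99.2, 83.7, 96.7, 99.2, 99.2),
}

# Allele frequencies (%) per gene as published alongside the genotypes.
_ALLELE_PERCENT = {
    "Deletion": (47.6, 0.4, 27.2, 0.4, 0.0, 0.4, 2.0, 0.0, 0.4, 0.4, 1.6, 0.0, 0.4, 0.0),
    "Duplication": (15.4, 0.0, 17.5, 0.0, 0.0, 0.0, 0.4, 0.4, 0.4, 0.0, 7.7, 1.6, 0.0, 0.4),
    "No CNV": (37.0, 99.6, 55.3, 99.6, 100.0, 99.6, 97.6, 99.6, 99.2, 99.6, 90.7, 98.4, 99.6, 99.6),
}


def cohort_genotype_percent() -> pd.DataFrame:
    """Published genotype frequencies (%), diplotype labels x genes."""
    return pd.DataFrame(_GENOTYPE_PERCENT, index=list(COHORT_GENES)).T


def cohort_allele_percent() -> pd.DataFrame:
    """Published allele frequencies (%), allele classes x genes."""
    return pd.DataFrame(_ALLELE_PERCENT, index=list(COHORT_GENES)).T


def cohort_genotype_counts(n: int = COHORT_N) -> pd.DataFrame:
    """Integer genotype counts per gene reconstructed at cohort size ``n``.

    Largest-remainder apportionment of the published percentages; at the
    original n = 123 each count is the nearest integer and columns sum
    to 123 exactly.
    """
    pct = cohort_genotype_percent()
    counts = {
        gene: apportion(pct[gene].to_numpy(), n) for gene in pct.columns
    }
    return pd.DataFrame(counts, index=pct.index)


def cohort_allele_freq_specs() -> list[AlleleFreqSpec]:
    """Published allele frequencies as simulator specs (fractions)."""
    pct = cohort_allele_percent()
    return [
        AlleleFreqSpec(
            gene=g,
            p_del=pct.loc["Deletion", g] / 100.0,
            p_dup=pct.loc["Duplication", g] / 100.0,
        )
        for g in pct.columns
    ]
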