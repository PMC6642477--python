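"""Cohort-level population-genetics summaries of gene CNV calls.

From per-sample gene calls this module derives the standard outputs of a
population CNV survey:

* genotype frequencies per gene (fractions of Del/Del, Del/Wt, Wt/Wt,
  Dup/Wt, Dup/Dup over called samples);
* allele frequencies per gene by direct allele counting,
  p_del = f(Del/Del) + f(Del/Wt)/2 and symmetrically for duplications;
* a 14-category taxonomy of individuals by the combination of
  gene-level CNV classes they carry;
* a 4-group carrier partition (deletions only / duplications only /
  both / none);
* a per-gene CNV-presence census (which genes harbor deletions,
  duplications, both, or neither in the cohort);
* the textbook sample-size calculation for estimating a proportion,
  with optional finite population correction.

Reported percentages use half-up rounding at a configurable number of
decimals (1 by default); internal arithmetic is at full precision.
Samples whose call at a gene is Unknown/ambiguous are excluded from
that gene's numerator and denominator, with exclusion counts retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPE_ORDER",
    "GenotypeFreqTable",
    "genotype_frequencies",
    "allele_frequencies",
    "categorize_individual",
    "assign_categories",
    "carrier_groups",
    "gene_cnv_census",
    "sample_size",
    "round_half_up",
]

GENOTYPE_ORDER = ("Del/Wt", "Del/Del", "Dup/Wt", "Dup/Dup", "Wt/Wt")

_DEL_CLASSES = frozenset({"HOM_DEL", "HET_DEL"})
_DUP_CLASSES = frozenset({"HOM_DUP", "HET_DUP"})
_NON_NORMAL = _DEL_CLASSES | _DUP_CLASSES

#: Category number for each combination of gene-level CNV classes present
#: in an individual (the class set).  Two textually indistinguishable
#: categories exist for "homo- and heterozygous deletions"; the classifier
#: emits 4 and category 7 is unreachable by construction.  Class sets with
#: no defined category map to 0 (unclassified extension).
CATEGORY_BY_CLASS_SET: dict[frozenset[str], int] = {
    frozenset(): 1,
    frozenset({"HOM_DEL"}): 2,
    frozenset({"HET_DEL"}): 3,
    frozenset({"HET_DEL", "HOM_DEL"}): 4,
    frozenset({"HOM_DUP"}): 5,
    frozenset({"HET_DUP"}): 6,
    frozenset({"HET_DUP", "HOM_DEL"}): 8,
    frozenset({"HOM_DUP", "HET_DEL"}): 9,
    frozenset({"HOM_DUP", "HOM_DEL"}): 10,
    frozenset({"HOM_DUP", "HET_DUP"}): 11,
    frozenset({"HET_DUP", "HOM_DEL", "HET_DEL"}): 12,
    frozenset({"HET_DEL", "HET_DUP", "HOM_DUP"}): 13,
    frozenset({"HET_DUP", "HOM_DUP", "HOM_DEL"}): 14,
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed survey tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeFreqTable:
    """Per-gene genotype fractions plus per-gene denominators.

    ``fractions`` is a label x gene DataFrame over called samples;
    ``n_called`` and ``n_excluded`` are per-gene Series counting the
    samples entering and excluded from each gene's denominator.
    """

    fractions: pd.DataFrame
    n_called: pd.Series
    n_excluded: pd.Series

    def percent(self, ndigits: int = 1) -> pd.DataFrame:
        return (self.fractions * 100.0).map(lambda v: round_half_up(v, ndigits))


def genotype_frequencies(calls: pd.DataFrame) -> GenotypeFreqTable:
    """Tabulate genotype fractions per gene from a calls table.

    ``calls`` needs columns ``sample_id, gene, genotype_label``.  Labels
    outside the five called diplotypes (Unknown, ambiguous, Del/Dup
    truth labels) are excluded from numerator and denominator; exclusion
    counts are reported per gene.  Genes with zero called samples are
    omitted with a warning.
    """
    import warnings

    fractions: dict[str, pd.Series] = {}
    n_called: dict[str, int] = {}
    n_excluded: dict[str, int] = {}
    for gene, grp in calls.groupby("gene", sort=False):
        labels = grp["genotype_label"]
        called = labels[labels.isin(GENOTYPE_ORDER)]
        n_excluded[gene] = len(labels) - len(called)
        if called.empty:
            warnings.warn(
                f"gene {gene}: no called samples; omitted from frequency table",
                stacklevel=2,
            )
            continue
        counts = called.value_counts().reindex(GENOTYPE_ORDER, fill_value=0)
        fractions[gene] = counts / len(called)
        n_called[gene] = len(called)
    if not fractions:
        raise ValueError("no gene has any called sample")
    frame = pd.DataFrame(fractions).reindex(list(GENOTYPE_ORDER))
    return GenotypeFreqTable(
        fractions=frame,
        n_called=pd.Series(n_called, dtype=int),
        n_excluded=pd.Series(n_excluded, dtype=int).reindex(frame.columns),
    )


def allele_frequencies(gt: GenotypeFreqTable) -> pd.DataFrame:
    """Allele frequencies by direct counting from genotype fractions.

    Returns a DataFrame with rows ``Deletion``, ``Duplication``,
    ``No CNV`` and one column per gene; each column sums to 1.
    """
    f = gt.fractions
    p_del = f.loc["Del/Del"] + f.loc["Del/Wt"] / 2.0
    p_dup = f.loc["Dup/Dup"] + f.loc["Dup/Wt"] / 2.0
    p_wt = f.loc["Wt/Wt"] + f.loc["Del/Wt"] / 2.0 + f.loc["Dup/Wt"] / 2.0
    return pd.DataFrame(
        [p_del, p_dup, p_wt], index=["Deletion", "Duplication", "No CNV"]
    )


def categorize_individual(class_set: Iterable[str]) -> int:
    """Category (1-14, or 0 for undefined combinations) of one individual.

    ``class_set`` is the set of non-NORMAL gene-level CNV classes the
    individual carries across all genes; an empty set is the wild-type
    category 1.
    """
    cs = frozenset(class_set)
    invalid = cs - _NON_NORMAL
    if invalid:
        raise ValueError(f"invalid CNV class(es) in class set: {sorted(invalid)}")
    return CATEGORY_BY_CLASS_SET.get(cs, 0)


def _class_sets(calls: pd.DataFrame) -> pd.Series:
    """Per-sample set of non-NORMAL called classes (Unknown/ambiguous dropped)."""
    called = calls[calls["genotype_label"].isin(GENOTYPE_ORDER)]
    if called.empty:
        raise ValueError("no called genes in calls table")
    return called.groupby("sample_id")["cnv_class"].agg(
        lambda s: frozenset(set(s) & _NON_NORMAL)
    )


def assign_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Assign every sample its mutational-status category.

    Returns a DataFrame ``sample_id, category, class_set`` (class_set as
    a sorted ``+``-joined string).  Samples with no called gene are
    excluded upstream by :func:`_class_sets`.
    """
    sets = _class_sets(calls)
    return pd.DataFrame(
        {
            "sample_id": sets.index,
            "category": [categorize_individual(cs) for cs in sets],
            "class_set": ["+".join(sorted(cs)) for cs in sets],
        }
    ).reset_index(drop=True)


def carrier_groups(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Partition samples into the 4 carrier groups and report fractions.

    Groups: ``deletions_only`` (at least one deletion-class gene and no
    duplication-class gene), ``duplications_only`` (symmetric), ``both``,
    ``none``.  Samples with no called gene are excluded and never enter
    the denominator.

    Returns ``(per_sample, fractions)`` where fractions is a dict over
    the four groups summing to 1.
    """
    sets = _class_sets(calls)

    def group_of(cs: frozenset[str]) -> str:
        has_del = bool(cs & _DEL_CLASSES)
        has_dup = bool(cs & _DUP_CLASSES)
        if has_del and has_dup:
            return "both"
        if has_del:
            return "deletions_only"
        if has_dup:
            return "duplications_only"
        return "none"

    per_sample = pd.DataFrame(
        {"sample_id": sets.index, "group": [group_of(cs) for cs in sets]}
    ).reset_index(drop=True)
    n = len(per_sample)
    fractions = {
        g: float((per_sample["group"] == g).sum()) / n
        for g in ("deletions_only", "duplications_only", "both", "none")
    }
    return per_sample, fractions


def gene_cnv_census(gt: GenotypeFreqTable, ndigits: int = 1) -> dict:
    """Which genes harbor deletions/duplications, and summary percentages.

    A gene carries deletions when f(Del/Del) + f(Del/Wt) > 0 over called
    samples; duplications symmetrically.  Percentages are over the genes
    present in the table, half-up rounded at ``ndigits``.
    """
    f = gt.fractions
    del_present = (f.loc["Del/Del"] + f.loc["Del/Wt"]) > 0
    dup_present = (f.loc["Dup/Dup"] + f.loc["Dup/Wt"]) > 0
    n_genes = f.shape[1]
    both = del_present & dup_present
    either = del_present ^ dup_present
    any_cnv = del_present | dup_present

    def pct(k: int) -> float:
        return round_half_up(100.0 * k / n_genes, ndigits)

    return {
        "per_gene": pd.DataFrame(
            {"del_present": del_present, "dup_present": dup_present}
        ),
        "n_genes": int(n_genes),
        "n_with_both": int(both.sum()),
        "n_with_either": int(either.sum()),
        "n_with_any": int(any_cnv.sum()),
        "n_without_cnv": int((~any_cnv).sum()),
        "pct_with_both": pct(int(both.sum())),
        "pct_with_either": pct(int(either.sum())),
        "pct_with_any": pct(int(any_cnv.sum())),
        "genes_with_both": sorted(f.columns[both]),
        "genes_without_cnv": sorted(f.columns[~any_cnv]),
    }


def sample_size(
    p: float, e: float, z: float = 1.96, N: int | None = None
) -> int:
    """Sample size for estimating a proportion, rounded up.

    n0 = z^2 p (1-p) / e^2; with a finite population of size ``N`` the
    correction n = n0 / (1 + (n0 - 1)/N) applies.  Defaults give the
    95%-confidence normal quantile z = 1.96.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if e <= 0:
        raise ValueError(f"e must be positive, got {e}")
    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    n0 = z * z * p * (1.0 - p) / (e * e)
    if N is not None:
        if N < 1:
            raise ValueError(f"N must be >= 1, got {N}")
        n0 = n0 / (1.0 + (n0 - 1.0) / N)
    return math.ceil(n0 - 1e-12)
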