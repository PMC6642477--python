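"""Copy-number calling from dosage quotients.

A dosage quotient (DQ) is the doubly normalized probe ratio of a test
sample; for an autosomal locus its expectation is copies/2.  DQs are
mapped to discrete copy-number classes through fixed intervals with
strict (open) boundaries; values falling in the gaps between intervals —
including every interval endpoint — are ambiguous:

====================  =====================
class                 DQ interval
====================  =====================
homozygous deletion   DQ < eps  (nominally DQ = 0)
heterozygous deletion 0.40 < DQ < 0.65
normal                0.80 < DQ < 1.20
heterozygous dup.     1.30 < DQ < 1.65
homozygous dup.       1.75 < DQ < 2.15
ambiguous             everything else
====================  =====================

A literal ``DQ = 0`` is unattainable under any measurement noise, so the
homozygous-deletion class accepts DQ below a small tolerance ``eps``
(default 0.10); DQ in [eps, 0.40] remains ambiguous.

Probe calls are aggregated to one call per gene: a deletion or
duplication seen on any exon marks the whole gene as deleted or
duplicated.  When probes of one gene disagree in zygosity but not in
direction, the more extreme class wins; when deletion- and
duplication-class probes co-occur in one gene the call is discordant and
the genotype is reported Unknown.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CopyNumberClass",
    "DqThresholds",
    "GeneCall",
    "PhenotypePrediction",
    "GENOTYPE_LABELS",
    "classify_dq",
    "classify_dq_array",
    "call_gene",
    "genotype_label",
    "predict_phenotype",
    "call_cohort",
]


class CopyNumberClass(str, enum.Enum):
    HOM_DEL = "HOM_DEL"
    HET_DEL = "HET_DEL"
    NORMAL = "NORMAL"
    HET_DUP = "HET_DUP"
    HOM_DUP = "HOM_DUP"
    AMBIGUOUS = "AMBIGUOUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Reporting order of the five called classes, lowest dosage first.
CLASS_ORDER = (
    CopyNumberClass.HOM_DEL,
    CopyNumberClass.HET_DEL,
    CopyNumberClass.NORMAL,
    CopyNumberClass.HET_DUP,
    CopyNumberClass.HOM_DUP,
)

GENOTYPE_LABELS: dict[CopyNumberClass, str] = {
    CopyNumberClass.HOM_DEL: "Del/Del",
    CopyNumberClass.HET_DEL: "Del/Wt",
    CopyNumberClass.NORMAL: "Wt/Wt",
    CopyNumberClass.HET_DUP: "Dup/Wt",
    CopyNumberClass.HOM_DUP: "Dup/Dup",
}

#: Total gene copies implied by each called genotype.
COPIES_BY_LABEL = {
    "Del/Del": 0,
    "Del/Wt": 1,
    "Wt/Wt": 2,
    "Dup/Wt": 3,
    "Dup/Dup": 4,
}

PHENOTYPE_BY_COPIES = {
    0: "poor",
    1: "intermediate",
    2: "normal",
    3: "ultrarapid",
    4: "ultrarapid",
}

PREDICTION_NOTE = "copy-number-only prediction; SNV alleles not assessed"


@dataclass(frozen=True)
class DqThresholds:
    """Interval bounds of the DQ-to-class mapping (all open intervals)."""

    hom_del_eps: float = 0.10
    het_del: tuple[float, float] = (0.40, 0.65)
    normal: tuple[float, float] = (0.80, 1.20)
    het_dup: tuple[float, float] = (1.30, 1.65)
    hom_dup: tuple[float, float] = (1.75, 2.15)

    def __post_init__(self) -> None:
        bounds = [self.hom_del_eps]
        for lo, hi in (self.het_del, self.normal, self.het_dup, self.hom_dup):
            if not lo < hi:
                raise ValueError(f"empty DQ interval ({lo}, {hi})")
            bounds.extend([lo, hi])
        if any(b2 < b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("DQ intervals must be ordered and pairwise disjoint")
        if self.hom_del_eps < 0:
            raise ValueError("hom_del_eps must be non-negative")

    @property
    def intervals(self) -> tuple[tuple[CopyNumberClass, float, float], ...]:
        return (
            (CopyNumberClass.HET_DEL, *self.het_del),
            (CopyNumberClass.NORMAL, *self.normal),
            (CopyNumberClass.HET_DUP, *self.het_dup),
            (CopyNumberClass.HOM_DUP, *self.hom_dup),
        )

    def to_dict(self) -> dict:
        return {
            "hom_del_eps": self.hom_del_eps,
            "het_del": list(self.het_del),
            "normal": list(self.normal),
            "het_dup": list(self.het_dup),
            "hom_dup": list(self.hom_dup),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DqThresholds":
        kwargs = {}
        for key in ("het_del", "normal", "het_dup", "hom_dup"):
            if key in doc:
                lo, hi = doc[key]
                kwargs[key] = (float(lo), float(hi))
        if "hom_del_eps" in doc:
            kwargs["hom_del_eps"] = float(doc["hom_del_eps"])
        return cls(**kwargs)


DEFAULT_THRESHOLDS = DqThresholds()


def classify_dq(
    dq: float, thresholds: DqThresholds = DEFAULT_THRESHOLDS
) -> CopyNumberClass:
    """Map one dosage quotient to a copy-number class.

    Total on [0, inf): every finite non-negative DQ yields exactly one
    class.  Interval endpoints are ambiguous (the intervals are open).
    """
    if not math.isfinite(dq):
        raise ValueError(f"dq must be finite, got {dq}")
    if dq < 0:
        raise ValueError(f"dq must be non-negative, got {dq}")
    if dq < thresholds.hom_del_eps:
        return CopyNumberClass.HOM_DEL
    for cls_, lo, hi in thresholds.intervals:
        if lo < dq < hi:
            return cls_
    return CopyNumberClass.AMBIGUOUS


def classify_dq_array(
    dq: np.ndarray, thresholds: DqThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Vectorized :func:`classify_dq`; returns an object array of classes."""
    dq = np.asarray(dq, dtype=float)
    if not np.all(np.isfinite(dq)) or np.any(dq < 0):
        raise ValueError("dq values must be finite and non-negative")
    conds = [dq < thresholds.hom_del_eps] + [
        (lo < dq) & (dq < hi) for _, lo, hi in thresholds.intervals
    ]
    choices = [CopyNumberClass.HOM_DEL] + [c for c, _, _ in thresholds.intervals]
    return np.select(conds, choices, default=CopyNumberClass.AMBIGUOUS)


@dataclass(frozen=True)
class GeneCall:
    """Gene-level CNV call aggregated from per-probe classes."""

    sample_id: str
    gene: str
    cnv_class: CopyNumberClass
    probe_classes: tuple[CopyNumberClass, ...]
    discordant: bool
    genotype_label: str

    @property
    def n_probes_called(self) -> int:
        return sum(1 for c in self.probe_classes if c != CopyNumberClass.AMBIGUOUS)


def _aggregate(
    classes: Sequence[CopyNumberClass],
) -> tuple[CopyNumberClass, bool]:
    """Collapse per-probe classes to (gene class, discordant flag)."""
    if len(classes) == 0:
        raise ValueError("call_gene requires at least one probe class")
    called = [c for c in classes if c != CopyNumberClass.AMBIGUOUS]
    if not called:
        return CopyNumberClass.AMBIGUOUS, False
    has_hom_del = CopyNumberClass.HOM_DEL in called
    has_het_del = CopyNumberClass.HET_DEL in called
    has_hom_dup = CopyNumberClass.HOM_DUP in called
    has_het_dup = CopyNumberClass.HET_DUP in called
    any_del = has_hom_del or has_het_del
    any_dup = has_hom_dup or has_het_dup
    if any_del and any_dup:
        return CopyNumberClass.AMBIGUOUS, True
    if any_del:
        # mixed zygosity in the same direction: most extreme probe wins
        return (
            CopyNumberClass.HOM_DEL if has_hom_del else CopyNumberClass.HET_DEL
        ), False
    if any_dup:
        return (
            CopyNumberClass.HOM_DUP if has_hom_dup else CopyNumberClass.HET_DUP
        ), False
    return CopyNumberClass.NORMAL, False


def call_gene(
    probe_classes: Iterable[CopyNumberClass],
    sample_id: str = "",
    gene: str = "",
) -> GeneCall:
    """Aggregate one gene's per-probe classes into a :class:`GeneCall`.

    Ambiguous probes are ignored whenever at least one sibling probe is
    called; a gene whose probes are all ambiguous is itself ambiguous.
    """
    classes = tuple(probe_classes)
    cnv_class, discordant = _aggregate(classes)
    label = "Unknown" if discordant else genotype_label(cnv_class)
    return GeneCall(
        sample_id=sample_id,
        gene=gene,
        cnv_class=cnv_class,
        probe_classes=classes,
        discordant=discordant,
        genotype_label=label,
    )


def genotype_label(cnv_class: CopyNumberClass) -> str:
    """Diplotype label for a called class; ``Unknown`` for ambiguous."""
    return GENOTYPE_LABELS.get(cnv_class, "Unknown")


@dataclass(frozen=True)
class PhenotypePrediction:
    """Predicted metabolizer phenotype from gene copy number alone.

    Zero active copies predicts a poor metabolizer; more than two copies
    an ultrarapid one.  The prediction cannot see SNV alleles, so a
    duplicated non-functional allele would be miscalled — the ``note``
    field flags this limitation on every record.
    """

    sample_id: str
    gene: str
    total_active_copies: int
    predicted: str
    note: str = PREDICTION_NOTE


def predict_phenotype(
    label: str, sample_id: str = "", gene: str = ""
) -> PhenotypePrediction:
    """Map a called diplotype label to a metabolizer-phenotype prediction."""
    if label not in COPIES_BY_LABEL:
        raise ValueError(f"no phenotype prediction for genotype {label!r}")
    copies = COPIES_BY_LABEL[label]
    return PhenotypePrediction(
        sample_id=sample_id,
        gene=gene,
        total_active_copies=copies,
        predicted=PHENOTYPE_BY_COPIES[copies],
    )


def call_cohort(
    dq: pd.DataFrame,
    panel,
    thresholds: DqThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Call every (sample, gene) pair from a long-format DQ table.

    Parameters
    ----------
    dq
        DataFrame with columns ``sample_id, probe_id, dq`` (target probes;
        other probes are ignored).
    panel
        :class:`~mlpacnv.panel.PanelDef` mapping probes to genes.
    thresholds
        DQ classification intervals.

    Returns
    -------
    DataFrame with columns ``sample_id, gene, cnv_class, genotype_label,
    discordant, n_probes_called``, one row per sample x gene with at
    least one measured probe.
    """
    gene_by_probe = {p.probe_id: p.gene for p in panel.target_probes}
    sub = dq[dq["probe_id"].isin(gene_by_probe)].copy()
    sub["gene"] = sub["probe_id"].map(gene_by_probe)
    sub["cls"] = classify_dq_array(sub["dq"].to_numpy(), thresholds)
    records = []
    for (sample_id, gene), grp in sub.groupby(["sample_id", "gene"], sort=True):
        gc = call_gene(grp["cls"].tolist(), sample_id=sample_id, gene=gene)
        records.append(
            {
                "sample_id": sample_id,
                "gene": gene,
                "cnv_class": gc.cnv_class.value,
                "genotype_label": gc.genotype_label,
                "discordant": gc.discordant,
                "n_probes_called": gc.n_probes_called,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "sample_id",
            "gene",
            "cnv_class",
            "genotype_label",
            "discordant",
            "n_probes_called",
        ],
    )
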