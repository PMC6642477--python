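"""Peak-height normalization: raw fluorescence to dosage quotients.

Normalization is two-staged, mirroring standard MLPA practice:

1. **Intra-sample**: each probe's peak height is divided by a robust
   aggregate (median by default) of the sample's reference-probe heights,
   removing the per-sample intensity scale.  The result is a relative
   signal that is invariant to rescaling the whole sample.
2. **Inter-sample**: each relative signal is divided by the aggregate
   (mean by default) of the same probe's relative signal across a set of
   reference samples assumed to carry two copies at every target.  The
   result is the dosage quotient (DQ), with expectation copies/2.

When no reference samples are designated the whole cohort serves as its
own reference via a per-probe median (population-median normalization);
this is only sound when CNVs are rare at every probe, so it triggers a
loud warning.

Control fragments support per-sample QC: Q-fragments rise relative to
real probes when input DNA is scarce, D-fragments collapse when sample
denaturation failed, and the X/Y fragments let sample sex be inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import PanelDef

__all__ = [
    "QcThresholds",
    "NormalizationError",
    "validate_peak_table",
    "intra_sample_normalize",
    "inter_sample_normalize",
    "qc_samples",
]

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised when a peak table cannot be normalized as requested."""


@dataclass(frozen=True)
class QcThresholds:
    """Cutoffs for control-fragment QC (fractions of reference signal).

    ``q_max``: a median Q-fragment relative signal above this fails the
    DNA-quantity check (Q-fragments are prominent only when template DNA
    is insufficient).  ``d_min``: a median D-fragment relative signal
    below this fails the denaturation check.  ``y_min``: minimal relative
    Y-fragment signal to infer an XY sample.  A result within
    ``warn_band`` (fractional) of a threshold on the passing side is
    flagged ``warn``.
    """

    q_max: float = 0.33
    d_min: float = 0.33
    y_min: float = 0.30
    warn_band: float = 0.25


def validate_peak_table(peaks: pd.DataFrame) -> None:
    """Check peak-table schema: required columns, uniqueness, heights >= 0."""
    required = ("sample_id", "probe_id", "peak_height")
    missing = [c for c in required if c not in peaks.columns]
    if missing:
        raise NormalizationError(f"peak table missing column(s) {missing}")
    heights = peaks["peak_height"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(heights) | (heights < 0))
    if bad.size:
        raise NormalizationError(
            f"peak table rows {bad[:5].tolist()}: peak_height must be a "
            "finite non-negative number"
        )
    dup = peaks.duplicated(subset=["sample_id", "probe_id"])
    if dup.any():
        rows = np.flatnonzero(dup.to_numpy())[:5].tolist()
        raise NormalizationError(
            f"peak table rows {rows}: duplicate (sample_id, probe_id) pairs"
        )


def intra_sample_normalize(
    peaks: pd.DataFrame, panel: PanelDef, stat: str = "median"
) -> pd.DataFrame:
    """Divide each peak by the sample's reference-probe aggregate.

    Samples whose reference aggregate is zero (no usable reference
    signal) are excluded from the output with a logged reason.

    Returns a DataFrame ``sample_id, probe_id, relative_signal``.
    """
    validate_peak_table(peaks)
    if stat not in ("median", "mean"):
        raise NormalizationError(f"unknown intra-sample statistic {stat!r}")
    ref_ids = set(panel.probe_ids("reference"))
    if not ref_ids:
        raise NormalizationError("panel has no reference probes")
    ref = peaks[peaks["probe_id"].isin(ref_ids)]
    if ref.empty:
        raise NormalizationError("peak table contains no reference-probe rows")
    denom = ref.groupby("sample_id")["peak_height"].agg(stat)
    unusable = denom[denom <= 0].index.tolist()
    if unusable:
        logger.warning(
            "excluding %d sample(s) with zero reference-probe signal: %s",
            len(unusable),
            ", ".join(map(str, unusable)),
        )
    out = peaks[~peaks["sample_id"].isin(unusable)].copy()
    out["relative_signal"] = out["peak_height"] / out["sample_id"].map(denom)
    return out[["sample_id", "probe_id", "relative_signal"]].reset_index(drop=True)


def inter_sample_normalize(
    rel: pd.DataFrame,
    reference_sample_ids: Iterable[str] | None = None,
    stat: str = "mean",
) -> pd.DataFrame:
    """Divide relative signals by the reference-sample aggregate per probe.

    ``reference_sample_ids`` designates samples assumed to carry two
    copies at every target probe.  When empty or ``None`` the whole
    cohort is used with a per-probe **median** (population-median
    normalization) and a loud warning, since that is only valid when
    CNVs are rare.

    Probes whose reference aggregate is zero are uncallable for the
    batch and dropped with a logged reason.

    Returns a DataFrame ``sample_id, probe_id, dq``.
    """
    if stat not in ("median", "mean"):
        raise NormalizationError(f"unknown inter-sample statistic {stat!r}")
    ref_ids = set(reference_sample_ids or ())
    if ref_ids:
        ref_rel = rel[rel["sample_id"].isin(ref_ids)]
        if ref_rel.empty:
            raise NormalizationError(
                "none of the designated reference samples are present "
                f"in the relative-signal table: {sorted(ref_ids)}"
            )
    else:
        logger.warning(
            "no reference samples designated; falling back to population-"
            "median normalization over all %d samples — valid only if CNVs "
            "are rare at every probe",
            rel["sample_id"].nunique(),
        )
        ref_rel = rel
        stat = "median"
    denom = ref_rel.groupby("probe_id")["relative_signal"].agg(stat)
    uncallable = denom[denom <= 0].index.tolist()
    if uncallable:
        logger.warning(
            "dropping %d probe(s) with zero reference signal (uncallable "
            "for this batch): %s",
            len(uncallable),
            ", ".join(map(str, uncallable)),
        )
    out = rel[~rel["probe_id"].isin(uncallable)].copy()
    out["dq"] = out["relative_signal"] / out["probe_id"].map(denom)
    return out[["sample_id", "probe_id", "dq"]].reset_index(drop=True)


def _flag(value: float, limit: float, direction: str, warn_band: float) -> str:
    """pass/warn/fail against a one-sided limit ('max' or 'min')."""
    if direction == "max":
        if value > limit:
            return "fail"
        return "warn" if value > limit * (1 - warn_band) else "pass"
    if value < limit:
        return "fail"
    return "warn" if value < limit * (1 + warn_band) else "pass"


def qc_samples(
    peaks: pd.DataFrame,
    panel: PanelDef,
    thresholds: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Per-sample control-fragment QC and sex inference.

    Returns a DataFrame ``sample_id, q_fragment_flag, d_fragment_flag,
    inferred_sex``.  Flags are deterministic given peaks and thresholds.
    Missing control fragments yield flag ``skipped`` (never a silent
    pass) with a logged warning.
    """
    validate_peak_table(peaks)
    ref_ids = set(panel.probe_ids("reference"))
    q_ids = set(panel.probe_ids("q_fragment"))
    d_ids = set(panel.probe_ids("d_fragment"))
    x_ids = set(panel.probe_ids("x_fragment"))
    y_ids = set(panel.probe_ids("y_fragment"))
    if not (q_ids and d_ids):
        logger.warning("panel lacks Q/D control fragments; QC will be skipped")

    records = []
    for sample_id, grp in peaks.groupby("sample_id", sort=True):
        by_probe = grp.set_index("probe_id")["peak_height"]
        ref_med = by_probe[by_probe.index.isin(ref_ids)].median()
        if not np.isfinite(ref_med) or ref_med <= 0:
            records.append(
                {
                    "sample_id": sample_id,
                    "q_fragment_flag": "skipped",
                    "d_fragment_flag": "skipped",
                    "inferred_sex": "undetermined",
                }
            )
            logger.warning(
                "sample %s: no reference-probe signal; QC skipped", sample_id
            )
            continue

        def _rel_median(ids: set[str]) -> float | None:
            vals = by_probe[by_probe.index.isin(ids)]
            if vals.empty:
                return None
            return float(vals.median() / ref_med)

        q_rel = _rel_median(q_ids)
        d_rel = _rel_median(d_ids)
        if q_rel is None:
            q_flag = "skipped"
            logger.warning("sample %s: Q-fragments missing; QC skipped", sample_id)
        else:
            q_flag = _flag(q_rel, thresholds.q_max, "max", thresholds.warn_band)
        if d_rel is None:
            d_flag = "skipped"
            logger.warning("sample %s: D-fragments missing; QC skipped", sample_id)
        else:
            d_flag = _flag(d_rel, thresholds.d_min, "min", thresholds.warn_band)

        x_rel = _rel_median(x_ids)
        y_rel = _rel_median(y_ids)
        if y_rel is None and x_rel is None:
            sex = "undetermined"
        elif y_rel is not None and y_rel >= thresholds.y_min:
            sex = "XY"
        elif x_rel is not None and x_rel > 0:
            sex = "XX"
        else:
            sex = "undetermined"
        records.append(
            {
                "sample_id": sample_id,
                "q_fragment_flag": q_flag,
                "d_fragment_flag": d_flag,
                "inferred_sex": sex,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["sample_id", "q_fragment_flag", "d_fragment_flag", "inferred_sex"],
    )
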