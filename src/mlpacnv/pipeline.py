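"""End-to-end convenience: raw peak table to gene-level CNV calls."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .calling import DEFAULT_THRESHOLDS, DqThresholds, call_cohort
from .normalize import inter_sample_normalize, intra_sample_normalize
from .panel import PanelDef

__all__ = ["call_samples"]


def call_samples(
    peaks: pd.DataFrame,
    panel: PanelDef,
    reference_sample_ids: Iterable[str] | None = None,
    thresholds: DqThresholds = DEFAULT_THRESHOLDS,
    intra_stat: str = "median",
    inter_stat: str = "mean",
    exclude_references: bool = True,
) -> pd.DataFrame:
    """Run intra- and inter-sample normalization then gene calling.

    Returns the calls table (``sample_id, gene, cnv_class,
    genotype_label, discordant, n_probes_called``); reference samples
    are dropped from the output unless ``exclude_references`` is false.
    """
    rel = intra_sample_normalize(peaks, panel, stat=intra_stat)
    dq = inter_sample_normalize(
        rel, reference_sample_ids=reference_sample_ids, stat=inter_stat
    )
    calls = call_cohort(dq, panel, thresholds=thresholds)
    if exclude_references and reference_sample_ids:
        calls = calls[~calls["sample_id"].isin(set(reference_sample_ids))]
    return calls.reset_index(drop=True)
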