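"""Plain-text table I/O shared by the pipeline stages.

All tabular exchange uses tab-separated files with a header row.  Lines
beginning with ``#`` are metadata comments (tool version, config hash)
and are skipped on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__

PEAK_COLUMNS = ("sample_id", "probe_id", "peak_height")
DQ_COLUMNS = ("sample_id", "probe_id", "dq")
TRUTH_COLUMNS = ("sample_id", "gene", "allele1", "allele2", "total_copies")
CALL_COLUMNS = (
    "sample_id",
    "gene",
    "cnv_class",
    "genotype_label",
    "discordant",
    "n_probes_called",
)


class TableError(ValueError):
    """Raised when a tabular input violates its schema."""


def write_table(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Write ``df`` as TSV with a ``# mlpacnv`` provenance comment."""
    path = Path(path)
    parts = [f"# mlpacnv v{__version__}"]
    for key, val in (meta or {}).items():
        parts.append(f"{key}={val}")
    with path.open("w") as fh:
        fh.write(" ".join(parts) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(
    path: str | Path, required: Sequence[str], string_cols: Sequence[str] = ()
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={c: str for c in string_cols})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    return df


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, PEAK_COLUMNS, string_cols=("sample_id", "probe_id"))
    return df[list(PEAK_COLUMNS)]


def read_dq_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, DQ_COLUMNS, string_cols=("sample_id", "probe_id"))
    return df[list(DQ_COLUMNS)]


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = read_table(
        path, TRUTH_COLUMNS, string_cols=("sample_id", "gene", "allele1", "allele2")
    )
    return df[list(TRUTH_COLUMNS)]


def read_calls_table(path: str | Path) -> pd.DataFrame:
    df = read_table(
        path,
        CALL_COLUMNS,
        string_cols=("sample_id", "gene", "cnv_class", "genotype_label"),
    )
    return df[list(CALL_COLUMNS)]
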