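"""Reading and writing of delimited expression matrices and result tables.

The matrix format is the one circulated with circadian microarray studies:
first column gene identifier, header row of sampling times in hours, tab-
or comma-delimited (inferred from the file extension, ``.csv`` vs anything
else).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from circadia.jtk import TimeGrid

__all__ = ["read_expression_matrix", "write_expression_matrix",
           "read_results_table", "write_results_table"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path: str | Path) -> tuple[pd.DataFrame, TimeGrid]:
    """Load a genes x timepoints matrix and its time grid.

    The header row must parse as hours; a malformed header raises with the
    offending column named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: matrix contains no genes")
    try:
        times = [float(c) for c in df.columns]
    except ValueError as exc:
        bad = [c for c in df.columns
               if not str(c).replace(".", "", 1).lstrip("-").isdigit()]
        raise ValueError(
            f"{path}: header must be time points in hours; "
            f"could not parse {bad[:3]}") from exc
    df.columns = times
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if not df.map(np.isreal).all().all():
        raise ValueError(f"{path}: matrix contains non-numeric values")
    return df, TimeGrid(times=tuple(times))


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path))


def write_results_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=True)


def read_results_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)
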