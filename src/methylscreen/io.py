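"""TSV/BED/JSON readers and writers for the pipeline's on-disk schemas.

Matrices are genes (or probes) x samples, tab-delimited, with the row
identifier in the first column and missing values encoded as ``NA``.
CpG-unit tables are long-format TSV; amplicons use 6-column BED
(0-based half-open intervals). Expression matrices carry a sidecar JSON
recording their scale so ratios are never taken on log-scale data.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

NA_REP = "NA"

#: column order of the long-format CpG-unit table
UNIT_COLUMNS = [
    "gene",
    "amplicon_id",
    "unit_index",
    "n_cpgs",
    "sample",
    "meth_ratio_pct",
    "error_pct",
    "overlap_flag",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_matrix(path: str | Path, index_name: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_REP, index_label=index_label)
    return path


def read_units(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    missing = [c for c in UNIT_COLUMNS if c not in df.columns]
    if missing:
        from .errors import InputError

        raise InputError(f"CpG-unit table {path} lacks columns: {missing}")
    df["overlap_flag"] = df["overlap_flag"].astype(bool)
    return df[UNIT_COLUMNS]


def write_units(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df[UNIT_COLUMNS].copy()
    out["overlap_flag"] = out["overlap_flag"].astype(int)
    out.to_csv(path, sep="\t", na_rep=NA_REP, index=False)
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    return path


def write_expression(
    df: pd.DataFrame, path: str | Path, scale: str, index_label: str = "gene"
) -> Path:
    """Write an expression matrix plus a ``<path>.json`` sidecar with its scale.

    ``scale`` is one of ``linear``, ``log2`` or ``log2-centered``.
    """
    path = write_matrix(df, path, index_label=index_label)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"scale": scale}) + "\n")
    return path


def read_expression(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read an expression matrix and its scale tag (defaults to ``linear``
    when no sidecar exists)."""
    df = read_matrix(path)
    sidecar = Path(str(path) + ".json")
    scale = "linear"
    if sidecar.exists():
        scale = json.loads(sidecar.read_text()).get("scale", "linear")
    return df, scale


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
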