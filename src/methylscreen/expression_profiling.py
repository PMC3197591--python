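"""Constitutive-expression normalisation and ratios to the melanocyte pool.

Linear-scale relative expression values are floored at 0.1, log2
transformed, then centrally normalised to the median expression of each
sample and then of each probe set / gene, in that order. Ratios to the
reference (melanocyte pool) column are taken on the *linear* scale; a gene
is "down >= k-fold" in a sample iff its ratio is <= 1/k (inclusive, so
exactly k-fold counts).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "floor_and_log",
    "median_center",
    "expression_ratio",
    "aggregate_probesets",
]


def floor_and_log(values: pd.DataFrame, floor: float = 0.1) -> pd.DataFrame:
    """Replace every value v by log2(max(v, floor)); missing propagates."""
    if not floor > 0:
        raise ConfigurationError(f"floor must be positive, got {floor}")
    return np.log2(values.clip(lower=floor))


def median_center(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-sample median, then the per-gene median.

    Input is expected on the log2 scale. All-missing rows/columns are
    emitted as missing with a warning. Afterwards every sample column has
    median 0 (the subsequent gene centering preserves column medians only
    approximately in general; the definitional guarantee is on the order
    stated).
    """
    empty_cols = values.columns[values.isna().all(axis=0)]
    empty_rows = values.index[values.isna().all(axis=1)]
    if len(empty_cols) or len(empty_rows):
        warnings.warn(
            f"median_center: {len(empty_rows)} all-missing row(s) and "
            f"{len(empty_cols)} all-missing column(s) left as missing",
            stacklevel=2,
        )
    centered = values.sub(values.median(axis=0, skipna=True), axis=1)
    centered = centered.sub(centered.median(axis=1, skipna=True), axis=0)
    return centered


def expression_ratio(values: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Fold ratio of each line to the reference column, on the linear scale.

    ratio[g, s] = value[g, s] / value[g, reference]; the reference column is
    dropped. Requires a strictly positive reference.
    """
    if reference not in values.columns:
        raise InputError(f"reference column {reference!r} not present")
    ref = values[reference]
    if (ref <= 0).any():
        bad = ref.index[ref <= 0][:5].tolist()
        raise InputError(f"non-positive reference expression for genes {bad}")
    return values.drop(columns=[reference]).div(ref, axis=0)


def aggregate_probesets(
    values: pd.DataFrame, annotation: pd.Series, how: str = "median"
) -> pd.DataFrame:
    """Collapse probe sets to gene symbols by median (default) or mean."""
    if how not in ("median", "mean"):
        raise ConfigurationError(f"how must be 'median' or 'mean', got {how!r}")
    symbols = annotation.reindex(values.index)
    if symbols.isna().any():
        raise InputError("every probe set must map to a gene symbol")
    grouped = values.groupby(symbols.to_numpy())
    out = grouped.median() if how == "median" else grouped.mean()
    out.index.name = "gene"
    return out
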