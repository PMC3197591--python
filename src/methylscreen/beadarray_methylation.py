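"""Infinium-style beta values and delta methylation versus a reference.

Percent methylation (beta) at a CpG probe is computed from the fluorescence
intensities of the methylated (M) and unmethylated (U) alleles as

    beta = Max(M, 0) / [Max(M, 0) + Max(U, 0) + offset] * 100

with ``offset = 0`` by default. Unmethylated sites give beta near 0, heavily
methylated sites approach 100. Each tumour line's methylation is then
expressed as a signed *delta* against a melanocyte reference pool: positive
delta is line-specific hypermethylation, negative delta hypomethylation.

The usual platform convention adds a positive stabilising constant to the
denominator; ``offset`` exposes that choice while keeping 0 as the default.
A zero denominator (both channels clamp to 0, offset 0) yields a missing
value: "no signal" rather than a number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InputError

__all__ = [
    "compute_beta",
    "beta_from_intensities",
    "compute_delta",
    "summarize_gene_methylation",
]


def compute_beta(M, U, offset: float = 0.0):
    """Percent methylation from allele intensities.

    Accepts scalars or array-likes; negative intensities (possible after
    background correction) are clamped to 0. Returns NaN where the
    denominator is 0.

    Parameters
    ----------
    M, U
        Methylated / unmethylated allele fluorescence intensities.
    offset
        Non-negative denominator constant, default 0.
    """
    if offset < 0:
        raise ConfigurationError(f"offset must be >= 0, got {offset}")
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise DataError("non-finite intensity value in M/U input")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0) * 100.0, np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def beta_from_intensities(
    intensities: pd.DataFrame, offset: float = 0.0
) -> pd.DataFrame:
    """Long-format intensity table -> wide beta matrix (probes x samples).

    ``intensities`` needs columns ``probe_id``, ``sample_id``, ``M``, ``U``.
    Raises :class:`DataError` identifying the offending probe/sample on
    non-finite input.
    """
    required = {"probe_id", "sample_id", "M", "U"}
    missing = required - set(intensities.columns)
    if missing:
        raise InputError(f"intensity table lacks columns: {sorted(missing)}")
    vals = intensities[["M", "U"]].to_numpy(dtype=float)
    bad = ~np.isfinite(vals).all(axis=1)
    if bad.any():
        row = intensities.loc[bad].iloc[0]
        raise DataError(
            f"non-finite intensity at probe={row['probe_id']!r} "
            f"sample={row['sample_id']!r}"
        )
    beta = compute_beta(intensities["M"], intensities["U"], offset=offset)
    out = intensities.assign(beta=beta).pivot_table(
        index="probe_id", columns="sample_id", values="beta", aggfunc="mean"
    )
    out.index.name = "probe_id"
    out.columns.name = None
    return out


def compute_delta(beta: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Subtract the reference column from every other sample.

    delta[p, s] = beta[p, s] - beta[p, reference]; the reference column is
    dropped from the output. Probes with a missing reference value are
    missing throughout. Values land in [-100, 100] by construction.
    """
    if reference not in beta.columns:
        raise InputError(f"reference column {reference!r} not present in beta matrix")
    ref = beta[reference]
    delta = beta.drop(columns=[reference]).sub(ref, axis=0)
    return delta


def summarize_gene_methylation(
    beta: pd.DataFrame, annotation: pd.Series, aggregator: str = "mean"
) -> pd.DataFrame:
    """Collapse a probe-level beta matrix to one row per gene symbol.

    ``annotation`` maps probe_id -> official gene symbol and must cover
    every probe in ``beta``. Missing values are excluded from aggregation;
    an all-missing group stays missing. ``aggregator`` is ``mean`` (default;
    symmetric across probes) or ``max`` ("any probe methylated" reading).
    """
    if aggregator not in ("mean", "max"):
        raise ConfigurationError(
            f"aggregator must be 'mean' or 'max', got {aggregator!r}"
        )
    unannotated = beta.index.difference(annotation.index)
    if len(unannotated):
        raise DataError(
            f"{len(unannotated)} probe(s) lack a gene annotation, "
            f"e.g. {list(unannotated[:5])}"
        )
    symbols = annotation.reindex(beta.index)
    grouped = beta.groupby(symbols.to_numpy())
    out = grouped.mean() if aggregator == "mean" else grouped.max()
    out.index.name = "gene"
    return out
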