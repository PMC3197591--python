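"""Re-expression after demethylating treatment (5AzadC + TSA).

Genes silenced by promoter methylation are reactivated when DNA
methyltransferase is inhibited. For each line, the treated/mock expression
ratio (fold change, FC) is computed per gene; a gene counts as re-expressed
in a line when FC > 2 (strict). Genes reactivated in *every* line are
removed: ubiquitous reactivation reflects generic drug stress or lineage
programs rather than tumour-specific silencing. The cascade later requires
an *average* FC > 4 across the panel.

The average is the arithmetic mean of fold ratios (matching the screen's
"average fold-change" reading); a geometric mean is available for the
log-symmetric alternative. A gene with any missing line can never be
"reactivated in all lines" — missing is treated as not-reactivated, which
removes conservatively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "fold_change",
    "reexpressed_genes",
    "filter_ubiquitous",
    "mean_reexpression",
    "response_summary",
]


def fold_change(treated: pd.DataFrame, mock: pd.DataFrame) -> pd.DataFrame:
    """Elementwise treated/mock ratio on a shared gene x line universe."""
    if not treated.index.equals(mock.index) or not treated.columns.equals(mock.columns):
        gene_diff = treated.index.symmetric_difference(mock.index)
        line_diff = treated.columns.symmetric_difference(mock.columns)
        raise InputError(
            "treated/mock identifiers differ: "
            f"genes {list(gene_diff[:5])}, lines {list(line_diff[:5])}"
        )
    if ((treated <= 0).any().any()) or ((mock <= 0).any().any()):
        raise InputError("expression values must be positive to form fold changes")
    return treated / mock


def _qualifying(FC: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Boolean gene x line table of FC > threshold, genes deduplicated to
    non-redundant symbols (a line qualifies if any row for the symbol does)."""
    qual = FC.gt(threshold)  # NaN -> False
    if FC.index.has_duplicates:
        qual = qual.groupby(level=0).any()
    return qual


def reexpressed_genes(
    FC: pd.DataFrame, threshold: float = 2.0, min_lines: int = 1
) -> tuple[set[str], pd.Series]:
    """Genes with FC > threshold (strict) in at least ``min_lines`` lines.

    Returns the gene set and the per-gene count of qualifying lines
    (for every non-redundant symbol, including zeros).
    """
    if not threshold > 1:
        raise ConfigurationError(f"threshold must be > 1, got {threshold}")
    if min_lines < 1:
        raise ConfigurationError(f"min_lines must be >= 1, got {min_lines}")
    counts = _qualifying(FC, threshold).sum(axis=1)
    counts.name = "n_reexpressed_lines"
    genes = set(counts.index[counts >= min_lines])
    return genes, counts


def filter_ubiquitous(
    genes: set[str], FC: pd.DataFrame, threshold: float = 2.0
) -> set[str]:
    """Drop genes re-expressed above threshold in every line.

    A line with a missing FC cannot count as reactivated, so a gene with any
    missing line is retained by this filter.
    """
    qual = _qualifying(FC, threshold)
    present = FC.notna()
    if FC.index.has_duplicates:
        present = present.groupby(level=0).any()
    ubiquitous = set(qual.index[qual.all(axis=1) & present.all(axis=1)])
    return set(genes) - ubiquitous


def mean_reexpression(FC: pd.DataFrame, geometric: bool = False) -> pd.Series:
    """Per-gene average fold change across available lines.

    Arithmetic mean by default; ``geometric=True`` averages on the log scale.
    All-missing genes stay missing.
    """
    if FC.index.has_duplicates:
        FC = FC.groupby(level=0).mean()
    if geometric:
        out = np.exp(np.log(FC).mean(axis=1, skipna=True))
    else:
        out = FC.mean(axis=1, skipna=True)
    out.name = "mean_FC"
    return out


def response_summary(FC: pd.DataFrame, threshold: float = 2.0) -> dict:
    """Bookkeeping counts: re-expressed, removed-as-ubiquitous, retained."""
    reexp, _ = reexpressed_genes(FC, threshold=threshold, min_lines=1)
    retained = filter_ubiquitous(reexp, FC, threshold=threshold)
    return {
        "n_reexpressed": len(reexp),
        "n_removed_ubiquitous": len(reexp) - len(retained),
        "n_retained": len(retained),
    }
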