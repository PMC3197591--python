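"""Methylation-expression correlation and its significance statistic.

Spearman rank correlation (Pearson on average ranks, ties sharing the mean
rank) relates per-sample promoter methylation to mRNA expression; a
negative coefficient indicates methylation-associated silencing.

Two t statistics are computed for a coefficient r over n pairs:

* ``standard``  — t = r * sqrt((n-2) / (1-r^2)), the textbook statistic for
  testing r = 0; the default for p-values.
* ``as_printed`` — t = r / Sr with Sr = (1-r^2)/n, the formula as published
  in the screen this package reimplements; reported alongside for fidelity,
  though it differs from the textbook standard error (probably a typo in
  the source).

Both convert to a two-sided p-value via the t distribution with n-2 degrees
of freedom. Missing values are handled pairwise-complete; fewer than 3
complete pairs, or a constant vector, leaves the result untested/missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ConfigurationError

__all__ = [
    "CorrelationResult",
    "spearman",
    "pearson",
    "correlation_test",
    "methylation_expression_panel",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_standard: float
    t_as_printed: float
    p: float
    method: str = "spearman"
    formula: str = "standard"
    exact_monotone: bool = False  # |r| = 1: p reported as 0

    @property
    def tested(self) -> bool:
        return self.r == self.r  # not NaN


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError(
            f"paired vectors must have equal length, got {x.shape} vs {y.shape}"
        )
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y) -> float:
    """Spearman rank-correlation coefficient; NaN when undefined."""
    x, y = _pairwise_complete(x, y)
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = _stats.spearmanr(x, y).statistic
    return float(r)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient; NaN when undefined."""
    x, y = _pairwise_complete(x, y)
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = _stats.pearsonr(x, y).statistic
    return float(r)


def t_standard(r: float, n: int) -> float:
    """Textbook t statistic for testing r = 0 (df = n-2)."""
    if abs(r) >= 1:
        return math.copysign(math.inf, r)
    return r * math.sqrt((n - 2) / (1 - r * r))


def t_as_printed(r: float, n: int) -> float:
    """The published variant: t = r / Sr with Sr = (1-r^2)/n."""
    if abs(r) >= 1:
        return math.copysign(math.inf, r)
    return r / ((1 - r * r) / n)


def correlation_test(
    r: float, n: int, formula: str = "standard", method: str = "spearman"
) -> CorrelationResult:
    """Two-sided significance of a correlation coefficient.

    ``formula`` selects which t feeds the p-value; both t values are always
    reported. |r| = 1 gives p = 0 with the exact-monotone flag set.
    """
    if formula not in ("standard", "as_printed"):
        raise ConfigurationError(
            f"formula must be 'standard' or 'as_printed', got {formula!r}"
        )
    if n < 3:
        raise ConfigurationError(f"need n >= 3 paired samples, got {n}")
    if r != r:  # NaN: untested
        return CorrelationResult(
            r=math.nan, n=n, t_standard=math.nan, t_as_printed=math.nan,
            p=math.nan, method=method, formula=formula,
        )
    ts, tp_ = t_standard(r, n), t_as_printed(r, n)
    if abs(r) >= 1:
        return CorrelationResult(
            r=float(r), n=n, t_standard=ts, t_as_printed=tp_, p=0.0,
            method=method, formula=formula, exact_monotone=True,
        )
    t = ts if formula == "standard" else tp_
    p = 2.0 * _stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(
        r=float(r), n=n, t_standard=ts, t_as_printed=tp_, p=float(p),
        method=method, formula=formula,
    )


def methylation_expression_panel(
    methylation: pd.DataFrame | dict,
    expression: pd.DataFrame,
    method: str = "spearman",
    formula: str = "standard",
) -> pd.DataFrame:
    """Per-gene correlation between methylation and expression panels.

    ``methylation`` is a genes x samples percent matrix (or a mapping of
    gene -> per-sample Series, e.g. from the EpiTYPER reduction);
    ``expression`` a genes x samples ratio matrix. Correlations are
    computed over the shared samples per gene; genes with fewer than 3
    complete pairs or constant input are reported untested with reason.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigurationError(f"method must be spearman|pearson, got {method!r}")
    corr = spearman if method == "spearman" else pearson
    if isinstance(methylation, dict):
        methylation = pd.DataFrame(
            {g: s for g, s in methylation.items()}
        ).T
    samples = methylation.columns.intersection(expression.columns)
    genes = methylation.index.intersection(expression.index)
    rows = []
    for g in genes:
        x, y = _pairwise_complete(
            methylation.loc[g, samples], expression.loc[g, samples]
        )
        n = len(x)
        if n < 3:
            rows.append(
                {"gene": g, "n": n, "r": math.nan, "t_standard": math.nan,
                 "t_as_printed": math.nan, "p": math.nan, "tested": False,
                 "reason": "fewer than 3 complete pairs"}
            )
            continue
        r = corr(x, y)
        res = correlation_test(r, n, formula=formula, method=method)
        rows.append(
            {"gene": g, "n": n, "r": res.r, "t_standard": res.t_standard,
             "t_as_printed": res.t_as_printed, "p": res.p,
             "tested": res.tested,
             "reason": "" if res.tested else "constant input"}
        )
    out = pd.DataFrame(
        rows, columns=["gene", "n", "r", "t_standard", "t_as_printed", "p",
                       "tested", "reason"]
    )
    return out.set_index("gene")
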