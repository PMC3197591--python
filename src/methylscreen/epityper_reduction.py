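"""Reduction of EpiTYPER CpG-unit measurements to per-gene methylation calls.

The mass-spectrometry assay reports methylation per *CpG unit* — a cleavage
fragment carrying one or more consecutive CpGs with a single methylation
ratio (percent) and an error estimate. Reduction proceeds:

1. **Unit QC** — drop units whose fragment mass overlaps another cleavage
   fragment, and units with an estimated error >= 10% (only ratios with
   error strictly below the threshold are precise enough to keep).
2. **Amplicon informativeness** — an amplicon is analysed only when its
   mean methylation across the tumour panel exceeds 20% (strict) while
   staying below 10% (strict) in the melanocyte reference.
3. **Informative-site selection** — within informative amplicons, keep the
   units with high panel-mean methylation (>= 20% by default).
4. **Gene call** — per-sample percent methylation is the mean of the
   selected units' ratios; the panel average is the mean of per-sample
   percents over tumour samples, compared against the same quantity in the
   reference; lines are grouped as no/low (0-20], medium (20-50] or
   high (>50) percent methylation.

Units are the atomic datum: per-CpG deconvolution within a unit is not
attempted (the assay cannot resolve it). Amplicon intervals follow BED
convention (0-based half-open); strand is recorded but unused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, DataError, InputError

__all__ = [
    "EpityperParams",
    "GeneMethylationCall",
    "qc_filter_units",
    "amplicon_informative",
    "informative_amplicons",
    "select_informative_sites",
    "gene_percent_methylation",
    "classify_methylation",
    "reference_ratio",
    "reduce_panel",
]

_UNIT_KEY = ["gene", "amplicon_id", "unit_index"]


@dataclass(frozen=True)
class EpityperParams:
    """Tunable thresholds of the reduction, all on the percent scale."""

    max_error: float = 10.0  # units kept only with error strictly below
    panel_min: float = 20.0  # amplicon panel mean must exceed (strict)
    ref_max: float = 10.0  # amplicon reference mean must stay below (strict)
    site_min: float = 20.0  # unit panel mean must reach (inclusive)

    def validate(self) -> None:
        if not self.max_error > 0:
            raise ConfigurationError(f"max_error must be > 0, got {self.max_error}")
        for name in ("panel_min", "ref_max", "site_min"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigurationError(f"{name} must be in [0,100], got {v}")


@dataclass
class GeneMethylationCall:
    """Per-gene reduction result."""

    gene: str
    per_sample: pd.Series  # percent methylation per panel sample
    panel_avg: float
    ref_avg: float
    groups: pd.Series  # methylation group per panel sample
    panel_group: str | None
    n_informative_sites: int
    informative_amplicons: tuple[str, ...]

    @property
    def ratio(self) -> float:
        return reference_ratio(self)


def qc_filter_units(units: pd.DataFrame, max_error: float = 10.0) -> pd.DataFrame:
    """Drop overlap-flagged units and units with error_pct >= max_error."""
    if not max_error > 0:
        raise ConfigurationError(f"max_error must be > 0, got {max_error}")
    keep = (~units["overlap_flag"].astype(bool)) & (units["error_pct"] < max_error)
    return units.loc[keep]


def _amplicon_sample_means(units: pd.DataFrame) -> pd.Series:
    """Amplicon-mean methylation per sample (mean over units)."""
    return units.groupby("sample")["meth_ratio_pct"].mean()


def amplicon_informative(
    units: pd.DataFrame,
    panel_samples,
    ref_samples,
    panel_min: float = 20.0,
    ref_max: float = 10.0,
) -> tuple[bool, dict]:
    """Verdict for a single amplicon's QC-filtered units.

    Informative iff the mean over panel samples of the amplicon-mean
    methylation is > panel_min (strict) and the reference amplicon-mean is
    < ref_max (strict). Returns the verdict with both means; an amplicon
    with no surviving units is 'uninformative: no data'.
    """
    panel_samples = set(panel_samples)
    ref_samples = set(ref_samples)
    if not panel_samples or not ref_samples:
        raise InputError("panel and reference sample sets must be non-empty")
    if panel_samples & ref_samples:
        raise InputError("panel and reference sample sets must be disjoint")
    if len(units) == 0:
        return False, {"panel_mean": math.nan, "ref_mean": math.nan,
                       "reason": "uninformative: no data"}
    means = _amplicon_sample_means(units)
    panel_mean = means.reindex(sorted(panel_samples)).mean(skipna=True)
    ref_mean = means.reindex(sorted(ref_samples)).mean(skipna=True)
    ok = bool(panel_mean > panel_min) and bool(ref_mean < ref_max)
    reason = "informative" if ok else "uninformative: outside thresholds"
    if math.isnan(panel_mean) or math.isnan(ref_mean):
        ok, reason = False, "uninformative: no data"
    return ok, {"panel_mean": float(panel_mean), "ref_mean": float(ref_mean),
                "reason": reason}


def informative_amplicons(
    units: pd.DataFrame,
    panel_samples,
    ref_samples,
    panel_min: float = 20.0,
    ref_max: float = 10.0,
) -> pd.DataFrame:
    """Per-(gene, amplicon) verdicts over a QC-filtered unit table."""
    rows = []
    for (gene, amp), grp in units.groupby(["gene", "amplicon_id"], sort=True):
        ok, info = amplicon_informative(
            grp, panel_samples, ref_samples, panel_min=panel_min, ref_max=ref_max
        )
        rows.append(
            {"gene": gene, "amplicon_id": amp, "informative": ok, **info}
        )
    return pd.DataFrame(
        rows, columns=["gene", "amplicon_id", "informative", "panel_mean",
                       "ref_mean", "reason"]
    )


def select_informative_sites(
    units: pd.DataFrame, panel_samples, site_min: float = 20.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Keep units with high methylation across the tumour panel.

    A unit is retained when its panel-mean methylation is >= site_min.
    Returns the retained rows and the per-gene count of informative CpG
    sites (sum of n_cpgs over retained distinct units).
    """
    panel_samples = set(panel_samples)
    panel_rows = units[units["sample"].isin(panel_samples)]
    unit_means = panel_rows.groupby(_UNIT_KEY)["meth_ratio_pct"].mean()
    keep_keys = unit_means.index[unit_means >= site_min]
    keyed = units.set_index(_UNIT_KEY)
    retained = keyed.loc[keyed.index.isin(keep_keys)].reset_index()
    distinct = retained[_UNIT_KEY + ["n_cpgs"]].drop_duplicates(_UNIT_KEY)
    n_sites = distinct.groupby("gene")["n_cpgs"].sum()
    n_sites.name = "n_informative_sites"
    return retained, n_sites


def gene_percent_methylation(
    selected: pd.DataFrame, panel_samples, ref_samples
) -> dict[str, dict]:
    """Two-level mean: units -> per-sample percent -> panel/reference average.

    Per-sample percent is the mean of the selected units' ratios in that
    sample (missing units skipped); samples with no surviving unit are
    missing. Returns, per gene, the per-sample Series plus panel and
    reference averages.
    """
    if len(selected) == 0:
        raise InputError("gene_percent_methylation requires a non-empty selection")
    panel_samples = sorted(set(panel_samples))
    ref_samples = sorted(set(ref_samples))
    out: dict[str, dict] = {}
    per_sample = selected.groupby(["gene", "sample"])["meth_ratio_pct"].mean()
    for gene, ser in per_sample.groupby(level=0):
        ser = ser.droplevel(0)
        panel = ser.reindex(panel_samples)
        ref = ser.reindex(ref_samples)
        out[gene] = {
            "per_sample": panel,
            "panel_avg": float(panel.mean(skipna=True)),
            "ref_avg": float(ref.mean(skipna=True)),
        }
    return out


def classify_methylation(percent: float) -> str | float:
    """Three-class call: no/low [0,20], medium (20,50], high (50,100].

    The printed labels "0-20%", "20-50%" and ">50%" are made disjoint with
    half-open upper boundaries; only the 50 boundary (">50%") is forced.
    Missing input stays missing.
    """
    if percent is None or (isinstance(percent, float) and math.isnan(percent)):
        return math.nan
    if not 0 <= percent <= 100:
        raise DataError(f"percent methylation out of [0,100]: {percent}")
    if percent <= 20:
        return "no/low"
    if percent <= 50:
        return "medium"
    return "high"


def reference_ratio(call: GeneMethylationCall) -> float:
    """Panel-average / reference-average fold, on unrounded values.

    Missing (with the zero-reference note left to the caller's report) when
    the reference average is 0 or unavailable.
    """
    if call.ref_avg is None or math.isnan(call.ref_avg) or call.ref_avg == 0:
        return math.nan
    return call.panel_avg / call.ref_avg


def reduce_panel(
    units: pd.DataFrame,
    panel_samples,
    ref_samples,
    params: EpityperParams | None = None,
) -> dict[str, GeneMethylationCall]:
    """Full reduction: QC -> informative amplicons -> site selection -> calls.

    Genes whose amplicons are all uninformative, or with no unit surviving
    selection, are absent from the result (no differential methylation /
    no data)."""
    params = params or EpityperParams()
    params.validate()
    clean = qc_filter_units(units, max_error=params.max_error)
    if len(clean) == 0:
        return {}
    verdicts = informative_amplicons(
        clean, panel_samples, ref_samples,
        panel_min=params.panel_min, ref_max=params.ref_max,
    )
    keep = verdicts.loc[verdicts["informative"], ["gene", "amplicon_id"]]
    merged = clean.merge(keep, on=["gene", "amplicon_id"], how="inner")
    if len(merged) == 0:
        return {}
    selected, n_sites = select_informative_sites(
        merged, panel_samples, site_min=params.site_min
    )
    if len(selected) == 0:
        return {}
    percents = gene_percent_methylation(selected, panel_samples, ref_samples)
    amps_by_gene = keep.groupby("gene")["amplicon_id"].apply(
        lambda s: tuple(sorted(s))
    )
    calls: dict[str, GeneMethylationCall] = {}
    for gene, info in percents.items():
        groups = info["per_sample"].map(classify_methylation)
        calls[gene] = GeneMethylationCall(
            gene=gene,
            per_sample=info["per_sample"],
            panel_avg=info["panel_avg"],
            ref_avg=info["ref_avg"],
            groups=groups,
            panel_group=classify_methylation(info["panel_avg"]),
            n_informative_sites=int(n_sites.get(gene, 0)),
            informative_amplicons=amps_by_gene.get(gene, ()),
        )
    return calls


def calls_frame(calls: dict[str, GeneMethylationCall]) -> pd.DataFrame:
    """Tabular per-gene call view (gene, panel_avg, ref_avg, ratio, group,
    n_informative_sites)."""
    rows = []
    for gene in sorted(calls):
        c = calls[gene]
        rows.append(
            {
                "gene": gene,
                "panel_avg": c.panel_avg,
                "ref_avg": c.ref_avg,
                "ratio": c.ratio,
                "group": c.panel_group,
                "n_informative_sites": c.n_informative_sites,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "panel_avg", "ref_avg", "ratio", "group",
                       "n_informative_sites"]
    )
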