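"""Cross-platform filter cascade for methylation-silenced candidate genes.

A gene becomes a candidate tumour-suppressor when, on a shared
official-symbol universe:

1. at least ``min_samples`` (default 2) lines show **both** delta
   methylation >= 60 percentage points over the melanocyte pool **and**
   constitutive expression down >= 4-fold versus the pool (ratio <= 1/4),
   evaluated in the *same* sample;
2. the average post-demethylation re-expression fold change across the
   panel is > 4 (strict);
3. it is not on the oncogene / previously-identified / unannotated
   exclusion lists; and
4. it is not an array false positive — highly methylated lines that show
   essentially no re-expression after demethylating treatment
   (delta >= 60 in >= 2 lines with FC <= 2 in those same lines).

Every input gene receives a complete ordered filter trail and a terminal
status, so the flow-through counts at each stage are reproducible from the
output alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "FilterThresholds",
    "ExclusionLists",
    "FilterStep",
    "CandidateGene",
    "joint_sample_filter",
    "detect_false_positives",
    "run_cascade",
    "cascade_summary",
]

#: unannotated-style symbols: open reading frames and provisional clone names
DEFAULT_UNANNOTATED_PATTERN = r"(?i)^(C\d+ORF\d+|FLJ\d+|CCDC\d+|LOC\d+|KIAA\d+)$"


@dataclass(frozen=True)
class FilterThresholds:
    """Numeric thresholds of the cascade (strictness as documented)."""

    meth_min: float = 60.0  # delta percentage points, inclusive >=
    min_samples: int = 2
    downreg_fold: float = 4.0  # ratio <= 1/downreg_fold, inclusive
    reexpr_mean_min: float = 4.0  # strict >

    def validate(self) -> None:
        if not 0 < self.meth_min <= 100:
            raise ConfigurationError(f"meth_min must be in (0,100], got {self.meth_min}")
        if self.min_samples < 1:
            raise ConfigurationError(f"min_samples must be >= 1, got {self.min_samples}")
        if not self.downreg_fold > 1:
            raise ConfigurationError(
                f"downreg_fold must be > 1, got {self.downreg_fold}"
            )
        if not self.reexpr_mean_min > 1:
            raise ConfigurationError(
                f"reexpr_mean_min must be > 1, got {self.reexpr_mean_min}"
            )


@dataclass
class ExclusionLists:
    """Symbol-based exclusions plus the false-positive decision rule."""

    oncogenes: set[str] = field(
        default_factory=lambda: {"ADM", "ENPP2", "RAC2", "SERPINE1"}
    )
    previously_identified: set[str] = field(default_factory=lambda: {"PPP1R3C"})
    unannotated: set[str] = field(default_factory=set)
    unannotated_pattern: str | None = DEFAULT_UNANNOTATED_PATTERN
    fp_meth_min: float = 60.0
    fp_fc_max: float = 2.0
    fp_min_lines: int = 2

    def __post_init__(self) -> None:
        self.oncogenes = {s.upper() for s in self.oncogenes}
        self.previously_identified = {s.upper() for s in self.previously_identified}
        self.unannotated = {s.upper() for s in self.unannotated}
        overlap = (
            (self.oncogenes & self.previously_identified)
            | (self.oncogenes & self.unannotated)
            | (self.previously_identified & self.unannotated)
        )
        if overlap:
            raise ConfigurationError(
                f"exclusion lists must be disjoint; shared symbols: {sorted(overlap)}"
            )

    def is_unannotated(self, symbol: str) -> bool:
        if symbol.upper() in self.unannotated:
            return True
        if self.unannotated_pattern:
            return re.match(self.unannotated_pattern, symbol) is not None
        return False


@dataclass(frozen=True)
class FilterStep:
    name: str
    passed: bool
    reason: str


@dataclass
class CandidateGene:
    """One gene's passage through the cascade, with full provenance."""

    symbol: str
    qualifying_samples: tuple[str, ...]
    mean_reexpression: float
    trail: list[FilterStep]
    status: str  # "candidate" or "excluded:<reason>"

    @property
    def is_candidate(self) -> bool:
        return self.status == "candidate"


def _upper_index(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out.index = out.index.astype(str).str.upper()
    return out


def align_symbols(*frames: pd.DataFrame) -> tuple[list[pd.DataFrame], list[str]]:
    """Uppercase symbols and report those not shared by every frame.

    Returns the uppercased frames and the sorted list of unmatched symbols
    (present in some frames but not all) — reported, never silently dropped.
    """
    upped = [_upper_index(f) for f in frames]
    common = upped[0].index
    union = upped[0].index
    for f in upped[1:]:
        common = common.intersection(f.index)
        union = union.union(f.index)
    unmatched = sorted(union.difference(common))
    return upped, unmatched


def joint_sample_filter(
    delta: pd.DataFrame,
    ratios: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> dict[str, tuple[str, ...]]:
    """Per-gene samples where hypermethylation and down-regulation co-occur.

    Sample s qualifies for gene g iff delta[g, s] >= meth_min AND
    ratio[g, s] <= 1/downreg_fold — both conditions in the same sample.
    Returns, for every gene shared by both inputs, the sorted tuple of
    qualifying samples (possibly empty).
    """
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    (delta, ratios), _ = align_symbols(delta, ratios)
    genes = delta.index.intersection(ratios.index)
    samples = delta.columns.intersection(ratios.columns)
    if len(samples) == 0:
        raise InputError("delta and expression-ratio matrices share no samples")
    d = delta.loc[genes, samples]
    r = ratios.loc[genes, samples]
    qual = d.ge(thresholds.meth_min) & r.le(1.0 / thresholds.downreg_fold)
    return {
        g: tuple(sorted(samples[row.to_numpy()])) for g, row in qual.iterrows()
    }


def detect_false_positives(
    delta: pd.DataFrame, FC: pd.DataFrame, exclusions: ExclusionLists | None = None
) -> set[str]:
    """Array false positives: methylated on the chip but not re-expressed.

    Flags genes with delta >= fp_meth_min in >= fp_min_lines lines where the
    post-treatment FC <= fp_fc_max in those same lines.
    """
    exclusions = exclusions or ExclusionLists()
    (delta, FC), _ = align_symbols(delta, FC)
    genes = delta.index.intersection(FC.index)
    lines = delta.columns.intersection(FC.columns)
    d = delta.loc[genes, lines]
    f = FC.loc[genes, lines]
    hit = d.ge(exclusions.fp_meth_min) & f.le(exclusions.fp_fc_max)
    counts = hit.sum(axis=1)
    return set(counts.index[counts >= exclusions.fp_min_lines])


def run_cascade(
    delta: pd.DataFrame,
    ratios: pd.DataFrame,
    FC: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    exclusions: ExclusionLists | None = None,
    keep_list: set[str] | None = None,
) -> list[CandidateGene]:
    """Apply the full cascade and return every gene with its trail.

    Order: joint methylation/down-regulation sample filter -> mean
    re-expression > threshold (strict) -> oncogene list -> previously
    identified -> unannotated -> array false positives [-> optional
    user-supplied keep-list standing in for downstream bench validation].
    Output sorted by (qualifying-sample count desc, mean re-expression desc,
    symbol asc).
    """
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    exclusions = exclusions or ExclusionLists()
    from .demethylation_response import mean_reexpression

    (delta_u, ratios_u, fc_u), _unmatched = align_symbols(delta, ratios, FC)
    qual_samples = joint_sample_filter(delta_u, ratios_u, thresholds)
    mean_fc = mean_reexpression(fc_u)
    false_pos = detect_false_positives(delta_u, fc_u, exclusions)
    genes = sorted(
        delta_u.index.intersection(ratios_u.index).intersection(fc_u.index).unique()
    )

    results: list[CandidateGene] = []
    for g in genes:
        samples = qual_samples.get(g, ())
        mfc = float(mean_fc.get(g, float("nan")))
        trail: list[FilterStep] = []
        status = "candidate"

        def step(name: str, passed: bool, reason: str) -> bool:
            trail.append(FilterStep(name, passed, reason))
            return passed

        if not step(
            "joint_sample_filter",
            len(samples) >= thresholds.min_samples,
            f"{len(samples)} qualifying sample(s), need >= {thresholds.min_samples}",
        ):
            status = "excluded:insufficient_joint_samples"
        elif not step(
            "mean_reexpression",
            mfc == mfc and mfc > thresholds.reexpr_mean_min,
            f"mean FC {mfc:.3g}, need > {thresholds.reexpr_mean_min}",
        ):
            status = "excluded:low_mean_reexpression"
        elif not step("oncogene", g not in exclusions.oncogenes, "on oncogene list"):
            status = "excluded:oncogene"
        elif not step(
            "previously_identified",
            g not in exclusions.previously_identified,
            "previously identified",
        ):
            status = "excluded:previously_identified"
        elif not step(
            "unannotated", not exclusions.is_unannotated(g), "unannotated symbol"
        ):
            status = "excluded:unannotated"
        elif not step(
            "false_positive", g not in false_pos, "methylated on array, no re-expression"
        ):
            status = "excluded:false_positive"
        elif keep_list is not None and not step(
            "keep_list",
            g in {s.upper() for s in keep_list},
            "not confirmed by downstream validation",
        ):
            status = "excluded:not_in_keep_list"

        results.append(
            CandidateGene(
                symbol=g,
                qualifying_samples=tuple(samples),
                mean_reexpression=mfc,
                trail=trail,
                status=status,
            )
        )

    results.sort(
        key=lambda c: (
            -len(c.qualifying_samples),
            -(c.mean_reexpression if c.mean_reexpression == c.mean_reexpression else float("-inf")),
            c.symbol,
        )
    )
    return results


def cascade_summary(results: list[CandidateGene]) -> dict:
    """Stage-by-stage flow-through counts from a cascade run."""
    stage_names = [
        "joint_sample_filter",
        "mean_reexpression",
        "oncogene",
        "previously_identified",
        "unannotated",
        "false_positive",
        "keep_list",
    ]
    summary: dict = {"n_input": len(results)}
    surviving = results
    for name in stage_names:
        surviving = [
            c
            for c in surviving
            if any(s.name == name and s.passed for s in c.trail)
        ]
        if any(any(s.name == name for s in c.trail) for c in results):
            summary[f"n_after_{name}"] = len(surviving)
    summary["n_candidates"] = sum(c.is_candidate for c in results)
    return summary


def candidates_frame(results: list[CandidateGene]) -> pd.DataFrame:
    """Tabular view of a cascade run (symbol, n_qualifying, mean_FC, status, trail)."""
    return pd.DataFrame(
        {
            "symbol": [c.symbol for c in results],
            "n_qualifying": [len(c.qualifying_samples) for c in results],
            "qualifying_samples": [",".join(c.qualifying_samples) for c in results],
            "mean_FC": [c.mean_reexpression for c in results],
            "status": [c.status for c in results],
            "trail": [
                ";".join(
                    f"{s.name}={'pass' if s.passed else 'fail'}" for s in c.trail
                )
                for c in results
            ],
        }
    )
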