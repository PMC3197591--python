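"""Synthetic paired methylation / expression / demethylation / EpiTYPER data.

The generator emulates the structure of the melanoma screen's inputs — a
small panel of tumour cell lines plus one melanocyte reference pool — with
a configurable number of *planted* silenced genes carrying the full
signature the cascade looks for:

* promoter methylation centred near ``meth_high_mean`` (default 80%) in a
  ``penetrance`` fraction of lines, against a background near
  ``meth_bg_mean`` (5%), so the delta versus the reference clears the
  60-point filter by construction;
* constitutive expression suppressed ``silencing_factor``-fold (8x) in
  exactly those methylated lines, multiplicatively before noise, so the
  line/reference ratio falls below 1/4;
* treated/mock re-expression fold changes near ``reexpr_fold_mean`` (10x)
  in the methylated lines and near 1 elsewhere, giving a panel-average
  fold above 4 without tripping the all-lines (ubiquitous) removal;
* an EpiTYPER-style CpG-unit panel in which planted genes carry high unit
  methylation in the methylated lines and a clean (<10%) reference, with a
  ``unit_error_rate`` fraction of units spoiled by large error estimates
  or overlap flags to exercise QC.

Methylation values are drawn from normal distributions on the percent
scale, clamped to [0, 100] — simple and sufficient to exercise every
threshold (a beta-distribution noise model would avoid the clamp but adds
nothing the filters can see). Expression noise is log-normal (normal on
log2). The reference expression column is the unsuppressed per-gene mean.
The ground-truth manifest is written as a separate TSV and never consumed
by the pipeline, keeping evaluation blind.

All randomness flows from ``SyntheticConfig.seed``; an identical config
yields byte-identical TSV output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .errors import ConfigurationError

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "generate_epityper_panel", "write_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generated screen."""

    n_genes: int = 500
    n_lines: int = 11
    n_planted: int = 20
    meth_high_mean: float = 80.0  # percent, planted genes in methylated lines
    meth_bg_mean: float = 5.0  # percent, background
    meth_noise_sd: float = 5.0  # percent
    silencing_factor: float = 8.0  # fold suppression in methylated lines
    reexpr_fold_mean: float = 10.0  # treated/mock fold in methylated lines
    penetrance: float = 0.5  # fraction of lines methylated per planted gene
    n_amplicons_per_gene: int = 2
    n_units_per_amplicon: int = 5
    unit_error_rate: float = 0.1  # fraction of units failing QC
    expr_base_log2_mean: float = 3.0  # log2 of unsuppressed expression centre
    expr_base_log2_sd: float = 1.0
    expr_log2_noise_sd: float = 0.4  # per-line expression noise (log2)
    fc_log2_noise_sd: float = 0.4  # fold-change noise (log2)
    reference_id: str = "MELPOOL"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_lines < 2:
            raise ConfigurationError(f"n_lines must be >= 2, got {self.n_lines}")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ConfigurationError(
                f"n_planted must be in [0, n_genes], got {self.n_planted}"
            )
        for name in ("meth_high_mean", "meth_bg_mean", "meth_noise_sd"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigurationError(f"{name} must be in [0,100], got {v}")
        for name in ("silencing_factor", "reexpr_fold_mean"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.penetrance <= 1:
            raise ConfigurationError(
                f"penetrance must be in [0,1], got {self.penetrance}"
            )
        if self.n_planted > 0 and self.penetrance * self.n_lines < 2:
            raise ConfigurationError(
                "penetrance * n_lines must be >= 2 so planted genes can pass "
                f"the >=2-sample filter, got {self.penetrance * self.n_lines:.2f}"
            )
        if not 0 <= self.unit_error_rate <= 1:
            raise ConfigurationError(
                f"unit_error_rate must be in [0,1], got {self.unit_error_rate}"
            )
        if self.n_amplicons_per_gene < 1 or self.n_units_per_amplicon < 1:
            raise ConfigurationError("amplicon/unit counts must be >= 1")


@dataclass
class SyntheticDataset:
    """The bundled tables plus the blind ground-truth manifest."""

    config: SyntheticConfig
    beta: pd.DataFrame  # genes x (lines + reference), percent
    expression: pd.DataFrame  # genes x (lines + reference), linear
    treated: pd.DataFrame  # genes x lines, linear
    mock: pd.DataFrame  # genes x lines, linear
    cpg_units: pd.DataFrame  # long-format CpG-unit table
    amplicons: pd.DataFrame  # 6-column BED
    truth: pd.DataFrame  # gene, line, methylated (planted genes only)

    @property
    def lines(self) -> list[str]:
        return [c for c in self.beta.columns if c != self.config.reference_id]

    @property
    def planted_genes(self) -> list[str]:
        return sorted(self.truth["gene"].unique())


def _gene_names(n: int) -> list[str]:
    return [f"SYN{i:04d}" for i in range(1, n + 1)]


def _line_names(n: int) -> list[str]:
    return [f"MM{i:02d}" for i in range(1, n + 1)]


def _clamped_normal(rng, mean, sd, size) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), 0.0, 100.0)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full bundle; identical config implies identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    lines = _line_names(config.n_lines)
    ref = config.reference_id
    n_g, n_l = config.n_genes, config.n_lines

    planted = sorted(rng.choice(genes, size=config.n_planted, replace=False))
    n_meth_lines = math.ceil(config.penetrance * n_l)
    meth_state = pd.DataFrame(False, index=genes, columns=lines)
    for g in planted:
        chosen = rng.choice(lines, size=n_meth_lines, replace=False)
        meth_state.loc[g, chosen] = True

    # --- methylation (percent, clamped normal) -------------------------------
    beta_vals = _clamped_normal(
        rng, config.meth_bg_mean, config.meth_noise_sd, (n_g, n_l)
    )
    high = _clamped_normal(
        rng, config.meth_high_mean, config.meth_noise_sd, (n_g, n_l)
    )
    mask = meth_state.to_numpy()
    beta_vals = np.where(mask, high, beta_vals)
    beta_ref = _clamped_normal(rng, config.meth_bg_mean, config.meth_noise_sd, n_g)
    beta = pd.DataFrame(beta_vals, index=genes, columns=lines)
    beta[ref] = beta_ref
    beta.index.name = "gene"

    # --- constitutive expression (linear; reference = unsuppressed mean) -----
    base = 2.0 ** rng.normal(
        config.expr_base_log2_mean, config.expr_base_log2_sd, size=n_g
    )
    noise = 2.0 ** rng.normal(0.0, config.expr_log2_noise_sd, size=(n_g, n_l))
    expr_vals = base[:, None] * noise
    expr_vals = np.where(mask, expr_vals / config.silencing_factor, expr_vals)
    expression = pd.DataFrame(expr_vals, index=genes, columns=lines)
    expression[ref] = base
    expression.index.name = "gene"

    # --- demethylation response (treated/mock pair) --------------------------
    mock_vals = base[:, None] * 2.0 ** rng.normal(
        0.0, config.expr_log2_noise_sd, size=(n_g, n_l)
    )
    mock_vals = np.where(mask, mock_vals / config.silencing_factor, mock_vals)
    fold = 2.0 ** rng.normal(0.0, config.fc_log2_noise_sd, size=(n_g, n_l))
    fold = np.where(mask, fold * config.reexpr_fold_mean, fold)
    treated_vals = mock_vals * fold
    mock = pd.DataFrame(mock_vals, index=genes, columns=lines)
    treated = pd.DataFrame(treated_vals, index=genes, columns=lines)
    mock.index.name = treated.index.name = "gene"

    # --- ground truth (separate manifest, planted genes only) ----------------
    truth = pd.DataFrame(
        [
            {"gene": g, "line": l, "methylated": int(meth_state.loc[g, l])}
            for g in planted
            for l in lines
        ],
        columns=["gene", "line", "methylated"],
    )

    # --- EpiTYPER panel + amplicon BED ---------------------------------------
    units = generate_epityper_panel(config, truth)
    amplicons = _amplicon_bed(config, genes)

    return SyntheticDataset(
        config=config,
        beta=beta,
        expression=expression,
        treated=treated,
        mock=mock,
        cpg_units=units,
        amplicons=amplicons,
        truth=truth,
    )


def _amplicon_bed(config: SyntheticConfig, genes: list[str]) -> pd.DataFrame:
    """Synthetic promoter amplicons: within 2500 bp upstream of each gene's
    nominal transcription start, tiled on a fictitious chromosome."""
    rows = []
    for i, g in enumerate(genes):
        tss = 10_000 + i * 10_000
        for a in range(config.n_amplicons_per_gene):
            start = tss - 2500 + a * (2500 // config.n_amplicons_per_gene)
            end = start + max(200, 2500 // config.n_amplicons_per_gene - 50)
            rows.append(
                {"chrom": "chrS", "start": start, "end": min(end, tss),
                 "name": f"{g}|amp{a + 1}", "score": 0, "strand": "+"}
            )
    return pd.DataFrame(rows, columns=msio.BED_COLUMNS)


def generate_epityper_panel(
    config: SyntheticConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """CpG-unit table for every gene over panel lines plus the reference.

    Planted genes mirror their per-line methylation states from ``truth``;
    background genes (and the reference pool) sit at the background level.
    A ``unit_error_rate`` fraction of units is spoiled — half with error
    estimates >= 10%, half with overlap flags — so QC has work to do.
    Uses its own seed stream derived from the config so the panel is
    reproducible independently of the main tables.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 0xEB1))
    genes = _gene_names(config.n_genes)
    lines = _line_names(config.n_lines)
    samples = lines + [config.reference_id]
    meth_lines: dict[str, set[str]] = {
        g: set(grp.loc[grp["methylated"] == 1, "line"])
        for g, grp in truth.groupby("gene")
    }

    n_units = config.n_amplicons_per_gene * config.n_units_per_amplicon
    records = []
    for g in genes:
        hot = meth_lines.get(g, set())
        n_cpgs = rng.integers(1, 5, size=n_units)
        bad = rng.random(n_units) < config.unit_error_rate
        bad_kind = rng.random(n_units) < 0.5  # True -> big error, False -> overlap
        for u in range(n_units):
            amp = f"amp{u // config.n_units_per_amplicon + 1}"
            unit_idx = u % config.n_units_per_amplicon + 1
            if bad[u]:
                err = float(rng.uniform(10.0, 30.0)) if bad_kind[u] else float(
                    rng.uniform(0.0, 9.5)
                )
                overlap = not bad_kind[u]
            else:
                err = float(rng.uniform(0.0, 9.5))
                overlap = False
            for s in samples:
                level = (
                    config.meth_high_mean
                    if (s in hot and s != config.reference_id)
                    else config.meth_bg_mean
                )
                ratio = float(
                    np.clip(rng.normal(level, config.meth_noise_sd), 0.0, 100.0)
                )
                records.append(
                    (g, f"{g}|{amp}", unit_idx, int(n_cpgs[u]), s, ratio, err,
                     overlap)
                )
    return pd.DataFrame.from_records(records, columns=msio.UNIT_COLUMNS)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every bundled table to TSV/BED plus the config as JSON.

    Returns the mapping of logical name -> path. The truth manifest is a
    separate file that no pipeline stage reads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": msio.write_matrix(dataset.beta, outdir / "beta.tsv"),
        "expression": msio.write_expression(
            dataset.expression, outdir / "expression.tsv", scale="linear"
        ),
        "treated": msio.write_expression(
            dataset.treated, outdir / "treated.tsv", scale="linear"
        ),
        "mock": msio.write_expression(
            dataset.mock, outdir / "mock.tsv", scale="linear"
        ),
        "cpg_units": msio.write_units(dataset.cpg_units, outdir / "cpg_units.tsv"),
        "amplicons": msio.write_bed(dataset.amplicons, outdir / "amplicons.bed"),
        "truth": outdir / "truth.tsv",
        "config": msio.write_json(
            dataclasses.asdict(dataset.config), outdir / "config.json"
        ),
    }
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
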