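"""EpiTYPER CpG-unit QC, informativeness, site selection and gene calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import methylscreen as ms
from methylscreen import (
    DataError,
    InputError,
    amplicon_informative,
    classify_methylation,
    gene_percent_methylation,
    qc_filter_units,
    reduce_panel,
    reference_ratio,
    select_informative_sites,
)
from methylscreen.epityper_reduction import GeneMethylationCall
from methylscreen.io import UNIT_COLUMNS


def make_units(rows):
    """rows: (gene, amp, unit, n_cpgs, sample, ratio, err, overlap)"""
    return pd.DataFrame.from_records(rows, columns=UNIT_COLUMNS)


def test_qc_filter_boundaries():
    units = make_units(
        [
            ("G", "a", 1, 1, "s", 50.0, 12.0, False),  # error above threshold
            ("G", "a", 2, 1, "s", 50.0, 10.0, False),  # exactly 10: dropped
            ("G", "a", 3, 1, "s", 50.0, 9.99, False),  # strictly below: kept
            ("G", "a", 4, 1, "s", 50.0, 1.0, True),  # overlap always dropped
        ]
    )
    kept = qc_filter_units(units, max_error=10.0)
    assert list(kept["unit_index"]) == [3]


def test_amplicon_informative_verdicts():
    def amp(panel_val, ref_val):
        rows = [("G", "a", 1, 1, f"mm{i}", panel_val, 1.0, False) for i in range(3)]
        rows.append(("G", "a", 1, 1, "REF", ref_val, 1.0, False))
        return make_units(rows)

    ok, info = amplicon_informative(amp(25.0, 5.0), [f"mm{i}" for i in range(3)], ["REF"])
    assert ok and info["panel_mean"] == pytest.approx(25.0)
    ok, info = amplicon_informative(amp(25.0, 12.0), [f"mm{i}" for i in range(3)], ["REF"])
    assert not ok  # reference too methylated
    ok, info = amplicon_informative(amp(15.0, 5.0), [f"mm{i}" for i in range(3)], ["REF"])
    assert not ok  # panel mean below 20


def test_amplicon_informative_strict_boundaries_and_empty():
    rows = [("G", "a", 1, 1, "mm0", 20.0, 1.0, False),
            ("G", "a", 1, 1, "REF", 10.0, 1.0, False)]
    ok, _ = amplicon_informative(make_units(rows), ["mm0"], ["REF"])
    assert not ok  # panel needs strictly > 20 and reference strictly < 10
    ok, info = amplicon_informative(make_units([]), ["mm0"], ["REF"])
    assert not ok and info["reason"] == "uninformative: no data"


def test_amplicon_informative_sample_set_validation():
    units = make_units([("G", "a", 1, 1, "s", 10.0, 1.0, False)])
    with pytest.raises(InputError):
        amplicon_informative(units, [], ["REF"])
    with pytest.raises(InputError):
        amplicon_informative(units, ["s"], ["s"])


def test_select_informative_sites_examples():
    rows = []
    for u, mean_val in [(1, 5.0), (2, 30.0), (3, 60.0)]:
        for s in ("mm0", "mm1"):
            rows.append(("G", "a", u, 2, s, mean_val, 1.0, False))
    units = make_units(rows)
    kept, n_sites = select_informative_sites(units, ["mm0", "mm1"], site_min=20.0)
    assert sorted(kept["unit_index"].unique()) == [2, 3]
    assert n_sites["G"] == 4  # two retained units x 2 CpGs each
    all_kept, n_all = select_informative_sites(units, ["mm0", "mm1"], site_min=0.0)
    assert len(all_kept) == len(units) and n_all["G"] == 6  # identity at 0


def test_select_informative_sites_brute_force_oracle(rng):
    rows = []
    for g in ("G1", "G2"):
        for u in range(6):
            n_cpgs = int(rng.integers(1, 4))
            for s in ("mm0", "mm1", "mm2", "REF"):
                rows.append((g, "a", u, n_cpgs, s,
                             float(rng.uniform(0, 100)), 1.0, False))
    units = make_units(rows)
    panel = ["mm0", "mm1", "mm2"]
    kept, n_sites = select_informative_sites(units, panel, site_min=40.0)
    for (g, a, u), grp in units.groupby(["gene", "amplicon_id", "unit_index"]):
        panel_mean = grp[grp["sample"].isin(panel)]["meth_ratio_pct"].mean()
        in_kept = ((kept["gene"] == g) & (kept["unit_index"] == u)).any()
        assert in_kept == (panel_mean >= 40.0)


def test_site_min_monotonicity(rng):
    rows = [("G", "a", u, 1, s, float(rng.uniform(0, 100)), 1.0, False)
            for u in range(10) for s in ("mm0", "mm1")]
    units = make_units(rows)
    counts = []
    for site_min in (80.0, 40.0, 10.0, 0.0):
        _, n = select_informative_sites(units, ["mm0", "mm1"], site_min=site_min)
        counts.append(int(n.get("G", 0)))
    assert counts == sorted(counts)  # lowering site_min never loses sites


def test_gene_percent_methylation_two_level_mean():
    rows = [("G", "a", 1, 1, "mm0", 40.0, 1.0, False),
            ("G", "a", 2, 1, "mm0", 60.0, 1.0, False),
            ("G", "a", 1, 1, "mm1", 20.0, 1.0, False),
            ("G", "a", 1, 1, "REF", 4.0, 1.0, False)]
    out = gene_percent_methylation(make_units(rows), ["mm0", "mm1"], ["REF"])
    g = out["G"]
    assert g["per_sample"]["mm0"] == pytest.approx(50.0)  # mean of 40 and 60
    assert g["per_sample"]["mm1"] == pytest.approx(20.0)
    assert g["panel_avg"] == pytest.approx(35.0)
    assert g["ref_avg"] == pytest.approx(4.0)


def test_gene_percent_methylation_oracle_and_invariances(rng):
    rows = [("G", "a", u, 1, s, float(rng.uniform(0, 100)), 1.0, False)
            for u in range(4) for s in ("mm0", "mm1", "mm2", "REF")]
    units = make_units(rows)
    panel = ["mm0", "mm1", "mm2"]
    out = gene_percent_methylation(units, panel, ["REF"])["G"]
    per_sample = {
        s: units[units["sample"] == s]["meth_ratio_pct"].mean() for s in panel
    }
    assert out["panel_avg"] == pytest.approx(np.mean(list(per_sample.values())))
    # invariant to row order and to duplication-then-deduplication
    shuffled = units.sample(frac=1.0, random_state=0)
    out2 = gene_percent_methylation(shuffled, panel, ["REF"])["G"]
    assert out2["panel_avg"] == pytest.approx(out["panel_avg"])
    dup = pd.concat([units, units]).drop_duplicates()
    out3 = gene_percent_methylation(dup, panel, ["REF"])["G"]
    assert out3["panel_avg"] == pytest.approx(out["panel_avg"])


def test_gene_percent_methylation_missing_sample_and_empty():
    rows = [("G", "a", 1, 1, "mm0", 30.0, 1.0, False)]
    out = gene_percent_methylation(make_units(rows), ["mm0", "mm1"], ["REF"])
    assert math.isnan(out["G"]["per_sample"]["mm1"])  # no surviving unit
    with pytest.raises(InputError):
        gene_percent_methylation(make_units([]), ["mm0"], ["REF"])


@pytest.mark.parametrize(
    "pct, group",
    [
        (0.0, "no/low"), (20.0, "no/low"), (20.01, "medium"), (42.0, "medium"),
        (50.0, "medium"), (50.01, "high"), (66.0, "high"), (100.0, "high"),
    ],
)
def test_classify_boundaries(pct, group):
    assert classify_methylation(pct) == group


@given(pct=st.floats(0, 100, allow_nan=False))
def test_classify_partitions_percent_scale(pct):
    assert classify_methylation(pct) in {"no/low", "medium", "high"}


def test_classify_out_of_range_and_missing():
    with pytest.raises(DataError):
        classify_methylation(101.0)
    with pytest.raises(DataError):
        classify_methylation(-0.5)
    assert math.isnan(classify_methylation(float("nan")))


def _call(panel_avg, ref_avg):
    return GeneMethylationCall(
        gene="G", per_sample=pd.Series(dtype=float), panel_avg=panel_avg,
        ref_avg=ref_avg, groups=pd.Series(dtype=object), panel_group=None,
        n_informative_sites=0, informative_amplicons=(),
    )


def test_reference_ratio():
    assert reference_ratio(_call(40.0, 5.0)) == pytest.approx(8.0)
    assert reference_ratio(_call(7.0, 7.0)) == pytest.approx(1.0)
    assert math.isnan(reference_ratio(_call(40.0, 0.0)))


def test_reduce_panel_end_to_end_matches_planted_truth(default_dataset):
    ds = default_dataset
    cfg = ds.config
    calls = reduce_panel(ds.cpg_units, ds.lines, [cfg.reference_id])
    planted = set(ds.planted_genes)
    assert planted <= set(calls)  # every planted gene receives a call
    for g in sorted(planted)[:5]:
        hot = set(ds.truth[(ds.truth.gene == g) & (ds.truth.methylated == 1)].line)
        call = calls[g]
        for line in sorted(hot):
            # methylated lines called within +/-10 points of the planted level
            assert abs(call.per_sample[line] - cfg.meth_high_mean) <= 10
            assert call.groups[line] == "high"
        assert call.ref_avg < 20  # reference stays no/low
        assert call.n_informative_sites > 0


def test_reduce_panel_background_genes_uninformative(default_dataset):
    ds = default_dataset
    calls = reduce_panel(ds.cpg_units, ds.lines, [ds.config.reference_id])
    background = set(ds.beta.index) - set(ds.planted_genes)
    assert set(calls) & background == set()  # no differential methylation


def test_reduce_panel_unit_error_rate_extremes():
    base = ms.SyntheticConfig(n_genes=10, n_planted=3, seed=5)
    clean = ms.generate_dataset(ms.SyntheticConfig(
        n_genes=10, n_planted=3, seed=5, unit_error_rate=0.0))
    assert len(qc_filter_units(clean.cpg_units)) == len(clean.cpg_units)
    spoiled = ms.generate_dataset(ms.SyntheticConfig(
        n_genes=10, n_planted=3, seed=5, unit_error_rate=1.0))
    assert len(qc_filter_units(spoiled.cpg_units)) == 0
    calls = reduce_panel(spoiled.cpg_units, spoiled.lines,
                         [base.reference_id])
    assert calls == {}  # all units dropped -> gene calls missing


def test_reduce_panel_planted_tenfold_differential_ratio():
    # high 50% in every line vs background 5% is a planted 10x differential
    cfg = ms.SyntheticConfig(
        n_genes=20, n_planted=4, seed=11, meth_high_mean=50.0,
        meth_bg_mean=5.0, meth_noise_sd=2.0, penetrance=1.0,
        n_units_per_amplicon=10,
    )
    ds = ms.generate_dataset(cfg)
    calls = reduce_panel(ds.cpg_units, ds.lines, [cfg.reference_id])
    for g in ds.planted_genes:
        assert calls[g].ratio == pytest.approx(10.0, rel=0.15)
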