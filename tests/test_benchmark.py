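"""Nested-CV workflow: plans, tuning, merged metrics, ranking, external sets."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from reaction_ad.benchmark import (
    BenchmarkConfig,
    CVPlan,
    MethodSpec,
    RankingRule,
    apply_methods,
    detect_nonnative,
    external_validate,
    rank_methods,
    run_benchmark,
    tune_ad,
    tune_qrpr,
)
from reaction_ad.synthetic_data import generate


# ---------------------------------------------------------------------------
# fold plans


def test_outer_folds_partition():
    plan = CVPlan(n_outer=5, seed=3)
    folds = plan.outer_folds(47)
    joined = np.concatenate(folds)
    assert sorted(joined) == list(range(47))
    assert len(folds) == 5


def test_folds_reproducible_from_seed():
    a = CVPlan(seed=9).outer_folds(30)
    b = CVPlan(seed=9).outer_folds(30)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
    c = CVPlan(seed=10).outer_folds(30)
    assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def test_inner_folds_differ_per_outer_index():
    plan = CVPlan(seed=1)
    a = plan.inner_folds(40, 0)
    b = plan.inner_folds(40, 1)
    assert any(not np.array_equal(x, y) for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# method names


@pytest.mark.parametrize(
    "name,base,composite,objective",
    [
        ("OZ", "OZ", False, None),
        ("BB*", "BB", True, None),
        ("RFR_VAR*/OIR", "RFR_VAR", True, "OIR"),
        ("2CC/OD", "2CC", False, "OD"),
        ("RTC1", "RTC1", False, None),
    ],
)
def test_method_spec_parsing(name, base, composite, objective):
    spec = MethodSpec.parse(name)
    assert (spec.base, spec.composite, spec.objective) == (base, composite, objective)
    assert spec.name == name


@pytest.mark.parametrize(
    "bad", ["XYZ", "RFR_VAR*", "BB/OIR", "2CC*/AUC"]
)
def test_method_spec_rejects_malformed(bad):
    with pytest.raises(ValueError):
        MethodSpec.parse(bad)


# ---------------------------------------------------------------------------
# tuning


def test_tune_qrpr_single_point_grid(substitution_dataset, fast_plan):
    ds = substitution_dataset.to_reaction_dataset()
    config = BenchmarkConfig(n_trees=30, qrpr_max_features_grid=(0.7,))
    forest, info = tune_qrpr(ds, fast_plan, config)
    assert info["max_features"] == 0.7
    assert forest.n_estimators == 30


def test_tune_qrpr_deterministic(substitution_dataset, fast_plan):
    ds = substitution_dataset.to_reaction_dataset()
    config = BenchmarkConfig(n_trees=30, qrpr_max_features_grid=(0.5, 1.0))
    _, a = tune_qrpr(ds, fast_plan, config)
    _, b = tune_qrpr(ds, fast_plan, config)
    assert a == b


def test_tune_ad_passthrough_for_untunable(substitution_dataset, fast_plan, fast_config):
    ds = substitution_dataset.to_reaction_dataset()
    model, chosen = tune_ad(ds, "BB", fast_plan, fast_config)
    assert chosen == {}
    assert model.name == "BB"


def test_tune_ad_oir_excludes_planted_outliers(substitution_dataset, fast_plan, fast_config):
    """OIR-tuned variance threshold keeps most data while flagging gross outliers."""
    ds = substitution_dataset.to_reaction_dataset()
    model, chosen = tune_ad(ds, "RFR_VAR/OIR", fast_plan, fast_config)
    assert "sigma_star" in chosen
    assert np.isfinite(chosen["sigma_star"])


# ---------------------------------------------------------------------------
# run_benchmark


@pytest.fixture(scope="module")
def small_report(substitution_dataset):
    ds = substitution_dataset.to_reaction_dataset()
    config = BenchmarkConfig(n_trees=40, qrpr_max_features_grid=(1.0,))
    plan = CVPlan(n_outer=3, n_inner=3, seed=7)
    methods = ["OZ", "PZ", "Perfect", "RTC1", "BB*", "Leverage*", "Z-1NN*",
               "RFR_VAR*/OIR", "RFR_VAR*/OD"]
    return run_benchmark(ds, methods, plan, config)


def test_zero_and_perfect_identities(small_report):
    m = small_report.metrics
    assert m.loc["OZ", "coverage"] == 1.0
    assert m.loc["PZ", "coverage"] == 0.0
    assert m.loc["OZ", "oir"] == 0.0
    assert m.loc["OZ", "delta_r2_ad"] == 0.0
    assert m.loc["OZ", "od"] == 0.5
    assert m.loc["PZ", "od"] == 0.5
    assert m.loc["Perfect", "od"] == 1.0
    assert m.loc["PZ", "delta_r2_ad"] == pytest.approx(-m.loc["OZ", "r2_all"])


def test_rtc1_self_type_coverage(small_report):
    # all benchmark reactions are of the native type; a few centers unseen in
    # a given outer-train fold may still be rejected
    assert small_report.metrics.loc["RTC1", "coverage"] >= 0.9


def test_composite_coverage_bounded_by_rtc1(small_report):
    m = small_report.metrics
    for name in ("BB*", "Leverage*", "Z-1NN*", "RFR_VAR*/OIR"):
        assert m.loc[name, "coverage"] <= m.loc["RTC1", "coverage"] + 1e-12


def test_quadrants_partition_dataset(small_report):
    n = len(small_report.predictions)
    for _, row in small_report.metrics.iterrows():
        assert row["TO"] + row["TI"] + row["FO"] + row["FI"] == n


def test_benchmark_deterministic(substitution_dataset):
    ds = substitution_dataset.to_reaction_dataset()
    config = BenchmarkConfig(n_trees=30, qrpr_max_features_grid=(1.0,))
    plan = CVPlan(n_outer=3, n_inner=3, seed=5)
    methods = ["OZ", "Perfect", "RTC1", "BB*", "RFR_VAR*/OIR"]
    a = run_benchmark(ds, methods, plan, config)
    b = run_benchmark(ds, methods, plan, config)
    assert a.to_json() == b.to_json()


def test_summary_lists_all_methods(small_report):
    text = small_report.summary()
    for name in ("OZ", "PZ", "Perfect", "RFR_VAR*/OIR"):
        assert name in text


# ---------------------------------------------------------------------------
# non-native detection


def test_detect_nonnative_rtc1(substitution_dataset, elimination_dataset):
    train = substitution_dataset.to_reaction_dataset()
    foreign = elimination_dataset.to_reaction_dataset()
    assert detect_nonnative(train, foreign, "RTC1") == 1.0


def test_detect_nonnative_self_is_zero(substitution_dataset):
    ds = substitution_dataset.to_reaction_dataset()
    assert detect_nonnative(ds, ds, "RTC1") == 0.0
    assert detect_nonnative(ds, ds, "FC") == 0.0


def test_fc_accepts_zwitterions_rtc_rejects(elimination_dataset, zwitterion_dataset):
    """The documented fragment-control blind spot for charge-only tautomerism."""
    train = elimination_dataset.to_reaction_dataset()
    foreign = zwitterion_dataset.to_reaction_dataset()
    fc_outlier_fraction = detect_nonnative(train, foreign, "FC")
    assert fc_outlier_fraction < 1.0       # at least one accepted
    assert detect_nonnative(train, foreign, "RTC1") == 1.0


# ---------------------------------------------------------------------------
# ranking


def _report_from_metrics(rows):
    frame = pd.DataFrame.from_dict(rows, orient="index")
    from reaction_ad.benchmark import BenchmarkReport

    return BenchmarkReport(metrics=frame, predictions=pd.DataFrame(),
                           chosen={}, seed=0, config={})


def test_rank_methods_perfect_on_top():
    rows = {
        "Perfect": {"coverage": 0.98, "delta_r2_ad": 0.08, "od": 1.0},
        "A": {"coverage": 0.90, "delta_r2_ad": 0.02, "od": 0.6},
        "B": {"coverage": 0.50, "delta_r2_ad": 0.01, "od": 0.55},
    }
    reports = {"ds1": _report_from_metrics(rows)}
    table = rank_methods(reports, nonnative_accepted={"ds1": {"A": True}})
    assert table.index[0] == "Perfect"
    assert table.loc["Perfect", "penalty_sum"] == 0
    assert table.loc["A", "ds1:nonnative"] == 1


def test_rank_methods_identical_methods_tie():
    rows = {
        "A": {"coverage": 0.9, "delta_r2_ad": 0.05, "od": 0.7},
        "B": {"coverage": 0.9, "delta_r2_ad": 0.05, "od": 0.7},
        "C": {"coverage": 0.2, "delta_r2_ad": 0.00, "od": 0.5},
    }
    table = rank_methods({"d": _report_from_metrics(rows)})
    assert table.loc["A", "penalty_sum"] == table.loc["B", "penalty_sum"]
    # alphabetical tie-break
    assert list(table.index[:2]) == ["A", "B"]


def test_rank_methods_median_rule():
    """Odd method count: strictly above the median is penalty-free."""
    rows = {
        "A": {"coverage": 0.9, "delta_r2_ad": 0.0, "od": 0.5},
        "B": {"coverage": 0.5, "delta_r2_ad": 0.0, "od": 0.5},
        "C": {"coverage": 0.1, "delta_r2_ad": 0.0, "od": 0.5},
    }
    table = rank_methods({"d": _report_from_metrics(rows)})
    assert table.loc["A", "d:coverage"] == 0
    assert table.loc["B", "d:coverage"] == 1  # the median itself is penalized
    assert table.loc["C", "d:coverage"] == 1


def test_rank_methods_needs_two(substitution_dataset):
    with pytest.raises(ValueError):
        rank_methods({"d": _report_from_metrics({"A": {"coverage": 1.0,
                                                       "delta_r2_ad": 0.0,
                                                       "od": 0.5}})})


# ---------------------------------------------------------------------------
# external validation


@pytest.fixture(scope="module")
def external_tables(suites, fast_plan):
    # training data carries its usual share of gross errors; an error-free
    # training set would leave the OIR objective without signal
    spec = replace(suites["substitution-like"], outlier_fraction=0.05)
    train = generate(spec, n=70, seed=21).to_reaction_dataset()
    shift = generate(suites["leaving-group-shift"], n=50, seed=22)
    test = shift.to_reaction_dataset()
    config = BenchmarkConfig(n_trees=40, qrpr_max_features_grid=(1.0,))
    methods = ["OZ", "PZ", "RTC1", "RFR_VAR*/OIR"]
    frame = external_validate(train, test, methods, fast_plan, config)
    preds = apply_methods(train, test, methods, fast_plan, config)
    return frame, preds, shift


def test_external_oz_equals_no_ad(external_tables):
    frame, (pred_rfr, _, decisions), shift = external_tables
    y = shift.table["property"].to_numpy()
    no_ad_rmse = float(np.sqrt(np.mean((y - pred_rfr) ** 2)))
    assert frame.loc["OZ", "rmse"] == pytest.approx(no_ad_rmse)
    assert frame.loc["OZ", "coverage"] == 1.0


def test_external_pz_flagged_unavailable(external_tables):
    frame, _, _ = external_tables
    assert frame.loc["PZ", "coverage"] == 0.0
    assert np.isnan(frame.loc["PZ", "rmse"])


def test_external_composite_excludes_novel_cluster(external_tables):
    """The variance/RTC1 composite drops the planted novel-leaving-group
    cluster and improves RMSE over the no-AD baseline."""
    frame, (pred_rfr, _, decisions), shift = external_tables
    novel = shift.flags["novel_cluster"].to_numpy()
    dec = decisions["RFR_VAR*/OIR"]
    assert not dec[novel].any()
    assert frame.loc["RFR_VAR*/OIR", "rmse"] < frame.loc["OZ", "rmse"]
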