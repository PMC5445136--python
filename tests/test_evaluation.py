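"""Scenario bookkeeping: splits, fold structure, summaries, and the
processed-beats-raw ordering on synthetic data."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import painsig as ps
from painsig import evaluation as ev
from painsig.evaluation import PipelineConfig, RunResult, ScenarioReport


def _balanced_frame(n_per_class):
    rng = np.random.default_rng(0)
    rows = n_per_class * 4
    df = pd.DataFrame(
        rng.standard_normal((rows, 2)), columns=["bvp_f1", "bvp_f2"]
    )
    df["label"] = np.repeat(ps.LEVELS, n_per_class)
    return df


def test_split_arithmetic_1200():
    df = _balanced_frame(300)
    tr, te = ev.stratified_split(df, 0.75, seed=0)
    assert (len(tr), len(te)) == (900, 300)
    assert tr["label"].value_counts().eq(225).all()
    assert te["label"].value_counts().eq(75).all()


def test_split_deterministic_disjoint_exhaustive():
    df = _balanced_frame(20)
    tr1, te1 = ev.stratified_split(df, 0.75, seed=3)
    tr2, te2 = ev.stratified_split(df, 0.75, seed=3)
    pd.testing.assert_frame_equal(tr1, tr2)
    merged = sorted(list(tr1.index) + list(te1.index))
    assert merged == list(df.index)


def test_split_small_class_errors():
    df = _balanced_frame(5).iloc[:16]  # L3 left with a single row
    with pytest.raises(ValueError, match="class"):
        ev.stratified_split(df)


def test_loso_fold_count(small_trials, small_features, fast_pipeline_config):
    cfg = dataclasses.replace(fast_pipeline_config, use_ga=False, use_pca=False)
    rep = ev.run_scenario(
        "between_subject_loso", small_trials, cfg, feature_df=small_features
    )
    groups = {(r.repeat, r.group) for r in rep.runs}
    assert len(groups) == cfg.n_repeats * 2  # 2 subjects -> 2 folds per repeat
    assert {g for _, g in groups} == {"S1", "S2"}


def test_lodo_fold_count():
    cfg = ps.ProtocolConfig(n_subjects=1, n_days=3, sessions_per_subject=2)
    trials = ps.simulate_cohort(cfg, 19)
    pcfg = dataclasses.replace(
        PipelineConfig(), use_ga=False, use_pca=False, classifiers=("lda",)
    )
    rep = ev.run_scenario("multi_day_lodo", trials, pcfg)
    assert sorted(r.group for r in rep.runs) == ["day1", "day2", "day3"]
    # each fold tests exactly one held-out day
    for r in rep.runs:
        assert r.n_test == cfg.trials_per_day * 10


def test_scenario_metadata_errors(single_subject_dataset, fast_pipeline_config):
    trials, df = single_subject_dataset
    with pytest.raises(ValueError, match="subject_id"):
        ev.run_scenario("between_subject_loso", trials, fast_pipeline_config,
                        feature_df=df)
    with pytest.raises(ValueError, match="day_index"):
        ev.run_scenario("multi_day_lodo", trials, fast_pipeline_config,
                        feature_df=df)
    with pytest.raises(ValueError, match="unknown scenario"):
        ev.run_scenario("nope", trials, fast_pipeline_config, feature_df=df)


def test_confusion_bookkeeping(small_trials, small_features):
    cfg = dataclasses.replace(
        PipelineConfig(), use_ga=False, use_pca=False,
        classifiers=("lda",), n_repeats=1,
    )
    rep = ev.run_scenario(
        "multi_signal_raw", small_trials, cfg, feature_df=small_features
    )
    r = rep.runs[0]
    assert r.confusion.sum() == r.n_test
    assert r.accuracy == pytest.approx(np.trace(r.confusion) / r.n_test)
    counts = pd.Series(r.confusion.sum(axis=1))
    assert counts.eq(r.n_test // 4).all()  # balanced classes, stratified split


def test_summarize_worked_examples():
    def run(acc, rep):
        return RunResult(
            scenario="multi_signal_raw", classifier="lda", group="",
            repeat=rep, accuracy=acc, per_class={"L0": acc},
            confusion=np.eye(2), n_test=4,
        )

    single = ScenarioReport("multi_signal_raw", [run(0.8, 0)], PipelineConfig())
    s = ev.summarize(single)
    assert s.loc[0, "sd_accuracy"] == 0.0
    assert s.loc[0, "chance"] == 0.25

    double = ScenarioReport(
        "multi_signal_raw", [run(0.8, 0), run(0.9, 1)], PipelineConfig()
    )
    d = ev.summarize(double)
    assert d.loc[0, "mean_accuracy"] == pytest.approx(0.85)
    assert d.loc[0, "sd_accuracy"] == pytest.approx(0.0707, abs=2e-4)


def test_single_signal_uses_each_channel(small_trials, small_features):
    cfg = dataclasses.replace(
        PipelineConfig(), use_ga=False, use_pca=False, n_repeats=1
    )
    rep = ev.run_scenario(
        "single_signal", small_trials, cfg, feature_df=small_features
    )
    assert {r.group for r in rep.runs} == {"bvp", "ecg", "scl"}
    assert all(r.classifier == "lda" for r in rep.runs)


def test_processed_ordering_beats_raw_on_average():
    """GA selection + PCA should not hurt mean LDA accuracy relative to
    the raw 36-feature model (10 split seeds, default cohort effects)."""
    proto = ps.ProtocolConfig(n_subjects=2, n_days=1, sessions_per_subject=6)
    trials = ps.simulate_cohort(proto, 77)
    base = dataclasses.replace(
        PipelineConfig(), classifiers=("lda",), n_repeats=10, seed=77
    )
    df = ev.extract_features(trials, base)
    raw_cfg = dataclasses.replace(base, use_ga=False, use_pca=False)
    proc_cfg = base.reduced_ga()
    raw = ev.run_scenario("multi_signal_raw", trials, raw_cfg, feature_df=df)
    proc = ev.run_scenario("multi_signal_processed", trials, proc_cfg, feature_df=df)
    assert proc.accuracies().mean() >= raw.accuracies().mean()
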