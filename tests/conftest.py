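import dataclasses

import pytest

import painsig as ps
from painsig import evaluation as ev


@pytest.fixture(scope="session")
def small_protocol():
    return ps.ProtocolConfig(n_subjects=2, n_days=1, sessions_per_subject=6)


@pytest.fixture(scope="session")
def small_trials(small_protocol):
    """2 subjects x 6 sessions x 4 levels = 48 one-minute trials."""
    return ps.simulate_cohort(small_protocol, 42)


@pytest.fixture(scope="session")
def small_features(small_trials):
    return ev.extract_features(small_trials, ev.PipelineConfig())


@pytest.fixture(scope="session")
def single_subject_dataset():
    """One subject, the full 30-session day: 120 trials, 1200 feature rows."""
    cfg = ps.ProtocolConfig(n_subjects=1, n_days=1)
    trials = ps.simulate_cohort(cfg, 7)
    df = ev.extract_features(trials, ev.PipelineConfig())
    return trials, df


@pytest.fixture(scope="session")
def null_features():
    """Null-effect setting: the four labels are statistically exchangeable."""
    cfg = ps.ProtocolConfig(n_subjects=1, n_days=1)
    trials = ps.simulate_cohort(cfg, 11, effect_scale=0.0)
    return ev.extract_features(trials, ev.PipelineConfig())


@pytest.fixture()
def fast_pipeline_config():
    """Pipeline config with a small GA budget for fold-structure tests."""
    return dataclasses.replace(
        ev.PipelineConfig(), classifiers=("lda",), n_repeats=2
    ).reduced_ga(population=10, generations=2, cv_folds=3)
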