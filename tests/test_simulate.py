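"""Generator contracts: determinism, level monotonicity, protocol counts."""

import dataclasses

import numpy as np
import pytest

import painsig as ps
from painsig.simulate import SCL_PHASIC_TAU_S, gen_subject_params, simulate_cohort, simulate_trial

FAST = ps.ProtocolConfig(
    n_subjects=1, n_days=1, sessions_per_subject=2, trial_duration_s=4.0
)


def test_subject_params_deterministic_and_distinct():
    a = gen_subject_params(123, 1)
    assert gen_subject_params(123, 1) == a
    assert gen_subject_params(123, 2) != a
    assert a.scl_phasic_gain_per_level > 0
    assert a.heart_rate_gain_per_level > 0


def test_trial_determinism_and_length():
    p = gen_subject_params(1, 1)
    a = simulate_trial(p, "L2", FAST, seed=99)
    b = simulate_trial(p, "L2", FAST, seed=99)
    for ch in ("bvp", "ecg", "scl"):
        assert np.array_equal(getattr(a, ch), getattr(b, ch))
        assert len(getattr(a, ch)) == FAST.samples_per_trial


def test_unknown_level_errors_with_label():
    p = gen_subject_params(1, 1)
    with pytest.raises(ValueError, match="L9"):
        simulate_trial(p, "L9", FAST, seed=0)


def test_baseline_zero_noise_scl_is_exactly_tonic():
    p = dataclasses.replace(
        gen_subject_params(1, 1), noise_sd_per_channel=(0.0, 0.0, 0.0)
    )
    tr = simulate_trial(p, "L0", FAST, seed=5)
    assert np.all(tr.scl == p.scl_tonic_level_uS)


def test_scl_mean_separation_monte_carlo():
    """Over 100 seeded trials the L3-vs-L0 mean-SCL margin follows the
    documented ramp model: 3 g (1 - (tau/T)(1 - e^(-T/tau))) >= g."""
    p = gen_subject_params(3, 1)
    cfg = dataclasses.replace(FAST, trial_duration_s=60.0)
    m0 = np.mean([simulate_trial(p, "L0", cfg, seed=s).scl.mean() for s in range(100)])
    m3 = np.mean(
        [simulate_trial(p, "L3", cfg, seed=1000 + s).scl.mean() for s in range(100)]
    )
    g = p.scl_phasic_gain_per_level
    tau, T = SCL_PHASIC_TAU_S, cfg.trial_duration_s
    expected_margin = 3 * g * (1 - (tau / T) * (1 - np.exp(-T / tau)))
    assert expected_margin >= 2 * g * 0.5
    assert m3 - m0 == pytest.approx(expected_margin, rel=0.05)
    assert m3 - m0 >= 2 * g * 0.5


def test_level_responses_monotone():
    """Mean SCL rises and BVP dispersion falls with level; the ECG beat
    count rises with level (heart-rate effect)."""
    from scipy.signal import find_peaks

    p = dataclasses.replace(
        gen_subject_params(4, 1), noise_sd_per_channel=(0.0, 0.0, 0.0)
    )
    cfg = dataclasses.replace(FAST, trial_duration_s=30.0)
    scl_means, bvp_sds, beats = [], [], []
    for lv in ps.LEVELS:
        means = []
        sds = []
        for s in range(10):
            tr = simulate_trial(p, lv, cfg, seed=s)
            means.append(tr.scl.mean())
            sds.append(tr.bvp.std())
        scl_means.append(np.mean(means))
        bvp_sds.append(np.mean(sds))
        tr = simulate_trial(p, lv, cfg, seed=0)
        peaks, _ = find_peaks(tr.ecg, height=400.0, distance=int(0.3 * 256))
        beats.append(len(peaks))
    assert np.all(np.diff(scl_means) > 0)
    assert np.all(np.diff(bvp_sds) < 0)
    assert beats[-1] > beats[0]


def test_cohort_counts_and_session_balance():
    cfg = ps.ProtocolConfig(n_subjects=1, n_days=1, trial_duration_s=2.0)
    trials = simulate_cohort(cfg, 21)
    assert len(trials) == 120  # 30 sessions x 4 levels per subject-day
    assert cfg.trials_per_day == 120
    by_session = {}
    for t in trials:
        by_session.setdefault(t.session_index, []).append(t.level)
    assert all(sorted(v) == sorted(ps.LEVELS) for v in by_session.values())


def test_multiday_subject_gets_all_days():
    cfg = ps.ProtocolConfig(
        n_subjects=2, n_days=3, sessions_per_subject=2, trial_duration_s=2.0
    )
    trials = simulate_cohort(cfg, 8)
    s1_days = sorted({t.day_index for t in trials if t.subject_id == "S1"})
    s2_days = sorted({t.day_index for t in trials if t.subject_id == "S2"})
    assert s1_days == [1, 2, 3]
    assert s2_days == [1]
    per_day = [
        sum(1 for t in trials if t.subject_id == "S1" and t.day_index == d)
        for d in s1_days
    ]
    assert per_day == [cfg.trials_per_day] * 3


def test_cohort_deterministic():
    cfg = ps.ProtocolConfig(
        n_subjects=1, n_days=1, sessions_per_subject=2, trial_duration_s=2.0
    )
    a = simulate_cohort(cfg, 5)
    b = simulate_cohort(cfg, 5)
    assert all(np.array_equal(x.scl, y.scl) for x, y in zip(a, b))
    assert [t.level for t in a] == [t.level for t in b]


def test_day_drift_dominates_between_day_variance():
    """With day_drift_sd > 0, the variance of per-day mean-SCL means
    exceeds the within-day variance of session means."""
    cfg = ps.ProtocolConfig(
        n_subjects=1, n_days=4, sessions_per_subject=4, trial_duration_s=10.0
    )
    trials = simulate_cohort(cfg, 13)
    day_session_means = {}
    for t in trials:
        day_session_means.setdefault(t.day_index, {}).setdefault(
            t.session_index, []
        ).append(t.scl.mean())
    day_means, within_vars = [], []
    for day, sessions in day_session_means.items():
        sess_means = [np.mean(v) for v in sessions.values()]
        day_means.append(np.mean(sess_means))
        within_vars.append(np.var(sess_means, ddof=1))
    assert np.var(day_means, ddof=1) > np.mean(within_vars)


def test_null_effect_scale_removes_level_structure():
    p = gen_subject_params(2, 1).scaled(0.0)
    assert p.scl_phasic_gain_per_level == 0.0
    assert p.heart_rate_gain_per_level == 0.0
    assert p.bvp_attenuation_per_level == 0.0
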