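"""Synthetic stimulus-locked BVP/ECG/SCL generator.

Emulates the electrical-stimulation protocol so the full recognition
pipeline is testable without recorded human data. Waveform models are
deliberately simple — a harmonic pulse wave for BVP, a template beat
train for ECG, and a tonic level plus exponential phasic ramp for SCL —
with the fidelity target that the four pain states are visibly and
statistically different, not that individual beats are physiological.

Per-level mean structure (documented model, relied on by tests):

* heart rate:      ``hr(r) = baseline + gain_hr * r``          (bpm)
* BVP amplitude:   ``A(r) = A0 * (1 - atten * r)``
* SCL:             ``scl(t; r) = tonic + gain_scl * r * (1 - exp(-t / tau))``
  with ``tau = 8 s``, so the trial-mean phasic component at level rank r is
  ``gain_scl * r * (1 - (tau/T) * (1 - exp(-T/tau)))`` for trial length T.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .protocol import (
    LEVELS,
    ProtocolConfig,
    SubjectParams,
    TrialRecord,
    level_rank,
)

SCL_PHASIC_TAU_S = 8.0

# Subject-parameter draw ranges (uniform). Chosen to span healthy young
# adults with clear but not saturating inter-subject overlap.
_PARAM_RANGES = {
    "baseline_heart_rate_bpm": (62.0, 78.0),
    "heart_rate_gain_per_level": (4.0, 7.0),
    "bvp_amplitude": (8.0, 12.0),
    "bvp_attenuation_per_level": (0.10, 0.18),
    "scl_tonic_level_uS": (4.0, 10.0),
    "scl_phasic_gain_per_level": (0.8, 1.5),
    "day_drift_sd": (0.2, 0.5),
}
_NOISE_RANGES = ((0.25, 0.45), (15.0, 30.0), (0.02, 0.05))  # bvp, ecg uV, scl uS


def gen_subject_params(master_seed: int, subject_index: int) -> SubjectParams:
    """Draw one subject's generative parameters, deterministically.

    The same ``(master_seed, subject_index)`` always yields the same
    parameters; different subject indices yield independent draws.
    """
    if subject_index < 1:
        raise ValueError("subject_index is 1-based")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(subject_index)])
    )
    draws = {k: rng.uniform(*v) for k, v in _PARAM_RANGES.items()}
    noise = tuple(rng.uniform(*r) for r in _NOISE_RANGES)
    return SubjectParams(noise_sd_per_channel=noise, **draws)


def _pulse_wave(phase: np.ndarray) -> np.ndarray:
    """Unit-amplitude pseudo-PPG pulse shape from three harmonics."""
    return (
        np.sin(phase)
        + 0.35 * np.sin(2.0 * phase + 0.8)
        + 0.15 * np.sin(3.0 * phase + 1.5)
    )


def _ecg_template(fs: float) -> tuple[np.ndarray, int]:
    """One PQRST complex sampled at fs; returns (template, R-offset samples)."""
    t = np.arange(-0.30, 0.45, 1.0 / fs)
    p = 90.0 * np.exp(-0.5 * ((t + 0.20) / 0.025) ** 2)
    q = -120.0 * np.exp(-0.5 * ((t + 0.025) / 0.010) ** 2)
    r = 900.0 * np.exp(-0.5 * (t / 0.012) ** 2)
    s = -180.0 * np.exp(-0.5 * ((t - 0.030) / 0.012) ** 2)
    tw = 220.0 * np.exp(-0.5 * ((t - 0.25) / 0.055) ** 2)
    template = p + q + r + s + tw
    return template, int(round(0.30 * fs))


def simulate_trial(
    params: SubjectParams,
    level: str,
    cfg: ProtocolConfig,
    seed: int,
    *,
    subject_id: str = "S1",
    day_index: int = 1,
    session_index: int = 1,
) -> TrialRecord:
    """Synthesize one 1-min trial at the given stimulus level.

    BVP is a pseudo-periodic pulse wave at the subject's (level-raised)
    heart rate with amplitude attenuated per level rank; ECG is a PQRST
    template train at the same rate over a slow baseline wander; SCL is
    the tonic level plus a stimulus-locked exponential ramp scaling with
    level. Independent Gaussian noise is added per channel. With zero
    noise and level L0 the SCL channel equals the tonic level exactly.
    """
    r = level_rank(level)
    if level not in cfg.stimulus_levels:
        raise ValueError(f"level {level!r} not in protocol levels {cfg.stimulus_levels}")
    rng = np.random.default_rng(int(seed))
    fs = cfg.sampling_rate_hz
    n = cfg.samples_per_trial
    t = np.arange(n) / fs
    sd_bvp, sd_ecg, sd_scl = params.noise_sd_per_channel

    hr_bpm = params.baseline_heart_rate_bpm + params.heart_rate_gain_per_level * r
    f_hr = hr_bpm / 60.0

    # --- BVP: harmonic pulse with mild respiratory frequency modulation.
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    inst_f = f_hr * (1.0 + 0.02 * np.sin(2.0 * np.pi * 0.25 * t + phi0))
    phase = 2.0 * np.pi * np.cumsum(inst_f) / fs
    amp = params.bvp_amplitude * (1.0 - params.bvp_attenuation_per_level * r)
    bvp = amp * _pulse_wave(phase)
    if sd_bvp > 0:
        bvp = bvp + rng.normal(0.0, sd_bvp, n)

    # --- ECG: template beat train with per-beat interval jitter, plus a
    # slow baseline wander that the preprocessing stage must remove.
    template, r_offset = _ecg_template(fs)
    ecg = np.zeros(n)
    mean_ibi = 60.0 / hr_bpm
    beat_time = rng.uniform(0.0, mean_ibi)
    while beat_time < cfg.trial_duration_s:
        start = int(round(beat_time * fs)) - r_offset
        lo, hi = max(start, 0), min(start + len(template), n)
        if hi > lo:
            ecg[lo:hi] += template[lo - start : hi - start]
        beat_time += mean_ibi * (1.0 + 0.03 * rng.standard_normal())
    wander_phi = rng.uniform(0.0, 2.0 * np.pi)
    ecg = ecg + 120.0 * np.sin(2.0 * np.pi * 0.12 * t + wander_phi)
    if sd_ecg > 0:
        ecg = ecg + rng.normal(0.0, sd_ecg, n)

    # --- SCL: tonic + stimulus-locked phasic ramp.
    scl = np.full(n, params.scl_tonic_level_uS)
    if r > 0:
        scl = scl + params.scl_phasic_gain_per_level * r * (
            1.0 - np.exp(-t / SCL_PHASIC_TAU_S)
        )
    if sd_scl > 0:
        scl = scl + rng.normal(0.0, sd_scl, n)

    return TrialRecord(
        subject_id=subject_id,
        day_index=day_index,
        session_index=session_index,
        level=level,
        seed=int(seed),
        sampling_rate_hz=fs,
        bvp=bvp,
        ecg=ecg,
        scl=scl,
    )


def _drift_params(
    params: SubjectParams, master_seed: int, subject_index: int, day: int
) -> SubjectParams:
    """Apply the day-to-day drift: small offsets to tonic SCL, heart rate
    and BVP amplitude, drawn deterministically per (subject, day)."""
    if params.day_drift_sd == 0:
        return params
    rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(subject_index), int(day), 7])
    )
    sd = params.day_drift_sd
    return dataclasses.replace(
        params,
        scl_tonic_level_uS=max(params.scl_tonic_level_uS + rng.normal(0.0, sd), 0.5),
        baseline_heart_rate_bpm=params.baseline_heart_rate_bpm
        + rng.normal(0.0, 6.0 * sd),
        bvp_amplitude=params.bvp_amplitude * (1.0 + 0.15 * sd * rng.standard_normal()),
    )


def simulate_cohort(
    cfg: ProtocolConfig,
    master_seed: int,
    *,
    effect_scale: float = 1.0,
) -> list[TrialRecord]:
    """Generate the full study cohort.

    Every subject is recorded on day 1; the designated multi-day subject
    (``cfg.multiday_subject``) is additionally recorded on days
    2..``cfg.n_days`` under day-drifted parameters. Each session holds one
    trial per level in a seeded random order, emulating the randomized
    stimulus sequencing of the protocol.

    ``effect_scale`` scales all three level effects; 0 gives the null
    setting in which the four labels are statistically exchangeable.
    """
    trials: list[TrialRecord] = []
    for s in range(1, cfg.n_subjects + 1):
        params = gen_subject_params(master_seed, s).scaled(effect_scale)
        days = range(1, cfg.n_days + 1) if s == cfg.multiday_subject else (1,)
        for day in days:
            day_params = _drift_params(params, master_seed, s, day)
            for sess in range(1, cfg.sessions_per_subject + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(master_seed), s, day, sess])
                )
                order = rng.permutation(len(cfg.stimulus_levels))
                for slot in order:
                    level = cfg.stimulus_levels[slot]
                    seed = int(rng.integers(0, 2**31))
                    trials.append(
                        simulate_trial(
                            day_params,
                            level,
                            cfg,
                            seed,
                            subject_id=f"S{s}",
                            day_index=day,
                            session_index=sess,
                        )
                    )
    return trials
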