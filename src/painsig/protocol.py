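"""Domain types for the electrical-stimulation pain protocol.

Four pain states are used throughout: ``L0`` (pre-stimulus baseline) and
electrical stimuli at 20/30/40 mA (``L1``–``L3``), spanning the calibrated
pain-threshold-to-tolerance range. Each trial is a 1-minute three-channel
recording (BVP, ECG, SCL) sampled at 256 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

LEVELS: tuple[str, ...] = ("L0", "L1", "L2", "L3")
LEVEL_CURRENT_MA: dict[str, float] = {"L0": 0.0, "L1": 20.0, "L2": 30.0, "L3": 40.0}
CHANNELS: tuple[str, ...] = ("bvp", "ecg", "scl")


def level_rank(level: str) -> int:
    """0-based rank of a stimulus level (L0 -> 0 ... L3 -> 3)."""
    try:
        return LEVELS.index(level)
    except ValueError:
        raise ValueError(
            f"unknown stimulus level {level!r}; expected one of {LEVELS}"
        ) from None


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition/stimulation protocol parameters.

    Defaults mirror the study protocol: 256 Hz sampling, 2 Hz stimulator,
    1-min trials, 30 sessions of 4 trials (one per level) per subject per
    day, 6 subjects, and 7 consecutive days for one designated subject.
    The 1.5–2 min recovery periods between trials are part of the protocol
    but carry no analysed signal, so they are never synthesized.
    """

    sampling_rate_hz: float = 256.0
    stimulus_levels: tuple[str, ...] = LEVELS
    stimulation_frequency_hz: float = 2.0
    trial_duration_s: float = 60.0
    recovery_range_s: tuple[float, float] = (90.0, 120.0)
    sessions_per_subject: int = 30
    trials_per_session: int = 4
    n_subjects: int = 6
    n_days: int = 7
    multiday_subject: int = 1

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        if self.sessions_per_subject < 1 or self.trials_per_session < 1:
            raise ValueError("session/trial counts must be positive")
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("n_subjects and n_days must be positive")
        if len(set(self.stimulus_levels)) != len(self.stimulus_levels):
            raise ValueError("stimulus levels must be distinct")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))

    @property
    def trials_per_day(self) -> int:
        """Total trials per subject per day (120 at defaults)."""
        return self.sessions_per_subject * self.trials_per_session


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters.

    Effect-size fields encode a response magnitude that is non-decreasing
    in stimulus level by construction: heart rate rises, BVP pulse
    amplitude attenuates (vasoconstriction), and the skin-conductance
    phasic component grows with the level rank.
    """

    baseline_heart_rate_bpm: float
    heart_rate_gain_per_level: float
    bvp_amplitude: float
    bvp_attenuation_per_level: float
    scl_tonic_level_uS: float
    scl_phasic_gain_per_level: float
    noise_sd_per_channel: tuple[float, float, float]
    day_drift_sd: float

    def __post_init__(self) -> None:
        if self.baseline_heart_rate_bpm <= 0 or self.bvp_amplitude <= 0:
            raise ValueError("rates and amplitudes must be positive")
        if not (0 <= self.bvp_attenuation_per_level < 1):
            raise ValueError("bvp_attenuation_per_level must lie in [0, 1)")
        if self.scl_tonic_level_uS <= 0:
            raise ValueError("scl_tonic_level_uS must be positive")
        if (
            self.heart_rate_gain_per_level < 0
            or self.scl_phasic_gain_per_level < 0
            or self.day_drift_sd < 0
            or any(s < 0 for s in self.noise_sd_per_channel)
        ):
            raise ValueError("effect sizes and noise SDs must be non-negative")

    def scaled(self, effect_scale: float) -> "SubjectParams":
        """Scale the three level-effect parameters; 0 gives the null setting."""
        return dataclasses.replace(
            self,
            heart_rate_gain_per_level=self.heart_rate_gain_per_level * effect_scale,
            bvp_attenuation_per_level=self.bvp_attenuation_per_level * effect_scale,
            scl_phasic_gain_per_level=self.scl_phasic_gain_per_level * effect_scale,
        )


@dataclass
class TrialRecord:
    """One labelled 1-min multi-channel recording.

    Channels are raw (pre-preprocessing): BVP in percent reflectance, ECG
    in microvolts, SCL in microsiemens, all at ``sampling_rate_hz``.
    """

    subject_id: str
    day_index: int
    session_index: int
    level: str
    seed: int
    sampling_rate_hz: float
    bvp: np.ndarray = field(repr=False)
    ecg: np.ndarray = field(repr=False)
    scl: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(
                f"unknown stimulus level {self.level!r}; expected one of {LEVELS}"
            )
        n = len(self.bvp)
        if len(self.ecg) != n or len(self.scl) != n:
            raise ValueError("all three channels must have the same length")
        if self.day_index < 1 or self.session_index < 1:
            raise ValueError("day_index and session_index are 1-based")
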