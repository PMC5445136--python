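"""Window segmentation and the 12 statistical features per channel.

Each preprocessed trial contributes windows from a 30-s analysis span
(by default the second half of the minute, allowing for the lag of the
pain reaction), cut by a 3-s sliding window with a 3-s step: 10 windows
per trial. Every window of every channel is summarized by 12 statistics:

====  =========================================================
f1    mean
f2    standard deviation (1/(N-1) divisor)
f3    mean absolute first difference
f4    f3 / f2 (mean absolute first difference of the standardized
      window; 0 when f2 = 0)
f5    mean absolute lag-2 difference (1/(N-2) divisor)
f6    f5 / f2 (0 when f2 = 0)
f7    minimum
f8    maximum
f9    minimum / N
f10   maximum / N
f11   range (max - min)
f12   median
====  =========================================================

f9 and f10 divide by the window length N as printed in the source
formulas, dimensionally odd but implemented literally. Rows are ordered
channel-major: BVP f1–f12, ECG f1–f12, SCL f1–f12 (36 columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocessedTrial

N_FEATURES_PER_CHANNEL = 12
FEATURE_COLUMNS: list[str] = [
    f"{ch}_f{j}" for ch in ("bvp", "ecg", "scl") for j in range(1, 13)
]
META_COLUMNS: list[str] = [
    "label",
    "subject_id",
    "day_index",
    "session_index",
    "trial_seed",
    "window_index",
]


def segment_windows(
    trial: PreprocessedTrial,
    analysis_span_s: float = 30.0,
    window_s: float = 3.0,
    step_s: float = 3.0,
    offset_s: float | None = None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Cut per-channel windows out of the analysis span of one trial.

    ``offset_s`` is where the span starts; by default the span is pushed
    to the end of the trial (the second half of a 60-s trial for the
    default 30-s span). Returns one (bvp, ecg, scl) tuple per window;
    window lengths differ across channels when sampling rates differ
    (768 samples at 256 Hz, 384 at 128 Hz, for 3-s windows).
    """
    duration = len(trial.bvp) / trial.bvp_fs
    if offset_s is None:
        offset_s = max(duration - analysis_span_s, 0.0)
    if offset_s + analysis_span_s > duration + 1e-9:
        raise ValueError(
            f"analysis span {analysis_span_s} s at offset {offset_s} s exceeds "
            f"trial length {duration} s"
        )
    if window_s > analysis_span_s:
        raise ValueError("window_s must not exceed analysis_span_s")
    n_windows = int(np.floor((analysis_span_s - window_s) / step_s)) + 1
    out = []
    channels = (
        (trial.bvp, trial.bvp_fs),
        (trial.ecg, trial.ecg_fs),
        (trial.scl, trial.scl_fs),
    )
    for w in range(n_windows):
        start_s = offset_s + w * step_s
        wins = []
        for x, fs in channels:
            a = int(round(start_s * fs))
            b = a + int(round(window_s * fs))
            wins.append(x[a:b])
        out.append(tuple(wins))
    return out


def _feature_block(W: np.ndarray) -> np.ndarray:
    """All 12 features for each row of a (n_windows, N) array."""
    n = W.shape[1]
    if n < 3:
        raise ValueError("window must hold at least 3 samples")
    mu = W.mean(axis=1)
    sd = W.std(axis=1, ddof=1)
    th1 = np.abs(np.diff(W, axis=1)).mean(axis=1)
    th2 = np.abs(W[:, 2:] - W[:, :-2]).sum(axis=1) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f4 = np.where(sd > 0, th1 / sd, 0.0)
        f6 = np.where(sd > 0, th2 / sd, 0.0)
    mn = W.min(axis=1)
    mx = W.max(axis=1)
    med = np.median(W, axis=1)
    return np.column_stack(
        [mu, sd, th1, f4, th2, f6, mn, mx, mn / n, mx / n, mx - mn, med]
    )


def extract_window_features(window: np.ndarray) -> np.ndarray:
    """The 12 statistics of a single window (length >= 3)."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be one-dimensional")
    return _feature_block(x[None, :])[0]


def assemble_feature_matrix(
    trials: list[PreprocessedTrial],
    analysis_span_s: float = 30.0,
    window_s: float = 3.0,
    step_s: float = 3.0,
    offset_s: float | None = None,
) -> pd.DataFrame:
    """One row per (trial, window): 36 feature columns plus label and
    provenance (subject, day, session, trial seed, window index)."""
    if not trials:
        raise ValueError("no trials to assemble features from")
    rows = []
    meta = []
    for tr in trials:
        wins = segment_windows(tr, analysis_span_s, window_s, step_s, offset_s)
        per_channel = [np.stack([w[c] for w in wins]) for c in range(3)]
        feats = np.hstack([_feature_block(block) for block in per_channel])
        rows.append(feats)
        meta.extend(
            (tr.level, tr.subject_id, tr.day_index, tr.session_index, tr.seed, w)
            for w in range(len(wins))
        )
    df = pd.DataFrame(np.vstack(rows), columns=FEATURE_COLUMNS)
    df[META_COLUMNS] = pd.DataFrame(meta, columns=META_COLUMNS)
    return df


def feature_values(df: pd.DataFrame, columns: list[str] | None = None) -> np.ndarray:
    """Feature columns of an assembled matrix as a float array."""
    return df[columns if columns is not None else FEATURE_COLUMNS].to_numpy(dtype=float)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column min–max bounds fitted on training data."""

    v_min: np.ndarray
    v_max: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        rng = self.v_max - self.v_min
        out = np.zeros_like(X, dtype=float)
        ok = rng > 0
        out[:, ok] = (X[:, ok] - self.v_min[ok]) / rng[ok]
        return out


def minmax_fit(train: np.ndarray) -> NormalizationParams:
    if train.size == 0:
        raise ValueError("cannot fit normalization on an empty matrix")
    return NormalizationParams(v_min=train.min(axis=0), v_max=train.max(axis=0))


def minmax_fit_apply(
    train: np.ndarray, *others: np.ndarray
) -> tuple[list[np.ndarray], NormalizationParams]:
    """Fit min–max bounds on the training matrix only and rescale every
    matrix with them. Training columns land in [0, 1]; held-out matrices
    may exceed that range. A constant column maps to 0."""
    params = minmax_fit(train)
    return [params.transform(m) for m in (train, *others)], params
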