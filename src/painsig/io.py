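"""Dataset persistence: one CSV per trial plus a YAML manifest.

Each trial file has columns ``time_s, bvp, ecg, scl`` (raw, at the
acquisition rate); the manifest records the protocol snapshot, format
version, and per-trial metadata (subject, day, session, level, seed,
file). Values are written with full float precision so a write/read
round trip reproduces the records bit-exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import LEVELS, ProtocolConfig, TrialRecord

MANIFEST_NAME = "manifest.yaml"
FORMAT_VERSION = 1


def write_dataset(
    trials: list[TrialRecord], out_dir: "str | Path", cfg: ProtocolConfig
) -> Path:
    """Write trials and manifest into ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(trials):
        fname = f"trial_{i:04d}.csv"
        t = np.arange(len(tr.bvp)) / tr.sampling_rate_hz
        pd.DataFrame(
            {"time_s": t, "bvp": tr.bvp, "ecg": tr.ecg, "scl": tr.scl}
        ).to_csv(out / fname, index=False, float_format="%.17g")
        entries.append(
            {
                "file": fname,
                "subject_id": tr.subject_id,
                "day_index": int(tr.day_index),
                "session_index": int(tr.session_index),
                "level": tr.level,
                "seed": int(tr.seed),
            }
        )
    manifest = {
        "format_version": FORMAT_VERSION,
        "protocol": dataclasses.asdict(cfg),
        "trials": entries,
    }
    path = out / MANIFEST_NAME
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_dataset(data_dir: "str | Path") -> tuple[list[TrialRecord], ProtocolConfig]:
    """Load a dataset written by :func:`write_dataset`."""
    data = Path(data_dir)
    mpath = data / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest ({MANIFEST_NAME}) found in {data}")
    manifest = yaml.safe_load(mpath.read_text())
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported dataset format version {version!r}")
    proto = manifest["protocol"]
    for key in ("stimulus_levels", "recovery_range_s"):
        if key in proto and isinstance(proto[key], list):
            proto[key] = tuple(proto[key])
    cfg = ProtocolConfig(**proto)
    trials = []
    for entry in manifest["trials"]:
        fpath = data / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(
                f"trial file {entry['file']!r} referenced by the manifest is missing"
            )
        if entry["level"] not in LEVELS:
            raise ValueError(
                f"trial {entry['file']!r} carries unknown level {entry['level']!r}"
            )
        df = pd.read_csv(fpath, float_precision="round_trip")
        missing = {"bvp", "ecg", "scl"} - set(df.columns)
        if missing:
            raise ValueError(
                f"trial {entry['file']!r} is malformed: missing columns {sorted(missing)}"
            )
        trials.append(
            TrialRecord(
                subject_id=entry["subject_id"],
                day_index=int(entry["day_index"]),
                session_index=int(entry["session_index"]),
                level=entry["level"],
                seed=int(entry["seed"]),
                sampling_rate_hz=float(cfg.sampling_rate_hz),
                bvp=df["bvp"].to_numpy(dtype=float),
                ecg=df["ecg"].to_numpy(dtype=float),
                scl=df["scl"].to_numpy(dtype=float),
            )
        )
    return trials, cfg
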