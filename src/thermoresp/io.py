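"""Session bundles on disk.

A bundle directory holds one CSV per channel (``nasal_temperature.csv``,
``chest_movement.csv``, ``chest_diameter.csv``, ``lick_vibration.csv``;
header ``# fs_hz=<float>, units=<str>, t0=0`` plus a single ``value``
column), ``schedule.json`` with the stimulus blocks and reward times,
``truth.json`` with the generator's ground-truth cycle boundaries and lick
onsets (simulated sessions only), and ``config.yaml`` echoing every
generator parameter and the seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .schedule import SessionSchedule
from .synthetic import GroundTruth, SessionBundle
from .trace import read_trace_csv, write_trace_csv

__all__ = ["write_bundle", "read_bundle", "CHANNEL_FILES"]

CHANNEL_FILES = {
    "temperature": "nasal_temperature.csv",
    "chest_diameter": "chest_diameter.csv",
    "chest_movement": "chest_movement.csv",
    "lick": "lick_vibration.csv",
}


def write_bundle(bundle: SessionBundle, out_dir: str | Path) -> Path:
    """Write a session bundle to a directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in CHANNEL_FILES.items():
        trace = getattr(bundle, attr)
        if trace is not None:
            write_trace_csv(trace, out / fname)
    with open(out / "schedule.json", "w") as fh:
        json.dump(bundle.schedule.to_dict(), fh, indent=1)
    if bundle.truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(bundle.truth.to_dict(), fh)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
    return out


def read_bundle(bundle_dir: str | Path) -> SessionBundle:
    """Read a session bundle directory.

    The temperature channel and schedule are mandatory; chest, lick,
    truth and config files are optional.
    """
    d = Path(bundle_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"bundle directory not found: {d}")
    temp_path = d / CHANNEL_FILES["temperature"]
    if not temp_path.exists():
        raise FileNotFoundError(
            f"missing mandatory channel {CHANNEL_FILES['temperature']} in {d}")
    sched_path = d / "schedule.json"
    if not sched_path.exists():
        raise FileNotFoundError(f"missing mandatory schedule.json in {d}")

    channels = {}
    for attr, fname in CHANNEL_FILES.items():
        p = d / fname
        channels[attr] = read_trace_csv(p, label=p.stem) if p.exists() else None
    with open(sched_path) as fh:
        schedule = SessionSchedule.from_dict(json.load(fh))
    truth = None
    if (d / "truth.json").exists():
        with open(d / "truth.json") as fh:
            truth = GroundTruth.from_dict(json.load(fh))
    config = {}
    if (d / "config.yaml").exists():
        with open(d / "config.yaml") as fh:
            config = yaml.safe_load(fh) or {}
    return SessionBundle(temperature=channels["temperature"],
                         chest_diameter=channels["chest_diameter"],
                         chest_movement=channels["chest_movement"],
                         lick=channels["lick"],
                         schedule=schedule, truth=truth, config=config)
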