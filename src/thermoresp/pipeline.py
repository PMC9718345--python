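"""End-to-end session analysis.

``analyze_session`` takes a session bundle (real recording or simulation),
extracts respiratory cycles from the nasal-temperature channel, splits the
inter-peak intervals by stimulus block, and runs the standard contrasts:
pooled music vs white noise (unpaired t test) and among the three music
tempos (one-way ANOVA).  If a chest channel is present the
thermosensor-vs-chest delay stage runs; if a lick channel is present the
lick-artifact stage (onset detection + temperature triggered average) runs.
The result is a structured, JSON-serializable :class:`SessionReport` with
full provenance (config hash, seed, package version) and an audit of every
parameter value actually used.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .delay import match_events, phase_event_times
from .events import detect_lick_onsets, triggered_average
from .respiration import (anchor_times, detect_extrema, integrate_chest_movement,
                          segment_cycles, summarize)
from .schedule import SessionSchedule
from .stats import anova_oneway, ttest_unpaired
from .synthetic import SessionBundle

__all__ = ["DEFAULT_CONFIG", "SessionReport", "PipelineStageError",
           "split_by_block", "analyze_session", "load_config", "merge_config"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "detection": {
        "smooth_window": 0.15,        # s, moving-average smoothing
        "min_prominence_frac": 0.3,   # fraction of robust amplitude
        "refractory": 0.6,            # s, same-kind extremum spacing
        "ipi_anchor": "peak",         # anchor extremum for the IPI series
        "detrend_window": 30.0,       # s, baseline window after integration
    },
    "events": {
        "k_mad": 5.0,
        "lick_refractory": 0.1,       # s
        "manual_threshold": None,
        "window_pre": 2.0,            # s before lick onset
        "window_post": 2.0,           # s after lick onset
    },
    "delay": {
        "peak_to_peak": False,        # literal peak-vs-peak matching mode
        "tolerance": None,            # s; None -> 0.45 x median IPI
    },
    "stats": {
        "t_variant": "pooled",
        "holm": False,
        "exclude_after_reward": 0.0,  # s; 0 disables post-reward IPI exclusion
    },
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto :data:`DEFAULT_CONFIG`."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (overrides or {}).items():
        if section in cfg and isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file and merge it onto the defaults."""
    import yaml

    if path is None:
        return merge_config(None)
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def split_by_block(anchors, schedule: SessionSchedule
                   ) -> tuple[dict[int, np.ndarray], int]:
    """Assign each inter-anchor interval to a stimulus block.

    An IPI is assigned to a block iff *both* bounding anchor events fall
    inside that block; intervals straddling a boundary or lying in an
    inter-block gap are discarded.  Returns ``{block_index: ipi_array}``
    (every block present, possibly empty) and the discarded count, so that
    assigned + discarded equals the total interval count.
    """
    anchors = np.asarray(anchors, float)
    if not schedule.blocks:
        raise ValueError("empty schedule: no blocks to split by")
    if np.any(np.diff(anchors) < 0):
        raise ValueError("anchor times must be sorted")
    by_block: dict[int, list[float]] = {i: [] for i in range(len(schedule.blocks))}
    discarded = 0
    for a, b in zip(anchors[:-1], anchors[1:]):
        ia = schedule.block_at(a)
        ib = schedule.block_at(b)
        if ia is not None and ia == ib:
            by_block[ia].append(b - a)
        else:
            discarded += 1
    return {i: np.asarray(v) for i, v in by_block.items()}, discarded


def _exclude_after_reward(anchors: np.ndarray, ipis_by_block, schedule,
                          window: float):
    """Drop IPIs whose span intersects a post-reward window (optional)."""
    if window <= 0:
        return ipis_by_block
    # rebuild the per-block assignment, skipping intervals near rewards
    out: dict[int, list[float]] = {i: [] for i in ipis_by_block}
    rewards = schedule.reward_times
    for a, b in zip(anchors[:-1], anchors[1:]):
        ia = schedule.block_at(a)
        ib = schedule.block_at(b)
        if ia is None or ia != ib:
            continue
        if np.any((rewards < b) & (rewards + window > a)):
            continue
        out[ia].append(b - a)
    return {i: np.asarray(v) for i, v in out.items()}


@dataclass
class SessionReport:
    """Aggregated results of one session analysis."""

    per_block: list[dict]                 # one entry per schedule block, in order
    music_vs_noise: dict | None
    among_music: dict | None
    overall: dict
    n_discarded_ipis: int
    delay_report: dict | None
    lick_report: dict | None
    parameters: dict                      # every knob actually used
    provenance: dict                      # config hash, seed, version

    def to_dict(self) -> dict:
        return {
            "per_block": self.per_block,
            "music_vs_noise": self.music_vs_noise,
            "among_music": self.among_music,
            "overall": self.overall,
            "n_discarded_ipis": self.n_discarded_ipis,
            "delay_report": self.delay_report,
            "lick_report": self.lick_report,
            "parameters": self.parameters,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SessionReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(per_block=d["per_block"], music_vs_noise=d["music_vs_noise"],
                   among_music=d["among_music"], overall=d["overall"],
                   n_discarded_ipis=d["n_discarded_ipis"],
                   delay_report=d["delay_report"], lick_report=d["lick_report"],
                   parameters=d["parameters"], provenance=d["provenance"])


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _block_summary(block, idx: int, ipis: np.ndarray, cycles) -> dict:
    inside = [c for c in cycles if block.contains(c.insp_start)]
    ratios = [c.ie_ratio for c in inside]
    return {
        "block": idx, "kind": block.kind, "tempo_bpm": block.tempo_bpm,
        "start": block.start, "duration": block.duration,
        "n_ipis": int(len(ipis)),
        "mean_ipi": float(np.mean(ipis)) if len(ipis) else None,
        "sd_ipi": float(np.std(ipis, ddof=1)) if len(ipis) > 1 else None,
        "ie_ratio": float(np.mean(ratios)) if ratios else None,
    }


def analyze_session(bundle, config: dict | None = None) -> SessionReport:
    """Run the full analysis on a session bundle (object or directory).

    Mandatory inputs are the nasal-temperature channel and the schedule.
    Optional chest channels trigger the delay stage; an optional lick
    channel triggers the lick-artifact stage.  Deterministic given inputs.
    """
    if not isinstance(bundle, SessionBundle):
        from .io import read_bundle
        bundle = read_bundle(bundle)
    cfg = merge_config(config)
    det = cfg["detection"]
    if bundle.temperature is None:
        raise ValueError("missing mandatory channel: nasal temperature")
    logger.info("analysis parameters: %s", json.dumps(cfg, sort_keys=True,
                                                      default=str))

    # --- respiration extraction -------------------------------------------
    try:
        extrema = detect_extrema(bundle.temperature,
                                 smooth_window=det["smooth_window"],
                                 min_prominence_frac=det["min_prominence_frac"],
                                 refractory=det["refractory"])
        cycles = segment_cycles(extrema, "temperature")
        summary = summarize(cycles, ipi_anchor=det["ipi_anchor"],
                            signal_kind="temperature")
        anchors = anchor_times(cycles, ipi_anchor=det["ipi_anchor"],
                               signal_kind="temperature")
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineStageError("respiration", e) from e

    # --- split by stimulus block and contrast -----------------------------
    try:
        by_block, discarded = split_by_block(anchors, bundle.schedule)
        by_block = _exclude_after_reward(anchors, by_block, bundle.schedule,
                                         cfg["stats"]["exclude_after_reward"])
        blocks = bundle.schedule.blocks
        music = [by_block[i] for i, b in enumerate(blocks) if b.kind == "music"]
        noise = [by_block[i] for i, b in enumerate(blocks) if b.kind == "noise"]
        music_pooled = np.concatenate(music) if music else np.empty(0)
        noise_pooled = np.concatenate(noise) if noise else np.empty(0)
        music_vs_noise = None
        if len(music_pooled) >= 2 and len(noise_pooled) >= 2:
            music_vs_noise = ttest_unpaired(
                music_pooled, noise_pooled,
                variant=cfg["stats"]["t_variant"]).to_dict()
        among_music = None
        if len(music) >= 2 and all(len(g) >= 2 for g in music):
            among_music = anova_oneway(music).to_dict()
        per_block = [_block_summary(b, i, by_block[i], cycles)
                     for i, b in enumerate(blocks)]
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("block_contrasts", e) from e

    # --- optional delay stage ---------------------------------------------
    delay_report = None
    chest_diam = bundle.chest_diameter
    if chest_diam is None and bundle.chest_movement is not None:
        chest_diam = integrate_chest_movement(
            bundle.chest_movement, detrend_window=det["detrend_window"])
    if chest_diam is not None:
        try:
            chest_ex = detect_extrema(chest_diam,
                                      smooth_window=det["smooth_window"],
                                      min_prominence_frac=det["min_prominence_frac"],
                                      refractory=det["refractory"])
            thermo_ev, chest_ev = phase_event_times(
                extrema, chest_ex, peak_to_peak=cfg["delay"]["peak_to_peak"])
            delay_report = match_events(
                thermo_ev, chest_ev, tolerance=cfg["delay"]["tolerance"]).to_dict()
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("delay", e) from e

    # --- optional lick stage ----------------------------------------------
    lick_report = None
    if bundle.lick is not None:
        try:
            ev_cfg = cfg["events"]
            licks = detect_lick_onsets(bundle.lick, k_mad=ev_cfg["k_mad"],
                                       refractory=ev_cfg["lick_refractory"],
                                       manual_threshold=ev_cfg["manual_threshold"])
            lick_report = {"events": licks.to_dict(), "triggered": None}
            if licks.n >= 1:
                ta = triggered_average(
                    bundle.temperature, licks.onsets,
                    window=(ev_cfg["window_pre"], ev_cfg["window_post"]))
                lick_report["triggered"] = ta.to_dict()
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError("lick", e) from e

    provenance = {
        "config_hash": _config_hash(cfg),
        "seed": bundle.config.get("seed") if bundle.config else None,
        "version": __version__,
        "schema": 1,
    }
    return SessionReport(
        per_block=per_block, music_vs_noise=music_vs_noise,
        among_music=among_music, overall=summary.to_dict(),
        n_discarded_ipis=int(discarded), delay_report=delay_report,
        lick_report=lick_report, parameters=cfg, provenance=provenance)
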