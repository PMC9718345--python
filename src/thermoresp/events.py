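"""Lick detection and event-triggered averaging.

Licking is read from a vibration sensor on the reward spout.  Onsets are
taken as upward threshold crossings of the rectified signal, with a
refractory period to suppress re-triggers within one lick; the threshold
is either supplied manually (field practice adjusts it per day) or set
automatically at median + k * MAD of the rectified trace.

Whether licking contaminates the temperature signal is assessed with an
event-triggered average: trace segments around each lick are aligned on a
common lag grid, baseline-subtracted by their pre-event mean, and averaged.
A *modulation index* — peak absolute post-event mean deviation divided by
the robust respiratory amplitude of the whole trace — quantifies any
event-locked structure; when licks are independent of respiration the
averaging washes out unlocked breathing cycles and the index is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trace import SampledTrace

__all__ = ["LickEvents", "TriggeredAverage", "detect_lick_onsets",
           "triggered_average", "null_modulation_indices"]

logger = logging.getLogger(__name__)

DEFAULT_K_MAD = 5.0
DEFAULT_LICK_REFRACTORY_S = 0.1
DEFAULT_WINDOW_S = (2.0, 2.0)


@dataclass
class LickEvents:
    onsets: np.ndarray          # seconds, strictly increasing
    threshold_used: float       # signal units (rectified scale)
    n: int

    def to_dict(self) -> dict:
        return {"onsets": self.onsets.tolist(),
                "threshold_used": self.threshold_used, "n": self.n}


@dataclass
class TriggeredAverage:
    lags: np.ndarray            # seconds
    mean: np.ndarray            # signal units
    sd: np.ndarray
    n_events: int
    modulation_index: float

    def to_dict(self) -> dict:
        return {"lags": self.lags.tolist(), "mean": self.mean.tolist(),
                "sd": self.sd.tolist(), "n_events": self.n_events,
                "modulation_index": self.modulation_index}


def detect_lick_onsets(vibration: SampledTrace,
                       k_mad: float = DEFAULT_K_MAD,
                       refractory: float = DEFAULT_LICK_REFRACTORY_S,
                       manual_threshold: float | None = None) -> LickEvents:
    """Threshold-crossing lick onsets on the rectified vibration signal.

    The trace is baseline-subtracted (median) and rectified; the threshold
    is ``manual_threshold`` if given, else ``median(rectified) + k_mad *
    sigma`` where ``sigma`` is the robust noise SD (1.4826 times the median
    absolute deviation of the baseline-subtracted signal).  An onset is an
    upward crossing; subsequent crossings within ``refractory`` seconds are
    suppressed.
    """
    if len(vibration) == 0:
        raise ValueError("empty vibration trace")
    centered = vibration.values - np.median(vibration.values)
    x = np.abs(centered)
    if manual_threshold is not None:
        thr = float(manual_threshold)
    else:
        sigma = 1.4826 * np.median(np.abs(centered))
        thr = float(np.median(x) + k_mad * sigma)
    above = x >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    if len(crossings) == 0:
        logger.warning("lick threshold %.4g above global maximum %.4g: no events",
                       thr, float(np.max(x)))
        return LickEvents(onsets=np.empty(0), threshold_used=thr, n=0)
    gap = int(round(refractory * vibration.fs))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= gap:
            kept.append(c)
    onsets = vibration.t0 + np.asarray(kept) / vibration.fs
    return LickEvents(onsets=onsets, threshold_used=thr, n=len(onsets))


def robust_amplitude(trace: SampledTrace) -> float:
    """90th minus 10th percentile: the respiratory excursion scale."""
    return float(np.percentile(trace.values, 90) - np.percentile(trace.values, 10))


def triggered_average(trace: SampledTrace, events,
                      window: tuple[float, float] = DEFAULT_WINDOW_S
                      ) -> TriggeredAverage:
    """Event-triggered mean and SD of a signal.

    Segments from ``-window[0]`` to ``+window[1]`` seconds around each
    event are sampled on a common lag grid (the trace's own sampling
    comb), baseline-subtracted by their pre-event mean, and averaged
    across events.  Events whose window overlaps a trace edge are dropped.
    """
    events = np.asarray(events, float)
    pre, post = window
    n_pre = int(round(pre * trace.fs))
    n_post = int(round(post * trace.fs))
    lag_idx = np.arange(-n_pre, n_post + 1)
    lags = lag_idx / trace.fs

    segments = []
    for t in events:
        i0 = int(round((t - trace.t0) * trace.fs))
        if i0 - n_pre < 0 or i0 + n_post >= len(trace.values):
            continue
        seg = trace.values[i0 + lag_idx].astype(float)
        baseline = seg[lag_idx < 0].mean() if n_pre > 0 else seg[0]
        segments.append(seg - baseline)
    if not segments:
        raise ValueError("no events lie fully inside the trace after windowing")
    segs = np.vstack(segments)
    mean = segs.mean(axis=0)
    sd = segs.std(axis=0, ddof=1) if len(segs) > 1 else np.zeros_like(mean)
    amp = robust_amplitude(trace)
    post_mask = lag_idx >= 0
    mi = float(np.max(np.abs(mean[post_mask])) / amp) if amp > 0 else 0.0
    return TriggeredAverage(lags=lags, mean=mean, sd=sd, n_events=len(segs),
                            modulation_index=mi)


def null_modulation_indices(trace: SampledTrace, n_events: int, n_draws: int,
                            seed: int,
                            window: tuple[float, float] = DEFAULT_WINDOW_S
                            ) -> np.ndarray:
    """Null distribution of the modulation index for events unrelated to
    the trace: ``n_draws`` sets of ``n_events`` uniformly random event
    times, each scored with :func:`triggered_average`."""
    rng = np.random.default_rng(seed)
    pre, post = window
    lo = trace.t0 + pre
    hi = trace.t0 + trace.duration - post
    out = np.empty(n_draws)
    for k in range(n_draws):
        ev = np.sort(rng.uniform(lo, hi, size=n_events))
        out[k] = triggered_average(trace, ev, window).modulation_index
    return out


def plot_triggered_average(ta: TriggeredAverage, path, title: str = "") -> None:
    """Save a mean +/- SD plot of a triggered average as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(ta.lags, ta.mean - ta.sd, ta.mean + ta.sd,
                    alpha=0.3, label="+/- SD")
    ax.plot(ta.lags, ta.mean, lw=1.5, label=f"mean (n={ta.n_events})")
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("lag from lick onset (s)")
    ax.set_ylabel("baseline-subtracted signal")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
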