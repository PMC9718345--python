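"""Respiratory cycle extraction and breath-interval summaries.

The respiration waveform (nasal temperature or chest diameter) is smoothed
with a short moving average, local extrema are detected with a prominence
floor and a refractory spacing, alternation between peaks and troughs is
enforced, and extremum times are refined to sub-sample precision by
parabolic interpolation.  Alternating extrema are then segmented into
breath cycles whose phase labels depend on the signal convention: the
nasal temperature *falls* during inspiration (cool ambient air in) and
*rises* during expiration (warm air out), while the chest diameter does
the opposite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .trace import SampledTrace

__all__ = [
    "Extrema",
    "RespCycle",
    "RespSummary",
    "NoRespirationError",
    "detect_extrema",
    "segment_cycles",
    "summarize",
    "anchor_times",
    "integrate_chest_movement",
    "moving_average",
    "parabolic_refine",
]

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_WINDOW_S = 0.15
DEFAULT_MIN_PROMINENCE_FRAC = 0.3
DEFAULT_REFRACTORY_S = 0.6

PEAK = "peak"
TROUGH = "trough"


class NoRespirationError(ValueError):
    """Raised when fewer than two respiratory extrema survive detection."""


@dataclass
class Extrema:
    """Alternating respiratory waveform extrema.

    ``times`` are sub-sample (parabolically interpolated) event times in
    seconds; ``kinds`` holds ``"peak"`` or ``"trough"`` per event and
    strictly alternates.
    """

    times: np.ndarray
    kinds: np.ndarray   # array of str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.kinds = np.asarray(self.kinds)
        if len(self.times) != len(self.kinds):
            raise ValueError("times and kinds must have equal length")
        if len(self.times) > 1:
            if not np.all(np.diff(self.times) > 0):
                raise ValueError("extrema times must strictly increase")
            if np.any(self.kinds[1:] == self.kinds[:-1]):
                raise ValueError("extrema kinds must strictly alternate")

    def of_kind(self, kind: str) -> np.ndarray:
        return self.times[self.kinds == kind]

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RespCycle:
    """One breath: inspiration then expiration."""

    insp_start: float
    exp_start: float
    insp_duration: float
    exp_duration: float

    def __post_init__(self) -> None:
        if not (self.insp_duration > 0 and self.exp_duration > 0):
            raise ValueError("cycle durations must be positive")

    @property
    def ie_ratio(self) -> float:
        return self.insp_duration / self.exp_duration


@dataclass
class RespSummary:
    """Inter-peak-interval and I/E summaries over a cycle list."""

    ipi_series: np.ndarray
    mean_ipi: float
    sd_ipi: float
    ie_ratio: float
    n_cycles: int

    def to_dict(self) -> dict:
        return {"mean_ipi": self.mean_ipi, "sd_ipi": self.sd_ipi,
                "ie_ratio": self.ie_ratio, "n_cycles": self.n_cycles,
                "ipi_series": np.asarray(self.ipi_series).tolist()}


def moving_average(values: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average with reflected edges.

    The window is forced odd so the kernel is exactly symmetric and
    introduces no phase shift.
    """
    w = max(int(window_samples), 1)
    if w % 2 == 0:
        w += 1
    x = np.asarray(values, float)
    if w <= 1:
        return x.copy()
    return uniform_filter1d(x, size=w, mode="reflect")


def parabolic_refine(values: np.ndarray, idx: np.ndarray, fs: float,
                     t0: float) -> np.ndarray:
    """Sub-sample extremum times from a parabola through three points.

    Needed because the thermosensor-vs-chest delays of interest are of the
    order of one sample at 100 Hz.
    """
    idx = np.asarray(idx, int)
    times = t0 + idx / fs
    inner = (idx > 0) & (idx < len(values) - 1)
    i = idx[inner]
    a = values[i - 1]
    b = values[i]
    c = values[i + 1]
    denom = a - 2 * b + c
    shift = np.where(denom != 0, 0.5 * (a - c) / np.where(denom == 0, 1.0, denom), 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    times[inner] = t0 + (i + shift) / fs
    return times


def enforce_alternation(idx: np.ndarray, kinds: np.ndarray,
                        prominences: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Drop the lower-prominence of two consecutive same-kind extrema until
    kinds strictly alternate (ties drop the later event)."""
    idx = list(idx)
    kinds = list(kinds)
    prom = list(prominences)
    changed = True
    while changed:
        changed = False
        for j in range(len(idx) - 1):
            if kinds[j] == kinds[j + 1]:
                drop = j + 1 if prom[j] >= prom[j + 1] else j
                del idx[drop], kinds[drop], prom[drop]
                changed = True
                break
    return np.asarray(idx, int), np.asarray(kinds)


def detect_extrema(trace: SampledTrace,
                   smooth_window: float = DEFAULT_SMOOTH_WINDOW_S,
                   min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
                   refractory: float = DEFAULT_REFRACTORY_S) -> Extrema:
    """Detect alternating peaks and troughs of a respiration waveform.

    The trace is smoothed with a centered moving average, then peaks and
    troughs are found with prominence at least ``min_prominence_frac``
    times the robust amplitude (90th minus 10th percentile of the smoothed
    trace) and spacing at least ``refractory`` within each kind.
    Consecutive same-kind extrema are resolved by keeping the more
    prominent one, and returned times are parabolically interpolated.
    """
    if trace.duration <= 3 * refractory:
        raise ValueError(
            f"trace must be longer than 3 x refractory = {3 * refractory:g} s")
    s = moving_average(trace.values, round(smooth_window * trace.fs))
    amp = np.percentile(s, 90) - np.percentile(s, 10)
    if amp <= 0:
        raise NoRespirationError("flat trace: no respiratory amplitude")
    prominence = min_prominence_frac * amp
    distance = max(int(round(refractory * trace.fs)), 1)

    pk, pk_props = find_peaks(s, distance=distance, prominence=prominence)
    tr, tr_props = find_peaks(-s, distance=distance, prominence=prominence)
    idx = np.concatenate([pk, tr])
    kinds = np.concatenate([np.full(len(pk), PEAK), np.full(len(tr), TROUGH)])
    proms = np.concatenate([pk_props["prominences"], tr_props["prominences"]])
    order = np.argsort(idx)
    idx, kinds, proms = idx[order], kinds[order], proms[order]

    idx, kinds = enforce_alternation(idx, kinds, proms)
    if len(idx) < 2:
        raise NoRespirationError(
            f"only {len(idx)} extrema survived detection; need at least 2")
    times = parabolic_refine(s, idx, trace.fs, trace.t0)
    return Extrema(times=times, kinds=kinds)


def segment_cycles(extrema: Extrema, signal_kind: str) -> list[RespCycle]:
    """Segment alternating extrema into breath cycles.

    For ``signal_kind="temperature"`` inspiration runs peak -> trough (the
    nasal air cools) and expiration trough -> peak; for
    ``signal_kind="chest_diameter"`` the labels are swapped (the chest
    expands during inspiration).  Partial cycles at the edges are dropped.
    """
    if signal_kind == "temperature":
        insp_kind = PEAK
    elif signal_kind == "chest_diameter":
        insp_kind = TROUGH
    else:
        raise ValueError(f"unknown signal_kind {signal_kind!r}")
    if len(extrema) < 3:
        raise ValueError("need at least 3 alternating extrema to form a cycle")

    t = extrema.times
    k = extrema.kinds
    cycles = []
    for i in range(len(t) - 2):
        if k[i] == insp_kind:   # k[i+1], k[i+2] alternate by construction
            cycles.append(RespCycle(
                insp_start=float(t[i]), exp_start=float(t[i + 1]),
                insp_duration=float(t[i + 1] - t[i]),
                exp_duration=float(t[i + 2] - t[i + 1])))
    return cycles


def _resolve_anchor(ipi_anchor: str, signal_kind: str) -> str:
    """Map a waveform-extremum anchor ("peak"/"trough") to the cycle phase
    boundary it marks under the given signal convention."""
    if ipi_anchor in ("insp_start", "exp_start"):
        return ipi_anchor
    if ipi_anchor not in (PEAK, TROUGH):
        raise ValueError(f"unknown ipi_anchor {ipi_anchor!r}")
    if signal_kind == "temperature":
        return "insp_start" if ipi_anchor == PEAK else "exp_start"
    if signal_kind == "chest_diameter":
        return "exp_start" if ipi_anchor == PEAK else "insp_start"
    raise ValueError(f"unknown signal_kind {signal_kind!r}")


def summarize(cycles: list[RespCycle], ipi_anchor: str = PEAK,
              signal_kind: str = "temperature") -> RespSummary:
    """IPI series and I/E ratio over a cycle list.

    ``ipi_anchor`` selects which waveform extremum anchors the inter-peak
    intervals: ``"peak"`` (the default; on a temperature trace these are
    the expiration-end peaks marked in field practice) or ``"trough"``.
    ``signal_kind`` maps the extremum onto the phase boundary it marks.
    The I/E ratio is the mean of per-cycle inspiration/expiration duration
    ratios.
    """
    if len(cycles) < 2:
        raise ValueError(f"need at least 2 cycles to summarize, got {len(cycles)}")
    field_name = _resolve_anchor(ipi_anchor, signal_kind)
    anchors = np.array([getattr(c, field_name) for c in cycles])
    ipi = np.diff(anchors)
    ratios = np.array([c.ie_ratio for c in cycles])
    return RespSummary(ipi_series=ipi, mean_ipi=float(np.mean(ipi)),
                       sd_ipi=float(np.std(ipi, ddof=1)) if len(ipi) > 1 else 0.0,
                       ie_ratio=float(np.mean(ratios)), n_cycles=len(cycles))


def anchor_times(cycles: list[RespCycle], ipi_anchor: str = PEAK,
                 signal_kind: str = "temperature") -> np.ndarray:
    """The anchor event times underlying the IPI series of :func:`summarize`."""
    field_name = _resolve_anchor(ipi_anchor, signal_kind)
    return np.array([getattr(c, field_name) for c in cycles])


def integrate_chest_movement(movement: SampledTrace,
                             detrend_window: float = 30.0) -> SampledTrace:
    """Chest diameter from the chest-band movement signal.

    Cumulative trapezoidal integration followed by subtraction of a
    running-mean baseline (default 30 s window) to suppress integration
    drift.  Output units are input units times seconds.
    """
    d = cumulative_trapezoid(movement.values, dx=1.0 / movement.fs, initial=0.0)
    if detrend_window and detrend_window > 0:
        d = d - moving_average(d, round(detrend_window * movement.fs))
    units = f"{movement.units}*s" if movement.units else ""
    return SampledTrace(d, fs=movement.fs, t0=movement.t0, units=units,
                        label="chest_diameter")
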