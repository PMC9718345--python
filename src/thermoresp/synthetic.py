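"""Ground-truthed synthetic recording sessions.

This module emulates the physics and protocol of nasal-thermosensor
respiration monitoring in head-fixed macaques, so that every downstream
analysis stage can be tested against known truth:

* a quasi-periodic breath-cycle train with controllable inter-peak-interval
  (IPI) mean and variability and inspiration/expiration (I/E) ratio, which
  accelerates during music blocks;
* a chest channel pair — smooth chest *diameter* and its derivative, the
  chest-band *movement* signal — built so that trapezoidal integration of
  the noiseless movement recovers the diameter exactly;
* a nasal-temperature channel: an idealized airflow-temperature waveform
  (cooling toward ambient during inspiration, warming toward expired-air
  temperature during expiration), shifted by a weight-dependent transport
  delay, attenuated and smeared depending on probe position, passed through
  the sensor's first-order lag (time constant 100 ms by default), plus noise;
* a lick-vibration channel with bursts of damped transients after each
  reward.

All randomness flows through explicit integer seeds; identical
(configuration, seed) pairs yield bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter, lfilter_zi

from .schedule import SessionSchedule
from .trace import SampledTrace

__all__ = [
    "BreathingProfile",
    "SensorModel",
    "GroundTruth",
    "generate_cycle_train",
    "render_chest_channels",
    "render_nasal_temperature",
    "render_lick_channel",
    "first_order_lag",
    "respiratory_phase",
    "simulate_session",
    "SessionBundle",
    "DEFAULT_FS_HZ",
]

#: Default sampling rate for all rendered channels, Hz.
DEFAULT_FS_HZ = 100.0

#: Shortest physiologically plausible breath; IPI draws are truncated here.
MIN_IPI_S = 0.3


@dataclass(frozen=True)
class BreathingProfile:
    """Breathing statistics of one (simulated) animal.

    ``mean_ipi`` is the mean inter-peak interval in seconds (reciprocal of
    breathing frequency); resting macaque breathing sits near 0.4-0.5 Hz.
    ``ie_ratio`` is inspiration duration / expiration duration within a
    cycle.  ``music_ipi_factor`` < 1 shortens the drawn IPI during music
    blocks (breathing accelerates under rhythmic auditory stimulation).
    """

    mean_ipi: float = 2.2            # s
    ipi_cv: float = 0.15             # coefficient of variation, dimensionless
    ie_ratio: float = 0.88           # dimensionless
    amplitude_chest: float = 1.0     # arbitrary diameter units
    body_weight: float = 6.0         # kg; study animals spanned 5.0-7.0 kg
    music_ipi_factor: float = 0.85   # dimensionless, <= 1

    def __post_init__(self) -> None:
        if not self.mean_ipi > 0:
            raise ValueError("mean_ipi must be > 0")
        if self.ipi_cv < 0:
            raise ValueError("ipi_cv must be >= 0")
        if not self.ie_ratio > 0:
            raise ValueError("ie_ratio must be > 0")
        if not self.body_weight > 0:
            raise ValueError("body_weight must be > 0")
        if not 0 < self.music_ipi_factor <= 1:
            raise ValueError("music_ipi_factor must be in (0, 1]")


@dataclass(frozen=True)
class SensorModel:
    """Thermosensor and placement physics.

    The sensor responds as a first-order low-pass with ``time_constant``
    (100 ms for the thermocouple probe used in the field).  The probe sits
    at one of three positions relative to the nostril entrance (-5 mm
    outside, 0 mm at the entrance, +5 mm inside).  Position affects the
    signal two ways: an amplitude gain (full expired-air excursion inside,
    attenuated outside where expired air mixes with ambient air) and an
    air-mixing smear modelled as an extra first-order lag (zero inside,
    growing outward) — the mixing term is what makes the measured peak delay
    shrink as the probe moves inward.  Bigger animals move more air, so the
    airflow arrives at the sensor later: transport delay =
    ``transport_delay_intercept + transport_delay_per_kg * body_weight``.
    """

    time_constant: float = 0.1       # s
    probe_position: int = 5          # mm; -5 = outside, 0 = entrance, +5 = inside
    attenuation_by_position: dict = field(
        default_factory=lambda: {-5: 0.5, 0: 0.75, 5: 1.0})
    mixing_tau_by_position: dict = field(
        default_factory=lambda: {-5: 0.08, 0: 0.04, 5: 0.0})
    transport_delay_per_kg: float = 0.01   # s/kg
    transport_delay_intercept: float = 0.0  # s
    ambient_temp: float = 25.0       # degC
    expired_temp: float = 34.0       # degC
    noise_sd: float = 0.05           # degC

    def __post_init__(self) -> None:
        if self.time_constant < 0:
            raise ValueError("time_constant must be >= 0")
        if not self.expired_temp > self.ambient_temp:
            raise ValueError("expired_temp must exceed ambient_temp")
        for g in self.attenuation_by_position.values():
            if not 0 < g <= 1:
                raise ValueError("position gains must be in (0, 1]")
        if self.probe_position not in self.attenuation_by_position:
            raise ValueError(
                f"probe_position {self.probe_position} has no gain entry "
                f"(allowed: {sorted(self.attenuation_by_position)})")

    @property
    def gain(self) -> float:
        return self.attenuation_by_position[self.probe_position]

    @property
    def mixing_tau(self) -> float:
        return self.mixing_tau_by_position.get(self.probe_position, 0.0)

    def transport_delay(self, body_weight: float) -> float:
        d = self.transport_delay_intercept + self.transport_delay_per_kg * body_weight
        if d < 0:
            raise ValueError("transport delay evaluated negative")
        return d


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests.

    ``cycle_boundaries`` holds one ``(inspiration_start, expiration_start)``
    pair per breath; successive inspiration starts differ by
    ``per_cycle_ipi``.  Lick onsets are filled in by the lick renderer.
    """

    cycle_boundaries: np.ndarray          # (n, 2): insp_start, exp_start
    per_cycle_ipi: np.ndarray             # (n,)
    lick_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.cycle_boundaries = np.asarray(self.cycle_boundaries, float).reshape(-1, 2)
        self.per_cycle_ipi = np.asarray(self.per_cycle_ipi, float)
        flat = self.cycle_boundaries.ravel()
        if len(flat) > 1 and not np.all(np.diff(flat) > 0):
            raise ValueError("cycle boundaries must strictly increase and alternate")

    @property
    def insp_starts(self) -> np.ndarray:
        return self.cycle_boundaries[:, 0]

    @property
    def exp_starts(self) -> np.ndarray:
        return self.cycle_boundaries[:, 1]

    @property
    def end(self) -> float:
        """Time at which the last cycle completes."""
        if len(self.per_cycle_ipi) == 0:
            return 0.0
        return float(self.insp_starts[-1] + self.per_cycle_ipi[-1])

    def insp_durations(self) -> np.ndarray:
        return self.exp_starts - self.insp_starts

    def exp_durations(self) -> np.ndarray:
        return self.insp_starts + self.per_cycle_ipi - self.exp_starts

    def to_dict(self) -> dict:
        return {"cycle_boundaries": self.cycle_boundaries.tolist(),
                "per_cycle_ipi": self.per_cycle_ipi.tolist(),
                "lick_onsets": self.lick_onsets.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(np.asarray(d["cycle_boundaries"]),
                   np.asarray(d["per_cycle_ipi"]),
                   np.asarray(d["lick_onsets"]))


def generate_cycle_train(profile: BreathingProfile,
                         schedule: SessionSchedule | None,
                         duration: float,
                         seed: int) -> GroundTruth:
    """Draw a breath-cycle train.

    Successive inspiration-start intervals are independent gamma draws with
    mean equal to the effective IPI and coefficient of variation
    ``profile.ipi_cv``, truncated below at 0.3 s (resampled).  During music
    blocks the effective IPI is ``mean_ipi * music_ipi_factor``.  Within a
    cycle of length IPI, inspiration lasts ``IPI * r / (1 + r)`` and
    expiration ``IPI / (1 + r)`` where ``r`` is the I/E ratio.  Only cycles
    that complete before ``duration`` are emitted.
    """
    min_dur = 3 * profile.mean_ipi
    if not duration > min_dur:
        raise ValueError(
            f"duration must exceed 3 * mean_ipi = {min_dur:g} s, got {duration:g} s")
    rng = np.random.default_rng(seed)
    r = profile.ie_ratio
    shape = 1.0 / profile.ipi_cv**2 if profile.ipi_cv > 0 else None

    boundaries: list[tuple[float, float]] = []
    ipis: list[float] = []
    t = 0.0
    while True:
        mean = profile.mean_ipi
        if schedule is not None:
            i = schedule.block_at(t)
            if i is not None and schedule.blocks[i].kind == "music":
                mean *= profile.music_ipi_factor
        if shape is None:
            ipi = mean
        else:
            ipi = float(rng.gamma(shape, mean / shape))
            while ipi < MIN_IPI_S:
                ipi = float(rng.gamma(shape, mean / shape))
        if t + ipi > duration:
            break
        insp_dur = ipi * r / (1.0 + r)
        boundaries.append((t, t + insp_dur))
        ipis.append(ipi)
        t += ipi
    return GroundTruth(np.asarray(boundaries), np.asarray(ipis))


def respiratory_phase(truth: GroundTruth, t: np.ndarray) -> np.ndarray:
    """Smooth respiratory phase theta(t): 0 at each inspiration start
    (minimal chest volume, warmest nasal air), 0.5 at each expiration
    start, advancing by 1 per breath.

    The phase rate is a per-half-phase quadratic chosen so that theta
    passes through the truth boundaries exactly AND theta' is continuous
    across them.  Rendering channels as cosines of this phase gives
    waveforms whose extrema fall exactly on the truth boundaries and whose
    curvature is equal on both sides of every extremum — no kink for a
    symmetric smoothing kernel to bias.  Outside the cycle train the phase
    is extrapolated linearly at the edge rate.
    """
    n = len(truth.per_cycle_ipi)
    if n == 0:
        return np.zeros_like(t)
    # half-phase boundaries: insp_0, exp_0, insp_1, ..., exp_{n-1}, end
    bounds = np.empty(2 * n + 1)
    bounds[0:-1:2] = truth.insp_starts
    bounds[1::2] = truth.exp_starts
    bounds[-1] = truth.end
    theta_b = 0.5 * np.arange(2 * n + 1)
    dur = np.diff(bounds)                       # half-phase durations
    m = 0.5 / dur                               # mean rate per half-phase
    rate = np.empty(2 * n + 1)                  # boundary rates, C1 phase
    rate[0] = m[0]
    rate[-1] = m[-1]
    rate[1:-1] = 0.5 * (m[:-1] + m[1:])
    r0, r1 = rate[:-1], rate[1:]
    # theta'(s) = r0 + b s + c s^2 with theta'(T) = r1 and integral 0.5
    c = 3.0 * (r0 + r1) / dur**2 - 3.0 / dur**3
    b = (r1 - r0) / dur - c * dur

    j = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, 2 * n - 1)
    s = t - bounds[j]
    theta = theta_b[j] + rate[j] * s + b[j] * s**2 / 2.0 + c[j] * s**3 / 3.0
    before = t < bounds[0]
    after = t >= bounds[-1]
    theta[before] = rate[0] * (t[before] - bounds[0])
    theta[after] = theta_b[-1] + rate[-1] * (t[after] - bounds[-1])
    return theta


def _diameter_waveform(truth: GroundTruth, amplitude: float,
                       t: np.ndarray) -> np.ndarray:
    """Chest diameter: a phase-warped cosine rising over inspiration and
    falling over expiration, peaking exactly at inspiration end."""
    if len(truth.per_cycle_ipi) == 0 or amplitude == 0:
        return np.zeros_like(t)
    theta = respiratory_phase(truth, t)
    return amplitude * 0.5 * (1.0 - np.cos(2 * np.pi * theta))


def _tustin_derivative(d: np.ndarray, fs: float) -> np.ndarray:
    """Trapezoidal-rule discrete differentiator.

    Solves (m[i] + m[i-1]) / (2 fs) = d[i] - d[i-1] with m[0] = 0, so that
    cumulative trapezoidal integration inverts it exactly (to round-off).
    Differs from a central difference only by a tiny Nyquist ripple.
    """
    delta = np.diff(d, prepend=d[0])
    sign = np.where(np.arange(len(d)) % 2 == 0, 1.0, -1.0)
    # m[i] = 2 fs * sum_{j<=i} (-1)^(i-j) delta[j]  with delta[0] = 0
    return 2.0 * fs * sign * np.cumsum(sign * delta)


def render_chest_channels(truth: GroundTruth, amplitude: float, fs: float,
                          noise_sd: float, seed: int,
                          duration: float | None = None,
                          ) -> tuple[SampledTrace, SampledTrace]:
    """Chest diameter and chest-band movement channels.

    The diameter is a smooth raised-cosine waveform per cycle (rising over
    inspiration, falling over expiration, peak at inspiration end).  The
    movement channel is the finite-difference derivative of the noiseless
    diameter — discretized with the trapezoidal rule so that cumulative
    trapezoidal integration is its exact inverse — plus white noise.
    Independent white noise of the same standard deviation is added to the
    diameter channel when ``noise_sd > 0``.
    """
    if fs < 20:
        raise ValueError(f"fs must be >= 20 Hz for chest rendering, got {fs} Hz")
    if duration is None:
        duration = truth.end
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    d = _diameter_waveform(truth, amplitude, t)
    m = _tustin_derivative(d, fs)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        m = m + rng.normal(0.0, noise_sd, size=n)
        d = d + rng.normal(0.0, noise_sd, size=n)
    diameter = SampledTrace(d, fs=fs, units="au", label="chest_diameter")
    movement = SampledTrace(m, fs=fs, units="au/s", label="chest_movement")
    return diameter, movement


def first_order_lag(x: np.ndarray, tau: float, fs: float) -> np.ndarray:
    """First-order low-pass y' = (x - y) / tau, discretized exactly for
    piecewise-linear input (first-order hold), initialized at y[0] = x[0].

    Exactness for piecewise-linear drive means the filter adds no spurious
    sampling delay: a sinusoid at frequency f comes out with the analytic
    phase lag arctan(2 pi f tau) up to O(h^2).
    """
    x = np.asarray(x, dtype=float)
    if tau <= 0:
        return x.copy()
    h = 1.0 / fs
    a = np.exp(-h / tau)
    c = tau * fs * (1.0 - a)
    # y[i] = a y[i-1] + (1 - c) x[i] + (c - a) x[i-1]
    b = np.array([1.0 - c, c - a])
    aa = np.array([1.0, -a])
    zi = lfilter_zi(b, aa) * x[0]  # start in steady state at x[0]
    y, _ = lfilter(b, aa, x, zi=zi)
    return y


def _airflow_waveform(truth: GroundTruth, ambient: float, delta: float,
                      t: np.ndarray) -> np.ndarray:
    """Idealized airflow temperature at the probe: a phase-warped cosine
    cooling from (ambient + delta) toward ambient across inspiration and
    warming back across expiration.  Peaks fall exactly on inspiration
    starts, troughs exactly on expiration starts."""
    if len(truth.per_cycle_ipi) == 0 or delta == 0:
        return np.full_like(t, ambient)
    theta = respiratory_phase(truth, t)
    return ambient + delta * 0.5 * (1.0 + np.cos(2 * np.pi * theta))


def render_nasal_temperature(truth: GroundTruth, sensor: SensorModel,
                             profile: BreathingProfile, fs: float, seed: int,
                             duration: float | None = None) -> SampledTrace:
    """Nasal-air temperature channel.

    The idealized airflow-temperature waveform is (a) shifted by the
    transport delay (intercept + per-kg slope times body weight),
    (b) attenuated by the position gain and smeared by the position mixing
    lag, (c) filtered by the sensor's first-order lag with time constant
    tau, and (d) corrupted with Gaussian noise.  Output extrema therefore
    lag the truth phase boundaries by an amount that grows with tau, with
    body weight, and with outward probe position.
    """
    if fs < 20:
        raise ValueError(f"fs must be >= 20 Hz for temperature rendering, got {fs} Hz")
    if duration is None:
        duration = truth.end
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    delay = sensor.transport_delay(profile.body_weight)
    delta = (sensor.expired_temp - sensor.ambient_temp) * sensor.gain
    # evaluate the analytic drive at t - delay: exact time shift, no resampling
    x = _airflow_waveform(truth, sensor.ambient_temp, delta, t - delay)
    x = first_order_lag(x, sensor.mixing_tau, fs)
    y = first_order_lag(x, sensor.time_constant, fs)
    rng = np.random.default_rng(seed)
    if sensor.noise_sd > 0:
        y = y + rng.normal(0.0, sensor.noise_sd, size=n)
    return SampledTrace(y, fs=fs, units="degC", label="nasal_temperature")


def render_lick_channel(schedule: SessionSchedule, licks_per_reward: int,
                        fs: float, seed: int,
                        duration: float | None = None,
                        lick_rate_hz: float = 4.0,
                        amplitude: float = 1.0,
                        noise_sd: float = 0.05,
                        ) -> tuple[SampledTrace, np.ndarray]:
    """Lick-vibration channel driven by reward events.

    Each reward spawns a burst of ``licks_per_reward`` licks (default burst
    rate ~4 Hz with jitter); each lick is rendered as a damped
    high-frequency transient on a Gaussian noise floor.  The exact onset
    times are returned alongside the trace.  Bursts are clipped at the end
    of their parent block so every onset stays inside a stimulus block.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz for lick rendering, got {fs} Hz")
    if duration is None:
        duration = schedule.end + 5.0
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    v = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    onsets: list[float] = []
    for reward in schedule.reward_times:
        i_block = schedule.block_at(reward)
        block_end = schedule.blocks[i_block].end if i_block is not None else duration
        t_on = reward
        for _ in range(licks_per_reward):
            t_on += abs(rng.normal(1.0 / lick_rate_hz, 0.03))
            if t_on >= min(block_end, duration):
                break
            onsets.append(t_on)

    # damped oscillatory transient; carrier kept below Nyquist
    carrier = min(80.0, 0.35 * fs)
    span = int(round(0.08 * fs))
    tt = np.arange(span) / fs
    kernel = amplitude * np.exp(-tt / 0.02) * np.sin(2 * np.pi * carrier * tt)
    for t_on in onsets:
        i0 = int(round(t_on * fs))
        i1 = min(i0 + span, n)
        if i0 < n:
            v[i0:i1] += kernel[: i1 - i0]
    onsets_arr = np.asarray(sorted(onsets))
    return SampledTrace(v, fs=fs, units="au", label="lick_vibration"), onsets_arr


@dataclass
class SessionBundle:
    """All channels of one simulated session plus schedule and truth."""

    temperature: SampledTrace
    chest_diameter: SampledTrace | None
    chest_movement: SampledTrace | None
    lick: SampledTrace | None
    schedule: SessionSchedule
    truth: GroundTruth | None
    config: dict = field(default_factory=dict)


def simulate_session(profile: BreathingProfile | None = None,
                     sensor: SensorModel | None = None,
                     schedule: SessionSchedule | None = None,
                     duration: float | None = None,
                     fs: float = DEFAULT_FS_HZ,
                     seed: int = 0,
                     chest_noise_sd: float = 0.02,
                     licks_per_reward: int = 8,
                     include_chest: bool = True,
                     include_lick: bool = True) -> SessionBundle:
    """Generate a full multi-channel session.

    Child seeds for the cycle train, each channel's noise, and the lick
    bursts are spawned deterministically from ``seed``.  If no schedule is
    given the default six-block music/noise protocol is built from the same
    seed; ``duration`` defaults to the schedule end plus a 10 s tail.
    """
    from .schedule import build_default_schedule

    profile = profile or BreathingProfile()
    sensor = sensor or SensorModel()
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    if schedule is None:
        schedule = build_default_schedule(child[0])
    if duration is None:
        duration = schedule.end + 10.0

    truth = generate_cycle_train(profile, schedule, duration, child[1])
    temperature = render_nasal_temperature(truth, sensor, profile, fs, child[2],
                                           duration=duration)
    diameter = movement = lick = None
    if include_chest:
        diameter, movement = render_chest_channels(
            truth, profile.amplitude_chest, fs, chest_noise_sd, child[3],
            duration=duration)
    if include_lick and licks_per_reward > 0 and len(schedule.reward_times):
        lick, lick_onsets = render_lick_channel(schedule, licks_per_reward, fs,
                                                child[4], duration=duration)
        truth.lick_onsets = lick_onsets
    config = {
        "profile": vars(profile).copy(),
        "sensor": {k: (dict(v) if isinstance(v, dict) else v)
                   for k, v in vars(sensor).items()},
        "fs": fs, "duration": duration, "seed": seed,
        "chest_noise_sd": chest_noise_sd, "licks_per_reward": licks_per_reward,
    }
    return SessionBundle(temperature=temperature, chest_diameter=diameter,
                         chest_movement=movement, lick=lick,
                         schedule=schedule, truth=truth, config=config)
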