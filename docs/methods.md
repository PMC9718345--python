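# Methods

This note records the model the package implements, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model

**Breath train.** Successive inspiration-start intervals are independent
gamma draws with mean equal to the effective inter-peak interval (IPI) and
a configurable coefficient of variation, truncated below at 0.3 s by
resampling. A gamma was chosen over a normal for positivity and over a
log-normal for its direct mean/CV parametrization; breathing-interval
distributions in the literature are unimodal and right-skewed, which the
gamma captures. Within a breath of length IPI, inspiration lasts
IPI·r/(1+r) and expiration IPI/(1+r), where r is the
inspiration/expiration (I/E) duration ratio. During music blocks the mean
IPI is multiplied by `music_ipi_factor` (default 0.85), emulating the
acceleration of breathing under rhythmic auditory stimulation; white-noise
blocks and inter-block gaps use the resting mean.

**Respiratory phase and channel waveforms.** Both analog channels are
rendered as cosines of a common respiratory phase θ(t): chest diameter
∝ (1 − cos 2πθ)/2 (minimal at inspiration start, maximal at inspiration
end) and airflow temperature at the probe as
ambient + Δ·(1 + cos 2πθ)/2 (warmest at inspiration start, coolest at
expiration start), with Δ = (expired − ambient) × position gain. The phase
advances by 0.5 per half-phase through the truth boundaries exactly, with a
per-half-phase quadratic rate chosen so that θ' is continuous across
boundaries. This C¹ phase (hence C² waveforms) matters: a waveform with a
curvature kink at its extrema is biased by any symmetric smoothing kernel —
the extremum shifts toward the flatter side — which would contaminate the
timing and I/E estimates with an artefact of the generator rather than a
property of the measurement. Real airflow and chest signals are smooth at
phase reversals, so curvature continuity is also the more realistic choice.
The phase is extrapolated linearly beyond the first/last cycle instead of
clamping, so the trace has no edge discontinuities.

**Sensor physics.** The temperature drive is (a) shifted by the transport
delay `intercept + per_kg × body_weight` (defaults 0 s and 0.01 s/kg —
free parameters; only the qualitative trend, heavier animal → longer
delay, is anchored), (b) attenuated by the probe-position gain (defaults
−5 mm: 0.5, 0 mm: 0.75, +5 mm: 1.0 — expired air mixes with ambient air
outside the nostril) and smeared by a position-dependent *mixing* lag
(first-order, defaults 80/40/0 ms outside/entrance/inside), and
(c) filtered by the sensor's own first-order lag with time constant
τ = 100 ms, then corrupted with white Gaussian noise. The mixing lag is
the package's mechanism for the observed dependence of delay on probe
position: a pure amplitude gain through a linear time-invariant filter
cannot move peak times, so attenuation alone cannot reproduce the
delay-shrinks-inward trend; turbulent mixing outside the nostril both
attenuates *and* smears the waveform, which the extra lag captures with
one parameter per position.

**Discretization of the first-order lag.** The lag is discretized with the
exponential integrator that is exact for piecewise-linear input
(first-order hold). The common zero-order-hold recursion is "exact" for
step inputs but adds a spurious half-sample (5 ms at 100 Hz) delay for
smooth drives — intolerable when the quantity under study is itself a
50–150 ms delay. With the FOH form, a sinusoid at frequency f emerges with
peak delay arctan(2πfτ)/(2πf) to within a sample at 100 Hz (verified in
the suite), and the delay of a locally-quadratic extremum approaches τ
from below. This is why the simulated thermosensor, at the inside position
with no transport delay, trails the chest band by ~90–98 ms at resting
breathing rates (0.4–0.5 Hz): always inside the 0–100 ms window, since
arctan(ωτ)/ω < τ for every ω.

**Chest movement channel.** The chest-band sensor reports the derivative
of chest diameter. The generator emits movement as the trapezoidal-rule
(Tustin) discrete derivative of the noiseless diameter — the exact inverse
of cumulative trapezoidal integration — plus white noise. An ordinary
central difference would leave the round trip (differentiate, then
integrate) with ~1e-4 relative error at 100 Hz; the Tustin form makes the
integration stage's correctness testable to round-off, and differs from
the central difference only by a Nyquist-frequency ripple of ~1e-4 of the
amplitude, far below the noise floor.

**Licks and schedule.** The default session is six 180 s auditory blocks
(three music pieces at 212/113/85 beats/min, three white-noise controls)
in seeded shuffled order with 60 s gaps (total 1380 s), six 0.2 ml rewards
per block drawn uniformly with ≥ 10 s spacing. Each reward triggers a
burst of up to eight licks at ~4 Hz with Gaussian jitter, rendered as
damped transients (carrier capped below Nyquist) on a Gaussian noise
floor. Only onset times matter downstream; the burst microstructure is
plumbing.

## Analysis defaults

| parameter | default | notes |
|---|---|---|
| smoothing window | 0.15 s | moving average, forced odd length (no phase shift) |
| prominence floor | 0.3 × robust amplitude | robust amplitude = p90 − p10 of smoothed trace |
| refractory | 0.6 s | same-kind extremum spacing; < shortest plausible breath |
| IPI anchor | temperature peaks | troughs selectable |
| integration detrend | 30 s running mean | suppresses chest integration drift |
| matching tolerance | 0.45 × median IPI | forbids cross-cycle pairing |
| lick threshold | median + 5σ (robust) | σ = 1.4826 × MAD of the baseline-subtracted trace |
| lick refractory | 0.1 s | |
| triggered-average window | ±2 s | baseline = pre-event mean per segment |
| sampling rate | 100 Hz | acquisition rate of the source data unstated |

Extremum times are refined by a parabola through three samples of the
smoothed trace; the delays of interest are of the order of one sample at
100 Hz, so integer-sample times would quantize them. Alternation of peaks
and troughs is enforced by discarding the lower-prominence of two
consecutive same-kind extrema (ties drop the later). Edge cycles are
dropped rather than extrapolated. The I/E ratio is the mean of per-cycle
ratios, not the ratio of summed durations, so that a per-cycle SD is
defined.

The lick threshold uses a robust SD (1.4826 × MAD of the raw
baseline-subtracted signal) rather than the MAD of the rectified signal:
the rectified MAD of a Gaussian floor is so small that a 5×-MAD threshold
sits near 2σ and fires constantly on noise, while 5 robust SD puts the
false-positive rate well under one event per minute (verified by
Monte-Carlo in the suite). A manual threshold override mirrors the field's
per-day manual adjustment.

**Event matching.** Temperature *peaks* are matched to chest-diameter
*troughs* by default: both mark the same physiological transition
(expiration end / inspiration start). The literal peak-to-peak convention
used in field reports compares physiologically different transitions; it
is available via `peak_to_peak=True` (`--peak-to-peak` on the CLI) and
yields the same delays for near-symmetric breathing. Matching is greedy on
increasing absolute delay within ± tolerance, each event used once, ties
toward the earlier chest event; on breathing-like trains with tolerance
below the cycle spacing this coincides with the optimal assignment
(checked exhaustively in the suite). Delay sign is thermosensor minus
chest, positive when the thermosensor lags.

**Block contrasts.** An IPI is assigned to a stimulus block only when both
bounding anchor events fall inside that block; straddling and gap
intervals are discarded (and counted, so assignment is conservative). The
music-vs-noise contrast pools the three music blocks against the pooled
noise blocks (classical pooled-variance unpaired t by default, Welch by
flag); the among-tempo contrast is a one-way ANOVA over the three music
blocks. Raw p-values are reported; Holm correction is available by flag.
An optional `exclude_after_reward` window drops IPIs near rewards (off by
default). Statistics and degrees of freedom are computed from the
classical formulas; t and F tail probabilities use `scipy.special`'s
vetted distribution functions, and scipy.stats serves only as an
independent cross-check in the tests. Multi-session paired designs are
supported by `ttest_paired` on session means.

**Modulation index.** The lick-triggered average baseline-subtracts each
±2 s segment by its pre-event mean; the modulation index is the maximum
absolute post-event mean deviation divided by the robust respiratory
amplitude of the whole trace. Under independence the index is small
because unlocked respiratory cycles average out (≈ amplitude/√n_events);
significance is judged against a Monte-Carlo null of uniformly random
event sets of the same size. Because an uncoupled session's index is
itself a draw from that null, the expected below-95th-percentile rate is
exactly 95%, and the suite checks it over 100 sessions so binomial noise
stays clear of the 90% acceptance bound.

## Problem sizes in the suite

The suite favours many short sessions over few long ones: stimulus-free
recovery sessions are 240–600 s, calibration batches use 20–100 seeds, the
t-test null uses 2000 replicates, and oracle comparisons use 150–200
random instances of ≤ 2000 samples or ≤ 12 events. These sizes give the
estimators enough events (a 300 s session holds ~135 breaths) for the
stated tolerances while keeping the whole suite under half a minute.

## Known estimator properties and limitations

- **I/E upward bias.** The peak-based I/E estimate is biased slightly high
  (~+0.015 noise-free, ~+0.03 at noise of 10% of the excursion): extremum
  jitter enters the denominator of the per-cycle ratio (Jensen), and noise
  wander preferentially moves detected extrema toward the flatter side of
  the waveform. The acceptance tolerance (±0.05) covers this; users who
  need unbiased phase durations should increase smoothing or average
  ratios over more cycles.
- The generator emulates quasi-stationary breathing; it has no sighs,
  apneas, sniffing bouts, pants, movement artefacts, sensor drift, or
  coupling between licking and respiration. Passing recovery tests
  therefore demonstrates correctness of the analysis under the modelled
  physics, not robustness to every artefact of real recordings.
- Breathing-frequency modulation by music is modelled as an instantaneous
  multiplicative IPI factor with no habituation or carry-over into the
  silent gaps.
- The transport-delay and mixing parameters are anchored only by
  qualitative trends (delay grows with weight and outward position), not
  by measured values; recovering their defaults from simulation validates
  the estimator, not the physiology.
- The delay regression treats per-session mean delays as independent
  points; no per-animal random effects are modelled.
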