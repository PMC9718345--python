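# thermoresp

Respiration monitoring of behaving macaque monkeys from **nasal-air
temperature**, as a tested, reusable analysis pipeline.

Macaques remove chest bands and face masks with their hands, so the standard
noninvasive respiration monitors fail in awake animals. A thin thermosensor
probe placed at the nostril entrance solves this: nasal air stays near
ambient temperature while cool air is drawn in (inspiration) and warms toward
body temperature while air is expired, so the temperature trace oscillates
with the breathing cycle. This package implements the full analysis around
that measurement for physiologists and systems neuroscientists who want
breathing as a readout of internal state:

- **cycle extraction** — smoothing, prominence/refractory peak-trough
  detection with sub-sample (parabolic) timing, segmentation into breaths,
  inter-peak intervals (IPI) and inspiration/expiration (I/E) ratios;
- **thermosensor-vs-chest-band delay** — greedy nearest-neighbour matching
  of same-phase events across modalities, per-pair delays, and regressions
  of delay on probe position or body weight;
- **lick-artifact assessment** — vibration-threshold lick detection and
  lick-triggered averaging of the temperature signal with a Monte-Carlo
  null for the modulation index;
- **stimulus contrasts** — IPIs split by music / white-noise block, pooled
  music-vs-noise unpaired t test and among-tempo one-way ANOVA (all test
  statistics implemented from the classical formulas);
- **a ground-truthed synthetic-data generator** that emulates the recording
  physics (gamma-distributed breath intervals, chest diameter and its
  derivative, a first-order thermosensor lag with 100 ms time constant,
  position-dependent attenuation and weight-dependent transport delay, lick
  bursts after rewards, and the six-block music/noise session protocol), so
  every stage is testable without any recordings.

## Model sketch

Breath $k$ has period $\mathrm{IPI}_k \sim \Gamma(\mu_\text{eff}, \mathrm{CV})$
(truncated at 0.3 s), split into inspiration
$\mathrm{IPI}_k\, r/(1{+}r)$ and expiration $\mathrm{IPI}_k/(1{+}r)$ with
I/E ratio $r$; during music blocks $\mu_\text{eff} = \mu \cdot
f_\text{music}$ with $f_\text{music} \le 1$. The airflow temperature at the
probe is a phase-locked waveform between ambient $T_a$ and
$T_a + (T_e - T_a)\,g(\text{position})$, delayed by the transport time
$d_0 + d_1 w$ (body weight $w$), and filtered by the sensor's first-order
lag $\tau \dot y = x - y$ with $\tau = 0.1$ s. For a sinusoidal drive at
frequency $f$ the lag delays peaks by $\arctan(2\pi f\tau)/(2\pi f)$, which
is why the thermosensor trails the chest band by tens of milliseconds at
resting breathing rates.

## Worked example

```sh
thermoresp simulate --seed 1 --out session/
thermoresp analyze --bundle session/ --out report.json
thermoresp compare --thermo session/nasal_temperature.csv \
    --chest session/chest_movement.csv --chest-movement --out compare.json
```

or equivalently in Python:

```python
import thermoresp as tr

bundle = tr.simulate_session(seed=1)     # full 1380 s music/noise session
report = tr.analyze_session(bundle)
```

For seed 1 the report contains (abridged):

```
overall:        678 cycles, mean IPI 2.045 s (SD 0.335), I/E ratio 0.897
delay stage:    679 matched pairs, mean thermo-chest delay 152.6 ms
lick stage:     274 licks detected, modulation index 0.016
music vs noise: t = -13.44, df = 531, p = 1.2e-35, mean diff -0.327 s
among music:    F = 0.90, df = (2, 286), p = 0.41
```

Reading: breathing runs near 0.49 Hz with inspiration 0.9x the length of
expiration; the thermosensor trails the chest band by ~153 ms (100 ms
first-order sensor lag plus a 60 ms transport delay for this 6 kg animal);
licking leaves the temperature signal essentially unmodulated (index 0.016
of the respiratory amplitude); IPIs during music are significantly shorter
than during white noise (breathing accelerates), with no detectable
difference among the three music tempos.

## Layout

```
src/thermoresp/
  trace.py        SampledTrace container + CSV dialect
  schedule.py     stimulus blocks, rewards, default session protocol
  synthetic.py    ground-truthed session generator (physics above)
  respiration.py  extrema detection, cycle segmentation, IPI/IE summaries
  delay.py        cross-modal event matching and delay regression
  events.py       lick detection and triggered averaging
  stats.py        t tests / ANOVA / Pearson from formulas
  pipeline.py     end-to-end session analysis and JSON report
  cli.py          thermoresp simulate | analyze | compare
docs/methods.md   modelling assumptions, defaults, numerics, limitations
```
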