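# rhythmkit

Circadian rest-activity rhythm analysis from two everyday data sources:
**smartphone interaction logs** and **wrist actigraphy**. The package is
aimed at digital-phenotyping and sleep researchers who want per-participant
sleep episodes and nonparametric circadian indicators without dedicated
laboratory instrumentation.

## What it computes

**The app-count method.** Timestamped smartphone events (screen on/off,
notifications, app use) are counted per minute and summed into
nonoverlapping 5-minute epochs — 288 per day — mirroring how actigraphy
turns wrist movement into activity counts. The epoch series is band-pass
filtered to the near-24-hour band (16–24 h periods), putative sleep is
placed at the half-cycle around the filtered signal's nadir, and within
that window:

* sleep **onset** = start of the first run of ≥ 8 consecutive zero-count
  epochs,
* **wake** = start of the first run of ≥ 6 consecutive nonzero epochs
  after onset,
* **WASO** = 5 min × nonzero epochs between onset and wake,
* **TST** = (wake − onset) − WASO.

**Actigraphy.** Raw 30 Hz tri-axial acceleration → Euclidean norm →
0.5–3 Hz band-pass → rectified, dead-banded, integrated over 2-s windows
and averaged per minute into activity counts. Sustained zero-count runs
are flagged off-wrist; days with > 6 h off-wrist are discarded. Sleep/wake
is scored per minute with the Cole–Kripke weighted sum
D = 0.001·(106 A₋₄ + 54 A₋₃ + 58 A₋₂ + 76 A₋₁ + 230 A₀ + 74 A₊₁ + 67 A₊₂),
D < 1 ⇒ sleep, and the longest consolidated sleep block per night becomes
the episode.

**Circadian indicators** (both modalities, hourly-binned, p = 24):

* interdaily stability IS = N·Σₕ(x̄ₕ − x̄)² / (p·Σᵢ(xᵢ − x̄)²) ∈ [0, 1],
* intradaily variability IV = N·Σᵢ(xᵢ − xᵢ₋₁)² / ((N−1)·Σᵢ(xᵢ − x̄)²),
* M10/L5 — mean level and onset of the most-active 10-h and least-active
  5-h windows,
* social jet lag = |mean free-day midsleep − mean workday midsleep|.

**Planning statistics.** Cohen's f, noncentral-F power for the balanced
k-group omnibus one-way ANOVA (λ = f²·N), the smallest balanced N reaching
a target power, and a standardized multivariable OLS reporter.

**Synthetic paired recordings.** `simulate_pair` generates a smartphone
event log and an actigraphy count series sharing one ground-truth sleep
schedule (phase jitter, night awakenings with phone-use bursts, weekend
delay), so every pipeline stage has a parameter-recovery test with no
participant data.

## Worked example

```python
from rhythmkit import (
    SimulationConfig, simulate_pair, events_to_appcounts,
    app_sleep_episodes, actigraphy_sleep_episodes, summarize_participant,
)

cfg = SimulationConfig(n_days=28, seed=7, weekend_phase_delay=1.0)
rec = simulate_pair(cfg)

appcounts = events_to_appcounts(rec.events)
app_row = summarize_participant(
    "P01", "app", app_sleep_episodes(appcounts), appcounts)
acti_row = summarize_participant(
    "P01", "actigraphy", actigraphy_sleep_episodes(rec.acti_counts),
    rec.acti_counts)

for row in (app_row, acti_row):
    print(f"{row.source:>10}: IS={row.IS:.3f} IV={row.IV:.3f} "
          f"midpoint={row.mean_midpoint:.2f} TST={row.mean_tst:.0f} min "
          f"WASO={row.mean_waso:.1f} min SJL={row.social_jetlag:.2f} h "
          f"(n_days={row.n_days})")
```

prints

```
       app: IS=0.797 IV=0.386 midpoint=27.30 TST=419 min WASO=15.5 min SJL=0.75 h (n_days=29)
actigraphy: IS=0.821 IV=0.347 midpoint=27.38 TST=419 min WASO=19.9 min SJL=0.96 h (n_days=29)
```

The participant was simulated with a mean sleep midpoint of 03:15
(27.25 in decimal hours past the reference midnight, where 24 + h means
h o'clock the next morning) and a 1-hour weekend delay. Both modalities
recover the midpoint within a few minutes of each other; IS near 0.8
reflects the moderate day-to-day phase jitter (0.5 h SD); app WASO runs a
little shorter here than the actigraphy value because only nonzero-count
epochs inside the sleep window count toward it. A command-line interface
(`rhythmkit simulate|appsleep|actisleep|metrics|power|regress`) wraps the
same functions.

## Layout

| module | contents |
| --- | --- |
| `rhythmkit.timeseries` | `EventLog`, `EpochSeries`, day segmentation, hourly profiles, delimited-text I/O |
| `rhythmkit.smartphone` | app-counts, 16–24 h cycle extraction, run-length sleep detection |
| `rhythmkit.actigraphy` | count derivation, off-wrist/day exclusion, Cole–Kripke scoring, nightly episodes |
| `rhythmkit.metrics` | IS, IV, M10/L5, social jet lag, participant aggregation |
| `rhythmkit.simulate` | paired synthetic recordings with ground truth |
| `rhythmkit.stats` | Cohen's f, noncentral-F power, balanced sample size, standardized OLS |
| `rhythmkit.cli` | `rhythmkit` command group |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
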