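# Methods

## Detection model

The detector treats airway pressure as the trigger channel and flow as the
measurement channel. Let `p(t)` be pressure (cmH₂O), `q(t)` flow (L/min,
positive toward the lung), both uniformly sampled at rate `fs` (256 Hz for
the field devices).

**Smoothing.** `s(t)` is the trailing (causal) moving average of `|q|` over
the window `(t − w, t]` with `w = 1 s`. At the record start the partial
window is averaged over the available samples, so a constant signal maps to
a constant. A trailing window was chosen over a centered one because the
end-of-breath test must not look at future samples, and because it makes
the partial-window rule at the record start unambiguous.

**Anchor.** A breath is anchored at the earliest sample where `p` crosses
the threshold A upward — a *fresh* crossing: the previous sample is below A,
or the sample is the first of the record — and `p ≥ A` holds at every sample
of the closed window `[t_a, t_a + B]`. Fresh-crossing semantics mean a
single long plateau can never yield two breaths. Crossings too close to the
record end to evaluate the sustain window are not anchors.

**Start.** `start = max(previous breath's extended end, t_a − C)`, clipped
at the record start.

**Baseline.** `baseline = min s(t)` over `[start, start + 6 s]`, clipped at
the record end. The baseline is computed on the *smoothed* series — the same
series the threshold D is applied to — so threshold and baseline are
commensurate. Restricting the window to the first 6 s of the breath keeps
later compression pauses (synchronous regimes) from being mistaken for the
quiescent floor. The baseline feeds *only* the end condition; volumes
integrate raw flow.

**End.** The active phase ends at the earliest sample
`t ≥ max(t_a + B, start + 0.3 s)` with `s(t) − baseline < D` **and**
`p(t) < A` (strict inequalities; ties count as still active). The 0.3-s
minimum duration is enforced by forbidding the search from terminating
earlier, not by discarding short breaths — with small grid values of B a
true breath could otherwise be dropped. If no sample qualifies, the breath
runs to the record end and is flagged *truncated* (kept in the breath
table; excluded from evaluation pairing). With the sentinel `D = −1` there
is no inactive phase: the active phase runs to the next anchor (or record
end, not flagged truncated, since in this mode the record end *is* the
defined end), and E is not applied.

**Extension.** `extended_end = min(end + E, record end, next anchor − one
sample)`. The last clip guarantees the extension can never swallow the next
breath's start. The anchor search for the next breath resumes at
`extended_end` (refractory rule), so event intervals are disjoint and
volume attribution is unambiguous.

## Per-breath measures

Over the half-open interval `[start, extended_end)` (the E-extension is
included deliberately, to capture the expiratory tail):

- inspiratory volume `= Σ max(q, 0) · dt / 60 · 1000` ml,
- expiratory volume `= |Σ min(q, 0)| · dt / 60 · 1000` ml,
- peak pressure `= max p`,
- leak fraction `= (insp − exp)/insp` (undefined when insp = 0).

Integration is rectangular (sum × dt); a trapezoidal rule would differ by
O(dt) and is not used. The instantaneous rate of breath *i* ≥ 2 is
`60/(start_i − start_{i−1})`; the first breath has none. etCO₂ is the
maximum of the CO₂ channel over `[start + delay, next start + delay)`
(record end standing in for the last breath's next start); the delay keeps
the final expired CO₂ from being credited to the following ventilation. No
published value exists for this delay; the default is **0.5 s** and it is
configurable — treat etCO₂ output as unvalidated.

## Tunable parameters

| name | unit | default (tuned) | optimized | grid |
|---|---|---|---|---|
| `pressure_threshold_A` | cmH₂O | 8 | 2 | 1, 2, 5, 8, 10 |
| `pressure_duration_B` | s | 0.3 | 0.3 | 0.1 … 0.5 |
| `ventilation_lead_C` | s | 0.3 | 0.1 | 0 … 0.5 |
| `abs_flow_threshold_D` | L/min | 5 | 1 | −1, 1, 5, 10 |
| `inactive_delay_E` | s | 0.2 | 0.2 | 0 … 0.3 |

Fixed constants: minimum duration 0.3 s, smoothing window 1 s, baseline
window 6 s, CO₂ delay 0.5 s. The "optimized" profile is the grid-search
argmin on clean bench data; the "tuned" profile raises A and D because
artefacts in clinical recordings are larger than on the bench, and is the
default.

## Calibration objective

For each run with known ventilator settings, every detected non-truncated
breath pairs its measures (inspiratory volume, expiratory volume, peak
pressure, and — when a set rate exists — instantaneous rate) with the run's
set values. Breaths missing relative to the expected count
`round(set_rate · duration/60)` contribute `(0, set)` pairs for the
volume/pressure measures; without this penalty a detector finding one
perfect breath per run would score zero. The penalty is switchable
(`include_missed=False`).

Per measure, the mean absolute deviation of its pairs (pooled over breaths
by default; per-run-first averaging is available) is divided by the sample
SD of that measure's *set* values across runs. Standardizing by set values
rather than measured values keeps the denominator independent of the
parameter vector under evaluation — a degenerate detector cannot shrink its
own yardstick. Measures whose set-value SD is zero or undefined are
excluded with a warning. The objective is the unweighted mean of the
standardized deviations; the exhaustive grid (2400 points by default) is
scored deterministically and ties break toward the smallest A, then B, C,
D, E (an arbitrary, documented order).

## Agreement statistics

Differences are `measured − set` per breath, summarized by median and
linear-interpolation quartiles (the convention is stated so results are
bit-reproducible). The percentage error is Bland–Altman:
`100·(measured − set)/((measured + set)/2)` per pair, median reported.
Printed summary tables built from medians cannot in general be reproduced
from one another (a median of per-pair percentages is not the percentage of
medians); this package standardizes on the per-pair definition. Lin's
concordance correlation coefficient uses population (1/n) moments,
`CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`; RMSE and the proportion of
breaths with |percentage error| < 10 % complete the summary. Runs with
unreliable reference expiratory measurements can be excluded from
expiratory pairing via the manifest's `exclude_exp` flag.

## Simulator

A single-compartment linear lung stands in for the physical test lung:
resistance R (cmH₂O/(L/s)), compliance C (ml/cmH₂O), passive time constant
τ = R·C/1000 s, PEEP 0 by default. Volume-controlled breaths deliver
constant flow `Q = VT/Ti` for the inspiratory time, giving airway pressure
`p = PEEP + R·Q + V/C`; pressure-controlled breaths hold `p` at the set
pressure, giving exponential inflow `V(t) → C·(P − PEEP)`. Expiration is
passive exponential decay; the sensor sees `(1 − leak)` of it (the leak is
a proportional per-breath volume loss, not a pressure-dependent orifice).
Flow samples are successive differences of the model volume divided by the
sample period, so integrating the waveform conserves volume exactly —
leak-free net flow over a breath cycle is zero to well under 1 ml.

Chest compressions displace `compression_volume` ml (default 40) through
the lung per cycle as a raised-cosine push with passive recoil — a biphasic,
zero-net flow oscillation at 110/min — plus the matching model pressure
oscillation `d/C + R·q_comp` (≈ 3 cmH₂O at the defaults, below the tuned
A = 8). Asynchronous mode runs compressions continuously; synchronous mode
alternates 30-compression blocks with pauses containing exactly two
insufflations, compressions resuming 2.5 s after the second insufflation's
inspiratory phase (when passive exhalation is complete for the demo lungs,
≥ 5τ). Ground truth (start, delivered inspiratory volume, expired volume
`(1 − leak)·insp`, peak pressure, set rate) comes from the model state,
never from the waveform. Gaussian sensor noise is optional and
deterministic given the seed; it defaults to zero so recovery checks are
exact. Ventilation begins 1 s into each recording so the first breath's
lead C is never clipped by the record edge.

The demo dataset is 37 two-minute runs — 20 without CPR (10 volume-, 10
pressure-controlled), 10 asynchronous, 7 synchronous — spanning tidal
volumes 177–612 ml, peak pressures ≈ 13–45 cmH₂O and rates 10–30/min.
Per-run R and C are set from the closed forms so that every delivered
breath satisfies the detectability preconditions of the tuned profile: the
pressure crossing of A occurs early enough to sustain B within the
inspiratory time, and the inter-breath trailing-window flow falls below D's
equivalent (≈ 83 ml moved per second). These are the bench conditions the
detector is specified for; runs violating them (e.g. a compliant lung at 30
breaths/min that never exhales to quiescence) are out of the detector's
stated operating regime.

**What the simulator does not emulate:** nonlinear airway resistance,
patient effort and spontaneous breaths, compression-depth variability and
operator drift, sensor drift/miscalibration, and CO₂ kinetics (the CO₂
channel is a fixed-amplitude expiratory plateau placeholder). Passing
recovery tests on simulated data therefore demonstrates correctness of the
detection logic under the stated artefact model, not clinical performance.

## Numerical conventions

- Seconds-to-samples conversions use an epsilon guard (1e-9) so exact
  multiples of the sample period land on the intended sample; closed
  windows use the floor of `sec·fs`, "first sample at or after" uses the
  ceiling.
- All threshold comparisons are strict; ties resolve toward "still active".
- Events are computed on the sample grid and carry both indices and times;
  sample *k* is at `start_time + k/fs`.
- The breath table is written with ≥ 6 significant digits and round-trips
  through its reader.

## Known limitations

- Prepending zeros to a recording is an exact time translation of all
  events only when the recording already starts with at least one
  smoothing window of quiet signal; otherwise the partial-window average at
  the record start differs from a zero-padded one. Shifting `start_time`
  is always an exact translation.
- Truncated trailing breaths are reported but excluded from evaluation
  pairing; their volumes are lower bounds.
- In the `D = −1` mode the minimum-duration guarantee does not apply (the
  next anchor may be arbitrarily close).
- The grid search is exhaustive and O(grid × samples); the default
  2400-point grid on long datasets is expensive — calibrate on reduced
  grids or shorter runs first.
- Reported problem sizes: the acceptance script and tests use the 37-run ×
  120-s demo dataset (≈ 978 breaths) at 256 Hz, 100 randomized ≤ 10-s
  recordings at 64 Hz for oracle equivalence, and an 8-point reduced grid
  for calibration self-consistency.
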