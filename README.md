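# ventwave

Per-breath ventilation parameters from pneumotachography waveforms recorded
during cardiopulmonary resuscitation (CPR).

Chest compressions drive oscillating, bidirectional airflow and pressure
spikes through the airway, so standard breath-detection logic applied to
flow/pressure waveforms recorded during CPR miscounts ventilations and
misestimates volumes. `ventwave` implements a detector built for this
setting — for resuscitation researchers analyzing pneumotachograph
recordings (flow in L/min, airway pressure in cmH₂O, optionally CO₂,
sampled at 256 Hz) from manual or mechanical ventilation during ongoing
compressions — together with the calibration, evaluation, and simulation
machinery needed to tune and validate it.

## The algorithm

A ventilation is detected from *pressure*, which compressions perturb far
less than flow. Five tunable thresholds define the geometry:

- **A** — pressure threshold (cmH₂O): a breath is anchored where airway
  pressure crosses A upward and stays ≥ A…
- **B** — pressure duration (s): …for at least B. Compression artefacts are
  small and brief, so they fail the A×B test; negative-pressure
  (spontaneous) efforts never reach it.
- **C** — ventilation lead (s): the insufflation is taken to begin C before
  the anchor, capturing flow that precedes the pressure rise.
- **D** — absolute-flow threshold (L/min): the breath's *active phase*
  (insufflation + detectable exsufflation) ends at the first instant where
  the trailing 1-s average of |flow|, minus a per-breath baseline, falls
  below D while pressure is back below A. The baseline is the minimum of
  the smoothed |flow| over the first 6 s of the breath: under continuous
  compressions absolute flow never rests at zero, and the baseline measures
  that floor. D = −1 disables the end condition (the breath runs to the
  next detection).
- **E** — inactive delay (s): the active phase is extended by E to capture
  the expiratory tail.

Per breath, the package reports inspiratory volume (∑ positive flow × dt),
expiratory volume (|∑ negative flow × dt|), peak pressure, instantaneous
rate (60 / inter-start interval), end-tidal CO₂ (windowed maximum with a
configurable delay), and leak fraction (insp − exp)/insp. A minimum
ventilation duration of 0.3 s prevents artefacts from splitting one breath
into several.

Two shipped profiles: `"tuned"` (A=8, B=0.3, C=0.3, D=5, E=0.2 — the
default, selected after review of clinical recordings) and `"optimized"`
(A=2, B=0.3, C=0.1, D=1, E=0.2 — the grid-search optimum on clean bench
data). `ventwave.grid_search` reproduces the calibration itself: it scores
every parameter combination by the average standardized absolute deviation
of the per-breath measures from the ventilator settings (each measure
standardized by the across-run spread of its set values; missed breaths
count as zero measurements).

## A worked example

`examples/detect_single_breath.py` builds one idealized square-wave breath
(flow +30 L/min for 1 s then −30 L/min for 1 s; pressure 20 cmH₂O for
1.2 s) and prints:

```
breaths detected:    1
start time:          0.7031 s   (anchor - lead C)
anchor time:         1.0000 s   (pressure crosses A=8 cmH2O)
active phase end:    3.8320 s   (smoothed |flow| < D=5 L/min)
extended end:        4.0312 s   (+ delay E=0.2 s)
inspiratory volume:  500.0 ml
expiratory volume:   500.0 ml
peak pressure:       20.0 cmH2O
leak fraction:       0.000   ((insp - exp) / insp)
```

Every number is hand-checkable: pressure crosses A = 8 at 1.0 s and holds
≥ 8 for 1.2 s > B; the start leads by C = 0.3 s; after the flow stops at
3 s the trailing 1-s average decays as 30·(4 − t) L/min, dropping below
D = 5 just after 3.833 s; each plateau moves 0.5 L/s × 1 s = 500 ml.

`examples/cpr_artefact_rejection.py` shows the CPR-specific behavior: the
same simulated run with and without asynchronous compressions at 110/min
yields the same 20 detected breaths, because the ~3 cmH₂O pressure
oscillation stays below A and the flow baseline (≈ 8 L/min under
compressions vs 0 without) absorbs the artefact's flow floor.

## Simulator

`ventwave.simulate` generates bench-style recordings from a
single-compartment lung (resistance R, compliance C) ventilated in
volume- or pressure-controlled mode, with optional asynchronous or
synchronous (30:2) compression artefacts, an adjustable leak, Gaussian
sensor noise, and per-breath ground truth recorded from the model state.
`demo_configs()` returns a 37-run, two-minute-per-run dataset (20 without
CPR, 10 asynchronous, 7 synchronous) spanning tidal volumes 177–612 ml,
peak pressures ~13–45 cmH₂O and rates 10–30/min.

## Command line

```bash
ventwave simulate --out data/                       # demo dataset
ventwave detect   --input data/vc_async_00.csv --output breaths.csv
ventwave tune     --dataset data/manifest.csv --grid grid.yaml --out gridresult.csv
ventwave evaluate --breaths breaths/ --manifest data/manifest.csv --out summary.csv
```

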