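"""Full pipeline on the 37-run demo dataset: simulate, detect, evaluate.

Generates the demo bench dataset (20 runs without CPR, 10 with asynchronous
compressions, 7 synchronous 30:2; two minutes each, tidal volumes 177-612 ml,
rates 10-30/min, both ventilator modes), runs the tuned detector on every
recording, and prints the agreement summary between the algorithm's
per-breath measures and the ventilator reference values, one row per
(CPR regime, measure) — median difference, Bland-Altman percentage error,
Lin's concordance, RMSE, and the share of breaths within 10 % error.
"""

import ventwave as vw

result = vw.run_demo_dataset(vw.demo_configs(seed=0))

counts = result["counts"].groupby("cpr_mode")[["detected", "truth"]].sum()
print("breaths detected vs delivered, by regime:")
print(counts.to_string())
print()

summary = result["summary"]
cols = ["cpr_mode", "measure", "n", "diff_median", "percent_error",
        "ccc", "rmse", "prop_within_10pct"]
print("agreement with ventilator reference values:")
print(summary[cols].round(3).to_string(index=False))
print()
print("diff_median is measured - set (ml, cmH2O or 1/min); percent_error is the")
print("median Bland-Altman percentage; the overestimated asynchronous peak")
print("pressures come from compression spikes riding on the inspiratory plateau.")
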