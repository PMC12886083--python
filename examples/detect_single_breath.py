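"""Detect and measure one idealized square-wave breath.

Builds a 6-s recording with a single ventilator breath (flow +30 L/min for
1 s, then -30 L/min for 1 s; pressure 20 cmH2O for 1.2 s), runs the tuned
detector and prints the breath boundaries and measures. The numbers have
closed-form values: the breath starts one lead (0.3 s) before the pressure
crossing at 1.0 s; the active phase ends where the trailing 1-s average of
|flow|, 30*(4-t) L/min, drops below the 5 L/min threshold (t > 3.833 s);
each flow plateau moves 0.5 L/s * 1 s = 500 ml.
"""

import numpy as np

import ventwave as vw

fs = 256
t = np.arange(6 * fs) / fs
flow = np.where((t >= 1) & (t < 2), 30.0, np.where((t >= 2) & (t < 3), -30.0, 0.0))
pressure = np.where((t >= 1) & (t < 2.2), 20.0, 0.0)
recording = vw.WaveformRecording(flow=flow, pressure=pressure, sampling_rate=fs)

events, measures = vw.analyze_recording(recording, vw.AlgorithmParams.tuned())
event, m = events[0], measures[0]

print(f"breaths detected:    {len(events)}")
print(f"start time:          {event.start_time:.4f} s   (anchor - lead C)")
print(f"anchor time:         {event.anchor_time:.4f} s   (pressure crosses A=8 cmH2O)")
print(f"active phase end:    {event.active_end_time:.4f} s   (smoothed |flow| < D=5 L/min)")
print(f"extended end:        {event.extended_end_time:.4f} s   (+ delay E=0.2 s)")
print(f"inspiratory volume:  {m.insp_volume:.1f} ml")
print(f"expiratory volume:   {m.exp_volume:.1f} ml")
print(f"peak pressure:       {m.peak_pressure:.1f} cmH2O")
print(f"leak fraction:       {m.leak_fraction:.3f}   ((insp - exp) / insp)")
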