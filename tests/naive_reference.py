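"""Naive per-sample reference segmentation, independent of the package internals.

Implements the breath-delimitation contract directly: every sample is tested
for the anchor and end conditions with explicit loops and window slices — no
cumulative sums, no vectorized crossing detection, no incremental state.
Used as the oracle for equivalence testing of ``segment_recording``.
"""

import math

EPS = 1e-9


def naive_segment(recording, params):
    """Return [(anchor, start, active_end, extended_end, baseline, truncated)] indices."""
    fs = recording.sampling_rate
    p = [float(x) for x in recording.pressure]
    f = [float(x) for x in recording.flow]
    n = len(p)
    A = params.pressure_threshold_A
    D = params.abs_flow_threshold_D

    def span(sec):
        return int(math.floor(sec * fs + EPS))

    def min_off(sec):
        return int(math.ceil(sec * fs - EPS))

    m = max(1, int(math.ceil(params.smooth_window * fs - EPS)))
    sm = []
    for k in range(n):
        window = f[max(0, k - m + 1) : k + 1]
        sm.append(sum(abs(x) for x in window) / len(window))

    n_sustain = span(params.pressure_duration_B)

    def is_anchor(i):
        if p[i] < A:
            return False
        if i > 0 and p[i - 1] >= A:
            return False
        if i + n_sustain > n - 1:
            return False
        return all(p[j] >= A for j in range(i, i + n_sustain + 1))

    def next_anchor(from_index):
        for i in range(from_index, n):
            if is_anchor(i):
                return i
        return None

    events = []
    search = 0
    while search < n:
        anchor = next_anchor(search)
        if anchor is None:
            break
        start = max(search, anchor - span(params.ventilation_lead_C), 0)
        baseline = min(sm[start : min(n, start + span(params.baseline_window) + 1)])
        if D == -1.0:
            nxt = next_anchor(anchor + 1)
            active_end = nxt if nxt is not None else n
            extended_end = active_end
            truncated = False
        else:
            first = max(
                anchor + min_off(params.pressure_duration_B),
                start + min_off(params.min_duration),
            )
            active_end = None
            for i in range(first, n):
                if sm[i] - baseline < D and p[i] < A:
                    active_end = i
                    break
            if active_end is None:
                active_end = n
                extended_end = n
                truncated = True
            else:
                truncated = False
                nxt = next_anchor(active_end)
                extended_end = min(
                    active_end + span(params.inactive_delay_E),
                    n,
                    nxt if nxt is not None else n,
                )
        events.append((anchor, start, active_end, extended_end, baseline, truncated))
        if extended_end <= search:
            break
        search = extended_end
        if truncated:
            break
    return events
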