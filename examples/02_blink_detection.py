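"""Detect blinks from missing-pupil runs in a hand-built trace.

Builds a 30-second, 100 Hz pupil trace containing a 30 ms tracker dropout,
two true blinks (120 ms and 500 ms), and an 800 ms microsleep, then shows
how the duration thresholds classify each missing run.
"""

import numpy as np
import pandas as pd

from vreye.blinks import classify_missing_runs, summarize_blinks
from vreye.session import SAMPLE_COLUMNS, SceneSession

n = 3000  # 30 s at 100 Hz
pupil = np.full(n, 4.2)
pupil[200:203] = np.nan    # 30 ms  -> noise, discarded
pupil[800:812] = np.nan    # 120 ms -> blink
pupil[1500:1550] = np.nan  # 500 ms -> blink (inclusive upper bound)
pupil[2200:2280] = np.nan  # 800 ms -> microsleep, discarded

samples = pd.DataFrame({
    "t_ms": np.arange(n, dtype=np.int64) * 10,
    "gx": 0.0, "gy": 1.0, "gz": 2.0, "hx": 0.0, "hy": 1.6, "hz": 0.0,
    "fx": 0.0, "fy": 0.0, "fz": 1.0,
    "pupil_l_mm": pupil, "pupil_r_mm": pupil,
    "open_l": 0.95, "open_r": 0.95, "object": "",
})[SAMPLE_COLUMNS]

cls = classify_missing_runs(samples)
print("blinks detected:")
for event in cls.blinks:
    print(f"  onset {event.onset_ms:>6} ms, duration {event.duration_ms} ms")
print(f"discarded as noise (<50 ms):       {cls.discarded_short}")
print(f"discarded as microsleep (>500 ms): {cls.discarded_long}")

scene = SceneSession("Library", samples, [], duration_ms=n * 10)
summary = summarize_blinks(cls.blinks, scene)
print(f"eye-blink rate: {summary.ebr_per_min:.1f} blinks/min "
      "(physiological range is roughly 12-40)")
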