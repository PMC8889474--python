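import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vreye.session import SAMPLE_COLUMNS, TICK_MS

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_trace(pupil_l, pupil_r=None, objects=None, openness=0.95):
    """Assemble a valid samples DataFrame from per-tick pupil value arrays.

    ``pupil_l``/``pupil_r`` are sequences of floats with NaN for missing;
    ``objects`` an optional sequence of gazed-object names ('' for none).
    Geometry columns are filled with a fixed valid pose.
    """
    pl = np.asarray(pupil_l, dtype=float)
    pr = pl.copy() if pupil_r is None else np.asarray(pupil_r, dtype=float)
    n = len(pl)
    if objects is None:
        objects = [""] * n
    df = pd.DataFrame({
        "t_ms": np.arange(n, dtype=np.int64) * TICK_MS,
        "gx": 0.0, "gy": 1.0, "gz": 2.0,
        "hx": 0.0, "hy": 1.6, "hz": 0.0,
        "fx": 0.0, "fy": 0.0, "fz": 1.0,
        "pupil_l_mm": pl, "pupil_r_mm": pr,
        "open_l": openness, "open_r": openness,
        "object": list(objects),
    })
    return df[SAMPLE_COLUMNS]


@pytest.fixture
def short_config():
    """A small, fast simulator configuration (30 s scenes, 3 participants)."""
    from vreye.simulate import SimConfig

    return SimConfig(seed=101, n_participants=3, scene_duration_ms=30_000)
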