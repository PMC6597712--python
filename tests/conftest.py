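import numpy as np
import pandas as pd
import pytest

from synquant.types import TimeSeriesTrace


def match_events(detected: pd.DataFrame, truth: pd.DataFrame,
                 max_dt_frames: int = 2, max_dist_px: float = 2.0) -> tuple:
    """Greedy one-to-one matching of detected events to injected events.

    Returns (true_positives, false_positives).
    """
    used = set()
    tp = 0
    for _, t in truth.iterrows():
        best = None
        for j, d in detected.iterrows():
            if j in used:
                continue
            if abs(d["frame"] - t["frame"]) <= max_dt_frames and \
                    np.hypot(d["row"] - t["row"], d["col"] - t["col"]) <= max_dist_px:
                best = j
                break
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(detected) - tp


@pytest.fixture
def simple_trace():
    """Basal 100 for t<20, plateau 200 for 20<=t<420, NH4Cl 300 after."""
    times = np.arange(0.0, 600.0, 2.0)
    values = np.where(times < 20, 100.0, np.where(times < 420, 200.0, 300.0))
    return TimeSeriesTrace(times, values, t_stim=20.0, t_nh4cl=420.0)
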