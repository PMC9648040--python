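import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_measures_table(rng):
    """Measures table for 8 subjects x 2 exercises with lognormal-ish
    variability measures; control subjects lower than preoperative."""
    from vestikin.kinematics import MEASURE_COLUMNS

    rows = []
    for i in range(8):
        group = "control" if i < 4 else "preoperative"
        scale = 1.0 if group == "control" else 2.0
        for e in (6, 7):
            row = {
                "subject": f"S{i:02d}",
                "group": group,
                "exercise": e,
            }
            for c in MEASURE_COLUMNS:
                if c == "duration_s":
                    row[c] = 30.0 - rng.uniform(0, 2) * scale
                else:
                    row[c] = float(scale * rng.lognormal(2.0, 0.4))
            rows.append(row)
    return pd.DataFrame(rows)
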