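import numpy as np
import pytest

import skintrib as sk


@pytest.fixture(scope="session")
def knit():
    return sk.preset("polycotton_knit")


@pytest.fixture(scope="session")
def small_plan():
    """Desk-scale trial plan: 6 s, 8 strokes, AE at 0.4 MSa/s."""
    return sk.TrialPlan(target_load=2.0, duration=6.0, n_strokes=8,
                        ae_rate=4e5, seed=7)


@pytest.fixture(scope="session")
def knit_trial(knit, small_plan):
    """One synthetic fabric trial: force recording + planted strokes."""
    rec, truth = sk.synthesize_force_recording(knit, small_plan)
    return rec, truth


@pytest.fixture(scope="session")
def knit_ae(knit, small_plan, knit_trial):
    _, truth = knit_trial
    return sk.synthesize_ae_recording(knit, small_plan, truth)


def percentile_oracle(values, q):
    """Independent sort-and-interpolate order statistic."""
    s = np.sort(np.asarray(values, dtype=float))
    n = len(s)
    h = (n - 1) * q / 100.0
    i = int(np.floor(h))
    if i >= n - 1:
        return float(s[-1])
    return float(s[i] + (h - i) * (s[i + 1] - s[i]))
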