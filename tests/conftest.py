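import numpy as np
import pytest

import somnostress as ss


@pytest.fixture(scope="session")
def one_day_schedule():
    return ss.ProtocolSchedule(days=[ss.DayPlan(0, "baseline")])


@pytest.fixture(scope="session")
def day_bundle(one_day_schedule):
    """One synthetic 24 h recording with ground truth, shared read-only."""
    params = ss.SimParams.from_preset("female_resilient", seed=42)
    hyp = ss.simulate_hypnogram(params, one_day_schedule)
    s = ss.homeostat_trajectory(hyp, params)
    rec = ss.synthesize_signals(hyp, s, params)
    return {"params": params, "hyp": hyp, "s": s, "rec": rec}


@pytest.fixture(scope="session")
def day_features(day_bundle):
    return ss.extract_features(day_bundle["rec"])


def make_hypnogram(pattern: str, epoch_s: float = 10.0) -> ss.Hypnogram:
    """Compact hypnograms from strings like 'WWNNNRW' (A = artifact)."""
    lut = {"W": ss.WAKE, "N": ss.NREM, "R": ss.REM, "A": ss.ARTIFACT}
    return ss.Hypnogram(np.array([lut[c] for c in pattern], dtype=object),
                        epoch_s=epoch_s)
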