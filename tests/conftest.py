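import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cpcea import InstrumentMap, TrialConfig, simulate_trial

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def imap() -> InstrumentMap:
    return InstrumentMap.default()


@pytest.fixture(scope="session")
def tiny_map() -> InstrumentMap:
    """A minimal valid instrument map with small domains, for arithmetic tests."""
    rows = []
    sizes = {
        "functioning": 4,
        "participation_physical": 2,
        "access_services": 2,
        "emotional_wellbeing": 2,
        "family_health": 2,
        "pain_disability": 2,
        "social_wellbeing": 2,
    }
    i = 0
    for dom, k in sizes.items():
        orient = "lower_is_better" if dom == "pain_disability" else "higher_is_better"
        for _ in range(k):
            i += 1
            rows.append({"item_id": f"x{i:02d}", "domain": dom, "orientation": orient})
    return InstrumentMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def complete_trial(imap):
    """One default-sized trial with no missingness (shared, read-only)."""
    cfg = TrialConfig(missing_rate=0.0, seed=1234)
    return simulate_trial(cfg, imap)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
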