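import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spots_field():
    """One converged spots-regime field at the documented example settings."""
    from apostim import RDParams, simulate

    return simulate(RDParams(regime="spots", seed=1, grid_height=128, grid_width=128))


@pytest.fixture(scope="session")
def default_cohort():
    from apostim import BehaviorParams, DesignSpec, simulate_cohort

    return simulate_cohort(DesignSpec(), BehaviorParams(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def interaction_cohort():
    """Cohort with a strong trial x pattern x contrast interaction baked
    into the approach stage, built directly from Bernoulli draws: in the
    high-contrast spots group only, late trials flip to near-certain
    avoidance."""
    import pandas as pd
    from scipy.special import expit

    gen = np.random.default_rng(77)
    rows = []
    chick = 0
    for group in ("low-stripes", "low-spots", "high-stripes", "high-spots"):
        contrast = "high" if group.startswith("high") else "low"
        pattern = "spots" if group.endswith("spots") else "stripes"
        for _ in range(100):
            b = gen.normal(0, 0.3)
            batch = 1 + chick % 2
            for trial in range(1, 6):
                eta = 0.3 + b
                if contrast == "high" and pattern == "spots" and trial >= 4:
                    eta -= 3.0
                approached = int(gen.random() < expit(eta))
                eaten = approached * int(gen.random() < 0.5)
                rows.append((chick, group, pattern, contrast, batch, trial,
                             approached, eaten))
            chick += 1
    return pd.DataFrame(rows, columns=[
        "chick_id", "group", "pattern_class", "contrast_level",
        "batch", "trial", "approached", "eaten"])
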