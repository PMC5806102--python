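import numpy as np
import pandas as pd
import pytest

from pairsig.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """n=300 cohort with one strong planted pair (beta = 1.5)."""
    cfg = SyntheticConfig(
        n_samples=300, n_genes=20, planted_pairs=((0, 1, 1.5),), seed=11
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """n=300 cohort with no planted signal."""
    cfg = SyntheticConfig(n_samples=300, n_genes=30, planted_pairs=(), seed=7)
    return generate_cohort(cfg)


@pytest.fixture()
def small_surv():
    """Ten samples, mixed events/censorings, no tied times."""
    rng = np.random.default_rng(5)
    times = np.sort(rng.exponential(10, 10)) + 1.0
    events = np.array([1, 0, 1, 1, 0, 1, 1, 0, 1, 1])
    return pd.DataFrame(
        {"time": times, "event": events},
        index=pd.Index([f"S{i}" for i in range(10)], name="sample_id"),
    )
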