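import numpy as np
import pandas as pd
import pytest

from epifinger import SimulationConfig, simulate_cohort
from epifinger.pipeline import preprocess_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest paired cohort with planted effects, shared by read-only tests."""
    config = SimulationConfig(seed=42, n_individuals=400, n_cpgs=200,
                              n_effect_cpgs=8, n_med_confounded_cpgs=2,
                              event_rate=0.1)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_delta(small_cohort):
    delta, _ = preprocess_cohort(small_cohort)
    return delta


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def make_phenotypes(individuals, mi=None, seed=0):
    """Minimal two-visit phenotype table for hand-built matrices."""
    rng = np.random.default_rng(seed)
    n = len(individuals)
    mi = np.zeros(n, dtype=int) if mi is None else np.asarray(mi, dtype=int)
    rows = []
    for visit in ("baseline", "followup"):
        frame = pd.DataFrame({
            "individual": individuals,
            "visit": visit,
            "age": rng.normal(60, 8, n),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(27, 4, n),
            "diabetes": rng.integers(0, 2, n),
            "hypertension": rng.integers(0, 2, n),
            "physical_activity": rng.integers(0, 2, n),
            "pack_years": rng.exponential(8, n),
            "alcohol": rng.exponential(10, n),
            "incident_mi": mi,
        })
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
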