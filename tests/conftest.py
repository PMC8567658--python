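import numpy as np
import pandas as pd
import pytest

import musclemeth as mm


@pytest.fixture(scope="session")
def small_null_trio():
    """Three small null cohorts (no planted effects) with annotation/truth."""
    cfg = mm.SimConfig(n_probes=4000, n_samples=(40, 40, 40), frac_sex_cpgs=0.0,
                       frac_fibre_cpgs=0.0, seed=101)
    return mm.simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def planted_trio():
    """Three cohorts with strong planted sex effects on 10% of probes."""
    cfg = mm.SimConfig(n_probes=4000, n_samples=(60, 60, 60), frac_sex_cpgs=0.10,
                       effect_size=0.15, frac_fibre_cpgs=0.0, seed=202)
    return mm.simulate_cohorts(cfg)


@pytest.fixture
def toy_study():
    """Tiny handmade cohort: 3 probes x 4 samples, two per sex."""
    beta = pd.DataFrame(
        [[0.10, 0.20, 0.30, 0.40],
         [0.50, 0.50, 0.60, 0.60],
         [0.90, 0.80, 0.70, 0.60]],
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    samples = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "subject_id": ["u1", "u2", "u3", "u4"],
        "sex": ["F", "F", "M", "M"],
        "age": [30.0, 40.0, 35.0, 45.0],
    }).set_index("sample_id")
    return mm.CohortStudy("toy", beta, samples, ["sex"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
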