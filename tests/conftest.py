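import numpy as np
import pandas as pd
import pytest

from meglat import (
    BAND_NAMES,
    REGIONS,
    SynthConfig,
    generate_power_cohort,
    li_table,
    make_toy_forward,
)

N_BANDS, N_REGIONS = len(BAND_NAMES), len(REGIONS)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort (102 controls, 16 left, 19 right patients)."""
    return generate_power_cohort(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_li(default_cohort):
    return li_table(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_power_cohort(SynthConfig(n_ctr=20, n_lt=10, n_rt=12, seed=11))


@pytest.fixture(scope="session")
def toy_fm():
    return make_toy_forward(n_sensors=32, sources_per_cell=4, seed=2)


def fast_li(cohort: pd.DataFrame, n_subjects: int) -> np.ndarray:
    """LI per subject as (n_subjects, n_bands, n_regions) without pandas pivots.

    Relies on the generator's deterministic row order (subject, band, region,
    hemisphere); its agreement with li_table is asserted in test_synth.
    """
    p = cohort["power"].to_numpy().reshape(n_subjects, N_BANDS, N_REGIONS, 2)
    return (p[..., 0] - p[..., 1]) / (p[..., 0] + p[..., 1])
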