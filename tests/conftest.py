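import numpy as np
import pandas as pd
import pytest

from csfmet.synthetic import SimConfig, cohort_to_frame, generate_cohort, generate_injection_table
from csfmet.tables import InjectionTable


def make_table(intensities: dict, types: dict, volumes: dict | None = None,
               sample_ids: dict | None = None, feature_meta: pd.DataFrame | None = None,
               is_log2: bool = False) -> InjectionTable:
    """Hand-build a small InjectionTable.

    ``intensities``: feature_id -> list of values (one per injection, in
    order); ``types``: injection_id -> type.
    """
    inj_ids = list(types)
    df = pd.DataFrame.from_dict(intensities, orient="index", columns=inj_ids)
    meta = pd.DataFrame({
        "type": [types[i] for i in inj_ids],
        "order": np.arange(1, len(inj_ids) + 1),
        "sample_id": [(sample_ids or {}).get(i) for i in inj_ids],
        "volume": [(volumes or {}).get(i) for i in inj_ids],
    }, index=pd.Index(inj_ids, name="injection_id"))
    return InjectionTable(df, meta, feature_meta, is_log2=is_log2)


@pytest.fixture(scope="session")
def quiet_config():
    """Low-noise default-design config used by several recovery tests."""
    return SimConfig(seed=11, noise_sd=0.05, missing_rate=0.01, n_features=80)


@pytest.fixture(scope="session")
def quiet_study(quiet_config):
    cohort = generate_cohort(quiet_config)
    table, truth = generate_injection_table(cohort, quiet_config)
    return cohort, cohort_to_frame(cohort), table, truth


@pytest.fixture(scope="session")
def clean_config():
    """Zero-noise, zero-artifact config: the cascade must be the identity."""
    return SimConfig(seed=5, noise_sd=0.0, missing_rate=0.0, drift_amplitude=0.0,
                     frac_contaminant=0.0, albumin_link_frac=0.0,
                     frac_age_dependent=0.0, n_features=40)
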