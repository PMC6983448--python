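import numpy as np
import pandas as pd
import pytest

from cfscreen.config import GeneratorConfig, age_band_of
from cfscreen.matching import build_matched_sets
from cfscreen.synth import generate_catalog, generate_population


def make_subjects(rows) -> pd.DataFrame:
    """Build a population table from (id, family, sex, age, months, group) tuples,
    with optional extra condition columns supplied as a dict of id -> {cid: 0/1}."""
    recs = []
    for sid, fam, sex, age, months, group in rows:
        recs.append({
            "subject_id": sid, "family_id": fam, "sex": sex,
            "age_first_enroll_years": age, "age_band": age_band_of([age])[0],
            "enroll_months": months, "group": group,
            "true_status": {"carrier": "carrier", "cf": "cf"}.get(group, "noncarrier"),
            "screened_flag": group == "carrier", "suspicion_flag": False,
            "child_cf_birth_month": pd.NA,
        })
    df = pd.DataFrame(recs)
    df["child_cf_birth_month"] = df["child_cf_birth_month"].astype("Int64")
    return df


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_carriers=400, n_cf=400, n_control_pool=16000, n_conditions=16,
        p0_range=(0.01, 0.12), beta_cf_range=(1.0, 2.5), frailty_sd=0.4,
        n_female_only=1, n_male_only=1, n_adult_only=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return generate_catalog(small_config)


@pytest.fixture(scope="session")
def small_population(small_catalog, small_config):
    return generate_population(small_catalog, small_config)


@pytest.fixture(scope="session")
def small_sets(small_population):
    return build_matched_sets(small_population, "carrier", M=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
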