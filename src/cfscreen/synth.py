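"""Synthetic condition catalogs and claims-like study populations.

The generator emulates the statistical structure the downstream analysis
assumes, not any real claims schema: abstract condition ids grouped into
organ systems, ever-diagnosed 0/1 indicators per enrollee, 1-204 month
enrollment windows, a carrier effect profile that is an attenuated noisy copy
of the CF profile, organ-system frailties inducing multimorbidity
correlation, and optional contamination of the labelled carrier group by
latent CF subjects.

For a subject ``s`` and condition ``c`` the diagnosis probability is::

    P = expit( logit(p0_c) + beta_c*[carrier] + gamma_c*[cf]
               + u_{s,system(c)} + delta*log(months_s / median months) )

with ``u ~ Normal(0, frailty_sd)`` independent per subject x organ system.
Indicators are realised as ``U < P`` from uniforms drawn independently of the
effect sizes, so paired runs with a common seed share random numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (
    AGE_BANDS,
    AGE_BAND_LABELS,
    MAX_ENROLL_MONTHS,
    GeneratorConfig,
    age_band_of,
)
from .clogit import SetTabulation, tabulate_from_arrays
from .errors import ConfigurationError

POPULATION_COLUMNS = [
    "subject_id", "family_id", "sex", "age_first_enroll_years", "age_band",
    "enroll_months", "group", "screened_flag", "suspicion_flag", "true_status",
    "child_cf_birth_month",
]


def condition_ids(n: int) -> list[str]:
    return [f"c{i + 1:03d}" for i in range(n)]


def generate_catalog(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a condition catalog: baseline prevalences, CF and carrier effects.

    CF log-odds effects are uniform on ``beta_cf_range``; carrier effects are
    ``lambda * beta_cf + Normal(0, noise_sd)``; baseline prevalences are
    log-uniform on ``p0_range``; organ systems are assigned round-robin.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 101])
    n = config.n_conditions
    ids = condition_ids(n)
    systems = [config.organ_systems[i % len(config.organ_systems)] for i in range(n)]
    lo, hi = config.p0_range
    p0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    blo, bhi = config.beta_cf_range
    beta_cf = rng.uniform(blo, bhi, size=n)
    beta_carrier = config.attenuation_lambda * beta_cf + rng.normal(
        0.0, config.attenuation_noise_sd, size=n
    )
    sex_mask = np.array(["any"] * n, dtype=object)
    special = rng.choice(n, size=config.n_female_only + config.n_male_only, replace=False)
    sex_mask[special[: config.n_female_only]] = "female_only"
    sex_mask[special[config.n_female_only:]] = "male_only"
    min_age = np.zeros(n, dtype=int)
    remaining = np.setdiff1d(np.arange(n), special)
    n_adult = min(config.n_adult_only, remaining.size)
    if n_adult > 0:
        min_age[rng.choice(remaining, size=n_adult, replace=False)] = 18
    return pd.DataFrame({
        "condition_id": ids,
        "name": [f"Condition {i + 1}" for i in range(n)],
        "organ_system": systems,
        "p0": p0,
        "beta_cf": beta_cf,
        "beta_carrier": beta_carrier,
        "sex_mask": sex_mask,
        "min_age_years": min_age,
    })


def _sample_demographics(rng, n, sex_dist, age_dist, median_months, log_sd):
    sex = rng.choice(np.array(["F", "M"], dtype=object), size=n,
                     p=[sex_dist["F"], sex_dist["M"]])
    band_idx = rng.choice(len(AGE_BAND_LABELS), size=n,
                          p=[age_dist[b] for b in AGE_BAND_LABELS])
    lows = np.array([b[1] for b in AGE_BANDS])
    highs = np.array([b[2] for b in AGE_BANDS])
    # sample the band, then jitter the exact age uniformly within the band
    age = rng.integers(lows[band_idx], highs[band_idx] + 1)
    months = np.rint(np.exp(rng.normal(np.log(median_months), log_sd, size=n)))
    months = np.clip(months, 1, MAX_ENROLL_MONTHS).astype(int)
    return sex, age.astype(int), months


def applicability_matrix(catalog: pd.DataFrame, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Boolean (n_subjects x n_conditions) mask of who can receive each condition."""
    sex = np.asarray(sex, dtype=object)
    age = np.asarray(age)
    mask = np.ones((sex.size, len(catalog)), dtype=bool)
    for j, (sm, ma) in enumerate(zip(catalog["sex_mask"], catalog["min_age_years"])):
        if sm == "female_only":
            mask[:, j] &= sex == "F"
        elif sm == "male_only":
            mask[:, j] &= sex == "M"
        if ma > 0:
            mask[:, j] &= age >= ma
    return mask


def _condition_linpred(catalog, true_status, months, median_months, config, rng):
    """Linear predictor (n_subjects x n_conditions), excluding applicability."""
    n = len(true_status)
    sys_index = np.array(
        [list(config.organ_systems).index(s) for s in catalog["organ_system"]]
    )
    lp = np.tile(logit(catalog["p0"].to_numpy(dtype=np.float64)), (n, 1)).astype(np.float32)
    carrier = (np.asarray(true_status, dtype=object) == "carrier")
    cf = (np.asarray(true_status, dtype=object) == "cf")
    lp += np.outer(carrier, catalog["beta_carrier"].to_numpy()).astype(np.float32)
    lp += np.outer(cf, catalog["beta_cf"].to_numpy()).astype(np.float32)
    u = rng.normal(0.0, config.frailty_sd, size=(n, len(config.organ_systems)))
    lp += u[:, sys_index].astype(np.float32)
    expo = config.enroll_exposure_coef * np.log(
        np.asarray(months, dtype=np.float64) / median_months
    )
    lp += expo[:, None].astype(np.float32)
    return lp.astype(np.float64)


def _condition_probs(catalog, true_status, sex, age, months, median_months, config, rng):
    lp = _condition_linpred(catalog, true_status, months, median_months, config, rng)
    p = expit(lp)
    p *= applicability_matrix(catalog, sex, age)
    return p


def generate_population(
    catalog: pd.DataFrame, config: GeneratorConfig, *, rng=None
) -> pd.DataFrame:
    """Generate the labelled carrier cohort, CF cohort and control pool.

    Exactly ``contamination_count`` subjects in the labelled carrier group are
    latent CF cases (``true_status == "cf"``); all control-pool subjects are
    true noncarriers.  A ``family_link_rate`` fraction of controls is placed
    in the family of a random carrier/CF subject so the matching stage's
    family exclusion has something to exclude.
    """
    config.validate()
    if len(catalog) == 0:
        raise ConfigurationError("catalog must be nonempty")
    if rng is None:
        rng = np.random.default_rng([int(config.seed) % (2**31), 202])

    n_car, n_cf, n_pool = config.n_carriers, config.n_cf, config.n_control_pool
    pool_sex = {s: 0.5 * (config.sex_distribution[s] + config.cf_sex_distribution[s])
                for s in ("F", "M")}
    pool_age = {b: 0.5 * (config.age_distribution[b] + config.cf_age_distribution[b])
                for b in AGE_BAND_LABELS}

    parts = []
    specs = [
        ("carrier", n_car, config.sex_distribution, config.age_distribution,
         config.enroll_median_months, config.enroll_log_sd),
        ("cf", n_cf, config.cf_sex_distribution, config.cf_age_distribution,
         config.cf_enroll_median_months, config.cf_enroll_log_sd),
        ("control_pool", n_pool, pool_sex, pool_age,
         config.enroll_median_months, config.enroll_log_sd),
    ]
    offset = 0
    for group, n, sd, ad, med, lsd in specs:
        sex, age, months = _sample_demographics(rng, n, sd, ad, med, lsd)
        df = pd.DataFrame({
            "subject_id": [f"s{offset + i:07d}" for i in range(n)],
            "family_id": [f"f{offset + i:07d}" for i in range(n)],
            "sex": sex,
            "age_first_enroll_years": age,
            "age_band": age_band_of(age),
            "enroll_months": months,
            "group": group,
        })
        offset += n
        parts.append(df)
    pop = pd.concat(parts, ignore_index=True)

    true_status = np.where(pop["group"] == "carrier", "carrier",
                           np.where(pop["group"] == "cf", "cf", "noncarrier"))
    if config.contamination_count > 0:
        hidden = rng.choice(n_car, size=config.contamination_count, replace=False)
        true_status[hidden] = "cf"
    pop["true_status"] = true_status
    pop["screened_flag"] = (pop["group"] == "carrier").to_numpy()
    pop["child_cf_birth_month"] = pd.array([pd.NA] * len(pop), dtype="Int64")

    # link some controls into carrier/CF families
    if config.family_link_rate > 0 and n_car + n_cf > 0:
        ctrl = np.flatnonzero((pop["group"] == "control_pool").to_numpy())
        linked = ctrl[rng.random(ctrl.size) < config.family_link_rate]
        donors = rng.integers(0, n_car + n_cf, size=linked.size)
        fam = pop["family_id"].to_numpy(dtype=object)
        fam[linked] = fam[donors]
        pop["family_id"] = fam

    median_months = float(np.median(pop["enroll_months"]))
    p = _condition_probs(catalog, pop["true_status"], pop["sex"],
                         pop["age_first_enroll_years"], pop["enroll_months"],
                         median_months, config, rng)
    unif = rng.random(p.shape)
    x = (unif < p)
    cond = pd.DataFrame(x.astype(np.int8), columns=list(catalog["condition_id"]))
    pop = pd.concat([pop, cond], axis=1)

    # suspicion flag: clinical-suspicion screening analog among labelled carriers
    susp = np.zeros(len(pop), dtype=bool)
    car_mask = (pop["group"] == "carrier").to_numpy()
    sys_cols = list(catalog.loc[catalog["organ_system"] == config.suspicion_system,
                                "condition_id"])
    has_sys = pop[sys_cols].to_numpy().sum(axis=1) > 0 if sys_cols else np.zeros(len(pop), bool)
    p_susp = np.clip(config.suspicion_base + config.suspicion_extra * has_sys, 0.0, 1.0)
    susp[car_mask] = rng.random(car_mask.sum()) < p_susp[car_mask]
    pop["suspicion_flag"] = susp
    return pop


def generate_families(
    catalog: pd.DataFrame, config: GeneratorConfig, n_pairs: int | None = None, *, rng=None
) -> pd.DataFrame:
    """Mother-child pairs for the familial validation cohort.

    Mothers are unscreened true carriers in the control pool whose CF child's
    birth month falls inside their enrollment window.  Each mother carries two
    indicator sets: the full-window columns and ``pre_<condition_id>`` columns
    restricted to the months before the birth; the pre-birth set is generated
    from the same latent uniforms, so it is a monotone restriction of the
    full-window set.
    """
    config.validate()
    n_pairs = config.n_family_pairs if n_pairs is None else int(n_pairs)
    if n_pairs < 1:
        raise ConfigurationError("n_family_pairs must be >= 1")
    if rng is None:
        rng = np.random.default_rng([int(config.seed) % (2**31), 303])

    adult = {b: config.age_distribution[b] for b in ("18-26", "27-35", "36-45", "46+")}
    tot = sum(adult.values())
    age_dist = {b: (adult[b] / tot if b in adult else 0.0) for b in AGE_BAND_LABELS}
    _, age, months = _sample_demographics(
        rng, n_pairs, {"F": 1.0, "M": 0.0}, age_dist,
        config.enroll_median_months, config.enroll_log_sd)
    sex = np.array(["F"] * n_pairs, dtype=object)
    birth = rng.integers(1, months + 1)

    mothers = pd.DataFrame({
        "subject_id": [f"vm{i:06d}" for i in range(n_pairs)],
        "family_id": [f"vf{i:06d}" for i in range(n_pairs)],
        "sex": sex,
        "age_first_enroll_years": age,
        "age_band": age_band_of(age),
        "enroll_months": months,
        "group": "control_pool",
        "true_status": "carrier",
        "screened_flag": False,
        "suspicion_flag": False,
        "child_cf_birth_month": pd.array(birth, dtype="Int64"),
    })
    median_months = float(np.median(months))
    lp_full = _condition_linpred(catalog, mothers["true_status"], months,
                                 median_months, config, rng)
    # pre-birth window: same linear predictor with the shorter exposure;
    # realised from the same uniforms so pre-birth diagnoses are a subset
    delta = config.enroll_exposure_coef
    lp_pre = lp_full + delta * np.log(birth / months)[:, None]
    app = applicability_matrix(catalog, sex, age)
    p_full = expit(lp_full) * app
    p_pre = expit(lp_pre) * app
    unif = rng.random(p_full.shape)
    full = (unif < p_full).astype(np.int8)
    pre = (unif < np.minimum(p_pre, p_full)).astype(np.int8)
    cids = list(catalog["condition_id"])
    mothers = pd.concat([mothers,
                         pd.DataFrame(full, columns=cids),
                         pd.DataFrame(pre, columns=[f"pre_{c}" for c in cids])], axis=1)

    child_sex, _, _ = _sample_demographics(
        rng, n_pairs, {"F": 0.5, "M": 0.5}, age_dist,
        config.cf_enroll_median_months, config.cf_enroll_log_sd)
    child_age = np.zeros(n_pairs, dtype=int)
    child_months = np.maximum(1, months - birth + 1)
    children = pd.DataFrame({
        "subject_id": [f"vc{i:06d}" for i in range(n_pairs)],
        "family_id": [f"vf{i:06d}" for i in range(n_pairs)],
        "sex": child_sex,
        "age_first_enroll_years": child_age,
        "age_band": age_band_of(child_age),
        "enroll_months": child_months,
        "group": "cf",
        "true_status": "cf",
        "screened_flag": False,
        "suspicion_flag": False,
        "child_cf_birth_month": pd.array([pd.NA] * n_pairs, dtype="Int64"),
    })
    p_child = _condition_probs(catalog, children["true_status"], child_sex, child_age,
                               child_months, median_months, config, rng)
    xc = (rng.random(p_child.shape) < p_child).astype(np.int8)
    children = pd.concat([children,
                          pd.DataFrame(xc, columns=cids),
                          pd.DataFrame(xc, columns=[f"pre_{c}" for c in cids])], axis=1)
    return pd.concat([mothers, children], ignore_index=True)


def simulate_matched_tabulation(
    p_index: float, p_control: float, n_sets: int, n_controls: int, rng
) -> SetTabulation:
    """Directly sample the sufficient statistics of ``n_sets`` 1:M matched sets.

    Within a set the index outcome is Bernoulli(``p_index``) and the control
    event count is Binomial(M, ``p_control``), independently, so the counts
    over the 2x(M+1) cells of (y1, control events) are one multinomial draw.
    This is the exact sampling distribution of the per-set tabulation under
    homogeneous within-set probabilities and is used for desk-scale
    calibration studies (coverage, type-I error, attenuation recovery).
    """
    M = int(n_controls)
    kc = np.arange(M + 1)
    from scipy.stats import binom

    pk = binom.pmf(kc, M, p_control)
    probs = np.concatenate([(1 - p_index) * pk, p_index * pk])
    probs = np.clip(probs, 0, None)
    probs = probs / probs.sum()
    draw = rng.multinomial(int(n_sets), probs)
    counts: dict[tuple[int, int, int], int] = {}
    for y1 in (0, 1):
        for j in range(M + 1):
            w = int(draw[y1 * (M + 1) + j])
            if w:
                counts[(M, j + y1, y1)] = w
    return SetTabulation(counts)


__all__ = [
    "generate_catalog", "generate_population", "generate_families",
    "simulate_matched_tabulation", "condition_ids", "applicability_matrix",
    "POPULATION_COLUMNS",
]
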