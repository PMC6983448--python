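"""Construction of 1:M matched sets.

Each index subject (carrier or CF) is matched to up to M controls sharing sex,
age band and months of enrollment (exact by default, optional +/- tolerance).
Controls from families containing a carrier or CF subject are ineligible, and
a control is never reused across sets.  Sets with fewer than M eligible
controls are emitted with the available count and flagged short; a set with
zero controls is flagged non-informative downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MatchPolicy
from .errors import ConfigurationError

SET_COLUMNS = ["set_id", "subject_id", "role", "sex", "age_band", "enroll_months",
               "n_controls", "short_set"]


def linked_family_ids(population: pd.DataFrame) -> set:
    """Family ids containing any labelled carrier or CF subject."""
    mask = population["group"].isin(["carrier", "cf"])
    return set(population.loc[mask, "family_id"])


def match_keys(population: pd.DataFrame) -> pd.DataFrame:
    """The (sex, age_band, enroll_months) matching key for every subject."""
    return population[["sex", "age_band", "enroll_months"]]


def eligible_controls(
    population: pd.DataFrame,
    index: pd.Series,
    policy: MatchPolicy = MatchPolicy(),
    used: set | None = None,
) -> pd.DataFrame:
    """Controls sharing the index subject's matching key, after exclusions."""
    used = used or set()
    pool = population[population["group"] == "control_pool"]
    if policy.exclude_linked_families:
        bad = linked_family_ids(population)
        pool = pool[~pool["family_id"].isin(bad)]
    tol = policy.months_tolerance
    mask = (
        (pool["sex"] == index["sex"])
        & (pool["age_band"] == index["age_band"])
        & ((pool["enroll_months"] - index["enroll_months"]).abs() <= tol)
        & (pool["subject_id"] != index["subject_id"])
        & ~pool["subject_id"].isin(used)
    )
    return pool[mask]


def build_matched_sets(
    population: pd.DataFrame,
    index_group: str = "carrier",
    M: int = 5,
    seed: int = 0,
    policy: MatchPolicy = MatchPolicy(),
    index_ids=None,
) -> pd.DataFrame:
    """Build one matched set per index subject.

    Returns a long-form table (one row per member) with columns
    ``set_id, subject_id, role, sex, age_band, enroll_months, n_controls,
    short_set``.  Controls are drawn uniformly without replacement (globally:
    no reuse across sets); index subjects are processed in seeded random order
    so scarce controls are allocated without systematic preference.
    """
    if M < 1:
        raise ConfigurationError("M must be >= 1")
    rng = np.random.default_rng(int(seed) % (2**31))

    if index_ids is not None:
        idx_df = population[population["subject_id"].isin(set(index_ids))]
    else:
        idx_df = population[population["group"] == index_group]
    if len(idx_df) == 0:
        raise ConfigurationError(f"no index subjects in group {index_group!r}")

    pool = population[population["group"] == "control_pool"]
    if policy.exclude_linked_families:
        bad = linked_family_ids(population)
        pool = pool[~pool["family_id"].isin(bad)]
    pool = pool[~pool["subject_id"].isin(set(idx_df["subject_id"]))]

    # bucket eligible controls by exact key in seeded random order
    order = rng.permutation(len(pool))
    pool = pool.iloc[order]
    buckets: dict[tuple, list] = {}
    for sid, sex, band, months in zip(pool["subject_id"], pool["sex"],
                                      pool["age_band"], pool["enroll_months"]):
        buckets.setdefault((sex, band, int(months)), []).append(sid)
    cursors: dict[tuple, int] = {key: 0 for key in buckets}

    tol = policy.months_tolerance
    offsets = [0]
    for t in range(1, tol + 1):
        offsets.extend([t, -t])

    idx_order = rng.permutation(len(idx_df))
    idx_df = idx_df.iloc[idx_order]

    rows = []
    for i, (sid, sex, band, months) in enumerate(zip(
            idx_df["subject_id"], idx_df["sex"], idx_df["age_band"],
            idx_df["enroll_months"])):
        months = int(months)
        chosen: list = []
        for off in offsets:
            if len(chosen) >= M:
                break
            key = (sex, band, months + off)
            lst = buckets.get(key)
            if not lst:
                continue
            cur = cursors[key]
            take = min(M - len(chosen), len(lst) - cur)
            if take > 0:
                chosen.extend(lst[cur:cur + take])
                cursors[key] = cur + take
        short = len(chosen) < M
        set_id = f"set{i:07d}"
        rows.append((set_id, sid, "index", sex, band, months, len(chosen), short))
        for cid in chosen:
            rows.append((set_id, cid, "control", sex, band, months, len(chosen), short))
    return pd.DataFrame(rows, columns=SET_COLUMNS)


def audit_sets(sets: pd.DataFrame, population: pd.DataFrame,
               policy: MatchPolicy = MatchPolicy()) -> None:
    """Raise AssertionError if key homogeneity or disjointness is violated."""
    key = population.set_index("subject_id")[["sex", "age_band", "enroll_months"]]
    merged = sets.join(key, on="subject_id", rsuffix="_pop")
    for g, grp in merged.groupby("set_id"):
        idx = grp[grp["role"] == "index"].iloc[0]
        assert (grp["sex_pop"] == idx["sex_pop"]).all(), f"sex mismatch in {g}"
        assert (grp["age_band_pop"] == idx["age_band_pop"]).all(), f"band mismatch in {g}"
        assert (grp["enroll_months_pop"] - idx["enroll_months_pop"]).abs().max() \
            <= policy.months_tolerance, f"months mismatch in {g}"
    assert sets["subject_id"].is_unique, "a subject appears in more than one set"
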