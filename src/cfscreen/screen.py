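"""Per-condition screens over a whole catalog for one cohort pairing.

For every retained condition the screen tabulates the matched sets'
sufficient statistics, fits the conditional-logit odds ratio and reports
prevalences (per 100 and per 1,000) for the index cohort and its matched
controls.  Conditions inapplicable to the cohort (wrong sex) are dropped;
conditions with fewer combined events than a configurable floor are marked
insufficient-data instead of being fitted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clogit
from .clogit import ORResult, SetTabulation, fit_conditional_logit
from .config import MatchPolicy
from .errors import ConfigurationError, DataError
from .matching import build_matched_sets


class SetSystem:
    """Index/control row positions of matched sets, for vectorized tabulation.

    Positions refer to rows of the population table the sets were built from.
    Controls are stored sorted by set with ``reduceat`` offsets, so per-set
    event totals for any 0/1 outcome column are a single segmented sum.
    """

    def __init__(self, sets: pd.DataFrame, population: pd.DataFrame):
        pos = pd.Series(np.arange(len(population)), index=population["subject_id"])
        missing = set(sets["subject_id"]) - set(population["subject_id"])
        if missing:
            raise DataError(f"sets reference subjects absent from the population, "
                            f"e.g. {sorted(missing)[:3]}")
        s = sets.sort_values(["set_id", "role"], kind="stable")  # controls after index
        is_index = (s["role"] == "index").to_numpy()
        set_codes, _ = pd.factorize(s["set_id"], sort=True)
        self.n_sets = int(set_codes.max()) + 1 if len(set_codes) else 0
        rows = pos[s["subject_id"]].to_numpy()
        self.index_pos = rows[is_index][np.argsort(set_codes[is_index], kind="stable")]
        ctrl_codes = set_codes[~is_index]
        order = np.argsort(ctrl_codes, kind="stable")
        self.control_pos = rows[~is_index][order]
        ctrl_sorted = ctrl_codes[order]
        self.m = np.bincount(ctrl_sorted, minlength=self.n_sets).astype(np.int64)
        self.control_offsets = np.concatenate([[0], np.cumsum(self.m)[:-1]])
        if len(self.index_pos) != self.n_sets:
            raise DataError("every set must have exactly one index member")

    def control_event_counts(self, outcome: np.ndarray) -> np.ndarray:
        if self.control_pos.size == 0:
            return np.zeros(self.n_sets, dtype=np.int64)
        vals = outcome[self.control_pos]
        # reduceat needs in-range offsets; zero-control segments are overwritten
        offsets = np.minimum(self.control_offsets, vals.size - 1)
        out = np.add.reduceat(vals, offsets)
        out[self.m == 0] = 0
        return out.astype(np.int64)

    def tabulate(self, outcome: np.ndarray) -> SetTabulation:
        y1 = outcome[self.index_pos].astype(np.int64)
        k = self.control_event_counts(outcome) + y1
        return clogit.tabulate_from_arrays(self.m, k, y1)


@dataclass
class ScreenResult:
    """Fitted per-condition table for one cohort pairing."""

    cohort_label: str
    table: pd.DataFrame  # one row per retained condition
    n_index: int
    n_control: int
    excluded: list = field(default_factory=list)  # (condition_id, reason)
    config_digest: str = ""

    def result_for(self, condition_id: str) -> ORResult:
        row = self.table.loc[self.table["condition_id"] == condition_id]
        if len(row) != 1:
            raise DataError(f"condition {condition_id!r} not in screen")
        r = row.iloc[0]
        return ORResult(r["beta_hat"], r["se"], r["or"], r["ci_low"], r["ci_high"],
                        r["p_one_sided"], r["p_two_sided"], int(r["n_informative"]),
                        r["status"])


def _digest(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(str(p).encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def retained_conditions(catalog: pd.DataFrame, index_df: pd.DataFrame,
                        drop_ids=()) -> tuple[pd.DataFrame, list]:
    """Applicability filter: drop sex-restricted conditions the cohort cannot have."""
    sexes = set(index_df["sex"])
    excluded = []
    keep = []
    for _, row in catalog.iterrows():
        cid = row["condition_id"]
        if cid in set(drop_ids):
            excluded.append((cid, "dropped_by_policy"))
        elif row["sex_mask"] == "female_only" and "F" not in sexes:
            excluded.append((cid, "no_female_subjects"))
        elif row["sex_mask"] == "male_only" and "M" not in sexes:
            excluded.append((cid, "no_male_subjects"))
        else:
            keep.append(row["condition_id"])
    return catalog[catalog["condition_id"].isin(keep)], excluded


def run_screen(
    population: pd.DataFrame,
    sets: pd.DataFrame,
    catalog: pd.DataFrame,
    cohort_label: str,
    *,
    min_events: int = 5,
    drop_ids=(),
) -> ScreenResult:
    """Fit the per-condition conditional-logit screen for one cohort pairing."""
    system = SetSystem(sets, population)
    index_ids = sets.loc[sets["role"] == "index", "subject_id"]
    if not set(index_ids).issubset(set(population["subject_id"])):
        raise DataError("cohort/sets mismatch: index subjects absent from population")
    index_df = population.iloc[system.index_pos]
    control_df = population.iloc[system.control_pos]
    n_index, n_control = len(index_df), len(control_df)
    if n_index == 0:
        raise DataError("empty index cohort")

    cat, excluded = retained_conditions(catalog, index_df, drop_ids)
    rows = []
    for _, c in cat.iterrows():
        cid = c["condition_id"]
        if cid not in population.columns:
            raise DataError(f"population lacks indicator column {cid!r}")
        outcome = population[cid].to_numpy(dtype=np.int64)
        ev_index = int(outcome[system.index_pos].sum())
        ev_control = int(outcome[system.control_pos].sum())
        prev_i = ev_index / n_index
        prev_c = ev_control / n_control if n_control else float("nan")
        if ev_index + ev_control == 0:
            res = fit_conditional_logit(system.tabulate(outcome))  # no_information
        elif ev_index + ev_control < min_events:
            res = clogit.insufficient_result()
        else:
            res = fit_conditional_logit(system.tabulate(outcome))
        rows.append({
            "condition_id": cid,
            "organ_system": c["organ_system"],
            "prev_index_per100": 100 * prev_i,
            "prev_control_per100": 100 * prev_c,
            "prev_index_per1000": 1000 * prev_i,
            "prev_control_per1000": 1000 * prev_c,
            **res.as_dict(),
        })
    table = pd.DataFrame(rows)
    return ScreenResult(
        cohort_label=cohort_label,
        table=table,
        n_index=n_index,
        n_control=n_control,
        excluded=excluded,
        config_digest=_digest(cohort_label, len(population), len(sets),
                              tuple(catalog["condition_id"]), min_events),
    )


def count_significant(screen: ScreenResult, alpha: float = 0.05) -> int:
    """Conditions with one-sided p below alpha (fitted or upward-separated)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    t = screen.table
    ok = t["status"].isin([clogit.STATUS_OK, clogit.STATUS_SEPARATION_UP])
    return int((ok & (t["p_one_sided"] < alpha)).sum())


def select_validation_cohort(population: pd.DataFrame) -> pd.Series:
    """Subject ids of mothers whose CF child's birth falls in their window."""
    mask = population["child_cf_birth_month"].notna()
    return population.loc[mask, "subject_id"]


def prepare_validation_population(population: pd.DataFrame,
                                  catalog: pd.DataFrame) -> pd.DataFrame:
    """Rewrite mother records to their pre-birth window.

    Mothers' enrollment months become the months before the CF child's birth
    and their indicator columns become the pre-birth indicators, so matching
    and screening see index subjects and controls with equal observation time.
    Mothers are relabelled ``group='validation_index'``.
    """
    pop = population.copy()
    mask = pop["child_cf_birth_month"].notna().to_numpy()
    if not mask.any():
        raise DataError("no mothers with an in-window CF birth in the population")
    pre_months = pop.loc[mask, "child_cf_birth_month"].astype(int).to_numpy()
    pop.loc[mask, "enroll_months"] = pre_months
    for cid in catalog["condition_id"]:
        pre_col = f"pre_{cid}"
        if pre_col in pop.columns:
            vals = pop.loc[mask, pre_col].to_numpy()
            pop.loc[mask, cid] = vals.astype(pop[cid].dtype)
    pop.loc[mask, "group"] = "validation_index"
    return pop


def run_validation_screen(
    population: pd.DataFrame,
    catalog: pd.DataFrame,
    *,
    M: int = 5,
    seed: int = 0,
    policy: MatchPolicy = MatchPolicy(),
    min_events: int = 5,
    extra_drop_ids=(),
) -> ScreenResult:
    """Familial validation screen: mothers of CF children, pre-birth phenotype only.

    Male-only conditions (and any ids in ``extra_drop_ids``) are excluded;
    controls are matched on the mothers' pre-birth window length.
    """
    pop = prepare_validation_population(population, catalog)
    sets = build_matched_sets(pop, index_group="validation_index", M=M,
                              seed=seed, policy=policy)
    drop = list(extra_drop_ids) + list(
        catalog.loc[catalog["sex_mask"] == "male_only", "condition_id"])
    return run_screen(pop, sets, catalog, "familial_validation",
                      min_events=min_events, drop_ids=drop)
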