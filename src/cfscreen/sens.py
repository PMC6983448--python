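"""Sensitivity analyses: misclassification, empirical false discovery, ascertainment.

* ``expected_misclassified`` — closed-form expected number of true CF cases
  hidden in a genetically screened carrier cohort, given the panel's
  per-allele detection probability and the population CF:carrier ratio.
* ``misclassification_sweep`` — contamination bootstrap: pseudo-carrier
  cohorts containing ``m`` true CF subjects are matched and screened to map
  mean odds ratios as a function of contamination.
* ``empirical_fdr`` — within-set exposure-label permutation preserving every
  condition indicator (hence the full condition-condition dependence), giving
  the expected number of significant conditions under the null.
* ``ascertainment_filter`` — drops carriers whose screening was triggered by
  clinical suspicion; rerunning match+screen on the result is the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clogit
from .config import MatchPolicy
from .errors import ConfigurationError, DataError
from .matching import build_matched_sets
from .screen import ScreenResult, SetSystem, retained_conditions, run_screen


@dataclass
class MisclassConfig:
    """Grid and replication settings for the contamination sweep.

    ``panel_sensitivity`` (d) is the probability the screening panel detects a
    given mutated allele; ``cf_to_carrier_ratio`` (rho) is the CF:carrier
    ratio among the screened population.
    """

    m_grid: list[int] = field(default_factory=lambda: [0, 100, 500, 1000, 3000])
    n_reps: int = 20
    seed: int = 0
    panel_sensitivity: float = 0.9
    cf_to_carrier_ratio: float = 0.01

    def validate(self) -> "MisclassConfig":
        if sorted(self.m_grid) != list(self.m_grid) or any(m < 0 for m in self.m_grid):
            raise ConfigurationError("m_grid must be sorted nonnegative integers")
        if not 0.0 < self.panel_sensitivity < 1.0:
            raise ConfigurationError("panel_sensitivity must lie strictly in (0, 1)")
        if self.cf_to_carrier_ratio <= 0:
            raise ConfigurationError("cf_to_carrier_ratio must be positive")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        return self


@dataclass
class FdrConfig:
    alpha: float = 0.05
    n_reps: int = 500
    seed: int = 0

    def validate(self) -> "FdrConfig":
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        return self


def expected_misclassified(n_observed_carriers: int, d: float, rho: float) -> float:
    """Expected true-CF count among observed carriers.

    A true carrier is labelled carrier with probability ``d`` (its one mutated
    allele is detected); a true CF case is labelled carrier with probability
    ``2d(1-d)`` (exactly one of its two alleles detected).  With ``rho`` CF
    cases per carrier among the screened, the expected contaminated fraction
    of the labelled carrier group is ``rho*2d(1-d) / (d + rho*2d(1-d))``.
    """
    if not 0.0 < d < 1.0:
        raise ConfigurationError("panel_sensitivity d must lie strictly in (0, 1)")
    if rho <= 0:
        raise ConfigurationError("cf_to_carrier_ratio rho must be positive")
    if n_observed_carriers < 0:
        raise ConfigurationError("n_observed_carriers must be nonnegative")
    one_detect = rho * 2.0 * d * (1.0 - d)
    return n_observed_carriers * one_detect / (d + one_detect)


def misclassification_sweep(
    population: pd.DataFrame,
    catalog: pd.DataFrame,
    config: MisclassConfig,
    targets: ScreenResult | None = None,
    *,
    cohort_size: int | None = None,
    M: int = 5,
    policy: MatchPolicy = MatchPolicy(),
    min_events: int = 5,
    record_joint: bool = False,
) -> pd.DataFrame:
    """Mean simulated OR per condition at each contamination count ``m``.

    Pseudo-carrier cohorts of ``cohort_size`` draw ``m`` subjects from the
    true-CF pool and the rest from the noncarrier pool (without replacement),
    are matched 1:``M`` against the remaining noncarriers and screened.
    Common random numbers across the grid: per replicate one shuffled ordering
    of each pool, with cohort(m) = first ``cohort_size - m`` noncarriers plus
    first ``m`` CF subjects.  If ``targets`` is given, the output includes the
    smallest grid ``m`` whose mean OR reaches each condition's target OR, and,
    with ``record_joint``, the number of replicates at each ``m`` where every
    targeted condition reaches its target simultaneously.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 404])
    cf_pool = population.loc[population["true_status"] == "cf", "subject_id"].to_numpy()
    nc_pool = population.loc[
        (population["group"] == "control_pool")
        & (population["true_status"] == "noncarrier"), "subject_id"].to_numpy()
    if cohort_size is None:
        cohort_size = int((population["group"] == "carrier").sum()) or 1000
    m_max = max(config.m_grid)
    if m_max > len(cf_pool):
        raise ConfigurationError(f"m_grid maximum {m_max} exceeds CF pool {len(cf_pool)}")
    if m_max > cohort_size:
        raise ConfigurationError("m_grid maximum exceeds cohort_size")
    if cohort_size > len(nc_pool) // 2:
        raise ConfigurationError("cohort_size too large for the noncarrier pool")

    base = population[population["group"].isin(["control_pool"])
                      | (population["true_status"] == "cf")]
    or_acc: dict[tuple[int, str], list[float]] = {}
    joint_hits = {m: 0 for m in config.m_grid}
    target_or = None
    if targets is not None:
        tt = targets.table
        target_or = dict(zip(tt["condition_id"],
                             tt["or"].where(tt["status"] == clogit.STATUS_OK)))
    for rep in range(config.n_reps):
        nc_order = rng.permutation(nc_pool)
        cf_order = rng.permutation(cf_pool)
        for m in config.m_grid:
            chosen = np.concatenate([nc_order[: cohort_size - m], cf_order[:m]])
            pop = base.copy()
            pop.loc[pop["subject_id"].isin(set(chosen)), "group"] = "carrier"
            sets = build_matched_sets(
                pop, index_group="carrier", M=M,
                seed=int(rng.integers(0, 2**31)), policy=policy)
            scr = run_screen(pop, sets, catalog, "pseudo_carrier",
                             min_events=min_events)
            all_reach = True
            for _, row in scr.table.iterrows():
                cid = row["condition_id"]
                if row["status"] == clogit.STATUS_OK:
                    or_acc.setdefault((m, cid), []).append(row["or"])
                if target_or is not None:
                    tgt = target_or.get(cid)
                    if tgt is not None and not np.isnan(tgt):
                        reached = (row["status"] == clogit.STATUS_OK
                                   and row["or"] >= tgt)
                        all_reach = all_reach and reached
            if target_or is not None and all_reach:
                joint_hits[m] += 1

    rows = []
    for cid in catalog["condition_id"]:
        for m in config.m_grid:
            vals = or_acc.get((m, cid), [])
            rows.append({"condition_id": cid, "m": m,
                         "mean_or": float(np.mean(vals)) if vals else float("nan"),
                         "n_reps_estimable": len(vals)})
    out = pd.DataFrame(rows)
    if target_or is not None:
        reach = []
        for cid in catalog["condition_id"]:
            tgt = target_or.get(cid)
            sub = out[out["condition_id"] == cid]
            m_reached = None
            if tgt is not None and not np.isnan(tgt):
                hit = sub[(sub["mean_or"] >= tgt) & sub["mean_or"].notna()]
                if len(hit):
                    m_reached = int(hit["m"].min())
            reach.append(m_reached)
        tgt_map = pd.DataFrame({"condition_id": list(catalog["condition_id"]),
                                "m_reaching_target": reach})
        out = out.merge(tgt_map, on="condition_id", how="left")
        if record_joint:
            out = out.merge(pd.DataFrame({"m": list(joint_hits),
                                          "joint_target_hits": list(joint_hits.values())}),
                            on="m", how="left")
    return out


def empirical_fdr(
    population: pd.DataFrame,
    sets: pd.DataFrame,
    catalog: pd.DataFrame,
    config: FdrConfig,
    *,
    min_events: int = 5,
) -> tuple[float, np.ndarray]:
    """Mean significant-condition count under within-set exposure permutation.

    Each replicate reassigns the index label uniformly at random among every
    set's members while holding all condition indicators fixed, so marginal
    prevalences and the full condition-condition association structure are
    preserved exactly; only the exposure labelling is broken.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 505])
    system = SetSystem(sets, population)
    index_df = population.iloc[system.index_pos]
    cat, _ = retained_conditions(catalog, index_df)

    # member rows per set: index first, then that set's controls
    n_sets = system.n_sets
    sizes = system.m + 1
    members = np.empty(int(sizes.sum()), dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    members[starts] = system.index_pos
    ctrl_dest = np.concatenate(
        [np.arange(starts[i] + 1, starts[i] + sizes[i]) for i in range(n_sets)]
    ) if n_sets else np.empty(0, dtype=np.int64)
    members[ctrl_dest] = system.control_pos

    cols = [c for c in cat["condition_id"]]
    O = population[cols].to_numpy(dtype=np.int8)
    k_all = np.vstack([
        np.add.reduceat(O[members, j].astype(np.int64),
                        np.minimum(starts, members.size - 1))
        for j in range(len(cols))
    ]).T  # (n_sets, K) total events per set, permutation-invariant
    ev_tot = O[members].sum(axis=0)  # combined events per condition
    tested = ev_tot >= min_events

    counts = np.zeros(config.n_reps, dtype=np.int64)
    m_arr = system.m
    for rep in range(config.n_reps):
        pick = starts + rng.integers(0, sizes)
        chosen_rows = members[pick]
        n_sig = 0
        for j, cid in enumerate(cols):
            if not tested[j]:
                continue
            y1 = O[chosen_rows, j].astype(np.int64)
            tab = clogit.tabulate_from_arrays(m_arr, k_all[:, j], y1)
            res = clogit.fit_conditional_logit(tab)
            if res.status in (clogit.STATUS_OK, clogit.STATUS_SEPARATION_UP) \
                    and res.p_one_sided < config.alpha:
                n_sig += 1
        counts[rep] = n_sig
    return float(counts.mean()), counts


def ascertainment_filter(population: pd.DataFrame) -> pd.DataFrame:
    """Drop carriers flagged as screened for clinical suspicion of CF."""
    if "suspicion_flag" not in population.columns:
        raise DataError("population lacks suspicion_flag")
    drop = (population["group"] == "carrier") & population["suspicion_flag"]
    return population[~drop].reset_index(drop=True)
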