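"""Carrier-vs-CF effect-profile comparison and multimorbidity burden analysis.

Two quantifications of the "muted phenotype":

* across conditions, the Pearson correlation and OLS slope of carrier natural
  log odds ratios on CF natural log odds ratios (the attenuation slope);
* per subject, the number of distinct conditions and distinct organ systems
  affected, bucketed and compared between index subjects and matched controls
  with the same conditional-logit machinery as the per-condition screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import clogit
from .errors import ConfigurationError, DataError
from .screen import ScreenResult, SetSystem

CONDITION_BUCKETS = ["0", "1-2", "3-4", "5-6", "7-8", "9-10", ">10"]
_CONDITION_EDGES = [0, 1, 3, 5, 7, 9, 11, np.inf]  # left-closed
SYSTEM_BUCKETS = ["0", "1", "2", "3", "4", ">4"]
_SYSTEM_EDGES = [0, 1, 2, 3, 4, 5, np.inf]


@dataclass
class ComparisonResult:
    pearson_r: float
    slope: float
    intercept: float
    slope_p: float
    n_conditions_used: int
    excluded_conditions: list = field(default_factory=list)  # (condition_id, reason)


def compare_log_ors(
    screen_carrier: ScreenResult,
    screen_cf: ScreenResult,
    *,
    weighted: bool = False,
) -> ComparisonResult:
    """Correlation and regression of carrier log ORs on CF log ORs.

    Only conditions estimable (status ``ok``) in both screens enter; the rest
    are listed with reasons.  The default regression is unweighted OLS; with
    ``weighted=True`` each condition is weighted by the inverse of the summed
    squared standard errors of its two log ORs.
    """
    a = screen_carrier.table.set_index("condition_id")
    b = screen_cf.table.set_index("condition_id")
    shared = [c for c in a.index if c in b.index]
    excluded = [(c, "missing_in_cf_screen") for c in a.index if c not in b.index]
    excluded += [(c, "missing_in_carrier_screen") for c in b.index if c not in a.index]
    xs, ys, ws = [], [], []
    for c in shared:
        sa, sb = a.loc[c, "status"], b.loc[c, "status"]
        if sa != clogit.STATUS_OK:
            excluded.append((c, f"carrier_{sa}"))
        elif sb != clogit.STATUS_OK:
            excluded.append((c, f"cf_{sb}"))
        else:
            ys.append(a.loc[c, "beta_hat"])
            xs.append(b.loc[c, "beta_hat"])
            ws.append(1.0 / (a.loc[c, "se"] ** 2 + b.loc[c, "se"] ** 2))
    n = len(xs)
    if n < 3:
        raise DataError(f"only {n} usable log-OR pairs; need at least 3")
    x, y, w = np.asarray(xs), np.asarray(ys), np.asarray(ws)
    r = float(stats.pearsonr(x, y)[0])
    if weighted:
        slope, intercept, p = _wls(x, y, w)
    else:
        fit = stats.linregress(x, y)
        slope, intercept, p = float(fit.slope), float(fit.intercept), float(fit.pvalue)
    return ComparisonResult(r, slope, intercept, p, n, excluded)


def _wls(x, y, w):
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    dof = len(x) - 2
    s2 = float(resid @ (w * resid)) / dof
    cov = s2 * np.linalg.inv(xtwx)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[1]), float(beta[0]), float(p)


def burden_counts(population: pd.DataFrame, catalog: pd.DataFrame,
                  cohort_ids=None) -> pd.DataFrame:
    """Per subject: number of distinct conditions and distinct organ systems."""
    pop = population
    if cohort_ids is not None:
        pop = pop[pop["subject_id"].isin(set(cohort_ids))]
    cids = list(catalog["condition_id"])
    X = pop[cids].to_numpy(dtype=np.int64)
    n_cond = X.sum(axis=1)
    systems = catalog["organ_system"].to_numpy()
    n_sys = np.zeros(len(pop), dtype=np.int64)
    for s in pd.unique(systems):
        cols = [c for c, ss in zip(cids, systems) if ss == s]
        n_sys += pop[cols].to_numpy(dtype=np.int64).max(axis=1)
    return pd.DataFrame({
        "subject_id": pop["subject_id"].to_numpy(),
        "n_conditions": n_cond,
        "n_systems": n_sys,
    })


def bucket_labels(axis: str) -> list[str]:
    if axis == "conditions":
        return CONDITION_BUCKETS
    if axis == "systems":
        return SYSTEM_BUCKETS
    raise ConfigurationError(f"unknown burden axis {axis!r}")


def assign_buckets(counts: np.ndarray, axis: str) -> np.ndarray:
    """Map per-subject counts to bucket labels (every count falls in exactly one)."""
    edges = _CONDITION_EDGES if axis == "conditions" else _SYSTEM_EDGES
    labels = bucket_labels(axis)
    idx = np.searchsorted(edges, np.asarray(counts), side="right") - 1
    return np.asarray(labels, dtype=object)[idx]


@dataclass
class BurdenResult:
    axis: str
    table: pd.DataFrame  # bucket, n_index, pct_index, n_control, pct_control, OR fields
    n_index: int
    n_control: int


def burden_percent(n: int, total: int) -> float:
    """Bucket percentage as printed in summary tables (2 dp)."""
    return round(100.0 * n / total, 2)


def burden_ors(
    population: pd.DataFrame,
    sets: pd.DataFrame,
    catalog: pd.DataFrame,
    axis: str = "conditions",
) -> BurdenResult:
    """Bucket-membership odds ratios on the same matched sets as the screen."""
    labels = bucket_labels(axis)
    counts = burden_counts(population, catalog)
    col = "n_conditions" if axis == "conditions" else "n_systems"
    per_subject = pd.Series(counts[col].to_numpy(), index=counts["subject_id"])
    vals = per_subject.reindex(population["subject_id"]).to_numpy()
    bucket = assign_buckets(vals, axis)

    system = SetSystem(sets, population)
    n_index, n_control = len(system.index_pos), len(system.control_pos)
    rows = []
    for lab in labels:
        outcome = (bucket == lab).astype(np.int64)
        ni = int(outcome[system.index_pos].sum())
        nc = int(outcome[system.control_pos].sum())
        res = clogit.fit_conditional_logit(system.tabulate(outcome))
        rows.append({
            "bucket": lab,
            "n_index": ni,
            "pct_index": burden_percent(ni, n_index),
            "n_control": nc,
            "pct_control": burden_percent(nc, n_control) if n_control else float("nan"),
            **res.as_dict(),
        })
    return BurdenResult(axis, pd.DataFrame(rows), n_index, n_control)
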