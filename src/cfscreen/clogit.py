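"""Exact conditional likelihood for a single binary exposure in 1:M matched sets.

Each matched set contains one index subject (the exposed member) and ``m``
controls.  Conditioning on the total number of diagnosed members ``k`` in the
set eliminates the set-level nuisance parameter and leaves, for a set with
index outcome ``y1``::

    l(beta) = beta*y1 - log( C(m, k-1)*exp(beta) + C(m, k) )

with ``C(m, -1) = 0``.  Sets with all-zero or all-one outcomes carry no
information about ``beta`` and contribute nothing.  The log-likelihood is
concave; the maximizer is found by safeguarded Newton iteration with a
bisection fallback on the monotone score function.

Sufficient statistics are the counts of sets by ``(m, k, y1)``, so whole
screens reduce to tiny tabulations regardless of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import DataError

Z975 = 1.959964  # two-sided 95% normal quantile

STATUS_OK = "ok"
STATUS_NO_INFORMATION = "no_information"
STATUS_SEPARATION_UP = "separation_up"
STATUS_SEPARATION_DOWN = "separation_down"
STATUS_INSUFFICIENT = "insufficient_data"


def _is_informative(m: int, k: int) -> bool:
    return 1 <= k <= m


@dataclass(frozen=True)
class SetTabulation:
    """Counts of matched sets keyed by (m controls, k total events, index event y1)."""

    counts: Mapping[tuple[int, int, int], int]

    def __post_init__(self):
        for (m, k, y1), w in self.counts.items():
            if w < 0:
                raise DataError(f"negative multiplicity for cell {(m, k, y1)}")
            if not (0 <= k <= m + 1 and 0 <= y1 <= 1 and y1 <= k and k - y1 <= m):
                raise DataError(f"invalid tabulation cell {(m, k, y1)}")

    @property
    def n_sets_total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_sets_informative(self) -> int:
        return int(sum(w for (m, k, _), w in self.counts.items() if _is_informative(m, k)))

    def informative_items(self) -> list[tuple[int, int, int, int]]:
        return [
            (m, k, y1, w)
            for (m, k, y1), w in sorted(self.counts.items())
            if w > 0 and _is_informative(m, k)
        ]


@dataclass(frozen=True)
class ORResult:
    """Per-condition conditional odds-ratio estimate.

    ``p_one_sided`` tests OR > 1 (Wald, 1 - Phi(beta/se)) when status is
    ``ok``; under separation it is the exact permutation tail probability of
    the observed index-event pattern given the per-set event totals.
    """

    beta_hat: float
    se: float
    or_hat: float
    ci_low: float
    ci_high: float
    p_one_sided: float
    p_two_sided: float
    n_informative: int
    status: str

    def as_dict(self) -> dict:
        return {
            "beta_hat": self.beta_hat, "se": self.se, "or": self.or_hat,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_one_sided": self.p_one_sided, "p_two_sided": self.p_two_sided,
            "n_informative": self.n_informative, "status": self.status,
        }


def tabulate_from_arrays(m, k, y1) -> SetTabulation:
    """Build a SetTabulation from per-set arrays of (m, k, y1)."""
    m = np.asarray(m, dtype=np.int64)
    k = np.asarray(k, dtype=np.int64)
    y1 = np.asarray(y1, dtype=np.int64)
    key = (m * (m.max(initial=0) + 2) + k) * 2 + y1
    uniq, counts = np.unique(key, return_counts=True)
    base = int(m.max(initial=0)) + 2
    out: dict[tuple[int, int, int], int] = {}
    for u, w in zip(uniq.tolist(), counts.tolist()):
        yy = u % 2
        mk = u // 2
        out[(mk // base, mk % base, yy)] = w
    return SetTabulation(out)


def tabulate_sets(sets, outcomes: Mapping[str, int]) -> SetTabulation:
    """Reduce matched sets plus a subject->0/1 outcome map to sufficient statistics.

    ``sets`` is the long-form table produced by :func:`cfscreen.matching.build_matched_sets`
    (columns set_id, subject_id, role).  Every subject must have an outcome.
    """
    get = outcomes.get
    per_set: dict[str, list[int]] = {}
    m_arr, k_arr, y_arr = [], [], []
    for set_id, sub, role in zip(sets["set_id"], sets["subject_id"], sets["role"]):
        y = get(sub)
        if y is None:
            raise DataError(f"missing outcome for subject {sub!r}")
        rec = per_set.setdefault(set_id, [0, 0, 0])  # m, k, y1
        if role == "index":
            rec[2] = int(y)
        else:
            rec[0] += 1
        rec[1] += int(y)
    for m, k, y1 in per_set.values():
        m_arr.append(m)
        k_arr.append(k)
        y_arr.append(y1)
    return tabulate_from_arrays(m_arr, k_arr, y_arr)


def conditional_loglik(tab: SetTabulation, beta: float) -> float:
    """Sum of per-set conditional log-likelihood contributions at ``beta``."""
    total = 0.0
    for m, k, y1, w in tab.informative_items():
        a = math.comb(m, k - 1)
        b = math.comb(m, k)
        total += w * (beta * y1 - np.logaddexp(beta + math.log(a), math.log(b)))
    return float(total)


def _score_info(items, beta: float) -> tuple[float, float]:
    score = 0.0
    info = 0.0
    for a, b, y1, w in items:
        pi = expit(beta + math.log(a) - math.log(b))
        score += w * (y1 - pi)
        info += w * pi * (1.0 - pi)
    return score, info


_NAN = float("nan")


def fit_conditional_logit(
    tab: SetTabulation,
    *,
    tol: float = 1e-10,
    max_iter: int = 50,
    bracket: tuple[float, float] = (-30.0, 30.0),
) -> ORResult:
    """Maximize the conditional likelihood for one binary exposure.

    Degenerate tabulations map to status codes: no informative sets ->
    ``no_information``; all informative index outcomes 1 (resp. 0) ->
    ``separation_up`` (``separation_down``) with an exact permutation
    one-sided p-value and no point estimate.
    """
    items_raw = tab.informative_items()
    n_inf = tab.n_sets_informative
    if n_inf == 0:
        return ORResult(_NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN, 0, STATUS_NO_INFORMATION)

    ys = {y1 for (_, _, y1, _) in items_raw}
    if ys == {1}:
        # MLE at +inf; exact null tail: P(all indexes diseased | event totals)
        logp = sum(w * math.log(k / (m + 1)) for m, k, _, w in items_raw)
        p1 = math.exp(logp)
        return ORResult(_NAN, _NAN, _NAN, _NAN, _NAN, p1, min(1.0, 2 * p1),
                        n_inf, STATUS_SEPARATION_UP)
    if ys == {0}:
        # MLE at -inf; observed statistic is minimal, upper tail is certain
        logp = sum(w * math.log(1.0 - k / (m + 1)) for m, k, _, w in items_raw)
        p2 = math.exp(logp)
        return ORResult(_NAN, _NAN, _NAN, _NAN, _NAN, 1.0, min(1.0, 2 * p2),
                        n_inf, STATUS_SEPARATION_DOWN)

    items = [(math.comb(m, k - 1), math.comb(m, k), y1, w) for m, k, y1, w in items_raw]
    lo, hi = bracket
    beta = 0.0
    for _ in range(max_iter):
        score, info = _score_info(items, beta)
        if abs(score) < tol or hi - lo < 1e-13:
            break
        if score > 0:  # score is decreasing in beta
            lo = beta
        else:
            hi = beta
        step = score / info if info > 0 else 0.0
        beta_new = beta + step
        if not (lo < beta_new < hi):
            beta_new = 0.5 * (lo + hi)
        beta = beta_new
    _, info = _score_info(items, beta)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    return ORResult(
        beta_hat=beta,
        se=se,
        or_hat=math.exp(beta),
        ci_low=math.exp(beta - Z975 * se),
        ci_high=math.exp(beta + Z975 * se),
        p_one_sided=float(norm.sf(z)),
        p_two_sided=float(2 * norm.sf(abs(z))),
        n_informative=n_inf,
        status=STATUS_OK,
    )


def insufficient_result(n_informative: int = 0) -> ORResult:
    """Placeholder result for conditions below the minimum-event floor."""
    return ORResult(_NAN, _NAN, _NAN, _NAN, _NAN, _NAN, _NAN,
                    int(n_informative), STATUS_INSUFFICIENT)


def prevalence(outcomes: Mapping[str, int] | Iterable[int], cohort_ids=None) -> float:
    """Fraction of a cohort with the condition (scale to per-100/per-1,000 in reports)."""
    if cohort_ids is not None:
        vals = [outcomes[i] for i in cohort_ids]
    else:
        vals = list(outcomes.values()) if isinstance(outcomes, Mapping) else list(outcomes)
    if len(vals) == 0:
        raise DataError("prevalence of an empty cohort is undefined")
    return float(np.mean(vals))
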