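"""Conditional-likelihood correctness: closed forms, enumeration oracle, degeneracies."""

import itertools
import math

import numpy as np
import pytest

from cfscreen.clogit import (
    STATUS_NO_INFORMATION,
    STATUS_OK,
    STATUS_SEPARATION_DOWN,
    STATUS_SEPARATION_UP,
    SetTabulation,
    conditional_loglik,
    fit_conditional_logit,
    prevalence,
    tabulate_from_arrays,
    tabulate_sets,
)
from cfscreen.errors import DataError


def random_tabulation(rng, max_m=5, max_count=20) -> SetTabulation:
    counts = {}
    for _ in range(int(rng.integers(2, 8))):
        m = int(rng.integers(1, max_m + 1))
        k = int(rng.integers(0, m + 2))
        y1 = int(rng.integers(0, 2))
        if y1 <= k and k - y1 <= m:
            counts[(m, k, y1)] = counts.get((m, k, y1), 0) + int(rng.integers(1, max_count))
    return SetTabulation(counts)


def enumeration_loglik(tab: SetTabulation, beta: float) -> float:
    """Independent oracle: sum over all C(m+1, k) event placements per set."""
    total = 0.0
    for (m, k, y1), w in tab.counts.items():
        if not 1 <= k <= m:
            continue
        denom = sum(
            math.exp(beta * (0 in picks))
            for picks in itertools.combinations(range(m + 1), k)
        )
        total += w * (beta * y1 - math.log(denom))
    return total


def grid_argmax(tab: SetTabulation, lo=-8.0, hi=8.0, step=1e-4) -> float:
    """Independent oracle: dense grid search of the closed-form log-likelihood."""
    grid = np.arange(lo, hi, step)
    items = tab.informative_items()
    a = np.array([math.comb(m, k - 1) for m, k, _, _ in items], float)
    b = np.array([math.comb(m, k) for m, k, _, _ in items], float)
    y = np.array([y1 for _, _, y1, _ in items], float)
    w = np.array([w for _, _, _, w in items], float)
    ll = (w * (grid[:, None] * y - np.logaddexp(grid[:, None] + np.log(a), np.log(b)))).sum(axis=1)
    return float(grid[np.argmax(ll)])


class TestLoglik:
    def test_uniform_null_single_set(self):
        tab = SetTabulation({(5, 1, 1): 1})
        assert conditional_loglik(tab, 0.0) == pytest.approx(-math.log(6))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            tab = random_tabulation(rng)
            for beta in (-1.3, 0.0, 0.7, 2.1):
                assert conditional_loglik(tab, beta) == pytest.approx(
                    enumeration_loglik(tab, beta), abs=1e-9)

    def test_noninformative_sets_contribute_zero(self):
        tab = SetTabulation({(5, 0, 0): 4, (5, 6, 1): 2})
        assert conditional_loglik(tab, 1.7) == 0.0

    def test_concavity_on_grid(self, rng):
        for _ in range(10):
            tab = random_tabulation(rng)
            grid = np.linspace(-6, 6, 201)
            ll = np.array([conditional_loglik(tab, b) for b in grid])
            assert np.all(np.diff(ll, 2) <= 1e-8)


class TestFit:
    def test_one_to_one_discordant_closed_form(self):
        res = fit_conditional_logit(SetTabulation({(1, 1, 1): 10, (1, 1, 0): 5}))
        assert res.beta_hat == pytest.approx(math.log(2.0), abs=1e-9)
        assert res.or_hat == pytest.approx(2.0, abs=1e-8)
        assert res.se == pytest.approx(math.sqrt(1 / 10 + 1 / 5), abs=1e-9)

    def test_null_balanced_configuration(self):
        res = fit_conditional_logit(SetTabulation({(5, 1, 1): 1, (5, 1, 0): 5}))
        assert res.beta_hat == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(60):
            tab = random_tabulation(rng)
            res = fit_conditional_logit(tab)
            if res.status != STATUS_OK:
                continue
            assert abs(res.beta_hat - grid_argmax(tab, step=1e-3)) <= 1e-2

    def test_matches_statsmodels_conditional_logit(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        groups, y, x = [], [], []
        for s in range(300):
            y1 = int(rng.random() < 0.3)
            kc = int(rng.binomial(5, 0.15))
            out = [y1] + [1] * kc + [0] * (5 - kc)
            groups += [s] * 6
            y += out
            x += [1] + [0] * 5
        ref = sm.ConditionalLogit(np.array(y), np.array(x)[:, None],
                                  groups=np.array(groups)).fit(disp=0)
        m = np.full(300, 5)
        ks = np.add.reduceat(np.array(y), np.arange(0, 1800, 6))
        y1s = np.array(y)[::6]
        mine = fit_conditional_logit(tabulate_from_arrays(m, ks, y1s))
        assert mine.beta_hat == pytest.approx(ref.params[0], abs=1e-4)
        assert mine.se == pytest.approx(ref.bse[0], abs=1e-4)

    def test_wald_interval_and_one_sided_p(self):
        res = fit_conditional_logit(SetTabulation({(1, 1, 1): 10, (1, 1, 0): 5}))
        assert res.ci_low <= res.or_hat <= res.ci_high
        from scipy.stats import norm
        assert res.p_one_sided == pytest.approx(norm.sf(res.beta_hat / res.se))

    def test_no_information(self):
        res = fit_conditional_logit(SetTabulation({(5, 0, 0): 10, (5, 6, 1): 3}))
        assert res.status == STATUS_NO_INFORMATION
        assert res.n_informative == 0

    def test_separation_up_exact_permutation_p(self):
        res = fit_conditional_logit(SetTabulation({(5, 1, 1): 2}))
        assert res.status == STATUS_SEPARATION_UP
        assert math.isnan(res.beta_hat)
        assert res.p_one_sided == pytest.approx((1 / 6) ** 2)

    def test_separation_down(self):
        res = fit_conditional_logit(SetTabulation({(5, 1, 0): 3}))
        assert res.status == STATUS_SEPARATION_DOWN
        assert res.p_one_sided == 1.0


class TestTabulate:
    def test_direct_count_and_conservation(self, rng):
        import pandas as pd
        rows = [("s0", "i0", "index")] + [(f"s0", f"c{j}", "control") for j in range(5)]
        sets = pd.DataFrame(rows, columns=["set_id", "subject_id", "role"])
        outcomes = {"i0": 1, **{f"c{j}": 0 for j in range(5)}}
        tab = tabulate_sets(sets, outcomes)
        assert tab.counts == {(5, 1, 1): 1}
        assert tab.n_sets_total == 1 and tab.n_sets_informative == 1

    def test_concordant_zero_set_flagged_noninformative(self):
        import pandas as pd
        rows = [("s0", "i0", "index")] + [("s0", f"c{j}", "control") for j in range(4)]
        sets = pd.DataFrame(rows, columns=["set_id", "subject_id", "role"])
        tab = tabulate_sets(sets, {sid: 0 for sid in ["i0", "c0", "c1", "c2", "c3"]})
        assert tab.n_sets_total == 1 and tab.n_sets_informative == 0

    def test_missing_outcome_names_subject(self):
        import pandas as pd
        sets = pd.DataFrame([("s0", "i0", "index"), ("s0", "c0", "control")],
                            columns=["set_id", "subject_id", "role"])
        with pytest.raises(DataError, match="c0"):
            tabulate_sets(sets, {"i0": 1})

    def test_control_order_invariance(self, rng):
        """Permuting member rows within sets leaves the tabulation identical."""
        import pandas as pd
        rows = []
        outcomes = {}
        for s in range(50):
            rows.append((f"s{s}", f"i{s}", "index"))
            outcomes[f"i{s}"] = int(rng.random() < 0.4)
            for j in range(5):
                rows.append((f"s{s}", f"c{s}_{j}", "control"))
                outcomes[f"c{s}_{j}"] = int(rng.random() < 0.2)
        sets = pd.DataFrame(rows, columns=["set_id", "subject_id", "role"])
        shuffled = sets.sample(frac=1.0, random_state=3)
        a = tabulate_sets(sets, outcomes)
        b = tabulate_sets(shuffled, outcomes)
        assert a.counts == b.counts
        ra, rb = fit_conditional_logit(a), fit_conditional_logit(b)
        assert ra == rb


class TestPrevalence:
    def test_reported_cohort_fraction(self):
        # 5,819 positives among 19,802 enrollees -> 29.39 per 100 at 2 dp
        outcomes = dict(enumerate([1] * 5819 + [0] * (19802 - 5819)))
        assert round(100 * prevalence(outcomes), 2) == 29.39

    @pytest.mark.parametrize("positives,total,expected", [(0, 10, 0.0), (7, 7, 100.0)])
    def test_edge_fractions(self, positives, total, expected):
        vals = [1] * positives + [0] * (total - positives)
        assert 100 * prevalence(vals) == expected

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(DataError):
            prevalence({})
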