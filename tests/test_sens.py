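"""Sensitivity analyses: misclassification formula and sweep, permutation FDR,
ascertainment filtering."""

import numpy as np
import pandas as pd
import pytest

from cfscreen.config import GeneratorConfig
from cfscreen.errors import ConfigurationError
from cfscreen.matching import build_matched_sets
from cfscreen.screen import run_screen
from cfscreen.sens import (
    FdrConfig,
    MisclassConfig,
    ascertainment_filter,
    empirical_fdr,
    expected_misclassified,
    misclassification_sweep,
)
from cfscreen.synth import generate_catalog, generate_population


class TestExpectedMisclassified:
    def test_direct_arithmetic(self):
        # n * rho*2d(1-d) / (d + rho*2d(1-d)) at the reference point
        val = expected_misclassified(19802, 0.9, 0.01)
        assert val == pytest.approx(19802 * 0.0018 / 0.9018, abs=1e-9)
        assert val == pytest.approx(39.5, abs=0.1)

    def test_perfect_panel_limit(self):
        assert expected_misclassified(19802, 1 - 1e-9, 0.01) == pytest.approx(0.0, abs=1e-3)

    def test_monotone_decreasing_in_sensitivity(self):
        grid = np.linspace(0.55, 0.99, 23)
        vals = [expected_misclassified(19802, d, 0.01) for d in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_bounded_by_cohort_size(self):
        for d in (0.2, 0.5, 0.9):
            for rho in (0.001, 0.1, 5.0):
                assert 0 <= expected_misclassified(1000, d, rho) <= 1000

    def test_invalid_sensitivity(self):
        for d in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ConfigurationError):
                expected_misclassified(100, d, 0.01)


@pytest.fixture(scope="module")
def sweep_inputs():
    cfg = GeneratorConfig(n_carriers=20, n_cf=500, n_control_pool=20000,
                          n_conditions=8, p0_range=(0.03, 0.1),
                          beta_cf_range=(1.5, 2.5), frailty_sd=0.3,
                          n_female_only=0, n_male_only=0, n_adult_only=0,
                          family_link_rate=0.0, seed=13)
    cat = generate_catalog(cfg)
    pop = generate_population(cat, cfg)
    return cat, pop


class TestMisclassificationSweep:
    def test_null_and_total_contamination_and_monotonicity(self, sweep_inputs):
        cat, pop = sweep_inputs
        size = 300
        sweep = misclassification_sweep(
            pop, cat, MisclassConfig(m_grid=[0, 150, 300], n_reps=8, seed=1),
            cohort_size=size)
        mean_log = (sweep.assign(l=np.log(sweep["mean_or"]))
                    .groupby("m")["l"].mean())
        # m=0: pseudo-carriers and controls share a pool -> OR ~ 1
        assert abs(mean_log[0]) < 0.1
        # full contamination approaches the direct CF-vs-control effect
        cf_sets = build_matched_sets(pop, "cf", M=5, seed=99)
        cf_scr = run_screen(pop, cf_sets, cat, "cf").table
        direct = np.log(cf_scr.loc[cf_scr["status"] == "ok", "or"]).mean()
        assert abs(mean_log[300] - direct) < 0.25
        # aggregate monotone in m
        assert mean_log[0] < mean_log[150] < mean_log[300]
        # per-condition: full contamination beats none for every gamma > 0
        wide = sweep.pivot(index="condition_id", columns="m", values="mean_or")
        assert (wide[300] > wide[0]).all()

    def test_targets_and_reachability(self, sweep_inputs):
        cat, pop = sweep_inputs
        cf_sets = build_matched_sets(pop, "cf", M=5, seed=99)
        cf_scr = run_screen(pop, cf_sets, cat, "cf")
        sweep = misclassification_sweep(
            pop, cat, MisclassConfig(m_grid=[0, 300], n_reps=4, seed=2),
            targets=cf_scr, cohort_size=300, record_joint=True)
        assert "m_reaching_target" in sweep.columns
        assert "joint_target_hits" in sweep.columns

    def test_grid_exceeding_pool_is_an_error(self, sweep_inputs):
        cat, pop = sweep_inputs
        with pytest.raises(ConfigurationError):
            misclassification_sweep(
                pop, cat, MisclassConfig(m_grid=[0, 10**6], n_reps=1, seed=0),
                cohort_size=300)


@pytest.fixture(scope="module")
def fdr_inputs():
    # default p0_range: the screened conditions are mostly rare, as in the
    # claims setting the generator emulates
    cfg = GeneratorConfig(n_carriers=1000, n_cf=20, n_control_pool=40000,
                          n_conditions=20,
                          beta_cf_range=(1.0, 2.0), frailty_sd=0.6,
                          n_female_only=1, n_male_only=1, n_adult_only=2, seed=17)
    cat = generate_catalog(cfg)
    pop = generate_population(cat, cfg)
    sets = build_matched_sets(pop, "carrier", M=5, seed=17)
    return cat, pop, sets


class TestEmpiricalFdr:
    def test_outcomes_untouched_and_alpha_limit(self, fdr_inputs):
        cat, pop, sets = fdr_inputs
        cols = list(cat["condition_id"])
        before = pop[cols].to_numpy().copy()
        assoc_before = np.corrcoef(before.T)
        mean, counts = empirical_fdr(pop, sets, cat,
                                     FdrConfig(alpha=1e-12, n_reps=20, seed=1))
        assert mean == 0.0 and (counts == 0).all()
        after = pop[cols].to_numpy()
        assert np.array_equal(before, after)
        assert np.array_equal(assoc_before, np.corrcoef(after.T))

    def test_mean_count_bounded_by_alpha_k(self, fdr_inputs):
        """Within-set permutation null: E[#significant] <= alpha * K."""
        cat, pop, sets = fdr_inputs
        cfg = FdrConfig(alpha=0.05, n_reps=200, seed=3)
        mean, counts = empirical_fdr(pop, sets, cat, cfg)
        k_tested = len(cat) - 0  # all conditions retained for the mixed cohort
        assert len(counts) == 200
        assert mean <= cfg.alpha * k_tested

    def test_frailty_does_not_break_validity_bound(self):
        """Doubling within-system correlation leaves E[count] <= alpha*K."""
        means = []
        for frailty in (0.5, 1.0):
            cfg = GeneratorConfig(n_carriers=1000, n_cf=20, n_control_pool=30000,
                                  n_conditions=12,
                                  beta_cf_range=(1.0, 2.0), frailty_sd=frailty,
                                  n_female_only=0, n_male_only=0, n_adult_only=0,
                                  seed=23)
            cat = generate_catalog(cfg)
            pop = generate_population(cat, cfg)
            sets = build_matched_sets(pop, "carrier", M=5, seed=23)
            mean, counts = empirical_fdr(pop, sets, cat,
                                         FdrConfig(alpha=0.05, n_reps=120, seed=5))
            means.append((mean, counts.std(ddof=1) / np.sqrt(len(counts))))
        # bound holds within simulation error at either correlation strength
        assert all(m <= 0.05 * 12 + 3 * se for m, se in means)


class TestAscertainmentFilter:
    def test_identity_when_unflagged(self, small_population):
        pop = small_population.copy()
        pop["suspicion_flag"] = False
        out = ascertainment_filter(pop)
        pd.testing.assert_frame_equal(out, pop.reset_index(drop=True))

    def test_all_flagged_empties_index_cohort(self, small_population):
        pop = small_population.copy()
        pop.loc[pop["group"] == "carrier", "suspicion_flag"] = True
        out = ascertainment_filter(pop)
        assert (out["group"] == "carrier").sum() == 0
        with pytest.raises(ConfigurationError, match="no index subjects"):
            build_matched_sets(out, "carrier", M=5, seed=0)

    def test_planted_bias_recovery(self):
        """Suspicion flags targeting respiratory disease deflate respiratory ORs
        once flagged carriers are removed."""
        diffs = []
        for seed in range(3):
            cfg = GeneratorConfig(n_carriers=700, n_cf=10, n_control_pool=25000,
                                  n_conditions=16, p0_range=(0.03, 0.12),
                                  beta_cf_range=(1.0, 2.0), frailty_sd=0.4,
                                  suspicion_base=0.02, suspicion_extra=0.6,
                                  suspicion_system="respiratory",
                                  n_female_only=0, n_male_only=0, n_adult_only=0,
                                  seed=31 + seed)
            cat = generate_catalog(cfg)
            cat["beta_carrier"] = 0.4 * cat["beta_cf"]
            pop = generate_population(cat, cfg)
            resp = cat.loc[cat["organ_system"] == "respiratory", "condition_id"]

            def resp_log_or(p):
                sets = build_matched_sets(p, "carrier", M=5, seed=seed)
                t = run_screen(p, sets, cat, "carrier").table
                t = t[t["condition_id"].isin(set(resp)) & (t["status"] == "ok")]
                return np.log(t["or"]).mean()

            diffs.append(resp_log_or(pop) - resp_log_or(ascertainment_filter(pop)))
        assert np.mean(diffs) > 0
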