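"""Yoked probabilities, trembling-hand likelihood, MCMC fits, PSIS."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import sdtbandit as sb
from sdtbandit.belief import LogisticBelief, posterior_p_samples, update_belief
from sdtbandit.choice_fit import (
    CANDIDATE_STRATEGIES,
    ChoiceModelSpec,
    FitSettings,
    compute_yoked_probabilities,
    compute_yoked_tables,
    fit_model,
    log_likelihood,
    psis_compare,
    recovery_study,
)

from conftest import make_short_treatment

FAST = FitSettings(n_walkers=16, n_steps=1500, n_burn=750, thin=5, seed=0)


@pytest.fixture(scope="module")
def cohort():
    return sb.generate_cohort(sb.PolicySpec("softmax", tau=0.37),
                              make_short_treatment(15), 3,
                              trembling_eps=0.2, sigma_q=0.8, seed=4)


class TestYokedTables:
    def test_random_strategy_is_constant_half(self, cohort):
        table = compute_yoked_probabilities(cohort, "random")
        assert np.all(table.values == 0.5)

    def test_greedy_first_trial_tie_rejects(self, cohort):
        """With an empty history the plug-in posterior mean is exactly 0.5,
        so at b = c the expected payoff is exactly 0 and greedy's strict
        rule emits 0."""
        table = compute_yoked_probabilities(cohort, "greedy")
        first = cohort.groupby("volunteer_id", sort=False).head(1).index
        assert np.all(table.values[np.asarray(first)] == 0.0)

    def test_softmax_stores_expected_payoff(self, cohort):
        table = compute_yoked_probabilities(cohort, "softmax")
        assert table.kind == "value"
        first = cohort.groupby("volunteer_id", sort=False).head(1).index
        assert np.allclose(table.values[np.asarray(first)], 0.0, atol=1e-12)

    def test_deterministic_given_mc_seed(self, cohort):
        a = compute_yoked_probabilities(cohort, "thompson", mc_seed=9)
        b = compute_yoked_probabilities(cohort, "thompson", mc_seed=9)
        c = compute_yoked_probabilities(cohort, "thompson", mc_seed=10)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_softmax_invariant_to_mc_seed(self, cohort):
        a = compute_yoked_probabilities(cohort, "softmax", mc_seed=9)
        b = compute_yoked_probabilities(cohort, "softmax", mc_seed=123)
        assert np.array_equal(a.values, b.values)

    def test_thompson_matches_enumeration_on_three_draws(self, cohort):
        """With n_draws = 3 the Thompson entry must equal the exhaustive
        enumeration over the three sampled p values."""
        table = compute_yoked_probabilities(cohort, "thompson", mc_seed=5,
                                            n_draws=3)
        assert set(np.round(table.values * 3).astype(int)) <= {0, 1, 2, 3}
        # reconstruct the draws for one volunteer and enumerate
        vid = table.volunteer_ids[0]
        sub = cohort[cohort["volunteer_id"] == vid].reset_index(drop=True)
        rng = np.random.default_rng(np.random.SeedSequence([5, 0]))
        belief = LogisticBelief.prior()
        hist = []
        for i, row in sub.iterrows():
            draws = posterior_p_samples(belief, row["x"], 3, rng)
            expected = np.mean(draws > 0.5)
            assert table.values[i] == pytest.approx(expected, abs=1e-12)
            if row["accepted"]:
                hist.append((row["x"], row["is_good"]))
                belief = update_belief(hist)

    def test_unordered_trials_rejected(self, cohort):
        shuffled = cohort.sample(frac=1.0, random_state=0)
        with pytest.raises(ValueError):
            compute_yoked_probabilities(shuffled, "random")

    def test_yoking_follows_realized_acceptances(self, cohort):
        """Midpoint entries flip from the bootstrap 1.0 only after the
        volunteer has actually accepted one signaller of each type."""
        table = compute_yoked_probabilities(cohort, "midpoint")
        for vid in table.volunteer_ids:
            sub = cohort[cohort["volunteer_id"] == vid].reset_index(drop=True)
            seen_good = (sub["accepted"] & sub["is_good"]).cumsum().shift(
                fill_value=0)
            seen_bad = (sub["accepted"] & ~sub["is_good"]).cumsum().shift(
                fill_value=0)
            boot = (seen_good == 0) | (seen_bad == 0)
            vals = table.values[table.volunteer_codes ==
                                table.volunteer_ids.index(vid)]
            assert np.all(vals[boot.to_numpy()] == 1.0)


class TestLikelihood:
    def test_matches_naive_loop_oracle(self, cohort):
        table = compute_yoked_probabilities(cohort, "softmax")
        params = {"eps": 0.3, "q": np.array([0.2, 0.6, 0.8]), "tau": 0.4}
        got = log_likelihood(cohort, table, params)
        # independent per-row reimplementation
        expected = 0.0
        vmap = {v: k for k, v in enumerate(table.volunteer_ids)}
        for i, row in cohort.reset_index(drop=True).iterrows():
            p_soft = 1.0 / (1.0 + math.exp(-table.values[i] / 0.4))
            p = 0.3 * params["q"][vmap[row["volunteer_id"]]] + 0.7 * p_soft
            expected += math.log(p) if row["accepted"] else math.log(1 - p)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_full_trembling_depends_only_on_q(self, cohort):
        table = compute_yoked_probabilities(cohort, "greedy")
        q = np.array([0.3, 0.5, 0.7])
        got = log_likelihood(cohort, table, {"eps": 1.0, "q": q})
        acc = cohort["accepted"].to_numpy()
        codes = table.volunteer_codes
        expected = np.where(acc, np.log(q[codes]), np.log(1 - q[codes])).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_pure_random_strategy_is_coin_flips(self, cohort):
        table = compute_yoked_probabilities(cohort, "random")
        got = log_likelihood(cohort, table,
                             {"eps": 0.0, "q": np.full(3, 0.5)})
        assert got == pytest.approx(len(cohort) * math.log(0.5), abs=1e-10)

    def test_pointwise_sums_to_total(self, cohort):
        table = compute_yoked_probabilities(cohort, "thompson")
        params = {"eps": 0.2, "q": np.array([0.4, 0.5, 0.6])}
        pw = log_likelihood(cohort, table, params, pointwise=True)
        assert pw.shape == (len(cohort),)
        assert pw.sum() == pytest.approx(log_likelihood(cohort, table, params))


class TestFitting:
    def test_prior_only_posterior_matches_priors(self, cohort):
        """Masking out every trial leaves the priors: eps ~ Uniform(0,1)
        (mean 1/2), sigma_q ~ Exp(1) (mean 1)."""
        res = fit_model(cohort, "greedy", settings=FAST,
                        trial_mask=np.zeros(len(cohort), dtype=bool))
        assert float(res.posterior_mean("eps")) == pytest.approx(0.5, abs=0.05)
        assert float(res.posterior_mean("sigma_q")) == pytest.approx(1.0, abs=0.2)

    def test_random_model_recovers_acceptance_rate(self):
        """eps and q trade off freely under the random strategy, so only
        the posterior-predictive acceptance rate is identified."""
        cohort = sb.generate_cohort(sb.PolicySpec("random"),
                                    make_short_treatment(25), 4,
                                    trembling_eps=0.3, sigma_q=0.5, seed=6)
        res = fit_model(cohort, "random", settings=FAST)
        eps = res.idata.posterior["eps"].values.ravel()
        q = res.idata.posterior["q"].values.reshape(-1, 4)
        p_pred = (eps[:, None] * q + (1 - eps[:, None]) * 0.5).mean()
        emp = cohort["accepted"].mean()
        assert p_pred == pytest.approx(emp, abs=0.05)

    def test_psis_self_comparison_is_degenerate(self, cohort):
        res = fit_model(cohort, "softmax", settings=FAST)
        comp = psis_compare([res, res])
        assert np.allclose(comp["dPSIS"], 0.0)
        assert np.allclose(comp["weight"], 0.5)

    def test_weights_normalize_over_model_set(self, cohort):
        tables = compute_yoked_tables(cohort, ["random", "greedy", "thompson"])
        fits = [fit_model(cohort, s, settings=FAST, table=tables[s])
                for s in ("random", "greedy", "thompson")]
        comp = psis_compare(fits)
        assert comp["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert comp["PSIS"].is_monotonic_increasing

    def test_mismatched_trial_sets_rejected(self, cohort):
        res = fit_model(cohort, "random", settings=FAST)
        other = fit_model(cohort.iloc[:30].copy(), "random", settings=FAST)
        with pytest.raises(ValueError):
            psis_compare([res, other])

    def test_unknown_strategy_rejected(self, cohort):
        with pytest.raises(ValueError):
            ChoiceModelSpec("eps_greedy")


class TestPsisVersusExactLoo:
    def test_psis_agrees_with_exact_leave_one_out(self):
        """Brute-force oracle: for each of 30 trials, refit with that trial
        excluded from the likelihood and score it out of sample; the
        summed exact elpd must agree with PSIS-LOO within 2 SE."""
        cohort = sb.generate_cohort(sb.PolicySpec("random"),
                                    make_short_treatment(30), 1,
                                    trembling_eps=0.3, sigma_q=0.5, seed=13)
        table = compute_yoked_probabilities(cohort, "random")
        res = fit_model(cohort, "random", settings=FAST, table=table)
        assert np.all(res.pareto_k < 0.7)
        acc = cohort["accepted"].to_numpy()
        n = len(cohort)
        exact = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            loo_fit = fit_model(cohort, "random", settings=FAST,
                                table=table, trial_mask=mask)
            eps = loo_fit.idata.posterior["eps"].values.ravel()
            q = loo_fit.idata.posterior["q"].values.reshape(eps.size)
            p = np.clip(eps * q + (1 - eps) * 0.5, 1e-12, 1 - 1e-12)
            lp = np.log(p) if acc[i] else np.log1p(-p)
            exact[i] = np.logaddexp.reduce(lp) - math.log(lp.size)
        elpd_psis = res.elpd_i.sum()
        se = res.deviance_se / 2.0
        assert abs(elpd_psis - exact.sum()) < 2 * se


def test_degenerate_single_trial_cohorts_do_not_crash():
    tiny = FitSettings(n_walkers=24, n_steps=600, n_burn=300, thin=3, seed=0)
    res = recovery_study(sb.PolicySpec("random"), make_short_treatment(1),
                         n_sims=1, n_volunteers=8, trembling_eps=0.1,
                         settings=tiny, seed=3,
                         strategies=("random", "greedy"))
    assert res.n_sims == 1
    assert res.identified[0] in ("random", "greedy")
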