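"""Tests for the maximum-likelihood attitude estimator and exclusion rules."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import riskamb as ra
from riskamb.estimation import FitResult

from helpers import dense_grid_search, likelihood_product_oracle


def _trial_frame(p, a, x, safe):
    n = len(np.broadcast_to(p, np.broadcast_shapes(np.shape(p), np.shape(x))))
    return pd.DataFrame(
        {
            "trial_id": np.arange(1, n + 1),
            "condition": np.where(np.asarray(a, float) > 0, "ambiguity", "risk"),
            "win_probability": np.broadcast_to(np.asarray(p, float), n),
            "ambiguity_level": np.broadcast_to(np.asarray(a, float), n),
            "gamble_amount": np.broadcast_to(np.asarray(x, float), n),
            "safe_amount": np.broadcast_to(np.asarray(safe, float), n),
        }
    )


class TestNegativeLogLikelihood:
    def test_indifferent_trials_give_n_log_two(self):
        """When gamble and safe EUs tie on every trial, each choice carries
        probability .5 regardless of the attitudes."""
        trials = _trial_frame(np.ones(80), np.zeros(80), np.full(80, 5.0), np.full(80, 5.0))
        choices = np.array(["gamble", "safe"] * 40, dtype=object)
        params = ra.AttitudeParams(0.8, 0.3, 0.7)
        nll = ra.negative_log_likelihood(params, trials, choices)
        assert nll == pytest.approx(80 * math.log(2), rel=1e-12)

    def test_single_trial_closed_form(self):
        """EU difference exactly mu: -ln(1/(1+e^-1)) = 0.3133."""
        trials = _trial_frame([1.0], [0.0], [6.0], [5.0])
        params = ra.AttitudeParams(1.0, 0.0, 1.0)
        nll = ra.negative_log_likelihood(params, trials, ["gamble"])
        assert nll == pytest.approx(-math.log(1.0 / (1.0 + math.exp(-1.0))), rel=1e-9)

    def test_matches_per_trial_product_oracle(self):
        """Vectorised likelihood equals a plain per-trial product re-evaluation
        on a simulated cohort member."""
        config = dataclasses.replace(ra.CohortConfig(), n_participants=3, seed=11)
        cohort = ra.simulate_cohort(config, include_fmri=False)
        part = cohort.participants[0]
        params = ra.AttitudeParams(0.6, 0.25, 0.5)
        nll = ra.negative_log_likelihood(
            params, cohort.behavioral_design, part.behavioral_choices["choice"]
        )
        oracle = likelihood_product_oracle(
            cohort.behavioral_design, part.behavioral_choices["choice"], 0.6, 0.25, 0.5
        )
        assert nll == pytest.approx(oracle, rel=1e-9)

    def test_missing_choices_are_dropped(self, behavioral_design):
        params = ra.AttitudeParams(0.6, 0.25, 0.5)
        choices = np.array(["gamble", "safe"] * 40, dtype=object)
        with_missing = choices.copy()
        with_missing[:10] = "missing"
        full = ra.negative_log_likelihood(params, behavioral_design, with_missing)
        subset = ra.negative_log_likelihood(
            params, behavioral_design.iloc[10:], choices[10:]
        )
        assert full == pytest.approx(subset, rel=1e-12)

    def test_rejects_empty_usable_set(self, behavioral_design):
        params = ra.AttitudeParams(0.6, 0.25, 0.5)
        with pytest.raises(ValueError, match="usable"):
            ra.negative_log_likelihood(
                params, behavioral_design, np.array(["missing"] * 80, dtype=object)
            )

    def test_log_floor_keeps_deterministic_responders_finite(self):
        trials = _trial_frame([1.0], [0.0], [50.0], [5.0])
        params = ra.AttitudeParams(1.0, 0.0, 1e-4)  # Pr(safe) ~ 0
        nll = ra.negative_log_likelihood(params, trials, ["safe"])
        assert np.isfinite(nll)
        assert nll == pytest.approx(-math.log(1e-12), rel=1e-6)

    def test_invariant_under_trial_permutation(self, behavioral_design):
        agent = ra.ParticipantRecord(0, 0.0, ra.AttitudeParams(0.6, 0.25, 0.1))
        choices = ra.simulate_choices(agent, behavioral_design, 5)["choice"].to_numpy()
        params = ra.AttitudeParams(0.7, -0.2, 0.3)
        perm = np.random.default_rng(0).permutation(80)
        straight = ra.negative_log_likelihood(params, behavioral_design, choices)
        shuffled = ra.negative_log_likelihood(
            params, behavioral_design.iloc[perm], choices[perm]
        )
        assert straight == pytest.approx(shuffled, rel=1e-9)
        fit_a = ra.fit_attitudes(behavioral_design, choices)
        fit_b = ra.fit_attitudes(behavioral_design.iloc[perm], choices[perm])
        assert fit_a.params.alpha == pytest.approx(fit_b.params.alpha, abs=1e-3)
        assert fit_a.params.beta == pytest.approx(fit_b.params.beta, abs=1e-3)


class TestAttitudeEstimator:
    def test_sklearn_conventions(self, behavioral_design):
        est = ra.AttitudeEstimator()
        params = est.get_params()
        assert set(params) == {"start_grid", "tol", "max_iter"}
        est.set_params(tol=1e-5)
        assert est.tol == 1e-5
        agent = ra.ParticipantRecord(0, 0.0, ra.AttitudeParams(0.6, 0.25, 0.1))
        choices = ra.simulate_choices(agent, behavioral_design, 1)["choice"]
        est.fit(behavioral_design, choices)
        for attr in ("alpha_", "beta_", "mu_", "nll_", "converged_", "n_trials_used_"):
            assert hasattr(est, attr)
        proba = est.predict_proba(behavioral_design)
        assert proba.shape == (80, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(behavioral_design)) <= {"gamble", "safe"}

    def test_unfitted_predict_raises(self, behavioral_design):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            ra.AttitudeEstimator().predict_proba(behavioral_design)

    def test_restart_dominance(self, behavioral_design):
        """The returned NLL never exceeds the objective at any grid start."""
        agent = ra.ParticipantRecord(0, 0.0, ra.AttitudeParams(0.9, -0.4, 0.2))
        choices = ra.simulate_choices(agent, behavioral_design, 2)["choice"]
        est = ra.AttitudeEstimator().fit(behavioral_design, choices)
        assert est.nll_ <= est.start_nlls_.min() + 1e-9

    def test_beats_dense_grid_oracle_on_small_instance(self, behavioral_design):
        """On a 30-trial instance the simplex-with-restarts optimum is at
        least as good as a brute-force grid search (step .01)."""
        trials = behavioral_design.iloc[:30].reset_index(drop=True)
        agent = ra.ParticipantRecord(0, 0.0, ra.AttitudeParams(0.6, 0.25, 0.1))
        choices = ra.simulate_choices(agent, trials, 3)["choice"]
        fit = ra.fit_attitudes(trials, choices)
        oracle_nll, _, _ = dense_grid_search(trials, choices)
        assert fit.nll <= oracle_nll + 1e-3

    def test_recovers_generating_attitudes(self):
        """Agent at alpha=.6, beta=.25, mu=.1 on five concatenated runs."""
        design = ra.build_behavioral_design(3)
        design = pd.concat([design] * 5, ignore_index=True)
        design["trial_id"] = np.arange(1, len(design) + 1)
        agent = ra.ParticipantRecord(0, 0.0, ra.AttitudeParams(0.6, 0.25, 0.1))
        choices = ra.simulate_choices(agent, design, 3)["choice"]
        fit = ra.fit_attitudes(design, choices)
        assert fit.params.alpha == pytest.approx(0.6, abs=0.1)
        assert fit.params.beta == pytest.approx(0.25, abs=0.15)

    def test_near_deterministic_neutral_agent(self):
        """With mu=.05 choices are near-deterministic: alpha is recovered,
        while beta is only set-identified (the likelihood is flat over the
        betas consistent with the choice pattern), so the estimate is checked
        against the oracle's near-optimal beta set."""
        design = ra.build_behavioral_design(3)
        design = pd.concat([design] * 5, ignore_index=True)
        design["trial_id"] = np.arange(1, len(design) + 1)
        agent = ra.ParticipantRecord(0, 0.0, ra.AttitudeParams(1.0, 0.0, 0.05))
        choices = ra.simulate_choices(agent, design, 4)["choice"]
        fit = ra.fit_attitudes(design, choices)
        assert fit.params.alpha == pytest.approx(1.0, abs=0.1)
        sub = design.iloc[:30].reset_index(drop=True)
        oracle_nll, _, near_betas = dense_grid_search(sub, choices.iloc[:30])
        assert near_betas.min() - 0.02 <= fit.params.beta <= near_betas.max() + 0.02
        assert near_betas.min() <= 0.0 <= near_betas.max()  # truth in the set

    def test_all_gamble_responder_is_degenerate(self, behavioral_design):
        choices = np.array(["gamble"] * 80, dtype=object)
        fit = ra.fit_attitudes(behavioral_design, choices)
        assert fit.excluded and fit.exclusion_reason == "degenerate"

    def test_too_few_usable_trials_rejected(self, behavioral_design):
        choices = np.array(["missing"] * 80, dtype=object)
        choices[:19] = "safe"
        with pytest.raises(ValueError, match="at least"):
            ra.fit_attitudes(behavioral_design, choices)


class TestDominanceViolations:
    @pytest.mark.parametrize("n_gambled, expected", [(0, 0.0), (20, 1.0), (5, 0.25)])
    def test_violation_fractions(self, behavioral_design, n_gambled, expected):
        probe = (
            behavioral_design["gamble_amount"] == behavioral_design["safe_amount"]
        ).to_numpy()
        choices = np.array(["safe"] * 80, dtype=object)
        idx = np.flatnonzero(probe)[:n_gambled]
        choices[idx] = "gamble"
        rate = ra.detect_dominance_violations(behavioral_design, choices)
        assert rate == pytest.approx(expected)

    def test_no_probe_trials_signalled(self, fmri_design):
        choices = np.array(["safe"] * len(fmri_design), dtype=object)
        with pytest.raises(ValueError, match="probe"):
            ra.detect_dominance_violations(fmri_design, choices)


def _fit(alpha, dom=0.0, reason="none", excluded=False):
    return FitResult(
        params=ra.AttitudeParams(alpha, 0.0, 0.1),
        nll=50.0,
        converged=True,
        n_trials_used=80,
        best_start=ra.AttitudeParams(0.6, 0.0, 0.5),
        dominance_violation_rate=dom,
        excluded=excluded,
        exclusion_reason=reason,
    )


class TestApplyExclusions:
    def test_identical_alphas_no_outlier(self):
        fits = ra.apply_exclusions([_fit(0.6) for _ in range(10)])
        assert all(not f.excluded for f in fits)

    def test_dominance_violator_excluded(self):
        fits = [_fit(0.6) for _ in range(9)] + [_fit(0.6, dom=0.6)]
        out = ra.apply_exclusions(fits)
        assert out[-1].excluded and out[-1].exclusion_reason == "dominance"
        assert sum(f.excluded for f in out) == 1

    def test_planted_outlier_excluded(self):
        rng = np.random.default_rng(0)
        alphas = 0.6 + 0.1 * rng.standard_normal(30)
        planted = alphas.mean() + 5 * alphas.std(ddof=1)
        fits = [_fit(a) for a in alphas] + [_fit(planted)]
        out = ra.apply_exclusions(fits)
        excluded = [f for f in out if f.excluded]
        assert len(excluded) == 1
        assert excluded[0].exclusion_reason == "outlier"
        assert excluded[0].params.alpha == pytest.approx(planted)

    def test_outlier_threshold_ignores_dominance_excluded(self):
        """A wild alpha on a dominance-excluded fit must not mask outliers."""
        fits = [_fit(0.6 + 0.01 * i) for i in range(20)]
        fits.append(_fit(2.4, dom=0.9))  # dominance violator with huge alpha
        out = ra.apply_exclusions(fits)
        assert out[-1].exclusion_reason == "dominance"

    def test_requires_two_fits(self):
        with pytest.raises(ValueError):
            ra.apply_exclusions([_fit(0.6)])

    def test_inputs_not_mutated(self):
        fits = [_fit(0.6), _fit(0.6, dom=0.9)]
        ra.apply_exclusions(fits)
        assert not fits[1].excluded


def test_bias_shrinks_with_replicated_designs():
    """Estimator consistency: mean error of alpha-hat and beta-hat falls as
    the 80-trial design is replicated (50 simulations per size)."""
    truth = ra.AttitudeParams(0.6, 0.25, 0.1)
    biases = {}
    for repeats in (1, 5, 25):
        design = ra.build_behavioral_design(3)
        design = pd.concat([design] * repeats, ignore_index=True)
        design["trial_id"] = np.arange(1, len(design) + 1)
        seeds = np.random.SeedSequence(202).spawn(50)
        errs_a, errs_b = [], []
        for s in seeds:
            agent = ra.ParticipantRecord(0, 0.0, truth)
            choices = ra.simulate_choices(agent, design, s)["choice"]
            fit = ra.fit_attitudes(design, choices)
            errs_a.append(fit.params.alpha - truth.alpha)
            errs_b.append(fit.params.beta - truth.beta)
        biases[repeats] = (abs(np.mean(errs_a)), abs(np.mean(errs_b)))
    slack = 0.01  # Monte-Carlo noise on a mean of 50
    assert biases[25][0] <= biases[1][0] + slack
    assert biases[25][1] <= biases[1][1] + slack
    assert biases[5][0] <= biases[1][0] + slack
    assert biases[5][1] <= biases[1][1] + slack
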