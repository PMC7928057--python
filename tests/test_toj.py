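"""Psychometric fitting, PSE/JND estimation and group inference."""

import math

import numpy as np
import pandas as pd
import pytest

from skinstretch import (
    DESIGN_LAGS_MS,
    PsychometricFit,
    ResponderParams,
    fit_psychometric,
    group_inference,
    jnd_from_curve,
    logistic_nll,
    pooled_curve,
    response_proportions,
    schedule_trials,
    simulate_responder,
    t_test_from_summary,
)

LN3 = math.log(3.0)
GROUP_MU = -18.37
GROUP_JND = 25.15


def make_table(lags, responses, participant="P01"):
    return pd.DataFrame(
        {
            "participant_id": participant,
            "lag_ms": np.asarray(lags),
            "response": np.asarray(responses),
        }
    )


@pytest.fixture(scope="module")
def responder_table():
    """One synthetic participant at the group parameters, full design."""
    sched = schedule_trials(seed=21)
    return simulate_responder(
        ResponderParams(mu=GROUP_MU, jnd=GROUP_JND, seed=77), sched
    )


class TestResponseProportions:
    def test_counting(self):
        table = make_table([40] * 15, [1] * 9 + [0] * 6)
        props = response_proportions(table, "P01")
        assert props["proportion"].iloc[0] == pytest.approx(0.6)
        assert props["n"].iloc[0] == 15

    def test_all_ones_give_proportion_one(self):
        table = make_table([40] * 5, [1] * 5)
        assert response_proportions(table, "P01")["proportion"].iloc[0] == 1.0

    def test_full_design_has_14_lags(self, responder_table):
        props = response_proportions(responder_table, "P01")
        assert len(props) == 14
        assert (props["n"] == 15).all()

    def test_unknown_participant_rejected(self, responder_table):
        with pytest.raises(ValueError, match="unknown participant"):
            response_proportions(responder_table, "nobody")


class TestFitPsychometric:
    @pytest.mark.parametrize("mode", ["mle", "proportions-ls"])
    def test_recovers_generating_parameters(self, responder_table, mode):
        fit = fit_psychometric(responder_table, "P01", mode=mode)
        assert fit.converged
        # a single 210-trial dataset: expect recovery within simulation error
        assert fit.pse == pytest.approx(GROUP_MU, abs=8.0)
        assert fit.jnd == pytest.approx(GROUP_JND, abs=8.0)

    def test_mle_beats_generating_parameters_in_likelihood(self, responder_table):
        fit = fit_psychometric(responder_table, "P01", mode="mle")
        lags = responder_table["lag_ms"].to_numpy(float)
        resp = responder_table["response"].to_numpy(float)
        nll_truth = logistic_nll(GROUP_MU, GROUP_JND / LN3, lags, resp)
        assert fit.neg_log_likelihood <= nll_truth + 1e-9

    def test_shift_equivariance(self, responder_table):
        delta = 25.0
        shifted = responder_table.assign(lag_ms=responder_table["lag_ms"] + delta)
        base = fit_psychometric(responder_table, "P01")
        moved = fit_psychometric(shifted, "P01")
        assert moved.pse == pytest.approx(base.pse + delta, abs=1e-3)
        assert moved.jnd == pytest.approx(base.jnd, abs=1e-3)

    def test_flat_coin_yields_large_scale(self):
        rng = np.random.default_rng(5)
        lags = np.repeat(DESIGN_LAGS_MS, 15)
        table = make_table(lags, rng.integers(0, 2, lags.size))
        fit = fit_psychometric(table, "P01")
        assert fit.s > 100.0

    def test_complete_separation_flagged_not_fatal(self):
        lags = np.repeat(DESIGN_LAGS_MS, 3)
        table = make_table(lags, (lags > 0).astype(int))
        fit = fit_psychometric(table, "P01")
        assert fit.at_bound
        assert fit.s == pytest.approx(1.0, abs=1e-3)  # bounded below

    def test_too_few_lags_rejected(self):
        table = make_table([0, 10, 20] * 5, [0, 1, 1] * 5)
        with pytest.raises(ValueError, match="distinct lags"):
            fit_psychometric(table, "P01")

    def test_single_category_rejected(self):
        table = make_table(list(DESIGN_LAGS_MS), [1] * 14)
        with pytest.raises(ValueError, match="both response categories"):
            fit_psychometric(table, "P01")


class TestJndFromCurve:
    def _fit(self, mu, s):
        return PsychometricFit(
            mu=mu, s=s, pse=mu, jnd=s * LN3, n_trials=210, converged=True,
            neg_log_likelihood=0.0,
        )

    def test_closed_form_identity(self):
        assert jnd_from_curve(self._fit(0.0, 10.0)) == pytest.approx(
            10.0 * LN3, rel=1e-9
        )

    def test_invariant_to_location(self):
        assert jnd_from_curve(self._fit(-50.0, 10.0)) == pytest.approx(
            jnd_from_curve(self._fit(+50.0, 10.0)), rel=1e-9
        )

    def test_linear_in_scale(self):
        assert jnd_from_curve(self._fit(0.0, 20.0)) == pytest.approx(
            2 * jnd_from_curve(self._fit(0.0, 10.0)), rel=1e-9
        )

    def test_matches_analytic_for_fitted_curve(self, responder_table):
        fit = fit_psychometric(responder_table, "P01")
        assert jnd_from_curve(fit) == pytest.approx(fit.s * LN3, rel=1e-6)

    def test_nonconverged_fit_rejected(self):
        bad = PsychometricFit(
            mu=0.0, s=10.0, pse=0.0, jnd=10 * LN3, n_trials=0, converged=False,
            neg_log_likelihood=0.0,
        )
        with pytest.raises(ValueError, match="non-converged"):
            jnd_from_curve(bad)


def _t_density_cdf_oracle(t, df, n_grid=1_000_001):
    """Brute-force numeric integration of the t density up to t.

    The lower limit must be far out: with df = 2 the tail is heavy and the
    mass below -10^4 is still ~5e-9.
    """
    lo = -10_000.0
    x = np.linspace(lo, t, n_grid)
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = c * (1 + x**2 / df) ** (-(df + 1) / 2)
    return float(np.trapezoid(pdf, x))


class TestGroupInference:
    def test_reported_summary_reproduces_marginal_p(self):
        t, df, p = t_test_from_summary(GROUP_MU, 7.21, 3, tail="less")
        assert t == pytest.approx(-2.548, abs=1e-3)
        assert df == 2
        assert 0.062 <= p <= 0.064

    def test_p_matches_numeric_integration_oracle(self):
        t, df, p = t_test_from_summary(GROUP_MU, 7.21, 3, tail="less")
        assert p == pytest.approx(_t_density_cdf_oracle(t, df), abs=1e-5)

    def test_symmetric_values_give_half(self):
        stats = group_inference([-1.0, 0.0, 1.0], tail="less")
        assert stats.t_stat == pytest.approx(0.0)
        assert stats.p_value == pytest.approx(0.5)

    def test_degenerate_all_zero_flagged(self):
        stats = group_inference([0.0, 0.0, 0.0], tail="less")
        assert stats.degenerate
        assert stats.p_value == 0.5

    def test_jnd_summary(self):
        stats = group_inference(
            [-10.0, -20.0, -25.0], tail="less", jnd_values=[20.0, 25.0, 30.0]
        )
        assert stats.mean_jnd == pytest.approx(25.0)
        assert stats.se_jnd == pytest.approx(np.std([20, 25, 30], ddof=1) / math.sqrt(3))

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_inference([-18.0], tail="less")

    def test_tail_must_be_explicit_and_valid(self):
        with pytest.raises(ValueError, match="tail"):
            t_test_from_summary(-18.37, 7.21, 3, tail="favorable")


class TestPooledCurve:
    def test_single_participant_pooled_equals_individual(self, responder_table):
        pooled, _ = pooled_curve(responder_table)
        props = response_proportions(responder_table, "P01")
        np.testing.assert_allclose(pooled["proportion"], props["proportion"])
        assert pooled["se"].isna().all()

    def test_identical_participants_zero_se(self, responder_table):
        trip = pd.concat(
            [responder_table.assign(participant_id=p) for p in ("A", "B", "C")],
            ignore_index=True,
        )
        pooled, _ = pooled_curve(trip)
        np.testing.assert_allclose(pooled["se"], 0.0, atol=1e-12)

    def test_pooled_proportions_rise_from_zero_to_one(self):
        # large-rep cohort at the group parameters: saturation at the ends
        sched = schedule_trials(reps=200, seed=31)
        table = simulate_responder(
            ResponderParams(mu=GROUP_MU, jnd=GROUP_JND, seed=31), sched
        )
        pooled, fit = pooled_curve(table)
        assert pooled["proportion"].iloc[0] < 0.05  # lag -120 ms
        assert pooled["proportion"].iloc[-1] > 0.95  # lag +120 ms
        assert fit.pse == pytest.approx(GROUP_MU, abs=5.0)
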