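"""Parameter estimation: objective, grid+polish fit, confidence intervals."""

import math
import warnings

import numpy as np
import pytest
from scipy.linalg import expm

from edupulse import (
    DotPlotModel,
    DotPlotSummary,
    FitConfig,
    apply_hypotheses,
    confidence_intervals,
    default_study_protocol,
    edu_to_rate,
    fit_sample,
    fit_table,
    objective,
    steady_state,
)


def expm_endpoint_triplet(a_G: float, a_M: float, protocol) -> np.ndarray:
    """Independent oracle: exact piecewise solution by matrix exponentials.

    Within each window the hypothesis-mode system is linear
    time-invariant, so the endpoint is a product of matrix exponentials
    with the instant-labelling transfer applied at each pulse start.
    """
    a_S = 1 / 6.5
    transfer = np.eye(6)
    transfer[4, 1] += 1.0  # S -> S'
    transfer[1, 1] = 0.0

    def window_matrix(pulse: bool) -> np.ndarray:
        A = np.zeros((6, 6))
        A[0, 2] = 2 * a_M          # divisions feed unlabelled G
        A[0, 0] = -2 * a_G         # a_G + d_G
        A[2, 1] = a_S
        A[2, 2] = -a_M
        A[3, 5] = 2 * a_M          # labelled divisions feed G'
        A[3, 3] = -2 * a_G
        A[4, 4] = -a_S
        A[5, 4] = a_S
        A[5, 5] = -a_M
        if pulse:
            A[1, 1] = -a_S         # G influx rerouted away from S
            A[4, 0] = a_G
            A[4, 3] = a_G
        else:
            A[1, 0] = a_G
            A[1, 1] = -a_S
            A[4, 3] = a_G
        return A

    ss = steady_state(apply_hypotheses(a_G, a_M)[0])
    y = np.array([ss.gg, ss.ss, ss.mm, 0.0, 0.0, 0.0])
    for start, end, pulse in protocol.windows:
        if pulse:
            y = transfer @ y
        y = expm(window_matrix(pulse) * (end - start)) @ y
    return np.array([y[0], y[2], y[3] + y[4] + y[5]])


class TestObjective:
    def test_self_distance_is_zero(self, forward_triplet, protocol):
        target = forward_triplet(0.01, 0.25)
        assert objective(0.01, 0.25, target, protocol) < 1e-6

    def test_identical_triplets_give_zero(self, protocol):
        t = DotPlotSummary(33.33, 33.33, 33.34)
        assert np.linalg.norm(t.as_array() - t.as_array()) == 0.0

    @pytest.mark.parametrize("a_G,a_M", [(0.01, 0.25), (0.1, 0.05), (0.002, 0.5)])
    def test_matches_matrix_exponential_oracle(self, a_G, a_M, protocol):
        """The RK4 objective agrees with the exact linear-system solution."""
        target = DotPlotSummary(90.0, 4.0, 6.0)
        oracle_trip = expm_endpoint_triplet(a_G, a_M, protocol)
        oracle_distance = float(np.linalg.norm(oracle_trip - target.as_array()))
        assert objective(a_G, a_M, target, protocol) == pytest.approx(
            oracle_distance, abs=1e-9
        )


class TestFitSample:
    def test_noiseless_recovery(self, forward_triplet, protocol):
        res = fit_sample(forward_triplet(0.005, 0.02), protocol)
        assert res.a_G_hat == pytest.approx(0.005, rel=1e-3)
        assert res.a_M_hat == pytest.approx(0.02, rel=1e-3)
        assert res.distance < 1e-4
        assert not res.boundary_flag and not res.distance_flag

    def test_symmetric_target_recovers_equal_rates(self, forward_triplet, protocol):
        res = fit_sample(forward_triplet(1 / 6.5, 1 / 6.5), protocol)
        assert res.a_G_hat == pytest.approx(1 / 6.5, rel=1e-3)
        assert res.a_M_hat == pytest.approx(1 / 6.5, rel=1e-3)

    def test_unlabelled_sample_hits_boundary_without_error(self, protocol):
        res = fit_sample(DotPlotSummary(95.0, 5.0, 0.0), protocol)
        assert res.boundary_flag
        assert res.a_G_hat == FitConfig().grid_min

    def test_inconsistent_triplet_renormalised(self, forward_triplet, protocol, caplog):
        t = forward_triplet(0.01, 0.25)
        skewed = DotPlotSummary(t.pct_G * 1.02, t.pct_M * 1.02, t.pct_labelled * 1.02)
        with caplog.at_level("WARNING", logger="edupulse.fit"):
            res = fit_sample(skewed, protocol)
        assert "renormalising" in caplog.text
        assert res.a_G_hat == pytest.approx(0.01, rel=1e-3)

    def test_grid_only_fit_lands_on_grid_node(self, forward_triplet, protocol):
        cfg = FitConfig(refine=False, grid_n=20)
        res = fit_sample(forward_triplet(0.01, 0.25), protocol, cfg)
        axis = np.logspace(math.log10(cfg.grid_min), math.log10(cfg.grid_max), cfg.grid_n)
        assert np.min(np.abs(axis - res.a_G_hat)) < 1e-12
        assert np.min(np.abs(axis - res.a_M_hat)) < 1e-12


class TestConfidenceIntervals:
    def test_noiseless_interval_contains_truth(self, forward_triplet, protocol):
        target = forward_triplet(0.01, 0.25)
        res = fit_sample(target, protocol)
        res = confidence_intervals(res, target, n_events=10_000, protocol=protocol)
        assert res.ci_a_G[0] <= 0.01 <= res.ci_a_G[1]
        assert res.ci_a_M[0] <= 0.25 <= res.ci_a_M[1]
        truth_p = res.kinetics.p_per_day
        assert res.ci_p[0] <= truth_p <= res.ci_p[1]
        assert res.se_p > 0

    def test_interval_width_shrinks_with_event_count(self, forward_triplet, protocol):
        target = forward_triplet(0.01, 0.25)
        res = fit_sample(target, protocol)
        narrow = confidence_intervals(res, target, 1_000_000, protocol)
        wide = confidence_intervals(res, target, 10_000, protocol)
        assert (narrow.ci_p[1] - narrow.ci_p[0]) < (wide.ci_p[1] - wide.ci_p[0])
        # width scales ~ 1/sqrt(n): factor 100 in n is factor ~10 in width
        ratio = (wide.ci_p[1] - wide.ci_p[0]) / (narrow.ci_p[1] - narrow.ci_p[0])
        assert ratio == pytest.approx(10.0, rel=0.05)


class TestEdUToRate:
    def test_printed_calibration_line(self):
        assert edu_to_rate(0.0) == pytest.approx(-0.000884)
        assert edu_to_rate(38.0) == pytest.approx(-0.000884 + 0.0119 * 38, rel=1e-12)
        assert edu_to_rate(38.0) == pytest.approx(0.45132, abs=1e-5)

    def test_strictly_increasing(self):
        xs = np.linspace(0, 100, 11)
        ys = [edu_to_rate(x) for x in xs]
        assert np.all(np.diff(ys) > 0)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolating"):
            edu_to_rate(105.0)


class TestModelResultsInterface:
    def test_model_fit_results_round_trip(self, forward_triplet, protocol):
        target = forward_triplet(0.02, 0.1)
        res = DotPlotModel(target, protocol=protocol, n_events=20_000).fit()
        assert res.params == pytest.approx([0.02, 0.1], rel=1e-3)
        ci = res.conf_int()
        assert ci.loc["p (%/day)", "lower"] <= res.kinetics.p_per_day
        assert res.predict().as_array() == pytest.approx(target.as_array(), abs=1e-3)
        text = res.summary()
        assert "proliferation rate" in text and "inter-mitotic" in text
        assert res.bse.shape == (2,)

    def test_model_accepts_plain_sequence(self, protocol):
        m = DotPlotModel((90.0, 4.0, 6.0), protocol=protocol)
        assert m.target.pct_labelled == 6.0

    def test_fit_table_appends_estimate_columns(self, forward_triplet, protocol):
        import pandas as pd

        t1, t2 = forward_triplet(0.01, 0.25), forward_triplet(0.05, 0.1)
        table = pd.DataFrame(
            [
                dict(sample_id="s1", strain="B6", age_months=2, organ="thymus",
                     population="total", n_events=10_000,
                     pct_g_unlabelled=t1.pct_G, pct_m_unlabelled=t1.pct_M,
                     pct_labelled=t1.pct_labelled),
                dict(sample_id="s2", strain="FVB", age_months=18, organ="spleen",
                     population="total", n_events=10_000,
                     pct_g_unlabelled=t2.pct_G, pct_m_unlabelled=t2.pct_M,
                     pct_labelled=t2.pct_labelled),
            ]
        )
        fits = fit_table(table, protocol=protocol)
        for col in ("a_g_per_h", "a_m_per_h", "distance", "p_pct_per_day",
                    "p_ci_low", "g1_h", "g2m_h", "s_h", "intermitotic_days",
                    "boundary_flag"):
            assert col in fits.columns
        assert fits.loc[0, "a_g_per_h"] == pytest.approx(0.01, rel=1e-3)
        assert fits.loc[1, "a_m_per_h"] == pytest.approx(0.1, rel=1e-3)
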