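"""Estimator: OLS and lme4 oracles, GGM identities, type-I calibration."""

import numpy as np
import pandas as pd
import pytest

import emanet
from emanet import (
    BeepSchedule,
    SimulationConfig,
    build_lagged,
    make_truth,
    person_statistics,
    pcor_from_precision,
    simulate_dataset,
)
from emanet.network_estimation import (
    EstimationError,
    TemporalFit,
    fit_between,
    fit_contemporaneous,
    fit_temporal,
)

ABCD = ("a", "b", "c", "d")


@pytest.fixture(scope="module")
def single_person_fit():
    truth = make_truth(m=3, edge_density=0.6, weight_low=0.15, weight_high=0.25, seed=6)
    config = SimulationConfig(
        n_persons=1,
        schedule=BeepSchedule(beeps_per_day=4, n_days=1200, prompt_labels=ABCD),
        missing_beep_rate=0.0,
        eating_item_missing_rate=0.0,
        seed=31,
    )
    dataset = simulate_dataset(truth, config)
    means = person_statistics(dataset)
    design = build_lagged(dataset, means)
    return truth, design, means, fit_temporal(design, means, standardize=False)


class TestTemporalSinglePerson:
    def test_flagged_single_level_path(self, single_person_fit):
        _, _, _, fit = single_person_fit
        assert fit.temporal.fallback.all()
        assert (fit.diagnostics["fallback"] == "single_person_ols").all()

    def test_equals_ols_oracle_to_numerical_precision(self, single_person_fit):
        truth, design, means, fit = single_person_fit
        items = design.item_names
        X = np.column_stack(
            [np.ones(len(design))] + [design.centered_lag(it).to_numpy() for it in items]
        )
        for j, it in enumerate(items):
            y = design.outcome(it).to_numpy()
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            np.testing.assert_allclose(
                fit.temporal.weights.loc[it].to_numpy(), beta[1:], atol=1e-8
            )

    def test_recovers_true_B(self, single_person_fit):
        truth, _, _, fit = single_person_fit
        assert np.max(np.abs(fit.temporal.weights.to_numpy() - truth.B)) < 0.05


class TestAgainstLme4:
    """Frozen reference values from an independent lme4 (REML) fit.

    The fixture dataset is bit-reproducible (truth seed 3, data seed 11);
    the frozen numbers were produced by lmer(y_V01 ~ c_V01 + c_V02 + c_V03
    + m_V02 + m_V03 + (1|person), REML=TRUE) on the standardised design.
    """

    LME4_COEF = {
        "lag:V01": 0.167699, "lag:V02": -0.177945, "lag:V03": -0.032279,
        "mean:V02": 0.326541, "mean:V03": -0.495439,
    }
    LME4_SE = {
        "lag:V01": 0.031611, "lag:V02": 0.029468, "lag:V03": 0.029383,
        "mean:V02": 0.187070, "mean:V03": 0.176079,
    }

    def test_node_model_matches_lme4(self):
        truth = make_truth(m=3, edge_density=0.5, weight_low=0.15, weight_high=0.25, seed=3)
        config = SimulationConfig(
            n_persons=30,
            schedule=BeepSchedule(4, 14, ABCD),
            missing_beep_rate=0.1,
            eating_item_missing_rate=0.0,
            seed=11,
        )
        dataset = simulate_dataset(truth, config)
        means = person_statistics(dataset)
        fit = fit_temporal(build_lagged(dataset, means), means, standardize=True)
        got_coef = {
            "lag:V01": fit.temporal.weights.loc["V01", "V01"],
            "lag:V02": fit.temporal.weights.loc["V01", "V02"],
            "lag:V03": fit.temporal.weights.loc["V01", "V03"],
            "mean:V02": fit.between_coef.loc["V01", "V02"],
            "mean:V03": fit.between_coef.loc["V01", "V03"],
        }
        got_se = {
            "lag:V01": fit.temporal.se.loc["V01", "V01"],
            "lag:V02": fit.temporal.se.loc["V01", "V02"],
            "lag:V03": fit.temporal.se.loc["V01", "V03"],
            "mean:V02": fit.between_se.loc["V01", "V02"],
            "mean:V03": fit.between_se.loc["V01", "V03"],
        }
        for key, ref in self.LME4_COEF.items():
            assert got_coef[key] == pytest.approx(ref, abs=1e-3), key
        for key, ref in self.LME4_SE.items():
            assert got_se[key] == pytest.approx(ref, abs=1e-3), key


def _fake_fit(items, coef, pvals, sd=None):
    idx = pd.Index(items, name="item")
    nan = pd.DataFrame(np.nan, index=idx, columns=idx)
    return TemporalFit(
        temporal=None,
        residuals=None,
        between_coef=pd.DataFrame(coef, index=idx, columns=idx),
        between_se=nan,
        between_p=pd.DataFrame(pvals, index=idx, columns=idx),
        person_mean_sd=pd.Series(sd if sd is not None else 1.0, index=idx),
        diagnostics=None,
        standardized=True,
        pvalue_method="normal",
    )


class TestFitBetween:
    def test_arithmetic_mean_of_two_directions(self):
        fit = _fake_fit(
            ["a", "b"],
            [[np.nan, 0.30], [0.18, np.nan]],
            [[np.nan, 0.064], [0.021, np.nan]],
        )
        net = fit_between(fit)
        assert net.weights.loc["a", "b"] == pytest.approx(0.24)
        assert net.weights.loc["b", "a"] == pytest.approx(0.24)
        assert net.p1.loc["a", "b"] == 0.064
        assert net.p2.loc["a", "b"] == 0.021

    def test_sign_conflict_zeroed_and_flagged(self):
        fit = _fake_fit(
            ["a", "b"],
            [[np.nan, 0.30], [-0.18, np.nan]],
            [[np.nan, 0.01], [0.01, np.nan]],
        )
        net = fit_between(fit)
        assert net.weights.loc["a", "b"] == 0.0
        assert bool(net.sign_conflict.loc["a", "b"])

    def test_standardisation_by_person_mean_sds(self):
        fit = _fake_fit(
            ["a", "b"],
            [[np.nan, 0.30], [0.18, np.nan]],
            [[np.nan, 0.01], [0.01, np.nan]],
            sd=[2.0, 1.0],
        )
        net = fit_between(fit)
        # b_a<-b scaled by sd_b/sd_a = .5 -> .15 ; b_b<-a by 2 -> .36
        assert net.weights.loc["a", "b"] == pytest.approx(0.5 * (0.15 + 0.36))


class TestFitContemporaneous:
    def test_two_nodes_equals_plain_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(4000)
        resid = pd.DataFrame({"x": x, "y": y})
        net = fit_contemporaneous(resid, ["x", "y"])
        r = np.corrcoef(x, y)[0, 1]
        assert net.weights.loc["x", "y"] == pytest.approx(r, abs=1e-10)

    def test_matches_precision_inversion_oracle(self):
        # residuals drawn from a known 3-node precision matrix
        theta = np.array(
            [[1.0, -0.3, 0.0], [-0.3, 1.0, 0.2], [0.0, 0.2, 1.0]]
        )
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal(np.zeros(3), np.linalg.inv(theta), size=5000)
        net = fit_contemporaneous(pd.DataFrame(z, columns=list("abc")), list("abc"))
        expected = pcor_from_precision(np.linalg.inv(theta))
        assert np.max(np.abs(net.weights.to_numpy() - expected)) < 0.02

    def test_independent_residuals_stay_near_zero(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal((5000, 4))
        net = fit_contemporaneous(pd.DataFrame(z, columns=list("abcd")), list("abcd"))
        off = ~np.eye(4, dtype=bool)
        assert np.all(np.abs(net.weights.to_numpy()[off]) < 0.05)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((200, 3))
        net = fit_contemporaneous(pd.DataFrame(z, columns=list("abc")), list("abc"))
        w = net.weights.to_numpy()
        assert np.allclose(w, w.T)
        assert np.allclose(np.diag(w), 0)
        assert np.all(np.abs(w) <= 1)

    def test_rank_deficient_names_collinear_nodes(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        resid = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(100)})
        with pytest.raises(EstimationError, match="a / b"):
            fit_contemporaneous(resid, ["a", "b", "c"])

    def test_too_few_rows_rejected(self):
        resid = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 3)), columns=list("abc"))
        with pytest.raises(EstimationError, match="complete residual rows"):
            fit_contemporaneous(resid, list("abc"))


class TestPcorFromPrecision:
    def test_identity_covariance_gives_zero(self):
        assert np.allclose(pcor_from_precision(np.eye(4)), 0.0)

    @pytest.mark.parametrize("r", [-0.8, -0.2, 0.5])
    def test_bivariate_identity(self, r):
        cov = np.array([[1.0, r], [r, 1.0]])
        pcor = pcor_from_precision(cov)
        assert pcor[0, 1] == pytest.approx(r)

    def test_cross_method_agreement_with_regression_route(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((4, 4))
        cov = a @ a.T + 4 * np.eye(4)
        z = rng.multivariate_normal(np.zeros(4), cov, size=5000)
        net = fit_contemporaneous(pd.DataFrame(z, columns=list("abcd")), list("abcd"))
        assert np.max(np.abs(net.weights.to_numpy() - pcor_from_precision(cov))) < 0.04

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            pcor_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            pcor_from_precision(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestTypeOneCalibration:
    def test_temporal_p_rejection_rate_near_nominal(self, null_study):
        # data generated with B = 0: off-diagonal p<.05 fraction ~ 5%
        assert null_study["sig"]["temporal"] == pytest.approx(0.05, abs=0.02)

    def test_detection_rate_band_per_network(self, null_study):
        for name in ("temporal", "contemporaneous", "between"):
            assert 0.02 <= null_study["sig"][name] <= 0.09, name


class TestRecoveryScenario:
    def test_temporal_and_contemporaneous_weight_recovery(self, recovery_benchmark):
        report = recovery_benchmark["report"].table
        assert report.loc["temporal", "weight_correlation"] >= 0.9
        assert report.loc["contemporaneous", "weight_correlation"] >= 0.85

    def test_between_matches_person_mean_pcor_oracle(self, recovery_benchmark):
        # the mixed-model between network agrees with partial correlations
        # computed directly from the sample person means
        means = person_statistics(recovery_benchmark["dataset"])
        oracle = pcor_from_precision(np.cov(means.means.to_numpy().T))
        est = recovery_benchmark["between"].weights.to_numpy()
        off = ~np.eye(est.shape[0], dtype=bool)
        # sign conflicts are zeroed in the estimator, not the oracle
        mask = off & (est != 0)
        assert np.corrcoef(est[mask], oracle[mask])[0, 1] > 0.95
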