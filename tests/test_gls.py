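import numpy as np
import pandas as pd
import pytest

from swtime import (
    Design,
    TreatmentStructure,
    VarianceComponents,
    aggregate_estimands,
    estimand_truth,
    fit_fgls,
    fit_gls,
)
from swtime.design import design_matrix
from swtime.gls import (
    EstimationError,
    GLSWorkspace,
    cluster_period_means,
    estimand_contrast,
)
from swtime.simulate import SimulationScenario, generate_trial, reference_scenario
from swtime.weights import it_sequence_period_weights


def _noiseless_frame(design, structure, trend):
    scenario = SimulationScenario(
        design=design,
        structure=structure,
        vc=VarianceComponents(0.0, 0.0, 1e-30),
        trend=trend,
        n_reps=1,
        seed=0,
    )
    idx = design.cell_index
    idx["ybar"] = scenario.expected_cell_means()
    return idx


class TestFitGLS:
    @pytest.mark.parametrize("kind, effects", [
        ("IT", [4.0]),
        ("ETI", [0.5, 1.0, 2.0]),
        ("CTI", [1.5, -0.5]),
    ])
    @pytest.mark.parametrize("g", [0.0, 0.4, 0.69])
    def test_noiseless_recovery(self, design_3x4, kind, effects, g):
        """Correctly specified fits interpolate noiseless means exactly."""
        trend = np.array([2.0, 2.5, 3.5, 5.0])
        structure = TreatmentStructure(kind, effects)
        data = _noiseless_frame(design_3x4, structure, trend)
        fit = fit_gls(data, design_3x4, kind, g)
        assert np.allclose(fit.coef_treatment, np.atleast_1d(effects), atol=1e-10)
        assert np.allclose(fit.coef_period, trend, atol=1e-10)

    @pytest.mark.parametrize("kind", ["IT", "ETI", "CTI"])
    def test_null_effect_recovers_trend(self, design_3x4, kind):
        trend = np.array([1.0, 2.0, 3.0, 4.0])
        n = design_3x4.n_treatment_columns(kind)
        structure = TreatmentStructure(kind, np.zeros(max(n, 1)) if kind != "IT" else [0.0])
        data = _noiseless_frame(design_3x4, structure, trend)
        fit = fit_gls(data, design_3x4, kind, 0.5)
        assert np.allclose(fit.coef_treatment, 0.0, atol=1e-10)
        assert np.allclose(fit.coef_period, trend, atol=1e-10)

    @pytest.mark.parametrize("kind", ["IT", "ETI", "CTI"])
    def test_total_var_cancels(self, design_3x4, kind, rng):
        """Point estimates agree with statsmodels GLS at any overall scale."""
        sm = pytest.importorskip("statsmodels.api")
        from swtime.correlation import cluster_block

        ybar = rng.normal(size=design_3x4.n_cells)
        ws = GLSWorkspace(design_3x4, kind)
        ours = fit_gls(ybar, design_3x4, kind, 0.55).coef
        for tot in (0.5, 1.0, 7.0):
            sigma = np.kron(np.eye(design_3x4.I), cluster_block(design_3x4.J, 0.55, tot))
            ref = sm.GLS(ybar, ws.Z, sigma=sigma).fit().params
            assert np.allclose(ours, ref, atol=1e-9)

    def test_gamma_zero_is_ols(self, ref_design, rng):
        ybar = rng.normal(size=ref_design.n_cells)
        Z, _ = design_matrix(ref_design, "ETI")
        ols = np.linalg.lstsq(Z, ybar, rcond=None)[0]
        fit = fit_gls(ybar, ref_design, "ETI", 0.0)
        assert np.allclose(fit.coef, ols, atol=1e-10)

    @pytest.mark.parametrize("Q", [2, 3, 6, 9])
    @pytest.mark.parametrize("g", [0.0, 0.3, 0.69, 0.9])
    def test_it_estimate_matches_sequence_weight_closed_form(self, Q, g, rng):
        """The IT estimator equals its printed weighted sum of sequence-period means."""
        d = Design(I=2 * Q, J=Q + 1, K=3)
        ybar = rng.normal(size=d.n_cells)
        fit = fit_gls(ybar, d, "IT", g)
        seq_means = ybar.reshape(Q, 2, Q + 1).mean(axis=1)
        closed = float(np.sum(it_sequence_period_weights(Q, g) * seq_means))
        assert fit.coef_treatment[0] == pytest.approx(closed, abs=1e-8)


class TestTrialDataValidation:
    def test_unbalanced_rejected(self, design_3x4, small_scenario):
        df = generate_trial(small_scenario, 0)
        with pytest.raises(EstimationError, match="unbalanced"):
            cluster_period_means(df.iloc[:-1], small_scenario.design)

    def test_wrong_sequence_labels_rejected(self, small_scenario):
        df = generate_trial(small_scenario, 0)
        df.loc[df.cluster == 1, "sequence"] = 3
        with pytest.raises(EstimationError, match="sequence"):
            cluster_period_means(df, small_scenario.design)

    def test_mean_input_round_trip(self, small_scenario):
        d = small_scenario.design
        df = generate_trial(small_scenario, 0)
        from_individuals = cluster_period_means(df, d)
        means = d.cell_index
        means["ybar"] = from_individuals
        assert np.allclose(cluster_period_means(means, d), from_individuals)


class TestFGLS:
    def test_against_mixed_model_oracle(self):
        """Frozen reference values from an lme4 REML fit (random intercept plus
        cluster-period interaction) of the deterministic seed-21 replicate."""
        sc = reference_scenario("IT", seed=21)
        fit = fit_fgls(generate_trial(sc, 0), sc.design, "IT")
        assert fit.components.tau_alpha_sq == pytest.approx(0.102017177, abs=5e-5)
        assert fit.components.tau_omega_sq == pytest.approx(0.007227508, abs=5e-5)
        assert fit.components.sigma_e_sq == pytest.approx(0.979949890, abs=5e-6)
        assert fit.coef_treatment[0] == pytest.approx(6.085783, abs=5e-5)

    def test_component_recovery(self):
        """Across replicates at larger I, component estimates center on the truth."""
        sc = reference_scenario("IT", seed=77)
        from dataclasses import replace

        big = replace(sc, design=Design(I=90, J=10, K=30))
        est = []
        for rep in range(8):
            fit = fit_fgls(generate_trial(big, rep), big.design, "IT")
            c = fit.components
            est.append([c.tau_alpha_sq, c.tau_omega_sq, c.sigma_e_sq])
        est = np.asarray(est)
        truth = np.array([0.1, 1 / 90, 1.0])
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - truth) < 4 * se + 1e-3)

    def test_degenerate_components_reach_ols(self, small_scenario):
        from dataclasses import replace

        sc = replace(small_scenario, vc=VarianceComponents(0.0, 0.0, 1.0))
        df = generate_trial(sc, 3)
        fit = fit_fgls(df, sc.design, "IT")
        assert fit.gamma_used < 0.35
        ols = fit_gls(cluster_period_means(df, sc.design), sc.design, "IT", 0.0)
        assert np.allclose(fit.coef, ols.coef, atol=0.2)

    def test_tiny_noise_interpolation(self, design_3x4):
        """With vanishing residual noise the fit is insensitive to gamma."""
        structure = TreatmentStructure("ETI", [0.5, 1.0, 2.0])
        trend = np.array([1.0, 2.0, 3.0, 4.0])
        sc = SimulationScenario(
            design=Design(I=3, J=4, K=5),
            structure=structure,
            vc=VarianceComponents(0.0, 0.0, 1e-12),
            trend=trend,
            seed=5,
        )
        df = generate_trial(sc, 0)
        f = fit_fgls(df, sc.design, "ETI")
        for g in (0.0, 0.5, 0.9):
            assert np.allclose(f.coef, fit_gls(df, sc.design, "ETI", g).coef, atol=1e-5)


class TestEstimands:
    def test_etate_value(self, ref_design, eti_curve):
        assert estimand_truth(eti_curve, ref_design) == pytest.approx(2.8333333333, abs=1e-9)

    def test_ctate_value(self, ref_design, cti_curve):
        assert estimand_truth(cti_curve, ref_design) == pytest.approx(1.325, abs=1e-12)

    def test_it_truth_is_theta(self, ref_design):
        assert estimand_truth(TreatmentStructure("IT", [6.0]), ref_design) == 6.0

    def test_constant_vector_aggregates_to_itself(self, ref_design):
        c = TreatmentStructure("ETI", np.full(9, 1.7))
        assert estimand_truth(c, ref_design) == pytest.approx(1.7)

    @pytest.mark.parametrize("kind, effects, label, value", [
        ("ETI", [0, 0, 0.5, 1, 2, 4, 6, 6, 6], "ETATE", 2.83333333333),
        ("CTI", [6, 3, 1, 0.5, 0.1, 0, 0, 0], "CTATE", 1.325),
        ("IT", [6.0], "IT", 6.0),
    ])
    def test_aggregate_from_fit(self, ref_design, kind, effects, label, value):
        """Fitting noiseless data and aggregating returns the estimand exactly."""
        structure = TreatmentStructure(kind, effects)
        trend = np.arange(5.0, 15.0)
        data = _noiseless_frame(ref_design, structure, trend)
        got_label, got = aggregate_estimands(fit_gls(data, ref_design, kind, 0.69))
        assert got_label == label
        assert got == pytest.approx(value, abs=1e-9)

    def test_contrast_matches_aggregate(self, ref_design, rng):
        ybar = rng.normal(size=ref_design.n_cells)
        fit = fit_gls(ybar, ref_design, "ETI", 0.3)
        c = estimand_contrast(ref_design, "ETI")
        assert float(c @ fit.coef) == pytest.approx(aggregate_estimands(fit)[1])
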