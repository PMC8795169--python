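"""Weighting-function evaluation, folding, the CI-weighted objective, unfolding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microq import (
    IonBeamSpec,
    LinealEnergySpectrum,
    QualityFunction,
    UnfoldingProblem,
    fold,
    frequency_to_dose,
    goodness_of_fit,
    objective,
    peak_location,
    q_eval,
    triangular_spectrum,
    unfold,
)
from microq.synthetic import make_unfolding_problem
from microq.unfolding import read_problem, write_problem, refine_grid

NTE_16UM = QualityFunction(2.91, 0.34, 0.95, effect_channel="NTE")


class TestQEval:
    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0, 10))
    def test_q_at_zero_is_one(self, k1, k2, k3):
        assert q_eval(QualityFunction(k1, k2, k3), 0.0) == 1.0

    def test_flat_when_k1_k3_zero(self):
        qf = QualityFunction(0.0, 2.0, 0.0)
        y = np.linspace(0, 500, 100)
        assert q_eval(qf, y) == pytest.approx(np.ones(100))

    def test_closed_form_value(self):
        # frozen independent arithmetic of exp[k1 u^k2 - k3 u^(1+k2)], u = 0.777
        assert q_eval(NTE_16UM, 77.7) == pytest.approx(7.339725236035634, rel=1e-12)

    def test_negative_y_rejected(self):
        with pytest.raises(ValueError):
            q_eval(NTE_16UM, -1.0)

    def test_parameters_outside_box_rejected(self):
        with pytest.raises(ValueError):
            QualityFunction(11.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            QualityFunction(1.0, -0.1, 1.0)


class TestPeakLocation:
    def test_symmetric_parameters_peak_at_50(self):
        # k1 = k3, k2 = 1: y* = 100 k2/(1+k2) = 50
        assert peak_location(QualityFunction(2.0, 1.0, 2.0)) == pytest.approx(50.0)

    def test_peak_is_local_maximum(self):
        y_star = peak_location(NTE_16UM)
        q_star = q_eval(NTE_16UM, y_star)
        assert q_star >= q_eval(NTE_16UM, y_star * 0.99)
        assert q_star >= q_eval(NTE_16UM, y_star * 1.01)

    def test_published_nte_peak_between_50_and_100(self):
        assert 50 < peak_location(NTE_16UM) < 100

    def test_degenerate_parameters_raise(self):
        with pytest.raises(ValueError, match="no interior peak"):
            peak_location(QualityFunction(1.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="no interior peak"):
            peak_location(QualityFunction(1.0, 1.0, 0.0))


class TestFold:
    def test_unit_q_folds_to_one(self, dose_spectra):
        qf = QualityFunction(0.0, 1.0, 0.0)
        for spec in dose_spectra:
            assert fold(qf, spec) == pytest.approx(1.0, abs=1e-9)

    def test_single_line_spectrum_sifts(self):
        y = np.linspace(1.0, 200.0, 2000)
        rho = np.zeros_like(y)
        idx = np.argmin(np.abs(y - 77.7))
        rho[idx] = 1.0
        spec = LinealEnergySpectrum(y, rho, representation="dose")
        assert fold(NTE_16UM, spec) == pytest.approx(q_eval(NTE_16UM, y[idx]), rel=1e-6)

    def test_frequency_input_autoconverted(self, carbon_beam):
        freq = triangular_spectrum(carbon_beam)
        assert fold(NTE_16UM, freq) == pytest.approx(
            fold(NTE_16UM, frequency_to_dose(freq)), rel=1e-12
        )

    def test_higher_let_spectrum_folds_larger_for_increasing_q(self):
        # monotone-increasing q over the support orders folds by dose-mean
        qf = QualityFunction(3.0, 1.0, 0.0)  # increasing up to y=inf
        low = frequency_to_dose(triangular_spectrum(IonBeamSpec("C", 13.0)))
        high = frequency_to_dose(triangular_spectrum(IonBeamSpec("Si", 69.0)))
        assert fold(qf, high) > fold(qf, low)

    def test_fold_converges_under_grid_refinement(self, carbon_beam):
        spec = frequency_to_dose(triangular_spectrum(carbon_beam, 128))
        coarse = fold(NTE_16UM, spec)
        fine = fold(NTE_16UM, refine_grid(spec, 4))
        assert fine == pytest.approx(coarse, rel=1e-3)


class TestObjective:
    def test_perfect_fit_is_zero(self, dose_spectra, beams):
        qf = QualityFunction(1.5, 0.8, 0.6)
        obs = np.array([fold(qf, sp) for sp in dose_spectra])
        prob = UnfoldingProblem(
            labels=tuple(b.label for b in beams), spectra=dose_spectra,
            observed=obs, ci_widths=np.full(obs.size, 0.1),
        )
        assert objective(qf.k, prob) == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_two_residual_toy(self, dose_spectra, beams):
        # residuals 0.1 and 0.2 with widths 0.5: F = 0.04 + 0.16 = 0.20
        qf = QualityFunction(0.0, 1.0, 0.0)  # predicts exactly 1 everywhere
        prob = UnfoldingProblem(
            labels=tuple(b.label for b in beams[:3]), spectra=dose_spectra[:3],
            observed=np.array([1.1, 1.2, 1.0]), ci_widths=np.array([0.5, 0.5, 1e9]),
        )
        assert objective(qf.k, prob) == pytest.approx(0.20, rel=1e-9)

    def test_doubling_ci_widths_quarters_objective(self, dose_spectra, beams):
        obs = np.array([1.2, 2.0, 3.0, 4.0, 5.0, 4.5])
        make = lambda w: UnfoldingProblem(
            labels=tuple(b.label for b in beams), spectra=dose_spectra,
            observed=obs, ci_widths=np.full(6, w),
        )
        k = (2.0, 0.5, 1.0)
        assert objective(k, make(0.4)) == pytest.approx(objective(k, make(0.2)) / 4, rel=1e-9)

    def test_reorder_invariance(self, dose_spectra, beams):
        obs = np.array([1.2, 2.0, 3.0, 4.0, 5.0, 4.5])
        widths = np.array([0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        perm = [3, 1, 5, 0, 4, 2]
        a = UnfoldingProblem(tuple(b.label for b in beams), dose_spectra, obs, widths)
        b = UnfoldingProblem(
            tuple(beams[i].label for i in perm),
            tuple(dose_spectra[i] for i in perm), obs[perm], widths[perm],
        )
        k = (1.0, 1.0, 1.0)
        assert objective(k, a) == pytest.approx(objective(k, b), rel=1e-12)

    def test_zero_ci_width_rejected_at_construction(self, dose_spectra, beams):
        with pytest.raises(ValueError, match="positive"):
            UnfoldingProblem(
                tuple(b.label for b in beams), dose_spectra,
                np.ones(6), np.array([0.1, 0.1, 0.0, 0.1, 0.1, 0.1]),
            )

    def test_fewer_than_three_types_rejected(self, dose_spectra, beams):
        with pytest.raises(ValueError, match="3"):
            UnfoldingProblem(
                tuple(b.label for b in beams[:2]), dose_spectra[:2],
                np.ones(2), np.full(2, 0.1),
            )


class TestUnfold:
    def test_noiseless_inverse_recovers_predictions(self):
        truth = (2.91, 0.34, 0.95)
        prob = make_unfolding_problem(truth, ci_width=0.1, noise_sd=0.0, seed=0)
        res = unfold(prob, n_restarts=40, seed=1)
        assert res.objective_value < 1e-6
        assert res.predicted == pytest.approx(prob.observed, abs=1e-4)

    def test_single_restart_at_optimum_is_fixed_point(self):
        truth = (2.0, 0.5, 0.8)
        prob = make_unfolding_problem(truth, ci_width=0.1, seed=0)
        res = unfold(prob, n_restarts=1, seed=1, x0=truth)
        assert res.objective_value < 1e-10
        assert res.best.k == pytest.approx(truth, abs=1e-3)

    def test_deterministic_given_seed(self):
        prob = make_unfolding_problem((1.5, 0.7, 0.4), noise_sd=0.05, seed=3)
        a = unfold(prob, n_restarts=20, seed=9)
        b = unfold(prob, n_restarts=20, seed=9)
        assert a.best.k == b.best.k
        assert a.objective_value == b.objective_value

    def test_best_objective_non_increasing_in_restarts(self):
        prob = make_unfolding_problem((1.5, 0.7, 0.4), noise_sd=0.3, seed=3)
        f_few = unfold(prob, n_restarts=3, seed=9).objective_value
        f_many = unfold(prob, n_restarts=30, seed=9).objective_value
        assert f_many <= f_few + 1e-12

    def test_noisy_objective_in_chi2_band(self):
        # noise sd = CI/3.92: residual scale implies F near n * (1/3.92)^2 band
        from scipy.stats import chi2

        prob = make_unfolding_problem(
            (2.91, 0.34, 0.95), ci_width=0.5, noise_sd=0.5 / 3.92, seed=12
        )
        res = unfold(prob, n_restarts=40, seed=2)
        # F/ (sd/ci)^2 behaves like a chi^2 with at most n=6 dof (3 fitted params)
        scaled = res.objective_value / (1 / 3.92) ** 2
        assert scaled < chi2.ppf(0.999, 6)

    def test_restart_log_sorted(self):
        prob = make_unfolding_problem((1.0, 1.0, 1.0), noise_sd=0.2, seed=4)
        res = unfold(prob, n_restarts=15, seed=4)
        objs = [f for f, _ in res.restarts]
        assert objs == sorted(objs)
        assert res.objective_value == pytest.approx(objs[0])

    def test_zero_restarts_rejected(self):
        prob = make_unfolding_problem((1.0, 1.0, 1.0), seed=4)
        with pytest.raises(ValueError):
            unfold(prob, n_restarts=0)


class TestGoodnessOfFit:
    def test_perfect_predictions(self):
        prob = make_unfolding_problem((2.0, 0.5, 0.8), seed=0)
        res = unfold(prob, n_restarts=10, seed=0)
        r2, rmse = goodness_of_fit(res, prob)
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert rmse == pytest.approx(0.0, abs=1e-4)

    def test_constant_prediction_at_mean_gives_zero_r2(self, dose_spectra, beams):
        from microq.unfolding import _r2_rmse

        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r2, _ = _r2_rmse(np.full(6, obs.mean()), obs)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_toy_rmse(self):
        from microq.unfolding import _r2_rmse

        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = obs + np.array([0.1, -0.1, 0.1, -0.1])
        _, rmse = _r2_rmse(pred, obs)
        assert rmse == pytest.approx(0.1, rel=1e-12)

    def test_constant_observations_flagged(self):
        from microq.unfolding import _r2_rmse

        with pytest.raises(ValueError, match="undefined"):
            _r2_rmse(np.array([1.0, 1.1]), np.array([1.0, 1.0]))


def test_problem_bundle_round_trip(tmp_path):
    prob = make_unfolding_problem((2.91, 0.34, 0.95), noise_sd=0.1, seed=6,
                                  effect_channel="NTE")
    path = tmp_path / "problem.yaml"
    write_problem(prob, path, spectrum_dir=tmp_path / "spectra")
    back = read_problem(path)
    assert back.labels == prob.labels
    assert back.effect_channel == "NTE"
    assert back.observed == pytest.approx(prob.observed, rel=1e-9)
    assert back.ci_widths == pytest.approx(prob.ci_widths)
    assert back.spectra[0].density == pytest.approx(prob.spectra[0].density, rel=1e-8)
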