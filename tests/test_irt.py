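import numpy as np
import pytest
from scipy import integrate, stats

import lpfsbench as lb
from lpfsbench.core import AnalysisConfig, ValidationError

THETA_GRID = np.linspace(-6, 6, 241)


class TestCategoryProbs:
    def test_grm_published_item_at_zero(self):
        p = lb.GRMItemParams(a=3.05, b=np.array([0.01, 0.77, 1.71]))
        probs = lb.grm_category_probs(p, [0.0])[0]
        assert np.allclose(probs, [0.5076, 0.4052, 0.0818, 0.0054], atol=1e-3)

    def test_grm_lower_boundary(self, ref_items):
        for p in ref_items:
            probs = lb.grm_category_probs(p, [-35.0])[0]
            assert np.allclose(probs, [1, 0, 0, 0], atol=1e-12)

    def test_probs_normalize_on_grid(self, ref_items):
        for p in ref_items:
            total = lb.grm_category_probs(p, THETA_GRID).sum(axis=1)
            assert np.allclose(total, 1.0, atol=1e-12)
            g = lb.GPCMItemParams(a=p.a, d=p.b)
            assert np.allclose(
                lb.gpcm_category_probs(g, THETA_GRID).sum(axis=1), 1.0, atol=1e-12
            )

    def test_gpcm_vanishing_slope_is_uniform(self):
        g = lb.GPCMItemParams(a=1e-9, d=np.array([-1.0, 0.0, 1.0]))
        probs = lb.gpcm_category_probs(g, THETA_GRID)
        assert np.allclose(probs, 0.25, atol=1e-6)

    def test_gpcm_binary_reduces_to_2pl(self):
        g = lb.GPCMItemParams(a=1.7, d=np.array([0.4]))
        probs = lb.gpcm_category_probs(g, THETA_GRID)
        expected = 1 / (1 + np.exp(-1.7 * (THETA_GRID - 0.4)))
        assert np.allclose(probs[:, 1], expected, atol=1e-12)
        assert np.allclose(probs[:, 0], 1 - expected, atol=1e-12)

    def test_gpcm_mode_brackets_theta(self):
        g = lb.GPCMItemParams(a=8.0, d=np.array([-1.0, 0.0, 1.0]))
        probs = lb.gpcm_category_probs(g, np.array([-0.5]))[0]
        assert probs.argmax() == 1  # between the first and second step

    def test_grm_cumulative_curves_ordered_and_increasing(self, ref_items):
        for p in ref_items:
            cum = lb.irt.grm_cumulative_probs(p, THETA_GRID)
            assert (np.diff(cum, axis=0) > 0).all()  # increasing in theta
            assert (np.diff(cum, axis=1) < 0).all()  # ordered in k


class TestInformation:
    def test_nonnegative(self, ref_items):
        for p in ref_items:
            assert (lb.item_information(p, THETA_GRID) >= 0).all()
        g = lb.GPCMItemParams(a=1.5, d=np.array([-0.5, 0.5]))
        assert (lb.item_information(g, THETA_GRID) >= 0).all()

    def test_doubling_slope_raises_peak(self):
        b = np.array([-0.5, 0.3, 1.2])
        low = lb.item_information(lb.GRMItemParams(a=1.2, b=b), THETA_GRID)
        high = lb.item_information(lb.GRMItemParams(a=2.4, b=b), THETA_GRID)
        assert high.max() > low.max()

    def test_reference_battery_peaks_in_reported_range(self, ref_items):
        curve = lb.test_information(ref_items, THETA_GRID)
        peak = THETA_GRID[np.argmax(curve)]
        assert -2.0 < peak < 4.0


class TestFit:
    def test_slope_recovery(self, ref_items, grm_fit_2000):
        a_true = np.array([p.a for p in ref_items])
        a_est = np.array([p.a for p in grm_fit_2000.items])
        assert np.corrcoef(a_true, a_est)[0, 1] > 0.9
        b_true = np.vstack([p.b for p in ref_items])
        b_est = np.vstack([p.b for p in grm_fit_2000.items])
        assert np.median(np.abs(b_true - b_est)) < 0.15

    def test_study_scale_sample_recovers_high_slopes(self):
        spec = lb.SimulationSpec(n=530, seed=12)
        responses, _ = lb.simulate_responses(spec)
        fit = lb.fit_grm(responses)
        assert all(p.a > 1.0 for p in fit.items)

    def test_refit_deterministic(self):
        spec = lb.SimulationSpec(n=300, seed=4)
        responses, _ = lb.simulate_responses(spec)
        f1 = lb.fit_grm(responses)
        f2 = lb.fit_grm(responses)
        assert abs(f1.loglik - f2.loglik) < 1e-8

    def test_loglik_monotone_over_cycles(self, grm_fit_2000, gpcm_fit_2000):
        for fit in (grm_fit_2000, gpcm_fit_2000):
            assert (np.diff(fit.loglik_history) > -1e-8).all()

    def test_quadrature_refinement_stable(self):
        spec = lb.SimulationSpec(n=300, seed=4)
        responses, _ = lb.simulate_responses(spec)
        coarse = lb.fit_grm(responses, lb.LatentGrid.equally_spaced(61))
        fine_grid = lb.LatentGrid.equally_spaced(121)
        ll_fine = lb.case_loglik(
            lb.FitResult(**{**coarse.__dict__, "grid": fine_grid}), responses
        ).sum()
        assert abs(ll_fine - coarse.loglik) < 1e-3

    def test_single_category_item_rejected(self):
        values = np.full((50, 12), 2)
        values[:, 1:] = np.tile([1, 2, 3, 4], (50, 3))[:, : 11]
        with pytest.raises(ValidationError, match="single observed category"):
            lb.fit_grm(lb.ResponseMatrix(values=values))


class TestCaseLoglik:
    def test_sums_to_marginal(self, grm_fit_2000, resp_2000):
        responses, _ = resp_2000
        cll = lb.case_loglik(grm_fit_2000, responses)
        assert np.allclose(cll, grm_fit_2000.case_loglik, atol=1e-10)
        assert abs(cll.sum() - grm_fit_2000.loglik) < 1e-8

    def test_matches_adaptive_integration(self, grm_fit_2000, resp_2000):
        responses, _ = resp_2000
        x0 = responses.zero_based()
        for row in [0, 17, 101, 555, 1999]:
            def integrand(theta):
                prod = stats.norm.pdf(theta)
                for i, p in enumerate(grm_fit_2000.items):
                    prod *= lb.grm_category_probs(p, np.array([theta]))[0, x0[row, i]]
                return prod
            exact, _ = integrate.quad(integrand, -9, 9, limit=200)
            assert abs(grm_fit_2000.case_loglik[row] - np.log(exact)) < 1e-4

    def test_zero_discrimination_is_theta_free(self):
        # with vanishing slopes the marginal likelihood is the product of the
        # prior-marginal category probabilities
        items = [
            lb.GRMItemParams(a=1e-9, b=np.array([-0.5, 0.5])),
            lb.GRMItemParams(a=1e-9, b=np.array([-0.5, 0.5])),
        ]
        grid = lb.LatentGrid.equally_spaced(61)
        responses = lb.ResponseMatrix(
            values=np.array([[1, 3]]), item_ids=("A", "B"), n_categories=3
        )
        fit = lb.FitResult(
            model="GRM", items=items, item_ids=("A", "B"), loglik=0.0,
            case_loglik=np.zeros(1), loglik_history=np.zeros(1), n_cycles=0,
            converged=True, grid=grid, eap=np.zeros(1), eap_sd=np.ones(1),
        )
        cll = lb.case_loglik(fit, responses)
        marginal = lb.grm_category_probs(items[0], [0.0])[0]
        assert cll[0] == pytest.approx(np.log(marginal[0]) + np.log(marginal[2]), abs=1e-6)


class TestVuong:
    def test_identical_fits_indistinguishable(self, grm_fit_2000):
        res = lb.vuong_test(grm_fit_2000, grm_fit_2000)
        assert not res.distinguishable
        assert res.z == 0.0

    def test_swap_flips_z(self, grm_fit_2000, gpcm_fit_2000):
        ab = lb.vuong_test(grm_fit_2000, gpcm_fit_2000)
        ba = lb.vuong_test(gpcm_fit_2000, grm_fit_2000)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.omega_sq == pytest.approx(ba.omega_sq, abs=1e-12)

    def test_generating_model_preferred(self, grm_fit_2000, gpcm_fit_2000):
        res = lb.vuong_test(grm_fit_2000, gpcm_fit_2000)
        assert res.distinguishable
        assert res.z > 0  # data were generated from the GRM
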