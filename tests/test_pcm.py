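"""Pattern-component correlation models: likelihood, fitting, group tools."""

import numpy as np
import pytest
from scipy import stats as sps

from prepmvpa.design import CONDITIONS
from prepmvpa.pcm import (
    CorrelationPCM,
    SecondMomentModel,
    build_correlation_model,
    correlation_grid,
    group_correlation_summary,
    loso_best_model,
    marginal_loglik,
    naive_correlation,
    predicted_g,
)
from prepmvpa.rdm import crossnobis_rdm, g_to_rdm
from prepmvpa.simulate import generate_ground_truth, simulate_subject_betas


class TestSecondMoment:
    def test_zero_correlation_has_zero_cross_finger_block(self):
        g = predicted_g(0.0, (0.3, 1.0, 0.5, 0.8))
        assert np.allclose(g[:3, 3:], 0.0)

    def test_perfect_correlation_matches_within_block_component(self):
        s = 0.7
        g = predicted_g(1.0, (0.0, 0.0, s, s))
        assert np.allclose(g[:3, 3:], s * np.eye(3))
        assert np.allclose(g[:3, :3], g[:3, 3:])

    def test_structure_of_blocks(self):
        a_p, a_e, s_p, s_e = 0.2, 2.0, 0.3, 1.1
        g = predicted_g(0.5, (a_p, a_e, s_p, s_e))
        assert np.allclose(g[:3, :3], a_p * np.ones((3, 3)) + s_p * np.eye(3))
        assert np.allclose(g[3:, 3:], a_e * np.ones((3, 3)) + s_e * np.eye(3))
        assert np.allclose(g[:3, 3:], 0.5 * np.sqrt(s_p * s_e) * np.eye(3))

    @pytest.mark.parametrize("r", [0.0, 0.3, 1.0])
    def test_predicted_g_is_psd(self, r):
        vals = np.linalg.eigvalsh(predicted_g(r, (0.1, 2.0, 0.4, 1.3)))
        assert vals.min() > -1e-12

    def test_five_free_parameters_for_any_r(self):
        for r in (0.0, 0.37, 1.0):
            assert build_correlation_model(r).n_free_parameters == 5

    def test_invalid_correlation_rejected(self):
        for r in (-0.1, 1.5):
            with pytest.raises(ValueError):
                build_correlation_model(r)

    def test_grid_definitions(self):
        g100 = correlation_grid(100)
        assert g100.size == 100 and g100[0] == 0.0 and g100[-1] == 1.0
        assert np.allclose(np.diff(g100), 1.0 / 99.0)
        g101 = correlation_grid(step_001=True)
        assert g101.size == 101 and np.allclose(np.diff(g101), 0.01)


class TestLoglik:
    def test_zero_signal_reduces_to_iid_gaussian(self, rng):
        """With G = 0 the marginal likelihood is the closed-form iid normal."""
        y = rng.standard_normal((8, 5))
        sigma2 = 1.7
        z = np.concatenate([np.eye(4)] * 2, axis=0)
        ll = marginal_loglik(y, z, np.zeros((4, 4)), sigma2)
        expected = np.sum(sps.norm.logpdf(y, scale=np.sqrt(sigma2)))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_matches_dense_multivariate_normal_oracle(self, rng):
        """Tiny instance (2 runs, 2 conditions, 3 voxels) against a literal
        dense density evaluated with scipy."""
        y = rng.standard_normal((4, 3))
        z = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        g = np.array([[1.2, 0.4], [0.4, 0.9]])
        sigma2 = 0.6
        ll = marginal_loglik(y, z, g, sigma2)
        v = z @ g @ z.T + sigma2 * np.eye(4)
        oracle = sum(
            sps.multivariate_normal.logpdf(y[:, p], mean=np.zeros(4), cov=v)
            for p in range(3)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_model_loglik_consistent_with_generic_function(self, rng):
        pats = rng.standard_normal((3, 6, 10))
        model = CorrelationPCM(pats, fix_run_means=False)
        theta = np.log([0.2, 1.5, 0.3, 1.0, 0.8])
        smm = SecondMomentModel(0.4)
        z = np.concatenate([np.eye(6)] * 3, axis=0)
        expected = marginal_loglik(pats.reshape(18, 10), z, smm.g(theta), 0.8)
        assert model.loglik(theta, 0.4) == pytest.approx(expected, abs=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        pats = rng.standard_normal((4, 6, 12))
        model = CorrelationPCM(pats)
        smm = SecondMomentModel(0.6)
        theta = np.log([0.5, 1.0, 0.4, 0.9, 1.1])
        ll, grad = model._loglik_grad(theta, smm)
        eps = 1e-6
        for h in range(5):
            up, dn = theta.copy(), theta.copy()
            up[h] += eps
            dn[h] -= eps
            num = (model.loglik(up, 0.6) - model.loglik(dn, 0.6)) / (2 * eps)
            assert grad[h] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestFit:
    def test_parameter_recovery_at_scale(self):
        """Generated exactly from the model with many voxels, the fitted
        variances land within 10% of truth."""
        variances = (0.3, 1.5, 0.5, 1.0)
        truth = generate_ground_truth(5000, 0.6, variances, seed=31, sigma2=0.5)
        pats = simulate_subject_betas(truth, 10, seed=32)
        fit = CorrelationPCM(pats, fix_run_means=False).fit(0.6)
        est = fit.variances
        assert est["s_plan"] == pytest.approx(0.5, rel=0.1)
        assert est["s_exec"] == pytest.approx(1.0, rel=0.1)
        assert est["sigma2_eps"] == pytest.approx(0.5, rel=0.1)
        assert fit.converged

    def test_scale_equivariance(self):
        """Scaling the data by c scales the fitted variances by c^2.

        With run means as fixed effects the two phase-mean variances are
        identified only through their sum (centering maps both onto the
        same plan-vs-exec contrast), so the sum is compared for them.
        """
        truth = generate_ground_truth(150, 0.5, seed=39, sigma2=0.5)
        pats = simulate_subject_betas(truth, 6, seed=40)
        v1 = CorrelationPCM(pats).fit(0.5).variances
        v2 = CorrelationPCM(3.0 * pats).fit(0.5).variances
        assert v2["a_plan"] + v2["a_exec"] == pytest.approx(9.0 * (v1["a_plan"] + v1["a_exec"]), rel=1e-2)
        for name in ("s_plan", "s_exec", "sigma2_eps"):
            assert v2[name] == pytest.approx(9.0 * v1[name], rel=1e-2)

    def test_voxel_permutation_leaves_loglik_unchanged(self, rng):
        pats = rng.standard_normal((4, 6, 30))
        perm = rng.permutation(30)
        f1 = CorrelationPCM(pats).fit(0.3)
        f2 = CorrelationPCM(pats[:, :, perm]).fit(0.3)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)

    def test_refit_from_perturbed_start_is_stable(self, rng):
        truth = generate_ground_truth(100, 0.5, seed=33, sigma2=0.5)
        pats = simulate_subject_betas(truth, 8, seed=34)
        model = CorrelationPCM(pats)
        fit = model.fit(0.5)
        refit = model.fit(0.5, start=fit.theta + 0.3, n_starts=1)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_grid_argmax_at_one_for_noiseless_perfect_correlation(self):
        truth = generate_ground_truth(300, 1.0, seed=35, sigma2=0.0)
        pats = simulate_subject_betas(truth, 4, seed=36, noise_var=1e-4)
        grid = CorrelationPCM(pats).fit_grid(20)
        assert grid.best_r == pytest.approx(1.0)

    def test_grid_recovers_interior_correlation(self):
        truth = generate_ground_truth(400, 0.8, seed=37, sigma2=0.1)
        pats = simulate_subject_betas(truth, 10, seed=38)
        grid = CorrelationPCM(pats).fit_grid(34)
        assert grid.best_r == pytest.approx(0.8, abs=0.12)
        assert grid.summary().shape[0] == 34

    @pytest.mark.parametrize("r_true", [0.0, 0.5, 1.0])
    def test_expected_likelihood_peaks_near_truth(self, r_true):
        """Averaged over replicates, the grid log-likelihood is maximal at
        the model nearest the generating correlation."""
        rs = np.linspace(0.0, 1.0, 11)
        acc = np.zeros(rs.size)
        for rep in range(8):
            truth = generate_ground_truth(150, r_true, seed=100 + rep, sigma2=0.3)
            pats = simulate_subject_betas(truth, 8, seed=200 + rep)
            grid = CorrelationPCM(pats).fit_grid(grid=rs)
            acc += grid.loglik
        nearest = np.argmin(np.abs(rs - r_true))
        assert abs(rs[np.argmax(acc)] - rs[nearest]) <= 0.1 + 1e-9


class TestRdmCorrespondence:
    def test_expected_crossnobis_matches_g_implied_rdm(self):
        """Mean crossnobis RDM over replicates converges to the RDM implied
        by the generating second moment (1:1 G <-> RDM relationship)."""
        variances = (0.2, 2.0, 0.2, 1.0)
        expected = g_to_rdm(predicted_g(0.8, variances)).values
        acc = np.zeros((6, 6))
        n_rep = 40
        for rep in range(n_rep):
            truth = generate_ground_truth(400, 0.8, variances, seed=300 + rep, sigma2=0.5)
            pats = simulate_subject_betas(truth, 6, seed=400 + rep)
            acc += crossnobis_rdm(pats).values
        acc /= n_rep
        iu = np.triu_indices(6, 1)
        assert np.corrcoef(acc[iu], expected[iu])[0, 1] > 0.98
        assert acc[iu].mean() == pytest.approx(expected[iu].mean(), rel=0.15)


class TestGroup:
    def _peaked_table(self, peak_col, n_subj=8, n_models=11, noise=0.0, rng=None):
        rs = np.linspace(0, 1, n_models)
        base = -((np.arange(n_models) - peak_col) ** 2).astype(float)
        table = np.tile(base, (n_subj, 1))
        if noise and rng is not None:
            table = table + rng.standard_normal(table.shape) * noise
        return table, rs

    def test_shared_peak_selected_and_not_worse(self):
        table, rs = self._peaked_table(peak_col=7)
        comp = loso_best_model(table)
        assert (comp.loso_winner == 7).all()
        assert not comp.worse[7]
        assert comp.worse[0] and comp.worse[-1]
        assert np.allclose(comp.relative_loglik.sum(axis=1), 0.0, atol=1e-9)

    def test_flat_curves_yield_empty_worse_set(self, rng):
        table = rng.standard_normal((10, 9)) * 1e-6
        comp = loso_best_model(table)
        # no real information: the best-model vector is not systematically
        # better, so at alpha=.05 almost nothing is flagged
        assert comp.worse.sum() <= 2

    def test_worse_set_matches_direct_t_test_oracle(self, rng):
        table, rs = self._peaked_table(peak_col=5, n_subj=12, noise=3.0, rng=rng)
        comp = loso_best_model(table)
        rel = table - table.mean(axis=1, keepdims=True)
        best = np.empty(12)
        for s in range(12):
            best[s] = rel[s, np.argmax(np.delete(rel, s, 0).mean(axis=0))]
        for m in range(rs.size):
            diff = best - rel[:, m]
            if np.std(diff, ddof=1) == 0:
                continue
            t = diff.mean() / (diff.std(ddof=1) / np.sqrt(12))
            p = sps.t.sf(t, 11)
            assert comp.pvalues[m] == pytest.approx(p, abs=1e-10)
            assert comp.worse[m] == (p < 0.05)

    def test_tie_break_prefers_lowest_correlation(self):
        table = np.zeros((5, 6))
        table[:, 2] = table[:, 4] = 1.0  # two equally good models
        comp = loso_best_model(table)
        assert (comp.loso_winner == 2).all()

    def test_group_summary_trivial_case(self):
        table, rs = self._peaked_table(peak_col=5, n_models=11)
        summ = group_correlation_summary(table)
        assert summ.mean_best_r == pytest.approx(0.5)
        assert summ.sem_best_r == pytest.approx(0.0)
        assert summ.p_vs_zero_model < 1e-6  # identical positive differences

    def test_group_summary_recovers_planted_mean(self, rng):
        rs = np.linspace(0, 1, 21)
        tables = []
        for s in range(10):
            peak = 12 + rng.integers(-2, 3)
            tables.append(-((np.arange(21) - peak) ** 2).astype(float))
        table = np.stack(tables)
        summ = group_correlation_summary(table)
        assert abs(summ.mean_best_r - 0.6) < 0.1
        assert summ.sem_best_r > 0


def test_naive_correlation_attenuated_but_pcm_unbiased():
    """At true r = 1 with noisy data the raw pattern correlation falls well
    below 1 while the likelihood-grid argmax stays near 1."""
    naive, best = [], []
    for rep in range(6):
        truth = generate_ground_truth(200, 1.0, seed=500 + rep, sigma2=2.0)
        pats = simulate_subject_betas(truth, 10, seed=600 + rep)
        naive.append(naive_correlation(pats))
        best.append(CorrelationPCM(pats).fit_grid(26).best_r)
    assert np.mean(naive) < 0.8
    assert np.mean(best) > 0.9
    assert np.mean(best) - np.mean(naive) > 0.1


def test_grid_results_plot_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    truth = generate_ground_truth(60, 0.5, seed=41, sigma2=0.5)
    pats = simulate_subject_betas(truth, 4, seed=42)
    grid = CorrelationPCM(pats).fit_grid(6)
    ax = grid.plot()
    assert ax.get_xlabel() == "model correlation r"
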