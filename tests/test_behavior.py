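"""Force preprocessing, behavioral features/RDMs and the confound fit."""

import numpy as np
import pytest

from prepmvpa.behavior import (
    EXECUTION_CONDITIONS,
    PLANNING_CONDITIONS,
    behavioral_features,
    behavioral_rdm,
    neural_vs_behavioral,
    phase_mean_distances,
    preprocess_forces,
)
from prepmvpa.design import generate_experiment
from prepmvpa.rdm import mean_distance
from prepmvpa.simulate import ForceTrace, simulate_force_traces


def _flat_trace(run, value=0.3, n=None):
    n = n or int(round(run.duration / 0.002))
    return ForceTrace(
        samples=np.full((n, 5), value),
        dt=0.002,
        phase_labels=np.zeros(n, dtype=np.int8),
        trial_index=np.full(n, -1, dtype=np.int32),
        run=run,
    )


@pytest.fixture(scope="module")
def run():
    return generate_experiment(1, seed=50).runs[0]


@pytest.fixture(scope="module")
def session():
    return generate_experiment(10, seed=51, reps_per_type=2)


class TestPreprocess:
    def test_constant_trace_unchanged(self, run):
        binned = preprocess_forces(_flat_trace(run, 0.3))
        assert np.allclose(binned.values, 0.3, atol=1e-12)

    def test_binning_rate(self, run):
        binned = preprocess_forces(_flat_trace(run))
        # 200 Hz input -> 100 bins per second
        assert binned.bin_dt == pytest.approx(0.010)
        assert binned.values.shape[0] == int(round(run.duration / 0.002)) // 5

    def test_impulse_matches_discrete_gaussian_kernel(self, run):
        """A unit impulse smooths to the closed-form discrete Gaussian and
        bins to its 5-sample means."""
        trace = _flat_trace(run, 0.0, n=2000)
        trace.samples[1000, 2] = 1.0
        fwhm = 9.42
        binned = preprocess_forces(trace, fwhm_ms=fwhm)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0  # in samples
        radius = int(4 * sigma + 0.5)
        j = np.arange(-radius, radius + 1)
        kernel = np.exp(-(j**2) / (2 * sigma**2))
        kernel /= kernel.sum()
        smoothed = np.zeros(2000)
        smoothed[1000 + j] = kernel
        expected = smoothed.reshape(-1, 5).mean(axis=1)
        assert np.allclose(binned.values[:, 2], expected, atol=1e-6)
        assert np.allclose(binned.values[:, [0, 1, 3, 4]], 0.0, atol=1e-12)

    def test_nonuniform_sampling_rejected(self, run):
        trace = _flat_trace(run)
        bad = ForceTrace(
            samples=trace.samples,
            dt=0.003,
            phase_labels=trace.phase_labels,
            trial_index=trace.trial_index,
            run=run,
        )
        with pytest.raises(ValueError, match="multiple"):
            preprocess_forces(bad)


class TestFeatures:
    def _features(self, session, leak, seed, prewhiten=True):
        traces = simulate_force_traces(session, leak, seed)
        binned = [preprocess_forces(t) for t in traces]
        return behavioral_features(binned, session, prewhiten=prewhiten)

    def test_shape_60_by_10(self, session):
        feats = self._features(session, 0.0, seed=60)
        assert feats.tensor.shape == (10, 6, 10)
        assert feats.matrix.shape == (60, 10)

    def test_identical_traces_give_equal_condition_features(self, run):
        binned = [preprocess_forces(_flat_trace(run, 0.31)) for _ in range(3)]
        feats = behavioral_features(binned, None, prewhiten=False)
        block = feats.tensor[0]
        assert np.allclose(block - block[0], 0.0, atol=1e-9)

    def test_thumb_leak_separates_thumb_condition(self, session):
        feats = self._features(session, 0.0, seed=61, prewhiten=False)
        leaky_traces = simulate_force_traces(session, 0.2, seed=61)
        leaky = behavioral_features([preprocess_forces(t) for t in leaky_traces], session, prewhiten=False)
        # leak moves the cued finger's mean-force features apart across
        # planning conditions; without leak they coincide
        plan = leaky.tensor[:, :3, :5]
        spread_leak = plan.std(axis=1).mean()
        spread_none = feats.tensor[:, :3, :5].std(axis=1).mean()
        assert spread_leak > 3 * spread_none


class TestRdm:
    def test_noiseless_limit_equals_plain_squared_euclidean(self, run):
        rng = np.random.default_rng(62)
        cond_patterns = rng.standard_normal((6, 10))
        tensor = np.tile(cond_patterns[None], (4, 1, 1))
        from prepmvpa.behavior import BehavioralFeatures

        feats = BehavioralFeatures(tensor=tensor, prewhitened=False)
        rdm = behavioral_rdm(feats)
        diff = cond_patterns[:, None] - cond_patterns[None]
        expected = (diff**2).sum(-1) / 10.0
        assert np.allclose(rdm.values, expected, atol=1e-10)

    def test_zero_leak_planning_distances_center_on_zero(self, session):
        """Unbiasedness: with no injected finger information the mean
        planning distance straddles zero across replicates."""
        means = []
        for rep in range(12):
            traces = simulate_force_traces(session, 0.0, seed=700 + rep)
            feats = behavioral_features([preprocess_forces(t) for t in traces], session)
            means.append(mean_distance(behavioral_rdm(feats), PLANNING_CONDITIONS))
        means = np.asarray(means)
        assert abs(means.mean()) < 3 * means.std(ddof=1) / np.sqrt(means.size)

    def test_leak_detected_and_execution_dwarfs_planning(self, session):
        traces = simulate_force_traces(session, 0.05, seed=63)
        feats = behavioral_features([preprocess_forces(t) for t in traces], session)
        rdm = behavioral_rdm(feats)
        d_plan, d_exec = phase_mean_distances(rdm)
        assert d_plan > 0
        assert d_exec / max(d_plan, 1e-12) > 10
        assert rdm.values.shape == (6, 6) and rdm.unique_values().size == 15


class TestNeuralVsBehavioral:
    def test_planted_linear_relation_recovered(self, rng):
        behav = rng.uniform(0.0, 1.0, 22)
        neural = 2.0 + 3.0 * behav + rng.standard_normal(22) * 0.05
        fit = neural_vs_behavioral(neural, behav)
        assert fit.slope == pytest.approx(3.0, abs=0.2)
        assert fit.intercept == pytest.approx(2.0, abs=0.1)
        assert fit.pvalue_intercept < 1e-6 and fit.pvalue_slope < 1e-6

    def test_matches_statsmodels_free_ols_oracle(self, rng):
        """Closed-form normal-equation OLS reproduces the fit."""
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        fit = neural_vs_behavioral(y, x)
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm))
        intercept = ym - slope * xm
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_zero_variance_behavior_falls_back_to_t_test(self, rng):
        from scipy import stats as sps

        neural = rng.standard_normal(15) + 0.8
        fit = neural_vs_behavioral(neural, np.zeros(15))
        assert np.isnan(fit.slope)
        assert fit.intercept == pytest.approx(neural.mean())
        assert fit.pvalue_intercept == pytest.approx(sps.ttest_1samp(neural, 0.0).pvalue)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            neural_vs_behavioral([1.0, 2.0], [0.1, 0.2])
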