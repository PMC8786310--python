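"""Behavioral (finger-force) pattern distances and the confound regression.

Even without overt movement, tiny finger-specific force patterns during the
preparatory hold could in principle explain planning information found in
cortex.  This module extracts multivariate force features per condition and
block, computes cross-validated behavioral distances with the same unbiased
estimator used for neural patterns, and regresses neural on behavioral
distances across subjects: a positive intercept with a flat slope indicates
neural information beyond anything present in behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d

from .design import CONDITIONS, FINGERS, MOVE_PHASE, ExperimentDesign
from .glm import estimate_noise_covariance
from .rdm import RDM, crossnobis_rdm, mean_distance
from .simulate import ForceTrace

__all__ = [
    "BinnedForces",
    "preprocess_forces",
    "BehavioralFeatures",
    "behavioral_features",
    "behavioral_rdm",
    "BehavioralNeuralFit",
    "neural_vs_behavioral",
    "PLANNING_CONDITIONS",
    "EXECUTION_CONDITIONS",
]

PLANNING_CONDITIONS = CONDITIONS[:3]
EXECUTION_CONDITIONS = CONDITIONS[3:]

#: Gaussian smoothing kernel width (FWHM) in milliseconds and bin width.
FORCE_FWHM_MS = 9.42
FORCE_BIN_MS = 10.0


@dataclass(frozen=True)
class BinnedForces:
    """Smoothed, 10 ms-binned force series of one block."""

    values: np.ndarray  # (n_bins, 5), newtons
    bin_dt: float  # seconds
    trace: ForceTrace  # the source trace (carries the run design)


def preprocess_forces(
    trace: ForceTrace,
    *,
    fwhm_ms: float = FORCE_FWHM_MS,
    bin_ms: float = FORCE_BIN_MS,
) -> BinnedForces:
    """Gaussian-smooth and bin a 2 ms force trace.

    Smoothing uses a Gaussian kernel of ``fwhm_ms`` full width at half
    maximum; binning averages within consecutive ``bin_ms`` windows.
    """
    if trace.dt <= 0:
        raise ValueError("non-positive sampling interval")
    per_bin = bin_ms / 1000.0 / trace.dt
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError(f"bin width {bin_ms} ms is not a multiple of the {trace.dt * 1000:g} ms sampling")
    per_bin = int(round(per_bin))
    sigma = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0))) / (trace.dt * 1000.0)
    smooth = gaussian_filter1d(trace.samples, sigma=sigma, axis=0, mode="nearest")
    n_bins = smooth.shape[0] // per_bin
    binned = smooth[: n_bins * per_bin].reshape(n_bins, per_bin, smooth.shape[1]).mean(axis=1)
    return BinnedForces(values=binned, bin_dt=bin_ms / 1000.0, trace=trace)


@dataclass(frozen=True)
class BehavioralFeatures:
    """Condition-wise force features across blocks.

    ``tensor`` is (n_blocks, 6 conditions, 10 features) where the 10
    features per condition are the across-trial mean and standard deviation
    of each finger channel's time-averaged force (2 statistics x 5
    fingers).  ``matrix`` exposes the same data as the conventional
    60 x n_blocks layout (statistic x finger x condition rows).
    """

    tensor: np.ndarray
    prewhitened: bool
    shrinkage: float | None = None

    @property
    def n_blocks(self) -> int:
        return self.tensor.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        # (blocks, cond, stat*finger) -> rows ordered stat, finger, condition
        b, c, f = self.tensor.shape
        t = self.tensor.reshape(b, c, 2, 5)
        return t.transpose(2, 3, 1, 0).reshape(2 * 5 * c, b)


def _condition_trial_averages(binned: BinnedForces):
    """Per-trial time-averaged force (5,) grouped by analyzed condition.

    Planning conditions average the preparation window of every trial of
    that finger (the hold is identical for go and no-go until the cue);
    execution conditions average the movement window of go trials.
    Sequence-type trials are ignored.
    """
    run = binned.trace.run
    dt = binned.bin_dt
    grouped: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    for trial in run.trials:
        if trial.is_sequence:
            continue
        i0 = int(round(trial.onset / dt))
        i1 = int(round(trial.go_time / dt))
        grouped[f"plan:{trial.finger}"].append(binned.values[i0:i1].mean(axis=0))
        if trial.is_go:
            i2 = int(round((trial.go_time + MOVE_PHASE) / dt))
            grouped[f"exec:{trial.finger}"].append(binned.values[i1:i2].mean(axis=0))
    return grouped


def behavioral_features(
    binned_blocks,
    design: ExperimentDesign | None = None,
    *,
    prewhiten: bool = True,
    shrinkage: float | None = None,
) -> BehavioralFeatures:
    """Extract the 60 x n_blocks force-feature matrix.

    For each block and condition the mean and standard deviation (across
    trials within the block) of each finger's time-averaged force form a
    10-dimensional condition pattern.  Patterns are multivariately
    prewhitened in feature space using the shrinkage covariance of the
    across-block residuals (same rule as the voxel noise covariance).

    Parameters
    ----------
    binned_blocks : sequence of BinnedForces
        One preprocessed trace per block (run).
    design : ExperimentDesign, optional
        Accepted for bookkeeping; trial windows come from each trace's own
        run design.
    prewhiten : bool
        Whiten the 10 feature dimensions (default True).
    shrinkage : float, optional
        Fixed shrinkage intensity; defaults to the analytic optimum.
    """
    tensors = []
    for binned in binned_blocks:
        grouped = _condition_trial_averages(binned)
        block = np.empty((6, 10))
        for ci, cond in enumerate(CONDITIONS):
            trials = grouped[cond]
            if len(trials) == 0:
                raise ValueError(f"condition {cond} has no trials in one block")
            arr = np.stack(trials)  # (n_trials, 5)
            block[ci] = np.concatenate([arr.mean(axis=0), arr.std(axis=0, ddof=0)])
        tensors.append(block)
    tensor = np.stack(tensors)  # (blocks, 6, 10)
    if tensor.shape[0] < 2:
        raise ValueError("need >= 2 blocks")

    lam = None
    if prewhiten:
        resid = tensor - tensor.mean(axis=0, keepdims=True)  # remove condition means
        flat = resid.reshape(-1, tensor.shape[2])
        cov = estimate_noise_covariance(flat, df=tensor.shape[1] * (tensor.shape[0] - 1), shrinkage=shrinkage)
        tensor = tensor @ cov.inverse_sqrt()
        lam = cov.shrinkage
    return BehavioralFeatures(tensor=tensor, prewhitened=prewhiten, shrinkage=lam)


def behavioral_rdm(features: BehavioralFeatures) -> RDM:
    """Cross-validated squared Euclidean distances between conditions.

    Blocks serve as the cross-validation partitions, so the estimator is
    unbiased: with no finger information (zero leak) planning distances
    scatter around zero.
    """
    if features.n_blocks < 2:
        raise ValueError("cross-validated distances need >= 2 blocks")
    return crossnobis_rdm(features.tensor, CONDITIONS)


def phase_mean_distances(rdm: RDM) -> tuple[float, float]:
    """(mean planning distance, mean execution distance) of a behavioral RDM."""
    return (
        mean_distance(rdm, PLANNING_CONDITIONS),
        mean_distance(rdm, EXECUTION_CONDITIONS),
    )


@dataclass(frozen=True)
class BehavioralNeuralFit:
    """OLS fit of per-subject neural on behavioral distances."""

    slope: float
    intercept: float
    pvalue_slope: float
    pvalue_intercept: float
    pairs: pd.DataFrame

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "intercept": self.intercept,
                "slope": self.slope,
                "pvalue_intercept": self.pvalue_intercept,
                "pvalue_slope": self.pvalue_slope,
            }
        )


def neural_vs_behavioral(neural, behavioral) -> BehavioralNeuralFit:
    """Regress per-subject neural distances on behavioral distances.

    A significantly positive intercept indicates neural information that
    survives correction for whatever subthreshold movement patterns exist;
    a flat slope indicates the neural distances are not driven by them.

    If the behavioral distances have (numerically) zero variance the slope
    is undefined and the intercept test falls back to a one-sample t-test
    of the neural distances.
    """
    neural = np.asarray(neural, dtype=float)
    behavioral = np.asarray(behavioral, dtype=float)
    if neural.shape != behavioral.shape or neural.ndim != 1:
        raise ValueError("neural and behavioral distances must be matched 1-d vectors")
    if neural.size < 3:
        raise ValueError("need >= 3 subjects")
    pairs = pd.DataFrame({"behavioral": behavioral, "neural": neural})

    scale = max(np.abs(behavioral).max(), 1e-30)
    if behavioral.std() <= 1e-12 * scale:
        t = sps.ttest_1samp(neural, 0.0)
        return BehavioralNeuralFit(
            slope=np.nan,
            intercept=float(neural.mean()),
            pvalue_slope=np.nan,
            pvalue_intercept=float(t.pvalue),
            pairs=pairs,
        )
    x = sm.add_constant(behavioral)
    fit = sm.OLS(neural, x).fit()
    return BehavioralNeuralFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pvalue_slope=float(fit.pvalues[1]),
        pvalue_intercept=float(fit.pvalues[0]),
        pairs=pairs,
    )
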