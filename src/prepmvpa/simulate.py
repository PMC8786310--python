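"""Synthetic data with the statistical structure the analysis assumes.

Three generators make every downstream stage testable without any
measurement: (i) ground-truth activity patterns for the six conditions
drawn so their second moment equals the pattern-component model G(r,
variances); (ii) BOLD time series produced by pushing those patterns
through the event design matrix plus Gaussian noise (optionally with a
voxel covariance, to exercise prewhitening); and (iii) 5-finger isometric
force traces at 2 ms resolution with a preparatory baseline hold, an
optional finger-specific preparatory "leak", and six suprathreshold presses
on go trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CONDITIONS, MOVE_PHASE, REWARD_PHASE, ExperimentDesign, RunDesign
from .designmatrix import DesignMatrix, build_design_matrix
from .hrf import HRFParams
from .pcm import predicted_g

__all__ = [
    "GroundTruth",
    "generate_ground_truth",
    "SimulatedBold",
    "simulate_bold",
    "simulate_subject_betas",
    "ForceTrace",
    "simulate_force_traces",
    "random_spd_covariance",
    "DEFAULT_VARIANCES",
    "HIGH_SNR_NOISE",
    "LOW_SNR_NOISE",
]

# ---------------------------------------------------------------------- #
# Study conditions for pattern simulations.
#
# The variance components (a_plan, a_exec, s_plan, s_exec) mirror the
# empirical geometry of the task: execution has a much stronger common
# pattern than planning (overall activation difference), and the
# finger-specific planning variance is ~20% of the execution variance
# (planning distances are 16-31% of execution distances).  Run-level
# measurement variances define a high-SNR regime (noise well below the
# execution signal; naive correlations attenuate by only ~7%) and a low-SNR
# regime (noise at 2x the execution finger variance; naive correlations
# attenuate to ~0.65 of truth at 10 runs).
DEFAULT_VARIANCES = (0.2, 2.0, 0.2, 1.0)
HIGH_SNR_NOISE = 0.25
LOW_SNR_NOISE = 2.0

#: Force-trace sampling interval, seconds (200 Hz transducers).
FORCE_DT = 0.002

#: Preparatory baseline force, newtons (center of the 0-0.5 N hold band).
FORCE_BASELINE = 0.3

#: Force noise SD, newtons.  The noise is temporally smooth (10 ms Gaussian
#: autocorrelation), emulating slow physiological force fluctuations rather
#: than white transducer noise, so press threshold crossings stay clean.
FORCE_NOISE_SD = 0.02
FORCE_NOISE_SMOOTH_S = 0.010

#: Number of presses per go trial and press threshold (N).
N_PRESSES = 6
PRESS_THRESHOLD = 1.0

#: Phase codes of ForceTrace.phase_labels.
PHASE_REST, PHASE_PREP, PHASE_MOVE, PHASE_REWARD = 0, 1, 2, 3


@dataclass(frozen=True)
class GroundTruth:
    """True condition patterns and their generative parameters.

    ``patterns`` is (6, n_voxels), conditions ordered as
    (plan:1, plan:3, plan:5, exec:1, exec:3, exec:5); its rows are drawn
    multivariate normal with second moment ``predicted_g(true_r,
    variances)``.  ``sigma2`` is the measurement-noise variance used by the
    BOLD/beta simulators.
    """

    true_r: float
    variances: tuple[float, float, float, float]
    sigma2: float
    patterns: np.ndarray

    @property
    def g(self) -> np.ndarray:
        return predicted_g(self.true_r, self.variances)

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]


def generate_ground_truth(
    n_voxels: int,
    true_r: float,
    variances=DEFAULT_VARIANCES,
    seed: int | np.random.Generator = 0,
    *,
    sigma2: float = HIGH_SNR_NOISE,
) -> GroundTruth:
    """Draw true condition patterns with second moment G(true_r, variances).

    Patterns are ``G^(1/2) @ N(0, I)`` so that the empirical second moment
    converges to G as the voxel count grows; the correlation between
    matching-finger planning and execution residual patterns converges to
    ``true_r``.
    """
    if not 0.0 <= abs(true_r) <= 1.0:
        raise ValueError(f"|true_r| must be <= 1, got {true_r}")
    if true_r < 0:
        raise ValueError("true_r must be in [0, 1]")
    if min(variances) < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g = predicted_g(true_r, variances)
    vals, vecs = np.linalg.eigh(g)
    root = (vecs * np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    patterns = root @ rng.standard_normal((6, n_voxels))
    return GroundTruth(
        true_r=float(true_r),
        variances=tuple(float(v) for v in variances),
        sigma2=float(sigma2),
        patterns=patterns,
    )


def random_spd_covariance(n_voxels: int, seed, *, strength: float = 0.5) -> np.ndarray:
    """A random symmetric positive-definite voxel covariance (unit trace/V).

    ``strength`` in [0, 1) controls how far the covariance departs from the
    identity; used to exercise the prewhitening path.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = rng.standard_normal((n_voxels, n_voxels)) / np.sqrt(n_voxels)
    cov = (1.0 - strength) * np.eye(n_voxels) + strength * (a @ a.T)
    cov *= n_voxels / np.trace(cov)
    return cov


@dataclass(frozen=True)
class SimulatedBold:
    """Simulated time series with the generating design and true betas."""

    series: tuple[np.ndarray, ...]  # per run, (n_volumes, n_voxels)
    design_matrices: tuple[DesignMatrix, ...]
    true_betas: np.ndarray  # (n_regressors, n_voxels), shared across runs
    truth: GroundTruth


def _true_beta_matrix(labels, truth: GroundTruth) -> np.ndarray:
    """Map regressor labels to true condition patterns.

    Planning regressors (go and no-go alike) of single-finger types carry
    the finger's planning pattern; execution regressors its execution
    pattern.  Sequence-type regressors and intercepts carry zeros (their
    patterns are not analyzed).
    """
    betas = np.zeros((len(labels), truth.n_voxels))
    for j, lab in enumerate(labels):
        parts = lab.split(":")
        if parts[0] not in ("plan", "exec") or parts[1].startswith("s"):
            continue
        finger = int(parts[1])
        cond = f"{parts[0]}:{finger}"
        betas[j] = truth.patterns[CONDITIONS.index(cond)]
    return betas


def simulate_bold(
    design: ExperimentDesign,
    truth: GroundTruth,
    seed: int | np.random.Generator,
    *,
    params: HRFParams | None = None,
    split_go_nogo: bool = True,
    noise_cov: np.ndarray | None = None,
) -> SimulatedBold:
    """Simulate BOLD series: design matrix x true betas + Gaussian noise.

    Noise is i.i.d. N(0, truth.sigma2) across time and voxels by default;
    passing ``noise_cov`` (a voxel covariance, scaled by truth.sigma2)
    yields spatially correlated noise for testing prewhitening.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    params = params or HRFParams()
    chol = None
    if noise_cov is not None:
        noise_cov = np.asarray(noise_cov, dtype=float)
        if noise_cov.shape != (truth.n_voxels, truth.n_voxels):
            raise ValueError("noise covariance does not match the voxel count")
        chol = np.linalg.cholesky(noise_cov)

    dms, series = [], []
    true_betas = None
    for run in design.runs:
        dm = build_design_matrix(run, params, tr=design.tr, split_go_nogo=split_go_nogo, warn_zero=False)
        if true_betas is None:
            true_betas = _true_beta_matrix(dm.labels, truth)
        noise = rng.standard_normal((dm.values.shape[0], truth.n_voxels)) * np.sqrt(truth.sigma2)
        if chol is not None:
            noise = noise @ chol.T
        series.append(dm.values @ true_betas + noise)
        dms.append(dm)
    return SimulatedBold(
        series=tuple(series),
        design_matrices=tuple(dms),
        true_betas=true_betas,
        truth=truth,
    )


def simulate_subject_betas(
    truth: GroundTruth,
    n_runs: int,
    seed: int | np.random.Generator,
    *,
    noise_var: float | None = None,
) -> np.ndarray:
    """Run-wise condition patterns: truth plus i.i.d. measurement noise.

    The direct beta-level counterpart of the BOLD + GLM pipeline: returns
    (n_runs, 6, n_voxels) with noise variance ``noise_var`` (defaults to
    truth.sigma2) per run, voxel and condition.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if noise_var is None:
        noise_var = truth.sigma2
    noise = rng.standard_normal((n_runs, 6, truth.n_voxels)) * np.sqrt(noise_var)
    return truth.patterns[None] + noise


def simulate_study(config, *, beta_level: bool = True):
    """Generate a whole synthetic group from a :class:`~prepmvpa.io.SimulationConfig`.

    Returns a list of per-subject (n_runs, 6, n_voxels) pattern arrays
    (beta-level by default; ``beta_level=False`` runs the BOLD + GLM +
    prewhitening path per subject, which is slower but exercises the full
    pipeline).
    """
    rng = np.random.default_rng(config.seed)
    subjects = []
    for _ in range(config.n_subjects):
        truth = generate_ground_truth(
            config.n_voxels, config.true_r, config.variances, rng, sigma2=config.sigma2
        )
        if beta_level:
            subjects.append(simulate_subject_betas(truth, config.n_runs, rng))
        else:
            from .glm import estimate_noise_covariance, fit_experiment_glm, prewhiten

            design = _study_design(config.n_runs, rng)
            sim = simulate_bold(design, truth, rng)
            est = fit_experiment_glm(sim.series, sim.design_matrices)
            cov = estimate_noise_covariance(est.residuals, est.df)
            subjects.append(prewhiten(est.condition_patterns(), cov))
    return subjects


def _study_design(n_runs: int, rng) -> ExperimentDesign:
    from .design import generate_experiment

    return generate_experiment(n_runs, rng)


# ------------------------------ forces ------------------------------ #


@dataclass(frozen=True)
class ForceTrace:
    """Continuous 5-finger force recording of one run.

    ``samples`` is (n_samples, 5) in newtons at ``dt`` resolution (2 ms);
    ``phase_labels`` codes each sample (0 rest/ITI, 1 preparation, 2
    movement, 3 reward); ``trial_index`` maps samples to trials (-1 outside
    trials); ``run`` is the generating design.
    """

    samples: np.ndarray
    dt: float
    phase_labels: np.ndarray
    trial_index: np.ndarray
    run: RunDesign

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


def _press_template(dt: float) -> np.ndarray:
    """One keypress: a 240 ms half-sine force pulse peaking at 2.2 N."""
    n = int(round(0.24 / dt))
    return 2.2 * np.sin(np.linspace(0.0, np.pi, n))


#: Transducer column of each cued digit (thumb, middle, little on 0, 2, 4).
_FINGER_COL = {1: 0, 3: 2, 5: 4}


def simulate_force_traces(
    run: RunDesign | ExperimentDesign,
    leak: float,
    seed: int | np.random.Generator,
    *,
    dt: float = FORCE_DT,
    baseline: float = FORCE_BASELINE,
    noise_sd: float = FORCE_NOISE_SD,
):
    """Simulate isometric finger forces for one run (or every run).

    All five fingers hold the preparatory baseline (~0.3 N) throughout the
    run.  During each preparation phase the cued finger's force is shifted
    by ``leak`` newtons - the subthreshold involuntary pattern the control
    analysis hunts for; ``leak=0`` injects no finger information.  On go
    trials the cued finger makes six presses crossing the 1 N threshold
    during the movement phase.

    Returns a ForceTrace (or a tuple of them for an ExperimentDesign).
    """
    if leak < 0:
        raise ValueError("leak must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(run, ExperimentDesign):
        return tuple(simulate_force_traces(r, leak, rng, dt=dt, baseline=baseline, noise_sd=noise_sd) for r in run.runs)

    n = int(round(run.duration / dt))
    phase = np.zeros(n, dtype=np.int8)
    trial_idx = np.full(n, -1, dtype=np.int32)
    cued = np.full(n, -1, dtype=np.int8)
    is_go = np.zeros(n, dtype=bool)
    for t, trial in enumerate(run.trials):
        i0 = int(round(trial.onset / dt))
        i1 = int(round(trial.go_time / dt))
        i2 = int(round((trial.go_time + MOVE_PHASE) / dt))
        i3 = min(int(round((trial.go_time + MOVE_PHASE + REWARD_PHASE) / dt)), n)
        i4 = min(int(round(trial.end / dt)), n)
        phase[i0:i1] = PHASE_PREP
        phase[i1:i2] = PHASE_MOVE
        phase[i2:i3] = PHASE_REWARD
        trial_idx[i0:i4] = t
        cued[i0:i2] = _FINGER_COL[trial.finger]
        is_go[i1:i2] = trial.is_go

    from scipy.ndimage import gaussian_filter1d

    sigma = FORCE_NOISE_SMOOTH_S / dt
    white = rng.standard_normal((n, 5))
    smooth = gaussian_filter1d(white, sigma=sigma, axis=0, mode="nearest")
    smooth *= np.sqrt(2.0 * sigma * np.sqrt(np.pi))  # restore unit variance
    samples = baseline + noise_sd * smooth
    if leak > 0:
        prep = phase == PHASE_PREP
        samples[prep, cued[prep]] += leak

    template = _press_template(dt)
    press_gap = int(round((MOVE_PHASE - 0.3) / N_PRESSES / dt))
    for t, trial in enumerate(run.trials):
        if not trial.is_go:
            continue
        col = _FINGER_COL[trial.finger]
        start = int(round((trial.go_time + 0.25) / dt))  # reaction time ~250 ms
        for k in range(N_PRESSES):
            i0 = start + k * press_gap
            i1 = min(i0 + template.size, n)
            samples[i0:i1, col] += template[: i1 - i0]
    return ForceTrace(samples=samples, dt=dt, phase_labels=phase, trial_index=trial_idx, run=run)
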