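"""GLM design matrices and variance-inflation-factor (VIF) design scoring.

Each phase of each trial type is modeled by a 2 s boxcar at the phase onset
convolved with the two-gamma HRF and sampled at the TR.  Designs are scored
by the VIF of the condition regressors: the ratio of each regressor's
estimation variance in the full model to its estimation variance had it been
fitted in isolation (always together with the run intercept).  A VIF of 1
means the regressor is orthogonal to the rest of the model; event-related
designs are chosen by random search to keep the mean VIF of the planning and
execution regressors low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FINGERS, ExperimentDesign, RunDesign, generate_experiment
from .hrf import HRFParams, sample_hrf

__all__ = [
    "DesignMatrix",
    "VIFReport",
    "OptimizationResult",
    "build_design_matrix",
    "compute_vif",
    "optimize_design",
    "BOXCAR_DURATION",
]

#: Duration of the phase boxcars, seconds (on for the first 2 s of each phase).
BOXCAR_DURATION = 2.0

#: Oversampled grid step for HRF convolution, seconds.
CONV_DT = 0.1


@dataclass(frozen=True)
class DesignMatrix:
    """A single-run first-level design matrix.

    Attributes
    ----------
    values : ndarray, shape (n_volumes, n_regressors)
        Sampled regressors; condition columns first, intercept last.
    labels : tuple of str
        Per-column labels, e.g. ``'plan:1'``, ``'exec:s3'``,
        ``'plan:5:nogo'``, ``'intercept'``.
    tr : float
        Sampling interval (repetition time), seconds.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    tr: float

    @property
    def condition_columns(self) -> list[int]:
        """Indices of the condition (non-intercept) regressors."""
        return [i for i, lab in enumerate(self.labels) if lab != "intercept"]

    @property
    def zero_columns(self) -> list[int]:
        """Indices of all-zero (eventless) condition regressors."""
        return [j for j in self.condition_columns if not np.any(self.values[:, j])]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.tr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.labels))


def _regressor_events(run: RunDesign, split_go_nogo: bool):
    """Map regressor label -> list of boxcar onset times for one run."""
    events: dict[str, list[float]] = {}
    for finger in FINGERS:
        for seq in (False, True):
            ttype = f"s{finger}" if seq else f"{finger}"
            if split_go_nogo:
                events[f"plan:{ttype}:go"] = []
                events[f"plan:{ttype}:nogo"] = []
            else:
                events[f"plan:{ttype}"] = []
            events[f"exec:{ttype}"] = []
    for trial in run.trials:
        ttype = trial.trial_type
        if split_go_nogo:
            key = f"plan:{ttype}:go" if trial.is_go else f"plan:{ttype}:nogo"
        else:
            key = f"plan:{ttype}"
        events[key].append(trial.onset)
        if trial.is_go:
            events[f"exec:{ttype}"].append(trial.go_time)
    return events


def build_design_matrix(
    run: RunDesign,
    params: HRFParams | None = None,
    *,
    tr: float = 1.0,
    split_go_nogo: bool = False,
    warn_zero: bool = True,
) -> DesignMatrix:
    """Build the first-level design matrix for one run.

    Each condition regressor is a 2 s boxcar at its events, convolved with
    the two-gamma HRF on a 0.1 s grid and decimated to the TR.  A run
    intercept is appended.

    Parameters
    ----------
    run : RunDesign
    params : HRFParams, optional
    tr : float, optional
        Repetition time, seconds; must be a multiple of the 0.1 s
        convolution grid.
    split_go_nogo : bool, optional
        If True, planning regressors are split by go/no-go (the 18-regressor
        model: 12 go + 6 no-go); if False (default) each trial type has one
        planning regressor covering go and no-go trials (12 regressors).
    warn_zero : bool, optional
        Warn about all-zero condition columns (eventless regressors).

    Returns
    -------
    DesignMatrix
    """
    params = params or HRFParams()
    ratio = tr / CONV_DT
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"tr={tr} must be a multiple of the {CONV_DT} s convolution grid")
    step = int(round(ratio))

    n_vols = run.n_volumes(tr)
    duration = n_vols * tr
    n_hi = int(round(duration / CONV_DT))
    hrf = sample_hrf(CONV_DT, params)

    events = _regressor_events(run, split_go_nogo)
    for label, onsets in events.items():
        for onset in onsets:
            if onset + BOXCAR_DURATION > run.duration + 1e-9:
                raise ValueError(
                    f"event for '{label}' at {onset:.1f}s extends past run end ({run.duration:.1f}s)"
                )

    columns = []
    for label, onsets in events.items():
        box = np.zeros(n_hi)
        for onset in onsets:
            i0 = int(round(onset / CONV_DT))
            i1 = min(int(round((onset + BOXCAR_DURATION) / CONV_DT)), n_hi)
            box[i0:i1] = 1.0
        conv = np.convolve(box, hrf)[:n_hi] * CONV_DT
        columns.append(conv[::step][:n_vols])
    values = np.column_stack(columns + [np.ones(n_vols)])
    labels = tuple(events.keys()) + ("intercept",)
    dm = DesignMatrix(values=values, labels=labels, tr=tr)
    if warn_zero and dm.zero_columns:
        names = [labels[j] for j in dm.zero_columns]
        warnings.warn(f"design matrix has eventless (all-zero) regressors: {names}", stacklevel=2)
    return dm


@dataclass(frozen=True)
class VIFReport:
    """Variance inflation factors of targeted regressors.

    ``var_e`` is the mean estimation variance of the targeted regression
    weights in the full model (diagonal of (X'X)^-1, unit noise variance);
    ``var_x`` the mean estimation variance had each regressor been estimated
    in isolation alongside the intercept.  ``mean_vif`` averages the
    per-regressor ratios; ``ratio_of_means`` is var_e / var_x.
    """

    per_regressor: pd.Series
    var_e: float
    var_x: float

    @property
    def mean_vif(self) -> float:
        return float(self.per_regressor.mean())

    @property
    def ratio_of_means(self) -> float:
        return self.var_e / self.var_x

    def to_frame(self) -> pd.DataFrame:
        df = self.per_regressor.rename("vif").to_frame()
        df.index.name = "regressor"
        return df


def _check_full_rank(X: np.ndarray, labels) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via the right null space
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[s < s.max() * max(X.shape) * np.finfo(float).eps * 10]
        if null.size == 0:
            null = vt[-1:]
        involved = sorted({labels[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]})
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {involved}"
        )


def compute_vif(dm: DesignMatrix, target: list[str] | None = None) -> VIFReport:
    """Per-regressor variance inflation factors.

    VIF_j = [(X'X)^-1]_jj / [(X_iso' X_iso)^-1]_jj, where X is the full
    design matrix and X_iso contains only regressor j and the intercept.
    Every VIF is >= 1, with equality iff the regressor is orthogonal to all
    other (intercept-centered) regressors.

    Parameters
    ----------
    dm : DesignMatrix
    target : list of str, optional
        Labels of the regressors to score; defaults to all condition
        regressors.

    Returns
    -------
    VIFReport
    """
    labels = list(dm.labels)
    if target is None:
        target_idx = dm.condition_columns
    else:
        missing = [lab for lab in target if lab not in labels]
        if missing:
            raise KeyError(f"unknown regressors: {missing}")
        target_idx = [labels.index(lab) for lab in target]

    X = dm.values
    _check_full_rank(X, labels)
    xtx_inv = np.linalg.inv(X.T @ X)
    intercept = np.ones((X.shape[0], 1))

    vifs = {}
    var_full = []
    var_iso = []
    for j in target_idx:
        x = X[:, [j]]
        Xi = np.hstack([x, intercept])
        vi = np.linalg.inv(Xi.T @ Xi)[0, 0]
        vf = xtx_inv[j, j]
        vifs[labels[j]] = vf / vi
        var_full.append(vf)
        var_iso.append(vi)
    return VIFReport(
        per_regressor=pd.Series(vifs),
        var_e=float(np.mean(var_full)),
        var_x=float(np.mean(var_iso)),
    )


@dataclass(frozen=True)
class OptimizationResult:
    """Winner of a random-search design optimization."""

    design: ExperimentDesign
    report: VIFReport
    trace: np.ndarray  # mean VIF of every candidate, in sampling order

    @property
    def mean_vif(self) -> float:
        return self.report.mean_vif


def optimize_design(
    n_candidates: int,
    seed: int | np.random.Generator,
    *,
    params: HRFParams | None = None,
    tr: float = 1.0,
    split_go_nogo: bool = False,
    target: list[str] | None = None,
    **design_kwargs,
) -> OptimizationResult:
    """Random-search design optimization by minimal mean VIF.

    Samples ``n_candidates`` single-run designs from the task distributions,
    scores each by the mean VIF of its planning/execution regressors, and
    returns the lowest-VIF candidate together with the VIF trace over all
    candidates.
    """
    if n_candidates < 1:
        raise ValueError(f"n_candidates must be >= 1, got {n_candidates}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    params = params or HRFParams()

    best = None
    trace = np.empty(n_candidates)
    for i in range(n_candidates):
        cand = generate_experiment(1, rng, tr=tr, **design_kwargs)
        dm = build_design_matrix(cand.runs[0], params, tr=tr, split_go_nogo=split_go_nogo)
        report = compute_vif(dm, target)
        trace[i] = report.mean_vif
        if best is None or report.mean_vif < best[1].mean_vif:
            best = (cand, report)
    return OptimizationResult(design=best[0], report=best[1], trace=trace)
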