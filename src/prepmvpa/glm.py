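"""First-level GLM estimation and multivariate noise normalization.

Run-wise ordinary least squares yields one activity estimate (beta) per
regressor per voxel.  The voxel-by-voxel noise covariance is estimated from
the GLM residuals, regularized toward its diagonal with an analytic
shrinkage coefficient, and its symmetric inverse square root is used to
spatially prewhiten the betas before any multivariate distance or model
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .designmatrix import DesignMatrix

__all__ = [
    "BetaEstimates",
    "NoiseCov",
    "fit_glm",
    "fit_experiment_glm",
    "estimate_noise_covariance",
    "prewhiten",
    "read_beta_images",
]


@dataclass(frozen=True)
class BetaEstimates:
    """Run-wise GLM estimates.

    Attributes
    ----------
    betas : ndarray, shape (n_runs, n_regressors, n_voxels)
    residuals : ndarray, shape (n_runs, n_time, n_voxels)
        Residual time series per run.  Runs of unequal length are padded
        with NaN; use :attr:`df` for the valid time points.
    df : ndarray, shape (n_runs,)
        Residual degrees of freedom per run (T_r - rank).
    labels : tuple of str
        Regressor labels shared across runs.
    """

    betas: np.ndarray
    residuals: np.ndarray
    df: np.ndarray
    labels: tuple[str, ...]

    def condition_patterns(
        self,
        fingers=(1, 3, 5),
        planning_source: str = "nogo",
    ) -> np.ndarray:
        """Extract the analyzed (runs, 6, voxels) single-finger patterns.

        Conditions are ordered (plan:1, plan:3, plan:5, exec:1, exec:3,
        exec:5).  Planning estimates come from no-go trials by default
        (``planning_source='nogo'``, requires the go/no-go-split design);
        ``'all'`` uses the combined planning regressors of the unsplit
        design.
        """
        if planning_source == "nogo":
            plan_labels = [f"plan:{f}:nogo" for f in fingers]
        elif planning_source == "all":
            plan_labels = [f"plan:{f}" for f in fingers]
        else:
            raise ValueError("planning_source must be 'nogo' or 'all'")
        wanted = plan_labels + [f"exec:{f}" for f in fingers]
        missing = [lab for lab in wanted if lab not in self.labels]
        if missing:
            raise KeyError(f"regressors not in this GLM: {missing}")
        idx = [self.labels.index(lab) for lab in wanted]
        return self.betas[:, idx, :]


def fit_glm(series: np.ndarray, dm: DesignMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Ordinary least squares for one run.

    Parameters
    ----------
    series : ndarray, shape (n_time, n_voxels)
    dm : DesignMatrix or ndarray

    Returns
    -------
    betas : ndarray, shape (n_regressors, n_voxels)
    residuals : ndarray, shape (n_time, n_voxels)
    df : int
        Residual degrees of freedom.
    """
    X = dm.values if isinstance(dm, DesignMatrix) else np.asarray(dm)
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[0] != X.shape[0]:
        raise ValueError(f"series shape {series.shape} does not match design {X.shape}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient; cannot fit GLM")
    betas, *_ = np.linalg.lstsq(X, series, rcond=None)
    residuals = series - X @ betas
    return betas, residuals, series.shape[0] - rank


def fit_experiment_glm(series_by_run, dms) -> BetaEstimates:
    """Fit the GLM run by run and collect the estimates.

    Parameters
    ----------
    series_by_run : sequence of (n_time_r, n_voxels) arrays
    dms : sequence of DesignMatrix (same labels in every run)
    """
    if len(series_by_run) != len(dms):
        raise ValueError("one design matrix per run required")
    labels = tuple(dms[0].labels)
    for dm in dms:
        if tuple(dm.labels) != labels:
            raise ValueError("all runs must share the same regressor labels")
    out_b, out_e, out_df = [], [], []
    for series, dm in zip(series_by_run, dms):
        b, e, df = fit_glm(series, dm)
        out_b.append(b)
        out_e.append(e)
        out_df.append(df)
    t_max = max(e.shape[0] for e in out_e)
    resid = np.full((len(out_e), t_max, out_e[0].shape[1]), np.nan)
    for r, e in enumerate(out_e):
        resid[r, : e.shape[0]] = e
    return BetaEstimates(
        betas=np.stack(out_b),
        residuals=resid,
        df=np.asarray(out_df),
        labels=labels,
    )


@dataclass(frozen=True)
class NoiseCov:
    """Shrinkage-regularized voxel noise covariance.

    ``sigma = (1 - shrinkage) * S + shrinkage * diag(S)`` where S is the
    (df-pooled) sample covariance of the GLM residuals.
    """

    sigma: np.ndarray
    shrinkage: float
    sample: np.ndarray

    def inverse_sqrt(self) -> np.ndarray:
        """Symmetric inverse square root of the regularized covariance."""
        vals, vecs = np.linalg.eigh(self.sigma)
        if vals.min() <= 0:
            raise np.linalg.LinAlgError("noise covariance is not positive definite")
        return (vecs / np.sqrt(vals)) @ vecs.T


def _shrinkage_coefficient(resid: np.ndarray) -> float:
    """Analytic optimal shrinkage toward the diagonal target.

    Ledoit-Wolf-style coefficient on the correlation scale
    (Schafer & Strimmer 2005): lambda* = sum var(r_ij) / sum r_ij^2 over
    off-diagonal entries, clipped to [0, 1].
    """
    n, p = resid.shape
    sd = resid.std(axis=0, ddof=1)
    x = resid / sd
    r = (x.T @ x) / (n - 1)
    x2 = x * x
    # var of the correlation entries: n/(n-1)^3 * sum_t (w_tij - w_ij)^2
    sum_w2 = x2.T @ x2
    sum_w = x.T @ x
    var_r = (n / (n - 1.0) ** 3) * (sum_w2 - sum_w**2 / n)
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(r[off] ** 2)
    if denom <= 0:
        return 1.0
    return float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))


def estimate_noise_covariance(
    residuals: np.ndarray,
    df: np.ndarray | int | None = None,
    shrinkage: float | None = None,
) -> NoiseCov:
    """Estimate the voxel noise covariance from GLM residuals.

    Residuals from all runs are pooled (weighted by residual degrees of
    freedom) into one sample covariance, which is shrunk toward its diagonal:
    ``(1 - lambda) S + lambda diag(S)``.  The shrinkage intensity defaults to
    the analytic optimum estimated from the data and may be overridden.

    Parameters
    ----------
    residuals : ndarray, shape (n_time, n_voxels) or (n_runs, n_time, n_voxels)
        NaN-padded rows (unequal run lengths) are ignored.
    df : int or array, optional
        Residual degrees of freedom (per run); defaults to n_time - 1.
    shrinkage : float in [0, 1], optional
        Fixed shrinkage intensity; 0 keeps the sample covariance, 1 keeps
        only its diagonal.

    Returns
    -------
    NoiseCov
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.ndim == 2:
        resid = resid[None]
    flat = []
    dfs = np.atleast_1d(df) if df is not None else None
    total_df = 0.0
    s_sum = None
    for r in range(resid.shape[0]):
        e = resid[r]
        e = e[~np.isnan(e).any(axis=1)]
        if e.shape[0] < 2 or e.shape[1] < 2:
            raise ValueError("need >= 2 time points and >= 2 voxels of residuals")
        d = float(dfs[r % len(dfs)]) if dfs is not None else e.shape[0] - 1.0
        if d <= 0:
            raise ValueError("non-positive residual degrees of freedom")
        s_run = e.T @ e
        s_sum = s_run if s_sum is None else s_sum + s_run
        total_df += d
        flat.append(e)
    sample = s_sum / total_df
    stacked = np.concatenate(flat, axis=0)
    if np.any(np.diag(sample) <= 0) or np.any(stacked.var(axis=0) <= 1e-300):
        raise ValueError("degenerate residuals: some voxels have (near-)constant residuals")

    if shrinkage is None:
        shrinkage = _shrinkage_coefficient(np.concatenate(flat, axis=0))
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError(f"shrinkage must be in [0, 1], got {shrinkage}")
    sigma = (1.0 - shrinkage) * sample + shrinkage * np.diag(np.diag(sample))
    return NoiseCov(sigma=sigma, shrinkage=float(shrinkage), sample=sample)


def prewhiten(betas: np.ndarray, cov: NoiseCov | np.ndarray) -> np.ndarray:
    """Spatially prewhiten activity patterns.

    Multiplies the voxel dimension (last axis) by the symmetric inverse
    square root of the noise covariance, making the measurement noise
    approximately isotropic across voxels.
    """
    w = cov.inverse_sqrt() if isinstance(cov, NoiseCov) else _inverse_sqrt(np.asarray(cov))
    betas = np.asarray(betas)
    if betas.shape[-1] != w.shape[0]:
        raise ValueError(
            f"voxel dimension mismatch: patterns have {betas.shape[-1]}, covariance {w.shape[0]}"
        )
    return betas @ w


def _inverse_sqrt(sigma: np.ndarray) -> np.ndarray:
    if not np.allclose(sigma, sigma.T):
        raise np.linalg.LinAlgError("covariance must be symmetric")
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    return (vecs / np.sqrt(vals)) @ vecs.T


def read_beta_images(paths, mask=None):
    """Read beta maps from NIfTI images into a (n_images, n_voxels) array.

    Thin convenience wrapper for applying the pipeline to real data; the
    primary path consumes in-memory arrays.

    Parameters
    ----------
    paths : sequence of str or Path
        One NIfTI image per beta map, all on the same grid.
    mask : ndarray of bool or str/Path, optional
        Voxel mask (array or NIfTI image); defaults to all voxels.
    """
    import nibabel as nib  # deferred: optional dependency

    imgs = [np.asanyarray(nib.load(str(p)).dataobj) for p in paths]
    shape = imgs[0].shape
    if mask is None:
        mask_arr = np.ones(shape, dtype=bool)
    elif isinstance(mask, (str, bytes)) or hasattr(mask, "__fspath__"):
        mask_arr = np.asanyarray(nib.load(str(mask)).dataobj) > 0
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    return np.stack([img[mask_arr] for img in imgs])
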