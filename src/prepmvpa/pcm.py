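"""Pattern component correlation models.

Measured activity patterns Y (conditions x voxels, per run) are modeled as
multivariate Gaussian with a condition-by-condition second-moment matrix

    G(r, theta) = a_p J_p + a_e J_e + s_p I_p + s_e I_e
                  + r sqrt(s_p s_e) X_pe

where J_p / J_e are all-ones blocks on the planning / execution conditions
(the common pattern of each phase), I_p / I_e are identities on the
finger-specific components, and X_pe couples matching fingers across phases
with a fixed correlation r.  Each model fixes r and maximizes the marginal
(matrix-normal) likelihood over the five free parameters: the four signal
variances (a_p, a_e, s_p, s_e) and the measurement-noise variance.

Because measurement noise biases sample correlations of noisy patterns far
below the true correlation, the correlation is inferred by comparing the
maximized likelihood across a grid of fixed-r models (100 models on [0, 1]
by default) rather than by correlating patterns directly.  Group-level
model selection uses leave-one-subject-out cross-validation.

The central entry point is :class:`CorrelationPCM`, a model object built
from run x condition x voxel patterns whose ``fit`` / ``fit_grid`` methods
return results objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .design import CONDITIONS

__all__ = [
    "SecondMomentModel",
    "build_correlation_model",
    "predicted_g",
    "correlation_components",
    "marginal_loglik",
    "correlation_grid",
    "CorrelationPCM",
    "PCMFit",
    "CorrelationGridResults",
    "GroupModelComparison",
    "loso_best_model",
    "GroupCorrelationSummary",
    "group_correlation_summary",
    "naive_correlation",
]

N_CONDITIONS = 6
_PLAN = slice(0, 3)
_EXEC = slice(3, 6)

#: Parameter names; theta holds their logs.
PARAM_NAMES = ("a_plan", "a_exec", "s_plan", "s_exec", "sigma2_eps")


def correlation_components(r: float) -> list[np.ndarray]:
    """The 6x6 component matrices G_h of the correlation model.

    Order: planning common pattern (J on the plan block), execution common
    pattern, planning finger-specific (I on the plan block), execution
    finger-specific, and the cross-phase finger coupling scaled by r.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"correlation must be in [0, 1], got {r}")
    j = np.ones((3, 3))
    i3 = np.eye(3)
    g_ap = np.zeros((6, 6))
    g_ap[_PLAN, _PLAN] = j
    g_ae = np.zeros((6, 6))
    g_ae[_EXEC, _EXEC] = j
    g_sp = np.zeros((6, 6))
    g_sp[_PLAN, _PLAN] = i3
    g_se = np.zeros((6, 6))
    g_se[_EXEC, _EXEC] = i3
    g_x = np.zeros((6, 6))
    g_x[_PLAN, _EXEC] = r * i3
    g_x[_EXEC, _PLAN] = r * i3
    return [g_ap, g_ae, g_sp, g_se, g_x]


def predicted_g(r: float, variances) -> np.ndarray:
    """Second-moment matrix G(r, variances).

    Parameters
    ----------
    r : float in [0, 1]
        Planning-execution pattern correlation for matching fingers.
    variances : sequence of 4 floats
        (a_plan, a_exec, s_plan, s_exec): variances of the phase-common and
        finger-specific pattern components.
    """
    a_p, a_e, s_p, s_e = (float(v) for v in variances)
    if min(a_p, a_e, s_p, s_e) < 0:
        raise ValueError("variances must be non-negative")
    g_ap, g_ae, g_sp, g_se, g_x = correlation_components(r)
    return (
        a_p * g_ap
        + a_e * g_ae
        + s_p * g_sp
        + s_e * g_se
        + np.sqrt(s_p * s_e) * g_x
    )


@dataclass(frozen=True)
class SecondMomentModel:
    """A pattern-component model with a fixed plan-exec correlation.

    ``theta`` are log-variances of the five free parameters
    (a_plan, a_exec, s_plan, s_exec, sigma2_eps).
    """

    r: float
    labels: tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"correlation must be in [0, 1], got {self.r}")

    @property
    def n_free_parameters(self) -> int:
        return 5

    @property
    def components(self) -> list[np.ndarray]:
        return correlation_components(self.r)

    def g(self, theta) -> np.ndarray:
        """Predicted second moment at log-variances theta (signal part)."""
        a_p, a_e, s_p, s_e = np.exp(np.asarray(theta, dtype=float)[:4])
        return predicted_g(self.r, (a_p, a_e, s_p, s_e))

    def g_derivatives(self, theta) -> list[np.ndarray]:
        """dG/dtheta_h for the four signal parameters (log scale)."""
        a_p, a_e, s_p, s_e = np.exp(np.asarray(theta, dtype=float)[:4])
        g_ap, g_ae, g_sp, g_se, g_x = self.components
        c = np.sqrt(s_p * s_e)
        return [
            a_p * g_ap,
            a_e * g_ae,
            s_p * g_sp + 0.5 * c * g_x,
            s_e * g_se + 0.5 * c * g_x,
        ]


def build_correlation_model(r: float, grid_index: int | None = None) -> SecondMomentModel:
    """Construct the fixed-correlation pattern-component model for r."""
    model = SecondMomentModel(r=float(r))
    if grid_index is not None and grid_index < 0:
        raise ValueError("grid_index must be non-negative")
    return model


def correlation_grid(n_models: int = 100, step_001: bool = False) -> np.ndarray:
    """Equally spaced correlation grid on [0, 1] including both endpoints.

    ``n_models=100`` gives step 1/99; ``step_001=True`` instead returns the
    101-point grid with exact 0.01 steps.
    """
    if step_001:
        return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    if n_models < 2:
        raise ValueError("need at least 2 models to span [0, 1]")
    return np.linspace(0.0, 1.0, n_models)


def marginal_loglik(y: np.ndarray, z: np.ndarray, g: np.ndarray, sigma2: float) -> float:
    """Matrix-normal marginal log-likelihood of patterns under (G, sigma2).

    The voxel columns of Y are modeled i.i.d. N(0, V) with
    V = Z G Z' + sigma2 I.  Voxel means are NOT removed (second-moment
    convention).

    Parameters
    ----------
    y : ndarray, shape (n_rows, n_voxels)
    z : ndarray, shape (n_rows, n_conditions)
        Row-to-condition indicator (or any design on the conditions).
    g : ndarray, shape (n_conditions, n_conditions)
    sigma2 : float

    Returns
    -------
    float
        Log-likelihood in nats.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n, p = y.shape
    v = z @ g @ z.T + sigma2 * np.eye(n)
    ll, _ = _loglik_core(v, y @ y.T, n, p)
    return ll


def _loglik_core(v: np.ndarray, s: np.ndarray, n: int, p: int):
    """(loglik, cho_factor) for V given the row Gram matrix S = Y Y'."""
    from scipy.linalg import cho_factor, cho_solve

    jitter = 0.0
    for _ in range(4):
        try:
            c, low = cho_factor(v + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * max(np.trace(v) / n, 1e-30))
    else:
        raise np.linalg.LinAlgError("covariance V is numerically singular")
    if jitter > 0:
        warnings.warn(f"covariance V regularized with jitter {jitter:.1e}", stacklevel=3)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    vinv_s = cho_solve((c, low), s)
    ll = -0.5 * (p * logdet + np.trace(vinv_s) + n * p * np.log(2.0 * np.pi))
    return float(ll), (c, low)


@dataclass(frozen=True)
class PCMFit:
    """Maximum-likelihood fit of one fixed-correlation model."""

    r: float
    loglik: float
    theta: np.ndarray  # log-variances, PARAM_NAMES order
    converged: bool
    n_iter: int

    @property
    def variances(self) -> pd.Series:
        return pd.Series(np.exp(self.theta), index=list(PARAM_NAMES))


class CorrelationPCM:
    """Pattern-component correlation model of planning/execution patterns.

    Parameters
    ----------
    patterns : ndarray, shape (n_runs, 6, n_voxels)
        Activity estimates per run for the six conditions, ordered
        (plan:1, plan:3, plan:5, exec:1, exec:3, exec:5); typically
        prewhitened GLM betas.
    fix_run_means : bool, optional
        Treat run-wise mean patterns as fixed effects: each run's rows are
        projected onto the orthonormal complement of the run mean before
        likelihood evaluation (default True).  The phase means across
        fingers are retained either way.
    labels : tuple of str, optional
        Condition labels (bookkeeping only).

    Notes
    -----
    The model assumes Gaussian signal and noise, one shared noise variance
    across runs, and exchangeable voxels.  ``fit(r)`` maximizes the
    marginal likelihood at a fixed correlation; ``fit_grid`` sweeps the
    correlation grid and is the basis of group inference.
    """

    def __init__(self, patterns, *, fix_run_means: bool = True, labels=CONDITIONS):
        patterns = np.asarray(patterns, dtype=float)
        if patterns.ndim != 3 or patterns.shape[1] != N_CONDITIONS:
            raise ValueError("patterns must have shape (n_runs, 6, n_voxels)")
        if patterns.shape[0] < 2:
            raise ValueError("need at least 2 runs")
        if not np.isfinite(patterns).all():
            raise ValueError("patterns must be finite")
        self.patterns = patterns
        self.labels = tuple(labels)
        self.fix_run_means = bool(fix_run_means)
        n_runs, _, n_vox = patterns.shape
        self.n_runs = n_runs
        self.n_voxels = n_vox

        if fix_run_means:
            # orthonormal basis of the complement of the run mean (5 x 6)
            k = _mean_complement_basis(N_CONDITIONS)
            rows = [k @ patterns[r] for r in range(n_runs)]
            self._y = np.concatenate(rows, axis=0)
            self._z = np.concatenate([k] * n_runs, axis=0)
        else:
            self._y = patterns.reshape(n_runs * N_CONDITIONS, n_vox)
            self._z = np.concatenate([np.eye(N_CONDITIONS)] * n_runs, axis=0)
        self._s = self._y @ self._y.T
        self._n = self._y.shape[0]
        # precomputed for the gradient: Z' ... Z contractions
        self._zt = self._z.T

    @classmethod
    def from_betas(cls, beta_estimates, noise_cov=None, **kwargs) -> "CorrelationPCM":
        """Build from GLM estimates, optionally prewhitening first."""
        from .glm import BetaEstimates, prewhiten

        if not isinstance(beta_estimates, BetaEstimates):
            raise TypeError("expected a BetaEstimates instance")
        pats = beta_estimates.condition_patterns()
        if noise_cov is not None:
            pats = prewhiten(pats, noise_cov)
        return cls(pats, **kwargs)

    # ------------------------------------------------------------------ #

    def loglik(self, theta, r: float) -> float:
        """Marginal log-likelihood at log-variances theta for model r."""
        ll, _ = self._loglik_grad(np.asarray(theta, dtype=float), SecondMomentModel(r), grad=False)
        return ll

    def _loglik_grad(self, theta, model: SecondMomentModel, grad: bool = True):
        from scipy.linalg import cho_solve

        sigma2 = float(np.exp(theta[4]))
        g = model.g(theta)
        v = self._z @ g @ self._zt + sigma2 * np.eye(self._n)
        p = self.n_voxels
        ll, cho = _loglik_core(v, self._s, self._n, p)
        if not grad:
            return ll, None
        vinv = cho_solve(cho, np.eye(self._n))
        a = vinv @ self._s @ vinv
        # contract through Z once: tr(M Z dG Z') = tr(dG (Z' M Z))
        zvz = self._zt @ vinv @ self._z
        zaz = self._zt @ a @ self._z
        grads = np.empty(5)
        for h, dg in enumerate(model.g_derivatives(theta)):
            grads[h] = -0.5 * p * np.sum(zvz * dg) + 0.5 * np.sum(zaz * dg)
        grads[4] = sigma2 * (-0.5 * p * np.trace(vinv) + 0.5 * np.trace(a))
        return ll, grads

    def _moment_start(self, r: float) -> np.ndarray:
        """Data-driven starting log-variances from cross-run moments."""
        pats = self.patterns
        n_runs, _, p = pats.shape
        total = pats.sum(axis=0)
        g_cross = (total @ total.T - np.einsum("rcv,rdv->cd", pats, pats)) / (
            n_runs * (n_runs - 1) * p
        )
        g_within = np.einsum("rcv,rcv->c", pats, pats).mean() / p  # mean diag of within-run G
        floor = 1e-3 * max(g_within, 1e-12)
        off = ~np.eye(3, dtype=bool)
        a_p = max(np.mean(g_cross[_PLAN, _PLAN][off]), floor)
        a_e = max(np.mean(g_cross[_EXEC, _EXEC][off]), floor)
        s_p = max(np.mean(np.diag(g_cross)[0:3]) - a_p, floor)
        s_e = max(np.mean(np.diag(g_cross)[3:6]) - a_e, floor)
        noise = max(g_within - np.mean(np.diag(g_cross)), floor)
        return np.log([a_p, a_e, s_p, s_e, noise])

    def fit(self, r: float, start=None, n_starts: int = 2, maxiter: int = 200) -> PCMFit:
        """Maximize the likelihood of the fixed-correlation model ``r``.

        Quasi-Newton (L-BFGS-B) on the log-variances with an analytic
        gradient, from a data-driven moment start plus optional extra
        starting points.

        Parameters
        ----------
        r : float in [0, 1]
        start : ndarray or list of ndarray, optional
            Starting log-variances (5,) to use in addition to (or, if
            ``n_starts == 1`` and one start is given, instead of) the
            default starts.
        n_starts : int
            Number of default starting points (moment-based and a generic
            one).
        """
        model = SecondMomentModel(float(r))
        starts = []
        if start is not None:
            start = np.asarray(start, dtype=float)
            starts.extend(list(start) if start.ndim == 2 else [start])
        if len(starts) == 0 or n_starts > 1:
            starts.append(self._moment_start(r))
        if n_starts > 1:
            scale = max(self._s.trace() / (self._n * self.n_voxels), 1e-12)
            starts.append(np.log(np.full(5, 0.5 * scale)))

        def objective(th):
            # transient near-singular V during line searches is expected;
            # silence the jitter warning inside the optimizer only
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                return _neg(self._loglik_grad(th, model))

        best = None
        for x0 in starts:
            res = optimize.minimize(
                objective,
                np.clip(x0, -15.0, 15.0),
                jac=True,
                method="L-BFGS-B",
                bounds=[(-18.0, 18.0)] * 5,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            # warm starts at a near-optimum can abort the line search with
            # success=False although the gradient is already negligible
            ok = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
            if best is None or -res.fun > best.loglik + 1e-12:
                best = PCMFit(
                    r=float(r),
                    loglik=float(-res.fun),
                    theta=np.asarray(res.x),
                    converged=ok,
                    n_iter=int(res.nit),
                )
        if not best.converged:
            warnings.warn(f"PCM fit at r={r:.3f} did not converge", stacklevel=2)
        return best

    def fit_grid(
        self,
        n_models: int = 100,
        *,
        grid: np.ndarray | None = None,
        step_001: bool = False,
    ) -> "CorrelationGridResults":
        """Fit every model on the correlation grid.

        Fits are warm-started from the neighboring model's optimum (the
        likelihood surface moves smoothly with r) in addition to the
        moment start.

        Returns
        -------
        CorrelationGridResults
        """
        rs = np.asarray(grid, dtype=float) if grid is not None else correlation_grid(n_models, step_001)
        if rs.size < 2:
            raise ValueError("grid must contain at least 2 models")
        fits = []
        prev_theta = None
        for r in rs:
            fit = self.fit(float(r), start=prev_theta, n_starts=1 if prev_theta is not None else 2)
            # guard against a warm start trapping the fit below the moment start
            if prev_theta is not None:
                alt = self.fit(float(r), n_starts=1)
                if alt.loglik > fit.loglik + 1e-9:
                    fit = alt
            fits.append(fit)
            prev_theta = fit.theta
        return CorrelationGridResults(model=self, fits=tuple(fits))


def _neg(ll_grad):
    ll, grad = ll_grad
    return -ll, -grad


def _mean_complement_basis(c: int) -> np.ndarray:
    """Orthonormal (c-1) x c basis of the complement of the constant vector."""
    a = np.eye(c) - np.ones((c, c)) / c
    vals, vecs = np.linalg.eigh(a)
    return vecs[:, vals > 0.5].T


@dataclass(frozen=True)
class CorrelationGridResults:
    """Likelihood curve of the correlation-model grid for one subject."""

    model: CorrelationPCM
    fits: tuple[PCMFit, ...]

    @property
    def rs(self) -> np.ndarray:
        return np.array([f.r for f in self.fits])

    @property
    def loglik(self) -> np.ndarray:
        return np.array([f.loglik for f in self.fits])

    @property
    def relative_loglik(self) -> np.ndarray:
        """Log-likelihoods relative to the across-model mean."""
        ll = self.loglik
        return ll - ll.mean()

    @property
    def best_r(self) -> float:
        """Maximum-likelihood correlation (lowest r wins ties)."""
        return float(self.rs[int(np.argmax(self.loglik))])

    @property
    def converged(self) -> np.ndarray:
        return np.array([f.converged for f in self.fits])

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "r": self.rs,
                "loglik": self.loglik,
                "relative_loglik": self.relative_loglik,
                "converged": self.converged,
            }
        )
        for i, name in enumerate(PARAM_NAMES):
            df[name] = [float(np.exp(f.theta[i])) for f in self.fits]
        return df

    def plot(self, ax=None):
        """Plot the relative log-likelihood curve over correlation models."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.rs, self.relative_loglik, color="0.3")
        ax.axvline(self.best_r, color="crimson", linestyle="--", label=f"best r = {self.best_r:.2f}")
        ax.set_xlabel("model correlation r")
        ax.set_ylabel("log-likelihood (rel. to model mean)")
        ax.legend()
        return ax


# --------------------------- group inference --------------------------- #


def _loglik_table(grids_or_table) -> tuple[np.ndarray, np.ndarray]:
    """(subject x model loglik array, model correlations) from inputs."""
    if isinstance(grids_or_table, pd.DataFrame):
        rs = np.asarray(grids_or_table.columns, dtype=float)
        return grids_or_table.to_numpy(dtype=float), rs
    if isinstance(grids_or_table, np.ndarray):
        table = np.asarray(grids_or_table, dtype=float)
        rs = np.linspace(0.0, 1.0, table.shape[1])
        return table, rs
    grids = list(grids_or_table)
    rs = grids[0].rs
    for g in grids[1:]:
        if not np.allclose(g.rs, rs):
            raise ValueError("all subjects must be fitted on the same correlation grid")
    return np.stack([g.loglik for g in grids]), rs


@dataclass(frozen=True)
class GroupModelComparison:
    """Leave-one-subject-out group model selection.

    ``relative_loglik`` is the subject x model table centered on each
    subject's across-model mean (rows sum to zero).  ``worse`` flags models
    significantly worse (one-sided paired t-test, p < alpha) than the
    cross-validated best model.
    """

    rs: np.ndarray
    relative_loglik: np.ndarray
    loso_winner: np.ndarray  # winning model index per left-out subject
    best_loglik: np.ndarray  # per-subject loglik at that fold's winner
    pvalues: np.ndarray
    worse: np.ndarray
    alpha: float

    @property
    def not_worse_range(self) -> tuple[float, float]:
        """Correlation range of models not significantly worse than best."""
        ok = self.rs[~self.worse]
        return float(ok.min()), float(ok.max())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.rs,
                "mean_relative_loglik": self.relative_loglik.mean(axis=0),
                "sem_relative_loglik": sps.sem(self.relative_loglik, axis=0),
                "pvalue_vs_best": self.pvalues,
                "significantly_worse": self.worse,
            }
        )


def loso_best_model(grids_or_table, alpha: float = 0.05) -> GroupModelComparison:
    """Cross-validated group comparison of the correlation models.

    For each left-out subject the winning model is the argmax of the mean
    log-likelihood over the remaining subjects (ties broken toward the
    lowest correlation); the left-out subject's log-likelihood at that
    winner forms the 'best-model' vector.  Each model is then compared to
    this vector with a one-sided paired t-test; models with p < alpha are
    flagged as significantly worse than the best model.

    Parameters
    ----------
    grids_or_table : list of CorrelationGridResults, DataFrame, or ndarray
        Per-subject likelihood curves (subjects x models).
    alpha : float
        Significance level of the one-sided test.
    """
    table, rs = _loglik_table(grids_or_table)
    n_subj, n_models = table.shape
    if n_subj < 3:
        raise ValueError("group comparison needs >= 3 subjects")
    rel = table - table.mean(axis=1, keepdims=True)

    winners = np.empty(n_subj, dtype=int)
    best = np.empty(n_subj)
    for s in range(n_subj):
        others = np.delete(rel, s, axis=0).mean(axis=0)
        winners[s] = int(np.argmax(others))  # argmax returns the first (lowest r) on ties
        best[s] = rel[s, winners[s]]

    pvals = np.empty(n_models)
    for m in range(n_models):
        diff = best - rel[:, m]
        if np.allclose(diff.std(ddof=1), 0.0):
            pvals[m] = 0.0 if diff.mean() > 1e-12 else 1.0
        else:
            pvals[m] = sps.ttest_rel(best, rel[:, m], alternative="greater").pvalue
    return GroupModelComparison(
        rs=rs,
        relative_loglik=rel,
        loso_winner=winners,
        best_loglik=best,
        pvalues=pvals,
        worse=pvals < alpha,
        alpha=alpha,
    )


@dataclass(frozen=True)
class GroupCorrelationSummary:
    """Group summary of per-subject maximum-likelihood correlations."""

    best_rs: np.ndarray
    mean_best_r: float
    sem_best_r: float
    t_vs_zero_model: float
    p_vs_zero_model: float

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "mean_best_r": self.mean_best_r,
                "sem_best_r": self.sem_best_r,
                "t_vs_zero_model": self.t_vs_zero_model,
                "p_vs_zero_model": self.p_vs_zero_model,
            }
        )


def group_correlation_summary(grids_or_table) -> GroupCorrelationSummary:
    """Mean and SEM of per-subject best correlations, and the zero-model test.

    The zero-model test is a two-tailed one-sample t-test of the
    per-subject log-likelihood difference (own best model minus the
    zero-correlation model) against zero.
    """
    table, rs = _loglik_table(grids_or_table)
    if table.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    best_idx = np.argmax(table, axis=1)
    best_rs = rs[best_idx]
    zero_col = int(np.argmin(np.abs(rs)))
    diff = table[np.arange(table.shape[0]), best_idx] - table[:, zero_col]
    if np.allclose(diff.std(ddof=1), 0.0):
        t, p = (np.inf, 0.0) if diff.mean() > 1e-12 else (0.0, 1.0)
    else:
        res = sps.ttest_1samp(diff, 0.0)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupCorrelationSummary(
        best_rs=best_rs,
        mean_best_r=float(best_rs.mean()),
        sem_best_r=float(sps.sem(best_rs)) if table.shape[0] > 1 else 0.0,
        t_vs_zero_model=t,
        p_vs_zero_model=p,
    )


def naive_correlation(patterns: np.ndarray) -> float:
    """Raw correlation of run-averaged planning and execution patterns.

    Averages patterns across runs, removes each phase's mean pattern across
    fingers, and correlates the stacked finger-specific planning residuals
    with the matching execution residuals.  On noisy data this estimate is
    biased toward zero, which is the motivation for the likelihood-based
    grid approach.
    """
    patterns = np.asarray(patterns, dtype=float)
    mean = patterns.mean(axis=0)  # (6, voxels)
    plan = mean[_PLAN] - mean[_PLAN].mean(axis=0, keepdims=True)
    exe = mean[_EXEC] - mean[_EXEC].mean(axis=0, keepdims=True)
    a, b = plan.ravel(), exe.ravel()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)
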