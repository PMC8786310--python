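"""Multivariate group statistics.

Currently the paired Hotelling T-squared test used to compare two
multivariate means (e.g. the x-y peak locations of planning vs execution
information maps across subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["HotellingResult", "hotelling_t2_paired"]


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f: float
    df1: int
    df2: int
    pvalue: float


def hotelling_t2_paired(coords_a: np.ndarray, coords_b: np.ndarray) -> HotellingResult:
    """One-sample Hotelling T-squared test on paired multivariate data.

    Tests whether the mean of the paired differences ``coords_a - coords_b``
    is zero.  T2 = n * dbar' S^-1 dbar is converted to an F statistic with
    (p, n - p) degrees of freedom.

    Parameters
    ----------
    coords_a, coords_b : ndarray, shape (n_subjects, p)
        Paired multivariate observations (p = 2 for map coordinates; p = 1
        reduces to the squared paired t statistic).

    Returns
    -------
    HotellingResult
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape[0] == 1:
        a, b = a.T, b.T
    if a.shape != b.shape:
        raise ValueError(f"paired samples must align, got {a.shape} vs {b.shape}")
    n, p = a.shape
    if n < p + 1:
        raise ValueError(f"need at least p + 1 = {p + 1} subjects, got {n}")
    d = a - b
    dbar = d.mean(axis=0)
    if np.allclose(d, d[0]):
        # all differences identical: zero-variance degenerate case
        if np.allclose(dbar, 0.0):
            return HotellingResult(t2=0.0, f=0.0, df1=p, df2=n - p, pvalue=1.0)
        raise np.linalg.LinAlgError("difference covariance is singular")
    s = np.cov(d, rowvar=False).reshape(p, p)
    try:
        sol = np.linalg.solve(s, dbar)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("difference covariance is singular") from err
    t2 = float(n * dbar @ sol)
    f = (n - p) / (p * (n - 1)) * t2
    pvalue = float(sps.f.sf(f, p, n - p))
    return HotellingResult(t2=t2, f=f, df1=p, df2=n - p, pvalue=pvalue)
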