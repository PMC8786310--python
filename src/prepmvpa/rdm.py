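"""Cross-validated Mahalanobis (crossnobis) distances and RDM geometry.

The crossnobis dissimilarity between two conditions multiplies the pattern
difference measured in one run with the same difference measured in every
other run, averaging over ordered run pairs and voxels.  Because the two
factors carry independent noise the estimator is unbiased: its expectation
is zero when two conditions differ only by noise, so estimates can be
negative.  Distances are expressed per voxel (squared prewhitened activity
units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .design import CONDITIONS

__all__ = [
    "RDM",
    "crossnobis_rdm",
    "mean_distance",
    "mds_embed",
    "distance_ratio",
    "g_to_rdm",
]


@dataclass(frozen=True)
class RDM:
    """A condition-by-condition representational dissimilarity matrix.

    ``values`` is symmetric with a zero diagonal; with C conditions it holds
    C*(C-1)/2 unique dissimilarities (15 for the 6 planning/execution
    conditions).  Entries may be negative (unbiased cross-validated
    estimator).
    """

    values: np.ndarray
    labels: tuple[str, ...]
    n_partitions: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("RDM values must be square and match the labels")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("RDM must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_conditions(self) -> int:
        return len(self.labels)

    def unique_values(self) -> np.ndarray:
        """The C*(C-1)/2 upper-triangular dissimilarities."""
        iu = np.triu_indices(self.n_conditions, k=1)
        return self.values[iu]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"condition_a": a, "condition_b": b, "dissimilarity": self.get(a, b)}
            for a, b in combinations(self.labels, 2)
        ]
        return pd.DataFrame(rows)


def crossnobis_rdm(
    patterns: np.ndarray,
    labels: tuple[str, ...] | None = None,
    *,
    estimator: str = "allpairs",
) -> RDM:
    """Cross-validated (squared) Mahalanobis dissimilarities.

    Parameters
    ----------
    patterns : ndarray, shape (n_partitions, n_conditions, n_voxels)
        Prewhitened activity patterns; one complete set of conditions per
        partition (imaging run).  NaNs are rejected (every condition must be
        present in every partition).
    labels : tuple of str, optional
        Condition labels; defaults to the 6 planning/execution conditions
        when n_conditions == 6.
    estimator : {'allpairs', 'loo'}
        'allpairs' (default) averages the cross-products over all ordered
        partition pairs m != n; 'loo' crosses each partition with the mean
        of the remaining partitions.  Both are unbiased and identical in
        expectation.

    Returns
    -------
    RDM
        d(i, j) = mean over partition pairs of delta_m' delta_n / P with
        delta = pattern_i - pattern_j and P the voxel count.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 3:
        raise ValueError("patterns must have shape (partitions, conditions, voxels)")
    n_part, n_cond, n_vox = patterns.shape
    if n_part < 2:
        raise ValueError("crossnobis needs >= 2 partitions")
    if np.isnan(patterns).any():
        bad = np.argwhere(np.isnan(patterns).any(axis=2))
        raise ValueError(f"missing condition patterns (partition, condition): {bad[:5].tolist()}")
    if labels is None:
        labels = CONDITIONS if n_cond == 6 else tuple(f"c{i}" for i in range(n_cond))

    # pairwise condition differences per partition: (n_part, n_pairs, n_vox)
    iu, ju = np.triu_indices(n_cond, k=1)
    delta = patterns[:, iu, :] - patterns[:, ju, :]
    if estimator == "allpairs":
        total = delta.sum(axis=0)
        cross = np.einsum("pv,pv->p", total, total) - np.einsum("mpv,mpv->p", delta, delta)
        d = cross / (n_part * (n_part - 1) * n_vox)
    elif estimator == "loo":
        total = delta.sum(axis=0)
        rest_mean = (total[None] - delta) / (n_part - 1)
        d = np.einsum("mpv,mpv->p", delta, rest_mean) / (n_part * n_vox)
    else:
        raise ValueError("estimator must be 'allpairs' or 'loo'")

    values = np.zeros((n_cond, n_cond))
    values[iu, ju] = d
    values[ju, iu] = d
    return RDM(values=values, labels=tuple(labels), n_partitions=n_part)


def mean_distance(rdm: RDM, subset) -> float:
    """Mean pairwise dissimilarity within a subset of conditions.

    With the three planning conditions this is the statistic assigned to
    searchlight centers (mean planning distance).
    """
    subset = list(subset)
    missing = [s for s in subset if s not in rdm.labels]
    if missing:
        raise KeyError(f"labels not in RDM: {missing}")
    if len(set(subset)) < 2:
        raise ValueError("mean_distance needs at least two distinct conditions")
    vals = [rdm.get(a, b) for a, b in combinations(sorted(set(subset), key=rdm.labels.index), 2)]
    return float(np.mean(vals))


@dataclass(frozen=True)
class MDSEmbedding:
    """Classical (Torgerson) multidimensional scaling of an RDM."""

    coords: np.ndarray  # (n_conditions, k)
    eigenvalues: np.ndarray  # all n_conditions eigenvalues, descending
    labels: tuple[str, ...]
    truncated_negative: bool  # True if negative eigenvalues were discarded


def mds_embed(rdm: RDM, k: int = 3) -> MDSEmbedding:
    """Classical MDS of the (squared) dissimilarities.

    Double-centers the RDM (placing the across-condition mean pattern at the
    origin), eigendecomposes it, and projects the conditions onto the top-k
    eigenvectors scaled by the square roots of their eigenvalues.  Negative
    eigenvalues (possible with cross-validated distances, meaning the RDM is
    not Euclidean-realizable) are truncated to zero in the projection and
    flagged.
    """
    c = rdm.n_conditions
    if not 1 <= k <= c - 1:
        raise ValueError(f"k must be in [1, {c - 1}], got {k}")
    d = rdm.values
    j = np.eye(c) - np.ones((c, c)) / c
    b = -0.5 * j @ d @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    truncated = bool(np.any(vals < -1e-12 * max(1.0, abs(vals).max())))
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    return MDSEmbedding(
        coords=coords,
        eigenvalues=vals,
        labels=rdm.labels,
        truncated_negative=truncated,
    )


def distance_ratio(plan_values, exec_values, regions=None) -> pd.Series:
    """Planning/execution distance ratio per region.

    Parameters
    ----------
    plan_values, exec_values : array_like
        Mean planning and execution distances per region (same order).
    regions : sequence of str, optional
        Region names for the index.

    Returns
    -------
    pandas.Series
        plan / exec per region; NaN (with a warning) where the execution
        distance is not positive.
    """
    plan = np.asarray(plan_values, dtype=float)
    exe = np.asarray(exec_values, dtype=float)
    if plan.shape != exe.shape:
        raise ValueError("planning and execution statistics must align")
    if regions is not None and len(regions) != plan.size:
        raise ValueError("region list does not match the statistics")
    bad = exe <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} region(s) have non-positive execution distance; ratio undefined",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, plan / exe)
    index = list(regions) if regions is not None else list(range(plan.size))
    return pd.Series(ratio, index=index, name="plan_exec_ratio")


def g_to_rdm(g: np.ndarray, labels: tuple[str, ...] | None = None) -> RDM:
    """RDM implied by a second-moment matrix: d(i,j) = g_ii + g_jj - 2 g_ij.

    This is the 1:1 correspondence between the second-moment matrix of the
    true patterns and the expected crossnobis RDM.
    """
    g = np.asarray(g, dtype=float)
    diag = np.diag(g)
    values = diag[:, None] + diag[None, :] - 2.0 * g
    if labels is None:
        labels = CONDITIONS if g.shape[0] == 6 else tuple(f"c{i}" for i in range(g.shape[0]))
    return RDM(values=values, labels=tuple(labels), n_partitions=0)
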