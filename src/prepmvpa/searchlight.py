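"""Searchlight mapping over generic voxel neighborhoods.

A searchlight evaluates a multivariate statistic (e.g. the mean planning
crossnobis distance) on a local neighborhood of voxels and assigns the value
to the neighborhood's center node, yielding an information map.  Real
cortical-surface meshes are out of scope; neighborhoods are defined on
synthetic grids (or any point cloud) as the fixed number of nearest voxels,
mirroring the fixed-count (100-voxel) searchlights used on surfaces, with
the nominal disc radius kept as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Neighborhoods", "grid_neighborhoods", "searchlight", "SearchlightMap"]

#: Standard searchlight size, voxels.
SEARCHLIGHT_SIZE = 100


@dataclass(frozen=True)
class Neighborhoods:
    """Node -> member-voxel-set searchlight definition.

    ``boundary`` flags nodes whose members spill beyond the nominal radius
    (the count constraint binds; the radius is metadata).
    """

    centers: np.ndarray  # (n_nodes, n_dims) node coordinates
    members: tuple[np.ndarray, ...]  # member voxel indices per node
    boundary: np.ndarray  # (n_nodes,) bool
    radius: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.members)


def grid_neighborhoods(
    coords: np.ndarray | tuple[int, ...],
    size: int = SEARCHLIGHT_SIZE,
    radius: float | None = None,
) -> Neighborhoods:
    """Fixed-count nearest-voxel searchlight neighborhoods.

    Parameters
    ----------
    coords : ndarray (n_voxels, n_dims) or grid shape tuple
        Voxel coordinates; a shape tuple builds a unit-spacing rectangular
        grid with one node per voxel.
    size : int
        Number of member voxels per searchlight (100 by default).
    radius : float, optional
        Nominal searchlight radius.  Nodes whose ``size``-th nearest voxel
        lies beyond it are flagged as boundary nodes.
    """
    if isinstance(coords, tuple):
        coords = np.stack(
            [g.ravel() for g in np.meshgrid(*[np.arange(n) for n in coords], indexing="ij")],
            axis=1,
        ).astype(float)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if size < 1 or size > n:
        raise ValueError(f"searchlight size {size} not attainable with {n} voxels")
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=size)
    if size == 1:
        dist, idx = dist[:, None], idx[:, None]
    if radius is None:
        boundary = np.zeros(n, dtype=bool)
    else:
        boundary = dist[:, -1] > radius
    return Neighborhoods(
        centers=coords,
        members=tuple(np.sort(row) for row in idx),
        boundary=boundary,
        radius=radius,
    )


@dataclass(frozen=True)
class SearchlightMap:
    """Per-node statistic values with the generating neighborhoods."""

    values: np.ndarray
    neighborhoods: Neighborhoods


def searchlight(patterns: np.ndarray, neighborhoods: Neighborhoods, stat_fn) -> SearchlightMap:
    """Evaluate a multivariate statistic in every searchlight.

    Parameters
    ----------
    patterns : ndarray, shape (n_partitions, n_conditions, n_voxels)
        Node-indexed activity patterns (voxel axis matches the neighborhood
        member indices).
    neighborhoods : Neighborhoods
    stat_fn : callable
        Maps a (n_partitions, n_conditions, size) sub-array to a scalar,
        e.g. ``lambda p: mean_distance(crossnobis_rdm(p), planning_labels)``.

    Returns
    -------
    SearchlightMap
    """
    patterns = np.asarray(patterns)
    values = np.empty(neighborhoods.n_nodes)
    for i, members in enumerate(neighborhoods.members):
        if members.size == 0:
            raise ValueError(f"empty neighborhood at node {i}")
        values[i] = stat_fn(patterns[..., members])
    return SearchlightMap(values=values, neighborhoods=neighborhoods)
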