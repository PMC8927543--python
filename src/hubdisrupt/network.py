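"""Voxel-wise binary functional networks at fixed link densities.

A correlation matrix over gray-matter voxels is Fisher-z transformed and
binarized by retaining the strongest L = round(density * V(V-1)/2) links.
Fixing the link density (1-10% here) equates network cost across subjects,
so the binarization threshold itself is subject-dependent.

Degree maps count a voxel's surviving links after excluding short-distance
edges (within two grid steps by default), which suppresses residual motion
artifacts in local connectivity.
"""

from __future__ import annotations

import numpy as np

from .types import BoldSeries, DegreeMap, FunctionalNetwork

__all__ = [
    "correlation_matrix",
    "threshold_by_density",
    "degree_map",
    "roi_degree_map",
    "mean_degree_in_cluster",
    "round_half_up",
]

#: |r| is capped here before atanh so duplicated time series stay finite.
R_CAP = 1.0 - 1e-7


def round_half_up(x: float) -> int:
    """Deterministic half-up rounding (numpy rounds half to even)."""
    return int(np.floor(x + 0.5))


def correlation_matrix(data: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of voxel time series, Fisher-z transformed.

    Returns a V x V symmetric matrix of z = atanh(r) with |r| capped at
    ``1 - 1e-7``.  The diagonal is set to -inf so self-links are never
    ranked; zero-variance voxels get all their entries set to -inf (they
    can never be selected by density thresholding).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("data must be V x T with T >= 3")
    sd = data.std(axis=1)
    degenerate = sd == 0
    safe = data.copy()
    if degenerate.any():
        # give flat voxels harmless unit variance, then overwrite their rows
        safe[degenerate] += np.arange(data.shape[1])
    r = np.corrcoef(safe)
    r = np.clip(r, -R_CAP, R_CAP)
    z = np.arctanh(r)
    z[degenerate, :] = -np.inf
    z[:, degenerate] = -np.inf
    np.fill_diagonal(z, -np.inf)
    return z


def edge_count_for_density(n_nodes: int, density: float) -> int:
    return round_half_up(density * n_nodes * (n_nodes - 1) / 2.0)


def threshold_by_density(
    z_matrix: np.ndarray,
    density: float,
    voxel_coords: np.ndarray | None = None,
    voxel_size: float = 1.0,
    use_absolute: bool = False,
) -> FunctionalNetwork:
    """Binarize a Fisher-z matrix by keeping the L strongest links.

    L = round(density * V(V-1)/2), half-up.  Ranking uses signed z by
    default (strongest positive correlations first); set ``use_absolute``
    to rank by |z|.  Ties are broken by ascending (i, j) pair order so the
    edge sets are nested across densities and identical across platforms.
    """
    z = np.asarray(z_matrix, dtype=float)
    v = z.shape[0]
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n_edges = edge_count_for_density(v, density)
    if n_edges < 1:
        raise ValueError(
            f"density {density} implies {n_edges} edges on {v} nodes; need >= 1"
        )
    iu, ju = np.triu_indices(v, k=1)
    scores = np.abs(z[iu, ju]) if use_absolute else z[iu, ju]
    # stable sort on (-score, i, j): lexsort keys are last-key-major
    order = np.lexsort((ju, iu, -scores))
    keep = order[:n_edges]
    adj = np.zeros((v, v), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    if voxel_coords is None:
        voxel_coords = np.column_stack([np.arange(v), np.zeros(v, int), np.zeros(v, int)])
    return FunctionalNetwork(adj, float(density), np.asarray(voxel_coords), voxel_size)


def _surviving_links(network: FunctionalNetwork, exclusion_distance: float) -> np.ndarray:
    """Adjacency with links at center-to-center grid distance <= excl removed."""
    coords = np.asarray(network.voxel_coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return network.adjacency & (dist > exclusion_distance)


def degree_map(network: FunctionalNetwork, exclusion_distance: float = 2.0) -> DegreeMap:
    """Per-voxel count of links longer than ``exclusion_distance`` grid units.

    The excluded short-distance edges remain in the network object; only the
    counting ignores them.  With ``exclusion_distance=0`` this is the plain
    graph degree.
    """
    surv = _surviving_links(network, exclusion_distance)
    return DegreeMap(
        surv.sum(axis=1).astype(float),
        exclusion_distance,
        network.density,
        network.voxel_coords,
        network.voxel_size,
    )


def roi_degree_map(
    network: FunctionalNetwork, roi_mask: np.ndarray, exclusion_distance: float = 2.0
) -> DegreeMap:
    """Seed-based degree map: links between each voxel and an ROI voxel set.

    Voxels outside the ROI count their surviving links into the ROI; ROI
    voxels count their surviving links to the outside.  The two sides of the
    map therefore sum to the same total (each ROI/non-ROI link is counted
    once on each side).
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != (network.n_nodes,):
        raise ValueError("roi_mask must be a boolean V-vector")
    if not roi.any():
        raise ValueError("ROI is empty")
    if roi.all():
        raise ValueError("ROI covers every voxel; no seed map is defined")
    surv = _surviving_links(network, exclusion_distance)
    values = np.where(
        roi, surv[:, ~roi].sum(axis=1), surv[:, roi].sum(axis=1)
    ).astype(float)
    return DegreeMap(
        values,
        exclusion_distance,
        network.density,
        network.voxel_coords,
        network.voxel_size,
    )


def mean_degree_in_cluster(degree_map_: DegreeMap, cluster_mask: np.ndarray) -> float:
    """Arithmetic mean of the degree map over a (non-empty) cluster of voxels."""
    mask = np.asarray(cluster_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cluster is empty")
    return float(np.mean(np.asarray(degree_map_.values)[mask]))


def network_from_bold(
    bold: BoldSeries, density: float, use_absolute: bool = False
) -> FunctionalNetwork:
    """Convenience: correlation -> Fisher z -> density threshold on a BoldSeries."""
    z = correlation_matrix(bold.data)
    return threshold_by_density(
        z, density, bold.voxel_coords, bold.voxel_size, use_absolute=use_absolute
    )
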