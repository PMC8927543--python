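"""Shared in-memory containers for the voxel-wise connectome pipeline.

All containers are thin dataclasses around numpy arrays.  Voxel indices are
0-based everywhere; time (volume) indices are 0-based as well, so "the first
volume" is column 0.  Grid coordinates are integer voxel indices on the
analysis grid; physical positions are ``coords * voxel_size`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoldSeries",
    "CensorRecord",
    "NuisanceSet",
    "FunctionalNetwork",
    "DegreeMap",
    "NodalMetricVector",
    "Partition",
    "KdProfile",
    "StatMap",
]

METRICS = ("D", "BC", "CC", "E", "PC")


@dataclass
class BoldSeries:
    """A voxel x time BOLD matrix with grid bookkeeping.

    Parameters
    ----------
    data:
        V x T array of signal intensities (arbitrary units).
    voxel_coords:
        V x 3 integer grid indices of each voxel.
    voxel_size:
        Edge length of one grid step, in mm (isotropic).
    tr:
        Repetition time in seconds.
    """

    data: np.ndarray
    voxel_coords: np.ndarray
    voxel_size: float
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be a V x T matrix")
        if self.voxel_coords.shape != (self.data.shape[0], 3):
            raise ValueError(
                f"voxel_coords shape {self.voxel_coords.shape} does not match "
                f"V={self.data.shape[0]}"
            )
        if len(np.unique(self.voxel_coords, axis=0)) != self.n_voxels:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class CensorRecord:
    """Per-volume motion/intensity spike measures and the resulting censor mask."""

    fd: np.ndarray
    dvars_z: np.ndarray
    sd_z: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(np.asarray(self.fd) < 0):
            raise ValueError("framewise displacement cannot be negative")

    @property
    def n_retained(self) -> int:
        return int((~self.censored).sum())


@dataclass
class NuisanceSet:
    """Nuisance regressors: 6 motion traces, mean CSF, mean WM, global signal."""

    motion: np.ndarray
    csf: np.ndarray
    wm: np.ndarray
    global_signal: np.ndarray

    def __post_init__(self) -> None:
        t = len(self.csf)
        if self.motion.shape != (t, 6) or len(self.wm) != t or len(self.global_signal) != t:
            raise ValueError("all nuisance regressors must share the same length T")

    def design(self) -> np.ndarray:
        """Stack into a T x 9 regressor matrix (no intercept)."""
        return np.column_stack(
            [self.motion, self.csf, self.wm, self.global_signal]
        )


@dataclass
class FunctionalNetwork:
    """Binary undirected functional network at a fixed link density."""

    adjacency: np.ndarray
    density: float
    voxel_coords: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a.astype(bool)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class DegreeMap:
    """Per-voxel link counts after short-distance edge exclusion."""

    values: np.ndarray
    exclusion_distance: float
    density: float
    voxel_coords: np.ndarray = field(default=None)  # type: ignore[assignment]
    voxel_size: float = 1.0


@dataclass
class NodalMetricVector:
    """One nodal graph property evaluated at every node of one network."""

    metric_name: str
    values: np.ndarray
    density: float

    def __post_init__(self) -> None:
        if self.metric_name not in METRICS:
            raise ValueError(f"metric_name must be one of {METRICS}")


@dataclass
class Partition:
    """A node-community assignment with its Newman modularity."""

    module_id: np.ndarray
    modularity: float

    def __post_init__(self) -> None:
        m = np.asarray(self.module_id, dtype=int)
        labels = np.unique(m)
        if not np.array_equal(labels, np.arange(1, len(labels) + 1)):
            raise ValueError("module labels must be contiguous integers from 1")
        self.module_id = m

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.module_id))


@dataclass
class KdProfile:
    """Hub-disruption slopes for one subject: 5 metrics x 10 link densities."""

    subject_id: str
    slopes: np.ndarray  # metrics (5) x densities (10)
    densities: np.ndarray
    reference_id: str

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.slopes.shape[0] != len(METRICS):
            raise ValueError("slopes must have one row per metric (D, BC, CC, E, PC)")
        if not np.all(np.isfinite(self.slopes)):
            raise ValueError("hub-disruption slopes must be finite")


@dataclass
class StatMap:
    """Voxel-wise statistic map with TFCE enhancement and FWE-corrected p-values."""

    stat: np.ndarray
    tfce: np.ndarray
    p_fwe: np.ndarray
    direction: str
    n_perm: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p_fwe, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p_fwe must lie in [0, 1]")
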