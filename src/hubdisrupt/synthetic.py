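"""Synthetic two-group cohort with planted, recoverable ground truth.

The generator emulates the study design the pipeline targets: a healthy
reference group whose functional networks share one hub-bearing modular
topology, and a patient group whose networks are hub-disrupted copies of it
with a known per-subject slope kappa; motion traces with planted spikes
that imply a known censor set; and a behavioral score (an upper-extremity
motor scale bounded to [0, 66]) coupled to the degree of a designated hub
ROI — negatively at baseline and positively for the recovery ratio.

Reference topology
------------------
The reference network is built from near-disjoint cliques ("functional
modules") with heavy-tailed sizes plus random inter-module bridge edges.
Two properties motivate this over a preferential-attachment graph: (1)
functional brain networks are strongly modular, with hubs embedded in
correlated communities rather than centers of independent spokes; and (2)
the covariance construction load*I + w*A is positive definite only for
w < 1/|lambda_min(A)|.  Tree-like hubs drive lambda_min to about
-sqrt(k_max), capping edge correlations near 0.1 — too weak to survive the
pipeline's own band-pass dof budget — whereas clique structure keeps
lambda_min near -2, supporting realistic correlation strengths (~0.4).

Randomness: one master seed fans out through ``numpy.random.SeedSequence``
spawning in a fixed documented order (stream 0: reference topology and
layout; stream 1: demographics; streams 2+i: subject i; final stream:
behavioral noise).  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import edge_count_for_density
from .types import BoldSeries

__all__ = [
    "GroundTruth",
    "SyntheticSubject",
    "CohortConfig",
    "generate_reference_network",
    "disrupt_network_metrics",
    "covariance_from_network",
    "sample_bold",
    "generate_motion",
    "generate_cohort",
    "default_grid_coords",
]

FMA_MAX = 66.0

SeedLike = int | np.random.SeedSequence | np.random.Generator


def _rng(seed: SeedLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class GroundTruth:
    """Everything a downstream test needs to score recovery of the truth."""

    reference_adjacency: np.ndarray
    reference_covariance: np.ndarray
    kappa_true: dict[str, float]
    roi_voxel_ids: np.ndarray
    behavior_coupling: dict[str, float]
    spike_volumes: dict[str, list[int]]
    seed: int
    edge_weight: float = np.nan
    planted_roi_degree: dict[str, float] | None = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.reference_covariance)
        if not np.allclose(cov, cov.T):
            raise ValueError("reference covariance must be symmetric")
        if np.linalg.eigvalsh(cov)[0] <= 0:
            raise ValueError("reference covariance must be positive definite")
        if not all(np.isfinite(list(self.kappa_true.values()) or [0.0])):
            raise ValueError("kappa_true must be finite")
        v = cov.shape[0]
        roi = np.asarray(self.roi_voxel_ids)
        if roi.size and (roi.min() < 0 or roi.max() >= v):
            raise ValueError("roi_voxel_ids outside the voxel index range")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "edge_weight": self.edge_weight,
            "planted_roi_degree": self.planted_roi_degree,
            "kappa_true": self.kappa_true,
            "roi_voxel_ids": np.asarray(self.roi_voxel_ids).tolist(),
            "behavior_coupling": self.behavior_coupling,
            "spike_volumes": self.spike_volumes,
            "reference_adjacency_edges": [
                [int(i), int(j)]
                for i, j in zip(*np.nonzero(np.triu(self.reference_adjacency, 1)))
            ],
            "n_voxels": int(self.reference_covariance.shape[0]),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticSubject:
    subject_id: str
    bold: BoldSeries
    motion: np.ndarray
    age: float
    gender: int  # 0 = F, 1 = M
    group: str  # "HC" or "patient"
    side: str  # lesion side; "none" for controls
    fma_baseline: float | None = None
    fma_followup: float | None = None

    def __post_init__(self) -> None:
        if self.bold.n_volumes < 124:
            raise ValueError("subjects need >= 124 volumes pre-discard")
        for score in (self.fma_baseline, self.fma_followup):
            if score is not None and not 0 <= score <= FMA_MAX:
                raise ValueError(f"FMA score {score} outside [0, {FMA_MAX}]")


@dataclass
class CohortConfig:
    """Study conditions of the default synthetic cohort.

    Group sizes mirror the target design (28 patients vs 32 controls); the
    gray-matter grid is scaled to 150 voxels; T = 230 volumes at TR = 2.5 s
    matches the acquisition the pipeline assumes.  Patient disruption
    slopes are drawn around -0.3 with a wide spread (sd 0.25): only the
    direction of the group effect is reported by the study, while the
    strong behavioral association it reports implies substantial
    between-patient heterogeneity in disruption.
    """

    n_controls: int = 32
    n_patients: int = 28
    n_voxels: int = 150
    n_volumes: int = 230
    tr: float = 2.5
    voxel_size: float = 6.0
    network_density: float = 0.10
    edge_weight: float | None = None  # None -> 0.9 / worst |lambda_min| over cohort
    diagonal_load: float = 1.0
    global_artifact_sd: float = 2.0  # shared global fluctuation, in voxel-sd units
    kappa_mean: float = -0.3
    kappa_sd: float = 0.25
    kappa_clip: tuple[float, float] = (-0.8, 0.3)
    roi_size: int = 6
    baseline_coupling: float = 1.2  # latent-logit units per SD of ROI degree
    baseline_noise: float = 0.35
    recovery_coupling: float = 0.30  # recovery-ratio units per SD of ROI degree
    recovery_noise: float = 0.12
    spike_fraction: float = 0.25
    spike_mm: float = 0.8
    seed: int = 0


def _intra_edges(sizes: list[int]) -> int:
    return sum(c * (c - 1) // 2 for c in sizes)


def _sizes_at_scale(pool: np.ndarray, scale: float, v: int, cap: int) -> list[int]:
    sizes: list[int] = []
    for x in pool:
        if sum(sizes) >= v:
            break
        c = min(2 + int(x * scale), cap, v - sum(sizes))
        sizes.append(max(c, 1))
    if len(sizes) > 1 and sizes[-1] < 3:
        last = sizes.pop()
        sizes[-1] += last
    return sorted(sizes, reverse=True)


def _module_sizes(v: int, n_edges: int, rng: np.random.Generator) -> list[int]:
    """Heavy-tailed module sizes summing to v whose within-module edge count
    lands just below the total edge budget.

    Sizes come from a Pareto draw whose scale is bisected so that roughly
    95% of the edge budget is spent inside modules: the remaining bridges
    stay rare because many random bridge edges behave like an Erdos-Renyi
    overlay whose spectrum destroys the positive-definiteness headroom the
    clique structure provides.  Spending the budget on few large modules is
    what creates strong hubs.
    """
    cap = max(3, v // 4)
    target = n_edges - min(max(1, round(0.02 * n_edges)), v // 2)
    pool = 1.0 + rng.pareto(1.3, size=4 * v)
    lo, hi = 0.05, float(cap)
    best = _sizes_at_scale(pool, lo, v, cap)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        sizes = _sizes_at_scale(pool, mid, v, cap)
        if _intra_edges(sizes) <= target:
            best, lo = sizes, mid
        else:
            hi = mid
    # fine-trim: shrink the largest module if we overshot the hard budget
    while _intra_edges(best) > n_edges and best[0] > 2:
        best[0] -= 1
        best.sort(reverse=True)
    # close any remaining deficit by moving nodes from the smallest modules
    # into larger ones (also sharpens the hub tail)
    while len(best) > 1:
        intra = _intra_edges(best)
        if intra >= target:
            break
        s = best[-1]
        moved = False
        for j in range(len(best)):
            gain = best[j] - (s - 1)
            if best[j] < cap and gain > 0 and intra + gain <= n_edges:
                best[j] += 1
                best[-1] -= 1
                if best[-1] == 0:
                    best.pop()
                best.sort(reverse=True)
                moved = True
                break
        if not moved:
            break
    return best


def _add_bridges(adj: np.ndarray, n_bridges: int, rng: np.random.Generator) -> None:
    """Add inter-module bridge edges, node-disjoint where possible.

    A matching of bridges keeps the adjacency spectrum bounded below by
    (cliques) + (matching) >= -2, which preserves the headroom for strong
    uniform edge correlations.  If more bridges are requested than a
    matching allows, the remainder falls back to arbitrary absent pairs.
    """
    v = adj.shape[0]
    iu, ju = np.triu_indices(v, k=1)
    absent = np.flatnonzero(~adj[iu, ju])
    order = rng.permutation(absent)
    used = np.zeros(v, dtype=bool)
    added = 0
    for idx in order:
        if added >= n_bridges:
            return
        i, j = iu[idx], ju[idx]
        if not used[i] and not used[j]:
            adj[i, j] = adj[j, i] = True
            used[i] = used[j] = True
            added += 1
    for idx in order:  # fallback: matching exhausted
        if added >= n_bridges:
            return
        i, j = iu[idx], ju[idx]
        if not adj[i, j]:
            adj[i, j] = adj[j, i] = True
            added += 1


def generate_reference_network(v: int, target_density: float, seed: SeedLike) -> np.ndarray:
    """Modular hub-bearing binary network with an exact edge count.

    Nodes are partitioned into cliques with heavy-tailed sizes (hubs are
    members of large modules), then a sparse node-disjoint set of
    inter-module bridges tops the edge count up to exactly
    round(density * v(v-1)/2).  Deterministic for a given seed.
    """
    if v < 4:
        raise ValueError("need at least 4 nodes")
    if not 0 < target_density <= 1.0:
        raise ValueError("target_density must lie in (0, 1]")
    n_edges = edge_count_for_density(v, target_density)
    if n_edges < 1:
        raise ValueError("density implies fewer than 1 edge")
    rng = _rng(seed)
    sizes = _module_sizes(v, n_edges, rng)
    adj = np.zeros((v, v), dtype=bool)
    nodes = rng.permutation(v)
    pos = 0
    for c in sizes:
        mem = nodes[pos : pos + c]
        pos += c
        adj[np.ix_(mem, mem)] = True
    np.fill_diagonal(adj, False)
    need = n_edges - int(adj.sum()) // 2
    if need > 0:
        _add_bridges(adj, need, rng)
    elif need < 0:  # ultra-sparse degenerate case: trim random intra edges
        iu, ju = np.triu_indices(v, k=1)
        present = np.flatnonzero(adj[iu, ju])
        drop = rng.choice(present, size=-need, replace=False)
        adj[iu[drop], ju[drop]] = adj[ju[drop], iu[drop]] = False
    return adj


def disrupt_network_metrics(
    reference_nodal: np.ndarray, kappa: float, noise_sd: float, seed: SeedLike
) -> np.ndarray:
    """Tilt a nodal profile about its mean so its disruption slope is kappa.

    ind_i = mean(ref) + (1 + kappa) * (ref_i - mean(ref)) + eps_i, so the
    OLS slope of (ind - ref) on ref has expectation exactly kappa.
    """
    if not -1 < kappa < 1:
        raise ValueError("kappa must lie in (-1, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ref = np.asarray(reference_nodal, dtype=float)
    out = ref.mean() + (1.0 + kappa) * (ref - ref.mean())
    if noise_sd > 0:
        out = out + _rng(seed).normal(0.0, noise_sd, size=ref.shape)
    return out


def covariance_from_network(
    adjacency: np.ndarray, edge_weight: float, diagonal_load: float
) -> np.ndarray:
    """Sigma = diagonal_load * I + edge_weight * A, verified positive definite."""
    if edge_weight <= 0:
        raise ValueError("edge_weight must be positive")
    a = np.asarray(adjacency, dtype=float)
    cov = diagonal_load * np.eye(a.shape[0]) + edge_weight * a
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min <= 0:
        raise ValueError(
            f"covariance is not positive definite (min eigenvalue {lam_min:.4g}); "
            "increase diagonal_load or decrease edge_weight"
        )
    return cov


def default_grid_coords(v: int) -> np.ndarray:
    """Compact near-cubic integer grid layout for v voxels."""
    side = int(np.ceil(v ** (1.0 / 3.0)))
    grid = np.stack(
        np.meshgrid(np.arange(side), np.arange(side), np.arange(side), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    return grid[:v]


def sample_bold(
    covariance: np.ndarray,
    n_volumes: int,
    tr: float,
    seed: SeedLike,
    voxel_coords: np.ndarray | None = None,
    voxel_size: float = 6.0,
    ar1: float = 0.0,
    mean: float = 1000.0,
) -> BoldSeries:
    """Gaussian BOLD-like series with the given spatial covariance.

    Volumes are i.i.d. by default (the correlation/thresholding logic under
    test does not depend on hemodynamics); ``ar1`` adds optional AR(1)
    temporal smoothing that preserves the spatial correlation structure.
    """
    if n_volumes < 10:
        raise ValueError("need at least 10 volumes")
    cov = np.asarray(covariance, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc
    rng = _rng(seed)
    innov = rng.standard_normal((cov.shape[0], n_volumes))
    if ar1:
        if not -1 < ar1 < 1:
            raise ValueError("ar1 must lie in (-1, 1)")
        scale = np.sqrt(1.0 - ar1**2)
        for t in range(1, n_volumes):
            innov[:, t] = ar1 * innov[:, t - 1] + scale * innov[:, t]
    data = mean + chol @ innov
    if voxel_coords is None:
        voxel_coords = default_grid_coords(cov.shape[0])
    return BoldSeries(data, voxel_coords, voxel_size, tr)


def generate_motion(
    n_volumes: int,
    spike_volumes: list[int] | np.ndarray = (),
    spike_mm: float = 0.8,
    seed: SeedLike = 0,
    baseline_fd_mm: float = 0.25,
) -> np.ndarray:
    """T x 6 motion trace (3 translations mm, then 3 rotations rad).

    Baseline jitter is a small random walk rescaled so FD stays strictly
    below 0.5 mm everywhere except at ``spike_volumes`` (0-based, >= 1),
    where a persistent translation step of ``spike_mm`` is planted, making
    FD >= spike_mm exactly there.
    """
    if spike_mm <= 0:
        raise ValueError("spike_mm must be positive")
    spikes = np.asarray(sorted(set(int(s) for s in np.atleast_1d(spike_volumes))), dtype=int)
    if spikes.size and (spikes.min() < 1 or spikes.max() >= n_volumes):
        raise ValueError(
            "spike volumes must lie in [1, T-1]; FD is undefined at the first volume"
        )
    rng = _rng(seed)
    steps = np.column_stack(
        [rng.normal(0, 0.02, (n_volumes, 3)), rng.normal(0, 0.0002, (n_volumes, 3))]
    )
    steps[0] = 0.0
    fd_steps = np.abs(steps[:, :3]).sum(axis=1) + 50.0 * np.abs(steps[:, 3:]).sum(axis=1)
    peak = fd_steps.max()
    if peak > 0:
        steps *= baseline_fd_mm / peak
    motion = np.cumsum(steps, axis=0)
    for s in spikes:
        motion[s:, 0] += spike_mm  # persistent step: one large FD, then baseline
    return motion


def _tilted_modular_adjacency(
    reference_degree: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
    n_bridges: int = 0,
) -> np.ndarray:
    """Patient network whose degree profile is the kappa-tilted reference.

    Nodes are re-partitioned into cliques sized by their tilted target
    degrees (clique membership of size c gives degree c - 1): sort nodes by
    target degree, let each unassigned node found a module of its target
    size, and fill it with the next unassigned nodes, whose targets are
    similar by construction.  Preserves the modular (positive-definiteness-
    friendly) structure while planting the disruption slope.
    """
    ref = np.asarray(reference_degree, dtype=float)
    v = len(ref)
    target = np.maximum(
        np.round(disrupt_network_metrics(ref, kappa, 0.0, rng)), 1
    ).astype(int)
    # stable order on shuffled ties: sort a shuffled node list by target
    shuffled = rng.permutation(v)
    order = shuffled[np.argsort(-target[shuffled], kind="stable")]
    adj = np.zeros((v, v), dtype=bool)
    used = np.zeros(v, dtype=bool)
    for n in order:
        if used[n]:
            continue
        size = int(target[n]) + 1
        members = [n]
        used[n] = True
        for m in order:
            if len(members) >= size:
                break
            if not used[m]:
                members.append(m)
                used[m] = True
        mem = np.asarray(members)
        adj[np.ix_(mem, mem)] = True
    np.fill_diagonal(adj, False)
    if n_bridges > 0:
        _add_bridges(adj, n_bridges, rng)
    return adj


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SyntheticSubject], GroundTruth]:
    """Generate the full two-group cohort plus its ground truth.

    Controls sample BOLD from the shared reference covariance; each patient
    from a covariance built on a hub-disrupted adjacency with its own
    planted slope.  One shared global fluctuation (the confound that global-
    signal regression exists to remove) is added on top of every subject's
    network signal.  Baseline motor scores decrease with planted ROI degree
    (logistic squashing into [0, 66]); the recovery ratio increases with it.
    """
    cfg = config or CohortConfig()
    if min(cfg.n_controls, cfg.n_patients) < 3:
        raise ValueError("need at least 3 subjects per group")
    master = np.random.SeedSequence(cfg.seed)
    n_subjects = cfg.n_controls + cfg.n_patients
    streams = master.spawn(3 + n_subjects)
    behavior_stream = streams[-1]

    topo_rng = _rng(streams[0])
    ref_adj = generate_reference_network(cfg.n_voxels, cfg.network_density, topo_rng)
    ref_deg = ref_adj.sum(axis=1).astype(float)
    # spatial layout: hubs are scattered over the grid, not index-adjacent
    coords = default_grid_coords(cfg.n_voxels)[topo_rng.permutation(cfg.n_voxels)]

    demo_rng = _rng(streams[1])
    ages = demo_rng.uniform(45, 80, size=n_subjects)
    genders = demo_rng.permutation(np.arange(n_subjects) % 2)
    spike_subjects = demo_rng.random(n_subjects) < cfg.spike_fraction

    # patient adjacencies first: the safe uniform edge weight depends on the
    # worst minimal eigenvalue across the whole cohort
    patient_adj: list[np.ndarray] = []
    kappas: list[float] = []
    for i in range(cfg.n_patients):
        rng = _rng(streams[2 + cfg.n_controls + i])
        kappa = float(
            np.clip(rng.normal(cfg.kappa_mean, cfg.kappa_sd), *cfg.kappa_clip)
        )
        kappas.append(kappa)
        n_bridges = min(max(1, round(0.02 * int(ref_adj.sum()) // 2)), cfg.n_voxels // 2)
        patient_adj.append(
            _tilted_modular_adjacency(ref_deg, kappa, rng, n_bridges=n_bridges)
        )
    if cfg.edge_weight is None:
        lam = max(
            abs(float(np.linalg.eigvalsh(a.astype(float))[0]))
            for a in [ref_adj, *patient_adj]
        )
        edge_weight = 0.9 * cfg.diagonal_load / lam
    else:
        edge_weight = cfg.edge_weight
    ref_cov = covariance_from_network(ref_adj, edge_weight, cfg.diagonal_load)

    # ROI: the highest-degree (hub) voxels
    roi_ids = np.argsort(-ref_deg, kind="stable")[: cfg.roi_size]

    subjects: list[SyntheticSubject] = []
    kappa_true: dict[str, float] = {}
    spike_log: dict[str, list[int]] = {}
    roi_degree: dict[str, float] = {}

    for i in range(n_subjects):
        is_control = i < cfg.n_controls
        idx = i if is_control else i - cfg.n_controls
        sid = f"{'hc' if is_control else 'pt'}{idx:03d}"
        rng = _rng(streams[2 + i])
        if is_control:
            cov = ref_cov
        else:
            adj = patient_adj[idx]
            cov = covariance_from_network(adj, edge_weight, cfg.diagonal_load)
            kappa_true[sid] = kappas[idx]
            roi_degree[sid] = float(adj[roi_ids].sum())
        bold = sample_bold(
            cov, cfg.n_volumes, cfg.tr, rng, voxel_coords=coords, voxel_size=cfg.voxel_size
        )
        if cfg.global_artifact_sd > 0:
            bold.data += cfg.global_artifact_sd * rng.standard_normal(cfg.n_volumes)[None, :]
        if spike_subjects[i]:
            spikes = sorted(
                rng.choice(np.arange(10, cfg.n_volumes - 5), 2, replace=False).tolist()
            )
        else:
            spikes = []
        spike_log[sid] = [int(s) for s in spikes]
        motion = generate_motion(cfg.n_volumes, spikes, cfg.spike_mm, rng)
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                bold=bold,
                motion=motion,
                age=float(ages[i]),
                gender=int(genders[i]),
                group="HC" if is_control else "patient",
                side="none" if is_control else "right",
            )
        )

    # behavioral coupling to planted ROI degree (patients only)
    pt_ids = [s.subject_id for s in subjects if s.group == "patient"]
    deg = np.array([roi_degree[sid] for sid in pt_ids])
    z = (deg - deg.mean()) / (deg.std() if deg.std() > 0 else 1.0)
    beh_rng = _rng(behavior_stream)
    base_latent = -cfg.baseline_coupling * z + cfg.baseline_noise * beh_rng.standard_normal(len(z))
    baseline = FMA_MAX * _sigmoid(base_latent - 0.2)
    recovery = np.clip(
        cfg.recovery_coupling * z
        + 0.45
        + cfg.recovery_noise * beh_rng.standard_normal(len(z)),
        -0.5,
        None,
    )
    followup = np.clip(baseline * (1.0 + recovery), 0.0, FMA_MAX)
    for sid, b, f in zip(pt_ids, baseline, followup):
        subj = next(s for s in subjects if s.subject_id == sid)
        subj.fma_baseline = float(np.clip(b, 1.0, FMA_MAX))
        subj.fma_followup = float(f)

    truth = GroundTruth(
        reference_adjacency=ref_adj,
        reference_covariance=ref_cov,
        kappa_true=kappa_true,
        roi_voxel_ids=np.asarray(roi_ids),
        behavior_coupling={
            "baseline": -cfg.baseline_coupling,
            "recovery": cfg.recovery_coupling,
        },
        spike_volumes=spike_log,
        seed=cfg.seed,
        edge_weight=edge_weight,
        planted_roi_degree=dict(roi_degree),
    )
    return subjects, truth
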