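"""Group-comparison and brain-behavior association statistics.

Covers the full inferential surface of the pipeline: the motor recovery
ratio, demographic-table tests (Welch t from summaries, 2x2 chi-squared),
the repeated-measures group test on hub-disruption profiles, covariate-
adjusted Spearman correlation, voxel-wise permutation GLM with TFCE
enhancement and max-statistic family-wise error correction, Bonferroni
thresholding, and cluster extraction.

Permutation scheme: Freedman-Lane.  The maps are residualized on the
nuisance columns of the design (intercept + covariates); the residual rows
are permuted, the nuisance fit added back, and the full-model t and TFCE
statistics recomputed.  p_fwe(v) = (1 + #{perm max >= observed}) /
(n_perm + 1), separately for each contrast direction.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from ._tfce_core import grid_neighbor_csr, tfce_from_values
from .types import StatMap

__all__ = [
    "rfma_ratio",
    "welch_t_from_summary",
    "chi_square_2x2",
    "rm_ancova_group",
    "partial_spearman",
    "bonferroni_threshold",
    "glm_tstat_map",
    "tfce_transform",
    "permutation_fwe",
    "extract_clusters",
]

TFCE_E = 0.5
TFCE_H = 2.0
TFCE_STEPS = 100


def rfma_ratio(baseline: float, followup: float) -> float:
    """Motor recovery ratio: (follow-up - baseline) / baseline.

    Positive means improvement, negative deterioration; undefined at a zero
    baseline.
    """
    if baseline <= 0:
        raise ValueError("recovery ratio is undefined for baseline <= 0")
    return (followup - baseline) / baseline


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t-test from summary statistics.

    Returns (t, Satterthwaite df, two-tailed p).
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if min(sd1, sd2) <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df = 1, no continuity correction."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if n == 0 or 0 in margins:
        raise ValueError("chi-squared is undefined when a margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def rm_ancova_group(
    kd: np.ndarray, group: np.ndarray, age: np.ndarray, gender: np.ndarray
) -> tuple[float, tuple[int, int], float]:
    """Group effect of a repeated-measures ANCOVA over link densities.

    The between-subject group effect of the classical split-plot model is
    exactly the one-way ANCOVA on each subject's density-mean score, so the
    test runs a GLM of mean(kd over densities) on [group, age, gender] and
    reports the group F with (1, N - 4) degrees of freedom.  This is
    sphericity-free because only the between-subject stratum is tested.
    """
    import statsmodels.api as sm

    kd = np.atleast_2d(np.asarray(kd, dtype=float))
    y = kd.mean(axis=1)
    g = np.asarray(group, dtype=float)
    for lab in np.unique(g):
        if (g == lab).sum() < 3:
            raise ValueError("need at least 3 subjects per group")
    x = sm.add_constant(np.column_stack([g, np.asarray(age, float), np.asarray(gender, float)]))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates?)")
    fit = sm.OLS(y, x).fit()
    t_group = fit.tvalues[1]
    f = float(t_group**2)
    df = (1, int(fit.df_resid))
    return f, df, float(stats.f.sf(f, *df))


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Spearman correlation of x and y adjusted for covariates.

    Both variables are rank-transformed, residualized on [intercept,
    covariates], and the Pearson correlation of the residuals is returned
    with the t-approximation p-value on n - 2 - k degrees of freedom.  With
    no covariates this reduces exactly to the plain Spearman coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5 or len(y) != n:
        raise ValueError("need equal-length x and y with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("missing values are not supported")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if covariates is None:
        z = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        z = np.column_stack([np.ones(n), cov])
        k = cov.shape[1]
    proj = z @ np.linalg.pinv(z)
    ex = rx - proj @ rx
    ey = ry - proj @ ry
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0:
        raise ValueError("residual variance is zero after covariate adjustment")
    rho = float(ex @ ey / denom)
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * math.sqrt(df / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), df))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _glm_prepare(design: np.ndarray, contrast: np.ndarray):
    x = np.atleast_2d(np.asarray(design, dtype=float))
    c = np.asarray(contrast, dtype=float)
    if c.shape != (x.shape[1],):
        raise ValueError("contrast length must equal the number of design columns")
    if x.shape[0] <= np.linalg.matrix_rank(x):
        raise ValueError("need more subjects than design rank")
    pinv = np.linalg.pinv(x)
    xtx_inv = pinv @ pinv.T
    cvar = float(c @ xtx_inv @ c)
    dof = x.shape[0] - np.linalg.matrix_rank(x)
    return x, c, pinv, cvar, dof


def glm_tstat_map(
    maps: np.ndarray, design: np.ndarray, contrast: np.ndarray
) -> np.ndarray:
    """Per-voxel OLS t statistic for one contrast.

    ``maps`` is subjects x voxels; the design typically holds [intercept,
    group, age, gender].  Voxels with zero residual variance but a nonzero
    effect saturate to +/- inf.
    """
    y = np.atleast_2d(np.asarray(maps, dtype=float))
    x, c, pinv, cvar, dof = _glm_prepare(design, contrast)
    if y.shape[0] != x.shape[0]:
        raise ValueError("maps and design row counts differ")
    beta = pinv @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    effect = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(sigma2 * cvar)
    t[np.isnan(t)] = 0.0  # 0/0: no effect, no variance
    return t


def tfce_transform(
    stat_map: np.ndarray,
    e_power: float = TFCE_E,
    h_power: float = TFCE_H,
    dh: float | None = None,
    connectivity: int = 26,
    n_steps: int = TFCE_STEPS,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D statistic map.

    Sums e(h, v)^E * h^H * dh over thresholds h = dh, 2dh, ... for the
    positive values; negative values are enhanced by transforming the
    negated map, and the output carries their sign.  ``dh`` defaults to
    max|stat| / n_steps per tail.
    """
    arr = np.asarray(stat_map, dtype=float)
    if arr.ndim != 3:
        raise ValueError("stat_map must be a 3-D grid")
    coords = np.argwhere(np.ones(arr.shape, dtype=bool))
    flat, ptr = grid_neighbor_csr(coords, arr.shape, connectivity)
    vals = arr.reshape(-1)
    pos = tfce_from_values(np.maximum(vals, 0.0), flat, ptr, dh, n_steps, e_power, h_power)
    neg = tfce_from_values(np.maximum(-vals, 0.0), flat, ptr, dh, n_steps, e_power, h_power)
    return (pos - neg).reshape(arr.shape)


def _all_row_permutations(n: int) -> np.ndarray:
    return np.array(list(_iter_permutations(range(n))), dtype=np.intp)


def permutation_fwe(
    maps: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, int, int],
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    e_power: float = TFCE_E,
    h_power: float = TFCE_H,
    connectivity: int = 26,
    n_steps: int = TFCE_STEPS,
) -> dict[str, StatMap]:
    """Permutation GLM with TFCE and max-statistic FWE correction.

    Returns StatMaps for both contrast directions, keyed ``"pos"`` (contrast
    > 0) and ``"neg"``.  ``coords`` places the V voxels of ``maps`` on the
    ``shape`` grid for the connected-component step.
    """
    y = np.atleast_2d(np.asarray(maps, dtype=float))
    n, v = y.shape
    x, c, pinv, cvar, dof = _glm_prepare(design, contrast)
    if len(coords) != v:
        raise ValueError("coords must list one grid position per voxel")
    flat, ptr = grid_neighbor_csr(np.asarray(coords), shape, connectivity)

    # Freedman-Lane: residualize on the nuisance partition (contrast == 0 cols)
    nuisance = x[:, np.asarray(contrast, dtype=float) == 0]
    hz = nuisance @ np.linalg.pinv(nuisance) if nuisance.size else np.zeros((n, n))
    fitted_z = hz @ y
    resid_z = y - fitted_z

    def _t_of(data: np.ndarray) -> np.ndarray:
        beta = pinv @ data
        resid = data - x @ beta
        sigma2 = (resid**2).sum(axis=0) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (c @ beta) / np.sqrt(sigma2 * cvar)
        t[~np.isfinite(t)] = 0.0
        return t

    def _enhance(t: np.ndarray, sign: float) -> np.ndarray:
        return tfce_from_values(
            np.maximum(sign * t, 0.0), flat, ptr, None, n_steps, e_power, h_power
        )

    t_obs = _t_of(y)
    tfce_pos = _enhance(t_obs, +1.0)
    tfce_neg = _enhance(t_obs, -1.0)

    n_distinct = math.factorial(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct relabelings exist; enumerating exhaustively",
            RuntimeWarning,
        )
        perms = _all_row_permutations(n)
    else:
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    max_pos = np.empty(len(perms))
    max_neg = np.empty(len(perms))
    for i, perm in enumerate(perms):
        t_p = _t_of(fitted_z + resid_z[perm])
        max_pos[i] = _enhance(t_p, +1.0).max(initial=0.0)
        max_neg[i] = _enhance(t_p, -1.0).max(initial=0.0)

    n_used = len(perms)
    p_pos = (1.0 + (max_pos[None, :] >= tfce_pos[:, None]).sum(axis=1)) / (n_used + 1.0)
    p_neg = (1.0 + (max_neg[None, :] >= tfce_neg[:, None]).sum(axis=1)) / (n_used + 1.0)
    return {
        "pos": StatMap(t_obs, tfce_pos, p_pos, "A>B", n_used),
        "neg": StatMap(-t_obs, tfce_neg, p_neg, "A<B", n_used),
    }


def extract_clusters(
    stat: np.ndarray,
    p_fwe: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, int, int],
    alpha: float = 0.05,
    connectivity: int = 26,
    voxel_size: float = 6.0,
) -> pd.DataFrame:
    """Connected components of {p_fwe < alpha} with peak and size bookkeeping.

    Returns one row per cluster: peak grid coordinate, size in voxels and
    mm^3 (voxels x voxel_size^3), peak statistic, and the smallest corrected
    p in the cluster.  An empty table is a legitimate outcome.
    """
    from scipy import ndimage

    stat = np.asarray(stat, dtype=float)
    p_fwe = np.asarray(p_fwe, dtype=float)
    coords = np.asarray(coords, dtype=int)
    sig = p_fwe < alpha
    columns = ["cluster_id", "peak_x", "peak_y", "peak_z", "n_voxels", "volume_mm3", "peak_stat", "min_p_fwe"]
    if not sig.any():
        return pd.DataFrame(columns=columns)
    grid = np.zeros(shape, dtype=bool)
    grid[tuple(coords[sig].T)] = True
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    structure = ndimage.generate_binary_structure(3, order)
    labels, n_clusters = ndimage.label(grid, structure=structure)
    voxel_labels = labels[tuple(coords.T)]
    rows = []
    for cid in range(1, n_clusters + 1):
        members = np.flatnonzero(voxel_labels == cid)
        peak = members[np.argmax(np.abs(stat[members]))]
        rows.append(
            {
                "cluster_id": cid,
                "peak_x": coords[peak, 0],
                "peak_y": coords[peak, 1],
                "peak_z": coords[peak, 2],
                "n_voxels": len(members),
                "volume_mm3": len(members) * voxel_size**3,
                "peak_stat": stat[peak],
                "min_p_fwe": p_fwe[members].min(),
            }
        )
    return pd.DataFrame(rows, columns=columns)
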