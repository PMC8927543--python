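"""Scrubbing-based cleaning of voxel x time BOLD matrices.

The cleaning stages, in their fixed order:

1. discard the first 4 volumes (T1-equilibration),
2. grand-mean intensity scaling (global 4-D mean -> 10,000),
3. high-pass filtering at 0.008 Hz (slow scanner drift),
4. nuisance regression (6 motion traces + CSF + WM + global signal),
5. spike detection: FD > 0.5 mm, or z-normalized DVARS or per-volume SD
   > 2.3, each flagged volume expanded to {i-2 .. i+2},
6. band-pass 0.008-0.1 Hz (4th-order Butterworth, zero-phase) applied on a
   temporally uniform grid in which censored volumes are bridged by linear
   interpolation,
7. deletion of the censored volumes.

Subjects retaining fewer than 120 volumes fail quality control (about five
minutes of usable data at TR = 2.5 s).

Motion trace convention: columns 0-2 are translations in mm (x, y, z),
columns 3-5 rotations in radians (pitch, yaw, roll).  FD sums the absolute
backward differences of the translations plus 50 x those of the rotations
(a 50 mm head radius converts radians to mm of scalp motion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import BoldSeries, CensorRecord, NuisanceSet

__all__ = [
    "discard_initial",
    "grand_mean_scale",
    "compute_fd",
    "compute_dvars",
    "compute_sd_series",
    "build_censor_mask",
    "regress_nuisance",
    "temporal_filter",
    "interpolate_censored",
    "apply_scrubbing",
    "qc_check",
    "downsample_volume",
    "downsample_grid",
    "clean_bold",
]

FD_THRESHOLD_MM = 0.5
Z_THRESHOLD = 2.3
ROTATION_SCALE_MM = 50.0
CENSOR_HALO = 2  # volumes censored on each side of a detected spike
MIN_RETAINED_VOLUMES = 120
GRAND_MEAN_TARGET = 10_000.0


def discard_initial(bold: BoldSeries, n: int = 4) -> BoldSeries:
    """Drop the first ``n`` volumes (scanner equilibration)."""
    if bold.n_volumes <= n:
        raise ValueError(f"cannot discard {n} volumes from a series of {bold.n_volumes}")
    return BoldSeries(bold.data[:, n:], bold.voxel_coords, bold.voxel_size, bold.tr)


def grand_mean_scale(data: np.ndarray, target: float = GRAND_MEAN_TARGET) -> np.ndarray:
    """Scale the whole matrix so its global mean equals ``target``."""
    m = float(np.mean(data))
    if m == 0:
        raise ValueError("cannot grand-mean scale data with zero global mean")
    return np.asarray(data, dtype=float) * (target / m)


def compute_fd(motion: np.ndarray, rotation_scale: float = ROTATION_SCALE_MM) -> np.ndarray:
    """Framewise displacement in mm; FD at the first volume is 0 by convention.

    FD_t = sum |delta translations| + rotation_scale * sum |delta rotations|.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValueError("motion must be a T x 6 matrix with T >= 2")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion trace contains non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + rotation_scale * d[:, 3:].sum(axis=1)
    return fd


def _z_excluding_first(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """z-normalize using mean/sd over t >= 1 (the first volume is a placeholder)."""
    body = raw[1:]
    sd = body.std()
    if sd <= 1e-10 * max(abs(float(body.mean())), 1.0):  # constant up to rounding
        return np.zeros_like(raw), True
    return (raw - body.mean()) / sd, False


def compute_dvars(
    data: np.ndarray, gm_mask: np.ndarray | None = None, normalize: bool = True
) -> np.ndarray:
    """RMS of the backward temporal difference over gray-matter voxels.

    The first volume has no backward difference and is set to 0.  With
    ``normalize`` the series is z-scored using moments over t >= 1; a
    constant series (sd 0) returns zeros with a warning.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("DVARS needs at least 2 volumes")
    masked = data if gm_mask is None else data[np.asarray(gm_mask, dtype=bool)]
    if masked.shape[0] == 0:
        raise ValueError("gray-matter mask is empty")
    raw = np.zeros(data.shape[1])
    raw[1:] = np.sqrt(np.mean(np.diff(masked, axis=1) ** 2, axis=0))
    if not normalize:
        return raw
    z, degenerate = _z_excluding_first(raw)
    if degenerate:
        warnings.warn("DVARS series is constant; z-scores set to 0", RuntimeWarning)
    return z


def compute_sd_series(
    data: np.ndarray, gm_mask: np.ndarray | None = None, normalize: bool = True
) -> np.ndarray:
    """Per-volume standard deviation of intensity over gray-matter voxels."""
    data = np.asarray(data, dtype=float)
    masked = data if gm_mask is None else data[np.asarray(gm_mask, dtype=bool)]
    if masked.shape[0] == 0:
        raise ValueError("gray-matter mask is empty")
    raw = masked.std(axis=0)
    if not normalize:
        return raw
    z, degenerate = _z_excluding_first(raw)
    if degenerate:
        warnings.warn("SD series is constant; z-scores set to 0", RuntimeWarning)
    return z


def build_censor_mask(
    fd: np.ndarray,
    dvars_z: np.ndarray,
    sd_z: np.ndarray,
    fd_thr: float = FD_THRESHOLD_MM,
    z_thr: float = Z_THRESHOLD,
    halo: int = CENSOR_HALO,
) -> np.ndarray:
    """Censor mask: any-criterion spikes expanded to {i-halo .. i+halo}.

    A volume is detected when FD > fd_thr, or z-DVARS > z_thr, or z-SD >
    z_thr; the censored set is the union of the +/- halo neighborhoods of
    all detected volumes, clipped to the series.
    """
    fd = np.asarray(fd, dtype=float)
    dvars_z = np.asarray(dvars_z, dtype=float)
    sd_z = np.asarray(sd_z, dtype=float)
    if not (len(fd) == len(dvars_z) == len(sd_z)):
        raise ValueError("fd, dvars_z and sd_z must have equal length")
    detected = (fd > fd_thr) | (dvars_z > z_thr) | (sd_z > z_thr)
    censored = np.zeros(len(fd), dtype=bool)
    for i in np.flatnonzero(detected):
        censored[max(0, i - halo) : i + halo + 1] = True
    return censored


def regress_nuisance(data: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Residualize every voxel on [intercept, 6 motion, CSF, WM, global].

    Ordinary least squares via the pseudo-inverse, so collinear regressors
    (warned about) are handled gracefully.
    """
    data = np.asarray(data, dtype=float)
    t = data.shape[1]
    x = np.column_stack([np.ones(t), nuisance.design()])
    if x.shape[0] != t:
        raise ValueError("nuisance regressors must match the number of volumes")
    if not np.all(np.isfinite(x)):
        raise ValueError("nuisance regressors contain non-finite values")
    if t <= 10:
        raise ValueError("nuisance regression needs more than 10 volumes")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("nuisance design is rank deficient; using pseudo-inverse", RuntimeWarning)
    beta = np.linalg.pinv(x) @ data.T
    return data - (x @ beta).T


def temporal_filter(
    data: np.ndarray,
    tr: float,
    low: float = 0.008,
    high: float | None = 0.1,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth filter along time.

    Band-pass between ``low`` and ``high`` Hz by default; ``high=None``
    gives the high-pass-only mode used before nuisance regression.
    Forward-backward application (filtfilt) doubles the effective order but
    keeps correlations free of phase distortion.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if tr <= 0:
        raise ValueError("tr must be positive")
    nyquist = 0.5 / tr
    if not 0 < low < nyquist:
        raise ValueError(f"low edge {low} Hz outside (0, {nyquist}) Hz")
    if high is None:
        sos = signal.butter(order, low, btype="highpass", fs=1.0 / tr, output="sos")
    else:
        if not low < high < nyquist:
            raise ValueError(f"high edge {high} Hz outside ({low}, {nyquist}) Hz")
        sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    padlen = min(data.shape[1] - 1, 3 * (2 * order + 1))
    return signal.sosfiltfilt(sos, data, axis=1, padlen=padlen)


def interpolate_censored(data: np.ndarray, censored: np.ndarray) -> np.ndarray:
    """Bridge censored volumes by per-voxel linear interpolation.

    Restores a temporally uniform grid so a frequency-domain filter retains
    its meaning; edge censored volumes are held at the nearest retained
    value.
    """
    censored = np.asarray(censored, dtype=bool)
    keep = ~censored
    if keep.sum() < 2:
        raise ValueError("need at least 2 retained volumes to interpolate")
    if not censored.any():
        return np.asarray(data, dtype=float).copy()
    t = np.arange(len(censored))
    out = np.asarray(data, dtype=float).copy()
    out[:, censored] = np.vstack(
        [np.interp(t[censored], t[keep], row[keep]) for row in out]
    )
    return out


def apply_scrubbing(data: np.ndarray, censored: np.ndarray) -> np.ndarray:
    """Delete censored columns, preserving the order of retained volumes."""
    censored = np.asarray(censored, dtype=bool)
    data = np.asarray(data)
    if data.shape[1] != len(censored):
        raise ValueError("censor mask length must equal the number of volumes")
    if (~censored).sum() < 2:
        raise ValueError("scrubbing would leave fewer than 2 volumes")
    return data[:, ~censored]


def qc_check(n_retained: int, minimum: int = MIN_RETAINED_VOLUMES) -> bool:
    """Retention rule: a subject passes iff >= ``minimum`` volumes survive."""
    if n_retained < 0:
        raise ValueError("n_retained cannot be negative")
    return n_retained >= minimum


def downsample_volume(data4d: np.ndarray, factor: int = 3) -> np.ndarray:
    """Block-mean downsampling of an X x Y x Z x T array by ``factor`` per axis.

    Trailing planes that do not fill a complete block are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return np.asarray(data4d, dtype=float).copy()
    d = np.asarray(data4d, dtype=float)
    nx, ny, nz = (s // factor for s in d.shape[:3])
    if min(nx, ny, nz) < 1:
        raise ValueError("grid smaller than one block")
    d = d[: nx * factor, : ny * factor, : nz * factor]
    d = d.reshape(nx, factor, ny, factor, nz, factor, -1)
    return d.mean(axis=(1, 3, 5))


def downsample_grid(bold: BoldSeries, factor: int = 3) -> BoldSeries:
    """Block-mean aggregation of a BoldSeries onto a coarser grid.

    Voxels whose coordinates fall in the same factor^3 block are averaged;
    the new coordinate is the block index and the voxel size grows by
    ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return BoldSeries(bold.data.copy(), bold.voxel_coords.copy(), bold.voxel_size, bold.tr)
    blocks = bold.voxel_coords // factor
    uniq, inverse = np.unique(blocks, axis=0, return_inverse=True)
    data = np.zeros((len(uniq), bold.n_volumes))
    np.add.at(data, inverse, bold.data)
    counts = np.bincount(inverse, minlength=len(uniq)).astype(float)
    data /= counts[:, None]
    return BoldSeries(data, uniq, bold.voxel_size * factor, bold.tr)


@dataclass
class CleanResult:
    """Cleaned series plus the censoring record and QC verdict."""

    bold: BoldSeries
    censor: CensorRecord
    qc_pass: bool


def clean_bold(
    bold: BoldSeries,
    motion: np.ndarray,
    gm_mask: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    wm: np.ndarray | None = None,
    n_discard: int = 4,
    fd_thr: float = FD_THRESHOLD_MM,
    z_thr: float = Z_THRESHOLD,
) -> CleanResult:
    """Run the full cleaning chain on one subject.

    ``motion`` covers the un-discarded series; its first ``n_discard`` rows
    are dropped alongside the volumes.  CSF/WM regressors default to zeros
    when no masks are available (synthetic data has no ventricles); the
    global signal is always the mean over all voxels.  Spike measures are
    computed on the data entering the censoring step, i.e. after nuisance
    regression.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] != bold.n_volumes:
        raise ValueError("motion trace must have one row per (pre-discard) volume")
    trimmed = discard_initial(bold, n_discard)
    motion = motion[n_discard:]
    t = trimmed.n_volumes

    data = grand_mean_scale(trimmed.data)
    data = temporal_filter(data, trimmed.tr, low=0.008, high=None)

    zeros = np.zeros(t)
    nuis = NuisanceSet(
        motion=motion,
        csf=zeros if csf is None else np.asarray(csf, dtype=float)[n_discard:],
        wm=zeros if wm is None else np.asarray(wm, dtype=float)[n_discard:],
        global_signal=data.mean(axis=0),
    )
    data = regress_nuisance(data, nuis)

    fd = compute_fd(motion)
    dvars_z = compute_dvars(data, gm_mask)
    sd_z = compute_sd_series(data, gm_mask)
    censored = build_censor_mask(fd, dvars_z, sd_z, fd_thr=fd_thr, z_thr=z_thr)
    record = CensorRecord(fd, dvars_z, sd_z, censored)

    bridged = interpolate_censored(data, censored)
    filtered = temporal_filter(bridged, trimmed.tr, low=0.008, high=0.1)
    final = apply_scrubbing(filtered, censored)

    cleaned = BoldSeries(final, trimmed.voxel_coords, trimmed.voxel_size, trimmed.tr)
    return CleanResult(cleaned, record, qc_check(record.n_retained))
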