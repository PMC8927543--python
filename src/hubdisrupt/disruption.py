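"""The hub-disruption index K_D against a normative reference group.

For one nodal metric at one link density, a subject's K_D is the ordinary
least-squares slope of (individual_i - reference_i) regressed on
reference_i across nodes i, where the reference profile is the voxel-wise
mean over the healthy-control group.  A slope of 0 means the individual
network tracks the normative topology; a negative slope means high-degree
(hub) nodes lost more than peripheral nodes gained, i.e. hub-selective
degradation.

Controls are scored against the leave-one-out reference (excluding the
subject itself); including a subject in its own reference deflates control
slopes toward 0 by construction and would bias group contrasts.  Patients
are scored against the full control mean.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import METRICS

__all__ = ["reference_profile", "kd_slope", "kd_profiles"]


def reference_profile(hc_metric_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Voxel-wise mean metric profile over >= 2 control subjects."""
    vecs = [np.asarray(v, dtype=float) for v in hc_metric_vectors]
    if len(vecs) < 2:
        raise ValueError("a normative reference needs at least 2 control subjects")
    lengths = {len(v) for v in vecs}
    if len(lengths) != 1:
        raise ValueError("control metric vectors must share a common voxel support")
    return np.mean(vecs, axis=0)


def kd_slope(individual: np.ndarray, reference: np.ndarray) -> float:
    """OLS slope (with intercept) of (individual - reference) on reference.

    Equals cov(individual - reference, reference) / var(reference).
    """
    ind = np.asarray(individual, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ind.shape != ref.shape or ind.ndim != 1 or len(ind) < 3:
        raise ValueError("individual and reference must be equal-length vectors, n >= 3")
    ref_c = ref - ref.mean()
    var = float(ref_c @ ref_c)
    if var == 0:
        raise ValueError("reference profile is constant; the slope is undefined")
    diff = ind - ref
    return float(ref_c @ (diff - diff.mean()) / var)


def kd_profiles(
    metric_vectors: Mapping[str, Mapping[str, Mapping[float, np.ndarray]]],
    groups: Mapping[str, str],
    reference_group: str = "HC",
    leave_one_out: bool = True,
) -> pd.DataFrame:
    """Hub-disruption slopes for a whole cohort, long format.

    Parameters
    ----------
    metric_vectors:
        ``metric_vectors[subject][metric][density]`` -> V-vector of the
        nodal metric for that subject at that link density.
    groups:
        subject id -> group label; subjects whose label equals
        ``reference_group`` form the normative set.
    leave_one_out:
        If True (default) each control is regressed against the reference
        built from the *other* controls; patients always use the full
        control mean.

    Returns
    -------
    DataFrame with columns (subject, group, metric, density, kd).
    """
    hc_ids = [s for s in metric_vectors if groups[s] == reference_group]
    if len(hc_ids) < 2:
        raise ValueError(f"need >= 2 subjects in reference group {reference_group!r}")
    # consistency of the metric/density grid
    first = next(iter(metric_vectors.values()))
    densities = {m: sorted(first[m]) for m in first}
    for sid, per_metric in metric_vectors.items():
        for m in densities:
            if sorted(per_metric.get(m, {})) != densities[m]:
                raise ValueError(f"subject {sid!r} is missing densities for metric {m!r}")

    rows = []
    for metric in densities:
        for density in densities[metric]:
            hc_stack = np.stack([np.asarray(metric_vectors[s][metric][density]) for s in hc_ids])
            hc_sum = hc_stack.sum(axis=0)
            full_ref = hc_sum / len(hc_ids)
            for sid, per_metric in metric_vectors.items():
                ind = np.asarray(per_metric[metric][density], dtype=float)
                if groups[sid] == reference_group and leave_one_out:
                    ref = (hc_sum - ind) / (len(hc_ids) - 1)
                else:
                    ref = full_ref
                if np.ptp(ref) < 1e-12:
                    # a flat reference (e.g. all-zero clustering at a very
                    # sparse density) carries no topology to disrupt
                    warnings.warn(
                        f"constant reference profile for {metric} at density "
                        f"{density}; recording kd = 0",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    kd = 0.0
                else:
                    kd = kd_slope(ind, ref)
                rows.append(
                    {
                        "subject": sid,
                        "group": groups[sid],
                        "metric": metric,
                        "density": density,
                        "kd": kd,
                    }
                )
    df = pd.DataFrame(rows)
    order = [m for m in METRICS if m in densities] + [m for m in densities if m not in METRICS]
    df["metric"] = pd.Categorical(df["metric"], categories=order, ordered=True)
    return df.sort_values(["metric", "density", "subject"], ignore_index=True)


def kd_wide(profiles: pd.DataFrame, metric: str) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot long-format profiles to a subject x density matrix for one metric.

    Returns (matrix, group labels aligned to its rows); the shape expected
    by the repeated-measures group test.
    """
    sub = profiles[profiles["metric"] == metric]
    mat = sub.pivot(index="subject", columns="density", values="kd")
    grp = sub.drop_duplicates("subject").set_index("subject")["group"].reindex(mat.index)
    return mat, grp
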