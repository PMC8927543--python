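"""End-to-end orchestration: simulate -> clean -> network -> metrics -> K_D -> stats.

The pipeline is deterministic given the master seed in the configuration;
the JSON report records every tunable setting actually used, plus QC
counts, hub-disruption summaries, the voxel-wise degree comparison, and the
ROI degree-behavior associations.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disruption import kd_profiles, kd_wide
from .graph_metrics import all_nodal_metrics
from .inference import (
    extract_clusters,
    partial_spearman,
    permutation_fwe,
    rfma_ratio,
    rm_ancova_group,
)
from .network import degree_map, network_from_bold, roi_degree_map
from .preprocess import clean_bold
from .synthetic import CohortConfig, GroundTruth, SyntheticSubject, generate_cohort
from .types import METRICS

__all__ = ["RunConfig", "run_pipeline", "preprocess_cohort", "roi_association"]

DEFAULT_DENSITIES = tuple(np.round(np.arange(0.01, 0.105, 0.01), 2))


@dataclass
class RunConfig:
    """Analysis settings for one pipeline run.

    ``n_perm`` defaults to 500 for the desk-scale synthetic run; the
    full-scale convention for the voxel-wise comparison is 5,000.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    exclusion_distance: float = 2.0  # grid units
    fd_threshold: float = 0.5
    z_threshold: float = 2.3
    n_perm: int = 500
    alpha: float = 0.05
    glm_density: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.densities) == 0:
            raise ValueError("at least one link density is required")
        if any(not 0 < d <= 1 for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")
        self.cohort.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        densities = tuple(raw.pop("densities", DEFAULT_DENSITIES))
        return cls(cohort=cohort, densities=densities, **raw)

    def settings(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def preprocess_cohort(
    subjects: list[SyntheticSubject], config: RunConfig
) -> tuple[dict[str, object], dict]:
    """Clean every subject; returns (cleaned by id, QC report)."""
    cleaned = {}
    qc = {"passed": [], "excluded": [], "n_retained": {}}
    for s in subjects:
        gm = np.ones(s.bold.n_voxels, dtype=bool)
        result = clean_bold(
            s.bold,
            s.motion,
            gm_mask=gm,
            fd_thr=config.fd_threshold,
            z_thr=config.z_threshold,
        )
        qc["n_retained"][s.subject_id] = result.censor.n_retained
        if result.qc_pass:
            qc["passed"].append(s.subject_id)
            cleaned[s.subject_id] = result
        else:
            qc["excluded"].append(s.subject_id)
    return cleaned, qc


def _metric_vectors(
    cleaned: dict, config: RunConfig
) -> dict[str, dict[str, dict[float, np.ndarray]]]:
    vectors: dict[str, dict[str, dict[float, np.ndarray]]] = {}
    for sid, result in cleaned.items():
        per_metric: dict[str, dict[float, np.ndarray]] = {m: {} for m in METRICS}
        for d in config.densities:
            net = network_from_bold(result.bold, d)
            metrics = all_nodal_metrics(net.adjacency, density=d)
            for m in METRICS:
                per_metric[m][d] = metrics[m].values
        vectors[sid] = per_metric
    return vectors


def roi_association(
    subjects: list[SyntheticSubject],
    truth: GroundTruth,
    cleaned: dict,
    config: RunConfig,
) -> dict:
    """Spearman association (age/gender-adjusted) of planted-ROI degree with
    the baseline motor score and with the recovery ratio, over patients."""
    patients = [
        s
        for s in subjects
        if s.group == "patient" and s.subject_id in cleaned and s.fma_baseline is not None
    ]
    roi = np.asarray(truth.roi_voxel_ids)
    deg, base, rec, ages, genders = [], [], [], [], []
    for s in patients:
        net = network_from_bold(cleaned[s.subject_id].bold, config.glm_density)
        dm = degree_map(net, config.exclusion_distance)
        deg.append(float(np.mean(dm.values[roi])))
        base.append(s.fma_baseline)
        rec.append(rfma_ratio(s.fma_baseline, s.fma_followup))
        ages.append(s.age)
        genders.append(s.gender)
    if len(patients) < 5:
        return {
            "n_patients": len(patients),
            "rho_baseline": None,
            "p_baseline": None,
            "rho_recovery": None,
            "p_recovery": None,
            "note": "too few patients for a covariate-adjusted rank correlation",
        }
    cov = np.column_stack([ages, genders])
    rho_b, p_b = partial_spearman(np.array(deg), np.array(base), cov)
    rho_r, p_r = partial_spearman(np.array(deg), np.array(rec), cov)
    return {
        "n_patients": len(patients),
        "rho_baseline": rho_b,
        "p_baseline": p_b,
        "rho_recovery": rho_r,
        "p_recovery": p_r,
    }


def run_roi_association(config: RunConfig | None = None) -> dict:
    """Reduced end-to-end run: generate the cohort, clean the patients, and
    compute the ROI degree-behavior associations only (no K_D, no GLM)."""
    config = config or RunConfig()
    subjects, truth = generate_cohort(config.cohort)
    patients = [s for s in subjects if s.group == "patient"]
    cleaned = {}
    for s in patients:
        result = clean_bold(
            s.bold,
            s.motion,
            gm_mask=np.ones(s.bold.n_voxels, dtype=bool),
            fd_thr=config.fd_threshold,
            z_thr=config.z_threshold,
        )
        if result.qc_pass:
            cleaned[s.subject_id] = result
    return roi_association(subjects, truth, cleaned, config)


def run_pipeline(config: RunConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic study and return the machine-readable report."""
    config = config or RunConfig()
    subjects, truth = generate_cohort(config.cohort)
    cleaned, qc = preprocess_cohort(subjects, config)
    groups = {s.subject_id: s.group for s in subjects}
    demo = {s.subject_id: (s.age, s.gender) for s in subjects}

    vectors = _metric_vectors(cleaned, config)
    profiles = kd_profiles(vectors, {sid: groups[sid] for sid in vectors})

    kd_report = {}
    for metric in METRICS:
        mat, grp = kd_wide(profiles, metric)
        labels = (grp == "patient").astype(int).to_numpy()
        ages = np.array([demo[s][0] for s in mat.index])
        genders = np.array([demo[s][1] for s in mat.index])
        f, df, p = rm_ancova_group(mat.to_numpy(), labels, ages, genders)
        kd_report[metric] = {
            "group_F": f,
            "df": list(df),
            "p": p,
            "mean_kd_patient": float(mat.to_numpy()[labels == 1].mean()),
            "mean_kd_hc": float(mat.to_numpy()[labels == 0].mean()),
        }

    # voxel-wise degree comparison at the GLM density
    ids = sorted(vectors)
    maps, design_rows = [], []
    coords = None
    for sid in ids:
        net = network_from_bold(cleaned[sid].bold, config.glm_density)
        dm = degree_map(net, config.exclusion_distance)
        maps.append(dm.values)
        coords = dm.voxel_coords
        design_rows.append([1.0, float(groups[sid] == "patient"), demo[sid][0], demo[sid][1]])
    maps_arr = np.asarray(maps)
    design = np.asarray(design_rows)
    shape = tuple(np.asarray(coords).max(axis=0) + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat_maps = permutation_fwe(
            maps_arr,
            design,
            np.array([0.0, 1.0, 0.0, 0.0]),
            coords,
            shape,
            n_perm=config.n_perm,
            seed=np.random.default_rng(config.seed + 1),
        )
    clusters = {
        direction: extract_clusters(
            sm.stat, sm.p_fwe, coords, shape, alpha=config.alpha,
            voxel_size=config.cohort.voxel_size,
        )
        for direction, sm in stat_maps.items()
    }

    association = roi_association(subjects, truth, cleaned, config)

    report = {
        "settings": config.settings(),
        "qc": qc,
        "kd": kd_report,
        "degree_glm": {
            direction: tab.to_dict(orient="records") for direction, tab in clusters.items()
        },
        "roi_association": association,
        "ground_truth": {
            "kappa_mean_planted": config.cohort.kappa_mean,
            "roi_voxel_ids": np.asarray(truth.roi_voxel_ids).tolist(),
            "behavior_coupling": truth.behavior_coupling,
        },
    }

    if out_dir is not None:
        from .io import subjects_to_phenotype, write_json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(report, out / "report.json")
        subjects_to_phenotype(subjects).to_csv(out / "phenotype.csv", index=False)
        profiles.to_csv(out / "kd_profiles.csv", index=False)
        truth.to_json(out / "ground_truth.json")
    return report
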