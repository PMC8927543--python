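# hubdisrupt

Voxel-wise graph analysis of resting-state fMRI functional connectivity for
studies of brain-network disruption — built around the questions a stroke
connectomics study asks: *has the whole-brain network topology of a patient
group degraded relative to healthy controls, and does local connectivity in
a specific region track motor impairment and its recovery?*

The package implements the full analysis chain as a tested library plus a
thin CLI:

1. **Scrubbing-based preprocessing** of voxel × time BOLD matrices: initial
   volume discard, grand-mean scaling, high-pass (0.008 Hz), nuisance
   regression (6 motion parameters, CSF, WM, global signal), motion/intensity
   spike censoring (FD > 0.5 mm, z-DVARS > 2.3, z-SD > 2.3, each spike
   expanded to its ±2-volume neighborhood), zero-phase 4th-order Butterworth
   band-pass 0.008–0.1 Hz, and a quality-control rule excluding subjects
   with fewer than 120 retained volumes.
2. **Binary functional networks at fixed link densities** (1–10%): pairwise
   Pearson correlation, Fisher z, and retention of the strongest
   L = round(d·V(V−1)/2) links, plus whole-brain and ROI-seeded degree maps
   with short-distance (≤ 2 voxel) edge exclusion.
3. **Five nodal graph metrics**: degree (D), betweenness centrality (BC),
   clustering coefficient (CC), nodal efficiency (E), and participation
   coefficient (PC).
4. **The hub-disruption index** K_D: for each metric and density, the OLS
   slope of (individual − reference) against the reference profile, where
   the reference is the voxel-wise control-group mean (leave-one-out for
   controls themselves). K_D = 0 means normative topology; K_D < 0 means
   hubs lost more than peripheral nodes gained.
5. **Inference**: repeated-measures group ANCOVA on K_D profiles (age and
   gender as covariates), covariate-adjusted Spearman correlation,
   voxel-wise permutation GLM (Freedman–Lane) with threshold-free cluster
   enhancement (TFCE) and max-statistic family-wise error correction,
   Bonferroni thresholds, and the motor recovery ratio
   rFMA = (follow-up − baseline)/baseline for the 0–66 upper-extremity
   motor scale.
6. **A synthetic cohort generator** with planted ground truth — a modular
   hub-bearing reference network, patients whose networks are tilted copies
   with known disruption slope κ, motion traces with planted spikes, and
   behavior scores coupled (negatively at baseline, positively for
   recovery) to the degree of a designated hub ROI — so every stage of the
   pipeline can be validated end to end.

## The central statistic

For nodal metric values `ind_i` of one subject and the normative reference
profile `ref_i` (control-group mean at the same link density), the
hub-disruption index is the slope of the affine regression

    ind_i − ref_i  =  a + K_D · ref_i + ε_i ,

equivalently K_D = cov(ind − ref, ref) / var(ref). Hub-selective
degradation pushes the points with large `ref_i` down, producing K_D < 0.

## Worked example

```python
import warnings
from hubdisrupt.pipeline import RunConfig, run_pipeline

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_pipeline(RunConfig(seed=1))

for metric, row in report["kd"].items():
    print(f"K_D_{metric}: F={row['group_F']:.2f} p={row['p']:.2g} "
          f"patients={row['mean_kd_patient']:.3f} controls={row['mean_kd_hc']:.3f}")
print(report["roi_association"])
```

prints (synthetic cohort of 32 controls and 28 patients, 150 gray-matter
voxels, 230 volumes at TR 2.5 s, planted mean disruption κ = −0.3):

```
K_D_D: F=61.95 p=1.3e-10 patients=-0.440 controls=-0.065
K_D_BC: F=369.70 p=2.5e-26 patients=-0.984 controls=-0.093
K_D_CC: F=86.10 p=6.4e-13 patients=-0.600 controls=-0.094
K_D_E: F=82.04 p=1.5e-12 patients=-0.433 controls=-0.037
K_D_PC: F=359.85 p=4.7e-26 patients=-0.914 controls=-0.638
{'n_patients': 28, 'rho_baseline': -0.526, 'p_baseline': 0.006,
 'rho_recovery': 0.640, 'p_recovery': 0.0003}
```

All five disruption indices are significantly lower in patients than in
controls, and the degree of the planted hub ROI correlates negatively with
the baseline motor score and positively with the recovery ratio — the sign
pattern the pipeline is designed to detect. (Both groups sit below zero
because finite scan length attenuates estimated hub profiles relative to
the noise-averaged normative reference; the group contrast is the
endpoint.)

The same run is available from the shell:

```bash
hubdisrupt run --out results/demo --seed 1
hubdisrupt stats table1 --counts 12 17 19 9      # chi2 = 4.0259, p = 0.0448
hubdisrupt stats welch --summary 62.38 11.10 29 65.22 3.07 32   # p = 0.1922
```

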