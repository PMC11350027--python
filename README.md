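# teasl — time-encoded ASL simulation, quantification, and group statistics

Cerebral blood flow (CBF) falls early in the Alzheimer's disease continuum,
but detecting the small reduction present in cognitively unimpaired (CU)
amyloid-positive (Aβ+) individuals pushes arterial spin labeling (ASL) MRI
to its limits. Time-encoded pseudo-continuous ASL (te-ASL) splits one 3.6 s
labeling train into seven sub-boluses toggled label/control across
acquisitions by a Hadamard-8 matrix; decoding yields multi-delay
perfusion-weighted signals from a single scan, so CBF *and* arterial
transit time (ATT) can be fitted per voxel — whereas conventional
single-PLD ASL must assume the label has fully arrived by its one
post-labeling delay.

`teasl` implements that whole computational chain as a tested,
synthetic-data pipeline for methodologists who want to study when te-ASL
buys sensitivity:

* **Hadamard codec** — Sylvester scheme construction, exact
  encode/decode, analytic noise propagation (`teasl.hadamard`);
* **Kinetics** — the single-compartment model
  `ΔM(t) = 2 α M0/λ · f · T1′ · e^(−att/T1b) · (1 − e^(−(t−att)/T1′))`
  (inflow phase, with the matching decay branch after the bolus), the
  consensus single-PLD formula, and a fast bounded least-squares CBF/ATT
  fitter (`teasl.kinetics`);
* **Synthetic cohort** — digital phantoms and a three-group cohort
  (CU Aβ−, CU Aβ+, CI Aβ+; n = 24/18/17) with group-dependent CBF
  reductions in an AD-vulnerable mask, age/sex-dependent ATT, and a CSF /
  PET / imaging / cognition biomarker table with calibrated partial
  correlations to true mask CBF (`teasl.cohort`);
* **Quantification** — te-ASL and single-PLD CBF maps, Gaussian smoothing,
  cerebellar normalization, ROI means, cluster-extent data-driven masks
  (`teasl.quantify`);
* **Group statistics** — age/sex-adjusted percent-change contrasts with
  95 % CIs, voxelwise GLM, partial Pearson correlations with
  Benjamini–Hochberg FDR, 3-SD outlier rule, chi-square tables, A/T-stage
  trend analysis (`teasl.stats`);
* **Orchestration** — YAML-configured `simulate → quantify → analyze`
  stages over NIfTI/CSV/JSON, as a library (`teasl.io`,
  `teasl.experiments`) and a CLI (`teasl simulate|quantify|analyze|experiment`).

See `docs/methods.md` for the model, parameter choices, and limitations.

## Worked example

Simulate one cohort at the study's group sizes, quantify every subject both
ways, and run the adjusted group contrasts on the cerebellar-normalized
AD-mask ROI values:

```python
from teasl import SubBolusSchedule, build_scheme
from teasl.cohort import (PhantomSpec, CohortConfig, make_phantom,
                          simulate_cohort, simulate_subject)
from teasl.kinetics import KineticParams
from teasl.quantify import fit_maps, single_pld_map, normalize_cerebellum, roi_mean
from teasl.stats import adjusted_percent_change

schedule = SubBolusSchedule()                 # 1800/600/.../150 ms sub-boluses
scheme = build_scheme(schedule.n_subboluses)  # Hadamard-8
params = KineticParams()
phantom = make_phantom(PhantomSpec.small(), seed=0)
cfg = CohortConfig(seed=42)                   # n = 24/18/17, −8.55 % / −18.03 %
subjects, table = simulate_cohort(cfg, phantom)

values = {"te": [], "spld": []}
for s in subjects:
    sim = simulate_subject(s["phantom"], schedule, scheme, params,
                           noise_sd=cfg.acquisition_noise_sd, seed=s["sim_seed"])
    for tag, maps in (("te", fit_maps(sim.series, sim.m0, schedule, scheme, params)),
                      ("spld", single_pld_map(sim.series, sim.m0, schedule, scheme, params))):
        nu = normalize_cerebellum(maps.cbf, s["phantom"].cerebellum_mask, maps.valid)
        values[tag].append(roi_mean(nu, s["phantom"].ad_mask, maps.valid))

for tag in ("te", "spld"):
    for c in adjusted_percent_change(values[tag], table["group"], table["age"],
                                     table["sex"], reference_group="CU_Abeta_neg"):
        print(f"{tag:5s} {c.group:13s} {c.percent_change:+6.2f}% "
              f"[{c.ci_low:+6.2f}, {c.ci_high:+6.2f}]  p={c.p_value:.4f}")
```

Output:

```
te    CU_Abeta_pos   -6.43% [-11.85,  -1.01]  p=0.0210
te    CI_Abeta_pos  -14.95% [-21.03,  -8.87]  p=0.0000
spld  CU_Abeta_pos   -4.94% [-11.89,  +2.01]  p=0.1602
spld  CI_Abeta_pos  -15.10% [-22.90,  -7.30]  p=0.0003
```

Both methods detect the large reduction in the impaired (CI Aβ+) group, but
at this seed only te-ASL resolves the subtle CU Aβ+ reduction (p = 0.021;
the single-PLD CI crosses zero) — the sensitivity pattern the replicated
experiments in `teasl.experiments` quantify as rejection rates over
hundreds of cohorts.

The same run is available from the shell:

```bash
teasl experiment --seed 42 --out runs/demo    # simulate + quantify + analyze
```

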