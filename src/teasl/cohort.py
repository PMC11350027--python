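"""Digital phantoms and synthetic cohorts for time-encoded ASL studies.

The phantom is a small labeled voxel grid (white matter, cortical gray
matter, a cerebellar gray-matter reference region, and an "AD-vulnerable"
gray-matter mask standing in for the temporo-parietal/hippocampal a-priori
mask) carrying true CBF, ATT, and M0 maps.  A cohort is a set of subjects
drawn from three diagnostic groups (CU Abeta-, CU Abeta+, CI Abeta+) whose
phantoms differ by a group-dependent CBF reduction inside the AD mask,
between-subject CBF scaling, and an age/sex-dependent arterial transit
time.  A biomarker table (CSF AD markers, synaptic and neurodegeneration
markers, imaging covariates, cognition) is generated with configurable
partial correlations to the true mask CBF, so the downstream statistics can
be validated against known ground truth.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hadamard import SubBolusSchedule, HadamardScheme, encode
from .kinetics import KineticParams, _signals_array

__all__ = [
    "PhantomSpec", "Phantom", "CohortConfig", "BiomarkerSpec",
    "BiomarkerConfig", "EncodedSeries", "make_phantom", "simulate_subject",
    "simulate_cohort", "simulate_biomarkers",
    "GROUPS", "LABELS",
]

GROUPS = ("CU_Abeta_neg", "CU_Abeta_pos", "CI_Abeta_pos")

#: tissue label codes
LABELS = {"background": 0, "WM": 1, "GM": 2, "cerebellar_GM": 3, "ad_mask_GM": 4}

Box = tuple  # ((x0, x1), (y0, y1), (z0, z1)) half-open voxel ranges


def _box_mask(shape, box) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and baseline tissue values of the digital phantom.

    The default grid matches the acquisition voxel size (2.29 x 2.29 x 6 mm,
    32 x 32 x 20 voxels).  Regions are axis-aligned boxes; the AD mask is
    the exact number of gray-matter voxels nearest to ``ad_center``.
    Baseline values: GM CBF 50 and WM CBF 20 mL/100g/min, GM ATT 1.3 s with
    a shorter cerebellar ATT and a longer WM ATT, M0 in arbitrary units.
    ``group_effect`` is the fractional CBF change applied inside the AD
    mask (e.g. -0.1803 for an 18.03 % reduction).
    """

    grid_shape: tuple = (32, 32, 20)
    voxel_mm: tuple = (2.29, 2.29, 6.0)
    cerebrum_box: Box = ((6, 26), (6, 26), (6, 16))
    wm_box: Box = ((11, 21), (11, 21), (8, 14))
    cerebellum_box: Box = ((10, 22), (10, 22), (0, 4))
    ad_center: tuple = (16.0, 16.0, 15.0)
    ad_mask_voxels: int = 500
    gm_cbf: float = 50.0
    wm_cbf: float = 20.0
    cereb_cbf: float = 50.0
    gm_att_s: float = 1.3
    wm_att_s: float = 1.6
    cereb_att_s: float = 0.8
    gm_m0: float = 1000.0
    wm_m0: float = 700.0
    group_effect: float = 0.0
    cbf_jitter_cv: float = 0.0
    att_jitter_sd: float = 0.0

    @classmethod
    def small(cls, **overrides) -> "PhantomSpec":
        """A reduced grid (12 x 12 x 6) for Monte-Carlo experiments."""
        defaults = dict(
            grid_shape=(12, 12, 6),
            cerebrum_box=((2, 10), (2, 10), (2, 6)),
            wm_box=((4, 8), (4, 8), (3, 5)),
            cerebellum_box=((3, 9), (3, 9), (0, 2)),
            ad_center=(6.0, 6.0, 5.0),
            ad_mask_voxels=48,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        def tup(x):
            return tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in x) \
                if isinstance(x, (list, tuple)) else x
        return cls(**{k: tup(v) for k, v in d.items()})


@dataclass
class Phantom:
    """Voxel grids of ground truth: tissue labels, CBF, ATT, M0."""

    tissue_labels: np.ndarray
    cbf_true: np.ndarray
    att_true: np.ndarray
    m0: np.ndarray
    voxel_mm: tuple
    spec: PhantomSpec | None = None

    def mask(self, *names: str) -> np.ndarray:
        out = np.zeros(self.tissue_labels.shape, dtype=bool)
        for n in names:
            out |= self.tissue_labels == LABELS[n]
        return out

    @property
    def ad_mask(self) -> np.ndarray:
        return self.mask("ad_mask_GM")

    @property
    def cerebellum_mask(self) -> np.ndarray:
        return self.mask("cerebellar_GM")

    @property
    def gm_mask(self) -> np.ndarray:
        return self.mask("GM", "ad_mask_GM", "cerebellar_GM")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_labels != LABELS["background"]


def make_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Build the deterministic phantom for ``spec``.

    Raises if the mandatory-disjoint regions overlap or the AD mask does
    not fit inside cerebral gray matter.
    """
    shape = tuple(spec.grid_shape)
    cerebrum = _box_mask(shape, spec.cerebrum_box)
    wm = _box_mask(shape, spec.wm_box)
    cereb = _box_mask(shape, spec.cerebellum_box)
    if (wm & ~cerebrum).any():
        raise ValueError("WM box must lie inside the cerebrum box")
    if (cerebrum & cereb).any():
        raise ValueError("cerebrum and cerebellum regions must be disjoint")
    gm = cerebrum & ~wm

    # AD mask: exactly ad_mask_voxels GM voxels nearest to ad_center,
    # deterministic tie-break by voxel index
    gm_idx = np.argwhere(gm)
    if spec.ad_mask_voxels > len(gm_idx):
        raise ValueError("ad_mask_voxels exceeds available GM voxels")
    d2 = ((gm_idx - np.asarray(spec.ad_center)) ** 2).sum(axis=1)
    order = np.lexsort((gm_idx[:, 2], gm_idx[:, 1], gm_idx[:, 0], d2))
    ad_idx = gm_idx[order[: spec.ad_mask_voxels]]
    ad = np.zeros(shape, dtype=bool)
    ad[tuple(ad_idx.T)] = True
    if (ad & cereb).any():
        raise ValueError("AD mask and cerebellar reference must be disjoint")

    labels = np.zeros(shape, dtype=np.int8)
    labels[wm] = LABELS["WM"]
    labels[gm] = LABELS["GM"]
    labels[cereb] = LABELS["cerebellar_GM"]
    labels[ad] = LABELS["ad_mask_GM"]

    cbf = np.zeros(shape)
    cbf[wm] = spec.wm_cbf
    cbf[gm] = spec.gm_cbf
    cbf[cereb] = spec.cereb_cbf
    cbf[ad] = spec.gm_cbf * (1.0 + spec.group_effect)

    att = np.full(shape, spec.gm_att_s)
    att[wm] = spec.wm_att_s
    att[cereb] = spec.cereb_att_s

    m0 = np.zeros(shape)
    m0[gm | cereb] = spec.gm_m0
    m0[wm] = spec.wm_m0

    rng = np.random.default_rng(seed)
    brain = labels != 0
    if spec.cbf_jitter_cv > 0:
        jit = 1.0 + spec.cbf_jitter_cv * rng.standard_normal(shape)
        cbf[brain] = np.clip(cbf[brain] * jit[brain], 0.0, None)
    if spec.att_jitter_sd > 0:
        att[brain] = np.clip(
            att[brain] + spec.att_jitter_sd * rng.standard_normal(brain.sum()),
            0.15, 3.5)
    att[~brain] = spec.gm_att_s  # irrelevant outside the brain

    return Phantom(tissue_labels=labels, cbf_true=cbf, att_true=att, m0=m0,
                   voxel_mm=tuple(spec.voxel_mm), spec=spec)


@dataclass
class EncodedSeries:
    """Simulated 4D acquisition: acquisition axis first, plus the M0 volume."""

    series: np.ndarray  # (n_acquisitions, *grid)
    m0: np.ndarray      # (*grid,)
    noise_sd: float
    seed: int


def simulate_subject(phantom: Phantom, schedule: SubBolusSchedule,
                     scheme: HadamardScheme,
                     params: KineticParams = KineticParams(),
                     noise_sd: float = 0.0, seed: int = 0) -> EncodedSeries:
    """Forward-simulate the Hadamard-encoded acquisition of one subject.

    Per voxel: kinetic sub-bolus signals -> Hadamard encoding -> i.i.d.
    Gaussian acquisition noise of SD ``noise_sd``.  The M0 volume is a
    noiseless copy of the phantom M0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    shape = phantom.cbf_true.shape
    signals = np.zeros(shape + (schedule.n_subboluses,))
    brain = phantom.brain_mask
    signals[brain] = _signals_array(
        schedule, phantom.cbf_true[brain], phantom.att_true[brain],
        phantom.m0[brain], params)
    acq = encode(phantom.m0, signals, scheme)       # (*grid, n_acq)
    series = np.moveaxis(acq, -1, 0).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        series += rng.normal(0.0, noise_sd, series.shape)
    return EncodedSeries(series=series, m0=phantom.m0.copy(),
                         noise_sd=noise_sd, seed=seed)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the three-group synthetic cohort.

    Group sizes, ages and sex ratios follow the study demographics
    (n = 24/18/17; ages 67.4 (4.2) / 66.1 (2.9) / 73.1 (6.5) years).  The
    AD-mask CBF effects default to the reported adjusted reductions
    (-8.55 % in CU Abeta+, -18.03 % in CI Abeta+).  Between-subject CBF
    variability has a global component (``between_subject_cv``, a scale on
    the whole map that cerebellar normalization removes) and a regional
    component (``regional_cv``, specific to the AD mask, which it cannot
    remove); the regional component is set so that the total dispersion of
    normalized ROI values (biology + ATT effects + acquisition noise)
    matches the ~10 % the study's confidence intervals imply.  ``acquisition_noise_sd`` is the
    effective noise of the averaged encoded series (the 5.5-min scan
    averages several Hadamard cycles).

    ATT is assigned per subject as ``intercept + age_slope * (age - 70) +
    sex_offset * male + noise`` (positive age slope, longer ATT in males),
    clipped to ``att_clip``; setting ``att_uniform_range`` instead draws
    subject ATT uniformly (the ATT-heterogeneity condition of the
    sensitivity experiments).  The cerebellar reference region receives an
    independent per-subject ATT offset (``att_cereb_noise_sd_s``) since
    transit to the posterior circulation does not track cortical transit
    exactly.  ``stage_effects``, when set, replaces the CU Abeta+ group
    effect by tau-stage-specific effects (fraction ``t_pos_fraction_cu`` of
    CU Abeta+ flagged T+).
    """

    n_per_group: tuple = (24, 18, 17)
    group_effects: tuple = (0.0, -0.0855, -0.1803)
    stage_effects: dict | None = None  # e.g. {"A+T-": -0.0486, "A+T+": -0.0930}
    t_pos_fraction_cu: float = 9.0 / 17.0
    t_pos_fraction_ci: float = 16.0 / 17.0
    between_subject_cv: float = 0.10
    regional_cv: float = 0.08
    acquisition_noise_sd: float = 2.0
    age_mean: tuple = (67.4, 66.1, 73.1)
    age_sd: tuple = (4.2, 2.9, 6.5)
    female_prop: tuple = (16 / 24, 15 / 18, 8 / 17)
    att_intercept_s: float = 1.3
    att_age_slope_s_per_yr: float = 0.01
    att_sex_offset_s: float = 0.10
    att_noise_sd_s: float = 0.15
    att_uniform_range: tuple | None = None
    att_cereb_noise_sd_s: float = 0.15
    att_clip_s: tuple = (0.5, 2.8)
    age_ref_yr: float = 70.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs at least 2 subjects")
        if self.acquisition_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.between_subject_cv < 0 or self.att_noise_sd_s < 0:
            raise ValueError("SDs must be non-negative")

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for k in ("n_per_group", "group_effects", "age_mean", "age_sd",
                  "female_prop", "att_clip_s", "att_uniform_range"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _subject_stage(group: str, t_pos: bool) -> str:
    if group == "CU_Abeta_neg":
        return "A-T-"
    if group == "CU_Abeta_pos":
        return "A+T+" if t_pos else "A+T-"
    return "CI"


def simulate_cohort(config: CohortConfig, phantom_template: Phantom,
                    build_phantoms: bool = True):
    """Draw the cohort and (optionally) each subject's phantom.

    Returns ``(subjects, table)`` where ``table`` is a DataFrame with
    columns id, group, stage, age, sex, tau_pos, subject ATT, and the true
    AD-mask mean CBF; ``subjects`` is a list of dicts carrying the
    per-subject phantom (when ``build_phantoms``) plus its scalars.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base = phantom_template
    ad = base.ad_mask
    brain = base.brain_mask
    lo, hi = config.att_clip_s

    subjects, rows = [], []
    sid = 0
    for gi, (group, n) in enumerate(zip(GROUPS, config.n_per_group)):
        ages = rng.normal(config.age_mean[gi], config.age_sd[gi], n)
        females = rng.random(n) < config.female_prop[gi]
        # deterministic tau-positive count per group
        if group == "CU_Abeta_neg":
            t_pos = np.zeros(n, dtype=bool)
        else:
            frac = (config.t_pos_fraction_cu if group == "CU_Abeta_pos"
                    else config.t_pos_fraction_ci)
            k = int(round(frac * n))
            t_pos = np.zeros(n, dtype=bool)
            t_pos[rng.permutation(n)[:k]] = True
        for j in range(n):
            stage = _subject_stage(group, bool(t_pos[j]))
            effect = config.group_effects[gi]
            if config.stage_effects is not None and stage in config.stage_effects:
                effect = config.stage_effects[stage]
            scale = max(1.0 + config.between_subject_cv * rng.standard_normal(),
                        0.2)
            mask_scale = max(1.0 + config.regional_cv * rng.standard_normal(),
                             0.2)
            if config.att_uniform_range is not None:
                att_subj = float(rng.uniform(*config.att_uniform_range))
            else:
                att_subj = (config.att_intercept_s
                            + config.att_age_slope_s_per_yr * (ages[j] - config.age_ref_yr)
                            + config.att_sex_offset_s * (not females[j])
                            + config.att_noise_sd_s * rng.standard_normal())
                att_subj = float(np.clip(att_subj, lo, hi))
            att_cereb_off = config.att_cereb_noise_sd_s * rng.standard_normal()

            cbf = base.cbf_true * scale
            cbf[ad] *= (1.0 + effect) * mask_scale
            att = base.att_true + (att_subj - (base.spec.gm_att_s if base.spec
                                               else 1.3))
            att[base.cerebellum_mask] += att_cereb_off
            att = np.clip(att, 0.15, 3.5)
            att[~brain] = 1.3
            true_mask_cbf = float(cbf[ad].mean())

            subj = {
                "id": f"sub-{sid:03d}", "group": group, "stage": stage,
                "age": float(ages[j]), "sex": "F" if females[j] else "M",
                "tau_pos": bool(t_pos[j]), "att_s": att_subj,
                "cbf_scale": float(scale), "effect": float(effect),
                "true_mask_cbf": true_mask_cbf,
                "sim_seed": int(rng.integers(0, 2**31 - 1)),
            }
            if build_phantoms:
                subj["phantom"] = Phantom(
                    tissue_labels=base.tissue_labels, cbf_true=cbf,
                    att_true=att, m0=base.m0, voxel_mm=base.voxel_mm,
                    spec=base.spec)
            subjects.append(subj)
            rows.append({k: subj[k] for k in
                         ("id", "group", "stage", "age", "sex", "tau_pos",
                          "att_s", "true_mask_cbf")})
            sid += 1
    table = pd.DataFrame(rows)
    return subjects, table


# ---------------------------------------------------------------------------
# biomarkers


@dataclass(frozen=True)
class BiomarkerSpec:
    """One biomarker column: marginal scale, CBF link, optional thresholds.

    ``target_r`` is the partial Pearson correlation (age/sex regressed out)
    with true AD-mask CBF in the CU sample that the generator calibrates to.
    ``group_means`` may key on group names or tau-stage flags for
    group-defining markers (CSF Abeta42/40, Centiloid, pTau181); other
    markers use the single marginal ``mean``.
    """

    name: str
    target_r: float
    mean: float
    sd: float
    group_means: dict | None = None
    positive_if_le: float | None = None   # positivity when value <= threshold
    positive_if_gt: float | None = None   # positivity when value > threshold

    def __post_init__(self):
        if abs(self.target_r) >= 1:
            raise ValueError("|target r| must be < 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def default_biomarkers() -> dict:
    """The study's biomarker panel with its reported CU partial correlations."""
    specs = [
        BiomarkerSpec("abeta42_40", +0.53, 0.068, 0.030,
                      group_means={"CU_Abeta_neg": 0.088, "CU_Abeta_pos": 0.041,
                                   "CI_Abeta_pos": 0.038},
                      positive_if_le=0.071),
        BiomarkerSpec("centiloid", -0.41, 15.0, 30.0,
                      group_means={"CU_Abeta_neg": -4.7, "CU_Abeta_pos": 40.9,
                                   "CI_Abeta_pos": 70.0}),
        BiomarkerSpec("ptau181", -0.43, 22.0, 12.0,
                      group_means={"A-T-": 15.0, "A+T-": 18.0, "A+T+": 32.0,
                                   "CI_T-": 55.0, "CI_T+": 95.0},
                      positive_if_gt=24.0),
        BiomarkerSpec("ptau217", -0.49, 3.0, 1.5),
        BiomarkerSpec("ptau231", -0.45, 12.0, 5.0),
        BiomarkerSpec("ptau235", -0.51, 2.0, 1.0),
        BiomarkerSpec("gap43", -0.46, 3500.0, 1200.0),
        BiomarkerSpec("neurogranin", -0.47, 800.0, 300.0),
        BiomarkerSpec("snap25", -0.42, 2.0, 0.8),
        BiomarkerSpec("synaptotagmin1", -0.36, 250.0, 90.0),
        BiomarkerSpec("nfl", -0.45, 90.0, 35.0),
        BiomarkerSpec("hippocampal_volume", 0.0, 7250.0, 650.0,
                      group_means={"CU_Abeta_neg": 7250.0,
                                   "CU_Abeta_pos": 7140.0,
                                   "CI_Abeta_pos": 5950.0}),
        BiomarkerSpec("ad_signature", 0.0, 2.55, 0.12,
                      group_means={"CU_Abeta_neg": 2.6, "CU_Abeta_pos": 2.6,
                                   "CI_Abeta_pos": 2.4}),
        BiomarkerSpec("wmh_pct", 0.0, 0.25, 0.2),
        BiomarkerSpec("pacc", 0.0, -0.2, 0.7,
                      group_means={"CU_Abeta_neg": 0.0, "CU_Abeta_pos": -0.5,
                                   "CI_Abeta_pos": -3.0}),
        BiomarkerSpec("mmse", 0.0, 28.0, 1.5,
                      group_means={"CU_Abeta_neg": 29.3, "CU_Abeta_pos": 28.8,
                                   "CI_Abeta_pos": 21.5}),
    ]
    return {s.name: s for s in specs}


@dataclass(frozen=True)
class BiomarkerConfig:
    """Panel of :class:`BiomarkerSpec` plus the positivity thresholds."""

    specs: dict = field(default_factory=default_biomarkers)
    abeta_threshold: float = 0.071
    ptau_threshold_cu: float = 24.0
    ptau_threshold_ci: float = 69.9

    def to_dict(self) -> dict:
        return {
            "specs": {k: {f: getattr(s, f) for f in s.__dataclass_fields__}
                      for k, s in self.specs.items()},
            "abeta_threshold": self.abeta_threshold,
            "ptau_threshold_cu": self.ptau_threshold_cu,
            "ptau_threshold_ci": self.ptau_threshold_ci,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiomarkerConfig":
        specs = {k: BiomarkerSpec(**v) for k, v in d["specs"].items()}
        return cls(specs=specs,
                   abeta_threshold=d.get("abeta_threshold", 0.071),
                   ptau_threshold_cu=d.get("ptau_threshold_cu", 24.0),
                   ptau_threshold_ci=d.get("ptau_threshold_ci", 69.9))


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covs])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _marker_means(spec: BiomarkerSpec, df: pd.DataFrame) -> np.ndarray:
    if spec.group_means is None:
        return np.full(len(df), spec.mean)
    out = np.full(len(df), spec.mean)
    for i, row in enumerate(df.itertuples()):
        key = row.group
        if key == "CI_Abeta_pos" and f"CI_T{'+' if row.tau_pos else '-'}" in spec.group_means:
            key = f"CI_T{'+' if row.tau_pos else '-'}"
        elif row.stage in spec.group_means:
            key = row.stage
        if key in spec.group_means:
            out[i] = spec.group_means[key]
    return out


def simulate_biomarkers(cohort: pd.DataFrame, config: BiomarkerConfig = BiomarkerConfig(),
                        seed: int = 0) -> pd.DataFrame:
    """Append biomarker columns and Abeta/tau status flags to the cohort.

    Within the CU sample each marker is ``mu(subject) + b * z + noise``
    where ``z`` is the standardized residual of true AD-mask CBF on age and
    sex; ``b`` and the noise SD are calibrated analytically so that the
    population partial correlation (given age and sex) equals the target,
    accounting for any group-mean structure the marker carries.  CI
    subjects receive group/stage-conditional values without the CBF link
    (their biomarkers are not part of the correlation analysis).  Values of
    group-defining markers are kept on their group's side of the positivity
    threshold.
    """
    df = cohort.copy()
    rng = np.random.default_rng(seed)
    cu = (df["group"].isin(["CU_Abeta_neg", "CU_Abeta_pos"])).to_numpy()
    covs = np.column_stack([df["age"].to_numpy(),
                            (df["sex"] == "M").to_numpy(float)])
    z = np.zeros(len(df))
    r_cu = _residualize(df["true_mask_cbf"].to_numpy()[cu], covs[cu])
    z[cu] = (r_cu - r_cu.mean()) / r_cu.std()

    for name, spec in config.specs.items():
        mu = _marker_means(spec, df)
        # calibrate the CBF link on the CU subsample
        mu_res = _residualize(mu[cu], covs[cu])
        zc = z[cu]
        cov_mu_z = float(np.mean(mu_res * zc))
        b = spec.target_r * spec.sd - cov_mu_z
        var_sys = float(np.var(mu_res + b * zc))
        var_e = spec.sd**2 - var_sys
        if var_e <= 0:
            raise ValueError(
                f"{name}: group-mean structure already exceeds the requested "
                f"marginal SD; cannot reach target r={spec.target_r}")
        values = mu + rng.normal(0.0, np.sqrt(var_e), len(df))
        values[cu] += b * z[cu]
        df[name] = values

    # positivity flags, with group-defining values forced onto the correct
    # side of their threshold (rare 3-sigma stragglers are clipped)
    thr = config.abeta_threshold
    abeta_pos = df["group"].isin(["CU_Abeta_pos", "CI_Abeta_pos"]).to_numpy()
    v = df["abeta42_40"].to_numpy()
    eps = 1e-3 * config.specs["abeta42_40"].sd
    v[abeta_pos] = np.minimum(v[abeta_pos], thr)
    v[~abeta_pos] = np.maximum(v[~abeta_pos], thr + eps)
    df["abeta42_40"] = v
    df["abeta_pos"] = abeta_pos

    tau_thr = np.where(df["group"] == "CI_Abeta_pos",
                       config.ptau_threshold_ci, config.ptau_threshold_cu)
    p = df["ptau181"].to_numpy()
    tpos = df["tau_pos"].to_numpy()
    epsp = 1e-3 * config.specs["ptau181"].sd
    p[tpos] = np.maximum(p[tpos], tau_thr[tpos] + epsp)
    p[~tpos] = np.minimum(p[~tpos], tau_thr[~tpos])
    df["ptau181"] = p
    return df
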