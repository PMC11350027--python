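"""Run configuration, NIfTI/CSV/YAML round-trips, and pipeline orchestration.

The three pipeline stages mirror a real study layout on disk::

    out/
      config.yaml            run configuration (seed recorded)
      phantom_labels.nii.gz  tissue label volume shared by all subjects
      cohort.csv             covariate + biomarker table
      sub-XXX/series.nii.gz  4D Hadamard-encoded acquisitions
      sub-XXX/m0.nii.gz      calibration volume
      sub-XXX/cbf_te.nii.gz, att_te.nii.gz, cbf_spld.nii.gz ... (quantify)
      roi.csv, contrasts.csv, correlations.csv, report.json    (analyze)

Every artifact-producing step embeds the seed and a hash of the
configuration in ``report.json`` so a run is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .hadamard import SubBolusSchedule, build_scheme
from .kinetics import KineticParams
from .cohort import (PhantomSpec, CohortConfig, BiomarkerConfig, LABELS,
                     make_phantom, simulate_subject, simulate_cohort,
                     simulate_biomarkers)
from . import quantify as q
from . import stats as st

__all__ = ["RunConfig", "save_nifti", "load_nifti", "cmd_simulate",
           "cmd_quantify", "cmd_analyze", "cmd_experiment"]

log = logging.getLogger("teasl")


@dataclass(frozen=True)
class RunConfig:
    """Everything a full simulate -> quantify -> analyze run needs."""

    schedule: SubBolusSchedule = field(default_factory=SubBolusSchedule)
    params: KineticParams = field(default_factory=KineticParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    biomarkers: BiomarkerConfig = field(default_factory=BiomarkerConfig)
    smoothing_fwhm_mm: float = 12.0
    p_voxel: float = 0.001
    min_cluster_voxels: int = 100
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "schedule": self.schedule.to_dict(),
            "params": self.params.to_dict(),
            "phantom": self.phantom.to_dict(),
            "cohort": self.cohort.to_dict(),
            "biomarkers": self.biomarkers.to_dict(),
            "smoothing_fwhm_mm": self.smoothing_fwhm_mm,
            "p_voxel": self.p_voxel,
            "min_cluster_voxels": self.min_cluster_voxels,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            schedule=SubBolusSchedule.from_dict(d["schedule"]),
            params=KineticParams.from_dict(d["params"]),
            phantom=PhantomSpec.from_dict(d["phantom"]),
            cohort=CohortConfig.from_dict(d["cohort"]),
            biomarkers=BiomarkerConfig.from_dict(d["biomarkers"]),
            smoothing_fwhm_mm=d["smoothing_fwhm_mm"],
            p_voxel=d["p_voxel"],
            min_cluster_voxels=d["min_cluster_voxels"],
            alpha=d["alpha"],
            seed=d["seed"],
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_nifti(path, data, voxel_mm) -> None:
    affine = np.diag(list(voxel_mm[:3]) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _series_to_nifti(series: np.ndarray) -> np.ndarray:
    """Acquisition-first array -> NIfTI (x, y, z, t) layout."""
    return np.moveaxis(series, 0, -1)


def _series_from_nifti(arr: np.ndarray) -> np.ndarray:
    return np.moveaxis(arr, -1, 0)


def cmd_simulate(config: RunConfig, out_dir) -> pd.DataFrame:
    """Simulate the cohort: per-subject encoded series + M0, cohort CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = build_scheme(config.schedule.n_subboluses)
    phantom = make_phantom(config.phantom, seed=config.seed)
    save_nifti(out / "phantom_labels.nii.gz", phantom.tissue_labels,
               phantom.voxel_mm)
    subjects, table = simulate_cohort(config.cohort, phantom)
    table = simulate_biomarkers(table, config.biomarkers,
                                seed=config.seed + 1)
    for subj in subjects:
        sdir = out / subj["id"]
        sdir.mkdir(exist_ok=True)
        sim = simulate_subject(subj["phantom"], config.schedule, scheme,
                               config.params,
                               noise_sd=config.cohort.acquisition_noise_sd,
                               seed=subj["sim_seed"])
        save_nifti(sdir / "series.nii.gz", _series_to_nifti(sim.series),
                   phantom.voxel_mm)
        save_nifti(sdir / "m0.nii.gz", sim.m0, phantom.voxel_mm)
    table.to_csv(out / "cohort.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(json.dumps(
        {"stage": "simulate", "seed": config.seed,
         "config_hash": config.hash(), "n_subjects": len(subjects)}, indent=2))
    log.info("simulated %d subjects into %s", len(subjects), out)
    return table


def _load_masks(cohort_dir: Path):
    labels = load_nifti(cohort_dir / "phantom_labels.nii.gz").astype(int)
    ad = labels == LABELS["ad_mask_GM"]
    cereb = labels == LABELS["cerebellar_GM"]
    return ad, cereb


def cmd_quantify(subject_dir, config: RunConfig,
                 method: str = "both") -> dict:
    """Quantify one subject: te-ASL and/or single-PLD maps + ROI values."""
    sdir = Path(subject_dir)
    if not (sdir / "m0.nii.gz").exists():
        raise FileNotFoundError(f"missing M0 volume in {sdir}")
    if not (sdir / "series.nii.gz").exists():
        raise FileNotFoundError(f"missing encoded series in {sdir}")
    series = _series_from_nifti(load_nifti(sdir / "series.nii.gz"))
    m0 = load_nifti(sdir / "m0.nii.gz")
    scheme = build_scheme(config.schedule.n_subboluses)
    ad, cereb = _load_masks(sdir.parent)
    voxel = config.phantom.voxel_mm
    row = {"id": sdir.name}
    methods = ("te_asl", "single_pld") if method == "both" else (
        {"te": "te_asl", "single": "single_pld"}.get(method, method),)
    for m in methods:
        if m == "te_asl":
            maps = q.fit_maps(series, m0, config.schedule, scheme,
                              config.params)
            save_nifti(sdir / "att_te.nii.gz", maps.att, voxel)
        else:
            maps = q.single_pld_map(series, m0, config.schedule, scheme,
                                    config.params)
        cbf_s = q.gaussian_smooth(maps.cbf, config.smoothing_fwhm_mm, voxel)
        cbf_nu = q.normalize_cerebellum(cbf_s, cereb, maps.valid)
        tag = "te" if m == "te_asl" else "spld"
        save_nifti(sdir / f"cbf_{tag}.nii.gz", maps.cbf, voxel)
        save_nifti(sdir / f"cbf_nu_{tag}.nii.gz", cbf_nu, voxel)
        row[f"roi_cbf_{tag}"] = q.roi_mean(maps.cbf, ad, maps.valid)
        row[f"roi_cbf_nu_{tag}"] = q.roi_mean(cbf_nu, ad, maps.valid)
        if m == "te_asl":
            row["roi_att_te"] = q.roi_mean(maps.att, ad, maps.valid)
    (sdir / "roi.json").write_text(json.dumps(row, indent=2))
    return row


BIOMARKER_VARS = ["abeta42_40", "centiloid", "ptau181", "ptau217", "ptau231",
                  "ptau235", "gap43", "neurogranin", "snap25",
                  "synaptotagmin1", "nfl", "hippocampal_volume",
                  "ad_signature", "wmh_pct"]


def cmd_analyze(cohort_dir, config: RunConfig) -> dict:
    """Group contrasts, data-driven mask, biomarker correlation table."""
    cdir = Path(cohort_dir)
    if not (cdir / "cohort.csv").exists():
        raise FileNotFoundError(f"no cohort.csv in {cdir} (run simulate first)")
    table = pd.read_csv(cdir / "cohort.csv")
    if table["group"].nunique() < 2:
        raise ValueError("need at least 2 groups to analyze")
    rows = []
    for sdir in sorted(cdir.glob("sub-*")):
        roi = json.loads((sdir / "roi.json").read_text())
        rows.append(roi)
    roi_df = pd.DataFrame(rows)
    df = table.merge(roi_df, on="id")
    df.to_csv(cdir / "roi.csv", index=False)

    # a-priori-mask contrasts for both methods
    contrasts = []
    for tag in ("te", "spld"):
        res = st.adjusted_percent_change(
            df[f"roi_cbf_nu_{tag}"], df["group"], df["age"], df["sex"],
            reference_group="CU_Abeta_neg")
        pf = st.bh_fdr([c.p_value for c in res])
        for c, padj in zip(res, pf):
            c.p_fdr = float(padj)
            contrasts.append({"method": tag, **c.__dict__})
    pd.DataFrame(contrasts).to_csv(cdir / "contrasts.csv", index=False)

    # voxelwise GLM on te-ASL normalized maps: CI Abeta+ reduction contrast
    maps = np.stack([load_nifti(cdir / sid / "cbf_nu_te.nii.gz")
                     for sid in df["id"]])
    levels = [g for g in pd.unique(df["group"]) if g != "CU_Abeta_neg"]
    contrast = np.zeros(1 + len(levels) + 2)
    if "CI_Abeta_pos" in levels:
        contrast[1 + levels.index("CI_Abeta_pos")] = -1.0  # reduction -> +t
    tmap, dof = st.voxelwise_glm(maps, df["group"], df["age"], df["sex"],
                                 contrast, reference_group="CU_Abeta_neg")
    dd_mask = q.derive_datadriven_mask(tmap, dof, config.p_voxel,
                                       config.min_cluster_voxels)
    save_nifti(cdir / "tmap_ci_vs_cuneg_te.nii.gz", tmap,
               config.phantom.voxel_mm)
    save_nifti(cdir / "datadriven_mask.nii.gz", dd_mask.astype(float),
               config.phantom.voxel_mm)

    # biomarker partial correlations in the CU sample (a-priori-mask CBF)
    cu = df[df["group"].isin(["CU_Abeta_neg", "CU_Abeta_pos"])]
    cors = []
    for var in BIOMARKER_VARS:
        if var not in cu.columns:
            continue
        keep = (st.exclude_outliers(cu[var].to_numpy())
                & st.exclude_outliers(cu["roi_cbf_nu_te"].to_numpy()))
        sub = cu[keep]
        res = st.partial_pearson(
            sub[var], sub["roi_cbf_nu_te"],
            np.column_stack([sub["age"], (sub["sex"] == "M").astype(float)]),
            variable=var)
        cors.append(res)
    padj = st.bh_fdr([c.p_value for c in cors])
    for c, pa in zip(cors, padj):
        c.p_fdr = float(pa)
    cor_df = pd.DataFrame([c.__dict__ for c in cors])
    cor_df.to_csv(cdir / "correlations.csv", index=False)

    report = {
        "stage": "analyze", "seed": config.seed,
        "config_hash": config.hash(),
        "n_subjects": int(len(df)),
        "contrasts": _plain(contrasts),
        "datadriven_mask_voxels": int(dd_mask.sum()),
        "correlations": _plain([c.__dict__ for c in cors]),
    }
    (cdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def cmd_experiment(config: RunConfig, out_dir) -> dict:
    """simulate -> quantify (all subjects) -> analyze, chained."""
    out = Path(out_dir)
    cmd_simulate(config, out)
    for sdir in sorted(out.glob("sub-*")):
        cmd_quantify(sdir, config)
    return cmd_analyze(out, config)
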