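"""Group statistics: adjusted contrasts, voxelwise GLM, partial correlations.

Implements the statistical layer of the study: ANCOVA-style group contrasts
expressed as covariate-adjusted percent change with 95 % CI, voxelwise OLS
with a group/age/sex design for cluster-extent inference, partial Pearson
correlations (age and sex regressed out) with Benjamini-Hochberg FDR, a
single-pass 3-SD outlier rule, Pearson chi-square for 2x2 tables, and the
amyloid/tau-stage trend analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastResult", "CorrelationResult", "adjusted_percent_change",
    "voxelwise_glm", "partial_pearson", "bh_fdr", "exclude_outliers",
    "chi_square_2x2", "at_stage_trend",
]

AT_STAGES = ("A-T-", "A+T-", "A+T+", "CI")


@dataclass
class ContrastResult:
    """Covariate-adjusted percent change of one group versus the reference."""

    group: str
    reference: str
    percent_change: float
    ci_low: float
    ci_high: float
    p_value: float
    p_fdr: float | None = None
    n: int | None = None


@dataclass
class CorrelationResult:
    """Partial Pearson correlation of one variable with ROI CBF."""

    variable: str
    r: float
    p_value: float
    n: int
    p_fdr: float | None = None


def _design(group: np.ndarray, age: np.ndarray, sex: np.ndarray,
            reference_group: str):
    """Treatment-coded design [1, group dummies, age, sex(male=1)]."""
    group = np.asarray(group)
    levels = [g for g in pd.unique(group) if g != reference_group]
    if reference_group not in group:
        raise ValueError(f"reference group {reference_group!r} not present")
    X = [np.ones(len(group))]
    for g in levels:
        X.append((group == g).astype(float))
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    sex_num = (sex == "M").astype(float) if sex.dtype.kind in "UO" \
        else sex.astype(float)
    X.extend([age, sex_num])
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (e.g. a covariate constant "
                         "within groups or a one-sex group)")
    return X, levels, age, sex_num


def adjusted_percent_change(values, group, age, sex,
                            reference_group: str) -> list[ContrastResult]:
    """Percent change per group versus the reference, adjusted for age/sex.

    Fits ``value ~ group + age + sex`` by OLS.  The percent change of group
    g is ``100 * beta_g / adjusted reference mean`` where the adjusted
    reference mean evaluates the model at the covariate grand means.  The
    95 % CI scales the contrast's standard error by the same reference mean
    (the reference mean's own uncertainty is ignored); p is the two-sided
    contrast t-test.
    """
    values = np.asarray(values, dtype=float)
    counts = pd.Series(group).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 subjects")
    X, levels, age_num, sex_num = _design(np.asarray(group), age, sex,
                                          reference_group)
    fit = sm.OLS(values, X).fit()
    ref_adj = float(fit.params[0] + fit.params[-2] * age_num.mean()
                    + fit.params[-1] * sex_num.mean())
    if ref_adj == 0:
        raise ValueError("adjusted reference mean is zero")
    tcrit = sps.t.ppf(0.975, fit.df_resid)
    out = []
    for i, g in enumerate(levels, start=1):
        beta = fit.params[i]
        se = fit.bse[i]
        pc = 100.0 * beta / ref_adj
        half = 100.0 * tcrit * se / abs(ref_adj)
        out.append(ContrastResult(
            group=str(g), reference=reference_group, percent_change=pc,
            ci_low=pc - half, ci_high=pc + half,
            p_value=float(fit.pvalues[i]),
            n=int(len(values))))
    return out


def voxelwise_glm(maps, group, age, sex, contrast,
                  reference_group: str | None = None):
    """Per-voxel OLS t-map for a group contrast with age/sex regressors.

    ``maps`` is (n_subjects, *grid); ``contrast`` is a vector over the
    design columns [intercept, group dummies..., age, sex].  Returns
    ``(tmap, dof)``; threshold downstream with
    :func:`teasl.quantify.derive_datadriven_mask`.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    grid = maps.shape[1:]
    if reference_group is None:
        reference_group = str(pd.unique(np.asarray(group))[0])
    X, levels, _, _ = _design(np.asarray(group), age, sex, reference_group)
    if len(contrast) != X.shape[1]:
        raise ValueError("contrast length must match %d design columns"
                         % X.shape[1])
    c = np.asarray(contrast, dtype=float)
    Y = maps.reshape(n, -1)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    # voxels whose residual variance is pure roundoff (e.g. constant maps)
    # carry no evidence: their t is defined as 0
    floor = 1e-24 * np.mean(Y**2, axis=0) + 1e-300
    var_c = float(c @ XtX_inv @ c)
    denom = np.sqrt(np.maximum(sigma2 * var_c, 1e-300))
    with np.errstate(invalid="ignore"):
        t = np.where(sigma2 > floor, (c @ beta) / denom, 0.0)
    return t.reshape(grid), dof


def partial_pearson(x, y, covariates=None,
                    variable: str = "") -> CorrelationResult:
    """Pearson correlation of x and y after regressing out covariates.

    Both variables are residualized on ``[1, covariates]`` by least squares;
    p is from ``t = r sqrt((n - 2 - k)/(1 - r^2))`` with k covariates (the
    dof accounts for residualization).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covs = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covs.shape[0] != n:
            covs = covs.T
        Z = np.column_stack([np.ones(n), covs])
        k = Z.shape[1] - 1
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance residuals")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return CorrelationResult(variable=variable, r=r, p_value=p, n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def exclude_outliers(values, n_sd: float = 3.0) -> np.ndarray:
    """Keep-mask of the single-pass mean +/- ``n_sd`` SD rule.

    Mean and SD come from the full sample (one pass, not iterated); a
    zero-SD sample keeps everything.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    sd = v.std()
    if sd == 0:
        return np.ones(v.shape, dtype=bool)
    return np.abs(v - v.mean()) <= n_sd * sd


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def at_stage_trend(values, stage, age, sex,
                   stages: tuple = AT_STAGES) -> list[ContrastResult]:
    """Adjusted percent differences across amyloid/tau stages.

    For every ordered stage pair (earlier stage as reference) the
    age/sex-adjusted percent change is computed, so a monotone injected
    stage effect yields monotone estimates.  All listed stages must be
    present with >= 2 subjects.
    """
    stage = np.asarray(stage)
    present = set(stage)
    missing = [s for s in stages if s not in present]
    if missing:
        raise ValueError(f"missing stage level(s): {missing}")
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    out = []
    for i, ref in enumerate(stages[:-1]):
        keep = np.isin(stage, stages[i:])
        res = adjusted_percent_change(values[keep], stage[keep], age[keep],
                                      sex[keep], reference_group=ref)
        by_group = {c.group: c for c in res}
        for later in stages[i + 1:]:
            out.append(by_group[later])
    return out
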