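"""Single-compartment (Buxton) kinetic model for pCASL.

The general kinetic model (GKM) describes the ASL difference signal dM(t)
produced by a labeling block of duration ``ld`` as delivery of labeled
arterial blood (decaying with blood T1 during transit) convolved with
tissue clearance.  With plug flow, arrival at the arterial transit time
``att``, and an apparent tissue relaxation time T1' given by
``1/T1' = 1/T1_tissue + f/lambda`` (f the perfusion rate in 1/s):

* ``t < att``:              dM = 0
* ``att <= t < att + ld``:  dM = A (1 - exp(-(t - att)/T1'))
* ``t >= att + ld``:        dM = A (1 - exp(-ld/T1')) exp(-(t - att - ld)/T1')

with ``A = 2 alpha_eff M0b f T1' exp(-att/T1_blood)`` and ``M0b = m0/lambda``.

Module contents: the forward model (:func:`gkm_delta_m`,
:func:`schedule_signals`), the consensus single-PLD quantification
(:func:`whitepaper_cbf`), and a bounded least-squares CBF/ATT estimator for
multi-delay (time-encoded) data (:func:`fit_gkm`, :func:`fit_gkm_many`).

The estimator exploits that dM is linear in CBF up to the weak f/lambda
dependence of T1': at fixed ATT the optimal CBF is obtained by a fixed-point
linear solve, and ATT is found by a coarse grid followed by golden-section
refinement of the profiled residual.  This is deterministic,
initialisation-free, and vectorises over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hadamard import SubBolusSchedule

__all__ = [
    "KineticParams",
    "VoxelKinetics",
    "gkm_delta_m",
    "schedule_signals",
    "whitepaper_cbf",
    "fit_gkm",
    "fit_gkm_many",
    "FitResult",
]

CBF_BOUNDS = (0.0, 300.0)
ATT_BOUNDS = (0.1, 3.0)


@dataclass(frozen=True)
class KineticParams:
    """Physiological constants of the kinetic model.

    Defaults follow the ASL consensus recommendations: blood T1 1.65 s at
    3 T, blood-brain partition coefficient 0.9 mL/g, pCASL labeling
    efficiency 0.85.  Background suppression is folded into a single
    multiplicative efficiency (1.0 = none).
    """

    t1_blood_s: float = 1.65
    t1_tissue_s: float = 1.3
    lambda_ml_per_g: float = 0.9
    alpha: float = 0.85
    bs_efficiency: float = 1.0

    def __post_init__(self):
        for name in ("t1_blood_s", "t1_tissue_s", "lambda_ml_per_g", "alpha",
                     "bs_efficiency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha * self.bs_efficiency > 1.0 + 1e-12:
            raise ValueError("alpha * bs_efficiency must not exceed 1")

    @property
    def alpha_eff(self) -> float:
        return self.alpha * self.bs_efficiency

    def to_dict(self) -> dict:
        return {
            "t1_blood_s": self.t1_blood_s,
            "t1_tissue_s": self.t1_tissue_s,
            "lambda_ml_per_g": self.lambda_ml_per_g,
            "alpha": self.alpha,
            "bs_efficiency": self.bs_efficiency,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        return cls(**d)


@dataclass(frozen=True)
class VoxelKinetics:
    """True perfusion state of one voxel."""

    cbf_ml_100g_min: float
    att_s: float
    m0: float

    def __post_init__(self):
        if self.cbf_ml_100g_min < 0:
            raise ValueError("cbf must be non-negative")
        if self.att_s <= 0:
            raise ValueError("att must be positive")


def _t1_apparent(cbf, params: KineticParams):
    f = np.asarray(cbf, dtype=float) / 6000.0
    return 1.0 / (1.0 / params.t1_tissue_s + f / params.lambda_ml_per_g)


def _delta_m(t, cbf, att, m0, ld, params: KineticParams):
    """Piecewise GKM, broadcasting over all array arguments."""
    t = np.asarray(t, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    att = np.asarray(att, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    ld = np.asarray(ld, dtype=float)
    f = cbf / 6000.0
    t1p = _t1_apparent(cbf, params)
    amp = (2.0 * params.alpha_eff * (m0 / params.lambda_ml_per_g) * f * t1p
           * np.exp(-att / params.t1_blood_s))
    dt = t - att
    rising = amp * (1.0 - np.exp(-np.clip(dt, 0.0, None) / t1p))
    decay = amp * (1.0 - np.exp(-ld / t1p)) * np.exp(
        -np.clip(dt - ld, 0.0, None) / t1p)
    out = np.where(dt < 0.0, 0.0, np.where(dt < ld, rising, decay))
    return out


def gkm_delta_m(t_s, kin: VoxelKinetics, ld_s: float,
                params: KineticParams = KineticParams()) -> np.ndarray | float:
    """ASL difference signal at time ``t_s`` after the start of labeling.

    ``t_s`` may be a scalar or array; negative times raise."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since start of labeling must be non-negative")
    out = _delta_m(t, kin.cbf_ml_100g_min, kin.att_s, kin.m0, ld_s, params)
    return float(out) if np.isscalar(t_s) else out


def schedule_signals(schedule: SubBolusSchedule, kin: VoxelKinetics,
                     params: KineticParams = KineticParams()) -> np.ndarray:
    """dM of every sub-bolus at its own readout time (``t = ld + pld``).

    By linearity of the GKM in the labeling function, the sum over
    sub-boluses equals the signal of one continuous bolus with the total
    label duration and the shortest PLD (superposition).
    """
    return _signals_array(schedule, kin.cbf_ml_100g_min, kin.att_s, kin.m0,
                          params)


def _signals_array(schedule: SubBolusSchedule, cbf, att, m0,
                   params: KineticParams) -> np.ndarray:
    """Vectorised :func:`schedule_signals`: broadcasts voxel arrays against
    the sub-bolus axis (last axis of the result)."""
    t = schedule.readout_time_s          # (K,)
    ld = schedule.label_duration_s       # (K,)
    cbf = np.asarray(cbf, dtype=float)[..., None]
    att = np.asarray(att, dtype=float)[..., None]
    m0 = np.asarray(m0, dtype=float)[..., None]
    return _delta_m(t, cbf, att, m0, ld, params)


def whitepaper_cbf(delta_m, m0, pld_s: float, ld_s: float,
                   params: KineticParams = KineticParams()):
    """Consensus ('white paper') single-PLD CBF quantification.

    ``CBF = 6000 lambda dM exp(pld/T1b) / (2 alpha_eff T1b m0 (1 - exp(-ld/T1b)))``

    Assumes the label has fully arrived (att <= pld) and decays with blood
    T1 throughout; linear in dM.  Invalid (m0 <= 0) voxels are the caller's
    responsibility when applied map-wise.
    """
    m0 = np.asarray(m0, dtype=float)
    if np.any(m0 <= 0):
        raise ValueError("m0 must be positive (mask invalid voxels first)")
    t1b = params.t1_blood_s
    num = 6000.0 * params.lambda_ml_per_g * np.asarray(delta_m, float) * np.exp(pld_s / t1b)
    den = 2.0 * params.alpha_eff * t1b * m0 * (1.0 - np.exp(-ld_s / t1b))
    return num / den


def matched_decay_tissue_t1(cbf: float, params: KineticParams) -> float:
    """Tissue T1 for which the apparent T1' equals blood T1 at this CBF.

    In this matched-decay limit (and att <= pld) the white-paper formula
    inverts the GKM exactly.
    """
    f = cbf / 6000.0
    inv = 1.0 / params.t1_blood_s - f / params.lambda_ml_per_g
    if inv <= 0:
        raise ValueError("no positive tissue T1 matches this CBF")
    return 1.0 / inv


@dataclass
class FitResult:
    cbf: np.ndarray
    att: np.ndarray
    residual_ss: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray


def _profile_cbf(signals, att, cbf0, schedule, m0, params, n_iter=4):
    """Optimal CBF at fixed ATT by fixed-point linear projection.

    dM = cbf * u(cbf, att) with u only weakly cbf-dependent (through T1'),
    so iterating cbf <- <s, u>/<u, u> converges in a few steps.
    """
    cbf = np.asarray(cbf0, dtype=float).copy()
    for _ in range(n_iter):
        c_eff = np.maximum(cbf, 1e-6)
        u = _signals_array(schedule, c_eff, att, m0, params) / c_eff[..., None]
        denom = np.einsum("...k,...k->...", u, u)
        num = np.einsum("...k,...k->...", signals, u)
        cbf = np.clip(np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0),
                      *CBF_BOUNDS)
    return cbf


def _profiled_ss(signals, att, cbf0, schedule, m0, params, n_iter=3):
    cbf = _profile_cbf(signals, att, cbf0, schedule, m0, params, n_iter)
    model = _signals_array(schedule, cbf, att, m0, params)
    ss = np.einsum("...k,...k->...", signals - model, signals - model)
    return ss, cbf


def fit_gkm_many(signals, schedule: SubBolusSchedule, m0,
                 params: KineticParams = KineticParams(),
                 att_grid_step: float = 0.1, golden_iters: int = 40) -> FitResult:
    """Bounded least-squares CBF/ATT per voxel, vectorised.

    ``signals`` has shape (..., K) with K = number of sub-boluses; ``m0`` is
    a scalar or array broadcastable to the voxel shape.  CBF is bounded to
    [0, 300] mL/100g/min and ATT to [0.1, 3.0] s.  Deterministic.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != schedule.n_subboluses:
        raise ValueError("signals last axis must match the number of sub-boluses")
    vox_shape = signals.shape[:-1]
    m0 = np.broadcast_to(np.asarray(m0, dtype=float), vox_shape)
    if np.any(m0 <= 0):
        raise ValueError("m0 must be positive for fitting")

    lo, hi = ATT_BOUNDS
    grid = np.arange(lo, hi + 1e-9, att_grid_step)
    # Late arrival censors all but the longest sub-bolus, leaving a
    # zero-residual ridge in (cbf, att); near-ties are broken toward the
    # smallest ATT, which pins that ridge at its physical lower edge.
    ss_tol = 1e-12 * np.einsum("...k,...k->...", signals, signals)
    best_ss = np.full(vox_shape, np.inf)
    best_att = np.full(vox_shape, lo)
    best_cbf = np.full(vox_shape, 50.0)
    cbf0 = np.full(vox_shape, 50.0)
    for a in grid:
        att = np.full(vox_shape, a)
        ss, cbf = _profiled_ss(signals, att, cbf0, schedule, m0, params, n_iter=4)
        better = ss < best_ss - ss_tol
        best_ss = np.where(better, ss, best_ss)
        best_att = np.where(better, a, best_att)
        best_cbf = np.where(better, cbf, best_cbf)

    # golden-section refinement of the profiled objective around the grid
    # minimum (bracket one grid step either side, clipped to bounds)
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a_lo = np.clip(best_att - att_grid_step, lo, hi)
    a_hi = np.clip(best_att + att_grid_step, lo, hi)
    x1 = a_hi - gr * (a_hi - a_lo)
    x2 = a_lo + gr * (a_hi - a_lo)
    f1, _ = _profiled_ss(signals, x1, best_cbf, schedule, m0, params)
    f2, _ = _profiled_ss(signals, x2, best_cbf, schedule, m0, params)
    for _ in range(golden_iters):
        take_left = f1 < f2
        a_hi = np.where(take_left, x2, a_hi)
        a_lo = np.where(take_left, a_lo, x1)
        x1_new = a_hi - gr * (a_hi - a_lo)
        x2_new = a_lo + gr * (a_hi - a_lo)
        f1_new, _ = _profiled_ss(signals, x1_new, best_cbf, schedule, m0, params)
        f2_new, _ = _profiled_ss(signals, x2_new, best_cbf, schedule, m0, params)
        x1, x2, f1, f2 = x1_new, x2_new, f1_new, f2_new
    att_hat = 0.5 * (a_lo + a_hi)

    # final convergence of the inner linear solve at the refined ATT
    cbf_hat = _profile_cbf(signals, att_hat, best_cbf, schedule, m0, params,
                           n_iter=2)
    converged = np.ones(vox_shape, dtype=bool)
    for _ in range(50):
        new = _profile_cbf(signals, att_hat, cbf_hat, schedule, m0, params,
                           n_iter=1)
        delta = np.abs(new - cbf_hat)
        cbf_hat = new
        if np.all(delta < 1e-10):
            break
    else:
        converged = delta < 1e-6

    # keep the grid solution unless refinement strictly improved the
    # objective (same smallest-ATT tie-break as the grid scan)
    model = _signals_array(schedule, cbf_hat, att_hat, m0, params)
    ss_hat = np.einsum("...k,...k->...", signals - model, signals - model)
    worse = ss_hat > best_ss - ss_tol
    cbf_hat = np.where(worse, best_cbf, cbf_hat)
    att_hat = np.where(worse, best_att, att_hat)
    ss_hat = np.where(worse, best_ss, ss_hat)

    degenerate = np.all(np.abs(signals) < 1e-300, axis=-1)
    cbf_hat = np.where(degenerate, 0.0, cbf_hat)
    att_hat = np.where(degenerate, lo, att_hat)
    ss_hat = np.where(degenerate, 0.0, ss_hat)
    converged = converged | degenerate
    return FitResult(cbf=cbf_hat, att=att_hat, residual_ss=ss_hat,
                     converged=converged, degenerate=degenerate)


def fit_gkm(signals, schedule: SubBolusSchedule, m0: float,
            params: KineticParams = KineticParams(), **options):
    """Single-voxel convenience wrapper around :func:`fit_gkm_many`.

    Returns ``(cbf, att, residual_ss, converged)``; the degenerate all-zero
    input yields ``cbf = 0`` with ``att`` at its lower bound.
    """
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    res = fit_gkm_many(np.asarray(signals, float)[None, :], schedule,
                       np.asarray([m0]), params, **options)
    return (float(res.cbf[0]), float(res.att[0]), float(res.residual_ss[0]),
            bool(res.converged[0]))
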