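"""Map estimation, smoothing, normalization, ROI means, cluster masks."""

import numpy as np
import pytest
from dataclasses import replace

from teasl.hadamard import build_scheme
from teasl.kinetics import KineticParams, matched_decay_tissue_t1
from teasl.cohort import (PhantomSpec, CohortConfig, make_phantom,
                          simulate_subject, simulate_cohort)
from teasl.quantify import (fit_maps, single_pld_map, gaussian_smooth,
                            normalize_cerebellum, roi_mean,
                            derive_datadriven_mask, brain_mask_from_m0)


class TestFitMaps:
    def test_noiseless_end_to_end_recovery(self, small_phantom, schedule,
                                           scheme, params):
        sim = simulate_subject(small_phantom, schedule, scheme, params, 0.0)
        maps = fit_maps(sim.series, sim.m0, schedule, scheme, params)
        gm = small_phantom.gm_mask
        rel = np.abs(maps.cbf[gm] - small_phantom.cbf_true[gm]) \
            / small_phantom.cbf_true[gm]
        assert rel.max() < 1e-3
        assert np.abs(maps.att[gm] - small_phantom.att_true[gm]).max() < 1e-3
        # ROI mean reproduces the phantom ROI truth
        assert roi_mean(maps.cbf, small_phantom.ad_mask, maps.valid) == \
            pytest.approx(small_phantom.cbf_true[small_phantom.ad_mask].mean(),
                          rel=1e-3)

    def test_background_invalid(self, small_phantom, schedule, scheme, params):
        sim = simulate_subject(small_phantom, schedule, scheme, params, 0.0)
        maps = fit_maps(sim.series, sim.m0, schedule, scheme, params)
        assert not maps.valid[~small_phantom.brain_mask].any()

    def test_shape_mismatch_rejected(self, small_phantom, schedule, scheme,
                                     params):
        with pytest.raises(ValueError):
            fit_maps(np.zeros((5, 4, 4, 4)), np.ones((4, 4, 4)), schedule,
                     scheme, params)

    def test_att_age_slope_recovered_across_subjects(self, schedule, scheme,
                                                     params):
        # noiseless cohort with ATT = intercept + 0.01 * (age - 70): the ROI
        # ATT from the fitted maps must recover the injected slope
        cfg = CohortConfig(n_per_group=(8, 6, 6), att_noise_sd_s=0.0,
                           att_sex_offset_s=0.0, acquisition_noise_sd=0.0,
                           seed=21)
        ph = make_phantom(PhantomSpec.small(), seed=0)
        subjects, table = simulate_cohort(cfg, ph)
        atts = []
        for s in subjects:
            sim = simulate_subject(s["phantom"], schedule, scheme, params, 0.0)
            maps = fit_maps(sim.series, sim.m0, schedule, scheme, params)
            atts.append(roi_mean(maps.att, ph.ad_mask, maps.valid))
        X = np.column_stack([np.ones(len(atts)), table["age"]])
        slope = np.linalg.lstsq(X, np.array(atts), rcond=None)[0][1]
        assert slope == pytest.approx(0.01, rel=0.05)


class TestSinglePld:
    def test_matched_decay_limit(self, schedule, scheme):
        cbf = 50.0
        p = KineticParams(
            t1_tissue_s=matched_decay_tissue_t1(cbf, KineticParams()))
        spec = PhantomSpec.small(gm_att_s=0.2, wm_att_s=0.2, cereb_att_s=0.2,
                                 wm_cbf=cbf)
        ph = make_phantom(spec, seed=0)
        sim = simulate_subject(ph, schedule, scheme, p, 0.0)
        maps = single_pld_map(sim.series, sim.m0, schedule, scheme, p)
        gm = ph.gm_mask
        rel = np.abs(maps.cbf[gm] - ph.cbf_true[gm]) / ph.cbf_true[gm]
        assert rel.max() < 0.005
        assert maps.att is None

    def test_underestimates_at_long_att(self, schedule, scheme, params):
        ph = make_phantom(PhantomSpec.small(gm_att_s=2.5, wm_att_s=2.5,
                                            cereb_att_s=2.5), seed=0)
        sim = simulate_subject(ph, schedule, scheme, params, 0.0)
        maps = single_pld_map(sim.series, sim.m0, schedule, scheme, params)
        gm = ph.gm_mask
        assert np.all(maps.cbf[gm] < ph.cbf_true[gm])

    def test_zero_series_gives_zero_map(self, small_phantom, schedule, scheme,
                                        params):
        series = np.zeros((8,) + small_phantom.m0.shape)
        maps = single_pld_map(series, small_phantom.m0, schedule, scheme,
                              params)
        assert np.all(maps.cbf == 0.0)

    def test_te_variance_not_larger_under_att_heterogeneity(
            self, schedule, scheme, params):
        # subjects differing only in ATT: the te-ASL ROI estimate must not
        # vary more than the single-PLD one (matched noise-free inputs)
        spec = PhantomSpec.small()
        atts = np.linspace(0.8, 2.2, 24)
        te, sp = [], []
        for i, a in enumerate(atts):
            ph = make_phantom(replace(spec, gm_att_s=float(a)), seed=0)
            sim = simulate_subject(ph, schedule, scheme, params, 0.0)
            m_te = fit_maps(sim.series, sim.m0, schedule, scheme, params)
            m_sp = single_pld_map(sim.series, sim.m0, schedule, scheme, params)
            te.append(roi_mean(m_te.cbf, ph.ad_mask, m_te.valid))
            sp.append(roi_mean(m_sp.cbf, ph.ad_mask, m_sp.valid))
        assert np.var(te) <= np.var(sp)


class TestSmoothing:
    def test_sigma_conversion_and_constant_invariance(self):
        # fwhm 12 mm -> sigma 5.0955 mm
        assert 12.0 / np.sqrt(8 * np.log(2)) == pytest.approx(5.0955, abs=1e-3)
        const = np.full((12, 12, 8), 3.3)
        out = gaussian_smooth(const, 12.0, (2.29, 2.29, 6.0))
        assert np.allclose(out, 3.3)

    def test_impulse_response_fwhm(self):
        vox = 2.0
        grid = np.zeros((41, 41, 41))
        grid[20, 20, 20] = 1.0
        out = gaussian_smooth(grid, 12.0, (vox, vox, vox))
        prof = out[:, 20, 20]
        half = prof.max() / 2
        above = np.where(prof >= half)[0]
        # linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        x_lo = lo - 1 + (half - prof[lo - 1]) / (prof[lo] - prof[lo - 1])
        x_hi = hi + (prof[hi] - half) / (prof[hi] - prof[hi + 1])
        fwhm = (x_hi - x_lo) * vox
        assert fwhm == pytest.approx(12.0, rel=0.05)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4, 4)), -1.0, (1, 1, 1))


class TestNormalizeAndRoi:
    def test_reference_mean_is_one_and_scale_invariance(self, rng):
        m = rng.uniform(10, 100, (8, 8, 4))
        mask = np.zeros_like(m, dtype=bool)
        mask[:4] = True
        out = normalize_cerebellum(m, mask)
        assert out[mask].mean() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(normalize_cerebellum(3.0 * m, mask), out)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            normalize_cerebellum(np.ones((4, 4, 4)),
                                 np.zeros((4, 4, 4), dtype=bool))

    def test_roi_mean_values_and_errors(self):
        m = np.zeros((4, 4, 2))
        m[0] = 2.0
        m[1] = 4.0
        mask = np.zeros_like(m, dtype=bool)
        mask[0] = mask[1] = True
        assert roi_mean(m, mask) == pytest.approx(3.0)
        assert roi_mean(np.full((3, 3, 3), 7.0),
                        np.ones((3, 3, 3), bool)) == 7.0
        with pytest.raises(ValueError):
            roi_mean(m, np.zeros_like(mask))

    def test_brain_mask_needs_positive_m0(self):
        with pytest.raises(ValueError):
            brain_mask_from_m0(np.zeros((4, 4, 4)))


class TestDataDrivenMask:
    DOF = 50

    def _tmap(self, shape=(20, 20, 10)):
        return np.zeros(shape)

    def test_zero_tmap_empty_mask(self):
        mask = derive_datadriven_mask(self._tmap(), self.DOF, 0.001, 100)
        assert not mask.any()

    def test_cluster_extent_boundary(self):
        t = self._tmap()
        t[2:7, 2:7, 2:6] = 10.0          # 5*5*4 = 100 voxels: kept
        t[12:17, 12:17, 2:6] = 10.0
        t[16, 16, 5] = 0.0               # 99 voxels: removed
        mask = derive_datadriven_mask(t, self.DOF, 0.001, 100)
        assert mask[2:7, 2:7, 2:6].all()
        assert not mask[12:17, 12:17, 2:6].any()

    def test_edge_diagonal_connectivity(self):
        # two blobs of 60 voxels touching along an edge diagonal are one
        # cluster under 18-connectivity; touching only at a corner they are
        # separate and both get removed
        t = self._tmap()
        t[2:7, 2:5, 2:6] = 10.0          # 5*3*4 = 60
        t[7:12, 5:8, 2:6] = 10.0         # edge-diagonal neighbour in (x, y)
        mask = derive_datadriven_mask(t, self.DOF, 0.001, 100)
        assert mask.sum() == 120

        t2 = self._tmap()
        t2[2:7, 2:5, 2:6] = 10.0
        t2[7:12, 5:8, 6:10] = 10.0       # corner-diagonal in (x, y, z)
        mask2 = derive_datadriven_mask(t2, self.DOF, 0.001, 100)
        assert not mask2.any()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            derive_datadriven_mask(self._tmap(), self.DOF, 0.0, 100)
        with pytest.raises(ValueError):
            derive_datadriven_mask(self._tmap(), self.DOF, 0.001, 0)
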