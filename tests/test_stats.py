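"""Adjusted contrasts, voxelwise GLM, partial correlations, FDR, outliers."""

import numpy as np
import pytest
from scipy import stats as sps

from teasl.stats import (adjusted_percent_change, voxelwise_glm,
                         partial_pearson, bh_fdr, exclude_outliers,
                         chi_square_2x2, at_stage_trend)


def make_groups(rng, n=(30, 30), labels=("ctrl", "case")):
    group = np.repeat(labels, n)
    age = rng.normal(68, 5, sum(n))
    sex = rng.choice(["F", "M"], sum(n))
    return group, age, sex


class TestAdjustedPercentChange:
    def test_recovers_exact_injected_effect(self, rng):
        # noiseless group means with covariate structure: the adjusted
        # contrast is exact
        group, age, sex = make_groups(rng, (40, 40))
        base = 50.0 + 0.1 * (age - 68)
        values = np.where(group == "case", base * (1 - 0.1803), base)
        res = adjusted_percent_change(values, group, age, sex, "ctrl")
        assert res[0].percent_change == pytest.approx(-18.03, abs=0.5)

    def test_null_case_covers_zero(self, rng):
        hits, covered = 0, 0
        for i in range(100):
            r = np.random.default_rng(1000 + i)
            group, age, sex = make_groups(r, (30, 30))
            values = r.normal(50, 5, 60)
            c = adjusted_percent_change(values, group, age, sex, "ctrl")[0]
            covered += c.ci_low <= 0 <= c.ci_high
            hits += c.p_value < 0.05
        assert covered >= 90
        assert hits <= 12  # ~5% type-I

    def test_confound_removal(self, rng):
        # the case group is older and CBF declines with age: the adjusted
        # contrast must be closer to the injected truth than the raw one
        n = 200
        group = np.repeat(["ctrl", "case"], n)
        age = np.concatenate([rng.normal(65, 3, n), rng.normal(75, 3, n)])
        sex = rng.choice(["F", "M"], 2 * n)
        truth = -0.10
        values = (60.0 - 0.8 * (age - 70)) \
            * np.where(group == "case", 1 + truth, 1.0) \
            + rng.normal(0, 1, 2 * n)
        adj = adjusted_percent_change(values, group, age, sex, "ctrl")[0]
        raw = 100 * (values[group == "case"].mean()
                     / values[group == "ctrl"].mean() - 1)
        assert abs(adj.percent_change - 100 * truth) < abs(raw - 100 * truth)

    def test_singular_design_rejected(self, rng):
        group, age, _ = make_groups(rng, (10, 10))
        sex = np.repeat("F", 20)  # constant: collinear with the intercept
        with pytest.raises(ValueError):
            adjusted_percent_change(np.ones(20), group, age, sex, "ctrl")

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            adjusted_percent_change([1.0, 2.0, 3.0], ["a", "b", "b"],
                                    [60, 61, 62], ["F", "M", "F"], "a")


class TestVoxelwiseGlm:
    def test_constant_maps_zero_t(self, rng):
        group, age, sex = make_groups(rng, (15, 15))
        maps = np.ones((30, 6, 6, 4))
        t, dof = voxelwise_glm(maps, group, age, sex, [0, 1, 0, 0], "ctrl")
        assert np.all(t == 0.0)
        assert dof == 30 - 4

    def test_null_type_i_rate(self, rng):
        group, age, sex = make_groups(rng, (30, 29))
        maps = rng.normal(0, 1, (59, 40, 30, 25))
        t, dof = voxelwise_glm(maps, group, age, sex, [0, 1, 0, 0], "ctrl")
        p = sps.t.sf(t, dof)
        rate = (p < 0.001).mean()
        n_vox = t.size
        se = np.sqrt(0.001 * 0.999 / n_vox)
        assert abs(rate - 0.001) < 4 * se

    def test_localized_effect_found(self, rng):
        group, age, sex = make_groups(rng, (25, 25))
        maps = rng.normal(50, 1, (50, 16, 16, 8))
        region = np.zeros((16, 16, 8), bool)
        region[4:10, 4:10, 2:6] = True
        maps[group == "case"] -= 5.0 * region
        t, dof = voxelwise_glm(maps, group, age, sex, [0, -1, 0, 0], "ctrl")
        from teasl.quantify import derive_datadriven_mask
        mask = derive_datadriven_mask(t, dof, 0.001, 10)
        dice = 2 * (mask & region).sum() / (mask.sum() + region.sum())
        assert dice > 0.5

    def test_rank_deficient_rejected(self, rng):
        group = np.repeat(["a", "b"], 10)
        age = np.ones(20)  # constant age: collinear with the intercept
        sex = np.tile(["F", "M"], 10)
        with pytest.raises(ValueError):
            voxelwise_glm(np.zeros((20, 2, 2, 2)), group, age, sex,
                          [0, 1, 0, 0], "a")


class TestPartialPearson:
    def test_identity_gives_r_one(self, rng):
        x = rng.normal(size=30)
        res = partial_pearson(x, x)
        assert res.r == pytest.approx(1.0)

    def test_null_p_uniform(self):
        ps = []
        for i in range(1000):
            r = np.random.default_rng(5000 + i)
            x, y = r.normal(size=(2, 30))
            covs = r.normal(size=(30, 2))
            ps.append(partial_pearson(x, y, covs).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_shared_confounder_removed(self):
        rs = []
        for i in range(50):
            r = np.random.default_rng(7000 + i)
            age = r.normal(70, 5, 200)
            x = 2 * age + r.normal(0, 5, 200)
            y = -3 * age + r.normal(0, 5, 200)
            rs.append(partial_pearson(x, y, age[:, None]).r)
        assert abs(np.mean(rs)) < 0.03

    def test_dof_adjustment(self, rng):
        # with k covariates the same residual r must give a larger p than
        # the naive n-2 dof would
        x = rng.normal(size=12)
        y = x + rng.normal(0, 2, 12)
        covs = rng.normal(size=(12, 5))
        res = partial_pearson(x, y, covs)
        t_naive = res.r * np.sqrt((12 - 2) / (1 - res.r**2))
        p_naive = 2 * sps.t.sf(abs(t_naive), 12 - 2)
        assert res.p_value > p_naive

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            partial_pearson(np.ones(10), rng.normal(size=10))
        with pytest.raises(ValueError):
            partial_pearson(np.arange(4.0), np.arange(4.0),
                            rng.normal(size=(4, 2)))


def bh_bruteforce(p):
    """Independent step-up oracle straight from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_equals_bruteforce_on_random_vectors(self):
        for i in range(1000):
            r = np.random.default_rng(9000 + i)
            p = r.uniform(size=r.integers(1, 40))
            assert np.allclose(bh_fdr(p), bh_bruteforce(p), atol=1e-12)

    def test_known_example_and_properties(self, rng):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestExcludeOutliers:
    def test_normal_tail_mass(self, rng):
        v = rng.standard_normal(100000)
        frac_excluded = 1.0 - exclude_outliers(v).mean()
        assert 0.002 < frac_excluded < 0.0035  # ~0.27%

    def test_spike_excluded_constant_kept(self, rng):
        v = np.append(rng.standard_normal(100), 10.0)
        assert not exclude_outliers(v)[-1]
        assert exclude_outliers(np.full(10, 3.3)).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            exclude_outliers([1.0, 2.0])


def hypergeom_exact_p(table):
    """Two-sided conditional exact p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n1, n2, m = a + b, c + d, a + c
    probs = []
    for x in range(max(0, m - n2), min(n1, m) + 1):
        probs.append((x, sps.hypergeom.pmf(x, n1 + n2, n1, m)))
    p_obs = sps.hypergeom.pmf(a, n1 + n2, n1, m)
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-9))


class TestChiSquare:
    def test_study_demographics_table(self):
        # females: 15/18 CU Abeta+ vs 8/17 CI Abeta+
        stat, p = chi_square_2x2([[15, 3], [8, 9]])
        assert p == pytest.approx(0.024, abs=1e-3)

    def test_proportional_table_null(self):
        stat, p = chi_square_2x2([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_against_exact_enumeration(self):
        # tau positivity 9/17 CU Abeta+ vs 16/17 CI Abeta+: the asymptotic p
        # tracks the exact conditional p at this sample size
        table = [[9, 8], [16, 1]]
        _, p = chi_square_2x2(table)
        p_exact = hypergeom_exact_p(table)
        assert p < 0.05 and p_exact < 0.05
        assert abs(p - p_exact) < 0.05

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 3]])


class TestAtStageTrend:
    def _cohort(self, rng, effects):
        stages = np.repeat(["A-T-", "A+T-", "A+T+", "CI"], 25)
        age = rng.normal(68, 4, 100)
        sex = rng.choice(["F", "M"], 100)
        mult = np.array([1 + effects[s] for s in stages])
        values = 50.0 * mult
        return values, stages, age, sex

    def test_monotone_effects_recovered_in_order(self, rng):
        eff = {"A-T-": 0.0, "A+T-": -0.05, "A+T+": -0.10, "CI": -0.18}
        values, stages, age, sex = self._cohort(rng, eff)
        res = at_stage_trend(values, stages, age, sex)
        vs_ref = [c.percent_change for c in res if c.reference == "A-T-"]
        assert vs_ref == sorted(vs_ref, reverse=True)
        assert vs_ref[0] == pytest.approx(-5.0, abs=0.5)
        assert vs_ref[-1] == pytest.approx(-18.0, abs=0.5)

    def test_identical_stages_near_zero(self, rng):
        eff = dict.fromkeys(["A-T-", "A+T-", "A+T+", "CI"], 0.0)
        values, stages, age, sex = self._cohort(rng, eff)
        values = values + rng.normal(0, 0.01, 100)
        res = at_stage_trend(values, stages, age, sex)
        assert all(abs(c.percent_change) < 0.1 for c in res)

    def test_missing_stage_rejected(self, rng):
        stages = np.repeat(["A-T-", "A+T-", "CI"], 10)
        with pytest.raises(ValueError):
            at_stage_trend(np.ones(30), stages, rng.normal(68, 4, 30),
                           rng.choice(["F", "M"], 30))
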