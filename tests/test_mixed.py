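import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from famprs.mixed import (
    bootstrap_ci,
    compute_grm,
    fast_assoc_many,
    fit_lmm_quant,
    fit_logistic_mixed,
    permutation_p,
    prune_ld,
)
from famprs.panels import DosagePanel
from famprs.simulate import SimulationConfig, simulate_founders, simulate_family_cohort


def panel_of(dosages):
    d = np.asarray(dosages, dtype=float)
    m = d.shape[1]
    variants = pd.DataFrame(
        {"SNP": [f"rs{i}" for i in range(m)], "CHR": 1, "BP": np.arange(m) + 1,
         "A1": "A", "A2": "G"}
    )
    return DosagePanel([f"s{i}" for i in range(d.shape[0])], variants, d)


class TestPruneLd:
    def test_perfect_pair_one_kept(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 100).astype(float)
        panel = panel_of(np.column_stack([a, a, rng.integers(0, 3, 100)]))
        out = prune_ld(panel, window=10, step=1, r2_max=0.99)
        assert out.n_variants == 2
        assert "rs0" in out.variant_ids and "rs1" not in out.variant_ids

    def test_independent_variants_survive(self, effect_panel):
        panel = simulate_founders(500, effect_panel, seed=1)
        out = prune_ld(panel, r2_max=0.5)
        assert out.n_variants / panel.n_variants > 0.9
        d = out.dosages
        r = np.corrcoef(d.T)
        np.fill_diagonal(r, 0.0)
        # exhaustive post-check within the pruning window
        for j in range(out.n_variants):
            lo, hi = max(0, j - 50), min(out.n_variants, j + 50)
            assert (r[j, lo:hi] ** 2 <= 0.5 + 1e-9).all()

    def test_r2_one_is_identity_up_to_monomorphic(self):
        d = np.column_stack(
            [np.zeros(30), np.random.default_rng(1).integers(0, 3, 30)]
        )
        out = prune_ld(panel_of(d), r2_max=1.0)
        assert out.variant_ids == ["rs1"]


class TestGrm:
    def test_duplicate_subject_identity_by_state(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, (5, 50)).astype(float)
        d = np.vstack([base, base[0]])
        grm = compute_grm(panel_of(d), ridge=0.0)
        k = grm.matrix
        assert k[0, 5] == pytest.approx(k[0, 0], abs=1e-6)
        assert k[0, 5] == pytest.approx(k[5, 5], abs=1e-6)

    def test_unrelated_off_diagonal_near_zero(self, effect_panel):
        n = 200
        panel = simulate_founders(n, effect_panel, seed=3)
        k = compute_grm(panel).matrix
        off = k[np.triu_indices_from(k, 1)]
        # sample-frequency centring makes each row sum to ~0, so the
        # off-diagonal mean is -diag/(n-1) rather than exactly 0
        expected = -np.diag(k).mean() / (n - 1)
        se = off.std(ddof=1) / np.sqrt(off.size)
        assert abs(off.mean() - expected) < 4 * se + 1e-4

    def test_symmetric_and_psd(self, effect_panel):
        panel = simulate_founders(50, effect_panel, seed=4)
        k = compute_grm(panel).matrix
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() > -1e-8

    def test_subject_permutation_equivariance(self, effect_panel):
        panel = simulate_founders(20, effect_panel, seed=5)
        k1 = compute_grm(panel).matrix
        perm = np.random.default_rng(0).permutation(20)
        shuffled = panel.subset_subjects([panel.subjects[i] for i in perm])
        k2 = compute_grm(shuffled).matrix
        assert np.allclose(k2, k1[np.ix_(perm, perm)])

    def test_no_polymorphic_errors(self):
        with pytest.raises(ValueError):
            compute_grm(panel_of(np.zeros((5, 3))))

    def test_parent_offspring_half(self):
        cfg = SimulationConfig(n_variants=500, n_families=100,
                               generations_per_family=2, seed=0)
        from famprs.simulate import make_effect_panel

        fx = make_effect_panel(cfg, seed=0)
        cohort, panel = simulate_family_cohort(cfg, fx, seed=0)
        grm = compute_grm(panel)
        pos = {s: i for i, s in enumerate(grm.subjects)}
        vals = [
            grm.matrix[pos[r["iid"]], pos[r["father"]]]
            for _, r in cohort.table.iterrows()
            if r["father"] != "0"
        ]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert len(vals) >= 100
        assert abs(vals.mean() - 0.5) < 4 * se


class TestLogisticMixed:
    def test_glm_oracle_at_zero_variance(self):
        rng = np.random.default_rng(1)
        n = 300
        z = rng.standard_normal(n)
        sex = rng.integers(0, 2, n).astype(float)
        eta = -0.3 + 0.6 * z + 0.2 * sex
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = fit_logistic_mixed(y, z, sex, np.eye(n), sigma2=0.0)
        x = np.column_stack([np.ones(n), z, sex])
        glm = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        assert res.beta == pytest.approx(glm.params[1], rel=1e-6)
        assert res.se == pytest.approx(glm.bse[1], rel=1e-6)

    def test_zero_effect_gives_half_p(self):
        # symmetric outcome with z exactly orthogonal to y
        y = np.array([0.0, 1.0] * 20)
        z = np.tile([1.0, 1.0, -1.0, -1.0], 10)
        res = fit_logistic_mixed(y, z, None, np.eye(40), sigma2=0.0)
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.p_one_sided == pytest.approx(0.5, abs=1e-6)

    def test_one_sided_is_half_two_sided_in_direction(self):
        rng = np.random.default_rng(2)
        n = 200
        z = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(float)
        res = fit_logistic_mixed(y, z, None, np.eye(n), sigma2=0.0)
        assert res.beta > 0
        assert res.p_one_sided == pytest.approx(res.p_two_sided / 2)

    def test_ci_brackets_or(self):
        rng = np.random.default_rng(3)
        n = 150
        z = rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(float)
        res = fit_logistic_mixed(y, z, None, np.eye(n), sigma2=0.0)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_mixed(np.ones(10), np.arange(10.0), None, np.eye(10))

    def test_separation_detected(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        z = np.array([-1.0] * 10 + [1.0] * 10)
        with pytest.raises(ValueError, match="separation"):
            fit_logistic_mixed(y, z, None, np.eye(20), sigma2=0.0)


class TestLmmQuant:
    def test_ols_oracle_at_zero_variance(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.standard_normal(n)
        cov = rng.standard_normal(n)
        y = 1.0 + 0.5 * x - 0.3 * cov + rng.standard_normal(n)
        res = fit_lmm_quant(y, x, cov, np.eye(n), fix_zero_variance=True)
        ols = sm.OLS(y, np.column_stack([np.ones(n), x, cov])).fit()
        assert res.beta == pytest.approx(ols.params[1], rel=1e-6)
        assert res.se == pytest.approx(ols.bse[1], rel=1e-6)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        n = 80
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        k = np.eye(n)
        a = fit_lmm_quant(y, x, None, k, fix_zero_variance=True)
        b = fit_lmm_quant(y + 100.0, x, None, k, fix_zero_variance=True)
        assert a.beta == pytest.approx(b.beta, rel=1e-9)

    def test_reml_recovers_family_variance(self, family_cohort, effect_panel):
        cohort, panel = family_cohort
        grm = compute_grm(panel)
        rng = np.random.default_rng(6)
        g = cohort.table["gscore_BD"].to_numpy()
        y = g + 0.5 * rng.standard_normal(len(g))
        x = rng.standard_normal(len(g))
        res = fit_lmm_quant(y, x, None, grm.aligned(cohort.subjects))
        assert res.sigma2_g > 0.2  # genetic signal detected

    def test_extra_random_effect_accepted(self, family_cohort):
        cohort, panel = family_cohort
        grm = compute_grm(panel)
        rng = np.random.default_rng(7)
        n = len(cohort.table)
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
        groups = cohort.table["married_in"].to_numpy().astype(int)
        res = fit_lmm_quant(y, x, None, grm.matrix, extra_re=groups)
        assert np.isfinite(res.beta)


class TestPermutation:
    @staticmethod
    def _fit_factory(x):
        def fit(y):
            n = len(y)
            ols = sm.OLS(y, np.column_stack([np.ones(n), x])).fit()
            return float(ols.pvalues[1])

        return fit

    def test_boundary_below_resolution(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.standard_normal(n)
        y = 3.0 * x + 0.1 * rng.standard_normal(n)  # overwhelming signal
        fit = self._fit_factory(x)
        p, count = permutation_p(fit, y, fit(y), n_perm=50, seed=1)
        assert count == 0
        assert p < 1 / 50

    def test_determinism(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        fit = self._fit_factory(x)
        p1 = permutation_p(fit, y, fit(y), n_perm=4, seed=7)
        p2 = permutation_p(fit, y, fit(y), n_perm=4, seed=7)
        assert p1 == p2

    def test_null_uniformity(self):
        rng = np.random.default_rng(10)
        n = 40
        ps = []
        for _ in range(60):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            fit = self._fit_factory(x)
            ps.append(permutation_p(fit, y, fit(y), n_perm=99, seed=3)[0])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestBootstrap:
    @staticmethod
    def _beta_fn(x, y):
        def fit(idx):
            ols = sm.OLS(
                y[idx], np.column_stack([np.ones(len(idx)), x[idx]])
            ).fit()
            return float(ols.params[1])

        return fit

    def test_determinism(self):
        rng = np.random.default_rng(11)
        n = 60
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        fams = np.repeat(np.arange(10), 6)
        fit = self._beta_fn(x, y)
        assert bootstrap_ci(fit, fams, 100, seed=5) == bootstrap_ci(
            fit, fams, 100, seed=5
        )

    def test_interval_contains_estimate(self):
        rng = np.random.default_rng(12)
        hits = 0
        for rep in range(20):
            n = 80
            x = rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n)
            fams = np.repeat(np.arange(16), 5)
            fit = self._beta_fn(x, y)
            lo, hi = bootstrap_ci(fit, fams, 200, seed=rep)
            est = fit(np.arange(n))
            hits += lo <= est <= hi
        assert hits >= 19

    def test_interval_shrinks_with_noise(self):
        rng = np.random.default_rng(13)
        n = 100
        x = rng.standard_normal(n)
        fams = np.repeat(np.arange(20), 5)
        widths = []
        for noise in (1.0, 0.01):
            y = 0.5 * x + noise * rng.standard_normal(n)
            lo, hi = bootstrap_ci(self._beta_fn(x, y), fams, 200, seed=1)
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 5


class TestFastAssoc:
    def test_matches_fixed_variance_wald(self):
        rng = np.random.default_rng(14)
        n = 100
        y = rng.standard_normal(n)
        scores = rng.standard_normal((n, 5))
        p = fast_assoc_many(y, None, np.eye(n), scores)
        assert p.shape == (5,)
        assert ((p > 0) & (p < 1)).all()

    def test_detects_signal(self):
        rng = np.random.default_rng(15)
        n = 200
        s = rng.standard_normal(n)
        y = s + 0.5 * rng.standard_normal(n)
        noise = rng.standard_normal((n, 3))
        p = fast_assoc_many(y, None, np.eye(n), np.column_stack([s, noise]))
        assert p[0] < 1e-6
        assert (p[1:] > 1e-3).all()
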