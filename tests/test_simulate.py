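import numpy as np
import pandas as pd
import pytest

from famprs.panels import PedigreeCohort, PHENO_COLUMNS
from famprs.simulate import (
    DISORDERS,
    SimulationConfig,
    TrueEffectPanel,
    ascertain_multiplex,
    assign_phenotypes,
    gene_drop,
    make_effect_panel,
    simulate_family_cohort,
    simulate_founders,
    simulate_sumstats,
)


def panel_with_mafs(mafs):
    m = len(mafs)
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(m)],
            "CHR": 1,
            "BP": np.arange(m) + 1,
            "A1": "A",
            "A2": "G",
            "MAF": mafs,
        }
    )
    betas = np.zeros((m, len(DISORDERS)))
    return TrueEffectPanel(variants, betas, np.ones_like(betas, dtype=bool))


def trivial_pedigree(rows):
    df = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother"]
    )
    for col, val in [
        ("sex", 1), ("diagnosis", "unaffected"), ("cohort", "FAM"),
        ("generation", 0), ("married_in", False),
        ("age_interview", 40.0), ("age_onset", np.nan),
    ]:
        df[col] = val
    return PedigreeCohort(df[PHENO_COLUMNS])


class TestConfig:
    def test_asymmetric_correlation_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            SimulationConfig(genetic_correlation=bad)

    def test_non_psd_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimulationConfig(genetic_correlation=bad)

    def test_neg_control_uncorrelated_by_default(self):
        cfg = SimulationConfig()
        i = DISORDERS.index("NEG")
        off = np.delete(cfg.genetic_correlation[i], i)
        assert np.allclose(off, 0.0)

    def test_bad_prevalence(self):
        with pytest.raises(ValueError):
            SimulationConfig(prevalence={"BD": 0.0, "SCZ": 0.1, "MDD": 0.1, "NEG": 0.1})


class TestFounders:
    def test_maf_zero_all_zero(self):
        p = simulate_founders(50, panel_with_mafs([1e-12]), seed=1)
        # effectively fixed: frequency ~0 gives all-zero dosage
        assert (p.dosages == 0).all()

    def test_degenerate_frequencies_exact(self):
        # the generator draws two Bernoulli(p) alleles; at p=0/1 the outcome
        # is deterministic, here exercised through an explicit panel
        panel = panel_with_mafs([0.0, 1.0])
        out = simulate_founders(30, panel, seed=2)
        assert (out.dosages[:, 0] == 0).all()
        assert (out.dosages[:, 1] == 2).all()

    def test_binomial_mean(self):
        n = 2000
        p = simulate_founders(n, panel_with_mafs([0.5]), seed=3)
        se = np.sqrt(0.5 / n)  # SD of mean dosage = sqrt(2 p q / n)
        assert abs(p.dosages[:, 0].mean() - 1.0) < 4 * se

    def test_nonfinite_maf_rejected(self):
        with pytest.raises(ValueError):
            simulate_founders(5, panel_with_mafs([np.nan]), seed=1)


class TestGeneDrop:
    def test_mendelian_constraints(self):
        ped = trivial_pedigree(
            [
                ("f1", "pa", "0", "0"),
                ("f1", "ma", "0", "0"),
                ("f1", "kid", "pa", "ma"),
            ]
        )
        founders = panel_with_mafs([0.5, 0.5])
        fpanel = simulate_founders(2, founders, seed=4)
        fpanel.subjects = ["pa", "ma"]
        # force homozygous patterns: pa = {0, 2}, ma = {0, 0}
        fpanel.haplotypes = np.array(
            [[[0, 0], [1, 1]], [[0, 0], [0, 0]]], dtype=np.int8
        )
        fpanel.dosages = fpanel.haplotypes.sum(axis=2).astype(float)
        out = gene_drop(ped, fpanel, seed=5)
        kid = out.dosages[out.subjects.index("kid")]
        assert kid[0] == 0.0  # both parents 0
        assert kid[1] == 1.0  # parents 2 and 0

    def test_transmission_frequency(self):
        # one heterozygous father, many children: allele passed ~ Bernoulli(1/2)
        n_kids = 10_000
        rows = [("f1", "pa", "0", "0"), ("f1", "ma", "0", "0")]
        rows += [("f1", f"k{i}", "pa", "ma") for i in range(n_kids)]
        ped = trivial_pedigree(rows)
        fpanel = simulate_founders(2, panel_with_mafs([0.5]), seed=6)
        fpanel.subjects = ["pa", "ma"]
        fpanel.haplotypes = np.array([[[1, 0]], [[0, 0]]], dtype=np.int8)
        fpanel.dosages = fpanel.haplotypes.sum(axis=2).astype(float)
        out = gene_drop(ped, fpanel, seed=7)
        kids = [s for s in out.subjects if s.startswith("k")]
        freq = out.dosages[out.subject_index(kids), 0].mean()
        se = np.sqrt(0.25 / n_kids)
        assert abs(freq - 0.5) < 4 * se

    def test_missing_parent_named(self):
        ped = trivial_pedigree(
            [("f1", "pa", "0", "0"), ("f1", "kid", "pa", "ghost")]
        )
        fpanel = simulate_founders(1, panel_with_mafs([0.5]), seed=8)
        fpanel.subjects = ["pa"]
        with pytest.raises(ValueError, match="kid"):
            gene_drop(ped, fpanel, seed=9)

    def test_no_drift_over_one_generation(self, effect_panel):
        cfg = SimulationConfig(n_variants=200, n_families=150,
                               generations_per_family=2, seed=0)
        cohort, panel = simulate_family_cohort(cfg, effect_panel, seed=0)
        kids = cohort.table["father"] != "0"
        kid_freq = panel.dosages[kids.to_numpy()].mean(axis=0) / 2
        diffs = kid_freq - effect_panel.mafs
        # across variants, no systematic shift
        assert abs(diffs.mean()) < 4 * diffs.std(ddof=1) / np.sqrt(len(diffs))


class TestPhenotypes:
    def test_h2_one_is_deterministic(self):
        cfg = SimulationConfig(
            h2={"BD": 1.0, "SCZ": 1.0, "MDD": 1.0, "NEG": 1.0},
            prevalence={"BD": 0.2, "SCZ": 0.05, "MDD": 0.3, "NEG": 0.05},
        )
        fx = make_effect_panel(cfg, seed=1)
        panel = simulate_founders(300, fx, seed=1)
        cohort = assign_phenotypes(panel, fx, cfg, seed=2)
        from scipy.stats import norm

        t_bd = norm.isf(0.2)
        g = fx.genetic_score(panel.dosages, "BD")
        assert (cohort.table.loc[g > t_bd, "diagnosis"] == "BD").all()

    def test_prevalence_recovered(self):
        cfg = SimulationConfig(n_variants=100, prevalence={
            "BD": 0.05, "SCZ": 0.05, "MDD": 0.2, "NEG": 0.05})
        fx = make_effect_panel(cfg, seed=3)
        n = 20_000
        panel = simulate_founders(n, fx, seed=3)
        cohort = assign_phenotypes(panel, fx, cfg, seed=4)
        frac = (cohort.table["diagnosis"] == "BD").mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 4 * se

    def test_bd_precedence_over_mdd(self, effect_panel, small_config):
        panel = simulate_founders(2000, effect_panel, seed=5)
        cohort = assign_phenotypes(panel, effect_panel, small_config, seed=5)
        from scipy.stats import norm

        t = cohort.table
        t_bd = norm.isf(small_config.prevalence["BD"])
        above_bd = t["liab_BD"] > t_bd
        assert (t.loc[above_bd, "diagnosis"] == "BD").all()
        assert not (t.loc[~above_bd, "diagnosis"] == "BD").any()

    def test_effect_correlation_matches_config(self):
        cfg = SimulationConfig(n_variants=5000)
        fx = make_effect_panel(cfg, seed=9)
        i, j = DISORDERS.index("BD"), DISORDERS.index("SCZ")
        r = np.corrcoef(fx.betas[:, i], fx.betas[:, j])[0, 1]
        se = (1 - 0.6**2) / np.sqrt(5000)
        assert abs(r - 0.6) < 4 * se


class TestAscertainment:
    def test_family_without_cases_removed(self, family_cohort):
        cohort, _ = family_cohort
        asc = ascertain_multiplex(cohort, 2)
        counts = asc.table.groupby("fid")["diagnosis"].apply(
            lambda s: (s == "BD").sum()
        )
        assert (counts >= 2).all()

    def test_zero_is_identity(self, family_cohort):
        cohort, _ = family_cohort
        out = ascertain_multiplex(cohort, 0)
        pd.testing.assert_frame_equal(out.table, cohort.table)

    def test_negative_rejected(self, family_cohort):
        with pytest.raises(ValueError):
            ascertain_multiplex(family_cohort[0], -1)

    def test_enrichment_of_genetic_score(self):
        # ascertained families carry higher mean true BD genetic score
        cfg = SimulationConfig(
            n_variants=150, n_families=40, assortative_mating_strength=0.5, seed=0
        )
        fx = make_effect_panel(cfg, seed=0)
        deltas = []
        for rep in range(25):
            cohort, _ = simulate_family_cohort(cfg, fx, seed=100 + rep)
            asc = ascertain_multiplex(cohort, 3)
            if len(asc) == 0:
                continue
            deltas.append(
                asc.table["gscore_BD"].mean() - cohort.table["gscore_BD"].mean()
            )
        assert np.mean(deltas) > 0

    def test_married_in_marked(self, family_cohort):
        cohort, _ = family_cohort
        mi = cohort.table[cohort.table["married_in"]]
        assert (mi["father"] == "0").all()
        assert (mi["generation"] > 0).all()


class TestSumstats:
    def test_null_p_uniform(self):
        panel = panel_with_mafs(np.random.default_rng(0).uniform(0.05, 0.5, 10_000))
        ss = simulate_sumstats(panel, "BD", 10_000, seed=11)
        frac = (ss.df["P"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(frac - 0.05) < 4 * se

    def test_se_scaling(self):
        panel = panel_with_mafs([0.3, 0.4])
        a = simulate_sumstats(panel, "BD", 10_000, seed=1)
        b = simulate_sumstats(panel, "BD", 40_000, seed=1)
        assert np.allclose(a.df["SE"], 2 * b.df["SE"])

    def test_se_closed_form(self):
        panel = panel_with_mafs([0.5])
        ss = simulate_sumstats(panel, "BD", 20_000, seed=1)
        assert ss.df["SE"].iloc[0] == pytest.approx(0.01)  # 1/sqrt(2*0.25*20000)

    def test_monomorphic_flagged(self):
        panel = panel_with_mafs([0.0, 0.3])
        ss = simulate_sumstats(panel, "BD", 10_000, seed=1)
        row = ss.df.iloc[0]
        assert row["FLAGGED"]
        assert np.isnan(row["BETA"]) and np.isnan(row["SE"]) and np.isnan(row["P"])

    def test_gwas_n_positive(self):
        with pytest.raises(ValueError):
            simulate_sumstats(panel_with_mafs([0.5]), "BD", 0, seed=1)


class TestAssortativeMating:
    def test_spouse_score_correlation(self):
        cfg = SimulationConfig(
            n_variants=150, n_families=120, generations_per_family=3,
            assortative_mating_strength=0.7, seed=0,
        )
        fx = make_effect_panel(cfg, seed=0)
        cohort, panel = simulate_family_cohort(cfg, fx, seed=0)
        t = cohort.table.set_index("iid")
        pairs = []
        non_founder = cohort.table[cohort.table["father"] != "0"]
        for _, row in non_founder.iterrows():
            pa, ma = row["father"], row["mother"]
            pairs.append((t.loc[pa, "gscore_BD"], t.loc[ma, "gscore_BD"]))
        pairs = pd.DataFrame(set(pairs))
        r = pairs.corr(method="spearman").iloc[0, 1]
        assert r > 0.3  # clearly positive under strength 0.7

    def test_random_mating_uncorrelated(self):
        cfg = SimulationConfig(
            n_variants=150, n_families=120, generations_per_family=3,
            assortative_mating_strength=0.0, seed=0,
        )
        fx = make_effect_panel(cfg, seed=0)
        cohort, _ = simulate_family_cohort(cfg, fx, seed=0)
        t = cohort.table.set_index("iid")
        non_founder = cohort.table[cohort.table["father"] != "0"]
        pairs = {
            (t.loc[r["father"], "gscore_BD"], t.loc[r["mother"], "gscore_BD"])
            for _, r in non_founder.iterrows()
        }
        pairs = pd.DataFrame(list(pairs))
        r = pairs.corr().iloc[0, 1]
        assert abs(r) < 4 / np.sqrt(len(pairs))


class TestDeterminism:
    def test_same_seed_same_cohort(self, small_config, effect_panel):
        a, pa = simulate_family_cohort(small_config, effect_panel, seed=77)
        b, pb = simulate_family_cohort(small_config, effect_panel, seed=77)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(pa.dosages, pb.dosages)
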