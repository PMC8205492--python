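import numpy as np
import pandas as pd
import pytest
from scipy import stats

from postgwas.ldpanel import LDPanel
from postgwas.simulate import (
    SimConfig, compute_sumstats, implied_genotype_r, load_truth,
    make_paired_studies, save_truth, simulate_genotypes, simulate_trait,
)
from postgwas.sumstats import apply_variant_qc, genomic_inflation
from postgwas.coloc import coloc_posteriors, harmonise_pair


class TestConfig:
    def test_variance_budget_enforced(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            SimConfig(causal={0: 0.7, 1: 0.6})

    def test_causal_index_bounds(self):
        with pytest.raises(ValueError, match="out of range"):
            SimConfig(n_variants=10, causal={10: 0.1}).causal_effects()

    def test_effects_merge_both_parameterisations(self):
        cfg = SimConfig(causal={0: 0.04}, causal_beta={1: -0.3})
        eff = cfg.causal_effects()
        assert eff[0] == pytest.approx(0.2)
        assert eff[1] == pytest.approx(-0.3)


class TestGenotypes:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_samples=500, n_variants=40, seed=12)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert set(np.unique(a.dosages)) <= {0.0, 1.0, 2.0}

    def test_null_ld_between_blocks(self):
        cfg = SimConfig(n_samples=5000, n_variants=100, blocks=[(1, 0.0)], seed=13)
        G = simulate_genotypes(cfg).dosages.astype(float)
        Gc = (G - G.mean(0)) / G.std(0)
        R = (Gc.T @ Gc) / 5000
        off = R[np.triu_indices(100, k=1)]
        assert np.mean(np.abs(off) < 0.05) >= 0.99

    def test_adjacent_ld_matches_orthant_oracle(self):
        cfg = SimConfig(n_samples=5000, n_variants=10, blocks=[(10, 0.95)], seed=14)
        panel = simulate_genotypes(cfg)
        f = panel.eaf()
        # target MAFs are recoverable only approximately; use realised ones
        G = panel.dosages.astype(float)
        for j in range(5):
            emp = np.corrcoef(G[:, j], G[:, j + 1])[0, 1]
            implied = implied_genotype_r(min(f[j], 1 - f[j]),
                                         min(f[j + 1], 1 - f[j + 1]), 0.95)
            assert emp == pytest.approx(implied, abs=0.1)

    def test_realised_frequency_tracks_target(self):
        cfg = SimConfig(n_samples=10000, n_variants=50, maf_range=(0.2, 0.4), seed=15)
        panel = simulate_genotypes(cfg)
        assert np.all(panel.eaf() > 0.15) and np.all(panel.eaf() < 0.45)

    def test_hardy_weinberg_heterozygosity(self):
        cfg = SimConfig(n_samples=20000, n_variants=20, maf_range=(0.3, 0.3001), seed=16)
        panel = simulate_genotypes(cfg)
        het = (panel.dosages == 1).mean(axis=0)
        np.testing.assert_allclose(het, 2 * 0.3 * 0.7, atol=0.02)


@pytest.fixture(scope="module")
def panel10k():
    cfg = SimConfig(n_samples=10000, n_variants=20, seed=20)
    return cfg, simulate_genotypes(cfg)


class TestTrait:
    def test_null_trait_unit_variance(self, panel10k):
        cfg, panel = panel10k
        y = simulate_trait(panel, cfg)
        assert 0.95 <= y.var() <= 1.05

    def test_single_causal_variance_explained(self, panel10k):
        _, panel = panel10k
        r2 = []
        for s in range(100):
            cfg = SimConfig(n_samples=10000, n_variants=20, causal={7: 0.01}, seed=20)
            y = simulate_trait(panel, cfg, seed=1000 + s)
            r2.append(np.corrcoef(panel.dosages[:, 7], y)[0, 1] ** 2)
        assert 0.005 <= np.median(r2) <= 0.018
        assert np.mean([(0.005 <= v <= 0.018) for v in r2]) > 0.8

    def test_liability_threshold_prevalence(self, panel10k):
        cfg, panel = panel10k
        cfg2 = SimConfig(n_samples=10000, n_variants=20, trait_type="case_control",
                         prevalence=0.1, causal={3: 0.05}, seed=20)
        y = simulate_trait(panel, cfg2)
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert abs(y.mean() - 0.1) <= 0.02


class TestSumstats:
    def test_ols_matches_closed_form_oracle(self, rng):
        cfg = SimConfig(n_samples=800, n_variants=5, causal={2: 0.05}, seed=30)
        panel = simulate_genotypes(cfg)
        y = simulate_trait(panel, cfg)
        ss = compute_sumstats(panel, y, "quantitative")
        for j in range(5):
            res = stats.linregress(panel.dosages[:, j].astype(float), y)
            assert ss.df["beta"].iat[j] == pytest.approx(res.slope, abs=1e-10)
            assert ss.df["se"].iat[j] == pytest.approx(res.stderr, abs=1e-10)

    def test_covariate_residualisation(self, rng):
        cfg = SimConfig(n_samples=2000, n_variants=5, seed=31)
        panel = simulate_genotypes(cfg)
        covar = rng.normal(size=2000)
        y = simulate_trait(panel, cfg) + 3.0 * covar
        ss = compute_sumstats(panel, y, "quantitative", covariates=covar)
        resid = y - np.polyval(np.polyfit(covar, y, 1), covar)
        oracle = stats.linregress(panel.dosages[:, 0].astype(float), resid)
        assert ss.df["beta"].iat[0] == pytest.approx(oracle.slope, abs=1e-8)

    def test_null_scan_type_one_error(self):
        # fraction of p < 0.05 on a null scan; lambda averaged over draws
        fracs, lams = [], []
        for s in range(5):
            cfg = SimConfig(n_samples=2000, n_variants=10000, blocks=[(1, 0.0)],
                            seed=40 + s)
            panel = simulate_genotypes(cfg)
            y = simulate_trait(panel, cfg)
            ss = compute_sumstats(panel, y, "quantitative")
            fracs.append((ss.df["p"] < 0.05).mean())
            lams.append(genomic_inflation(ss))
        assert 0.04 <= np.mean(fracs) <= 0.06
        assert 0.97 <= np.mean(lams) <= 1.03

    def test_planted_variant_power(self):
        # 1% variance explained at n=10,000: non-centrality ~100, so
        # genome-wide significance is reached essentially always
        cfg = SimConfig(n_samples=10000, n_variants=10, causal={4: 0.01}, seed=50)
        panel = simulate_genotypes(cfg)
        hits = 0
        for s in range(100):
            y = simulate_trait(panel, cfg, seed=2000 + s)
            ss = compute_sumstats(panel, y, "quantitative")
            hits += ss.df["p"].iat[4] < 5e-8
        assert hits >= 95

    def test_monomorphic_flagged_and_filtered(self):
        dosages = np.column_stack([np.full(100, 2.0),
                                   np.tile([0.0, 1.0], 50)])
        panel = LDPanel(dosages, pd.DataFrame({"chrom": "1", "pos": [100, 200],
                                               "ref": "A", "alt": "G"}))
        y = np.random.default_rng(0).normal(size=100)
        ss = compute_sumstats(panel, y, "quantitative")
        assert ("monomorphic_flagged", 1) in ss.qc_log
        assert len(ss) == 2
        assert len(apply_variant_qc(ss)) == 1

    def test_logistic_mode_log_odds_scale(self):
        cfg = SimConfig(n_samples=3000, n_variants=3, trait_type="case_control",
                        prevalence=0.3, causal={1: 0.05}, seed=60)
        panel = simulate_genotypes(cfg)
        y = simulate_trait(panel, cfg)
        ss = compute_sumstats(panel, y, "case_control", binary_model="logistic")
        import statsmodels.api as sm
        fit = sm.Logit(y, sm.add_constant(panel.dosages[:, 1].astype(float))).fit(disp=0)
        assert ss.df["beta"].iat[1] == pytest.approx(fit.params[1], rel=1e-6)


class TestPairedStudies:
    def test_truth_roundtrip(self, tmp_path):
        cfg = SimConfig(n_samples=400, n_variants=50, causal={10: 0.05}, seed=70)
        _, _, truth = make_paired_studies(cfg, "shared")
        save_truth(truth, tmp_path / "truth.json")
        assert load_truth(tmp_path / "truth.json") == truth

    def test_distinct_mode_low_ld(self):
        cfg = SimConfig(n_samples=3000, n_variants=100, causal={30: 0.02}, seed=71)
        ss1, ss2, truth = make_paired_studies(cfg, "distinct", r2_cap=0.01)
        assert truth["causal2"] != truth["causal1"]
        # causal variants land in different LD blocks (block length 25)
        assert abs(truth["causal1"][0] // 25 - truth["causal2"][0] // 25) >= 1

    def test_shared_frequencies_agree_between_cohorts(self):
        cfg = SimConfig(n_samples=4000, n_variants=60, causal={10: 0.02}, seed=72)
        ss1, ss2, _ = make_paired_studies(cfg, "shared")
        np.testing.assert_allclose(ss1.df["eaf"], ss2.df["eaf"], atol=0.05)

    def test_independent_mode_favours_no_shared_signal(self):
        cfg = SimConfig(n_samples=5000, n_variants=100, causal={30: 0.01}, seed=73)
        ss1, ss2, truth = make_paired_studies(cfg, "independent")
        assert truth["causal2"] == []
        res = coloc_posteriors(harmonise_pair(ss1, ss2))
        assert res.pp[0] + res.pp[1] > 0.9

    def test_unknown_mode_rejected(self):
        cfg = SimConfig(causal={0: 0.01})
        with pytest.raises(ValueError, match="unknown mode"):
            make_paired_studies(cfg, "entangled")
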