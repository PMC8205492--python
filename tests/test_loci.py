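import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from postgwas.loci import (
    Locus, conditional_estimates, find_loci, load_gene_table, nearest_gene,
    stepwise_conditional, _JointModel,
)
from postgwas.ldpanel import LDPanel, pairwise_r
from postgwas.simulate import SimConfig, simulate_genotypes, simulate_trait, \
    compute_sumstats
from postgwas.sumstats import SummaryStats
from conftest import make_sumstats


def spike_sumstats(spike_positions, spike_se=0.01, m=50, span=2_000_000, seed=0):
    """Null background with strong association spikes at given positions."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, span), m, replace=False))
    pos = np.unique(np.concatenate([pos, spike_positions]))
    beta = rng.normal(0, 0.005, len(pos))
    se = np.full(len(pos), 0.01)
    for sp in spike_positions:
        beta[np.searchsorted(pos, sp)] = 0.08  # z = 8, p ~ 1e-15
    return make_sumstats(pos, beta, se)


class TestFindLoci:
    def test_no_significant_variants_gives_empty(self, random_sumstats):
        assert find_loci(random_sumstats, 1e-12) == []

    def test_single_spike_window(self):
        ss = spike_sumstats([1_000_000])
        loci = find_loci(ss, 1e-8, flank_bp=500_000)
        assert len(loci) == 1
        L = loci[0]
        assert L.end - L.start <= 1_000_000
        assert int(ss.df["pos"].iat[L.index]) == 1_000_000

    def test_nearby_spikes_merge_distant_split(self):
        near = spike_sumstats([1_000_000, 1_400_000])   # 400 kb apart -> merge
        far = spike_sumstats([1_000_000, 2_200_000])    # 1.2 Mb apart -> two loci
        assert len(find_loci(near, 1e-8)) == 1
        assert len(find_loci(far, 1e-8)) == 2

    def test_merged_locus_keeps_smallest_p_index(self):
        ss = spike_sumstats([1_000_000, 1_400_000])
        df = ss.df.copy()
        i = int(np.searchsorted(df["pos"].to_numpy(), 1_400_000))
        df.loc[i, "beta"] = 0.12  # stronger of the two spikes
        df.loc[i, "p"] = 1e-30
        ss2 = SummaryStats("t", "quantitative", df)
        (L,) = find_loci(ss2, 1e-8)
        assert int(ss2.df["pos"].iat[L.index]) == 1_400_000

    def test_flank_clipped_at_one(self):
        ss = make_sumstats([100], [0.08], [0.01])
        (L,) = find_loci(ss, 1e-8, flank_bp=500_000)
        assert L.start == 1

    def test_invariant_to_record_order(self):
        ss = spike_sumstats([1_000_000, 2_200_000])
        shuffled = SummaryStats("t", "quantitative",
                                ss.df.sample(frac=1, random_state=4))
        a = [(L.chrom, L.start, L.end) for L in find_loci(ss, 1e-8)]
        b = [(L.chrom, L.start, L.end) for L in find_loci(shuffled, 1e-8)]
        assert a == b


def whole_region_locus(ss):
    return Locus(index=int(ss.df["p"].idxmin()), chrom=str(ss.df["chrom"].iat[0]),
                 start=1, end=int(ss.df["pos"].max()) + 1,
                 member_indices=np.arange(len(ss)), index_p=float(ss.df["p"].min()))


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(n_samples=4000, n_variants=60, causal={15: 0.02, 45: 0.02},
                    seed=17)
    panel = simulate_genotypes(cfg)
    y = simulate_trait(panel, cfg)
    ss = compute_sumstats(panel, y, "quantitative")
    return cfg, panel, y, ss


class TestStepwiseConditional:
    def test_joint_fit_matches_insample_ols(self, sim):
        _, panel, y, ss = sim
        model = _JointModel(ss, panel, whole_region_locus(ss), 0.2, "panel")
        sel = [15, 45, 30]
        b, se, _ = model.fit(sel)
        fit = sm.OLS(y, sm.add_constant(panel.dosages[:, sel].astype(float))).fit()
        np.testing.assert_allclose(b, fit.params[1:], rtol=1e-6)
        np.testing.assert_allclose(se, fit.bse[1:], rtol=1e-6)

    def test_two_causals_recovered_and_independent(self, sim):
        _, panel, _, ss = sim
        sigs = stepwise_conditional(ss, panel, whole_region_locus(ss))
        assert len(sigs) >= 2
        assert all(s.p_joint < 1e-8 for s in sigs)
        tag = lambda c: any(pairwise_r(panel, s.lead_index, c) ** 2 >= 0.8
                            for s in sigs)
        assert tag(15) and tag(45)
        # mutual conditional independence: refit of the final set
        model = _JointModel(ss, panel, whole_region_locus(ss), 0.2, "panel")
        _, _, p = model.fit([s.lead_index for s in sigs])
        assert np.all(p < 1e-8)

    def test_selected_leads_not_collinear(self, sim):
        _, panel, _, ss = sim
        sigs = stepwise_conditional(ss, panel, whole_region_locus(ss))
        for a in range(len(sigs)):
            for b in range(a + 1, len(sigs)):
                assert pairwise_r(panel, sigs[a].lead_index,
                                  sigs[b].lead_index) ** 2 < 0.9

    def test_no_signal_below_threshold(self, sim):
        _, panel, _, ss = sim
        assert stepwise_conditional(ss, panel, whole_region_locus(ss),
                                    p_joint_max=1e-300) == []

    def test_missing_panel_variant_errors(self, sim):
        _, panel, _, ss = sim
        bad = LDPanel(panel.dosages, panel.variants.assign(pos=panel.variants["pos"] + 7))
        with pytest.raises(ValueError, match="panel"):
            stepwise_conditional(ss, bad, whole_region_locus(ss))

    def test_orthogonal_candidate_keeps_marginal_beta(self):
        # two exactly orthogonal (after centring) dosage columns
        c1 = np.tile([0.0, 2.0], 50)
        c2 = np.tile([0.0, 0.0, 2.0, 2.0], 25)
        rng = np.random.default_rng(3)
        y = 0.2 * c1 + 0.1 * c2 + rng.normal(0, 1, 100)
        panel = LDPanel(np.column_stack([c1, c2]),
                        pd.DataFrame({"chrom": "1", "pos": [1000, 2000],
                                      "ref": "A", "alt": "G"}))
        ss = compute_sumstats(panel, y, "quantitative")
        locus = whole_region_locus(ss)
        lead = int(ss.df["p"].idxmin())
        other = 1 - lead
        cond = conditional_estimates(ss, panel, locus, [lead])
        marginal = float(ss.df["beta"].iat[other])
        assert cond["beta_cond"].iloc[0] == pytest.approx(marginal, abs=1e-10)


class TestNearestGene:
    @pytest.fixture
    def genes(self, tmp_path):
        path = tmp_path / "genes.tsv"
        pd.DataFrame({
            "chrom": ["1", "1", "1", "2"],
            "txStart": [500_000, 900_000, 1_200_000, 100],
            "txEnd": [600_000, 1_000_000, 1_300_000, 200],
            "strand": ["+", "-", "+", "+"],
            "name": ["GENEA", "GENEB", "GENEC", "GENED"],
        }).to_csv(path, sep="\t", index=False)
        return load_gene_table(path)

    def test_distance_to_nearest_tss(self, genes):
        # GENEA TSS at 500,000 (+); lead 175 kb upstream
        name, dist = nearest_gene("1", 325_000, genes)
        assert (name, dist) == ("GENEA", 175_000)

    def test_inside_gene_body_distance_zero(self, genes):
        name, dist = nearest_gene("1", 550_000, genes)
        assert (name, dist) == ("GENEA", 0)

    def test_minus_strand_tss_is_txend(self, genes):
        # GENEB is on -, TSS at 1,000,000: a lead at 1,090,000 is 90 kb
        # from GENEB's TSS but 110 kb from GENEC's
        name, dist = nearest_gene("1", 1_090_000, genes)
        assert (name, dist) == ("GENEB", 90_000)

    def test_equidistant_tie_breaks_on_smaller_tss(self, genes):
        # midpoint between GENEB TSS (1,000,000) and GENEC TSS (1,200,000)
        name, dist = nearest_gene("1", 1_100_000, genes)
        assert (name, dist) == ("GENEB", 100_000)

    def test_missing_chromosome(self, genes):
        assert nearest_gene("9", 1000, genes) == (None, None)

    def test_gene_table_validation(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"chrom": ["1"], "txStart": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="txEnd"):
            load_gene_table(path)
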