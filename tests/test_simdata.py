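import numpy as np
import pytest
from scipy import stats

import maizegs as mg
from maizegs.geno import GenotypeError
from maizegs.simdata import SimError


class TestSimConfig:
    @pytest.mark.parametrize("field, value", [
        ("n_ind", 0), ("h2_target", 0.0), ("h2_target", 1.5),
        ("missing_rate_target", 1.0), ("pop_type", "f2"),
        ("n_qtl", 10_001), ("map_length_cM", -1.0),
    ])
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(SimError):
            mg.SimConfig(**{field: value})


class TestSimulatePanel:
    def test_degenerate_prior_gives_all_zero(self):
        # prior mass essentially at allele frequency 0
        cfg = mg.SimConfig(n_ind=50, n_chrom=2, markers_per_chrom=50,
                           maf_spectrum=(1e-3, 1e3), seed=0)
        g = mg.simulate_panel(cfg)
        assert (g.dosages == 0).all()

    def test_deterministic_under_seed(self):
        cfg = mg.SimConfig(n_ind=30, n_chrom=2, markers_per_chrom=40, seed=5)
        a = mg.simulate_panel(cfg)
        b = mg.simulate_panel(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_fully_homozygous(self):
        g = mg.simulate_panel(mg.SimConfig(n_ind=40, seed=1))
        assert np.isin(g.dosages, [0.0, 2.0]).all()

    def test_rare_maf_fraction_matches_prior_predictive_oracle(self):
        # Monte-Carlo oracle: marker freq ~ Beta(0.3, 0.3), carrier count
        # ~ Binomial(n, p); realized MAF < 0.05 fraction
        n_ind, m = 2000, 5000
        cfg = mg.SimConfig(n_ind=n_ind, n_chrom=10, markers_per_chrom=500,
                           maf_spectrum=(0.3, 0.3), seed=7)
        g = mg.simulate_panel(cfg)
        freq = g.dosages.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        observed = (maf < 0.05).mean()

        rng = np.random.default_rng(999)
        n_mc = 40_000
        p = rng.beta(0.3, 0.3, n_mc)
        carriers = rng.binomial(n_ind, p)
        maf_mc = np.minimum(carriers, n_ind - carriers) / n_ind
        expected = (maf_mc < 0.05).mean()
        se = np.sqrt(expected * (1 - expected) * (1 / m + 1 / n_mc))
        assert abs(observed - expected) < 2 * se + 1e-9

    def test_wrong_pop_type_rejected(self):
        with pytest.raises(SimError):
            mg.simulate_panel(mg.SimConfig(pop_type="dh"))


class TestSimulateDH:
    def make_parents(self, cfg, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        p1 = 2.0 * rng.integers(0, 2, cfg.n_markers).astype(float)
        p2 = p1.copy() if identical else 2.0 - p1
        return p1, p2

    def test_identical_parents_monomorphic(self):
        cfg = mg.SimConfig(pop_type="dh", n_ind=50, n_chrom=2,
                           markers_per_chrom=30, seed=3)
        p1, p2 = self.make_parents(cfg, identical=True)
        g = mg.simulate_dh(cfg, p1, p2)
        assert (g.dosages == p1[None, :]).all()

    def test_zero_map_length_gives_intact_parental_chromosomes(self):
        cfg = mg.SimConfig(pop_type="dh", n_ind=400, n_chrom=1,
                           markers_per_chrom=50, map_length_cM=0.0, seed=4)
        p1, p2 = self.make_parents(cfg)
        g = mg.simulate_dh(cfg, p1, p2)
        from1 = 0
        for row in g.dosages:
            if (row == p1).all():
                from1 += 1
            else:
                assert (row == p2).all()
        # fraction from parent1 ~ Binomial(400, 0.5)
        assert stats.binomtest(from1, 400, 0.5).pvalue > 0.001

    def test_segregating_allele_frequency_near_half(self):
        cfg = mg.SimConfig(pop_type="dh", n_ind=1000, n_chrom=2,
                           markers_per_chrom=50, seed=6)
        p1, p2 = self.make_parents(cfg)
        g = mg.simulate_dh(cfg, p1, p2)
        freq = (g.dosages == p1[None, :]).mean(axis=0)
        se = np.sqrt(0.25 / 1000)
        # marker-level frequencies are correlated through linkage; test
        # each marker against the binomial oracle band
        assert (np.abs(freq - 0.5) < 5 * se).mean() > 0.95

    def test_heterozygous_parent_rejected(self):
        cfg = mg.SimConfig(pop_type="dh", n_ind=10, n_chrom=1,
                           markers_per_chrom=5, n_qtl=2, seed=0)
        bad = np.array([0.0, 1.0, 2.0, 0.0, 2.0])
        with pytest.raises(SimError, match="homozygous"):
            mg.simulate_dh(cfg, bad, 2.0 - bad)

    def test_only_parental_alleles(self):
        cfg = mg.SimConfig(pop_type="dh", n_ind=80, n_chrom=3,
                           markers_per_chrom=40, seed=8)
        rng = np.random.default_rng(2)
        p1 = 2.0 * rng.integers(0, 2, cfg.n_markers).astype(float)
        p2 = 2.0 * rng.integers(0, 2, cfg.n_markers).astype(float)
        g = mg.simulate_dh(cfg, p1, p2)
        ok = (g.dosages == p1[None, :]) | (g.dosages == p2[None, :])
        assert ok.all()

    def test_linkage_decays_with_distance(self):
        cfg = mg.SimConfig(pop_type="dh", n_ind=600, n_chrom=1,
                           markers_per_chrom=60, map_length_cM=200.0, seed=9)
        p1, p2 = self.make_parents(cfg)
        g = mg.simulate_dh(cfg, p1, p2)
        z = (g.dosages == p1[None, :]).astype(float)
        r_near = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        r_far = np.corrcoef(z[:, 0], z[:, 59])[0, 1]
        assert r_near > 0.8
        assert abs(r_far) < 0.3


class TestToDominant:
    def test_presence_definition(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        g = mg.GenotypeMatrix(line_ids=["a", "b", "c"], marker_ids=["m"],
                              dosages=d)
        out = mg.to_dominant(g, seed=0)
        col = out.dosages[:, 0]
        assert set(col[~np.isnan(col)]) == {0.0, 1.0}
        assert np.isnan(col[2])
        assert out.marker_class == "dominant"

    def test_monomorphic_marker_stays_monomorphic(self):
        d = np.full((5, 1), 2.0)
        g = mg.GenotypeMatrix(line_ids=list("abcde"), marker_ids=["m"], dosages=d)
        out = mg.to_dominant(g, seed=1)
        assert len(set(out.dosages[:, 0])) == 1

    def test_round_trip_on_inbred_data(self):
        # on {0,2} dosages the collapse is a relabeling per marker:
        # presence pattern matches either the alt-carriers or ref-carriers
        cfg = mg.SimConfig(n_ind=60, n_chrom=2, markers_per_chrom=40, seed=12)
        g = mg.simulate_panel(cfg)
        dom = mg.to_dominant(g, seed=13)
        for j in range(g.n_markers):
            col = g.dosages[:, j]
            pres = dom.dosages[:, j]
            alt_pattern = (col == 2.0).astype(float)
            assert (pres == alt_pattern).all() or (pres == 1 - alt_pattern).all()

    def test_already_dominant_rejected(self):
        d = np.array([[0.0], [1.0]])
        g = mg.GenotypeMatrix(line_ids=["a", "b"], marker_ids=["m"],
                              dosages=d, marker_class="dominant")
        with pytest.raises(GenotypeError, match="already dominant"):
            mg.to_dominant(g)


class TestInjectMissing:
    def test_rate_zero_identity(self, small_panel):
        out = mg.inject_missing(small_panel["geno"], 0.0, seed=0)
        np.testing.assert_array_equal(out.dosages, small_panel["geno"].dosages)

    def test_realized_rate_binomial_oracle(self):
        cfg = mg.SimConfig(n_ind=1000, n_chrom=10, markers_per_chrom=100, seed=2)
        g = mg.simulate_panel(cfg)  # 10^5... use 10^6 cells
        out = mg.inject_missing(g, 0.29, seed=3)
        n_cells = out.dosages.size
        realized = np.isnan(out.dosages).mean()
        se = np.sqrt(0.29 * 0.71 / n_cells)
        assert abs(realized - 0.29) < 3 * se

    def test_rate_one_rejected(self, small_panel):
        with pytest.raises(SimError):
            mg.inject_missing(small_panel["geno"], 1.0, seed=0)

    def test_masked_cells_excluded_from_maf(self):
        d = np.array([[0.0, 2.0], [2.0, 2.0], [2.0, 0.0], [0.0, 0.0]])
        g = mg.GenotypeMatrix(line_ids=list("abcd"), marker_ids=["m1", "m2"],
                              dosages=d)
        masked = g.dosages.copy()
        masked[0, 0] = np.nan
        g2 = mg.GenotypeMatrix(line_ids=list("abcd"), marker_ids=["m1", "m2"],
                               dosages=masked)
        qc = mg.compute_qc(g2)
        assert qc.maf[0] == pytest.approx(min(4 / 6, 2 / 6))


class TestSimulatePhenotypes:
    def test_noise_free_limit(self):
        cfg = mg.SimConfig(n_ind=100, n_chrom=2, markers_per_chrom=50,
                           n_qtl=10, h2_target=1.0, seed=21)
        g = mg.simulate_panel(cfg)
        recs, arch = mg.simulate_phenotypes(g, cfg)
        lsm = mg.ls_means(recs).reindex(g.line_ids.astype(str)).to_numpy()
        assert mg.accuracy(lsm, arch.true_breeding_values) == pytest.approx(1.0)

    def test_null_architecture(self):
        cfg = mg.SimConfig(n_ind=80, n_chrom=2, markers_per_chrom=50,
                           n_qtl=0, h2_target=0.5, seed=22)
        g = mg.simulate_panel(cfg)
        recs, arch = mg.simulate_phenotypes(g, cfg)
        assert np.ptp(arch.true_breeding_values) == 0
        # no genetic signal: between-location genotype-mean correlation ~ 0
        corr = mg.location_correlations(recs)
        offdiag = corr.to_numpy()[np.triu_indices(3, 1)]
        assert np.all(np.abs(offdiag) < 0.35)

    def test_h2_zero_rejected(self, small_panel):
        with pytest.raises(SimError):
            mg.SimConfig(h2_target=0.0)

    def test_realized_h2_calibration_oracle(self):
        # realized Var(TBV)/Var(lsmean) averaged over 50 seeds within
        # +/- 0.05 of the 0.75 target
        vals = []
        for seed in range(50):
            cfg = mg.SimConfig(n_ind=300, n_chrom=4, markers_per_chrom=100,
                               n_qtl=40, h2_target=0.75, n_env=3, seed=seed)
            g = mg.simulate_panel(cfg)
            recs, arch = mg.simulate_phenotypes(g, cfg)
            lsm = mg.ls_means(recs).reindex(g.line_ids.astype(str)).to_numpy()
            vals.append(np.var(arch.true_breeding_values) / np.var(lsm))
        assert abs(np.mean(vals) - 0.75) < 0.05

    def test_tbv_consistent_with_architecture(self, small_panel):
        g, arch = small_panel["geno"], small_panel["arch"]
        Q = g.dosages[:, arch.qtl_indices]
        expected = (Q - Q.mean(axis=0)) @ arch.qtl_effects
        np.testing.assert_allclose(arch.true_breeding_values, expected, atol=1e-10)

    def test_deterministic(self, small_panel):
        cfg, g = small_panel["cfg"], small_panel["geno"]
        r1, a1 = mg.simulate_phenotypes(g, cfg)
        r2, a2 = mg.simulate_phenotypes(g, cfg)
        np.testing.assert_array_equal(r1["value"], r2["value"])
        np.testing.assert_array_equal(a1.qtl_effects, a2.qtl_effects)

    def test_realized_h2_slope_across_targets(self):
        # regression of realized on target h2 over {0.2, 0.5, 0.8}
        targets = [0.2, 0.5, 0.8]
        realized = []
        for t in targets:
            vals = []
            for seed in range(50):
                cfg = mg.SimConfig(n_ind=500, n_chrom=2, markers_per_chrom=100,
                                   n_qtl=40, h2_target=t, seed=seed)
                g = mg.simulate_panel(cfg)
                recs, arch = mg.simulate_phenotypes(g, cfg)
                lsm = mg.ls_means(recs).reindex(g.line_ids.astype(str)).to_numpy()
                vals.append(np.var(arch.true_breeding_values) / np.var(lsm))
            realized.append(np.mean(vals))
        slope = np.polyfit(targets, realized, 1)[0]
        assert 0.9 < slope < 1.1
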