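"""Population simulator: meiosis, MAGIC funnels, trait architecture."""

import numpy as np
import pytest

from inducergp.simulate import (SimConfig, TraitArch, default_config,
                                inject_missing_genotypes, simulate_dh_family,
                                simulate_founders, simulate_magic,
                                simulate_phenotypes, simulate_study)
from inducergp.pheno import fit_blue


def small_cfg(seed=1, n_founders=8):
    return SimConfig(n_founders=n_founders, n_chrom=10, snps_per_chrom=700,
                     chrom_length_cM=150, seed=seed)


class TestFounders:
    def test_shape_homozygosity_and_determinism(self):
        cfg = small_cfg(seed=1)
        g1 = simulate_founders(cfg)
        g2 = simulate_founders(small_cfg(seed=1))
        assert g1.codes.shape == (8, 7000)
        assert np.isin(g1.codes, (-1.0, 1.0)).all()
        np.testing.assert_array_equal(g1.codes, g2.codes)

    def test_most_snps_segregate(self):
        g = simulate_founders(small_cfg(seed=2))
        p = g.major_allele_freq()
        assert ((p > 0) & (p < 1)).mean() >= 0.95

    def test_positions_strictly_increasing(self):
        g = simulate_founders(small_cfg(seed=3))
        for _, sub in g.markers.groupby("chrom"):
            assert (np.diff(sub["pos"].to_numpy()) > 0).all()

    def test_two_founder_segregation_flag(self):
        """With 2 founders, a SNP segregates iff the founders differ there."""
        g = simulate_founders(small_cfg(seed=4, n_founders=2))
        p = g.major_allele_freq()
        differ = g.codes[0] != g.codes[1]
        np.testing.assert_array_equal((p > 0) & (p < 1), differ)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_founders=1)
        with pytest.raises(ValueError):
            SimConfig(snps_per_chrom=0)


class TestDHFamily:
    def test_identical_parents_clone(self):
        founders = simulate_founders(small_cfg(seed=5))
        fam = simulate_dh_family(founders.codes[0], founders.codes[0], 10,
                                 founders.markers, seed=1)
        assert (fam.codes == founders.codes[0]).all()

    def test_heterozygous_parent_rejected(self):
        founders = simulate_founders(small_cfg(seed=5))
        bad = founders.codes[0].copy()
        bad[0] = 0.0
        with pytest.raises(ValueError, match="homozygous"):
            simulate_dh_family(bad, founders.codes[1], 5, founders.markers, seed=1)

    def test_allele_frequency_binomial_oracle(self):
        """Parents differing everywhere: per-locus frequency -> 0.5 within
        3 binomial standard errors at n=2000."""
        cfg = SimConfig(n_founders=2, n_chrom=2, snps_per_chrom=100, seed=6)
        founders = simulate_founders(cfg)
        a = np.ones(founders.n_markers)
        fam = simulate_dh_family(a, -a, 2000, founders.markers, seed=2)
        freq = (fam.codes == 1).mean(axis=0)
        se3 = 3 * np.sqrt(0.25 / 2000)
        assert (np.abs(freq - 0.5) < se3).mean() > 0.95

    def test_close_markers_rarely_recombine(self):
        """Adjacent markers 0.1 cM apart recombine in < 1% of DH gametes
        (Haldane: r = (1 - exp(-2d/100)) / 2 ~ 0.001)."""
        import pandas as pd
        markers = pd.DataFrame({
            "id": ["A", "B"], "chrom": ["1", "1"], "pos": [1, 2],
            "cm": [50.0, 50.1]})
        a = np.ones(2)
        fam = simulate_dh_family(a, -a, 2000, markers, seed=3)
        recomb = (fam.codes[:, 0] != fam.codes[:, 1]).mean()
        assert recomb < 0.01

    def test_ld_decays_with_distance(self):
        """Inter-marker genotype correlation decreases with cM distance."""
        cfg = SimConfig(n_founders=2, n_chrom=1, snps_per_chrom=200,
                        chrom_length_cM=150, seed=7)
        founders = simulate_founders(cfg)
        a = np.ones(founders.n_markers)
        fam = simulate_dh_family(a, -a, 1000, founders.markers, seed=4)
        cm = founders.markers["cm"].to_numpy()
        corr = np.corrcoef(fam.codes, rowvar=False)
        dist = np.abs(cm[:, None] - cm[None, :])
        iu = np.triu_indices_from(dist, k=1)
        bins = np.digitize(dist[iu], [5, 20, 50, 100])
        means = [np.abs(corr[iu][bins == b]).mean() for b in range(5)]
        assert all(means[i] > means[i + 1] for i in range(4))


class TestMagic:
    def test_counts_homozygosity_identical_founders(self):
        founders = simulate_founders(small_cfg(seed=8))
        magic = simulate_magic(founders, 11, seed=1)
        assert magic.n_lines == 11
        assert np.isin(magic.codes, (-1.0, 1.0)).all()
        clone = founders.subset_lines([0] * 8)
        same = simulate_magic(clone, 5, seed=2)
        assert (same.codes == founders.codes[0]).all()

    def test_founder_ancestry_shares_balanced(self):
        """Mean founder-genome share approaches 1/8 at 800 lines."""
        cfg = SimConfig(n_founders=8, n_chrom=5, snps_per_chrom=60, seed=9)
        founders = simulate_founders(cfg)
        _, anc = simulate_magic(founders, 800, seed=3, track_ancestry=True)
        shares = np.bincount(anc.ravel(), minlength=8) / anc.size
        assert np.abs(shares - 0.125).max() < 0.01

    def test_too_few_founders_rejected(self):
        founders = simulate_founders(small_cfg(seed=8)).subset_lines([0])
        with pytest.raises(ValueError):
            simulate_magic(founders, 5, seed=1)


class TestPhenotypes:
    def test_noiseless_blues_recover_truth(self):
        """h2_plot = 1: BLUEs equal true genotypic values up to an additive
        identification constant."""
        cfg = SimConfig(n_founders=4, n_chrom=3, snps_per_chrom=80, seed=10,
                        traits=[TraitArch("T", 0, 100, 0.0, h2_plot=1.0)],
                        missing_pheno_rate=0.2)
        founders = simulate_founders(cfg)
        magic = simulate_magic(founders.subset_lines(range(4)), 60, seed=4)
        rec, truth = simulate_phenotypes(magic, cfg.traits, cfg, seed=5)
        blues = fit_blue(rec, "T")
        truth_vals = truth.genetic_values["T"].reindex(blues.index)
        diff = blues - truth_vals
        assert diff.std() < 1e-8

    def test_realized_genetic_correlations_on_target(self):
        """Four traits with weak targets (incl. -0.228 between traits 1-2)
        realize within +-0.05 at 2000 lines."""
        cfg = default_config(11)
        founders = simulate_founders(cfg)
        magic = simulate_magic(founders.subset_lines(range(8)), 2000, seed=6)
        _, truth = simulate_phenotypes(magic, cfg.traits, cfg, seed=7)
        target = cfg.corr_matrix()
        realized = truth.realized_corr.to_numpy()
        assert np.abs(realized - target).max() < 0.05
        assert truth.realized_corr.loc["DTF", "HIR"] == pytest.approx(-0.228, abs=0.05)

    def test_heritability_calibrated(self):
        """Plot-level Var(g)/(Var(g)+Var(e)) within +-0.05 of the 0.5
        target at 2000 lines x 2 replicates."""
        cfg = SimConfig(n_founders=8, n_chrom=3, snps_per_chrom=80, seed=12,
                        traits=[TraitArch("T", 0, 150, 0.0, h2_plot=0.5,
                                          genetic_var=4.0)],
                        years=1, blocks_per_year=2, missing_pheno_rate=0.0)
        founders = simulate_founders(cfg)
        magic = simulate_magic(founders, 2000, seed=8)
        rec, truth = simulate_phenotypes(magic, cfg.traits, cfg, seed=9)
        var_g = truth.genetic_values["T"].var()
        piv = rec.pivot_table(index="genotype", columns="block", values="value")
        var_e = ((piv["B1"] - piv["B2"]) ** 2).mean() / 2
        h2 = var_g / (var_g + var_e)
        assert h2 == pytest.approx(0.5, abs=0.05)

    def test_effects_table_reconstructs_genetic_values(self):
        cfg = default_config(13)
        cfg.snps_per_chrom = 60
        study = simulate_study(cfg)
        g_pred = study.train.codes @ study.truth.effects.to_numpy()
        g_true = study.truth.genetic_values.reindex(study.train.line_ids).to_numpy()
        resid = g_true - g_pred
        assert np.abs(resid - resid.mean(axis=0)).max() < 1e-8

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            TraitArch("T", 0, 10, 0.0, h2_plot=1.5)
        with pytest.raises(ValueError):
            TraitArch("T", 0, 10, 0.0, h2_plot=0.0)


class TestStudy:
    def test_structure_and_determinism(self, small_study):
        assert small_study.train.n_lines >= 300
        assert small_study.test.n_lines == 11
        assert not set(small_study.train.line_ids) & set(small_study.test.line_ids)
        # all simulated genotypes homozygous before missingness injection
        assert np.isin(small_study.train.codes, (-1.0, 1.0)).all()
        assert small_study.train_missing.has_missing
        cfg = default_config(1)
        cfg.snps_per_chrom = 120
        again = simulate_study(cfg)
        np.testing.assert_array_equal(again.train.codes, small_study.train.codes)
        pd_rec = again.records
        assert pd_rec.equals(small_study.records)

    def test_missingness_injection_rate(self, small_study):
        rate = np.isnan(small_study.train_missing.codes).mean()
        assert rate == pytest.approx(0.02, abs=0.005)
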