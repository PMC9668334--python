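"""Synthetic panel generator: determinism, ground truth and design features."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiogwas.syndata import (SimConfig, simulate_motif_windows,
                                simulate_panel, simulate_phenotypes)


def _cfg(**kw):
    base = dict(n_lines=40, n_per_line=10, n_variants=200,
                genome_length=50_000, outlier_rate=0.0, seed=11)
    base.update(kw)
    return SimConfig(**base)


class TestSimulatePanel:
    def test_deterministic_under_seed(self):
        p1, g1, s1 = simulate_panel(_cfg())
        p2, g2, s2 = simulate_panel(_cfg())
        assert np.array_equal(p1.genotypes, p2.genotypes)
        assert p1.variants.equals(p2.variants)
        assert s1 == s2
        assert [g.gene_id for g in g1] == [g.gene_id for g in g2]

    def test_maf_half_symmetric(self):
        panel, _, _ = simulate_panel(_cfg(maf_range=(0.5, 0.5),
                                          n_lines=300, n_variants=100))
        assert abs(panel.allele_freq().mean() - 0.5) < 0.02

    def test_genotypes_binary_no_missing(self):
        panel, _, _ = simulate_panel(_cfg())
        assert np.isin(panel.genotypes, (0.0, 1.0)).all()

    def test_matrix_shape_and_mapped_unmapped_variants(self):
        cfg = _cfg(n_lines=167, n_per_line=12, n_variants=1000,
                   genome_length=100_000)
        panel, genes, genome = simulate_panel(cfg)
        assert panel.genotypes.shape == (167, 1000)
        pos = panel.variants["pos"].to_numpy()
        in_gene = np.zeros(len(pos), dtype=bool)
        far = np.ones(len(pos), dtype=bool)
        for g in genes:
            in_gene |= (pos >= g.start) & (pos <= g.end)
            far &= np.minimum(np.abs(pos - g.start),
                              np.abs(pos - g.end)) > 1000
        assert in_gene.any(), "some variants overlap genes"
        assert (far & ~in_gene).any(), "some variants lie > 1 kb from any gene"

    def test_gene_models_internally_consistent(self):
        _, genes, genome = simulate_panel(_cfg())
        L = len(genome["chr1"])
        prev_end = 0
        for g in genes:
            assert 1 <= g.start < g.end <= L
            assert g.start - prev_end > 2000  # intergenic gap > 2 kb
            for a, b in g.exons + g.utr5 + g.utr3:
                assert g.start <= a <= b <= g.end
            prev_end = g.end

    def test_too_many_variants_rejected(self):
        with pytest.raises(ValueError):
            simulate_panel(_cfg(n_variants=40_000, genome_length=50_000))

    def test_ref_alleles_match_genome(self):
        panel, _, genome = simulate_panel(_cfg())
        seq = genome["chr1"]
        for rec in panel.variants.head(50).itertuples(index=False):
            assert seq[rec.pos - 1] == rec.ref
            assert rec.alt != rec.ref


class TestSimulatePhenotypes:
    def test_deterministic_under_seed(self):
        cfg = _cfg()
        panel, _, _ = simulate_panel(cfg)
        ph1, cov1, t1 = simulate_phenotypes(panel, cfg)
        ph2, cov2, t2 = simulate_phenotypes(panel, cfg)
        assert ph1.equals(ph2)
        assert cov1.equals(cov2)
        assert t1.simulated_H2 == t2.simulated_H2

    def test_null_model_gives_near_zero_h2(self):
        cfg = _cfg(beta_mean=0.0, gamma_var=1.0, n_causal_mean=0,
                   n_causal_var=0, n_lines=80)
        cfg.trait_baselines = {t: (mu, w, 0.0) for t, (mu, w, b)
                               in cfg.trait_baselines.items()}
        panel, _, _ = simulate_panel(cfg)
        pheno, _, truth = simulate_phenotypes(panel, cfg)
        assert truth.simulated_H2["EDD"] == pytest.approx(0.0, abs=1e-9)
        from cardiogwas.quantgen import anova_components

        assert anova_components(pheno, "EDD").H2 < 0.1

    def test_variance_qtl_inflates_carrier_line_sd(self):
        cfg = _cfg(n_lines=100, n_causal_mean=0, n_causal_var=1,
                   gamma_var=3.0, seed=21)
        panel, _, _ = simulate_panel(cfg)
        pheno, _, truth = simulate_phenotypes(panel, cfg)
        (vid, info), = truth.causal_var_variants.items()
        j = list(panel.variants["variant_id"]).index(vid)
        carriers = panel.genotypes[:, j] == 1
        sds = pheno.groupby("line_id")[info["trait"]].std()
        sds = sds.loc[panel.line_ids].to_numpy()
        res = stats.mannwhitneyu(sds[carriers], sds[~carriers],
                                 alternative="greater")
        assert res.pvalue < 0.01

    def test_hp_is_di_plus_si(self):
        cfg = _cfg()
        panel, _, _ = simulate_panel(cfg)
        pheno, _, _ = simulate_phenotypes(panel, cfg)
        assert np.allclose(pheno["HP"], pheno["DI"] + pheno["SI"])

    def test_between_line_variance_calibrated(self):
        """Realized among-line variance of genetic values tracks the
        configured between-SD^2 (averaged over replicates)."""
        target = SimConfig().trait_baselines["EDD"][2] ** 2
        realized = []
        for rep in range(25):
            cfg = _cfg(n_lines=167, n_causal_mean=0, n_causal_var=0,
                       seed=300 + rep)
            panel, _, _ = simulate_panel(cfg)
            _, _, truth = simulate_phenotypes(panel, cfg)
            realized.append(np.var(truth.line_genetic_values["EDD"], ddof=1))
        assert abs(np.mean(realized) - target) / target < 0.15

    def test_truth_record_consistency(self):
        cfg = _cfg(n_causal_mean=5, n_causal_var=3)
        panel, _, _ = simulate_panel(cfg)
        _, _, truth = simulate_phenotypes(panel, cfg)
        vids = set(panel.variants["variant_id"])
        assert set(truth.causal_mean_variants) <= vids
        assert set(truth.causal_var_variants) <= vids
        assert all(0 <= h <= 1 for h in truth.simulated_H2.values())

    def test_outlier_rate_inflates_tails(self):
        cfg_clean = _cfg(n_lines=150, seed=31)
        cfg_out = _cfg(n_lines=150, outlier_rate=0.05, seed=31)
        panel, _, _ = simulate_panel(cfg_clean)
        ph_clean, _, _ = simulate_phenotypes(panel, cfg_clean)
        ph_out, _, _ = simulate_phenotypes(panel, cfg_out)
        assert ph_out["EDD"].std() > ph_clean["EDD"].std()


class TestSimulateMotifWindows:
    def test_no_plant_no_motif_excess(self):
        seqs = simulate_motif_windows(100, 60, "TCAAGTGCGG", 0.0, seed=5)
        hits = sum("TCAAGTGCGG" in s for s in seqs)
        assert hits <= 1  # 10-mer by chance is ~vanishing

    def test_full_plant_minimal_length(self):
        seqs = simulate_motif_windows(20, 7, "TCAAGTG", 1.0, seed=5)
        assert all(s == "TCAAGTG" for s in seqs)

    def test_plant_count_within_binomial_bounds(self):
        seqs = simulate_motif_windows(200, 151, "TCAAGTG", 0.4, seed=5)
        count = sum("TCAAGTG" in s for s in seqs)
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.4)
        assert lo <= count <= hi

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_motif_windows(10, 20, "ACGT", 1.5)

    def test_deterministic(self):
        a = simulate_motif_windows(20, 30, "ACGTACG", 0.5, seed=9)
        b = simulate_motif_windows(20, 30, "ACGTACG", 0.5, seed=9)
        assert a == b


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n_lines=0)
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.1, 0.6))
    with pytest.raises(ValueError):
        SimConfig(outlier_rate=1.0)
    with pytest.raises(ValueError):
        SimConfig(n_variants=5, n_causal_mean=6)
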