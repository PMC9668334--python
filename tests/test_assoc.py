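"""Kinship, leverage filtering and the mixed-model single-marker scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiogwas.assoc import (MixedGWAS, compute_grm, leverage_filter,
                              select_candidates)
from cardiogwas.panel import Panel
from cardiogwas.pheno import QCRule
from cardiogwas.syndata import SimConfig, simulate_panel


def _panel(geno, positions=None):
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    positions = positions or list(range(100, 100 + 10 * m, 10))
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": "chr1", "pos": positions,
        "ref": "A", "alt": "T", "site_class": "intron"})
    return Panel([f"L{i}" for i in range(n)], geno, variants)


class TestComputeGrm:
    def test_identical_lines_share_kinship(self):
        p = _panel([[0, 1, 1, 0], [0, 1, 1, 0], [1, 0, 0, 1]])
        K = compute_grm(p)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_two_line_hand_standardization(self):
        # lines (0,0) and (1,1): each column standardizes to (-1, +1)
        K = compute_grm(_panel([[0, 0], [1, 1]]))
        assert K == pytest.approx(np.array([[1.0, -1.0], [-1.0, 1.0]]))

    def test_diagonal_mean_one_for_random_panel(self, rng):
        geno = (rng.random((80, 300)) < 0.3).astype(float)
        K = compute_grm(_panel(geno))
        assert np.diag(K).mean() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_all_monomorphic_errors(self):
        with pytest.raises(ValueError):
            compute_grm(_panel([[0, 0], [0, 0]]))


class TestLeverageFilter:
    def test_extreme_line_dropped(self, rng):
        vals = pd.Series(rng.normal(0.7, 0.02, size=167),
                         index=[f"L{i}" for i in range(167)])
        vals.iloc[3] = 3.0
        kept = leverage_filter(vals)
        assert "L3" not in kept
        assert len(kept) >= 160

    def test_no_extremes_all_retained(self):
        vals = pd.Series(np.linspace(0.5, 0.9, 30),
                         index=[f"L{i}" for i in range(30)])
        assert len(leverage_filter(vals)) == 30


class TestMixedGWASScan:
    def _ols_pvalues(self, y, X, W):
        """Independent per-variant OLS F-test oracle (statsmodels)."""
        import statsmodels.api as sm

        out = []
        for j in range(X.shape[1]):
            design = np.column_stack([W, X[:, j]])
            fit = sm.OLS(y, design).fit()
            out.append(fit.pvalues[-1])
        return np.array(out)

    def test_identity_kinship_matches_ols_oracle(self, rng):
        n, m = 60, 80
        geno = (rng.random((n, m)) < rng.uniform(0.1, 0.5, size=m)).astype(float)
        panel = _panel(geno)
        y = pd.Series(rng.normal(size=n), index=panel.line_ids)
        res = MixedGWAS(y, panel, kinship=np.eye(n)).fit()
        tab = res.table.set_index("variant_id")
        poly = geno.std(axis=0) > 0
        oracle = self._ols_pvalues(y.to_numpy(), geno[:, poly],
                                   np.ones((n, 1)))
        got = tab.loc[[f"v{j}" for j in np.flatnonzero(poly)], "p"].to_numpy()
        assert np.max(np.abs(np.log10(got) - np.log10(oracle))) < 0.01

    def test_identity_kinship_matches_ols_with_covariates(self, rng):
        n, m = 50, 40
        geno = (rng.random((n, m)) < 0.4).astype(float)
        panel = _panel(geno)
        cov = pd.DataFrame({"wolbachia": rng.integers(0, 2, n)},
                           index=panel.line_ids)
        y = pd.Series(rng.normal(size=n) + 0.5 * cov["wolbachia"].to_numpy(),
                      index=panel.line_ids)
        res = MixedGWAS(y, panel, cov, kinship=np.eye(n)).fit()
        tab = res.table.set_index("variant_id")
        W = np.column_stack([np.ones(n), cov.to_numpy()])
        poly = geno.std(axis=0) > 0
        oracle = self._ols_pvalues(y.to_numpy(), geno[:, poly], W)
        got = tab.loc[[f"v{j}" for j in np.flatnonzero(poly)], "p"].to_numpy()
        assert np.max(np.abs(np.log10(got) - np.log10(oracle))) < 0.01

    def test_planted_causal_variant_ranks_first(self):
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            n, m = 167, 150
            geno = (rng.random((n, m)) < rng.uniform(0.1, 0.5, m)).astype(float)
            panel = _panel(geno)
            y = 1.5 * geno[:, 42] + rng.normal(size=n)
            res = MixedGWAS(pd.Series(y, index=panel.line_ids), panel).fit()
            if res.table.iloc[0]["variant_id"] == "v42":
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_permuted_response_null_calibration(self, small_sim, rng):
        panel = small_sim["panel"]
        y = pd.Series(rng.permutation(rng.normal(size=panel.n_lines)),
                      index=panel.line_ids)
        res = MixedGWAS(y, panel).fit()
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_affine_response_invariance(self, small_sim, rng):
        panel = small_sim["panel"]
        y = pd.Series(rng.normal(size=panel.n_lines), index=panel.line_ids)
        p1 = MixedGWAS(y, panel).fit().table.set_index("variant_id")["p"]
        p2 = MixedGWAS(3.0 - 2.5 * y, panel).fit().table.set_index(
            "variant_id")["p"]
        assert np.allclose(p1.sort_index(), p2.sort_index(), rtol=1e-6)

    def test_mean_and_cve_share_code_path(self, small_sim, rng):
        panel = small_sim["panel"]
        y = pd.Series(rng.normal(size=panel.n_lines), index=panel.line_ids)
        t_mean = MixedGWAS(y, panel, response_kind="mean").fit().table
        t_cve = MixedGWAS(y, panel, response_kind="cve").fit().table
        assert (t_mean["p"].to_numpy() == t_cve["p"].to_numpy()).all()
        assert set(t_cve["response_kind"]) == {"cve"}

    def test_collinear_covariate_named(self, small_sim):
        panel = small_sim["panel"]
        cov = pd.DataFrame({"a": np.ones(panel.n_lines),
                            "b": np.ones(panel.n_lines)},
                           index=panel.line_ids)
        y = pd.Series(np.arange(panel.n_lines, dtype=float),
                      index=panel.line_ids)
        with pytest.raises(ValueError, match="collinear"):
            MixedGWAS(y, panel, cov).fit()


class TestSelectCandidates:
    def _records(self, m=150, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "variant_id": [f"v{j}" for j in range(m)],
            "pos": rng.permutation(m) * 10 + 1,
            "p": rng.uniform(size=m),
            "maf": rng.uniform(0.01, 0.5, size=m),
            "site_class": rng.choice(["intron", "synonymous", "upstream_1kb"], m),
        })

    def test_filter_after_selection_order(self):
        rec = self._records()
        top = rec.sort_values(["p", "pos", "variant_id"]).head(100)
        expected = top[(top["maf"] > 0.04)
                       & (top["site_class"] != "synonymous")]
        got = select_candidates(rec, 100, 0.04, drop_synonymous=True)
        assert list(got["variant_id"]) == list(expected["variant_id"])
        assert len(got) <= 100

    def test_all_high_maf_keeps_exactly_top_k(self):
        rec = self._records()
        rec["maf"] = 0.5
        got = select_candidates(rec, 100, 0.04, drop_synonymous=False)
        assert len(got) == 100

    def test_maf_threshold_is_strict(self):
        rec = self._records(m=50)
        rec["maf"] = 0.04
        got = select_candidates(rec, 100, 0.04, drop_synonymous=False)
        assert len(got) == 0

    def test_tie_break_invariant_to_input_order(self):
        rec = self._records(m=120, seed=3)
        rec.loc[:, "p"] = 0.5  # all tied: order must come from (pos, id)
        a = select_candidates(rec, 10, 0.0, drop_synonymous=False)
        b = select_candidates(rec.sample(frac=1, random_state=9), 10, 0.0,
                              drop_synonymous=False)
        assert list(a["variant_id"]) == list(b["variant_id"])


def test_qq_table_monotone(small_sim, rng):
    panel = small_sim["panel"]
    y = pd.Series(rng.normal(size=panel.n_lines), index=panel.line_ids)
    qq = MixedGWAS(y, panel).fit().qq_table()
    assert (np.diff(qq["expected"]) <= 0).all()
    assert (np.diff(qq["observed"]) <= 1e-12).all()
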