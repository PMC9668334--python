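"""Single-marker mixed-model association scans on line-level phenotypes.

The model for a line-level response y (trait means or trait CVe values over
``n`` retained lines) at one variant with genotype vector x is

    y = W a + x b + u + e,    u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with W the fixed-effect design (intercept plus binary line covariates such as
endosymbiont infection and inversion markers) and K a realized-relationship
kinship matrix from the panel genotypes. Following the FaST-LMM approach, K is
spectrally decomposed once, the variance ratio delta = se^2/sg^2 is estimated
by maximum likelihood on the covariates-only null model and then held fixed,
and each variant is tested by generalized least squares in the rotated basis
with an F test (1 df) on b.

``MixedGWAS`` is the model object; ``MixedGWAS.fit()`` returns
``MixedGWASResults`` carrying the ranked association table, the fitted
variance ratio and candidate-selection / QQ helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import outside_fences
from .panel import Panel
from .pheno import QCRule

log = logging.getLogger(__name__)


def compute_grm(panel: Panel, kind: str = "standardized") -> np.ndarray:
    """Realized-relationship kinship K = Z Z'/m over polymorphic variants.

    Columns are mean-imputed, then centered and (for ``kind='standardized'``)
    scaled by sqrt(p(1-p)); monomorphic columns are excluded.
    """
    if kind not in ("standardized", "centered"):
        raise ValueError("kind must be 'standardized' or 'centered'")
    G = panel.genotypes.copy()
    col_mean = np.nanmean(G, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(G))
    G[nan_r, nan_c] = col_mean[nan_c]
    p = G.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all variants are monomorphic; cannot build kinship")
    Z = G[:, poly] - p[poly]
    if kind == "standardized":
        Z = Z / np.sqrt(p[poly] * (1 - p[poly]))
    m = Z.shape[1]
    return Z @ Z.T / m


def leverage_filter(line_values: pd.Series, rule: QCRule = QCRule()) -> pd.Index:
    """Drop lines whose summary value lies outside the Tukey fences.

    Mirrors the per-individual QC at the line level: line mean/CVe values with
    strong leverage are removed before association. Returns the retained index.
    """
    vals = line_values.dropna()
    if len(vals) < 8:
        return vals.index
    mask = outside_fences(vals.to_numpy(), k=rule.k,
                          quartile_method=rule.quartile_method)
    dropped = vals.index[mask]
    if len(dropped):
        log.info("leverage filter dropped %d line(s): %s",
                 len(dropped), list(dropped))
    return vals.index[~mask]


def _check_design(W: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(W)
    if rank < W.shape[1]:
        for j in range(1, W.shape[1]):
            others = np.delete(W, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(f"singular fixed-effect design: covariate "
                                 f"{names[j]!r} is collinear")
        raise ValueError("singular fixed-effect design")


def _null_delta_ml(yt: np.ndarray, Wt: np.ndarray, S: np.ndarray) -> float:
    """ML estimate of delta = se^2/sg^2 on the null model in rotated basis."""
    n = len(yt)

    def nll(log10d):
        d = 10.0 ** log10d
        w = 1.0 / (S + d)
        Ws = Wt * np.sqrt(w)[:, None]
        ys = yt * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Ws, ys, rcond=None)
        rss = float(((ys - Ws @ coef) ** 2).sum())
        sg2 = rss / n
        return 0.5 * (n * np.log(2 * np.pi * sg2) + np.sum(np.log(S + d)) + n)

    grid = np.linspace(-5, 5, 21)
    vals = [nll(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    return float(10.0 ** res.x)


@dataclass
class AssociationRecord:
    variant_id: str
    trait: str
    response_kind: str
    beta: float
    se: float
    statistic: float
    p: float
    rank: int


class MixedGWAS:
    """Linear mixed-model single-marker scan over a line panel.

    Parameters
    ----------
    response : Series of line-level values (trait mean or CVe) indexed by
        line_id; NaN lines are dropped.
    panel : genotype Panel.
    covariates : optional DataFrame of binary line covariates indexed by
        line_id (e.g. Wolbachia infection, inversion markers).
    kinship : optional precomputed K over the retained lines; computed from
        the panel with ``kinship_kind`` otherwise.
    trait, response_kind : labels carried into the output table.
    """

    def __init__(self, response: pd.Series, panel: Panel,
                 covariates: pd.DataFrame | None = None,
                 kinship: np.ndarray | None = None,
                 kinship_kind: str = "standardized",
                 trait: str = "", response_kind: str = "mean"):
        if response_kind not in ("mean", "cve"):
            raise ValueError("response_kind must be 'mean' or 'cve'")
        response = response.dropna()
        response.index = response.index.astype(str)
        keep = [l for l in panel.line_ids if l in set(response.index)]
        if len(keep) < 8:
            raise ValueError("need at least 8 lines with response values")
        self.panel = panel.subset_lines(keep)
        self.response = response.loc[keep]
        if covariates is not None:
            covariates = covariates.copy()
            covariates.index = covariates.index.astype(str)
            missing = [l for l in keep if l not in covariates.index]
            if missing:
                raise ValueError(f"covariates missing for lines {missing[:5]}")
            covariates = covariates.loc[keep]
        self.covariates = covariates
        self.kinship = kinship
        self.kinship_kind = kinship_kind
        self.trait = trait
        self.response_kind = response_kind

    def _design(self):
        n = self.panel.n_lines
        if self.covariates is None:
            return np.ones((n, 1)), ["intercept"]
        W = np.column_stack([np.ones(n), self.covariates.to_numpy(dtype=float)])
        return W, ["intercept"] + list(self.covariates.columns)

    def fit(self) -> "MixedGWASResults":
        y = self.response.to_numpy(dtype=float)
        n = len(y)
        W, names = self._design()
        _check_design(W, names)
        K = self.kinship if self.kinship is not None else compute_grm(
            self.panel, self.kinship_kind)
        if K.shape != (n, n):
            raise ValueError("kinship shape does not match retained lines")
        S, U = np.linalg.eigh((K + K.T) / 2)
        S = np.clip(S, 0.0, None)
        yt = U.T @ y
        Wt = U.T @ W
        delta = _null_delta_ml(yt, Wt, S)
        w = 1.0 / (S + delta)
        sw = np.sqrt(w)
        ys = yt * sw
        Ws = Wt * sw[:, None]

        # genotype matrix: mean-impute, rotate, project out fixed effects
        G = self.panel.genotypes.copy()
        col_mean = np.nanmean(G, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(G))
        G[nan_r, nan_c] = col_mean[nan_c]
        p_alt = G.mean(axis=0)
        poly = (p_alt > 0) & (p_alt < 1)
        n_skip = int((~poly).sum())
        if n_skip:
            log.info("skipping %d variant(s) monomorphic in retained lines", n_skip)

        Xs = (U.T @ G) * sw[:, None]
        WtW = Ws.T @ Ws
        proj = np.linalg.solve(WtW, Ws.T)  # (p, n)
        yr = ys - Ws @ (proj @ ys)
        Xr = Xs - Ws @ (proj @ Xs)
        dfree = n - W.shape[1] - 1
        xtx = np.einsum("ij,ij->j", Xr, Xr)
        xty = Xr.T @ yr
        yty = float(yr @ yr)
        ok = poly & (xtx > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(ok, xty / np.where(xtx > 0, xtx, 1.0), np.nan)
            rss = yty - beta * xty
            sigma2 = rss / dfree
            se = np.sqrt(sigma2 / np.where(xtx > 0, xtx, np.nan))
            fstat = (beta / se) ** 2
        pvals = np.where(ok, stats.f.sf(fstat, 1, dfree), np.nan)

        tab = self.panel.variants.copy()
        tab["maf"] = self.panel.maf()
        tab["beta"] = beta
        tab["se"] = se
        tab["statistic"] = fstat
        tab["p"] = pvals
        tab["trait"] = self.trait
        tab["response_kind"] = self.response_kind
        tab = tab[ok].copy()
        tab = tab.sort_values(["p", "pos", "variant_id"],
                              kind="mergesort").reset_index(drop=True)
        tab["rank"] = tab["p"].rank(method="dense").astype(int)
        return MixedGWASResults(self, tab, delta, K, dfree)


class MixedGWASResults:
    """Ranked association table plus fitted variance ratio and helpers."""

    def __init__(self, model: MixedGWAS, table: pd.DataFrame, delta: float,
                 kinship: np.ndarray, df_resid: int):
        self.model = model
        self.table = table
        self.delta = delta
        self.kinship = kinship
        self.df_resid = df_resid

    def summary(self, top: int = 10) -> pd.DataFrame:
        cols = ["rank", "variant_id", "chrom", "pos", "maf", "site_class",
                "beta", "se", "statistic", "p"]
        return self.table.head(top)[cols]

    def qq_table(self) -> pd.DataFrame:
        """Observed vs expected -log10 p quantiles for a QQ plot."""
        obs = np.sort(self.table["p"].to_numpy())
        m = len(obs)
        exp = (np.arange(1, m + 1) - 0.5) / m
        return pd.DataFrame({"expected": -np.log10(exp),
                             "observed": -np.log10(obs)})

    def select_candidates(self, top_k: int = 100, maf_min: float = 0.04,
                          drop_synonymous: bool = True) -> pd.DataFrame:
        return select_candidates(self.table, top_k, maf_min, drop_synonymous)

    def plot_qq(self, ax=None):
        import matplotlib.pyplot as plt

        qq = self.qq_table()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(qq["expected"], qq["observed"], s=6)
        lim = max(qq["expected"].max(), qq["observed"].max())
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax


def lmm_scan(panel: Panel, response: pd.Series,
             covariates: pd.DataFrame | None = None, **kwargs) -> pd.DataFrame:
    """Functional wrapper: fit a MixedGWAS and return the association table."""
    return MixedGWAS(response, panel, covariates, **kwargs).fit().table


def select_candidates(records: pd.DataFrame, top_k: int = 100,
                      maf_min: float = 0.04,
                      drop_synonymous: bool = True) -> pd.DataFrame:
    """Top-k-by-p selection followed by MAF and synonymous-site filters.

    Selection precedes filtering, so the output may hold fewer than ``top_k``
    variants. Ties at the cut are broken deterministically by (position, ID).
    """
    if len(records) < top_k:
        log.warning("only %d tested variants (< top_k=%d): taking all",
                    len(records), top_k)
    ordered = records.sort_values(["p", "pos", "variant_id"], kind="mergesort")
    top = ordered.head(top_k)
    out = top[top["maf"] > maf_min]
    if drop_synonymous:
        out = out[out["site_class"] != "synonymous"]
    return out.reset_index(drop=True)
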