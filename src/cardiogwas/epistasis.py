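"""Exhaustive pairwise interaction scan from focal variants.

For each focal variant f (typically a single-marker GWAS candidate) and every
partner t above a MAF threshold, the line-level model

    y = mu + b_f g_f + b_t g_t + b_ft (g_f * g_t) + e

is fitted by least squares on the 0/1 inbred genotype coding and the
interaction coefficient is tested with a 1-df F test. The partner with the
smallest interaction p-value is reported per focal variant, as in
FastEpistasis-style scans. Partner regressions are solved in closed form from
batched cross-products, which is algebraically identical to fitting each pair
separately, only faster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Panel

log = logging.getLogger(__name__)


@dataclass
class EpistasisRecord:
    focal_variant_id: str
    partner_variant_id: str | None
    statistic: float
    p_interaction: float
    beta_focal: float
    beta_partner: float
    beta_interaction: float


class EpistasisScan:
    """Focal-variant interaction scan over a line panel.

    Parameters
    ----------
    response : line-level Series indexed by line_id.
    panel : genotype Panel.
    focal_ids : iterable of focal variant IDs (must exist in the panel).
    partner_maf_min : strict lower MAF bound for tested partners (default 5%).
    residualize_covariates : optional DataFrame; when given, the response is
        replaced by its OLS residual on [1, covariates] before scanning.
    """

    def __init__(self, response: pd.Series, panel: Panel, focal_ids,
                 partner_maf_min: float = 0.05,
                 residualize_covariates: pd.DataFrame | None = None):
        response = response.dropna()
        response.index = response.index.astype(str)
        keep = [l for l in panel.line_ids if l in set(response.index)]
        self.panel = panel.subset_lines(keep)
        y = response.loc[keep].to_numpy(dtype=float)
        if residualize_covariates is not None:
            C = residualize_covariates.loc[keep].to_numpy(dtype=float)
            W = np.column_stack([np.ones(len(y)), C])
            coef, *_ = np.linalg.lstsq(W, y, rcond=None)
            y = y - W @ coef
        self.y = y
        self.focal_ids = [str(f) for f in focal_ids]
        vid = list(self.panel.variants["variant_id"])
        missing = [f for f in self.focal_ids if f not in vid]
        if missing:
            raise ValueError(f"focal variants not in panel: {missing[:5]}")
        self.partner_maf_min = partner_maf_min

    def fit(self) -> "EpistasisResults":
        panel = self.panel
        y = self.y
        n = len(y)
        G = panel.genotypes
        if np.isnan(G).any():
            G = G.copy()
            col_mean = np.nanmean(G, axis=0)
            r, c = np.nonzero(np.isnan(G))
            G[r, c] = col_mean[c]
        var_tab = panel.variants
        vindex = {v: j for j, v in enumerate(var_tab["variant_id"])}
        maf = panel.maf()
        partner_ok = maf > self.partner_maf_min

        rows = []
        for fid in self.focal_ids:
            jf = vindex[fid]
            gf = G[:, jf]
            if gf.min() == gf.max():
                log.warning("focal variant %s monomorphic in retained lines", fid)
                rows.append(EpistasisRecord(fid, None, np.nan, np.nan,
                                            np.nan, np.nan, np.nan))
                continue
            cand = partner_ok.copy()
            cand[jf] = False
            # partners in perfect LD with the focal carry no interaction signal
            same = np.all(G == gf[:, None], axis=0) | np.all(G == (1 - gf)[:, None], axis=0)
            if (cand & same).any():
                log.info("focal %s: skipping %d partner(s) in perfect LD",
                         fid, int((cand & same).sum()))
            cand &= ~same
            idx = np.flatnonzero(cand)
            if idx.size == 0:
                rows.append(EpistasisRecord(fid, None, np.nan, np.nan,
                                            np.nan, np.nan, np.nan))
                continue
            Gt = G[:, idx]                       # (n, m)
            Gi = Gt * gf[:, None]                # interaction columns
            stat, p, betas, valid = _batched_interaction(y, gf, Gt, Gi, n)
            if not valid.any():
                rows.append(EpistasisRecord(fid, None, np.nan, np.nan,
                                            np.nan, np.nan, np.nan))
                continue
            sub = pd.DataFrame({
                "j": idx[valid],
                "p": p[valid],
                "stat": stat[valid],
                "bf": betas[valid, 1],
                "bt": betas[valid, 2],
                "bi": betas[valid, 3],
            })
            sub["pos"] = var_tab["pos"].to_numpy()[sub["j"]]
            sub["vid"] = var_tab["variant_id"].to_numpy()[sub["j"]]
            best = sub.sort_values(["p", "pos", "vid"], kind="mergesort").iloc[0]
            rows.append(EpistasisRecord(fid, best["vid"], float(best["stat"]),
                                        float(best["p"]), float(best["bf"]),
                                        float(best["bt"]), float(best["bi"])))
        return EpistasisResults(self, rows)


def _batched_interaction(y, gf, Gt, Gi, n):
    """Interaction F tests for all partners of one focal variant at once.

    Builds the 4x4 normal equations of [1, g_f, g_t, g_f*g_t] per partner from
    shared cross-products and compares against the additive 3-term model.
    """
    m = Gt.shape[1]
    one = np.ones(n)
    sy = float(y.sum())
    sf = float(gf.sum())
    sff = float(gf @ gf)
    sfy = float(gf @ y)
    yy = float(y @ y)
    st = Gt.sum(axis=0)
    si = Gi.sum(axis=0)
    stt = np.einsum("ij,ij->j", Gt, Gt)
    sti = np.einsum("ij,ij->j", Gt, Gi)
    sii = np.einsum("ij,ij->j", Gi, Gi)
    sft = gf @ Gt
    sfi = gf @ Gi
    sty = Gt.T @ y
    siy = Gi.T @ y

    XtX = np.empty((m, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = sf
    XtX[:, 0, 2] = XtX[:, 2, 0] = st
    XtX[:, 0, 3] = XtX[:, 3, 0] = si
    XtX[:, 1, 1] = sff
    XtX[:, 1, 2] = XtX[:, 2, 1] = sft
    XtX[:, 1, 3] = XtX[:, 3, 1] = sfi
    XtX[:, 2, 2] = stt
    XtX[:, 2, 3] = XtX[:, 3, 2] = sti
    XtX[:, 3, 3] = sii
    Xty = np.stack([np.full(m, sy), np.full(m, sfy), sty, siy], axis=1)

    valid = np.abs(np.linalg.det(XtX)) > 1e-9
    betas = np.full((m, 4), np.nan)
    rss_full = np.full(m, np.nan)
    if valid.any():
        sol = np.linalg.solve(XtX[valid], Xty[valid][..., None])[..., 0]
        betas[valid] = sol
        rss_full[valid] = yy - np.einsum("ij,ij->i", sol, Xty[valid])

    # reduced (additive) model
    XtXr = XtX[:, :3, :3]
    Xtyr = Xty[:, :3]
    valid_r = np.abs(np.linalg.det(XtXr)) > 1e-9
    rss_red = np.full(m, np.nan)
    if valid_r.any():
        solr = np.linalg.solve(XtXr[valid_r], Xtyr[valid_r][..., None])[..., 0]
        rss_red[valid_r] = yy - np.einsum("ij,ij->i", solr, Xtyr[valid_r])

    dfree = n - 4
    valid = valid & valid_r
    # a perfect interaction fit gives rss_full ~ 0: clamp the denominator so
    # the F statistic saturates instead of being discarded
    denom = np.maximum(rss_full, 1e-12 * max(yy, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (rss_red - rss_full) * dfree / denom
    stat = np.clip(stat, 0.0, None)
    p = np.where(valid,
                 np.maximum(stats.f.sf(stat, 1, dfree), 5e-324), np.nan)
    return stat, p, betas, valid


class EpistasisResults:
    """One best-partner record per focal variant."""

    def __init__(self, model: EpistasisScan, records: list):
        self.model = model
        self.records = records

    @property
    def table(self) -> pd.DataFrame:
        tab = pd.DataFrame([r.__dict__ for r in self.records])
        meta = self.model.panel.variants.set_index("variant_id")
        for role, col in (("focal", "focal_variant_id"),
                          ("partner", "partner_variant_id")):
            tab[f"{role}_chrom"] = [
                meta.loc[v, "chrom"] if v in meta.index else None
                for v in tab[col].fillna("")]
            tab[f"{role}_pos"] = [
                meta.loc[v, "pos"] if v in meta.index else np.nan
                for v in tab[col].fillna("")]
        return tab

    def summary(self) -> pd.DataFrame:
        return self.table[["focal_variant_id", "partner_variant_id",
                           "statistic", "p_interaction"]]


def pairwise_scan(panel: Panel, response: pd.Series, focal_set,
                  partner_maf_min: float = 0.05, **kwargs) -> pd.DataFrame:
    """Functional wrapper: run an EpistasisScan and return its table."""
    return EpistasisScan(response, panel, focal_set, partner_maf_min,
                         **kwargs).fit().table
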