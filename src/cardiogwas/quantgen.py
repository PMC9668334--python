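"""Variance components, broad-sense heritability and Levene variance tests.

A one-way random-effects ANOVA across inbred lines decomposes the phenotypic
variance of individual measurements into an among-line (genetic) component Vg
and a within-line (micro-environmental) component Ve:

    Ve = MS_within
    Vg = max(0, (MS_among - MS_within) / n0),   n0 = (N - sum(n_i^2)/N)/(a-1)
    H2 = Vg / (Vg + Ve)

where ``a`` is the number of lines, ``n_i`` the per-line replicate counts and
``n0`` the effective replicate number for unbalanced designs. The Levene test
for heterogeneity of within-line variance is the one-way fixed-effects ANOVA
on absolute deviations from the per-line center (mean by default; median gives
the Brown-Forsythe variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class VarianceComponents:
    trait: str
    n_lines: int
    n_indiv: int
    ms_among: float
    ms_within: float
    n0: float
    Vg: float
    Ve: float
    Vp: float
    H2: float
    F: float
    p_anova: float


@dataclass
class LeveneResult:
    trait: str
    statistic: float
    df: tuple
    p: float
    center: str


def heritability_from_components(vg: float, ve: float) -> float:
    """Broad-sense heritability H2 = Vg / (Vg + Ve) from variance components."""
    if vg < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    if vg + ve == 0:
        raise ValueError("Vg + Ve must be positive")
    return vg / (vg + ve)


def _line_groups(pheno: pd.DataFrame, trait: str):
    groups = [g.dropna().to_numpy(dtype=float)
              for _, g in pheno.groupby("line_id")[trait]]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError(f"trait {trait}: need >= 2 lines with >= 2 individuals")
    return groups


def anova_components(pheno: pd.DataFrame, trait: str) -> VarianceComponents:
    """One-way random-effects ANOVA variance decomposition for one trait."""
    groups = _line_groups(pheno, trait)
    a = len(groups)
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_among = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - (sizes**2).sum() / N) / (a - 1)
    ve = ms_within
    vg = max(0.0, (ms_among - ms_within) / n0)
    if ve == 0.0:
        warnings.warn(f"trait {trait}: zero within-line variance; H2 set to 1")
        h2 = 1.0
        f = np.inf
        p = 0.0
    else:
        h2 = vg / (vg + ve)
        f = ms_among / ms_within
        p = float(stats.f.sf(f, a - 1, N - a))
    return VarianceComponents(trait, a, int(N), ms_among, ms_within, float(n0),
                              vg, ve, vg + ve, h2, float(f), p)


def levene_test(pheno: pd.DataFrame, trait: str, center: str = "mean") -> LeveneResult:
    """Levene (or Brown-Forsythe, center='median') variance-heterogeneity test."""
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    groups = _line_groups(pheno, trait)
    cfun = np.mean if center == "mean" else np.median
    z = [np.abs(g - cfun(g)) for g in groups]
    a = len(z)
    sizes = np.array([len(g) for g in z], dtype=float)
    N = sizes.sum()
    allz = np.concatenate(z)
    grand = allz.mean()
    means = np.array([g.mean() for g in z])
    ss_among = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(z, means)))
    df = (a - 1, int(N - a))
    if ss_within == 0.0:
        if ss_among == 0.0:
            return LeveneResult(trait, 0.0, df, 1.0, center)
        return LeveneResult(trait, np.inf, df, 0.0, center)
    stat = (ss_among / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(stat, *df))
    return LeveneResult(trait, float(stat), df, p, center)


class TraitVarianceModel:
    """Random-effects variance decomposition of one trait across inbred lines.

    Parameters
    ----------
    pheno : DataFrame with ``line_id`` and the trait column (QC already applied).
    trait : trait column name.
    levene_center : 'mean' (classical Levene) or 'median' (Brown-Forsythe).
    """

    def __init__(self, pheno: pd.DataFrame, trait: str, levene_center: str = "mean"):
        self.pheno = pheno
        self.trait = trait
        self.levene_center = levene_center

    def fit(self) -> "TraitVarianceResults":
        vc = anova_components(self.pheno, self.trait)
        lev = levene_test(self.pheno, self.trait, self.levene_center)
        return TraitVarianceResults(self, vc, lev)


class TraitVarianceResults:
    def __init__(self, model: TraitVarianceModel, components: VarianceComponents,
                 levene: LeveneResult):
        self.model = model
        self.components = components
        self.levene = levene

    @property
    def H2(self) -> float:
        return self.components.H2

    def summary(self) -> pd.DataFrame:
        c = self.components
        return pd.DataFrame([{
            "trait": c.trait, "n_lines": c.n_lines, "n_indiv": c.n_indiv,
            "Vg": c.Vg, "Ve": c.Ve, "Vp": c.Vp, "H2": c.H2,
            "F": c.F, "p_anova": c.p_anova,
            "levene_stat": self.levene.statistic, "levene_p": self.levene.p,
        }])


def quantgen_table(pheno: pd.DataFrame, traits: list, levene_center: str = "mean") -> pd.DataFrame:
    """Per-trait summary table: pooled stats, variance components, Levene p."""
    from .pheno import population_stats

    pop = population_stats(pheno, traits).set_index("trait")
    rows = []
    for trait in traits:
        res = TraitVarianceModel(pheno, trait, levene_center).fit()
        row = res.summary().iloc[0].to_dict()
        row.update(mean=pop.loc[trait, "mean"], sd=pop.loc[trait, "sd"],
                   cv=pop.loc[trait, "cv"])
        rows.append(row)
    cols = ["trait", "n_lines", "n_indiv", "mean", "sd", "cv",
            "Vg", "Ve", "Vp", "H2", "F", "p_anova", "levene_stat", "levene_p"]
    return pd.DataFrame(rows)[cols]
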