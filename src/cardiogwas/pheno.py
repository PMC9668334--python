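"""Cardiac trait derivation, outlier QC and per-line summaries.

Traits follow the semi-intact fly heart assay conventions: per-beat diastolic
(DI) and systolic (SI) intervals give the heart period HP = DI + SI; the
arrhythmia index AI is the standard deviation of per-beat HP normalised by a
central HP value; end-diastolic/systolic diameters (EDD, ESD) give the
fractional shortening FS = (EDD - ESD) / EDD.

Per-line QC uses Tukey fences [Q1 - k*IQR, Q3 + k*IQR] (closed interval, k
defaults to 1.5) applied separately per line and per trait, and lines keep a
trait only when at least ``min_line_n`` observations survive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import outside_fences

log = logging.getLogger(__name__)

#: canonical trait column order
TRAITS = ["DI", "SI", "HP", "EDD", "ESD", "FS", "AI"]


@dataclass
class BeatSeries:
    """Per-beat interval series and diameters for one fly.

    di/si are lists of per-beat diastolic/systolic intervals in seconds;
    edd/esd are diameters in micrometres.
    """

    di: list
    si: list
    edd: float
    esd: float

    def __post_init__(self):
        self.di = list(map(float, self.di))
        self.si = list(map(float, self.si))
        if len(self.di) != len(self.si):
            raise ValueError("di and si must have equal length")
        if any(x <= 0 for x in self.di + self.si):
            raise ValueError("intervals must be positive")
        if self.edd <= 0:
            raise ValueError("EDD must be positive")
        if self.esd < 0:
            raise ValueError("ESD must be non-negative")


@dataclass
class FlyTraits:
    DI: float
    SI: float
    HP: float
    AI: float
    EDD: float
    ESD: float
    FS: float

    def as_dict(self) -> dict:
        return {t: getattr(self, t) for t in TRAITS}


@dataclass
class QCRule:
    """Outlier-removal rule: Tukey fence multiplier and minimum line size."""

    k: float = 1.5
    min_line_n: int = 7
    quartile_method: str = "linear"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.min_line_n < 2:
            raise ValueError("min_line_n must be >= 2")


@dataclass
class LineSummary:
    line_id: str
    trait: str
    n_kept: int
    mean: float
    sd: float
    cve: float
    n_removed: int


def derive_fly_traits(beats: BeatSeries, ai_center: str = "median") -> FlyTraits:
    """Derive the seven per-fly traits from a beat series.

    AI is SD(per-beat HP)/center(per-beat HP); the center is the median by
    default (``ai_center={'median','mean'}``). With fewer than two beats AI is
    undefined and returned as NaN.
    """
    if ai_center not in ("median", "mean"):
        raise ValueError("ai_center must be 'median' or 'mean'")
    di = np.asarray(beats.di, dtype=float)
    si = np.asarray(beats.si, dtype=float)
    hp_per_beat = di + si
    hp = float(np.mean(hp_per_beat))
    if len(hp_per_beat) >= 2:
        center = float(np.median(hp_per_beat) if ai_center == "median" else np.mean(hp_per_beat))
        ai = float(np.std(hp_per_beat, ddof=1) / center)
    else:
        ai = float("nan")
    fs = (beats.edd - beats.esd) / beats.edd
    return FlyTraits(
        DI=float(np.mean(di)),
        SI=float(np.mean(si)),
        HP=hp,
        AI=ai,
        EDD=float(beats.edd),
        ESD=float(beats.esd),
        FS=float(fs),
    )


def qc_outliers(values, rule: QCRule = QCRule()):
    """Flag and drop values strictly outside the Tukey fences.

    Returns ``(kept, removed_mask)``. Boundary values are kept (closed
    interval). With fewer than 4 values no filtering is attempted.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("fewer than 4 values: no outlier filtering applied")
        return v.copy(), np.zeros(v.shape, dtype=bool)
    removed = outside_fences(v, k=rule.k, quartile_method=rule.quartile_method)
    return v[~removed], removed


def read_phenotypes(path) -> pd.DataFrame:
    """Read a per-individual phenotype CSV (line_id, indiv_id, trait columns)."""
    df = pd.read_csv(path)
    required = {"line_id", "indiv_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must contain columns {sorted(required)}")
    df["line_id"] = df["line_id"].astype(str)
    return df


def apply_qc(pheno: pd.DataFrame, rule: QCRule = QCRule(),
             traits: list | None = None) -> pd.DataFrame:
    """Per-line, per-trait outlier removal on a long phenotype table.

    Returns a copy where flagged measurements are set to NaN; a boolean
    ``{trait}__removed`` column records removals for the QC report.
    """
    traits = traits or [t for t in TRAITS if t in pheno.columns]
    out = pheno.copy()
    for trait in traits:
        removed_all = np.zeros(len(out), dtype=bool)
        for _, idx in out.groupby("line_id").groups.items():
            vals = out.loc[idx, trait].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() < 4:
                continue
            mask = outside_fences(vals, k=rule.k, quartile_method=rule.quartile_method)
            removed_all[out.index.get_indexer(idx)] = mask
        out.loc[removed_all, trait] = np.nan
        out[f"{trait}__removed"] = removed_all
    return out


def line_summaries(pheno: pd.DataFrame, rule: QCRule = QCRule(),
                   traits: list | None = None, qc: bool = True) -> pd.DataFrame:
    """Per-line mean, SD (n-1) and CVe per trait after QC.

    Lines with fewer than ``rule.min_line_n`` surviving observations are
    excluded for that trait. CVe = sd/mean is set to NaN (with a warning) when
    the line mean is non-positive.
    """
    traits = traits or [t for t in TRAITS if t in pheno.columns]
    df = apply_qc(pheno, rule, traits) if qc else pheno
    rows = []
    for trait in traits:
        removed_col = f"{trait}__removed"
        for line_id, grp in df.groupby("line_id"):
            vals = grp[trait].dropna().to_numpy(dtype=float)
            n_removed = int(grp[removed_col].sum()) if removed_col in grp else 0
            if len(vals) < rule.min_line_n:
                log.info("line %s dropped for %s (n=%d < %d)",
                         line_id, trait, len(vals), rule.min_line_n)
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1))
            if mean > 0:
                cve = sd / mean
            else:
                warnings.warn(f"non-positive mean for line {line_id}, trait {trait}: "
                              "CVe set to NaN")
                cve = float("nan")
            rows.append(LineSummary(str(line_id), trait, len(vals), mean, sd, cve,
                                    n_removed))
    return pd.DataFrame([r.__dict__ for r in rows])


def line_value_matrix(summaries: pd.DataFrame, kind: str = "mean") -> pd.DataFrame:
    """Pivot line summaries to a line x trait matrix of means or CVe values."""
    if kind not in ("mean", "cve"):
        raise ValueError("kind must be 'mean' or 'cve'")
    return summaries.pivot(index="line_id", columns="trait", values=kind)


def population_stats(pheno: pd.DataFrame, traits: list | None = None) -> pd.DataFrame:
    """Whole-population per-trait statistics over retained individuals.

    Returns per trait: number of contributing lines and individuals, pooled
    mean, SD (n-1) and CV = sd/mean.
    """
    traits = traits or [t for t in TRAITS if t in pheno.columns]
    rows = []
    for trait in traits:
        sub = pheno[["line_id", trait]].dropna()
        if len(sub) < 2:
            raise ValueError(f"trait {trait}: need >= 2 observations for SD")
        vals = sub[trait].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append({
            "trait": trait,
            "n_lines": int(sub["line_id"].nunique()),
            "n_indiv": int(len(sub)),
            "mean": mean,
            "sd": sd,
            "cv": sd / mean,
        })
    return pd.DataFrame(rows)


def write_qc_report(pheno_qc: pd.DataFrame, path) -> None:
    """Write a TSV report of removed observations with removal reasons."""
    removed_cols = [c for c in pheno_qc.columns if c.endswith("__removed")]
    records = []
    for col in removed_cols:
        trait = col[: -len("__removed")]
        sub = pheno_qc.loc[pheno_qc[col], ["line_id", "indiv_id"]].copy()
        sub["trait"] = trait
        sub["reason"] = "outside_tukey_fences"
        records.append(sub)
    report = (pd.concat(records, ignore_index=True) if records
              else pd.DataFrame(columns=["line_id", "indiv_id", "trait", "reason"]))
    report.to_csv(path, sep="\t", index=False)
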