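"""Synthetic inbred-panel generator with known ground truth.

Emulates the design of a DGRP-style screen: ~167 homozygous lines assayed for
~12 individuals each over seven cardiac traits (DI, SI, HP = DI + SI, EDD,
ESD, FS, AI), with line-level additive SNP effects on trait means,
variance-QTLs that scale the within-line SD, binary line covariates
(Wolbachia-like infection and inversion-like markers) and occasional
heavy-tailed outliers. Trait baselines default to the observed scales of the
real panel (population mean, within-line SD = sqrt(Ve), between-line SD =
sqrt(Vg)). Genotypes are haploid-equivalent 0/1; variants are independent by
default with an optional crude block-correlation mode.

The synthetic genome is a random nucleotide sequence tiled with gene models
(UTR/exon/intron substructure) separated by intergenic gaps > 2 kb, so that
mapped and unmapped variants both exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_rng, spawn_seed
from .genemap import GeneModel
from .panel import Panel

#: traits simulated directly; HP is derived as DI + SI per individual
SIM_TRAITS = ["DI", "SI", "EDD", "ESD", "FS", "AI"]
ALL_TRAITS = ["DI", "SI", "HP", "EDD", "ESD", "FS", "AI"]

#: (population mean, within-line SD, between-line SD) per simulated trait,
#: on the scales observed in the reference panel
DEFAULT_BASELINES = {
    "DI": (0.4638, 0.2088, 0.1609),
    "SI": (0.2166, 0.0231, 0.0224),
    "EDD": (79.42, 9.295, 10.63),
    "ESD": (51.05, 6.819, 6.626),
    "FS": (0.3538, 0.0558, 0.0396),
    "AI": (0.2475, 0.2520, 0.1487),
}

# gene template (relative 1-based intervals within a 2000 bp gene span)
_GENE_LEN = 2000
_GAP = 2500  # intergenic gap; > 2 kb so some variants stay unmapped
_TEMPLATE = {
    "utr5": [(1, 150)],
    "exons": [(151, 600), (1101, 1600), (1751, 1850)],
    "utr3": [(1851, 2000)],
}


@dataclass
class SimConfig:
    n_lines: int = 167
    n_per_line: int = 12
    n_variants: int = 5000
    genome_length: int = 250_000
    maf_range: tuple = (0.05, 0.5)
    n_causal_mean: int = 10
    n_causal_var: int = 5
    beta_mean: float = 0.3          # additive effect, trait-SD units
    gamma_var: float = 1.5          # within-line SD factor per alt allele
    trait_baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    covariate_prevalence: float = 0.5
    covariate_effect: float = 0.1   # trait-SD units
    outlier_rate: float = 0.01
    ld_block_size: int = 0          # 0 = independent variants
    heavy_tail_df: float | None = None  # Student-t noise when set
    seed: int = 0

    def __post_init__(self):
        if min(self.n_lines, self.n_per_line, self.n_variants) <= 0:
            raise ValueError("counts must be positive")
        if self.n_causal_mean > self.n_variants or self.n_causal_var > self.n_variants:
            raise ValueError("n_causal_* must not exceed n_variants")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    causal_mean_variants: dict  # variant_id -> {"trait", "beta"}
    causal_var_variants: dict   # variant_id -> {"trait", "gamma"}
    line_genetic_values: pd.DataFrame  # lines x traits
    simulated_H2: dict          # trait -> realized H2

    def to_json(self, path) -> None:
        payload = {
            "causal_mean_variants": self.causal_mean_variants,
            "causal_var_variants": self.causal_var_variants,
            "line_genetic_values": self.line_genetic_values.to_dict(),
            "simulated_H2": self.simulated_H2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _tile_gene_models(genome_length: int) -> list:
    genes = []
    pos = _GAP + 1
    i = 0
    while pos + _GENE_LEN - 1 + _GAP <= genome_length:
        i += 1
        strand = "+" if i % 2 else "-"
        start, end = pos, pos + _GENE_LEN - 1

        def shift(ivs):
            return [(start + a - 1, start + b - 1) for a, b in ivs]

        if strand == "+":
            utr5, utr3 = shift(_TEMPLATE["utr5"]), shift(_TEMPLATE["utr3"])
        else:  # mirror the template so the 5'UTR sits at the high-coord end
            span = _GENE_LEN + 1

            def mirror(ivs):
                return [(start + span - b - 1, start + span - a - 1)
                        for a, b in ivs]

            utr5, utr3 = mirror(_TEMPLATE["utr5"]), mirror(_TEMPLATE["utr3"])
        if strand == "+":
            exons = [(start + a - 1, start + b - 1) for a, b in _TEMPLATE["exons"]]
        else:
            span = _GENE_LEN + 1
            exons = sorted((start + span - b - 1, start + span - a - 1)
                           for a, b in _TEMPLATE["exons"])
        genes.append(GeneModel(f"gene{i:04d}", "chr1", strand, start, end,
                               exons=exons, utr5=utr5, utr3=utr3))
        pos = end + _GAP + 1
    return genes


def _site_class(pos: int, genes: list, rng) -> str:
    for g in genes:
        if g.start <= pos <= g.end:
            if any(a <= pos <= b for a, b in g.utr5):
                return "5'UTR"
            if any(a <= pos <= b for a, b in g.utr3):
                return "3'UTR"
            if any(a <= pos <= b for a, b in g.exons):
                return "synonymous" if rng.random() < 0.5 else "non-synonymous"
            return "intron"
        d = min(abs(pos - g.start), abs(pos - g.end))
        if d <= 1000:
            if g.strand == "+":
                return "upstream_1kb" if pos < g.start else "downstream_1kb"
            return "upstream_1kb" if pos > g.end else "downstream_1kb"
    return "NA"


def simulate_panel(config: SimConfig):
    """Simulate (Panel, gene models, genome) for one synthetic chromosome."""
    rng = check_rng(config.seed)
    L = config.genome_length
    if config.n_variants > L // 4:
        raise ValueError(f"{config.n_variants} variants do not fit a genome of "
                         f"length {L}")
    genome_arr = rng.choice(list("ACGT"), size=L)
    genome = {"chr1": "".join(genome_arr)}
    genes = _tile_gene_models(L)

    positions = np.sort(rng.choice(np.arange(1, L + 1), size=config.n_variants,
                                   replace=False))
    refs = [genome["chr1"][p - 1] for p in positions]
    alts = [rng.choice([b for b in "ACGT" if b != r]) for r in refs]

    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_variants)
    if config.ld_block_size > 1:
        geno = np.empty((config.n_lines, config.n_variants))
        j = 0
        while j < config.n_variants:
            block = slice(j, min(j + config.ld_block_size, config.n_variants))
            seedcol = (rng.random(config.n_lines) < freqs[j]).astype(float)
            for jj in range(block.start, block.stop):
                flip = rng.random(config.n_lines) < 0.1
                geno[:, jj] = np.where(flip, 1 - seedcol, seedcol)
            j = block.stop
    else:
        geno = (rng.random((config.n_lines, config.n_variants))
                < freqs[None, :]).astype(float)

    variants = pd.DataFrame({
        "variant_id": [f"v{j:05d}" for j in range(config.n_variants)],
        "chrom": "chr1",
        "pos": positions.astype(int),
        "ref": refs,
        "alt": alts,
        "site_class": [_site_class(int(p), genes, rng) for p in positions],
    })
    line_ids = [f"line{i:03d}" for i in range(1, config.n_lines + 1)]
    return Panel(line_ids, geno, variants), genes, genome


def simulate_phenotypes(panel: Panel, config: SimConfig):
    """Simulate per-individual phenotypes with known causal architecture.

    Returns (phenotype table, covariate table, TruthRecord). Individual values
    are baseline + additive causal effects + covariate effects + line random
    effect + within-line noise whose SD is multiplied by gamma per alternate
    allele at each variance-QTL; outliers inflate the noise draw tenfold.
    """
    rng = check_rng(spawn_seed(check_rng(config.seed)) + 1)
    n, m = panel.n_lines, panel.n_variants
    vids = list(panel.variants["variant_id"])

    causal_idx = rng.choice(m, size=config.n_causal_mean, replace=False)
    remaining = np.setdiff1d(np.arange(m), causal_idx)
    var_idx = rng.choice(remaining, size=config.n_causal_var, replace=False)

    causal_mean, causal_var = {}, {}
    sigma_p = {t: float(np.hypot(w, b))
               for t, (mu, w, b) in config.trait_baselines.items()}
    betas = {t: np.zeros(m) for t in SIM_TRAITS}
    for j in causal_idx:
        trait = SIM_TRAITS[rng.integers(len(SIM_TRAITS))]
        beta = config.beta_mean * sigma_p[trait] * rng.choice([-1.0, 1.0])
        betas[trait][j] = beta
        causal_mean[vids[j]] = {"trait": trait, "beta": float(beta)}
    log_gamma = {t: np.zeros(m) for t in SIM_TRAITS}
    for j in var_idx:
        trait = SIM_TRAITS[rng.integers(len(SIM_TRAITS))]
        log_gamma[trait][j] = np.log(config.gamma_var)
        causal_var[vids[j]] = {"trait": trait, "gamma": float(config.gamma_var)}

    G = np.nan_to_num(panel.genotypes, nan=0.0)
    wolb = (rng.random(n) < config.covariate_prevalence).astype(int)
    inv1 = (rng.random(n) < config.covariate_prevalence).astype(int)
    inv2 = (rng.random(n) < config.covariate_prevalence).astype(int)
    covariates = pd.DataFrame({"wolbachia": wolb, "inv1": inv1, "inv2": inv2},
                              index=pd.Index(panel.line_ids, name="line_id"))

    line_vals = {}      # genetic value (causal + line random effect)
    within_sd = {}      # per-line noise SD after variance-QTL scaling
    for t in SIM_TRAITS:
        mu, w_sd, b_sd = config.trait_baselines[t]
        genetic = G @ betas[t] + rng.normal(0.0, b_sd, size=n)
        line_vals[t] = genetic
        within_sd[t] = w_sd * np.exp(G @ log_gamma[t])

    rows = []
    per_line_values = {t: [] for t in SIM_TRAITS}
    for i, lid in enumerate(panel.line_ids):
        for ind in range(config.n_per_line):
            rec = {"line_id": lid, "indiv_id": f"{lid}_f{ind + 1}"}
            for t in SIM_TRAITS:
                mu, w_sd, b_sd = config.trait_baselines[t]
                if config.heavy_tail_df:
                    noise = rng.standard_t(config.heavy_tail_df) * within_sd[t][i]
                else:
                    noise = rng.normal(0.0, within_sd[t][i])
                if config.outlier_rate and rng.random() < config.outlier_rate:
                    noise *= 10.0
                cov_eff = sigma_p[t] * (config.covariate_effect * wolb[i]
                                        + 0.5 * config.covariate_effect * (inv1[i] - inv2[i]))
                rec[t] = mu + line_vals[t][i] + cov_eff + noise
            rec["HP"] = rec["DI"] + rec["SI"]
            rows.append(rec)
    pheno = pd.DataFrame(rows)[["line_id", "indiv_id"] + ALL_TRAITS]

    truth_vals = pd.DataFrame(line_vals, index=panel.line_ids)
    truth_vals["HP"] = truth_vals["DI"] + truth_vals["SI"]
    sim_h2 = {}
    for t in ALL_TRAITS:
        vg = float(np.var(truth_vals[t], ddof=1))
        if t == "HP":
            ve = float(np.mean(within_sd["DI"]**2 + within_sd["SI"]**2))
        else:
            ve = float(np.mean(within_sd[t] ** 2))
        sim_h2[t] = vg / (vg + ve)
    return pheno, covariates, TruthRecord(causal_mean, causal_var, truth_vals,
                                          sim_h2)


def simulate_motif_windows(n_seqs: int, length: int, motif: str,
                           plant_fraction: float, seed=0,
                           composition=None) -> list:
    """I.i.d. background sequences with the motif planted in a random subset.

    Each sequence independently receives one motif instance at a uniform
    random offset with probability ``plant_fraction``.
    """
    if not (0 <= plant_fraction <= 1):
        raise ValueError("plant_fraction must be in [0, 1]")
    if length < len(motif):
        raise ValueError("length must be >= motif length")
    rng = check_rng(seed)
    p = np.asarray(composition if composition is not None else [0.25] * 4,
                   dtype=float)
    p = p / p.sum()
    seqs = []
    for _ in range(n_seqs):
        s = rng.choice(list("ACGT"), size=length, p=p)
        if rng.random() < plant_fraction:
            off = rng.integers(0, length - len(motif) + 1)
            s[off:off + len(motif)] = list(motif)
        seqs.append("".join(s))
    return seqs


def simulate_conservation_inputs(fly_genes: list, seed=0,
                                 ortholog_fraction: float = 0.54,
                                 disease_fraction: float = 0.10):
    """Orthologue map and a disease gene list over a fly gene universe.

    Roughly half the fly genes receive a human orthologue; a subset of the
    human genes forms a 'cardiac disorder'-style disease list.
    """
    rng = check_rng(seed)
    fly_genes = list(fly_genes)
    has_orth = rng.random(len(fly_genes)) < ortholog_fraction
    rows = [{"fly_gene": g, "human_gene": f"HS_{g.upper()}"}
            for g, h in zip(fly_genes, has_orth) if h]
    orth = pd.DataFrame(rows, columns=["fly_gene", "human_gene"])
    human = list(orth["human_gene"])
    n_dis = max(1, int(round(disease_fraction * len(human))))
    disease = set(rng.choice(human, size=n_dis, replace=False)) if human else set()
    return orth, {"cardiac_disorders": disease}


def write_genome_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
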