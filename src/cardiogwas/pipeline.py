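"""End-to-end orchestration of the analysis stages.

Stage order: phenotype QC -> variance components / Levene -> mean GWAS ->
CVe GWAS -> epistasis from GWAS candidates -> variant-to-gene mapping ->
gene-set enrichment / conservation -> variant-window motif discovery. Every
stage writes its tabular outputs into the run directory and is recorded in a
manifest (file hashes, settings, seed, version) so identical configurations
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import MixedGWAS, compute_grm, leverage_filter
from .enrich import (combine_gene_sets, conservation_table,
                     pairwise_overlap_matrix)
from .epistasis import EpistasisScan
from .genemap import (category_bias_test, category_counts, map_variants,
                      mapped_gene_set, read_gff3, write_gff3)
from .motifs import (annotate_pssms, assemble_pssms, extract_windows,
                     kmer_overrepresentation, read_meme, write_meme,
                     write_windows_fasta)
from .panel import Panel
from .pheno import (TRAITS, QCRule, apply_qc, line_summaries,
                    line_value_matrix, population_stats, read_phenotypes,
                    write_qc_report)
from .quantgen import quantgen_table
from .syndata import (SimConfig, simulate_conservation_inputs, simulate_panel,
                      simulate_phenotypes, write_genome_fasta)

log = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid run configuration (exit code 2)."""


class DataError(Exception):
    """Invalid or inconsistent input data (exit code 3)."""


@dataclass
class RunConfig:
    out_dir: str = "cardiogwas_run"
    seed: int = 0
    synthetic: bool = True
    sim: SimConfig | None = None
    # user-data paths (used when synthetic=False)
    panel_path: str | None = None
    pheno_path: str | None = None
    gff3_path: str | None = None
    genome_path: str | None = None
    ortholog_path: str | None = None
    disease_paths: dict = field(default_factory=dict)
    motif_library_path: str | None = None
    # stage settings
    qc_k: float = 1.5
    min_line_n: int = 7
    traits: list = field(default_factory=lambda: list(TRAITS))
    top_k: int = 100
    maf_min: float = 0.04
    partner_maf_min: float = 0.05
    n_focal_epistasis: int = 20
    flank: int = 75
    k_range: tuple = (6, 7, 8)
    e_threshold: float = 1e-4
    genome_size_for_enrichment: int = 17_500
    run_motifs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list = []

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
        written.append(path)
        return path

    # ---------------------------------------------------------- inputs
    if config.synthetic:
        sim = config.sim or SimConfig(seed=config.seed)
        panel, genes, genome = simulate_panel(sim)
        pheno, covariates, truth = simulate_phenotypes(panel, sim)
        panel.to_vcf(out / "panel.vcf")
        panel.to_tsv(out / "panel.tsv")
        write_gff3(genes, out / "genes.gff3")
        write_genome_fasta(genome, out / "genome.fa")
        pheno.to_csv(out / "phenotypes.csv", index=False)
        covariates.to_csv(out / "covariates.tsv", sep="\t")
        truth.to_json(out / "truth.json")
        written += [out / n for n in ("panel.vcf", "panel.tsv", "genes.gff3",
                                      "genome.fa", "phenotypes.csv",
                                      "covariates.tsv", "truth.json")]
        orth_map, disease_lists = simulate_conservation_inputs(
            [g.gene_id for g in genes], seed=sim.seed)
        genome_size = len(genes)
    else:
        if not config.panel_path or not config.pheno_path:
            raise ConfigError("panel_path and pheno_path are required for "
                              "non-synthetic runs")
        if config.run_motifs and not config.genome_path:
            raise ConfigError("motif discovery enabled but no genome_path given")
        p = Path(config.panel_path)
        panel = Panel.from_vcf(p) if p.suffix == ".vcf" else Panel.from_tsv(p)
        pheno = read_phenotypes(config.pheno_path)
        covariates = None
        genes = read_gff3(config.gff3_path) if config.gff3_path else []
        genome = None
        if config.genome_path:
            from pyfaidx import Fasta

            fa = Fasta(config.genome_path)
            genome = {name: str(fa[name][:]) for name in fa.keys()}
        if config.ortholog_path:
            from .enrich import read_gene_set, read_ortholog_map

            orth_map = read_ortholog_map(config.ortholog_path)
            disease_lists = {k: read_gene_set(v)
                             for k, v in config.disease_paths.items()}
        else:
            orth_map, disease_lists = None, {}
        genome_size = config.genome_size_for_enrichment
    if config.run_motifs and genome is None:
        raise ConfigError("motif discovery enabled but no genome available")

    traits = [t for t in config.traits if t in pheno.columns]
    if not traits:
        raise DataError("no configured trait column found in phenotype table")

    rule = QCRule(k=config.qc_k, min_line_n=config.min_line_n)

    # ---------------------------------------------------------- pheno QC
    pheno_qc = apply_qc(pheno, rule, traits)
    write_qc_report(pheno_qc, out / "qc_report.tsv")
    written.append(out / "qc_report.tsv")
    summaries = line_summaries(pheno, rule, traits)
    save(summaries, "line_summaries.tsv")
    save(population_stats(pheno_qc, traits), "population_stats.tsv")

    # ---------------------------------------------------------- quantgen
    save(quantgen_table(pheno_qc, traits), "quantgen_table.tsv")

    # ---------------------------------------------------------- GWAS (mean, CVe)
    kin = compute_grm(panel)
    kin_index = {l: i for i, l in enumerate(panel.line_ids)}
    candidates = {}
    gene_sets_by_trait = {}
    for kind in ("mean", "cve"):
        values = line_value_matrix(summaries, kind)
        all_cand = []
        for trait in traits:
            if trait not in values.columns:
                continue
            resp = values[trait].dropna()
            keep = leverage_filter(resp, rule)
            resp = resp.loc[keep]
            idx = [kin_index[l] for l in resp.index if l in kin_index]
            resp = resp[[l in kin_index for l in resp.index]]
            K = kin[np.ix_(idx, idx)]
            cov = covariates.loc[resp.index] if covariates is not None else None
            res = MixedGWAS(resp, panel, cov, kinship=K, trait=trait,
                            response_kind=kind).fit()
            save(res.table, f"assoc_{kind}_{trait}.tsv")
            save(res.qq_table(), f"qq_{kind}_{trait}.tsv")
            cand = res.select_candidates(config.top_k, config.maf_min)
            all_cand.append(cand)
        candidates[kind] = (pd.concat(all_cand, ignore_index=True)
                            if all_cand else pd.DataFrame())
        save(candidates[kind], f"candidates_{kind}.tsv")

    # ---------------------------------------------------------- epistasis
    values = line_value_matrix(summaries, "mean")
    epi_tables = []
    for trait in traits:
        cand = candidates["mean"]
        cand_t = cand[cand["trait"] == trait] if len(cand) else cand
        if not len(cand_t):
            continue
        focal = list(cand_t["variant_id"].head(config.n_focal_epistasis))
        resp = values[trait].dropna()
        res = EpistasisScan(resp, panel, focal,
                            partner_maf_min=config.partner_maf_min).fit()
        tab = res.table
        tab["trait"] = trait
        epi_tables.append(tab)
    epi = (pd.concat(epi_tables, ignore_index=True)
           if epi_tables else pd.DataFrame())
    save(epi, "epistasis.tsv")

    # ---------------------------------------------------------- gene mapping
    cand_variants = panel.variants[
        panel.variants["variant_id"].isin(candidates["mean"].get("variant_id", []))]
    mapping = map_variants(cand_variants, genes)
    save(mapping, "variant_gene_map.tsv")
    bias = None
    if len(mapping) and len(panel.variants):
        background = map_variants(panel.variants, genes)
        try:
            bias = category_bias_test(category_counts(mapping),
                                      category_counts(background))
            payload = {"chi2": bias.chi2, "df": bias.df, "p": bias.p,
                       "residuals": bias.pearson_residuals.to_dict()}
            (out / "category_bias.json").write_text(json.dumps(payload, indent=1))
            written.append(out / "category_bias.json")
        except ValueError as err:
            log.warning("category bias test skipped: %s", err)

    # ---------------------------------------------------------- enrichment
    single_genes = mapped_gene_set(mapping)
    epi_partner_variants = panel.variants[
        panel.variants["variant_id"].isin(
            epi["partner_variant_id"].dropna() if len(epi) else [])]
    epi_genes = mapped_gene_set(map_variants(epi_partner_variants, genes))
    union, inter, enr = combine_gene_sets(single_genes or {"_none"},
                                          epi_genes or {"_none"},
                                          genome_size)
    enrich_payload = {
        "n_single_marker_genes": len(single_genes),
        "n_epistasis_genes": len(epi_genes),
        "n_union": len(union), "n_intersection": len(inter),
        "overlap_fold_change": enr.fold_change, "overlap_p": enr.p,
    }
    if orth_map is not None and len(union):
        cons = conservation_table({"gwas_mean": union}, orth_map,
                                  disease_lists, genome_size)
        save(cons, "conservation.tsv")
    (out / "gene_sets.json").write_text(json.dumps(enrich_payload, indent=1))
    written.append(out / "gene_sets.json")

    # ---------------------------------------------------------- motifs
    if config.run_motifs and len(cand_variants):
        noncoding = cand_variants[
            ~cand_variants["site_class"].isin(["synonymous", "non-synonymous"])]
        if len(noncoding) >= 10:
            windows = extract_windows(noncoding, genome, config.flank)
            write_windows_fasta(windows, out / "windows.fa")
            written.append(out / "windows.fa")
            kmers = kmer_overrepresentation(
                windows, config.k_range, "intrinsic", config.e_threshold,
                seed=config.seed)
            save(kmers, "kmers.tsv")
            pssms = assemble_pssms(kmers)
            if pssms:
                write_meme(pssms, out / "motifs.meme")
                written.append(out / "motifs.meme")
                if config.motif_library_path:
                    library = read_meme(config.motif_library_path)
                    save(annotate_pssms(pssms, library), "motif_annotation.tsv")
        else:
            log.info("fewer than 10 non-coding candidate windows; motif stage "
                     "skipped")

    # ---------------------------------------------------------- manifest
    settings = dataclasses.asdict(config)
    if settings.get("sim") is not None:
        settings["sim"] = dataclasses.asdict(config.sim) if config.sim else None
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "settings": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in settings.items()},
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
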