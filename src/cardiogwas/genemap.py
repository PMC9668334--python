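"""Variant-to-gene mapping and genomic-category bias testing.

Mapping rules (applied per variant, 1-based inclusive coordinates):

(i)  a variant inside a gene span (TSS..TES) maps to that gene, with category
     5'UTR / 3'UTR / exon (synonymous or non-synonymous, taken from the
     variant annotation) / intron by containment, in that precedence;
(ii) otherwise, a variant within 1 kb of a gene-span boundary maps to that
     gene as upstream_1kb or downstream_1kb depending on strand;
(iii) otherwise the variant is unmapped (NA).

Rule (i) takes precedence over (ii); a variant may map to several genes (e.g.
inside gene A and within 1 kb of gene B). For category counting each variant
contributes its single highest-precedence category
(UTR/exon/intron > upstream > downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: precedence for collapsing a variant's mappings to one category
CATEGORY_PRECEDENCE = ["5'UTR", "3'UTR", "exon_nonsyn", "exon_syn", "intron",
                       "upstream_1kb", "downstream_1kb", "NA"]

PROXIMAL_DISTANCE = 1000  # bp, inclusive


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # gene span, 1-based inclusive; start <= end always
    end: int
    exons: list = field(default_factory=list)       # list of (start, end)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class Mapping:
    gene_id: str
    category: str


@dataclass
class MappingResult:
    variant_id: str
    mappings: list  # list of Mapping; empty iff unmapped

    @property
    def is_mapped(self) -> bool:
        return len(self.mappings) > 0

    @property
    def category(self) -> str:
        """Highest-precedence single category (NA if unmapped)."""
        if not self.mappings:
            return "NA"
        cats = {m.category for m in self.mappings}
        for c in CATEGORY_PRECEDENCE:
            if c in cats:
                return c
        return "NA"


def _within(pos: int, intervals) -> bool:
    return any(a <= pos <= b for a, b in intervals)


def _categorize_inside(gene: GeneModel, pos: int, exonic_class: str) -> str:
    if _within(pos, gene.utr5):
        return "5'UTR"
    if _within(pos, gene.utr3):
        return "3'UTR"
    if _within(pos, gene.exons):
        return "exon_nonsyn" if exonic_class == "non-synonymous" else "exon_syn"
    return "intron"


def map_variant(chrom: str, pos: int, variant_id: str, gene_models: list,
                exonic_class: str = "synonymous",
                max_distance: int = PROXIMAL_DISTANCE) -> MappingResult:
    """Map one variant to genes by the containment-then-proximity rules.

    ``exonic_class`` is the site annotation consumed from the variant table
    ('synonymous' or 'non-synonymous'); it only matters for exonic hits.
    """
    mappings = []
    for gene in gene_models:
        if gene.chrom != chrom:
            continue
        if gene.start <= pos <= gene.end:
            mappings.append(Mapping(gene.gene_id,
                                    _categorize_inside(gene, pos, exonic_class)))
            continue
        dist = min(abs(pos - gene.start), abs(pos - gene.end))
        if dist <= max_distance:
            if gene.strand == "+":
                cat = "upstream_1kb" if pos < gene.start else "downstream_1kb"
            else:
                cat = "upstream_1kb" if pos > gene.end else "downstream_1kb"
            mappings.append(Mapping(gene.gene_id, cat))
    return MappingResult(variant_id, mappings)


def map_variants(variants: pd.DataFrame, gene_models: list,
                 max_distance: int = PROXIMAL_DISTANCE) -> pd.DataFrame:
    """Map a variant table; returns one row per (variant, gene) mapping plus
    an NA row per unmapped variant.

    Expects columns variant_id, chrom, pos and optionally site_class (used to
    resolve exonic synonymous/non-synonymous status).
    """
    by_chrom: dict = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    # vectorized prefilter: only genes whose padded span contains the variant
    # need the detailed per-gene rules
    spans = {c: (np.array([g.start for g in gs]), np.array([g.end for g in gs]))
             for c, gs in by_chrom.items()}
    rows = []
    for rec in variants.itertuples(index=False):
        exonic = getattr(rec, "site_class", "synonymous")
        genes_c = by_chrom.get(rec.chrom, [])
        if genes_c:
            starts, ends = spans[rec.chrom]
            hit = np.flatnonzero((starts <= rec.pos + max_distance)
                                 & (ends >= rec.pos - max_distance))
            genes_c = [genes_c[i] for i in hit]
        res = map_variant(rec.chrom, int(rec.pos), rec.variant_id,
                          genes_c, exonic_class=exonic,
                          max_distance=max_distance)
        if res.mappings:
            for m in res.mappings:
                rows.append({"variant_id": rec.variant_id, "gene_id": m.gene_id,
                             "category": m.category,
                             "collapsed_category": res.category})
        else:
            rows.append({"variant_id": rec.variant_id, "gene_id": None,
                         "category": "NA", "collapsed_category": "NA"})
    return pd.DataFrame(rows)


def mapped_gene_set(mapping_table: pd.DataFrame) -> set:
    return set(mapping_table["gene_id"].dropna())


def category_counts(mapping_table: pd.DataFrame) -> pd.Series:
    """One highest-precedence category per variant, tabulated."""
    per_variant = mapping_table.groupby("variant_id")["collapsed_category"].first()
    return per_variant.value_counts()


@dataclass
class CategoryBiasResult:
    observed: pd.Series
    expected: pd.Series
    chi2: float
    df: int
    p: float
    pearson_residuals: pd.Series


def category_bias_test(candidate_counts: pd.Series,
                       background_counts: pd.Series) -> CategoryBiasResult:
    """Pearson chi-square test of candidate category counts against background
    proportions, with per-category residuals (O-E)/sqrt(E)."""
    cats = list(background_counts.index)
    extra = set(candidate_counts.index) - set(cats)
    if extra:
        raise ValueError(f"categories {sorted(extra)} absent from background; "
                         "merge categories before testing")
    obs = candidate_counts.reindex(cats).fillna(0).astype(float)
    bg = background_counts.astype(float)
    if (bg <= 0).any():
        raise ValueError("background categories must have positive counts; "
                         "merge zero-count categories")
    expected = bg / bg.sum() * obs.sum()
    resid = (obs - expected) / np.sqrt(expected)
    chi2 = float((resid**2).sum())
    df = len(cats) - 1
    p = float(stats.chi2.sf(chi2, df))
    return CategoryBiasResult(obs, expected, chi2, df, p, resid)


# ----------------------------------------------------------------- GFF3 I/O

def write_gff3(gene_models: list, path) -> None:
    """Write gene models as GFF3 (gene, mRNA, exon, UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_models:
            base = f"{g.chrom}\tcardiogwas\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(base + f"gene\t{g.start}\t{g.end}" + tail
                     + f"\tID={g.gene_id}\n")
            fh.write(base + f"mRNA\t{g.start}\t{g.end}" + tail
                     + f"\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(base + f"exon\t{a}\t{b}" + tail
                         + f"\tID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n")
            for a, b in g.utr5:
                fh.write(base + f"five_prime_UTR\t{a}\t{b}" + tail
                         + f"\tParent={g.gene_id}.t1\n")
            for a, b in g.utr3:
                fh.write(base + f"three_prime_UTR\t{a}\t{b}" + tail
                         + f"\tParent={g.gene_id}.t1\n")


def read_gff3(path) -> list:
    """Read gene models from a GFF3 with gene/mRNA/exon/UTR features."""
    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "phase", "attrs"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols,
                     dtype={"chrom": str})

    def attr(s, key):
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1:]
        return None

    genes: dict = {}
    tx_to_gene: dict = {}
    for rec in df.itertuples(index=False):
        if rec.type == "gene":
            gid = attr(rec.attrs, "ID")
            genes[gid] = GeneModel(gid, rec.chrom, rec.strand,
                                   int(rec.start), int(rec.end))
        elif rec.type == "mRNA":
            tx_to_gene[attr(rec.attrs, "ID")] = attr(rec.attrs, "Parent")
    for rec in df.itertuples(index=False):
        parent = attr(rec.attrs, "Parent")
        gid = tx_to_gene.get(parent, parent)
        if gid not in genes:
            continue
        iv = (int(rec.start), int(rec.end))
        if rec.type == "exon":
            genes[gid].exons.append(iv)
        elif rec.type == "five_prime_UTR":
            genes[gid].utr5.append(iv)
        elif rec.type == "three_prime_UTR":
            genes[gid].utr3.append(iv)
    return list(genes.values())
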