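"""Genotype panel container and I/O for inbred-line panels.

Inbred lines are effectively homozygous, so genotypes are coded
haploid-equivalent: 0 (reference homozygote) or 1 (alternate homozygote) per
line, with optional missing values (NaN). The line allele frequency is then
just the genotype column mean and the MAF its folded value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SITE_CLASSES = ["5'UTR", "3'UTR", "synonymous", "non-synonymous", "intron",
                "upstream_1kb", "downstream_1kb", "NA"]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "site_class"]


@dataclass
class VariantRecord:
    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float
    site_class: str = "NA"


class Panel:
    """Line x variant genotype matrix with variant metadata.

    Parameters
    ----------
    line_ids : sequence of line identifiers (length n).
    genotypes : (n, m) array with values in {0, 1} or NaN for missing calls.
    variants : DataFrame with columns variant_id, chrom, pos, ref, alt,
        site_class (one row per matrix column).
    """

    def __init__(self, line_ids, genotypes, variants: pd.DataFrame):
        self.line_ids = list(map(str, line_ids))
        self.genotypes = np.asarray(genotypes, dtype=float)
        self.variants = variants.reset_index(drop=True)
        if self.genotypes.shape != (len(self.line_ids), len(self.variants)):
            raise ValueError("genotype matrix shape does not match line/variant lists")
        finite = self.genotypes[~np.isnan(self.genotypes)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("genotypes must be 0/1 (homozygous inbred coding) or NaN")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele line frequency per variant (missing ignored)."""
        return np.nanmean(self.genotypes, axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_lines(self, keep_ids) -> "Panel":
        keep_ids = [str(i) for i in keep_ids]
        idx = [self.line_ids.index(i) for i in keep_ids]
        return Panel(keep_ids, self.genotypes[idx], self.variants)

    def subset_variants(self, mask) -> "Panel":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return Panel(self.line_ids, self.genotypes[:, cols],
                     self.variants.iloc[cols])

    def records(self):
        maf = self.maf()
        for j, row in self.variants.iterrows():
            yield VariantRecord(row.variant_id, row.chrom, int(row.pos),
                                row.ref, row.alt, float(maf[j]), row.site_class)

    # ------------------------------------------------------------------ I/O

    def to_vcf(self, path) -> None:
        """Write the panel as a plain-text VCF with one pseudo-sample per line.

        The site class is stored in the INFO field (``SC=``); genotypes are
        homozygous GT calls (0/0 or 1/1, ./. for missing).
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=SC,Number=1,Type=String,Description="Site class">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in self.variants["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.line_ids) + "\n")
            gt_map = {0.0: "0/0", 1.0: "1/1"}
            for j, row in self.variants.iterrows():
                calls = [gt_map.get(g, "./.") if not np.isnan(g) else "./."
                         for g in self.genotypes[:, j]]
                fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                         f"{row.alt}\t.\tPASS\tSC={row.site_class}\tGT\t"
                         + "\t".join(calls) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "Panel":
        """Read a panel from a VCF of homozygous biallelic calls (via cyvcf2)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        line_ids = list(vcf.samples)
        rows, cols = [], []
        for i, v in enumerate(vcf):
            if len(v.ALT) != 1:
                raise ValueError(f"variant {v.ID}: only biallelic sites supported")
            gts = np.full(len(line_ids), np.nan)
            for s, g in enumerate(v.genotypes):
                alleles = g[:-1]
                if any(a == -1 for a in alleles):
                    continue
                if len(set(alleles)) > 1:
                    raise ValueError(f"variant {v.ID}: heterozygous call in an "
                                     "inbred panel")
                gts[s] = float(alleles[0])
            cols.append(gts)
            rows.append({
                "variant_id": v.ID or f"{v.CHROM}_{v.POS}",
                "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0],
                "site_class": v.INFO.get("SC", "NA"),
            })
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        return cls(line_ids, np.column_stack(cols), variants)

    def to_tsv(self, path) -> None:
        """Write the panel as a TSV matrix (variant metadata then line columns)."""
        df = self.variants.copy()
        for i, lid in enumerate(self.line_ids):
            df[lid] = self.genotypes[i, :]
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "Panel":
        df = pd.read_csv(path, sep="\t", na_values="NA")
        meta = df[VARIANT_COLUMNS].copy()
        line_ids = [c for c in df.columns if c not in VARIANT_COLUMNS]
        geno = df[line_ids].to_numpy(dtype=float).T
        return cls(line_ids, geno, meta)
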