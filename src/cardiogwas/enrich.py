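"""Gene-set statistics: overlap coefficient, hypergeometric enrichment with
fold change, set bookkeeping, and fly-to-human conservation tables.

Enrichment of an overlap k between a sample of size n and a category of size
K in a universe of N genes uses the upper-tail hypergeometric p-value
P(X >= k) and the fold change FC = k / expected with expected = n*K/N
(observed over expected successes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    N: int
    K: int
    n: int
    k: int
    expected: float
    fold_change: float
    p: float
    log10_p: float


def overlap_coefficient(a: set, b: set) -> float:
    """|A ∩ B| / min(|A|, |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of k hits among n draws.

    N: universe size, K: category size, n: sample size, k: observed overlap.
    The tail is computed in log space so p-values far below float underflow
    remain meaningful through ``log10_p``.
    """
    if not (0 <= k <= min(n, K)) or N < max(n, K) or min(N, K, n) < 0:
        raise ValueError(f"impossible counts N={N} K={K} n={n} k={k}")
    expected = n * K / N
    fc = k / expected if expected > 0 else float("nan")
    logp = float(stats.hypergeom.logsf(k - 1, N, K, n))
    p = float(np.exp(logp))
    return EnrichmentResult(N, K, n, k, expected, fc, max(p, 0.0),
                            logp / np.log(10))


def combine_gene_sets(single_marker: set, epistatic: set, universe_size: int):
    """Union/intersection of the single-marker and epistasis gene sets plus
    enrichment of their overlap against the gene universe."""
    a, b = set(single_marker), set(epistatic)
    union = a | b
    inter = a & b
    assert len(union) + len(inter) == len(a) + len(b)
    enr = hypergeom_enrichment(universe_size, len(a), len(b), len(inter))
    return union, inter, enr


def pairwise_overlap_matrix(gene_sets: dict) -> pd.DataFrame:
    """Overlap coefficients between all pairs of labelled gene sets."""
    labels = list(gene_sets)
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            v = overlap_coefficient(gene_sets[la], gene_sets[lb])
            out.loc[la, lb] = out.loc[lb, la] = v
    return out


def conservation_table(gene_sets: dict, ortholog_map: pd.DataFrame,
                       disease_lists: dict, genome_size: int,
                       disease_universe: str = "orthologous") -> pd.DataFrame:
    """Fly-to-human conservation enrichment rows.

    ``ortholog_map`` has columns fly_gene, human_gene (0..many rows per fly
    gene); fly genes absent from the map count as orthologue-free. The first
    row per gene set tests orthologue-bearing genes against the whole-genome
    universe; disease rows test, within the orthologue-bearing sub-universe
    (default; ``disease_universe='genome'`` switches to the full genome),
    fly genes any of whose orthologues appear in the human disease list.
    """
    by_fly = ortholog_map.groupby("fly_gene")["human_gene"].apply(set)
    fly_with_orth = set(by_fly.index)
    rows = []
    for label, genes in gene_sets.items():
        genes = set(genes)
        absent = genes - fly_with_orth
        if absent:
            log.info("%s: %d gene(s) without orthologue map entry",
                     label, len(absent))
        orth_genes = genes & fly_with_orth
        enr = hypergeom_enrichment(genome_size, len(fly_with_orth),
                                   len(genes), len(orth_genes))
        rows.append({"gene_set": label, "list": "human_orthologue",
                     "universe": genome_size, "category": len(fly_with_orth),
                     "sample": len(genes), "hits": len(orth_genes),
                     "fold_change": enr.fold_change, "p": enr.p})
        for dlabel, dgenes in disease_lists.items():
            dgenes = set(dgenes)
            if not dgenes:
                rows.append({"gene_set": label, "list": dlabel,
                             "universe": np.nan, "category": 0,
                             "sample": len(orth_genes), "hits": 0,
                             "fold_change": np.nan, "p": np.nan})
                continue
            fly_in_list = {g for g in fly_with_orth if by_fly[g] & dgenes}
            if disease_universe == "orthologous":
                N = len(fly_with_orth)
                sample = orth_genes
            else:
                N = genome_size
                sample = genes
            hits = len(set(sample) & fly_in_list)
            enr = hypergeom_enrichment(N, len(fly_in_list), len(sample), hits)
            rows.append({"gene_set": label, "list": dlabel, "universe": N,
                         "category": len(fly_in_list), "sample": len(sample),
                         "hits": hits, "fold_change": enr.fold_change,
                         "p": enr.p})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- I/O

def read_gene_set(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes: set, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"fly_gene", "human_gene"}.issubset(df.columns):
        raise ValueError("orthologue map needs fly_gene and human_gene columns")
    return df
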