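"""Variant-window motif discovery: k-mer over-representation, PSSM assembly
and annotation against a reference motif library.

The workflow mirrors classic oligo-analysis: fixed-width windows around
non-coding variants are scanned on both strands for over-represented k-mers
(each k-mer pooled with its reverse complement), with expected frequencies
from either an order-(k-2) Markov model fitted on the windows themselves
("intrinsic" background) or from composition-matched random sequences
("random" background). Significant k-mers (binomial upper tail, E-value
= p x number of k-mers tested at that width, threshold 1e-4) are greedily
assembled into position-specific scoring matrices and annotated by best
column-correlation match against a PSSM library. This is a deliberately
simplified reimplementation of the peak-motifs/matrix-clustering toolchain:
merge rules and similarity metric are package choices, not replications.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import check_rng

log = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# ------------------------------------------------------------------ windows

@dataclass
class SequenceWindow:
    variant_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    clipped: bool = False


def extract_windows(variants: pd.DataFrame, genome, flank: int = 75) -> list:
    """Plus-strand windows [pos-flank, pos+flank] around variant positions.

    ``genome`` is a pyfaidx.Fasta or a dict of contig name -> sequence string.
    Windows are clipped (and flagged) at contig edges; a variant beyond its
    contig raises an error naming the variant. Duplicate windows from nearby
    variants are retained.
    """
    def contig_seq(chrom):
        if isinstance(genome, dict):
            return genome[chrom]
        return str(genome[chrom][:])

    windows = []
    for rec in variants.itertuples(index=False):
        seq = contig_seq(rec.chrom)
        pos = int(rec.pos)
        if pos < 1 or pos > len(seq):
            raise ValueError(f"variant {rec.variant_id} at {rec.chrom}:{pos} "
                             f"outside contig (length {len(seq)})")
        start = max(1, pos - flank)
        end = min(len(seq), pos + flank)
        windows.append(SequenceWindow(
            rec.variant_id, rec.chrom, start, end,
            seq[start - 1:end].upper(),
            clipped=(start != pos - flank or end != pos + flank)))
    return windows


def write_windows_fasta(windows: list, path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.variant_id} {w.chrom}:{w.start}-{w.end}\n{w.sequence}\n")


# ----------------------------------------------------- k-mer over-representation

def _count_kmers(seqs, k: int, canonical_collapse: bool = True,
                 both_strands: bool = False):
    """K-mer occurrence counts; returns (counts dict, number of trials).

    Canonical collapsing maps each k-mer to the lexicographic minimum of
    itself and its reverse complement, so a single forward-strand scan
    already pools both orientations without double-counting occurrences.
    Scanning both strands explicitly (``both_strands=True``) is used only to
    fit strand-symmetric background frequencies.
    """
    counts: dict = {}
    trials = 0
    for s in seqs:
        strands = (s, revcomp(s)) if both_strands else (s,)
        for strand_seq in strands:
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i:i + k]
                if any(b not in BASES for b in kmer):
                    continue
                key = canonical(kmer) if canonical_collapse else kmer
                counts[key] = counts.get(key, 0) + 1
                trials += 1
    return counts, trials


def _markov_prob(kmer: str, sub_freq: dict, order: int) -> float:
    """Order-m Markov probability of one k-mer orientation.

    p(w) = prod of (m+1)-mer frequencies of w divided by the product of its
    interior m-mer frequencies, with f the strand-pooled substring
    frequencies of the windows (pseudocount-smoothed). For m = k-2 this is
    f(prefix) * f(suffix) / f(middle).
    """
    k = len(kmer)
    m = order

    def f(s):
        return sub_freq[len(s)].get(s, sub_freq["floor"][len(s)])

    num = 1.0
    for i in range(k - m):
        num *= f(kmer[i:i + m + 1])
    den = 1.0
    for i in range(1, k - m):
        den *= f(kmer[i:i + m])
    return num / den


def kmer_overrepresentation(windows, k_range=(6, 7, 8),
                            background: str = "intrinsic",
                            e_threshold: float = 1e-4,
                            seed: int | None = 0,
                            background_seqs=None,
                            markov_order: int | None = 2) -> pd.DataFrame:
    """Binomial over-representation of canonical k-mers in a window set.

    Returns one row per distinct canonical k-mer and width with observed and
    expected counts, the one-sided binomial p, the per-width E-value and a
    significance flag (E <= e_threshold).

    ``markov_order`` sets the order of the intrinsic background model fitted
    on the windows (default 2; ``None`` selects the maximal order k-2, which
    is far more conservative because motif subwords absorb their own signal).
    """
    seqs = [w.sequence if isinstance(w, SequenceWindow) else str(w).upper()
            for w in windows]
    if len(seqs) < 10:
        raise ValueError("need at least 10 windows")
    if background not in ("intrinsic", "random"):
        raise ValueError("background must be 'intrinsic' or 'random'")
    if any(k > min(len(s) for s in seqs) for k in k_range):
        raise ValueError("k larger than shortest window")

    if background == "random" and background_seqs is None:
        background_seqs = composition_matched_background(
            seqs, n_factor=10, seed=seed)

    rows = []
    for k in k_range:
        counts, trials = _count_kmers(seqs, k)
        if background == "intrinsic":
            order = min(markov_order if markov_order is not None else k - 2,
                        k - 2)
            order = max(order, 0)
            sub_freq = {"floor": {}}
            for klen in (order, order + 1):
                if klen == 0:
                    sub_freq[0] = {"": 1.0}
                    sub_freq["floor"][0] = 1.0
                    continue
                c, t = _count_kmers(seqs, klen, canonical_collapse=False,
                                    both_strands=True)
                denom = t + 0.5 * 4**klen
                sub_freq[klen] = {w: (n + 0.5) / denom for w, n in c.items()}
                sub_freq["floor"][klen] = 0.5 / denom
            def p_exp(kmer):
                p = _markov_prob(kmer, sub_freq, order)
                rc = revcomp(kmer)
                if rc != kmer:
                    p += _markov_prob(rc, sub_freq, order)
                return p
        else:
            bg_counts, bg_trials = _count_kmers(background_seqs, k)
            def p_exp(kmer):
                return (bg_counts.get(kmer, 0) + 0.5) / (bg_trials + 0.25 * 4**k)

        n_tested = len(counts)
        for kmer, obs in sorted(counts.items()):
            pe = min(p_exp(kmer), 1.0)
            p = float(stats.binom.sf(obs - 1, trials, pe))
            e = p * n_tested
            rows.append({"kmer": kmer, "k": k, "observed": obs,
                         "expected": trials * pe, "p": p, "e_value": e,
                         "significant": e <= e_threshold})
    out = pd.DataFrame(rows)
    return out.sort_values(["e_value", "kmer"], kind="mergesort").reset_index(drop=True)


def composition_matched_background(seqs, n_factor: int = 10, seed=0) -> list:
    """Random sequences matching the lengths and base composition of ``seqs``."""
    rng = check_rng(seed)
    pooled = "".join(seqs)
    freqs = np.array([pooled.count(b) for b in BASES], dtype=float)
    freqs = freqs / freqs.sum()
    out = []
    for _ in range(n_factor):
        for s in seqs:
            out.append("".join(rng.choice(list(BASES), size=len(s), p=freqs)))
    return out


# ------------------------------------------------------------- PSSM assembly

@dataclass
class PSSM:
    """Per-position nucleotide probability matrix (columns = positions)."""

    name: str
    matrix: np.ndarray  # (width, 4) probabilities, base order ACGT
    source_kmers: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PSSM matrix must be (width, 4)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PSSM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.name, self.matrix[::-1, ::-1], self.source_kmers)

    @classmethod
    def from_kmer(cls, kmer: str, weight: float = 1.0,
                  pseudocount: float = 0.25) -> "PSSM":
        counts = np.full((len(kmer), 4), pseudocount)
        for i, b in enumerate(kmer):
            counts[i, BASES.index(b)] += weight
        return cls(kmer, counts / counts.sum(axis=1, keepdims=True), [kmer])


def _best_alignment(consensus: str, kmer: str, min_overlap: int,
                    max_mismatch: int):
    """Best (offset, orientation) of kmer against consensus, or None."""
    best = None
    for orient, cand in (("+", kmer), ("-", revcomp(kmer))):
        for off in range(-(len(cand) - min_overlap),
                         len(consensus) - min_overlap + 1):
            lo = max(0, off)
            hi = min(len(consensus), off + len(cand))
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            mism = sum(consensus[i] != cand[i - off] for i in range(lo, hi))
            if mism > max_mismatch:
                continue
            key = (overlap, -mism)
            if best is None or key > best[0]:
                best = (key, off, orient)
    if best is None:
        return None
    return best[1], best[2]


def assemble_pssms(kmer_results: pd.DataFrame, pseudocount: float = 0.25,
                   max_mismatch: int = 1) -> list:
    """Greedy agglomeration of significant k-mers into PSSMs.

    Seeds clusters with the most significant k-mer; a k-mer joins a cluster
    when it aligns to the cluster consensus with overlap >= k-2 and at most
    one mismatch in either orientation; column counts are weighted by the
    k-mers' observed occurrence counts. Unmerged k-mers become single-k-mer
    PSSMs.
    """
    sig = kmer_results[kmer_results["significant"]]
    sig = sig.sort_values(["e_value", "kmer"], kind="mergesort")
    if sig.empty:
        return []
    clusters = []  # each: list of (kmer, weight, offset)
    for rec in sig.itertuples(index=False):
        kmer, weight = rec.kmer, float(rec.observed)
        placed = False
        for cl in clusters:
            cons = _cluster_consensus(cl, pseudocount)
            aln = _best_alignment(cons["consensus"], kmer,
                                  min_overlap=len(kmer) - 2,
                                  max_mismatch=max_mismatch)
            if aln is not None:
                off, orient = aln
                s = kmer if orient == "+" else revcomp(kmer)
                cl.append((s, weight, off + cons["start"]))
                placed = True
                break
        if not placed:
            clusters.append([(kmer, weight, 0)])
    pssms = []
    for i, cl in enumerate(clusters, 1):
        cons = _cluster_consensus(cl, pseudocount)
        pssms.append(PSSM(f"motif_{i}", cons["matrix"],
                          source_kmers=[s for s, _, _ in cl]))
    return pssms


def _cluster_consensus(members, pseudocount: float):
    """Weighted count matrix, consensus and start offset for a cluster."""
    start = min(off for _, _, off in members)
    end = max(off + len(s) for s, _, off in members)
    counts = np.full((end - start, 4), pseudocount)
    for s, w, off in members:
        for i, b in enumerate(s):
            counts[off - start + i, BASES.index(b)] += w
    matrix = counts / counts.sum(axis=1, keepdims=True)
    consensus = "".join(BASES[j] for j in matrix.argmax(axis=1))
    return {"matrix": matrix, "consensus": consensus, "start": start}


# --------------------------------------------------------------- annotation

@dataclass
class MotifAnnotation:
    query: str
    best_match: str | None
    score: float
    offset: int
    orientation: str


def _column_corr(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su < 1e-12 or sv < 1e-12:
        return 1.0 if np.allclose(u, v, atol=1e-9) else 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _pssm_similarity(q: np.ndarray, l: np.ndarray, min_overlap: int = 4):
    """Best width-normalised summed column correlation over all offsets.

    score = sum over aligned columns of the per-column Pearson correlation,
    divided by min(widths); 1.0 for an exact (sub)match of equal-width motifs.
    """
    wq, wl = len(q), len(l)
    best = (-np.inf, 0)
    for off in range(-(wq - min_overlap), wl - min_overlap + 1):
        lo = max(0, off)
        hi = min(wl, off + wq)
        if hi - lo < min_overlap:
            continue
        r = sum(_column_corr(q[i - off], l[i]) for i in range(lo, hi))
        score = r / min(wq, wl)
        if score > best[0]:
            best = (score, off)
    return best


def annotate_pssms(queries: list, library: list,
                   min_overlap: int = 4) -> pd.DataFrame:
    """Best library match per query PSSM over all offsets and orientations."""
    if not library:
        raise ValueError("empty PSSM library")
    rows = []
    for q in queries:
        if q.width < 4:
            raise ValueError(f"query {q.name}: width must be >= 4")
        best = MotifAnnotation(q.name, None, -np.inf, 0, "+")
        for lib in library:
            for orient, mat in (("+", q.matrix),
                                ("-", q.reverse_complement().matrix)):
                score, off = _pssm_similarity(mat, lib.matrix, min_overlap)
                if score > best.score:
                    best = MotifAnnotation(q.name, lib.name, score, off, orient)
        rows.append(best.__dict__)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- MEME I/O

def write_meme(pssms: list, path, background=None) -> None:
    """Write PSSMs in MEME minimal format."""
    bg = background or [0.25] * 4
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for p in pssms:
            fh.write(f"MOTIF {p.name}\n")
            # large nsites keeps probability fidelity through parsers that
            # reconstruct integer counts
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width} "
                     f"nsites= 100000 E= 0\n")
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list:
    """Read a MEME minimal-format PSSM library (via Biopython)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    out = []
    for m in record:
        mat = np.array([[m.pwm[b][i] for b in BASES] for i in range(m.length)])
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(PSSM(m.name, mat))
    return out
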