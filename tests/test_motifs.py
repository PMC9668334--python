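"""Window extraction, k-mer over-representation, PSSM assembly/annotation."""

import numpy as np
import pandas as pd
import pytest

from cardiogwas.motifs import (PSSM, annotate_pssms, assemble_pssms, canonical,
                               extract_windows, kmer_overrepresentation,
                               read_meme, revcomp, write_meme)
from cardiogwas.syndata import simulate_motif_windows


def _variants(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])


class TestExtractWindows:
    GENOME = {"chr1": "ACGT" * 2500}  # 10 kb

    def test_full_window_coordinates(self):
        w, = extract_windows(_variants([("v1", "chr1", 100)]), self.GENOME, 75)
        assert (w.start, w.end) == (25, 175)
        assert len(w.sequence) == 151
        assert not w.clipped

    def test_edge_clipping(self):
        w, = extract_windows(_variants([("v1", "chr1", 30)]), self.GENOME, 75)
        assert (w.start, w.end) == (1, 105)
        assert w.clipped

    def test_sequence_equals_direct_substring(self):
        w, = extract_windows(_variants([("v1", "chr1", 500)]), self.GENOME, 75)
        assert w.sequence == self.GENOME["chr1"][w.start - 1:w.end]

    def test_out_of_contig_error_names_variant(self):
        with pytest.raises(ValueError, match="v9"):
            extract_windows(_variants([("v9", "chr1", 20_000)]), self.GENOME)


class TestKmerOverrepresentation:
    def test_null_calibration_uniform_windows(self):
        fp = 0
        n_rep = 10
        for rep in range(n_rep):
            seqs = simulate_motif_windows(60, 151, "A", 0.0, seed=1000 + rep)
            res = kmer_overrepresentation(seqs, (6, 7), "intrinsic")
            fp += int(res["significant"].any())
        assert fp <= 0.2 * n_rep

    @pytest.mark.parametrize("background", ["intrinsic", "random"])
    def test_planted_motif_top_ranked(self, background):
        seqs = simulate_motif_windows(200, 151, "TCAAGTG", 0.4, seed=4)
        res = kmer_overrepresentation(seqs, (7,), background, seed=4)
        top = res.iloc[0]
        assert top["kmer"] == canonical("TCAAGTG")
        assert top["significant"]

    def test_e_value_row_identity(self):
        seqs = simulate_motif_windows(50, 80, "TCAAGTG", 0.3, seed=6)
        res = kmer_overrepresentation(seqs, (6,), "intrinsic")
        n_tested = res[res["k"] == 6].shape[0]
        assert np.allclose(res["e_value"], res["p"] * n_tested)
        assert (res["e_value"] >= res["p"] - 1e-15).all()

    def test_reverse_complement_invariance(self):
        seqs = simulate_motif_windows(80, 101, "TCAAGTG", 0.5, seed=8)
        res_f = kmer_overrepresentation(seqs, (7,), "intrinsic")
        res_r = kmer_overrepresentation([revcomp(s) for s in seqs], (7,),
                                        "intrinsic")
        sig_f = set(res_f[res_f["significant"]]["kmer"])
        sig_r = set(res_r[res_r["significant"]]["kmer"])
        assert sig_f == sig_r

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            kmer_overrepresentation(["ACGT"] * 12, (6,))

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError):
            kmer_overrepresentation(["ACGTACGTAC"] * 5, (6,))


class TestAssemblePssms:
    def _sig(self, kmers, evals=None):
        evals = evals or [1e-8 * (i + 1) for i in range(len(kmers))]
        return pd.DataFrame({
            "kmer": kmers, "k": [len(k) for k in kmers],
            "observed": [50] * len(kmers), "expected": [5.0] * len(kmers),
            "p": evals, "e_value": evals,
            "significant": [True] * len(kmers)})

    def test_overlapping_kmers_merge_to_consensus(self):
        pssms = assemble_pssms(self._sig(["TCAAGT", "CAAGTG"]))
        assert len(pssms) == 1
        assert pssms[0].width == 7
        assert pssms[0].consensus == "TCAAGTG"

    def test_single_kmer_pssm(self):
        pssms = assemble_pssms(self._sig(["TCAAGT"]))
        assert len(pssms) == 1 and pssms[0].width == 6
        # pseudocount-smoothed columns: dominant base prob < 1
        assert 0.9 < pssms[0].matrix.max() < 1.0

    def test_disjoint_kmers_stay_separate(self):
        pssms = assemble_pssms(self._sig(["AAAAAA", "CGCGCG"]))
        assert len(pssms) == 2

    def test_reverse_complement_merges(self):
        # CACTTG is revcomp(CAAGTG); should merge with TCAAGT
        pssms = assemble_pssms(self._sig(["TCAAGT", "CACTTG"]))
        assert len(pssms) == 1

    def test_columns_sum_to_one(self):
        pssms = assemble_pssms(self._sig(["TCAAGT", "CAAGTG", "AAGTGA"]))
        for p in pssms:
            assert np.allclose(p.matrix.sum(axis=1), 1.0, atol=1e-9)


class TestAnnotatePssms:
    def _library(self):
        return [PSSM.from_kmer("TCAAGTG", weight=100),
                PSSM.from_kmer("GGGGCCC", weight=100),
                PSSM.from_kmer("ATATATA", weight=100)]

    def test_self_match_scores_one(self):
        lib = self._library()
        tab = annotate_pssms([lib[0]], lib)
        row = tab.iloc[0]
        assert row["best_match"] == "TCAAGTG"
        assert row["score"] == pytest.approx(1.0, abs=1e-9)
        assert row["offset"] == 0

    def test_reverse_complement_match(self):
        lib = self._library()
        query = lib[0].reverse_complement()
        row = annotate_pssms([query], lib).iloc[0]
        assert row["best_match"] == "TCAAGTG"
        assert row["score"] == pytest.approx(1.0, abs=1e-9)
        assert row["orientation"] == "-"

    def test_shuffled_columns_score_below_match(self, rng):
        lib = self._library()
        below = 0
        n_rep = 30
        for _ in range(n_rep):
            perm = rng.permutation(7)
            q = PSSM("shuf", lib[0].matrix[perm])
            if annotate_pssms([q], lib).iloc[0]["score"] < 0.75:
                below += 1
        assert below >= 0.8 * n_rep

    def test_narrow_query_rejected(self):
        with pytest.raises(ValueError):
            annotate_pssms([PSSM.from_kmer("ACG")], self._library())

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            annotate_pssms([PSSM.from_kmer("ACGTACG")], [])


def test_meme_roundtrip(tmp_path):
    pssms = [PSSM.from_kmer("TCAAGTG", weight=20),
             PSSM.from_kmer("GGATTA", weight=10)]
    path = tmp_path / "lib.meme"
    write_meme(pssms, path)
    back = read_meme(path)
    assert [m.name for m in back] == ["TCAAGTG", "GGATTA"]
    for orig, rec in zip(pssms, back):
        assert np.allclose(orig.matrix, rec.matrix, atol=1e-4)


def test_planted_motif_end_to_end_recovery():
    """Windows -> k-mers -> PSSM -> annotation recovers a planted motif."""
    hits = 0
    n_rep = 10
    library = [PSSM.from_kmer("TCAAGTG", weight=100),
               PSSM.from_kmer("CCGGAAT", weight=100),
               PSSM.from_kmer("TTTTACG", weight=100)]
    for rep in range(n_rep):
        seqs = simulate_motif_windows(200, 151, "TCAAGTG", 0.4,
                                      seed=2000 + rep)
        res = kmer_overrepresentation(seqs, (6, 7, 8), "intrinsic")
        if not res["significant"].any():
            continue
        pssms = assemble_pssms(res)
        ann = annotate_pssms(pssms[:1], library).iloc[0]
        if ann["best_match"] == "TCAAGTG" and ann["score"] > 0.9:
            hits += 1
    assert hits >= 0.9 * n_rep
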