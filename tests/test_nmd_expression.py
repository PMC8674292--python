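import numpy as np
import pandas as pd
import pytest

from psiexon.core_io import GenomeSequence, TranscriptModel, revcomp
from psiexon.nmd_expression import classify_nmd, lfc_shift_test, volcano_classify

from oracles import ranksum_two_sided


def host_with_insert(exon_seq, ins_at=200, minus=False):
    """Two-exon CDS-bearing host with *exon_seq* planted inside its intron.

    The insertion point is at a codon boundary (frame 0) so in-frame stop
    content of the exon is directly interpretable.
    """
    rng = np.random.default_rng(42)

    def codons(n):
        out = []
        while len(out) < n:
            c = "".join(rng.choice(list("ACGT"), 3))
            if c not in ("TAA", "TAG", "TGA"):
                out.append(c)
        return "".join(out)

    exon1 = "C" * 30 + "ATG" + codons(39)  # len 150, CDS from 30
    exon2 = codons(60) + "TAA" + "C" * 27  # len 210, stop at 180 offset
    intron = "GT" + "C" * 296 + "AG"  # len 300
    seq = exon1 + intron + exon2
    seq = seq[:ins_at] + exon_seq + seq[ins_at + len(exon_seq) :]
    if not minus:
        genome = GenomeSequence({"c": seq})
        tx = TranscriptModel(
            "g", "t", "c", "+", [(0, 150), (450, 660)], cds=(30, 633)
        )
        ins = (ins_at, ins_at + len(exon_seq))
    else:
        L = len(seq)
        genome = GenomeSequence({"c": revcomp(seq)})
        tx = TranscriptModel(
            "g", "t", "c", "-", [(L - 150, L), (0, L - 450)], cds=(L - 633, L - 30)
        )
        ins = (L - ins_at - len(exon_seq), L - ins_at)
    return genome, tx, ins


def exon_of(length, with_stop, seed=1):
    rng = np.random.default_rng(seed)
    out = []
    while len("".join(out)) < length:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in ("TAA", "TAG", "TGA"):
            out.append(c)
    body = "".join(out)[:length]
    if with_stop:
        body = body[:3] + "TAA" + body[6:]  # in-frame stop at codon 2
    return body


class TestClassifyNmd:
    @pytest.mark.parametrize("length", [63, 64, 72, 75])
    @pytest.mark.parametrize("with_stop", [True, False])
    def test_truth_table_over_lengths_and_stop_content(self, length, with_stop):
        genome, tx, ins = host_with_insert(exon_of(length, with_stop))
        call = classify_nmd(ins, tx, genome)
        assert call.frameshift == (length % 3 != 0)
        if with_stop:
            assert call.ptc
        expected_nmd = (length % 3 != 0) or with_stop
        # a frameshift may also expose a downstream PTC; is_nmd is what matters
        assert call.is_nmd == expected_nmd or (call.is_nmd and length % 3 != 0)
        assert call.is_nmd == ((length % 3 != 0) or call.ptc)
        if not with_stop and length % 3 == 0:
            assert not call.is_nmd

    @pytest.mark.parametrize("length,with_stop", [(75, True), (64, False), (72, False)])
    def test_strand_invariance(self, length, with_stop):
        exon = exon_of(length, with_stop)
        g1, t1, i1 = host_with_insert(exon, minus=False)
        g2, t2, i2 = host_with_insert(exon, minus=True)
        c1 = classify_nmd(i1, t1, g1)
        c2 = classify_nmd(i2, t2, g2)
        assert (c1.frameshift, c1.ptc, c1.is_nmd) == (c2.frameshift, c2.ptc, c2.is_nmd)

    def test_insertion_upstream_of_start_is_non_coding(self):
        # insertion into the 5'UTR region: build a host whose first exon is
        # all UTR and whose CDS starts in exon 2
        rng = np.random.default_rng(0)
        exon1 = "C" * 100
        exon2 = "ATG" + "GCA" * 60 + "TAA" + "C" * 20
        intron = "GT" + "C" * 196 + "AG"
        seq = exon1 + intron + exon2
        ex = "GCA" * 25
        seq = seq[:150] + ex + seq[150 + 75 :]
        genome = GenomeSequence({"c": seq})
        tx = TranscriptModel(
            "g", "t", "c", "+", [(0, 100), (300, 300 + len(exon2))],
            cds=(300, 300 + 3 + 180 + 3),
        )
        call = classify_nmd((150, 225), tx, genome)
        assert not call.is_nmd
        assert call.reason == "non-coding insertion"

    def test_exon_outside_intron_rejected(self):
        genome, tx, _ = host_with_insert(exon_of(63, False))
        with pytest.raises(ValueError, match="intron"):
            classify_nmd((0, 63), tx, genome)


class TestLfcShift:
    def test_exact_enumeration_agreement_small_groups(self):
        rng = np.random.default_rng(8)
        lfc = rng.normal(0, 1, 18)
        genes = [f"g{i}" for i in range(18)]
        df = pd.DataFrame({"gene_id": genes, "log2fc": lfc, "fdr": 0.5})
        gene_set = genes[:7]
        res = lfc_shift_test(df, gene_set)
        expected = ranksum_two_sided(list(lfc[:7]), list(lfc[7:]))
        assert res.method == "exact"
        assert res.p == pytest.approx(expected, abs=1e-9)

    def test_most_downregulated_genes_detected(self):
        rng = np.random.default_rng(9)
        n = 1000
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fc": rng.normal(0, 0.5, n),
                "fdr": 0.5,
            }
        )
        worst = df.nsmallest(10, "log2fc")["gene_id"].tolist()
        res = lfc_shift_test(df, worst)
        assert res.p < 1e-6

    def test_null_draw_not_significant(self):
        rng = np.random.default_rng(10)
        n = 500
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fc": rng.normal(0, 0.5, n),
                "fdr": 0.5,
            }
        )
        picked = list(rng.choice(df["gene_id"], 30, replace=False))
        assert lfc_shift_test(df, picked).p > 0.05

    def test_planted_shift_detected(self):
        from psiexon.synthetic_data import simulate_expression_table

        df, hosts = simulate_expression_table(seed=3)
        res = lfc_shift_test(df, hosts)
        assert res.p < 0.05
        # direction: the hosts are downregulated
        host_mean = df.set_index("gene_id").loc[hosts, "log2fc"].mean()
        other_mean = df.loc[~df["gene_id"].isin(hosts), "log2fc"].mean()
        assert host_mean < other_mean

    def test_cdf_output_shape(self):
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "log2fc": range(10), "fdr": 0.5}
        )
        res = lfc_shift_test(df, ["g0", "g1", "g2"])
        assert set(res.cdf["group"]) == {"set", "other"}
        assert res.cdf.groupby("group")["cdf"].max().eq(1.0).all()

    def test_too_small_gene_set_rejected(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "log2fc": [1, 2, 3, 4], "fdr": 0.5}
        )
        with pytest.raises(ValueError, match=">= 3"):
            lfc_shift_test(df, ["a", "b"])


class TestVolcano:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (-1.0, 0.01, "down"),
            (-1.0, 0.10, "NC"),
            (0.4, 0.001, "NC"),  # 2^0.4 ≈ 1.32 < 1.5-fold
            (1.0, 0.01, "up"),
            (0.59, 0.01, "up"),  # 2^0.59 ≈ 1.505 > 1.5
        ],
    )
    def test_thresholds(self, lfc, fdr, expected):
        df = pd.DataFrame({"gene_id": ["g"], "log2fc": [lfc], "fdr": [fdr]})
        assert volcano_classify(df)["label"].iloc[0] == expected

    def test_missing_fdr_is_nc_with_reason(self):
        df = pd.DataFrame({"gene_id": ["g"], "log2fc": [-2.0], "fdr": [None]})
        out = volcano_classify(df)
        assert out["label"].iloc[0] == "NC"
        assert out["reason"].iloc[0] == "missing-fdr"
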