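import pytest

from psiexon.core_io import GenomeSequence, IntronRecord, TranscriptModel, revcomp
from psiexon.psiexon_scan import (
    annotate_candidates,
    exon_end_dinucleotide_census,
    scan_introns,
)
from psiexon.splice_site_models import shipped_pwm

ACCEPTOR = shipped_pwm("acceptor23")


def intron_with_plant(exon_len=60):
    """Plus-strand intron carrying one planted psiExon; returns (seq, start, end).

    Layout inside the intron (sense): 240 filler, 18-base pyrimidine tract,
    AG, exon (ends AGA), GTAAG, filler.  Coordinates are intron-relative.
    """
    filler = ("CTTCCT" * 80)[:240]
    tract = "CT" * 9
    body = ("CTACCT" * 40)[: exon_len - 3] + "AGA"
    tail = ("CCTTCC" * 40)[:200]
    seq = filler + tract + "AG" + body + "GTAAG" + tail
    start = 240 + 20
    return seq, start, start + exon_len


class TestScan:
    def test_planted_exon_recovered_with_exact_boundaries(self):
        iseq, s, e = intron_with_plant(60)
        genome = GenomeSequence({"c": "A" + iseq + "A"})
        intron = IntronRecord("g.I1", "g", "c", "+", 1, 1 + len(iseq), 1)
        cands = scan_introns(genome, [intron], ACCEPTOR)
        passing = [c for c in cands if c.passes_filters]
        assert len(passing) == 1
        c = passing[0]
        assert (c.start, c.end) == (1 + s, 1 + e)
        assert c.length == 60
        assert c.primary
        # boundary invariant: exon ends AGA, next five intronic bases GTAAG
        assert genome.fetch("c", c.end - 3, c.end, "+") == "AGA"
        assert genome.fetch("c", c.end, c.end + 5, "+") == "GTAAG"

    def test_minus_strand_mirror_reports_identical_sequences(self):
        iseq, s, e = intron_with_plant(60)
        plus = GenomeSequence({"c": "A" + iseq + "A"})
        minus = GenomeSequence({"c": "A" + revcomp(iseq) + "A"})
        ip = IntronRecord("g.I1", "g", "c", "+", 1, 1 + len(iseq), 1)
        im = IntronRecord("g.I1", "g", "c", "-", 1, 1 + len(iseq), 1)
        (cp,) = [c for c in scan_introns(plus, [ip], ACCEPTOR) if c.passes_filters]
        (cm,) = [c for c in scan_introns(minus, [im], ACCEPTOR) if c.passes_filters]
        assert cp.acceptor_window == cm.acceptor_window
        assert cp.acceptor_score == pytest.approx(cm.acceptor_score)
        assert cp.length == cm.length
        # mirrored genomic interval
        L = len(iseq)
        assert (cm.start, cm.end) == (1 + L - (e), 1 + L - (s))

    @pytest.mark.parametrize("length,reason", [(5, "length"), (201, "length")])
    def test_length_decoys_fail_with_reason(self, length, reason):
        iseq, s, e = intron_with_plant(length)
        genome = GenomeSequence({"c": "A" + iseq + "A"})
        intron = IntronRecord("g.I1", "g", "c", "+", 1, 1 + len(iseq), 1)
        cands = scan_introns(genome, [intron], ACCEPTOR)
        target = [c for c in cands if (c.start, c.end) == (1 + s, 1 + e)]
        assert len(target) == 1
        assert not target[0].passes_filters
        assert target[0].failure_reasons == [reason]

    def test_weak_acceptor_fails_score_filter(self):
        filler = ("CTTCCT" * 80)[:240]
        tract = "CA" * 9  # purine-rich, scores poorly
        body = ("CTACCT" * 40)[:57] + "AGA"
        seq = filler + tract + "AG" + body + "GTAAG" + ("CCTTCC" * 40)[:200]
        genome = GenomeSequence({"c": "A" + seq + "A"})
        intron = IntronRecord("g.I1", "g", "c", "+", 1, 1 + len(seq), 1)
        cands = scan_introns(genome, [intron], ACCEPTOR)
        target = [c for c in cands if c.length == 60]
        assert target and not target[0].passes_filters
        assert "score" in target[0].failure_reasons

    def test_truncated_acceptor_window_candidates_dropped(self):
        # motif close to the intron start: no room for a 23-mer window
        iseq = "CT" * 5 + "AG" + "CTACCTAGA" + "GTAAG" + "C" * 100
        genome = GenomeSequence({"c": "A" + iseq + "A"})
        intron = IntronRecord("g.I1", "g", "c", "+", 1, 1 + len(iseq), 1)
        assert scan_introns(genome, [intron], ACCEPTOR) == []

    def test_no_motif_no_candidates(self):
        genome = GenomeSequence({"c": "CT" * 300})
        intron = IntronRecord("g.I1", "g", "c", "+", 0, 600, 1)
        assert scan_introns(genome, [intron], ACCEPTOR) == []


class TestAnnotateCandidates:
    def _candidate_genome(self):
        iseq, s, e = intron_with_plant(60)
        genome = GenomeSequence({"c": "A" + iseq + "A"})
        intron = IntronRecord("g.I1", "g", "c", "+", 1, 1 + len(iseq), 1)
        (cand,) = [c for c in scan_introns(genome, [intron], ACCEPTOR) if c.passes_filters]
        return genome, cand

    def test_exact_exon_match_marks_annotated(self):
        genome, cand = self._candidate_genome()
        twin = TranscriptModel("g", "twin", "c", "+", [(cand.start, cand.end)])
        annotate_candidates([cand], [twin])
        assert cand.annotated and not cand.passes_filters
        assert "annotated" in cand.failure_reasons

    def test_shared_acceptor_only_remains_unannotated(self):
        genome, cand = self._candidate_genome()
        other = TranscriptModel(
            "g", "other", "c", "+", [(cand.start, cand.end + 50)]
        )
        annotate_candidates([cand], [other])
        assert not cand.annotated and cand.passes_filters


class TestDinucleotideCensus:
    def _genome_for(self, endings):
        """Plus-strand gene whose internal exons end with the given dinucleotides."""
        seq = ["C"] * (300 * (len(endings) + 2))
        exons = []
        pos = 10
        for d in endings + ["TT"]:  # last exon is terminal, excluded
            exons.append((pos, pos + 50))
            seq[pos + 48] = d[0]
            seq[pos + 49] = d[1]
            pos += 250
        return GenomeSequence({"c": "".join(seq)}), TranscriptModel(
            "g", "t", "c", "+", exons
        )

    def test_all_ag_is_100_percent_canonical(self):
        genome, tx = self._genome_for(["AG"] * 5)
        df = exon_end_dinucleotide_census([tx], genome)
        ag = df[df["dinucleotide"] == "AG"].iloc[0]
        assert ag["percent"] == 100.0 and ag["canonical"]

    def test_planted_ga_fraction_counted(self):
        genome, tx = self._genome_for(["GA"] * 3 + ["AG"] * 7)
        df = exon_end_dinucleotide_census([tx], genome)
        assert df.set_index("dinucleotide").loc["GA", "percent"] == pytest.approx(30.0)

    def test_terminal_exons_excluded(self):
        genome, tx = self._genome_for(["AG"] * 4)
        df = exon_end_dinucleotide_census([tx], genome)
        assert df["count"].sum() == 4  # 5 exons, one terminal

    def test_minus_strand_reads_biological_orientation(self):
        # one internal exon on minus strand; biological -2,-1 = revcomp of start
        seq = list("C" * 400)
        # exon [200,250) on '-': biological end bases = revcomp(seq[200:202])
        seq[200:202] = list("TC")  # revcomp -> GA
        genome = GenomeSequence({"c": "".join(seq)})
        tx = TranscriptModel("g", "t", "c", "-", [(100, 150), (200, 250)])
        # transcription order on '-': (200,250) first, (100,150) terminal
        df = exon_end_dinucleotide_census([tx], genome)
        assert df.set_index("dinucleotide").loc["GA", "count"] == 1
        assert df["count"].sum() == 1
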