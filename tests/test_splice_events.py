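import numpy as np
import pytest

from psiexon.core_io import TranscriptModel
from psiexon.splice_events import (
    SpliceEvent,
    analyze_events,
    build_event_catalog,
    call_regulated_events,
    classify_psiexons,
    compute_psi,
    fisher_event_test,
)

from conftest import make_junctions, make_manifest
from oracles import fisher_two_sided


def ce_event(contig="chrT", strand="+", exon=(200, 300), flanks=(100, 400)):
    d, a = flanks
    return SpliceEvent(
        event_id="CE:test",
        kind="CE",
        contig=contig,
        strand=strand,
        gene_id="g",
        inclusion=[(d, exon[0]), (exon[1], a)],
        exclusion=[(d, a)],
        exon=exon,
    )


class TestComputePsi:
    def test_mean_of_inclusion_junctions(self):
        ev = ce_event()
        jt = make_junctions(
            [
                ("chrT", 100, 200, "+", "s1", 30),
                ("chrT", 300, 400, "+", "s1", 50),
                ("chrT", 100, 400, "+", "s1", 60),
            ]
        )
        assert compute_psi(ev, jt, "s1") == pytest.approx(40.0)

    def test_na_below_denominator_20(self):
        ev = ce_event()
        jt = make_junctions(
            [
                ("chrT", 100, 200, "+", "s1", 9),
                ("chrT", 300, 400, "+", "s1", 9),
                ("chrT", 100, 400, "+", "s1", 10),
            ]
        )
        assert compute_psi(ev, jt, "s1") is None  # 9 + 10 = 19 < 20

    def test_denominator_20_is_defined(self):
        ev = ce_event()
        jt = make_junctions(
            [
                ("chrT", 100, 200, "+", "s1", 10),
                ("chrT", 300, 400, "+", "s1", 10),
                ("chrT", 100, 400, "+", "s1", 10),
            ]
        )
        assert compute_psi(ev, jt, "s1") == pytest.approx(50.0)

    def test_full_inclusion_is_100(self):
        ev = ce_event()
        jt = make_junctions(
            [
                ("chrT", 100, 200, "+", "s1", 25),
                ("chrT", 300, 400, "+", "s1", 25),
            ]
        )
        assert compute_psi(ev, jt, "s1") == 100.0


class TestFisher:
    def manifest(self):
        return make_manifest({"A": ["a1"], "B": ["b1"]})

    def table_for(self, inc_a, exc_a, inc_b, exc_b):
        rows = []
        for sample, inc, exc in (("a1", inc_a, exc_a), ("b1", inc_b, exc_b)):
            rows += [
                ("chrT", 100, 200, "+", sample, inc),
                ("chrT", 300, 400, "+", sample, inc),
                ("chrT", 100, 400, "+", sample, exc),
            ]
        return make_junctions(rows)

    def test_identical_proportions_give_p1(self):
        p, deg = fisher_event_test(
            ce_event(), self.table_for(5, 5, 5, 5), self.manifest(), "A", "B"
        )
        assert p == 1.0 and not deg

    def test_extreme_table_matches_enumeration_oracle(self):
        p, _ = fisher_event_test(
            ce_event(), self.table_for(0, 20, 20, 0), self.manifest(), "A", "B"
        )
        assert p == pytest.approx(fisher_two_sided(0, 20, 20, 0), abs=1e-12)

    def test_degenerate_margin_flagged_p1(self):
        p, deg = fisher_event_test(
            ce_event(), self.table_for(10, 0, 10, 0), self.manifest(), "A", "B"
        )
        assert p == 1.0 and deg

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(5)
        from scipy.stats import fisher_exact

        for _ in range(200):
            n = int(rng.integers(1, 201))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = int(rng.integers(0, n - a - b + 1))
            d = n - a - b - c
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-12)


class TestCalls:
    @pytest.mark.parametrize(
        "dpsi,p,expected",
        [
            (25.0, 1e-4, "Inc"),
            (25.0, 0.01, "NC"),
            (-30.0, 1e-5, "Skp"),
            (20.0, 1e-9, "NC"),  # boundary excluded
            (-20.0, 1e-9, "NC"),
            (15.0, 1e-9, "NC"),
            (None, 1e-9, "NC"),
        ],
    )
    def test_thresholds(self, dpsi, p, expected):
        call, _ = call_regulated_events(dpsi, p)
        assert call == expected

    def test_group_swap_maps_inc_to_skp_with_same_p(self):
        ev = ce_event()
        rows = []
        for sample, inc, exc in (("a1", 80, 20), ("b1", 20, 80)):
            rows += [
                ("chrT", 100, 200, "+", sample, inc),
                ("chrT", 300, 400, "+", sample, inc),
                ("chrT", 100, 400, "+", sample, exc),
            ]
        jt = make_junctions(rows)
        mani = make_manifest({"A": ["a1"], "B": ["b1"]})
        (fwd,) = analyze_events([ev], jt, mani, "A", "B")
        (rev,) = analyze_events([ev], jt, mani, "B", "A")
        assert fwd.call == "Skp" and rev.call == "Inc"
        assert fwd.p == rev.p
        assert fwd.dpsi == pytest.approx(-rev.dpsi)


class TestCatalog:
    def test_annotated_three_exon_gene_yields_one_ce(self, three_exon_gene):
        _, tx = three_exon_gene
        jt = make_junctions(
            [
                ("chrT", 100, 200, "+", "s1", 10),
                ("chrT", 300, 400, "+", "s1", 10),
                ("chrT", 100, 400, "+", "s1", 5),
            ]
        )
        events = build_event_catalog(jt, [tx])
        ces = [e for e in events if e.kind == "CE"]
        assert len(ces) == 1
        assert ces[0].exon == (200, 300)
        # both splice sites annotated in the single source
        assert all(any(v.values()) for v in ces[0].ss_annotation.values())

    def test_novel_exon_flagged_unannotated_at_both_sites(self, three_exon_gene):
        _, tx = three_exon_gene
        # novel exon [140,160) inside intron 1, bridged by the skip e1-e2
        jt = make_junctions(
            [
                ("chrT", 100, 140, "+", "s1", 10),
                ("chrT", 160, 200, "+", "s1", 10),
                ("chrT", 100, 200, "+", "s1", 50),
            ]
        )
        events = build_event_catalog(jt, [tx])
        novel = [e for e in events if e.kind == "CE" and e.exon == (140, 160)]
        assert len(novel) == 1
        assert all(
            not any(per_src.values()) for per_src in novel[0].ss_annotation.values()
        )

    def test_shared_donor_pair_without_bridge_is_a3ss(self, three_exon_gene):
        _, tx = three_exon_gene
        jt = make_junctions(
            [
                ("chrT", 100, 190, "+", "s1", 10),
                ("chrT", 100, 200, "+", "s1", 10),
            ]
        )
        events = build_event_catalog(jt, [tx])
        kinds = {e.kind for e in events}
        assert "A3SS" in kinds
        a3 = next(e for e in events if e.kind == "A3SS")
        # shorter intron (earlier acceptor) is the inclusion isoform
        assert a3.inclusion == [(100, 190)]
        assert a3.exclusion == [(100, 200)]


class TestPsiExonClassification:
    def test_window_arithmetic_on_planted_exon(self, sim_corpus):
        sim, junctions, manifest, _ = sim_corpus
        events = build_event_catalog(junctions, sim.transcripts)
        results = analyze_events(events, junctions, manifest, "DMSO", "DRUG")
        records = classify_psiexons(events, results, sim.transcripts, sim.genome)
        planted = {
            (p.contig, p.start, p.end): p for p in sim.plants if p.kind == "pass"
        }
        hits = [r for r in records if (r.contig, *r.exon) in planted]
        assert len(hits) == len(planted)
        for r in hits:
            assert r.is_psiexon
            assert r.donor_window.startswith("AGAGTAAG")  # AGA|gtaag boundary
            assert r.length == r.exon[1] - r.exon[0]
            assert len(r.acceptor_window) == 23
            assert r.acceptor_window[18:20] == "AG"

    def test_annotated_exon_is_not_psiexon(self, three_exon_gene):
        genome, tx = three_exon_gene
        jt = make_junctions(
            [
                ("chrT", 100, 200, "+", s, c)
                for s, c in (("a1", 90), ("b1", 90))
            ]
            + [
                ("chrT", 300, 400, "+", s, c)
                for s, c in (("a1", 90), ("b1", 90))
            ]
            + [("chrT", 100, 400, "+", "a1", 90), ("chrT", 100, 400, "+", "b1", 10)]
        )
        mani = make_manifest({"A": ["a1"], "B": ["b1"]})
        events = build_event_catalog(jt, [tx])
        results = analyze_events(events, jt, mani, "A", "B")
        records = classify_psiexons(events, results, [tx], genome)
        assert all(not r.is_psiexon for r in records)
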