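import numpy as np
import pandas as pd
import pytest

from psiexon.core_io import derive_introns
from psiexon.splice_site_models import shipped_pwm
from psiexon.synthetic_data import (
    SimConfig,
    draw_event_counts,
    simulate_genome,
    simulate_junction_counts,
    simulate_quant_fixtures,
    simulate_threshold_events,
    write_corpus,
)


class TestGenomeSimulation:
    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = SimConfig(seed=5, n_genes=3, n_pass=2)
        a = tmp_path / "a.fa"
        b = tmp_path / "b.fa"
        simulate_genome(cfg).genome.to_fasta(a)
        simulate_genome(cfg).genome.to_fasta(b)
        assert a.read_bytes() == b.read_bytes()

    def test_zero_plants_gives_zero_candidates(self):
        from psiexon.psiexon_scan import scan_introns

        sim = simulate_genome(SimConfig(seed=6, n_genes=3, n_pass=0))
        introns = derive_introns(sim.transcripts)
        cands = scan_introns(sim.genome, introns, shipped_pwm("acceptor23"))
        assert cands == []

    def test_truth_manifest_lists_every_plant(self):
        cfg = SimConfig(
            seed=7, n_genes=6, n_pass=3, n_decoy_short=1, n_decoy_long=1,
            n_decoy_weak=1, n_decoy_annotated=1,
        )
        sim = simulate_genome(cfg)
        assert len(sim.truth) == 7
        assert (sim.truth["expected_pass"].sum()) == 3

    def test_planted_boundaries_have_the_donor_signature(self, sim_corpus):
        sim, *_ = sim_corpus
        for p in sim.plants:
            assert sim.genome.fetch(p.contig, p.start, p.end, p.strand)[-3:] == "AGA"
            if p.strand == "+":
                intronic = sim.genome.fetch(p.contig, p.end, p.end + 5, "+")
            else:
                intronic = sim.genome.fetch(p.contig, p.start - 5, p.start, "-")
            assert intronic == "GTAAG"

    def test_acceptor_score_classes_verified_against_shipped_model(self, sim_corpus):
        sim, *_ = sim_corpus
        for p in sim.plants:
            if p.kind == "weak":
                assert p.acceptor_score <= 2.3
            else:
                assert p.acceptor_score > 2.3

    def test_cds_is_translatable(self, sim_corpus):
        sim, *_ = sim_corpus
        for tx in sim.transcripts:
            if tx.cds is None:
                continue
            mrna = tx.spliced_sequence(sim.genome)
            # locate the CDS in mature coordinates via the exon walk
            from psiexon.nmd_expression import _first_stop, _mature_position

            start_genomic = tx.cds[0] if tx.strand == "+" else tx.cds[1] - 1
            start = _mature_position(tx.exons, tx.strand, start_genomic)
            assert mrna[start : start + 3] == "ATG"
            stop = _first_stop(mrna, start)
            assert stop is not None
            # the annotated stop codon terminates the CDS exactly
            cds_len = tx.cds[1] - tx.cds[0] if len(tx.exons) == 1 else None
            assert mrna[stop : stop + 3] in ("TAA", "TAG", "TGA")

    def test_too_many_plants_rejected(self):
        with pytest.raises(ValueError, match="introns available"):
            simulate_genome(SimConfig(seed=0, n_genes=1, n_pass=50))


class TestJunctionSimulation:
    def test_extreme_psi_values(self):
        rng = np.random.default_rng(0)
        j1, j2, skip = draw_event_counts(rng, 500, 0.0)
        assert (j1, j2, skip) == (0, 0, 500)
        j1, j2, skip = draw_event_counts(rng, 500, 100.0)
        assert (j1, j2) == (500, 500) and skip == 0

    def test_out_of_range_psi_rejected(self):
        with pytest.raises(ValueError):
            draw_event_counts(np.random.default_rng(0), 100, 120.0)

    def test_recovery_at_depth_10000(self):
        from psiexon.splice_events import compute_psi, SpliceEvent
        from conftest import make_junctions

        rng = np.random.default_rng(13)
        j1, j2, skip = draw_event_counts(rng, 10_000, 30.0)
        jt = make_junctions(
            [
                ("c", 100, 200, "+", "s", j1),
                ("c", 300, 400, "+", "s", j2),
                ("c", 100, 400, "+", "s", skip),
            ]
        )
        ev = SpliceEvent(
            "e", "CE", "c", "+", "g",
            inclusion=[(100, 200), (300, 400)], exclusion=[(100, 400)],
            exon=(200, 300),
        )
        assert compute_psi(ev, jt, "s") == pytest.approx(30.0, abs=2.0)

    def test_determinism(self, sim_corpus):
        sim, junctions, _, _ = sim_corpus
        again, _, _ = simulate_junction_counts(sim)
        pd.testing.assert_frame_equal(junctions.df, again.df)


class TestThresholdEvents:
    def test_truth_includes_boundary_exclusive_cases(self):
        events, junctions, manifest, truth = simulate_threshold_events()
        assert len(events) == 20
        boundary = truth[truth["true_dpsi"].abs() == 20.0]
        assert not boundary.empty
        assert (boundary["true_call"] == "NC").all()
        assert {"Inc", "Skp", "NC"} <= set(truth["true_call"])


class TestQuantFixtures:
    def test_zero_noise_recovers_lowering_exactly(self):
        from psiexon.quantification import ecl_lowering

        q = simulate_quant_fixtures(SimConfig(seed=1, ecl_noise_sd=0.0))
        per, summary = ecl_lowering(q["ecl"], "vehicle")
        s = summary.set_index("group")["mean_lowering"]
        for group, low in q["truth"]["lowering"].items():
            assert s[group] == pytest.approx(low, abs=1e-9)

    def test_noisy_group_mean_within_clt_bound(self):
        from psiexon.quantification import ecl_lowering

        sd = 0.05
        cfg = SimConfig(seed=2, ecl_noise_sd=sd, n_animals=10)
        q = simulate_quant_fixtures(cfg)
        per, summary = ecl_lowering(q["ecl"], "vehicle")
        s = summary.set_index("group")["mean_lowering"]
        for group, low in q["truth"]["lowering"].items():
            # multiplicative noise of sd 5% -> lowering sd ~ 7 points
            assert abs(s[group] - low) <= 3 * (100 * sd * np.sqrt(2)) / np.sqrt(10)

    def test_encoded_papp_recovered_to_machine_precision(self):
        from psiexon.quantification import papp

        q = simulate_quant_fixtures(SimConfig(seed=3))
        by_dir = {r.direction: r for r in q["permeability"]}
        assert papp(by_dir["A->B"]) == pytest.approx(
            q["truth"]["papp_ab"], rel=1e-12
        )
        assert papp(by_dir["B->A"]) == pytest.approx(
            q["truth"]["papp_ba"], rel=1e-12
        )

    def test_qpcr_fixture_recovers_percent(self):
        from psiexon.quantification import qpcr_percent

        q = simulate_quant_fixtures(SimConfig(seed=4))
        df = qpcr_percent(q["qpcr"], "vehicle")
        means = df.groupby("group")["percent_of_vehicle"].mean()
        for group, pct in q["truth"]["qpcr_percent"].items():
            assert means[group] == pytest.approx(pct, abs=1e-9)


def test_write_corpus_outputs_readable(tmp_path):
    from psiexon import core_io

    cfg = SimConfig(seed=9, n_genes=3, n_pass=1)
    paths = write_corpus(cfg, tmp_path / "corpus")
    genome = core_io.read_genome(paths["genome"])
    transcripts = core_io.read_annotation(paths["annotation"], "gtf")
    junctions = core_io.read_junctions(paths["junctions"], dialect="generic")
    manifest = core_io.read_manifest(paths["manifest"])
    assert len(genome.contigs) == 3
    assert len(transcripts) >= 3
    assert set(junctions.samples) == set(manifest.samples)
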