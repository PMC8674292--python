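"""Synthetic study corpora with known ground truth.

Everything the pipeline consumes can be generated here: a multi-gene genome
whose introns carry planted GA-psiExons (exact ``AGA|GTAAG`` boundaries,
acceptors constructed by rejection sampling against the shipped fallback
acceptor model to hit a target score class), decoys violating exactly one
scan filter each, per-sample junction counts at specified true inclusion
levels for two conditions with replicates, an amplicon-panel-style junction
table with a cryptic junction inside one intron, differential-expression
tables with planted shifts, and quantification fixtures (ECL, qPCR,
permeability) with recorded truth.

Determinism: identical config + seed give byte-identical outputs.  All
randomness flows through one ``numpy`` generator seeded from the config.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    GenomeSequence,
    IntronRecord,
    JunctionTable,
    JUNCTION_COLUMNS,
    SampleManifest,
    TranscriptModel,
    revcomp,
    write_gtf,
)
from .splice_events import SpliceEvent
from .splice_site_models import SpliceSiteModel, shipped_pwm

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_junction_counts",
    "simulate_threshold_events",
    "simulate_ampliseq",
    "simulate_expression_table",
    "simulate_quant_fixtures",
    "draw_event_counts",
    "write_corpus",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_MOTIF = "AGAGTAAG"


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate the source study's design: two conditions (DMSO control
    vs compound) with three biological replicates, psiExons nearly silent at
    baseline and strongly included under treatment, junction depths in the
    hundreds-to-thousands range typical of targeted/bulk RNA-seq.
    """

    seed: int = 0
    # genome architecture
    n_genes: int = 6
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (90, 180)
    intron_length: tuple[int, int] = (700, 1100)
    utr_length: int = 30
    # plants: passing psiExons and single-violation decoys
    n_pass: int = 4
    n_decoy_short: int = 0  # length 5
    n_decoy_long: int = 0  # length 201
    n_decoy_weak: int = 0  # acceptor score <= 2.3
    n_decoy_annotated: int = 0  # annotated twin
    pass_length: tuple[int, int] = (30, 150)
    min_acceptor_score: float = 2.3
    # junction simulation
    control: str = "DMSO"
    treated: str = "DRUG"
    replicates: int = 3
    psi_control: float = 1.0
    psi_treated: float = 40.0
    event_depth: int = 1000
    constitutive_depth: int = 200
    # quant fixtures
    true_lowering: tuple[float, ...] = (30.0, 60.0)
    n_animals: int = 5
    ecl_noise_sd: float = 0.0  # multiplicative log-space sd
    qpcr_efficiency: float = 0.95
    true_papp_ab: float = 5e-6
    true_papp_ba: float = 2.5e-5


@dataclass
class Plant:
    kind: str  # pass | short | long | weak | annotated
    contig: str
    strand: str
    start: int  # genomic exon interval
    end: int
    length: int
    gene_id: str
    intron_donor: int
    intron_acceptor: int
    acceptor_score: float
    expected_pass: bool
    expected_reason: str


@dataclass
class SimulatedGenome:
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    plants: list[Plant]
    config: SimConfig

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.plants])


def _ag_free(rng: np.random.Generator, n: int) -> str:
    """Random ACGT string with every AG dinucleotide broken (G -> C)."""
    s = list(rng.choice(_BASES, size=n))
    for i in range(1, n):
        if s[i - 1] == "A" and s[i] == "G":
            s[i] = "C"
    return "".join(s)


def _pyrimidine(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(np.array(list("CT")), size=n))


def _codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop codons, free of the psiExon donor motif."""
    out: list[str] = []
    for _ in range(n):
        while True:
            c = "".join(rng.choice(_BASES, size=3))
            if c in _STOPS:
                continue
            if _MOTIF in ("".join(out[-3:]) + c):
                continue
            out.append(c)
            break
    return "".join(out)


def _plant_block(
    rng: np.random.Generator,
    length: int,
    score_class: str,
    acceptor: SpliceSiteModel,
    min_score: float,
    max_attempts: int = 1000,
) -> tuple[str, str, float]:
    """Acceptor tract + AG + exon body + GTAAG hitting a target score class.

    Returns (block sequence, exon sequence, acceptor score).  The exon ends
    with AGA and contains no other AG so the scan sees exactly one candidate
    per plant.
    """
    body_len = length - 3
    for _ in range(max_attempts):
        body = _ag_free(rng, body_len) + "AGA"
        if score_class == "pass":
            tract = _pyrimidine(rng, 18)
        else:  # weak acceptor: purine/pyrimidine mix with no G
            tract = "".join(rng.choice(np.array(list("AC")), size=18, p=[0.7, 0.3]))
        window = tract + "AG" + body[:3]
        score = acceptor.score(window)
        if score_class == "pass" and score > min_score + 1.0:
            return tract + "AG" + body + "GTAAG", body, float(score)
        if score_class == "weak" and score <= min_score - 0.3:
            return tract + "AG" + body + "GTAAG", body, float(score)
    raise RuntimeError(
        f"could not construct a {score_class!r} acceptor in {max_attempts} attempts"
    )


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Genome + annotation + ground-truth manifest with planted psiExons.

    Genes alternate strands across contigs (one gene per contig).  Each gene
    has an annotated CDS (start in the first coding exon, stop in the last)
    so NMD classification is decidable.  At most one psiExon or decoy is
    planted per intron; an error is raised when the architecture offers too
    few introns.
    """
    rng = np.random.default_rng(config.seed)
    acceptor = shipped_pwm("acceptor23")

    plant_kinds = (
        ["pass"] * config.n_pass
        + ["short"] * config.n_decoy_short
        + ["long"] * config.n_decoy_long
        + ["weak"] * config.n_decoy_weak
        + ["annotated"] * config.n_decoy_annotated
    )
    n_introns_available = 0

    contigs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    plants: list[Plant] = []

    # assign plants to (gene, intron) slots round-robin
    gene_specs = []
    for g in range(config.n_genes):
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        gene_specs.append(k)
        n_introns_available += k - 1
    if len(plant_kinds) > n_introns_available:
        raise ValueError(
            f"{len(plant_kinds)} plants requested but only "
            f"{n_introns_available} introns available; increase n_genes"
        )
    slots: list[tuple[int, int]] = [
        (g, i) for g, k in enumerate(gene_specs) for i in range(k - 1)
    ]
    chosen = rng.choice(len(slots), size=len(plant_kinds), replace=False)
    plant_at = {slots[int(ix)]: kind for ix, kind in zip(chosen, plant_kinds)}

    for g, k in enumerate(gene_specs):
        gene_id = f"G{g+1:03d}"
        contig = f"chr{g+1}"
        strand = "+" if g % 2 == 0 else "-"
        exon_lens = [
            int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            for _ in range(k)
        ]
        total_exonic = sum(exon_lens)
        utr5 = config.utr_length
        coding_len = total_exonic - 2 * utr5
        coding_len -= coding_len % 3
        utr3 = total_exonic - utr5 - coding_len
        mrna = (
            _ag_free(rng, utr5)
            + "ATG"
            + _codons(rng, coding_len // 3 - 2)
            + "TAA"
            + _ag_free(rng, utr3)
        )
        assert len(mrna) == total_exonic

        # slice mRNA into exons, then interleave introns (sense space)
        sense_parts: list[str] = []
        exon_sense: list[tuple[int, int]] = []
        plant_sense: list[tuple[str, int, int, float]] = []  # kind, start, end, score
        off = 0
        pos = 0
        for i, elen in enumerate(exon_lens):
            exon_sense.append((pos, pos + elen))
            sense_parts.append(mrna[off : off + elen])
            off += elen
            pos += elen
            if i == k - 1:
                break
            kind = plant_at.get((g, i))
            block = ""
            if kind is not None:
                length = {
                    "pass": int(rng.integers(config.pass_length[0], config.pass_length[1] + 1)),
                    "annotated": int(rng.integers(config.pass_length[0], config.pass_length[1] + 1)),
                    "short": 5,
                    "long": 201,
                    "weak": int(rng.integers(config.pass_length[0], config.pass_length[1] + 1)),
                }[kind]
                score_class = "weak" if kind == "weak" else "pass"
                block, exon_seq, score = _plant_block(
                    rng, length, score_class, acceptor, config.min_acceptor_score
                )
                ilen = max(
                    config.intron_length[0], 300 + len(block) + 40
                )
                ilen = int(rng.integers(ilen, max(config.intron_length[1], ilen + 50) + 1))
                pre = 240  # bases before the acceptor tract
                post = ilen - pre - len(block)  # remainder incl. real 3'ss
                intron = (
                    "GT"
                    + _ag_free(rng, pre - 2)
                    + block
                    + _ag_free(rng, post - 20)
                    + _pyrimidine(rng, 18)
                    + "AG"
                )
                # sense interval of the planted exon inside this intron
                ps = pos + pre + 20  # after tract(18)+AG
                pe = ps + length
                plant_sense.append((kind, ps, pe, score))
            else:
                ilen = int(
                    rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                )
                intron = (
                    "GT"
                    + _ag_free(rng, ilen - 22)
                    + _pyrimidine(rng, 18)
                    + "AG"
                )
            sense_parts.append(intron)
            pos += ilen
        sense = "".join(sense_parts)
        glen = len(sense)

        pad = 60
        block_seq = sense if strand == "+" else revcomp(sense)
        contig_seq = _ag_free(rng, pad) + block_seq + _ag_free(rng, pad)

        # scrub unplanned motif occurrences (both genomic strands)
        planted_genomic: list[tuple[int, int]] = []

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            s, e = iv
            if strand == "+":
                return pad + s, pad + e
            return pad + glen - e, pad + glen - s

        exons_genomic = sorted(to_genomic(iv) for iv in exon_sense)
        for kind, ps, pe, score in plant_sense:
            gs, ge = to_genomic((ps, pe))
            planted_genomic.append((gs - 25, ge + 8))  # window incl. tract+GTAAG

        # both genomic orientations of the motif are broken by forcing the
        # sense +3 position to C, which can create neither a stop codon nor
        # an AG dinucleotide; iterate in case a substitution shifts a match
        seq = contig_seq
        for _ in range(5):
            dirty = False
            chars = list(seq)
            for target, sub_at, sub in ((_MOTIF, 4, "C"), (revcomp(_MOTIF), 3, "G")):
                start = 0
                while True:
                    j = seq.find(target, start)
                    if j == -1:
                        break
                    if not any(lo <= j and j + 8 <= hi for lo, hi in planted_genomic):
                        chars[j + sub_at] = sub
                        dirty = True
                    start = j + 1
            seq = "".join(chars)
            if not dirty:
                break
        contig_seq = seq
        contigs[contig] = contig_seq

        # CDS span in genomic coordinates
        cds_lo_off, cds_hi_off = utr5, utr5 + coding_len  # mRNA offsets
        def mrna_to_genomic(offset: int) -> int:
            rem = offset
            for (s, e), (gs, ge) in zip(
                exon_sense, [to_genomic(iv) for iv in exon_sense]
            ):
                if rem < e - s:
                    return (gs + rem) if strand == "+" else (ge - 1 - rem)
                rem -= e - s
            raise ValueError("offset outside mRNA")

        a = mrna_to_genomic(cds_lo_off)
        b = mrna_to_genomic(cds_hi_off - 1)
        cds_genomic = (min(a, b), max(a, b) + 1)

        tx = TranscriptModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.t1",
            contig=contig,
            strand=strand,
            exons=exons_genomic,
            cds=cds_genomic,
            source="synthetic",
        )
        transcripts.append(tx)

        # intron genomic spans for the truth manifest
        introns_genomic = [
            (e1, s2) for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:])
        ]
        for kind, ps, pe, score in plant_sense:
            gs, ge = to_genomic((ps, pe))
            host = next(
                (d, aa) for d, aa in introns_genomic if d <= gs and ge <= aa
            )
            length = pe - ps
            reasons = []
            if not (6 <= length <= 200):
                reasons.append("length")
            if kind == "weak":
                reasons.append("score")
            if kind == "annotated":
                reasons.append("annotated")
                transcripts.append(
                    TranscriptModel(
                        gene_id=gene_id,
                        transcript_id=f"{gene_id}.twin{gs}",
                        contig=contig,
                        strand=strand,
                        exons=[(gs, ge)],
                        source="synthetic",
                    )
                )
            plants.append(
                Plant(
                    kind=kind,
                    contig=contig,
                    strand=strand,
                    start=gs,
                    end=ge,
                    length=length,
                    gene_id=gene_id,
                    intron_donor=host[0],
                    intron_acceptor=host[1],
                    acceptor_score=score,
                    expected_pass=not reasons,
                    expected_reason=",".join(reasons),
                )
            )

    return SimulatedGenome(
        genome=GenomeSequence(contigs),
        transcripts=transcripts,
        plants=plants,
        config=config,
    )


def draw_event_counts(
    rng: np.random.Generator, depth: int, psi: float
) -> tuple[int, int, int]:
    """Junction counts for one cassette event at true PSI (percent).

    ``M ~ Binomial(depth, psi/100)`` inclusion molecules each evidence both
    inclusion junctions; exclusion molecules produce the skip reads.
    Returns (inclusion junction 1, inclusion junction 2, skip).
    """
    if not 0 <= psi <= 100:
        raise ValueError(f"true PSI {psi} outside [0, 100]")
    m = int(rng.binomial(depth, psi / 100.0))
    return m, m, depth - m


def simulate_junction_counts(
    sim: SimulatedGenome, config: SimConfig | None = None
) -> tuple[JunctionTable, SampleManifest, pd.DataFrame]:
    """Per-sample junction counts for the planted events + constitutive introns.

    Passing planted psiExons are cassette events at ``psi_control`` /
    ``psi_treated``; all annotated introns receive constitutive junction
    reads.  Returns the junction table, a manifest, and an event truth table.
    """
    config = config or sim.config
    rng = np.random.default_rng(config.seed + 1)

    samples = [
        (f"{grp}_{r+1}", grp, r + 1)
        for grp in (config.control, config.treated)
        for r in range(config.replicates)
    ]
    manifest = SampleManifest(
        pd.DataFrame(samples, columns=["sample_id", "group", "replicate"])
    )

    planted_introns = {
        (p.contig, p.intron_donor, p.intron_acceptor)
        for p in sim.plants
        if p.kind in ("pass", "annotated")
    }

    rows = []
    truth_rows = []
    for p in sim.plants:
        if p.kind not in ("pass", "annotated"):
            continue
        inc1 = (p.intron_donor, p.start)
        inc2 = (p.end, p.intron_acceptor)
        skip = (p.intron_donor, p.intron_acceptor)
        for sample_id, grp, _ in samples:
            psi = config.psi_control if grp == config.control else config.psi_treated
            depth = int(rng.poisson(config.event_depth))
            j1, j2, sk = draw_event_counts(rng, depth, psi)
            for (d, a), c in ((inc1, j1), (inc2, j2), (skip, sk)):
                rows.append((p.contig, d, a, p.strand, sample_id, c))
        truth_rows.append(
            {
                "contig": p.contig,
                "strand": p.strand,
                "exon_start": p.start,
                "exon_end": p.end,
                "gene_id": p.gene_id,
                "true_psi_control": config.psi_control,
                "true_psi_treated": config.psi_treated,
            }
        )

    for tx in sim.transcripts:
        if len(tx.exons) < 2:
            continue
        for d, a in tx.introns():
            if (tx.contig, d, a) in planted_introns:
                continue
            for sample_id, _, _ in samples:
                rows.append(
                    (
                        tx.contig, d, a, tx.strand, sample_id,
                        int(rng.poisson(config.constitutive_depth)),
                    )
                )

    table = JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS))
    return table, manifest, pd.DataFrame(truth_rows)


def simulate_ampliseq(
    sim: SimulatedGenome,
    cryptic_fraction_control: float = 0.0,
    cryptic_fraction_treated: float = 0.5,
    depth: int = 2000,
    config: SimConfig | None = None,
) -> tuple[JunctionTable, SampleManifest, pd.DataFrame]:
    """Amplicon-panel-style junction table with one cryptic junction.

    The first passing plant's host intron carries a cryptic acceptor at the
    planted exon start: a fraction f of donor-sharing reads splice
    donor->cryptic instead of the exact intron, so the intron's true JEI is
    100*(1-f).  All other introns splice exactly (JEI 100).  Counts are
    deterministic (rounded) so truth is exact up to rounding.
    """
    config = config or sim.config
    target = next(p for p in sim.plants if p.kind == "pass")

    samples = [
        (f"{grp}_{r+1}", grp, r + 1)
        for grp in (config.control, config.treated)
        for r in range(config.replicates)
    ]
    manifest = SampleManifest(
        pd.DataFrame(samples, columns=["sample_id", "group", "replicate"])
    )

    rows = []
    for tx in sim.transcripts:
        if len(tx.exons) < 2:
            continue
        for d, a in tx.introns():
            is_target = (
                tx.contig == target.contig
                and d == target.intron_donor
                and a == target.intron_acceptor
            )
            for sample_id, grp, _ in samples:
                if is_target:
                    f = (
                        cryptic_fraction_control
                        if grp == config.control
                        else cryptic_fraction_treated
                    )
                    exact = round(depth * (1.0 - f))
                    cryptic = depth - exact
                    rows.append((tx.contig, d, a, tx.strand, sample_id, exact))
                    if cryptic:
                        rows.append(
                            (tx.contig, d, target.start, tx.strand, sample_id, cryptic)
                        )
                else:
                    rows.append((tx.contig, d, a, tx.strand, sample_id, depth))

    truth = pd.DataFrame(
        [
            {
                "contig": target.contig,
                "intron_donor": target.intron_donor,
                "intron_acceptor": target.intron_acceptor,
                "jei_control": 100.0 * (1.0 - cryptic_fraction_control),
                "jei_treated": 100.0 * (1.0 - cryptic_fraction_treated),
            }
        ]
    )
    return (
        JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS)),
        manifest,
        truth,
    )


def simulate_threshold_events(
    seed: int = 0,
) -> tuple[list[SpliceEvent], JunctionTable, SampleManifest, pd.DataFrame]:
    """20 cassette events with deterministic counts straddling the call thresholds.

    dPSI takes values around the 20-point boundary (including exactly 20 and
    -20, which must NOT be called) and read depths are chosen so the Fisher P
    straddles 0.001.  The truth table records the expected call computed from
    hand arithmetic and an exact hypergeometric enumeration independent of
    the package's own test path.
    """
    # (basal PSI, treated PSI, per-sample denominator)
    specs = [
        (10, 40, 200), (10, 35, 200), (10, 31, 200), (50, 80, 200),
        (10, 30, 200),  # dPSI exactly 20 -> NC
        (40, 20, 200), (80, 50, 200), (60, 20, 200),
        (30, 10, 200),  # dPSI exactly -20 -> NC
        (10, 40, 24),   # big dPSI, tiny depth -> P too large -> NC
        (40, 10, 24),
        (10, 12, 400), (50, 52, 400), (50, 48, 400),
        (5, 95, 100), (95, 5, 100),
        (10, 45, 60), (45, 10, 60),
        (25, 50, 150), (50, 25, 150),
    ]
    n_rep = 3
    samples = [(f"DMSO_{r+1}", "DMSO", r + 1) for r in range(n_rep)] + [
        (f"DRUG_{r+1}", "DRUG", r + 1) for r in range(n_rep)
    ]
    manifest = SampleManifest(
        pd.DataFrame(samples, columns=["sample_id", "group", "replicate"])
    )

    events: list[SpliceEvent] = []
    rows = []
    truth_rows = []
    base = 10_000
    for i, (psi_a, psi_b, denom) in enumerate(specs):
        o = base + i * 1000
        exon = (o + 300, o + 400)
        inc = [(o + 100, o + 300), (o + 400, o + 600)]
        exc = [(o + 100, o + 600)]
        ev = SpliceEvent(
            event_id=f"CE:sim:+:{exon[0]}-{exon[1]}",
            kind="CE",
            contig="sim",
            strand="+",
            gene_id=f"T{i:02d}",
            inclusion=inc,
            exclusion=exc,
            exon=exon,
        )
        events.append(ev)
        table = []
        for sample_id, grp, _ in samples:
            psi = psi_a if grp == "DMSO" else psi_b
            inc_n = round(denom * psi / 100)
            exc_n = denom - inc_n
            for (d, a), c in ((inc[0], inc_n), (inc[1], inc_n), (exc[0], exc_n)):
                rows.append(("sim", d, a, "+", sample_id, c))
        inc_a = n_rep * round(denom * psi_a / 100)
        exc_a = n_rep * denom - inc_a
        inc_b = n_rep * round(denom * psi_b / 100)
        exc_b = n_rep * denom - inc_b
        p = _fisher_enumeration(inc_a, exc_a, inc_b, exc_b)
        dpsi = 100 * round(denom * psi_b / 100) / denom - 100 * round(denom * psi_a / 100) / denom
        if dpsi > 20 and p < 1e-3:
            call = "Inc"
        elif dpsi < -20 and p < 1e-3:
            call = "Skp"
        else:
            call = "NC"
        truth_rows.append(
            {"event_id": ev.event_id, "true_dpsi": dpsi, "true_p": p, "true_call": call}
        )
    junctions = JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS))
    return events, junctions, manifest, pd.DataFrame(truth_rows)


def _fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exhaustive fixed-margin enumeration (log-space)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lgam = math.lgamma

    def log_hyper(x):
        return (
            lgam(r1 + 1) - lgam(x + 1) - lgam(r1 - x + 1)
            + lgam(r2 + 1) - lgam(c1 - x + 1) - lgam(r2 - (c1 - x) + 1)
            - (lgam(n + 1) - lgam(c1 + 1) - lgam(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = log_hyper(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_hyper(x)
        if lp <= obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def simulate_expression_table(
    seed: int = 0,
    n_genes: int = 1000,
    n_nmd_hosts: int = 20,
    shift: float = -1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Differential-expression table with a planted LFC shift in host genes.

    Null genes: log2fc ~ N(0, 0.5), FDR ~ U(0.05, 1).  The ``n_nmd_hosts``
    planted genes get log2fc shifted by ``shift`` and small FDRs, emulating
    downregulation of NMD-psiExon host genes.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"EXPR{i:05d}" for i in range(n_genes)]
    lfc = rng.normal(0.0, 0.5, size=n_genes)
    fdr = rng.uniform(0.05, 1.0, size=n_genes)
    hosts = [gene_ids[i] for i in rng.choice(n_genes, size=n_nmd_hosts, replace=False)]
    host_ix = [gene_ids.index(h) for h in hosts]
    lfc[host_ix] += shift
    fdr[host_ix] = rng.uniform(0.0001, 0.04, size=n_nmd_hosts)
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": lfc,
            "fdr": fdr,
            "base_mean": rng.lognormal(6, 1, size=n_genes),
        }
    )
    return df, hosts


def simulate_quant_fixtures(config: SimConfig) -> dict:
    """ECL, qPCR and permeability fixtures with recorded truth.

    With ``ecl_noise_sd = 0`` the pipeline recovers the planted lowering
    exactly; the permeability series is linear so ``papp`` returns the
    encoded Papp to machine precision.
    """
    rng = np.random.default_rng(config.seed + 2)
    from .quantification import EclRecord, PermeabilityRecord, QpcrRecord

    def noisy(x):
        if config.ecl_noise_sd == 0:
            return x
        return x * float(np.exp(rng.normal(0, config.ecl_noise_sd)))

    base_t, base_n = 4000.0, 2000.0
    ecl: list[EclRecord] = []
    groups = ["vehicle"] + [f"dose{i+1}" for i in range(len(config.true_lowering))]
    lowering = {g: l for g, l in zip(groups[1:], config.true_lowering)}
    for g in groups:
        rel = 1.0 - lowering.get(g, 0.0) / 100.0
        for a in range(config.n_animals):
            t = noisy(base_t * rel)
            n = noisy(base_n)
            ecl.append(
                EclRecord(
                    animal_id=f"{g}_a{a+1}",
                    tissue="brain",
                    group=g,
                    target_signals=[t, t],
                    normaliser_signals=[n, n],
                )
            )

    E = config.qpcr_efficiency
    norm_ct = 20.0
    norm_abund = (1 + E) ** (-norm_ct)
    qpcr: list[QpcrRecord] = []
    for g in groups:
        rel = 1.0 - lowering.get(g, 0.0) / 100.0
        for a in range(config.n_animals):
            target_abund = rel * norm_abund
            ct = -math.log(target_abund) / math.log(1 + E)
            qpcr.append(
                QpcrRecord(
                    sample_id=f"{g}_a{a+1}",
                    group=g,
                    target_ct=ct,
                    normaliser_ct=norm_ct,
                    target_efficiency=E,
                    normaliser_efficiency=E,
                )
            )

    vr, a_cm2, c0, vd = 0.5, 1.13, 10.0, 0.4
    times = [0.0, 1200.0, 2400.0, 3600.0]
    perm = []
    for direction, p_true in (("A->B", config.true_papp_ab), ("B->A", config.true_papp_ba)):
        slope = p_true * a_cm2 * c0 / vr
        perm.append(
            PermeabilityRecord(
                direction=direction,
                times_s=times,
                receiver_uM=[slope * t for t in times],
                vr_cm3=vr,
                a_cm2=a_cm2,
                c0_uM=c0,
                vd_cm3=vd,
            )
        )

    return {
        "ecl": ecl,
        "qpcr": qpcr,
        "permeability": perm,
        "truth": {
            "lowering": lowering,
            "qpcr_percent": {
                g: 100.0 * (1.0 - lowering.get(g, 0.0) / 100.0) for g in groups
            },
            "papp_ab": config.true_papp_ab,
            "papp_ba": config.true_papp_ba,
        },
    }


def write_corpus(config: SimConfig, outdir: str | os.PathLike) -> dict:
    """Materialise a full synthetic corpus under *outdir* (text formats only)."""
    os.makedirs(outdir, exist_ok=True)
    sim = simulate_genome(config)
    junctions, manifest, event_truth = simulate_junction_counts(sim)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.gtf"),
        "junctions": os.path.join(outdir, "junctions.tsv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "event_truth": os.path.join(outdir, "event_truth.tsv"),
    }
    sim.genome.to_fasta(paths["genome"])
    write_gtf(sim.transcripts, paths["annotation"])
    junctions.to_tsv(paths["junctions"])
    manifest.to_tsv(paths["manifest"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    event_truth.to_csv(paths["event_truth"], sep="\t", index=False)

    quant = simulate_quant_fixtures(config)
    qdir = os.path.join(outdir, "quant")
    os.makedirs(qdir, exist_ok=True)
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "tissue": r.tissue,
                "group": r.group,
                "target_1": r.target_signals[0],
                "target_2": r.target_signals[1],
                "normaliser_1": r.normaliser_signals[0],
                "normaliser_2": r.normaliser_signals[1],
            }
            for r in quant["ecl"]
        ]
    ).to_csv(os.path.join(qdir, "ecl.csv"), index=False)
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "target_ct": r.target_ct,
                "normaliser_ct": r.normaliser_ct,
                "target_efficiency": r.target_efficiency,
                "normaliser_efficiency": r.normaliser_efficiency,
            }
            for r in quant["qpcr"]
        ]
    ).to_csv(os.path.join(qdir, "qpcr.csv"), index=False)
    perm_rows = []
    for r in quant["permeability"]:
        for t, c in zip(r.times_s, r.receiver_uM):
            perm_rows.append(
                {
                    "direction": r.direction,
                    "time_s": t,
                    "receiver_uM": c,
                    "vr_cm3": r.vr_cm3,
                    "a_cm2": r.a_cm2,
                    "c0_uM": r.c0_uM,
                    "vd_cm3": r.vd_cm3,
                }
            )
    pd.DataFrame(perm_rows).to_csv(os.path.join(qdir, "permeability.csv"), index=False)
    paths["quant_dir"] = qdir
    return paths
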