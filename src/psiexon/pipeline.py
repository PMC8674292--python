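"""End-to-end orchestration of the splicing-analysis stages.

``run_pipeline`` wires the stages in dependency order — IO, JEI, event
catalogue + PSI + calls, psiExon classification, splice-site scoring, the
genome-wide GA-psiExon scan, optional NMD/expression analysis and k-mer
enrichment — writing one TSV per stage plus a run manifest with the config
hash, input checksums and per-stage row counts.  All thresholds default to
the study values and live in one place so sensitivity analyses are one-line
config edits.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import core_io, jei as jei_mod, kmer_enrichment, nmd_expression
from . import psiexon_scan, splice_events, splice_site_models

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    genome: str
    annotations: list[str]  # GTF paths; first is the primary scaffold
    junctions: str  # generic 6-column TSV
    manifest: str
    control: str
    treated: str
    outdir: str
    expression: str | None = None  # optional DE table TSV
    seed: int = 0
    # thresholds (study defaults)
    dpsi_threshold: float = 20.0
    psi_p_threshold: float = 1e-3
    psi_min_denominator: int = 20
    jei_reduction_threshold: float = 25.0
    jei_p_threshold: float = 0.05
    fold_threshold: float = 1.5
    fdr_threshold: float = 0.05
    scan_min_len: int = 6
    scan_max_len: int = 200
    scan_min_acceptor_score: float = 2.3

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the run manifest (also written to run.json)."""
    for path in [config.genome, config.junctions, config.manifest, *config.annotations]:
        if not os.path.exists(path):
            raise FileNotFoundError(f"input not found before run start: {path}")
    os.makedirs(config.outdir, exist_ok=True)

    genome = core_io.read_genome(config.genome)
    transcripts = []
    for path in config.annotations:
        transcripts.extend(core_io.read_annotation(path, "gtf"))
    introns = core_io.derive_introns(transcripts)
    junctions = core_io.read_junctions(config.junctions, dialect="generic")
    junctions = junctions.resolve_strands(introns)
    manifest = core_io.read_manifest(config.manifest)

    counts: dict[str, int] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        df.to_csv(os.path.join(config.outdir, f"{name}.tsv"), sep="\t", index=False)
        counts[name] = len(df)

    # JEI per intron
    jei_df = jei_mod.jei_table(
        junctions, introns, manifest, config.control, config.treated
    )
    emit("jei", jei_df)

    # events, PSI, calls
    events = splice_events.build_event_catalog(junctions, transcripts)
    results = splice_events.analyze_events(
        events, junctions, manifest, config.control, config.treated
    )
    emit("events", splice_events.results_table(events, results))

    # psiExon classification of Inc-called cassette exons
    records = splice_events.classify_psiexons(events, results, transcripts, genome)
    emit(
        "psiexons",
        pd.DataFrame(
            [
                {
                    "event_id": r.event_id,
                    "contig": r.contig,
                    "strand": r.strand,
                    "start": r.exon[0],
                    "end": r.exon[1],
                    "length": r.length,
                    "basal_psi": r.basal_psi,
                    "is_psiexon": r.is_psiexon,
                }
                for r in records
            ]
        ),
    )
    with open(os.path.join(config.outdir, "psiexons.bed"), "w") as fh:
        for r in records:
            if r.is_psiexon:
                fh.write(
                    f"{r.contig}\t{r.exon[0]}\t{r.exon[1]}\t{r.event_id}\t0\t{r.strand}\n"
                )

    # genome-wide GA-psiExon scan with the shipped fallback acceptor model
    acceptor = splice_site_models.shipped_pwm("acceptor23")
    candidates = psiexon_scan.scan_introns(
        genome,
        introns,
        acceptor,
        min_len=config.scan_min_len,
        max_len=config.scan_max_len,
        min_score=config.scan_min_acceptor_score,
    )
    candidates = psiexon_scan.annotate_candidates(candidates, transcripts)
    emit("scan", psiexon_scan.candidates_table(candidates))

    # k-mer enrichment at the 5'ss, Inc vs NC cassette exons
    by_call: dict[str, list] = {"Inc": [], "NC": []}
    res_by_id = {r.event_id: r for r in results}
    for ev in events:
        if ev.kind == "CE" and ev.exon is not None:
            call = res_by_id[ev.event_id].call
            if call in by_call:
                by_call[call].append((ev.contig, ev.strand, *ev.exon))
    kmer_rows = []
    if by_call["Inc"] and by_call["NC"]:
        for label, region in (("exonic_-4_-1", (-4, -1)), ("intronic_+1_+6", (1, 6))):
            w1, _ = kmer_enrichment.extract_ss_windows(by_call["Inc"], genome, region)
            w2, _ = kmer_enrichment.extract_ss_windows(by_call["NC"], genome, region)
            for k in (4, 5, 6):
                if min(len(x) for x in w1 + w2) >= k:
                    for r in kmer_enrichment.kmer_significance(w1, w2, k):
                        kmer_rows.append(
                            {
                                "window": label, "k": k, "kmer": r.kmer,
                                "n1": r.n1, "n2": r.n2, "p": r.p,
                                "S": r.sign, "SS": r.ss,
                            }
                        )
    emit("kmer", pd.DataFrame(kmer_rows))

    # optional expression stage
    if config.expression:
        expr = pd.read_csv(config.expression, sep="\t")
        emit(
            "volcano",
            nmd_expression.volcano_classify(
                expr, config.fold_threshold, config.fdr_threshold
            ),
        )

    run = {
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "inputs": {
            p: _checksum(p)
            for p in [config.genome, config.junctions, config.manifest]
            + config.annotations
        },
        "rows": counts,
    }
    with open(os.path.join(config.outdir, "run.json"), "w") as fh:
        json.dump(run, fh, indent=2)
    return run
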