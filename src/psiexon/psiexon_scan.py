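"""Genome-wide discovery of putative GA-psiExons.

A GA-psiExon candidate is an intronic interval that ends with the
noncanonical donor signature ``AGA|gtaag`` (exon-final AGA followed by the
intronic GTAAG, so the 5'ss reads AGAgtaag) and begins immediately after an
upstream AG acceptor dinucleotide.  The scan runs on the biological sense
strand of every annotated intron; each AG upstream of a motif occurrence is
scored as a 23-mer acceptor window (20 intronic + 3 exonic bases), and a
candidate passes when it is 6-200 nt long, its acceptor scores above 2.3,
and the exon is not already annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core_io import GenomeSequence, IntronRecord, TranscriptModel
from .splice_site_models import SpliceSiteModel

__all__ = [
    "PsiExonCandidate",
    "scan_introns",
    "annotate_candidates",
    "exon_end_dinucleotide_census",
    "candidates_table",
]

DEFAULT_MOTIF = "AGAGTAAG"  # exon-final AGA + intronic GTAAG
MIN_LENGTH = 6
MAX_LENGTH = 200
MIN_ACCEPTOR_SCORE = 2.3


@dataclass
class PsiExonCandidate:
    contig: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int
    gene_id: str
    intron_id: str
    intron_ordinal: int
    acceptor_window: str
    acceptor_score: float
    length: int
    annotated: bool = False
    primary: bool = False
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def passes_filters(self) -> bool:
        return not self.failure_reasons


def scan_introns(
    genome: GenomeSequence,
    introns: Sequence[IntronRecord],
    acceptor_model: SpliceSiteModel,
    motif: str = DEFAULT_MOTIF,
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
    min_score: float = MIN_ACCEPTOR_SCORE,
) -> list[PsiExonCandidate]:
    """Scan intron sense strands for motif occurrences and score acceptors.

    For every motif hit, every upstream AG dinucleotide whose implied exon is
    at most ``max_len + 23`` bases is enumerated as a candidate acceptor; the
    23-mer window ending 3 bases into the exon is scored.  All candidates are
    returned with filter verdicts (``length`` / ``score`` annotated later by
    :func:`annotate_candidates`); per motif occurrence the best-scoring
    passing candidate is marked ``primary`` (ties broken by shorter exon).
    Candidates whose acceptor window would cross the intron boundary are
    dropped.  Duplicate candidates shared by overlapping transcripts or genes
    collapse to one record keyed by (contig, strand, interval).
    """
    motif = motif.upper()
    exonic_tail = 3  # the AGA belongs to the exon
    out: dict[tuple, PsiExonCandidate] = {}

    for intron in introns:
        seq = genome.fetch(intron.contig, intron.donor, intron.acceptor, intron.strand)
        ilen = len(seq)
        i = seq.find(motif)
        while i != -1:
            exon_end_s = i + exonic_tail  # sense coordinate, exclusive
            # GTAAG must be intronic of the candidate boundary and the exon
            # interior strictly inside the intron
            if i + len(motif) <= ilen and exon_end_s < ilen:
                occ: list[PsiExonCandidate] = []
                max_enum = max_len + 23  # enumerate past the length filter
                for length in range(3, max_enum + 1):
                    p = exon_end_s - length  # sense exon start
                    if p < 2:
                        break
                    if seq[p - 2 : p] != "AG":
                        continue
                    if p < 20:
                        continue  # acceptor window truncated by intron start
                    window = seq[p - 20 : p + 3]
                    score = acceptor_model.score(window)
                    # genomic interval of the sense-space exon [p, exon_end_s)
                    if intron.strand == "+":
                        g_start = intron.donor + p
                        g_end = intron.donor + exon_end_s
                    else:
                        g_start = intron.acceptor - exon_end_s
                        g_end = intron.acceptor - p
                    reasons = []
                    if not (min_len <= length <= max_len):
                        reasons.append("length")
                    if not score > min_score:
                        reasons.append("score")
                    occ.append(
                        PsiExonCandidate(
                            contig=intron.contig,
                            strand=intron.strand,
                            start=g_start,
                            end=g_end,
                            gene_id=intron.gene_id,
                            intron_id=intron.intron_id,
                            intron_ordinal=intron.ordinal,
                            acceptor_window=window,
                            acceptor_score=float(score),
                            length=length,
                            failure_reasons=reasons,
                        )
                    )
                passing = [c for c in occ if c.passes_filters]
                if passing:
                    best = min(passing, key=lambda c: (-c.acceptor_score, c.length))
                    best.primary = True
                for c in occ:
                    key = (c.contig, c.strand, c.start, c.end)
                    prev = out.get(key)
                    if prev is None or (c.primary and not prev.primary):
                        out[key] = c
            i = seq.find(motif, i + 1)
    return sorted(out.values(), key=lambda c: (c.contig, c.start, c.end, c.strand))


def annotate_candidates(
    candidates: Sequence[PsiExonCandidate],
    transcripts: Sequence[TranscriptModel],
) -> list[PsiExonCandidate]:
    """Mark candidates already present in annotation.

    A candidate is annotated when its interval exactly matches an annotated
    exon, or when both its splice sites appear as exon boundaries in any one
    source.  Annotated candidates gain the ``annotated`` failure reason and
    lose primary status.
    """
    exon_ivs = set()
    starts: set = set()
    ends: set = set()
    for t in transcripts:
        for s, e in t.exons:
            exon_ivs.add((t.contig, t.strand, s, e))
            starts.add((t.contig, t.strand, s))
            ends.add((t.contig, t.strand, e))
    for c in candidates:
        exact = (c.contig, c.strand, c.start, c.end) in exon_ivs
        both_ss = (c.contig, c.strand, c.start) in starts and (
            c.contig, c.strand, c.end
        ) in ends
        c.annotated = exact or both_ss
        if c.annotated and "annotated" not in c.failure_reasons:
            c.failure_reasons.append("annotated")
            c.primary = False
    return list(candidates)


def exon_end_dinucleotide_census(
    transcripts: Sequence[TranscriptModel], genome: GenomeSequence
) -> pd.DataFrame:
    """Frequencies of the -2,-1 exon-terminal dinucleotide over internal exons.

    Internal exons are exons possessing a downstream intron in transcription
    order; terminal exons are excluded.  Exons are deduplicated by genomic
    interval; counts are strand-aware (the dinucleotide is read in biological
    orientation).  AG is the canonical 5'ss exonic signature.
    """
    seen = set()
    counts: dict[str, int] = {}
    for t in transcripts:
        tx_exons = t.exons if t.strand == "+" else list(reversed(t.exons))
        for s, e in tx_exons[:-1]:  # all but transcription-order last
            key = (t.contig, t.strand, s, e)
            if key in seen:
                continue
            seen.add(key)
            if t.strand == "+":
                dinuc = genome.fetch(t.contig, e - 2, e, "+")
            else:
                dinuc = genome.fetch(t.contig, s, s + 2, "-")
            counts[dinuc] = counts.get(dinuc, 0) + 1
    total = sum(counts.values())
    bases = "ACGT"
    rows = []
    for d in (a + b for a in bases for b in bases):
        n = counts.get(d, 0)
        rows.append(
            {
                "dinucleotide": d,
                "count": n,
                "percent": 100.0 * n / total if total else 0.0,
                "canonical": d == "AG",
            }
        )
    return pd.DataFrame(rows)


def candidates_table(candidates: Sequence[PsiExonCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.contig,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "gene_id": c.gene_id,
                "intron_id": c.intron_id,
                "acceptor_score": c.acceptor_score,
                "acceptor_window": c.acceptor_window,
                "annotated": c.annotated,
                "passes_filters": c.passes_filters,
                "primary": c.primary,
                "failure_reasons": ",".join(c.failure_reasons),
            }
            for c in candidates
        ]
    )


def write_bed(
    candidates: Sequence[PsiExonCandidate], path, passing_only: bool = True
) -> None:
    """BED6; score column is the acceptor score x100, truncated."""
    with open(path, "w") as fh:
        for c in candidates:
            if passing_only and not c.passes_filters:
                continue
            name = f"{c.gene_id}|{c.intron_id}"
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{name}\t"
                f"{int(c.acceptor_score * 100)}\t{c.strand}\n"
            )
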