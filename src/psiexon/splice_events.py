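"""Alternative-splicing event catalogue, PSI statistics and psiExon calls.

Events are discovered from observed junction reads scaffolded on transcript
annotation:

* **CE** (cassette exon): an exon interval between two flanking annotated
  exons, supported by two inclusion junctions (flank->exon, exon->flank) and
  one exclusion (skip) junction bridging the flanks.  Unannotated intervals
  qualify when both inclusion junctions are observed and the skip junction is
  observed too.
* **A5SS / A3SS**: two observed junctions sharing one end; the junction
  retaining more exonic sequence (shorter intron) is the inclusion isoform.

Per sample, PSI = 100 * inc / (inc + exc) where ``inc`` is the arithmetic
mean of the inclusion-junction counts and ``exc`` the exclusion count; the
value is NA when the denominator is below 20 reads.  Group comparison uses a
two-sided Fisher exact test on replicate-pooled counts, and events are called
Inc (dPSI > 20, P < 0.001), Skp (dPSI < -20, P < 0.001) or NC.

psiExons are Inc-called cassette exons with at least one splice site absent
from every supplied annotation source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    GenomeSequence,
    JunctionTable,
    SampleManifest,
    TranscriptModel,
)
from .splice_site_models import acceptor_window, donor_window

__all__ = [
    "SpliceEvent",
    "PsiResult",
    "PsiExonRecord",
    "build_event_catalog",
    "compute_psi",
    "fisher_event_test",
    "call_regulated_events",
    "analyze_events",
    "classify_psiexons",
]

PSI_MIN_DENOMINATOR = 20
DPSI_THRESHOLD = 20.0
P_THRESHOLD = 1e-3

Junction = tuple[int, int]  # (donor, acceptor) in internal coordinates


@dataclass
class SpliceEvent:
    event_id: str
    kind: str  # CE | A5SS | A3SS
    contig: str
    strand: str
    gene_id: str
    inclusion: list[Junction]
    exclusion: list[Junction]
    exon: tuple[int, int] | None = None  # CE target exon
    ss_annotation: dict = field(default_factory=dict)  # site -> {source: bool}
    ambiguous_gene: bool = False

    def __post_init__(self) -> None:
        if set(self.inclusion) & set(self.exclusion):
            raise ValueError(f"{self.event_id}: inclusion/exclusion overlap")
        if self.kind == "CE" and (
            len(self.inclusion) != 2 or len(self.exclusion) != 1
        ):
            raise ValueError(f"{self.event_id}: CE needs 2 inc + 1 exc junctions")
        if self.kind in ("A5SS", "A3SS") and (
            len(self.inclusion) != 1 or len(self.exclusion) != 1
        ):
            raise ValueError(f"{self.event_id}: {self.kind} needs 1 inc + 1 exc")

    def sites(self) -> dict[str, int]:
        """Splice-site coordinates of the variable exon, labelled 3ss/5ss."""
        if self.exon is None:
            return {}
        s, e = self.exon
        return {"3ss": s, "5ss": e} if self.strand == "+" else {"3ss": e, "5ss": s}


@dataclass
class PsiResult:
    event_id: str
    per_sample: dict[str, float | None]
    mean_control: float | None
    mean_treated: float | None
    basal_psi: float | None  # control-group average
    dpsi: float | None  # treated - control
    p: float | None
    call: str  # Inc | Skp | NC
    reason: str = ""
    degenerate: bool = False


@dataclass
class PsiExonRecord:
    event_id: str
    contig: str
    strand: str
    exon: tuple[int, int]
    length: int
    donor_window: str | None
    acceptor_window: str | None
    ss_annotation: dict
    basal_psi: float | None
    is_psiexon: bool


def _annotation_index(transcripts: Sequence[TranscriptModel]):
    """Exon boundary sets per annotation source, plus per-gene structures."""
    sources = sorted({t.source for t in transcripts})
    starts: dict[str, set] = {src: set() for src in sources}
    ends: dict[str, set] = {src: set() for src in sources}
    exon_ivs: dict[str, set] = {src: set() for src in sources}
    for t in transcripts:
        for s, e in t.exons:
            starts[t.source].add((t.contig, t.strand, s))
            ends[t.source].add((t.contig, t.strand, e))
            exon_ivs[t.source].add((t.contig, t.strand, s, e))
    return sources, starts, ends, exon_ivs


def annotation_status(
    event: SpliceEvent, transcripts: Sequence[TranscriptModel]
) -> dict:
    """Per-source annotated/unannotated status of the event's splice sites."""
    sources, starts, ends, _ = _annotation_index(transcripts)
    out: dict[str, dict[str, bool]] = {}
    for label, coord in event.sites().items():
        boundary = starts if (label == "3ss") == (event.strand == "+") else ends
        out[label] = {
            src: (event.contig, event.strand, coord) in boundary[src]
            for src in sources
        }
    return out


def build_event_catalog(
    junctions: JunctionTable, transcripts: Sequence[TranscriptModel]
) -> list[SpliceEvent]:
    """Discover CE / A5SS / A3SS events from observed junctions + annotation.

    Events with zero observed reads across all samples and junctions are
    dropped.  Each event records the per-source annotation status of the
    variable exon's splice sites.
    """
    observed = junctions.observed_junctions()
    obs_keys = set(
        zip(observed["contig"], observed["strand"], observed["donor"], observed["acceptor"])
    )

    def is_observed(contig, strand, d, a):
        return (contig, strand, d, a) in obs_keys or (contig, ".", d, a) in obs_keys

    # gene spans for assignment
    gene_spans: dict[str, tuple[str, str, int, int]] = {}
    for t in transcripts:
        g = gene_spans.get(t.gene_id)
        if g is None:
            gene_spans[t.gene_id] = (t.contig, t.strand, t.start, t.end)
        else:
            gene_spans[t.gene_id] = (
                g[0], g[1], min(g[2], t.start), max(g[3], t.end)
            )

    def assign_gene(contig, strand, lo, hi):
        hits = [
            gid
            for gid, (c, st, s, e) in gene_spans.items()
            if c == contig and st == strand and s <= lo and hi <= e
        ]
        if not hits:
            return "NA", False
        return hits[0], len(hits) > 1

    annotated_ends = set()
    annotated_starts = set()
    for t in transcripts:
        for s, e in t.exons:
            annotated_starts.add((t.contig, t.strand, s))
            annotated_ends.add((t.contig, t.strand, e))

    # flank pairs: annotated introns plus observed junctions linking
    # annotated exon boundaries (skip junctions of annotated cassette exons)
    flank_pairs: set[tuple[str, str, int, int]] = set()
    for t in transcripts:
        for d, a in t.introns():
            flank_pairs.add((t.contig, t.strand, d, a))
    for _, row in observed.iterrows():
        key = (row["contig"], row["strand"], row["donor"], row["acceptor"])
        for strand in ("+", "-") if row["strand"] == "." else (row["strand"],):
            if (row["contig"], strand, row["donor"]) in annotated_ends and (
                row["contig"], strand, row["acceptor"]
            ) in annotated_starts:
                flank_pairs.add((row["contig"], strand, row["donor"], row["acceptor"]))

    # observed junctions indexed by contig for interior lookup
    obs_by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in observed.iterrows():
        obs_by_contig.setdefault(row["contig"], []).append(
            (row["donor"], row["acceptor"], row["strand"])
        )

    events: list[SpliceEvent] = []
    seen: set = set()

    def add_event(kind, contig, strand, inclusion, exclusion, exon=None):
        key = (kind, contig, strand, tuple(sorted(inclusion)), tuple(sorted(exclusion)))
        if key in seen:
            return
        seen.add(key)
        lo = min(min(j) for j in inclusion + exclusion)
        hi = max(max(j) for j in inclusion + exclusion)
        gene, ambig = assign_gene(contig, strand, lo, hi)
        ev = SpliceEvent(
            event_id=f"{kind}:{contig}:{strand}:"
            + (f"{exon[0]}-{exon[1]}" if exon else f"{lo}-{hi}"),
            kind=kind,
            contig=contig,
            strand=strand,
            gene_id=gene,
            inclusion=sorted(inclusion),
            exclusion=sorted(exclusion),
            exon=exon,
            ambiguous_gene=ambig,
        )
        ev.ss_annotation = annotation_status(ev, transcripts)
        events.append(ev)

    # --- cassette exons inside each flank pair -------------------------------
    for contig, strand, d, a in sorted(flank_pairs):
        strand_ok = lambda st: st in (strand, ".")
        inner = [
            (jd, ja)
            for (jd, ja, jst) in obs_by_contig.get(contig, [])
            if strand_ok(jst)
        ]
        starts_from_d = sorted({ja for (jd, ja) in inner if jd == d and ja < a})
        ends_to_a = sorted({jd for (jd, ja) in inner if ja == a and jd > d})
        exon_annotated = {
            (s, e)
            for t in transcripts
            if t.contig == contig and t.strand == strand
            for (s, e) in t.exons
        }
        for xs in starts_from_d:
            for xe in ends_to_a:
                if xs >= xe:
                    continue
                skip_obs = is_observed(contig, strand, d, a)
                if not skip_obs and (xs, xe) not in exon_annotated:
                    continue
                add_event(
                    "CE", contig, strand,
                    inclusion=[(d, xs), (xe, a)],
                    exclusion=[(d, a)],
                    exon=(xs, xe),
                )

    # annotated cassette exons from transcript triples (covers skip-only data)
    for t in transcripts:
        for (s1, e1), (s2, e2), (s3, e3) in zip(t.exons, t.exons[1:], t.exons[2:]):
            if is_observed(t.contig, t.strand, e1, s3) or (
                is_observed(t.contig, t.strand, e1, s2)
                and is_observed(t.contig, t.strand, e2, s3)
            ):
                add_event(
                    "CE", t.contig, t.strand,
                    inclusion=[(e1, s2), (e2, s3)],
                    exclusion=[(e1, s3)],
                    exon=(s2, e2),
                )

    ce_junctions = {
        (ev.contig, j) for ev in events for j in ev.inclusion + ev.exclusion
    }

    # --- alternative 5'/3' splice sites --------------------------------------
    by_donor: dict[tuple, list[int]] = {}
    by_acceptor: dict[tuple, list[int]] = {}
    for _, row in observed.iterrows():
        st = row["strand"]
        if st == ".":
            continue
        by_donor.setdefault((row["contig"], st, row["donor"]), []).append(
            row["acceptor"]
        )
        by_acceptor.setdefault((row["contig"], st, row["acceptor"]), []).append(
            row["donor"]
        )

    for (contig, strand, d), accs in by_donor.items():
        accs = sorted(set(accs))
        for i, a1 in enumerate(accs):
            for a2 in accs[i + 1 :]:
                # skip pairs that belong to a cassette-exon triad
                if (contig, (d, a1)) in ce_junctions and (contig, (d, a2)) in ce_junctions:
                    continue
                # acceptor-side variation: shorter intron = inclusion
                kind = "A3SS" if strand == "+" else "A5SS"
                add_event(
                    kind, contig, strand,
                    inclusion=[(d, a1)], exclusion=[(d, a2)],
                )
    for (contig, strand, a), dons in by_acceptor.items():
        dons = sorted(set(dons))
        for i, d1 in enumerate(dons):
            for d2 in dons[i + 1 :]:
                if (contig, (d1, a)) in ce_junctions and (contig, (d2, a)) in ce_junctions:
                    continue
                kind = "A5SS" if strand == "+" else "A3SS"
                # larger donor coordinate = shorter intron = inclusion on '+'
                add_event(
                    kind, contig, strand,
                    inclusion=[(d2, a)], exclusion=[(d1, a)],
                )

    # drop events with zero reads everywhere
    def total_reads(ev):
        return sum(
            int(
                junctions.df[
                    (junctions.df["contig"] == ev.contig)
                    & (junctions.df["donor"] == j[0])
                    & (junctions.df["acceptor"] == j[1])
                ]["count"].sum()
            )
            for j in ev.inclusion + ev.exclusion
        )

    return [ev for ev in events if total_reads(ev) > 0]


def _support(event: SpliceEvent, junctions: JunctionTable, sample_id: str):
    inc_counts = [
        junctions.count(event.contig, d, a, sample_id) for d, a in event.inclusion
    ]
    exc = sum(
        junctions.count(event.contig, d, a, sample_id) for d, a in event.exclusion
    )
    return float(np.mean(inc_counts)), float(exc)


def compute_psi(
    event: SpliceEvent, junctions: JunctionTable, sample_id: str
) -> float | None:
    """Sample-level PSI in percent, or None (NA) when inc+exc < 20 reads.

    Inclusion support is the arithmetic mean of the inclusion-junction
    counts (two junctions for CE, one for A5SS/A3SS).
    """
    inc, exc = _support(event, junctions, sample_id)
    if inc + exc < PSI_MIN_DENOMINATOR:
        return None
    return 100.0 * inc / (inc + exc)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_event_test(
    event: SpliceEvent,
    junctions: JunctionTable,
    manifest: SampleManifest,
    group_a: str,
    group_b: str,
) -> tuple[float, bool]:
    """Two-sided Fisher exact P on replicate-pooled inclusion/exclusion counts.

    Returns ``(p, degenerate)``; a table with an all-zero row or column
    margin is degenerate and reported as P = 1.
    """
    table = []
    for group in (group_a, group_b):
        inc = exc = 0.0
        for s in manifest.samples_in(group):
            i, e = _support(event, junctions, s)
            inc += i
            exc += e
        table.append([_round_half_up(inc), _round_half_up(exc)])
    arr = np.array(table).T  # rows: inclusion/exclusion, cols: groups
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0, True
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p), False


def call_regulated_events(
    dpsi: float | None, p: float | None
) -> tuple[str, str]:
    """Inc / Skp / NC call from (dPSI, Fisher P); returns (call, reason)."""
    if dpsi is None or p is None:
        return "NC", "dpsi-undefined"
    if dpsi > DPSI_THRESHOLD and p < P_THRESHOLD:
        return "Inc", ""
    if dpsi < -DPSI_THRESHOLD and p < P_THRESHOLD:
        return "Skp", ""
    return "NC", ""


def analyze_events(
    events: Sequence[SpliceEvent],
    junctions: JunctionTable,
    manifest: SampleManifest,
    control: str,
    treated: str,
) -> list[PsiResult]:
    """Full PSI workup per event: per-sample PSI, group means, test, call."""
    out = []
    for ev in events:
        per_sample = {
            s: compute_psi(ev, junctions, s) for s in manifest.samples
        }
        ctl = [per_sample[s] for s in manifest.samples_in(control)]
        trt = [per_sample[s] for s in manifest.samples_in(treated)]
        ctl = [x for x in ctl if x is not None]
        trt = [x for x in trt if x is not None]
        mc = float(np.mean(ctl)) if ctl else None
        mt = float(np.mean(trt)) if trt else None
        dpsi = (mt - mc) if (mc is not None and mt is not None) else None
        p, degenerate = fisher_event_test(ev, junctions, manifest, control, treated)
        call, reason = call_regulated_events(dpsi, p)
        out.append(
            PsiResult(
                event_id=ev.event_id,
                per_sample=per_sample,
                mean_control=mc,
                mean_treated=mt,
                basal_psi=mc,
                dpsi=dpsi,
                p=p,
                call=call,
                reason=reason,
                degenerate=degenerate,
            )
        )
    return out


def inc_skp_ratio(results: Sequence[PsiResult]) -> float | None:
    n_inc = sum(1 for r in results if r.call == "Inc")
    n_skp = sum(1 for r in results if r.call == "Skp")
    return (n_inc / n_skp) if n_skp else None


def classify_psiexons(
    events: Sequence[SpliceEvent],
    results: Sequence[PsiResult],
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    calls: tuple[str, ...] = ("Inc",),
) -> list[PsiExonRecord]:
    """psiExon classification of called cassette exons.

    An exon is a psiExon when at least one of its splice sites is annotated
    in none of the supplied annotation sources.  The 9-mer 5'ss and 23-mer
    3'ss windows are extracted strand-aware; windows running off the contig
    are recorded as unavailable.
    """
    by_id = {r.event_id: r for r in results}
    out = []
    for ev in events:
        if ev.kind != "CE" or ev.exon is None:
            continue
        res = by_id.get(ev.event_id)
        if res is None or res.call not in calls:
            continue
        status = ev.ss_annotation or annotation_status(ev, transcripts)
        is_psi = any(
            not any(per_src.values()) for per_src in status.values()
        )
        s, e = ev.exon
        if ev.strand == "+":
            dwin = donor_window(genome, ev.contig, "+", e)
            awin = acceptor_window(genome, ev.contig, "+", s)
        else:
            dwin = donor_window(genome, ev.contig, "-", s)
            awin = acceptor_window(genome, ev.contig, "-", e)
        out.append(
            PsiExonRecord(
                event_id=ev.event_id,
                contig=ev.contig,
                strand=ev.strand,
                exon=ev.exon,
                length=e - s,
                donor_window=dwin,
                acceptor_window=awin,
                ss_annotation=status,
                basal_psi=res.basal_psi,
                is_psiexon=is_psi,
            )
        )
    return out


def psiexon_summary(records: Sequence[PsiExonRecord]) -> dict:
    """Median basal PSI and median length over psiExon records."""
    hits = [r for r in records if r.is_psiexon]
    basal = [r.basal_psi for r in hits if r.basal_psi is not None]
    return {
        "n_psiexons": len(hits),
        "median_basal_psi": float(np.median(basal)) if basal else None,
        "median_length": float(np.median([r.length for r in hits])) if hits else None,
    }


def results_table(
    events: Sequence[SpliceEvent], results: Sequence[PsiResult]
) -> pd.DataFrame:
    by_id = {r.event_id: r for r in results}
    rows = []
    for ev in events:
        r = by_id[ev.event_id]
        rows.append(
            {
                "event_id": ev.event_id,
                "kind": ev.kind,
                "contig": ev.contig,
                "strand": ev.strand,
                "gene_id": ev.gene_id,
                "exon_start": ev.exon[0] if ev.exon else None,
                "exon_end": ev.exon[1] if ev.exon else None,
                "mean_control": r.mean_control,
                "mean_treated": r.mean_treated,
                "dpsi": r.dpsi,
                "p": r.p,
                "call": r.call,
            }
        )
    return pd.DataFrame(rows)
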