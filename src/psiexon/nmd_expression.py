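"""NMD classification of included exons and host-gene expression shifts.

An NMD-psiExon is an exon whose inclusion in the mature mRNA introduces a
premature termination codon (PTC), causes a frameshift (length not divisible
by 3), or both.  Classification splices the exon into its host transcript at
its genomic position and walks codons from the annotated start; the
50-nucleotide exon-junction rule is deliberately not applied by default.

Expression context is consumed as an externally computed differential-
expression table (gene_id, log2fc, fdr, base_mean).  A Wilcoxon rank-sum
test compares the log2 fold changes of a gene set (e.g. NMD-psiExon hosts)
against all other genes, and a volcano-style classifier labels genes
up/down/NC at >1.5-fold and FDR < 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomeSequence, TranscriptModel

__all__ = [
    "NmdCall",
    "classify_nmd",
    "LfcShiftResult",
    "lfc_shift_test",
    "volcano_classify",
]

_STOPS = {"TAA", "TAG", "TGA"}

FOLD_THRESHOLD = 1.5
FDR_THRESHOLD = 0.05


@dataclass
class NmdCall:
    event_id: str
    frameshift: bool
    ptc: bool
    is_nmd: bool
    stop_position: int | None = None  # mature-mRNA offset of first introduced stop
    frame_at_insertion: int | None = None
    reason: str = ""


def _mature_position(exons: list[tuple[int, int]], strand: str, genomic: int) -> int:
    """Offset of a genomic position in the spliced transcript (transcription order)."""
    tx_exons = exons if strand == "+" else list(reversed(exons))
    off = 0
    for s, e in tx_exons:
        if s <= genomic < e:
            return off + (genomic - s if strand == "+" else e - 1 - genomic)
        off += e - s
    raise ValueError(f"genomic position {genomic} not exonic")


def _spliced(genome: GenomeSequence, contig: str, strand: str, exons) -> str:
    seq = "".join(genome.fetch(contig, s, e, "+") for s, e in sorted(exons))
    if strand == "-":
        from .core_io import revcomp

        seq = revcomp(seq)
    return seq


def _first_stop(seq: str, start: int) -> int | None:
    """Codon-start offset (relative to transcript) of first in-frame stop."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            return i
    return None


def classify_nmd(
    exon: tuple[int, int],
    transcript: TranscriptModel,
    genome: GenomeSequence,
    event_id: str = "",
) -> NmdCall:
    """NMD call for *exon* inserted into *transcript* (which must carry a CDS).

    frameshift is purely arithmetic (length mod 3 != 0).  ptc is true when
    the first stop codon reached from the annotated start either lies within
    the inserted exon or, for frameshifted insertions, occurs upstream of the
    transcript's original stop in the shifted frame.  Insertions upstream of
    the start codon (or downstream of the stop) cannot trigger NMD and return
    is_nmd = False with reason "non-coding insertion".
    """
    if transcript.cds is None:
        raise ValueError(f"{transcript.transcript_id} has no annotated CDS")
    s, e = exon
    if not any(d <= s and e <= a for d, a in transcript.introns()):
        raise ValueError(
            f"exon [{s},{e}) is not inside an intron of {transcript.transcript_id}"
        )
    exon_len = e - s
    frameshift = exon_len % 3 != 0

    new_exons = sorted(transcript.exons + [(s, e)])
    mature = _spliced(genome, transcript.contig, transcript.strand, new_exons)
    orig = _spliced(genome, transcript.contig, transcript.strand, transcript.exons)

    cs, ce = transcript.cds
    start_genomic = cs if transcript.strand == "+" else ce - 1
    start_new = _mature_position(new_exons, transcript.strand, start_genomic)
    start_orig = _mature_position(transcript.exons, transcript.strand, start_genomic)

    ins_lo = _mature_position(new_exons, transcript.strand, s if transcript.strand == "+" else e - 1)
    ins_hi = ins_lo + exon_len

    if ins_hi <= start_new:
        return NmdCall(event_id, False, False, False, reason="non-coding insertion")

    orig_stop = _first_stop(orig, start_orig)
    # positions upstream of the insertion are identical in both coordinate
    # systems, so comparing ins_lo to the original stop is well defined
    if orig_stop is not None and ins_lo >= orig_stop + 3:
        # insertion entirely downstream of the original stop codon
        return NmdCall(event_id, False, False, False, reason="non-coding insertion")

    frame_at_insertion = (ins_lo - start_new) % 3
    new_stop = _first_stop(mature, start_new)

    ptc = False
    stop_position = None
    if new_stop is not None:
        stop_iv = (new_stop, new_stop + 3)
        overlaps_exon = stop_iv[0] < ins_hi and stop_iv[1] > ins_lo
        if overlaps_exon:
            ptc = True
            stop_position = new_stop
        elif new_stop >= ins_hi and frameshift:
            # downstream stop in the shifted frame; premature iff earlier than
            # the original stop once the insertion length is removed
            if orig_stop is None or (new_stop - exon_len) < orig_stop:
                ptc = True
                stop_position = new_stop

    return NmdCall(
        event_id=event_id,
        frameshift=frameshift,
        ptc=ptc,
        is_nmd=frameshift or ptc,
        stop_position=stop_position,
        frame_at_insertion=frame_at_insertion,
    )


@dataclass
class LfcShiftResult:
    statistic: float  # rank-sum of the gene set
    p: float
    n_set: int
    n_other: int
    method: str
    cdf: pd.DataFrame  # empirical CDF per group


def lfc_shift_test(
    expression: pd.DataFrame,
    gene_set: Sequence[str],
    reference: Sequence[str] | None = None,
) -> LfcShiftResult:
    """Two-sided Wilcoxon rank-sum test of log2 fold changes, set vs rest.

    Exact null distribution when the smaller group has <= 20 genes and there
    are no ties; normal approximation with tie correction otherwise.
    """
    genes = set(expression["gene_id"])
    a_ids = [g for g in gene_set if g in genes]
    if len(a_ids) < 3:
        raise ValueError("gene set must contain >= 3 genes present in the table")
    if reference is None:
        b_ids = sorted(genes - set(a_ids))
    else:
        b_ids = [g for g in reference if g in genes and g not in set(a_ids)]
    if not b_ids:
        raise ValueError("empty complement")
    lfc = expression.set_index("gene_id")["log2fc"]
    a = lfc.loc[a_ids].to_numpy(float)
    b = lfc.loc[b_ids].to_numpy(float)

    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = min(len(a), len(b)) <= 20 and not ties
    method = "exact" if exact else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    rank_sum = float(u + len(a) * (len(a) + 1) / 2)  # W = U + n(n+1)/2

    rows = []
    for label, vals in (("set", a), ("other", b)):
        xs = np.sort(vals)
        for i, x in enumerate(xs, 1):
            rows.append({"group": label, "log2fc": float(x), "cdf": i / len(xs)})
    return LfcShiftResult(
        statistic=rank_sum,
        p=float(p),
        n_set=len(a),
        n_other=len(b),
        method=method,
        cdf=pd.DataFrame(rows),
    )


def volcano_classify(
    expression: pd.DataFrame,
    fold_threshold: float = FOLD_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Label each gene down / up / NC at the fold and FDR thresholds.

    down: fold change < 1/fold_threshold and FDR < fdr_threshold;
    up: fold change > fold_threshold and FDR < fdr_threshold.  Genes with a
    missing FDR are NC with reason recorded.
    """
    lfc_cut = math.log2(fold_threshold)
    labels, reasons = [], []
    for _, row in expression.iterrows():
        if pd.isna(row.get("fdr")):
            labels.append("NC")
            reasons.append("missing-fdr")
            continue
        sig = row["fdr"] < fdr_threshold
        if sig and row["log2fc"] < -lfc_cut:
            labels.append("down")
        elif sig and row["log2fc"] > lfc_cut:
            labels.append("up")
        else:
            labels.append("NC")
        reasons.append("")
    out = expression.copy()
    out["label"] = labels
    out["reason"] = reasons
    return out
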