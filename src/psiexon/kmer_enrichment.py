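"""k-mer enrichment between exon groups in fixed windows around the 5'ss.

For two groups of windows (e.g. Inc exons vs NC exons, at the exonic -4..-1
or intronic +1..+6 region of the 5'ss), every observed k-mer (k = 4-6) is
tested with a two-sided Fisher exact test on the 2x2 table

    [count of k-mer in group 1, all other k-mers in group 1]
    [count of k-mer in group 2, all other k-mers in group 2]

and reported as a signed significance score SS = -S * log10(P), where
S = +1 when the k-mer is relatively enriched in group 1 and -1 when
depleted.  Occurrences are counted with overlaps.  P values are reported
uncorrected: SS is a ranking score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomeSequence
from .splice_events import PsiExonRecord

__all__ = [
    "KmerEnrichment",
    "extract_ss_windows",
    "kmer_significance",
    "position_frequency_matrix",
]


@dataclass
class KmerEnrichment:
    window: str
    k: int
    kmer: str
    n1: int
    n2: int
    p: float
    sign: int
    ss: float


def extract_ss_windows(
    exons: Sequence[tuple[str, str, int, int]],
    genome: GenomeSequence,
    region: tuple[int, int] = (-4, -1),
) -> tuple[list[str], int]:
    """Window sequences around each exon's 5'ss, biological orientation.

    ``exons`` are (contig, strand, start, end) intervals; ``region`` is given
    relative to the exon/intron boundary at the 5'ss with -1 the last exonic
    base and +1 the first intronic base (no position 0).  Windows that would
    leave the contig are skipped; the skip count is returned alongside.
    """
    lo, hi = region
    if lo == 0 or hi == 0 or lo > hi:
        raise ValueError(f"bad region spec {region}")
    windows = []
    skipped = 0
    for contig, strand, start, end in exons:
        if strand == "+":
            # boundary after the half-open exon end: -1 -> end-1, +1 -> end
            a = end + (lo if lo < 0 else lo - 1)
            b = end + (hi + 1 if hi < 0 else hi)
        else:
            # mirrored around the exon start: -1 -> start, +1 -> start-1
            a = start - hi - (1 if hi < 0 else 0)
            b = (start - lo - (1 if lo < 0 else 0)) + 1
        try:
            windows.append(genome.fetch(contig, a, b, strand))
        except IndexError:
            skipped += 1
    return windows, skipped


def kmer_significance(
    group1: Sequence[str], group2: Sequence[str], k: int
) -> list[KmerEnrichment]:
    """Signed Fisher significance per observed k-mer, group 1 vs group 2.

    Windows shorter than k are skipped.  Degenerate tables (a zero margin)
    give P = 1 and SS = 0.  Results are sorted by |SS| descending.
    """
    if not (group1 and group2):
        raise ValueError("both groups must be non-empty")

    def count(windows):
        c: dict[str, int] = {}
        for w in windows:
            w = w.upper()
            for i in range(len(w) - k + 1):
                kmer = w[i : i + k]
                c[kmer] = c.get(kmer, 0) + 1
        return c

    c1, c2 = count(group1), count(group2)
    t1, t2 = sum(c1.values()), sum(c2.values())
    out = []
    for kmer in sorted(set(c1) | set(c2)):
        n1, n2 = c1.get(kmer, 0), c2.get(kmer, 0)
        table = np.array([[n1, t1 - n1], [n2, t2 - n2]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p, sign, ss = 1.0, 0, 0.0
        else:
            _, p = stats.fisher_exact(table, alternative="two-sided")
            f1, f2 = n1 / t1, n2 / t2
            sign = 1 if f1 > f2 else (-1 if f1 < f2 else 0)
            ss = -sign * math.log10(p) if sign else 0.0
        out.append(KmerEnrichment("user", k, kmer, n1, n2, float(p), sign, float(ss)))
    out.sort(key=lambda r: -abs(r.ss))
    return out


def enrichment_table(results: Sequence[KmerEnrichment], window_label: str) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "window": window_label,
                "k": r.k,
                "kmer": r.kmer,
                "n1": r.n1,
                "n2": r.n2,
                "p": r.p,
                "S": r.sign,
                "SS": r.ss,
            }
            for r in results
        ]
    )
    return df.sort_values("SS", key=lambda s: s.abs(), ascending=False).reset_index(
        drop=True
    )


def position_frequency_matrix(windows: Sequence[str]) -> pd.DataFrame:
    """Per-position base frequencies of equal-length windows (logo input)."""
    if not windows:
        raise ValueError("no windows")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise ValueError("windows must be equal length")
    counts = np.zeros((L, 4))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n = 0
    for w in windows:
        w = w.upper()
        if set(w) - set("ACGT"):
            continue
        n += 1
        for i, c in enumerate(w):
            counts[i, idx[c]] += 1
    freq = counts / max(n, 1)
    df = pd.DataFrame(freq, columns=list("ACGT"))
    df.insert(0, "pos", range(L))
    return df
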