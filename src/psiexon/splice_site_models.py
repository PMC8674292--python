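"""Splice-site strength models.

Two window geometries are scored, both in biological (sense) orientation:

* donor (5'ss): 9-mer, the last 3 exonic + first 6 intronic bases;
* acceptor (3'ss): 23-mer, the last 20 intronic + first 3 exonic bases.

Two backends are available.  ``maxent-tables`` loads the published
maximum-entropy score tables from their distributed file layout (``me2x5``
for donors, ``me2x3acc1``..``me2x3acc9`` for acceptors) and reproduces the
reference log2-odds scores; the tables are user-supplied, not bundled.
``pwm-fallback`` is a position weight matrix trained on annotated splice
sites (or any window collection) with an additive pseudocount against a
uniform 0.25 background, so the whole pipeline is testable self-contained.
Scores from both backends are log2 odds; the provenance (backend, training
source) is carried on the model and recorded in outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import GenomeSequence, TranscriptModel

__all__ = [
    "SpliceSiteModel",
    "load_maxent_tables",
    "train_pwm_fallback",
    "train_pwm",
    "score_site",
    "donor_window",
    "acceptor_window",
    "load_pwm",
    "shipped_pwm",
]

SITE_LENGTHS = {"donor9": 9, "acceptor23": 23}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}

# consensus probabilities from the reference maximum-entropy scorer:
# donor positions +1/+2 (G, T) and acceptor positions -2/-1 (A, G)
_DONOR_CONS1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0032}
_DONOR_CONS2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884}
_ACC_CONS1 = {"A": 0.9903, "C": 0.0032, "G": 0.0034, "T": 0.0030}
_ACC_CONS2 = {"A": 0.0027, "C": 0.0037, "G": 0.9905, "T": 0.0030}


def _seq_index(seq: str) -> int:
    """Base-4 index of an ACGT string (A=0, C=1, G=2, T=3)."""
    idx = 0
    for c in seq:
        idx = idx * 4 + _BASE_INDEX[c]
    return idx


@dataclass
class SpliceSiteModel:
    site_kind: str  # donor9 | acceptor23
    backend: str  # maxent-tables | pwm-fallback
    pwm: np.ndarray | None = None  # (L, 4) log2 odds, pwm-fallback only
    tables: list[np.ndarray] | None = None  # maxent-tables only
    meta: dict = field(default_factory=dict)

    @property
    def window_length(self) -> int:
        return SITE_LENGTHS[self.site_kind]

    def score(self, window: str) -> float:
        """Log2-odds score of a window; NaN when the window contains N."""
        window = window.upper()
        if len(window) != self.window_length:
            raise ValueError(
                f"{self.site_kind} expects {self.window_length}-base windows, "
                f"got {len(window)}"
            )
        bad = set(window) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in window: {sorted(bad)}")
        if "N" in window:
            return math.nan
        if self.backend == "pwm-fallback":
            return float(
                sum(self.pwm[i, _BASE_INDEX[c]] for i, c in enumerate(window))
            )
        if self.site_kind == "donor9":
            return self._score_donor_maxent(window)
        return self._score_acceptor_maxent(window)

    def _score_donor_maxent(self, w: str) -> float:
        cons = (
            _DONOR_CONS1[w[3]] * _DONOR_CONS2[w[4]] / (_BGD[w[3]] * _BGD[w[4]])
        )
        rest = w[:3] + w[5:]  # drop the GT consensus positions -> 7-mer
        return math.log2(cons * self.tables[0][_seq_index(rest)])

    def _score_acceptor_maxent(self, w: str) -> float:
        cons = (
            _ACC_CONS1[w[18]] * _ACC_CONS2[w[19]] / (_BGD[w[18]] * _BGD[w[19]])
        )
        rest = w[:18] + w[20:]  # drop the AG consensus positions -> 21-mer
        t = self.tables
        num = (
            t[0][_seq_index(rest[0:7])]
            * t[1][_seq_index(rest[7:14])]
            * t[2][_seq_index(rest[14:21])]
            * t[3][_seq_index(rest[4:11])]
            * t[4][_seq_index(rest[11:18])]
        )
        den = (
            t[5][_seq_index(rest[4:7])]
            * t[6][_seq_index(rest[7:11])]
            * t[7][_seq_index(rest[11:14])]
            * t[8][_seq_index(rest[14:18])]
        )
        return math.log2(cons * num / den)

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Serialise a PWM-fallback model with its training provenance."""
        if self.backend != "pwm-fallback":
            raise ValueError("only pwm-fallback models serialise to TSV")
        with open(path, "w") as fh:
            fh.write(f"# psiexon PWM {self.site_kind}")
            for k, v in sorted(self.meta.items()):
                fh.write(f" {k}={v}")
            fh.write("\npos\tA\tC\tG\tT\n")
            for i, row in enumerate(self.pwm):
                fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def load_pwm(path: str | os.PathLike) -> SpliceSiteModel:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# psiexon PWM"):
            raise ValueError(f"{os.fspath(path)!r} is not a psiexon PWM file")
        fields = header.split()
        site_kind = fields[3]
        meta = dict(f.split("=", 1) for f in fields[4:] if "=" in f)
        fh.readline()  # column header
        rows = [
            [float(x) for x in line.split("\t")[1:5]]
            for line in fh
            if line.strip()
        ]
    pwm = np.array(rows)
    if pwm.shape != (SITE_LENGTHS[site_kind], 4):
        raise ValueError(f"PWM shape {pwm.shape} wrong for {site_kind}")
    return SpliceSiteModel(site_kind, "pwm-fallback", pwm=pwm, meta=meta)


_MAXENT_FILES = {
    "donor9": ["me2x5"],
    "acceptor23": [f"me2x3acc{i}" for i in range(1, 10)],
}
_MAXENT_LENGTHS = {
    "me2x5": 4**7,
    "me2x3acc1": 4**7, "me2x3acc2": 4**7, "me2x3acc3": 4**7,
    "me2x3acc4": 4**7, "me2x3acc5": 4**7,
    "me2x3acc6": 4**3, "me2x3acc7": 4**4, "me2x3acc8": 4**3,
    "me2x3acc9": 4**4,
}


def load_maxent_tables(path: str | os.PathLike, site_kind: str) -> SpliceSiteModel:
    """Load published maximum-entropy tables from their distributed layout.

    ``path`` is the directory containing ``me2x5`` (donor) or
    ``me2x3acc1``..``me2x3acc9`` (acceptor); each file holds one probability
    per line.  Files may carry a trailing sequence column (as distributed);
    only the leading numeric field is used.
    """
    if site_kind not in _MAXENT_FILES:
        raise ValueError(f"unknown site_kind {site_kind!r}")
    tables = []
    for name in _MAXENT_FILES[site_kind]:
        fpath = os.path.join(os.fspath(path), name)
        if not os.path.exists(fpath):
            raise FileNotFoundError(f"missing maxent table file: {fpath}")
        vals = []
        with open(fpath) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    vals.append(float(line.split()[0]))
        if len(vals) != _MAXENT_LENGTHS[name]:
            raise ValueError(
                f"truncated maxent table {fpath}: expected "
                f"{_MAXENT_LENGTHS[name]} entries, got {len(vals)}"
            )
        tables.append(np.array(vals))
    return SpliceSiteModel(
        site_kind, "maxent-tables", tables=tables, meta={"source": os.fspath(path)}
    )


def train_pwm(
    windows: Sequence[str],
    site_kind: str,
    pseudocount: float = 1.0,
    min_sites: int = 50,
    source: str = "windows",
) -> SpliceSiteModel:
    """Train the PWM fallback from aligned windows.

    Per position: log2( (count + pseudocount) / (n + 4*pseudocount) / 0.25 ).
    """
    L = SITE_LENGTHS[site_kind]
    windows = [w.upper() for w in windows]
    if len(windows) < min_sites:
        raise ValueError(
            f"need >= {min_sites} training sites, got {len(windows)}"
        )
    for w in windows:
        if len(w) != L or set(w) - set("ACGT"):
            raise ValueError(f"bad training window {w!r}")
    counts = np.zeros((L, 4))
    for w in windows:
        for i, c in enumerate(w):
            counts[i, _BASE_INDEX[c]] += 1
    n = len(windows)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    pwm = np.log2(probs / 0.25)
    return SpliceSiteModel(
        site_kind,
        "pwm-fallback",
        pwm=pwm,
        meta={"source": source, "n": n, "pseudocount": pseudocount},
    )


def donor_window(genome: GenomeSequence, contig: str, strand: str, exon_end: int) -> str | None:
    """9-mer 5'ss window (3 exonic + 6 intronic) for an exon's donor side.

    ``exon_end`` is the half-open exon end on '+' / the exon start on '-'.
    Returns None when the window would leave the contig.
    """
    if strand == "+":
        lo, hi = exon_end - 3, exon_end + 6
    else:
        lo, hi = exon_end - 6, exon_end + 3
    if lo < 0 or hi > genome.length(contig):
        return None
    return genome.fetch(contig, lo, hi, strand)


def acceptor_window(genome: GenomeSequence, contig: str, strand: str, exon_start: int) -> str | None:
    """23-mer 3'ss window (20 intronic + 3 exonic) for an exon's acceptor side.

    ``exon_start`` is the exon start on '+' / the half-open exon end on '-'.
    """
    if strand == "+":
        lo, hi = exon_start - 20, exon_start + 3
    else:
        lo, hi = exon_start - 3, exon_start + 20
    if lo < 0 or hi > genome.length(contig):
        return None
    return genome.fetch(contig, lo, hi, strand)


def train_pwm_fallback(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    site_kind: str,
    pseudocount: float = 1.0,
    min_sites: int = 50,
) -> SpliceSiteModel:
    """Train the PWM fallback on annotated splice sites of *transcripts*."""
    windows = []
    for t in transcripts:
        exons = t.exons if t.strand == "+" else list(reversed(t.exons))
        for i, (s, e) in enumerate(exons):
            last = i == len(exons) - 1
            first = i == 0
            if site_kind == "donor9" and not last:
                w = donor_window(genome, t.contig, t.strand, e if t.strand == "+" else s)
                if w and "N" not in w:
                    windows.append(w)
            if site_kind == "acceptor23" and not first:
                w = acceptor_window(genome, t.contig, t.strand, s if t.strand == "+" else e)
                if w and "N" not in w:
                    windows.append(w)
    return train_pwm(
        windows, site_kind, pseudocount, min_sites, source="annotated-sites"
    )


def score_site(model: SpliceSiteModel, window: str) -> float:
    """Score one window with *model* (thin functional wrapper)."""
    return model.score(window)


# Default PWM probabilities for fully self-contained runs (synthetic priors
# shaped like canonical metazoan splice sites: GT..AG consensus flanked by a
# pyrimidine-rich tract on the acceptor side).  These are NOT trained on any
# genome; they exist so that simulation and testing need no external tables.
_DEFAULT_ACCEPTOR_PROBS = (
    [(0.08, 0.42, 0.08, 0.42)] * 18  # intronic polypyrimidine tract
    + [(0.95, 0.02, 0.01, 0.02)]  # -2: A
    + [(0.01, 0.02, 0.95, 0.02)]  # -1: G
    + [(0.30, 0.25, 0.25, 0.20)] * 3  # first exonic bases
)
_DEFAULT_DONOR_PROBS = (
    [(0.35, 0.30, 0.20, 0.15)] * 2  # exonic -3, -2
    + [(0.10, 0.05, 0.80, 0.05)]  # exonic -1: G-biased
    + [(0.02, 0.02, 0.94, 0.02)]  # +1: G
    + [(0.02, 0.02, 0.02, 0.94)]  # +2: T
    + [(0.60, 0.10, 0.15, 0.15)]  # +3
    + [(0.70, 0.10, 0.10, 0.10)]  # +4
    + [(0.10, 0.10, 0.70, 0.10)]  # +5
    + [(0.15, 0.15, 0.20, 0.50)]  # +6
)


def shipped_pwm(site_kind: str) -> SpliceSiteModel:
    """The bundled synthetic PWM for donor9 / acceptor23 windows."""
    probs = {
        "acceptor23": _DEFAULT_ACCEPTOR_PROBS,
        "donor9": _DEFAULT_DONOR_PROBS,
    }[site_kind]
    pwm = np.log2(np.array(probs) / 0.25)
    return SpliceSiteModel(
        site_kind, "pwm-fallback", pwm=pwm, meta={"source": "shipped-synthetic"}
    )
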