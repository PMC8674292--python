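"""Genome, annotation and junction-table IO.

All coordinates are 0-based half-open internally.  The 1-based inclusive
dialects (GTF, spliced-aligner junction tabs) are converted at the boundary
so that downstream modules never see mixed conventions.

A splice junction is keyed by ``(contig, donor, acceptor, strand)`` where
``donor`` is the genomic coordinate of the first intronic base and
``acceptor`` is one past the last intronic base, i.e. the intron occupies
``[donor, acceptor)`` regardless of strand.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "IntronRecord",
    "JunctionTable",
    "SampleManifest",
    "read_genome",
    "read_annotation",
    "derive_introns",
    "read_junctions",
    "read_manifest",
    "write_gtf",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALLOWED = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: contig name -> upper-case ACGTN string.

    ``fetch`` returns the reverse complement for strand ``'-'`` so callers
    always receive sequence in biological (sense) orientation.
    """

    def __init__(self, contigs: Mapping[str, str]):
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _ALLOWED
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"contig {name!r} has non-ACGTN character "
                    f"{seq[pos]!r} at position {pos}"
                )
            clean[name] = seq
        self.contigs = clean

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on *contig*; reverse-complemented on '-'."""
        if start < 0 or end > len(self.contigs[contig]) or start > end:
            raise IndexError(
                f"window [{start}, {end}) outside contig {contig!r} "
                f"of length {len(self.contigs[contig])}"
            )
        seq = self.contigs[contig][start:end]
        return revcomp(seq) if strand == "-" else seq

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class TranscriptModel:
    """A transcript: ordered, disjoint exons plus an optional CDS span."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    source: str = "."

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        if self.cds is not None:
            cs, ce = self.cds
            if not any(s <= cs < e for s, e in self.exons) or not any(
                s < ce <= e for s, e in self.exons
            ):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{cs},{ce}) outside exons"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_sequence(self, genome: GenomeSequence) -> str:
        """Mature (spliced) transcript sequence in biological orientation."""
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a gene; ordinal counts in transcription order (1-based)."""

    intron_id: str
    gene_id: str
    contig: str
    strand: str
    donor: int  # first intronic base
    acceptor: int  # one past last intronic base
    ordinal: int

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(f"{self.intron_id}: donor >= acceptor")


JUNCTION_COLUMNS = ["contig", "donor", "acceptor", "strand", "sample_id", "count"]


class JunctionTable:
    """Per-sample spliced-junction read counts.

    Backed by a pandas DataFrame with columns
    ``contig, donor, acceptor, strand, sample_id, count``; one row per
    (junction, sample) pair.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(JUNCTION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"junction table missing columns: {sorted(missing)}")
        df = df[JUNCTION_COLUMNS].copy()
        df["donor"] = df["donor"].astype(int)
        df["acceptor"] = df["acceptor"].astype(int)
        df["count"] = df["count"].astype(int)
        if (df["count"] < 0).any():
            raise ValueError("negative junction read counts")
        if (df["donor"] >= df["acceptor"]).any():
            bad = df[df["donor"] >= df["acceptor"]].iloc[0]
            raise ValueError(
                f"acceptor <= donor at {bad['contig']}:{bad['donor']}-{bad['acceptor']}"
            )
        key = ["contig", "donor", "acceptor", "strand", "sample_id"]
        dup = df.duplicated(subset=key)
        if dup.any():
            bad = df[dup].iloc[0]
            raise ValueError(
                "duplicate (junction, sample) row: "
                f"{bad['contig']}:{bad['donor']}-{bad['acceptor']}/{bad['sample_id']}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def count(
        self, contig: str, donor: int, acceptor: int, sample_id: str
    ) -> int:
        df = self.df
        sel = (
            (df["contig"] == contig)
            & (df["donor"] == donor)
            & (df["acceptor"] == acceptor)
            & (df["sample_id"] == sample_id)
        )
        return int(df.loc[sel, "count"].sum())

    def observed_junctions(self) -> pd.DataFrame:
        """Unique junctions with total counts across samples (count > 0)."""
        g = (
            self.df.groupby(["contig", "donor", "acceptor", "strand"], as_index=False)[
                "count"
            ]
            .sum()
        )
        return g[g["count"] > 0].reset_index(drop=True)

    def resolve_strands(self, introns: Sequence[IntronRecord]) -> "JunctionTable":
        """Assign gene strand to '.'-strand junctions by unique intron containment.

        Junctions contained in introns of genes on both strands (ambiguous) or
        in no gene are dropped; the number dropped is recorded in
        ``self.n_strand_dropped`` of the returned table.
        """
        spans: list[tuple[str, int, int, str]] = [
            (i.contig, i.donor, i.acceptor, i.strand) for i in introns
        ]
        rows = []
        dropped = 0
        for _, row in self.df.iterrows():
            if row["strand"] in ("+", "-"):
                rows.append(row)
                continue
            hits = {
                st
                for (c, s, e, st) in spans
                if c == row["contig"] and s <= row["donor"] and row["acceptor"] <= e
            }
            if len(hits) == 1:
                row = row.copy()
                row["strand"] = hits.pop()
                rows.append(row)
            else:
                dropped += 1
        out = JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS))
        out.n_strand_dropped = dropped
        return out

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "JunctionTable":
        return cls(pd.read_csv(path, sep="\t"))


class SampleManifest:
    """Maps sample_id -> (group, replicate)."""

    def __init__(self, df: pd.DataFrame):
        for col in ("sample_id", "group", "replicate"):
            if col not in df.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in manifest")
        self.df = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.df["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.df[self.df["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in manifest")
        return str(row["group"].iloc[0])

    def samples_in(self, group: str) -> list[str]:
        return list(self.df.loc[self.df["group"] == group, "sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _open_text(path: str | os.PathLike):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_genome(path: str | os.PathLike) -> GenomeSequence:
    """Load a (possibly gzipped) FASTA into a :class:`GenomeSequence`.

    Contig names are the first whitespace-delimited token of the header.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig name {rec.id!r}")
            contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise ValueError(f"no FASTA records in {os.fspath(path)!r}")
    return GenomeSequence(contigs)


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    return SampleManifest(pd.read_csv(path, sep="\t"))


def _read_gxf(path, dialect, source):
    import gffutils

    db = gffutils.create_db(
        os.fspath(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, contig, strand)

    def tx_of(feat):
        if "transcript_id" in feat.attributes:
            return feat.attributes["transcript_id"][0]
        if "Parent" in feat.attributes:
            return feat.attributes["Parent"][0]
        raise ValueError(f"feature without transcript_id/Parent: {feat}")

    def gene_of(feat, tx):
        if "gene_id" in feat.attributes:
            return feat.attributes["gene_id"][0]
        # GFF3: walk to the transcript feature's Parent
        try:
            parent = db[tx]
            if "Parent" in parent.attributes:
                return parent.attributes["Parent"][0]
        except Exception:
            pass
        return tx

    for feat in db.features_of_type(("exon", "CDS")):
        tx = tx_of(feat)
        iv = (feat.start - 1, feat.end)  # GTF/GFF3 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            exons.setdefault(tx, []).append(iv)
        else:
            cds.setdefault(tx, []).append(iv)
        meta.setdefault(tx, (gene_of(feat, tx), feat.seqid, feat.strand))

    out = []
    for tx, ex in exons.items():
        gene, contig, strand = meta[tx]
        cspan = None
        if tx in cds:
            blocks = sorted(cds[tx])
            cspan = (blocks[0][0], blocks[-1][1])
        out.append(
            TranscriptModel(
                gene_id=gene,
                transcript_id=tx,
                contig=contig,
                strand=strand,
                exons=ex,
                cds=cspan,
                source=source,
            )
        )
    return out


def _read_bed12(path, source):
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"line {lineno}: BED12 needs 12 columns")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n or len(starts) != n:
                raise ValueError(f"line {lineno}: blockCount mismatch")
            ex = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
            cspan = (thick_start, thick_end) if thick_end > thick_start else None
            out.append(
                TranscriptModel(
                    gene_id=name,
                    transcript_id=name,
                    contig=chrom,
                    strand=strand,
                    exons=ex,
                    cds=cspan,
                    source=source,
                )
            )
    return out


def read_annotation(
    path: str | os.PathLike, dialect: str = "gtf", source: str | None = None
) -> list[TranscriptModel]:
    """Parse GTF / GFF3 / BED12 into transcript models (0-based half-open).

    ``source`` tags every transcript with the annotation-set name so that
    multiple annotation files can be distinguished downstream (annotation
    status of splice sites is reported per source).
    """
    dialect = dialect.lower()
    if source is None:
        source = os.path.basename(os.fspath(path))
    if dialect in ("gtf", "gff3", "gff"):
        return _read_gxf(path, dialect, source)
    if dialect == "bed12":
        return _read_bed12(path, source)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcript models as GTF 2.2 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                "\t".join(
                    [
                        t.contig, "psiexon", "transcript",
                        str(t.start + 1), str(t.end), ".", t.strand, ".", attrs,
                    ]
                )
                + "\n"
            )
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.contig, "psiexon", "exon", str(s + 1), str(e), ".",
                         t.strand, ".", attrs]
                    )
                    + "\n"
                )
            if t.cds is not None:
                cs, ce = t.cds
                for s, e in t.exons:
                    lo, hi = max(s, cs), min(e, ce)
                    if lo < hi:
                        fh.write(
                            "\t".join(
                                [t.contig, "psiexon", "CDS", str(lo + 1), str(hi),
                                 ".", t.strand, "0", attrs]
                            )
                            + "\n"
                        )


def derive_introns(
    transcripts: Sequence[TranscriptModel], union: bool = True
) -> list[IntronRecord]:
    """Introns between consecutive exons of each transcript.

    With ``union=True`` identical introns shared by transcripts of the same
    gene collapse to one record; ordinals are assigned in transcription order
    (strand-aware), per gene in union mode and per transcript otherwise.
    """
    out: list[IntronRecord] = []
    if union:
        by_gene: dict[str, dict] = {}
        for t in transcripts:
            g = by_gene.setdefault(
                t.gene_id, {"contig": t.contig, "strand": t.strand, "introns": set()}
            )
            g["introns"].update(t.introns())
        for gene_id, g in by_gene.items():
            ivs = sorted(g["introns"], reverse=(g["strand"] == "-"))
            for i, (d, a) in enumerate(ivs, 1):
                out.append(
                    IntronRecord(
                        intron_id=f"{gene_id}.I{i}",
                        gene_id=gene_id,
                        contig=g["contig"],
                        strand=g["strand"],
                        donor=d,
                        acceptor=a,
                        ordinal=i,
                    )
                )
    else:
        for t in transcripts:
            ivs = sorted(t.introns(), reverse=(t.strand == "-"))
            for i, (d, a) in enumerate(ivs, 1):
                out.append(
                    IntronRecord(
                        intron_id=f"{t.transcript_id}.I{i}",
                        gene_id=t.gene_id,
                        contig=t.contig,
                        strand=t.strand,
                        donor=d,
                        acceptor=a,
                        ordinal=i,
                    )
                )
    return out


# spliced-aligner junction tab: contig, intron start (1-based), intron end
# (1-based inclusive), strand code (0 undefined / 1 '+' / 2 '-'), motif,
# annotated, unique reads, multi reads, max overhang
_STRAND_CODE = {"0": ".", "1": "+", "2": "-"}


def read_junctions(
    path: str | os.PathLike,
    dialect: str = "aligner",
    sample_id: str | None = None,
) -> JunctionTable:
    """Read a junction table.

    ``aligner`` dialect is the 9-column spliced-aligner tab (one sample per
    file; ``sample_id`` required); ``generic`` is a 6-column TSV with header
    ``contig donor acceptor strand sample_id count`` already in internal
    coordinates.
    """
    if dialect == "generic":
        return JunctionTable.from_tsv(path)
    if dialect != "aligner":
        raise ValueError(f"unknown junction dialect {dialect!r}")
    if sample_id is None:
        raise ValueError("aligner dialect requires sample_id")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"line {lineno}: expected >=7 columns")
            contig = f[0]
            donor = int(f[1]) - 1  # first intronic base, 1-based -> 0-based
            acceptor = int(f[2])  # last intronic base 1-based == half-open end
            strand = _STRAND_CODE.get(f[3], ".")
            count = int(f[6])
            rows.append((contig, donor, acceptor, strand, sample_id, count))
    return JunctionTable(pd.DataFrame(rows, columns=JUNCTION_COLUMNS))
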