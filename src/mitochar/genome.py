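"""Circular-genome data model, annotation I/O and gene-organization accounting.

Coordinates are 1-based inclusive throughout, as in standard organelle
annotation tables.  A feature whose start exceeds its stop wraps through the
sequence origin (runs ``start..L`` then ``1..stop``).  Printed "length" columns
in annotation tables are treated as checksums: lengths are always recomputed
from coordinates.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneClass",
    "GeneFeature",
    "CircularGenome",
    "OrganizationRow",
    "OrganizationReport",
    "AnnotationError",
    "read_annotation_table",
    "write_annotation_table",
    "feature_length",
    "intergenic_nt",
    "organization_report",
    "pcg_union_length",
    "read_fasta",
    "write_fasta",
    "write_organization_tsv",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation rows or inconsistent coordinates."""


class GeneClass(str, enum.Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"


def _infer_class(name: str) -> GeneClass:
    low = name.lower()
    if low.startswith("trn"):
        return GeneClass.TRNA
    if low.startswith("rrn"):
        return GeneClass.RRNA
    if low.startswith(("control", "d-loop", "dloop", "d_loop")):
        return GeneClass.CONTROL
    return GeneClass.PCG


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: 1-based inclusive coordinates on the circle."""

    name: str
    start: int
    stop: int
    strand: str  # "+" (heavy) or "-" (light)
    gene_class: GeneClass
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.name}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start < 1 or self.stop < 1:
            raise AnnotationError(
                f"{self.name}: coordinates must be >= 1 "
                f"(start={self.start}, stop={self.stop})"
            )
        if not self.wraps and self.start > self.stop:
            raise AnnotationError(
                f"{self.name}: start {self.start} > stop {self.stop} "
                "for a non-wrapping feature"
            )

    def length(self, genome_length: int) -> int:
        return feature_length(self, genome_length)

    def validate_against(self, genome_length: int) -> None:
        if self.start > genome_length or self.stop > genome_length:
            raise AnnotationError(
                f"{self.name}: coordinate out of [1, {genome_length}] "
                f"(start={self.start}, stop={self.stop})"
            )


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Span of a feature in bp, wrap-aware on a circle of ``genome_length``."""
    f.validate_against(genome_length)
    if f.wraps:
        return (genome_length - f.start + 1) + f.stop
    return f.stop - f.start + 1


def intergenic_nt(prev: GeneFeature, nxt: GeneFeature) -> int:
    """Signed spacing between consecutive features: negative means overlap."""
    return nxt.start - prev.stop - 1


@dataclass
class CircularGenome:
    """A circular nucleotide sequence plus its ordered gene features."""

    seq: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)
        starts = [f.start for f in self.features]
        if len(set(starts)) != len(starts):
            raise AnnotationError("duplicate feature start coordinates")
        self.features = sorted(self.features, key=lambda f: f.start)
        for f in self.features:
            f.validate_against(self.length)

    @property
    def length(self) -> int:
        return len(self.seq)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def features_of_class(self, gene_class: GeneClass) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_class == gene_class]


_VALID_BASES = set("ACGTN")


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T; reject characters outside {A,C,G,T,N}."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return out


# ---------------------------------------------------------------------------
# annotation table I/O


def _parse_strand(tok: str) -> str:
    # tolerate the unicode minus some tables print
    if tok in ("+", "H", "h"):
        return "+"
    if tok in ("-", "−", "L", "l"):
        return "-"
    raise AnnotationError(f"unrecognized strand token {tok!r}")


def read_annotation_table(
    path: str | Path | io.TextIOBase, genome_length: int
) -> list[GeneFeature]:
    """Read a gene-annotation TSV into features sorted by start.

    Expected columns (header-driven): ``name``, ``start``, ``stop``,
    ``strand`` and optionally ``class``.  Extra columns (e.g. a printed
    length) are ignored — lengths are recomputed from coordinates.
    ``#`` lines are comments.  A row whose start exceeds its stop is taken
    to wrap through the origin.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()

    rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise AnnotationError("empty annotation table")
    header = [h.strip().lower() for h in rows[0].split("\t")]
    required = ("name", "start", "stop", "strand")
    for col in required:
        if col not in header:
            raise AnnotationError(f"missing required column {col!r}")
    idx = {col: header.index(col) for col in header}

    features: list[GeneFeature] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(rows[1:], start=2):
        toks = [t.strip() for t in ln.split("\t")]
        try:
            name = toks[idx["name"]].strip("*")
            start = int(toks[idx["start"]].replace(",", ""))
            stop = int(toks[idx["stop"]].replace(",", ""))
            strand = _parse_strand(toks[idx["strand"]])
        except (IndexError, ValueError) as exc:
            raise AnnotationError(f"line {lineno}: malformed row: {ln!r}") from exc
        if name in seen:
            raise AnnotationError(f"line {lineno}: duplicate gene name {name!r}")
        seen.add(name)
        if not (1 <= start <= genome_length) or not (1 <= stop <= genome_length):
            raise AnnotationError(
                f"line {lineno}: {name}: coordinate out of [1, {genome_length}]"
            )
        if "class" in idx and len(toks) > idx["class"] and toks[idx["class"]]:
            gene_class = GeneClass(toks[idx["class"]])
        else:
            gene_class = _infer_class(name)
        features.append(
            GeneFeature(
                name=name,
                start=start,
                stop=stop,
                strand=strand,
                gene_class=gene_class,
                wraps=start > stop,
            )
        )
    features.sort(key=lambda f: f.start)
    return features


def write_annotation_table(features: Sequence[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tstop\tstrand\tclass\n")
        for f in sorted(features, key=lambda x: x.start):
            fh.write(
                f"{f.name}\t{f.start}\t{f.stop}\t{f.strand}\t{f.gene_class.value}\n"
            )


# ---------------------------------------------------------------------------
# FASTA I/O (single circular record)


def read_fasta(path: str | Path) -> str:
    """Read a single-record FASTA; uppercased, U normalized to T."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    return normalize_sequence(str(records[0].seq))


def write_fasta(seq: str, path: str | Path, name: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# organization accounting


@dataclass(frozen=True)
class OrganizationRow:
    name: str
    start: int
    stop: int
    strand: str
    gene_class: GeneClass
    length: int
    intergenic_nt: int | None  # spacing to the PREVIOUS listed gene; None for first row


@dataclass
class OrganizationReport:
    rows: list[OrganizationRow]
    overlap_count: int
    overlap_total_bp: int
    overlap_max_bp: int
    spacer_count: int
    spacer_total_bp: int
    spacer_max_bp: int
    h_strand_gene_count: int
    l_strand_gene_count: int
    gene_count: int


def organization_report(
    genome_or_features: CircularGenome | Sequence[GeneFeature],
    genome_length: int | None = None,
) -> OrganizationReport:
    """Spacer/overlap census and strand counts over consecutive gene pairs.

    Control-class features are excluded from the pairwise walk (annotation
    tables list genes only); the circuit-closure pair (last gene back to the
    first, across the origin) is included only when no control feature fills
    that gap.
    """
    if isinstance(genome_or_features, CircularGenome):
        features = genome_or_features.features
        genome_length = genome_or_features.length
    else:
        features = sorted(genome_or_features, key=lambda f: f.start)
    genes = [f for f in features if f.gene_class != GeneClass.CONTROL]
    has_control = any(f.gene_class == GeneClass.CONTROL for f in features)
    if len(genes) < 2:
        raise ValueError("need at least two non-control features")

    spacings: list[int | None] = [None]
    for prev, nxt in zip(genes, genes[1:]):
        spacings.append(intergenic_nt(prev, nxt))
    if not has_control:
        if genome_length is None:
            raise ValueError("genome_length required when no control feature closes the circle")
        closure = (genes[0].start - 1) + (genome_length - genes[-1].stop)
        spacings[0] = closure

    if genome_length is None:
        genome_length = max(f.stop for f in genes)

    rows = [
        OrganizationRow(
            name=f.name,
            start=f.start,
            stop=f.stop,
            strand=f.strand,
            gene_class=f.gene_class,
            length=feature_length(f, genome_length),
            intergenic_nt=s,
        )
        for f, s in zip(genes, spacings)
    ]
    gaps = [s for s in spacings if s is not None]
    overlaps = [-s for s in gaps if s < 0]
    spacers = [s for s in gaps if s > 0]
    return OrganizationReport(
        rows=rows,
        overlap_count=len(overlaps),
        overlap_total_bp=sum(overlaps),
        overlap_max_bp=max(overlaps, default=0),
        spacer_count=len(spacers),
        spacer_total_bp=sum(spacers),
        spacer_max_bp=max(spacers, default=0),
        h_strand_gene_count=sum(1 for f in genes if f.strand == "+"),
        l_strand_gene_count=sum(1 for f in genes if f.strand == "-"),
        gene_count=len(genes),
    )


def _unrolled_intervals(
    features: Iterable[GeneFeature], genome_length: int
) -> list[tuple[int, int]]:
    """0-based half-open intervals; wrapping features split into two pieces."""
    out = []
    for f in features:
        if f.wraps:
            out.append((f.start - 1, genome_length))
            out.append((0, f.stop))
        else:
            out.append((f.start - 1, f.stop))
    return out


def pcg_union_length(
    genome_or_features: CircularGenome | Sequence[GeneFeature],
    genome_length: int | None = None,
) -> int:
    """Size of the positional union of all protein-coding gene intervals.

    Positions covered by two overlapping PCGs count once, so the union can be
    smaller than the sum of PCG lengths.
    """
    if isinstance(genome_or_features, CircularGenome):
        features = genome_or_features.features
        genome_length = genome_or_features.length
    else:
        features = list(genome_or_features)
        if genome_length is None:
            raise ValueError("genome_length required")
    pcgs = [f for f in features if f.gene_class == GeneClass.PCG]
    if not pcgs:
        raise ValueError("no protein-coding features")
    intervals = sorted(_unrolled_intervals(pcgs, genome_length))
    total = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
    total += cur_end - cur_start
    return min(total, genome_length)


def write_organization_tsv(report: OrganizationReport, path: str | Path) -> None:
    """Emit the per-gene table plus a summary block of the census numbers."""
    with open(path, "w") as fh:
        fh.write("name\tstart\tstop\tstrand\tclass\tlength\tintergenic_nt\n")
        for r in report.rows:
            gap = "" if r.intergenic_nt is None else str(r.intergenic_nt)
            fh.write(
                f"{r.name}\t{r.start}\t{r.stop}\t{r.strand}\t"
                f"{r.gene_class.value}\t{r.length}\t{gap}\n"
            )
        fh.write("# summary\n")
        fh.write(f"# gene_count\t{report.gene_count}\n")
        fh.write(
            f"# overlaps\tcount={report.overlap_count}\t"
            f"total_bp={report.overlap_total_bp}\tmax_bp={report.overlap_max_bp}\n"
        )
        fh.write(
            f"# spacers\tcount={report.spacer_count}\t"
            f"total_bp={report.spacer_total_bp}\tmax_bp={report.spacer_max_bp}\n"
        )
        fh.write(
            f"# strands\tH={report.h_strand_gene_count}\t"
            f"L={report.l_strand_gene_count}\n"
        )
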