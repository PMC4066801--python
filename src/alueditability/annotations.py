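"""Repeat and gene-model annotation I/O.

All coordinates are 0-based half-open internally; dialect conversion happens
only at the file boundary.  Only Alu/FLAM records are retained from repeat
annotations, since those are the elements whose double-stranded pairing drives
A-to-I editing.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

FAMILY_PREFIXES = ("AluJ", "AluS", "AluY", "FLAM")
REPEAT_DIALECTS = ("rmsk_out", "ucsc_rmsk", "bed6")
GENE_DIALECTS = ("refflat", "bed12")


class AnnotationError(ValueError):
    """Raised for unparseable or inconsistent annotation input."""


def parse_family(name: str) -> str:
    """Map a RepeatMasker repeat name to its family label.

    Longest matching prefix among AluJ/AluS/AluY/FLAM; anything else is
    "other" (callers normally filter those out earlier).
    """
    if not name:
        raise AnnotationError("empty repeat name")
    best = ""
    for prefix in FAMILY_PREFIXES:
        if name.startswith(prefix) and len(prefix) > len(best):
            best = prefix
    return best or "other"


@dataclass(frozen=True)
class RepeatElement:
    """One annotated repeat element (the unit of the whole analysis)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    family: str = field(default="")

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start},{self.end}) for {self.id}"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"invalid strand {self.strand!r} for {self.id}")
        if not self.family:
            object.__setattr__(self, "family", parse_family(self.name))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple  # sorted, merged (start, end) half-open intervals

    def __post_init__(self):
        if not (0 <= self.tx_start < self.tx_end):
            raise AnnotationError(f"invalid transcript span for {self.gene_id}")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise AnnotationError(
                    f"exon [{s},{e}) outside transcript bounds of {self.gene_id}"
                )
            if s < prev_end:
                raise AnnotationError(f"unsorted/overlapping exons in {self.gene_id}")
            prev_end = e

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class GenicAlu:
    """An Alu contained in a gene, with its expressed strand class.

    polyA: the annotated (consensus) strand of the repeat is the one
    transcribed; polyU: the reverse complement is transcribed, so the
    poly-A tracts appear as poly-U in the mRNA.
    """

    element: RepeatElement
    gene_id: str
    gene_strand: str
    expressed_strand_class: str  # "polyA" | "polyU"


def _is_alu_like(name: str) -> bool:
    return name.startswith("Alu") or name.startswith("FLAM")


def _unique_ids(records):
    seen = {}
    out = []
    for rec in records:
        base = rec.id
        if base in seen:
            seen[base] += 1
            rec = RepeatElement(
                f"{base}#{seen[base]}", rec.chrom, rec.start, rec.end,
                rec.strand, rec.name,
            )
        else:
            seen[base] = 0
        out.append(rec)
    return out


def read_repeat_annotations(path, dialect: str) -> list[RepeatElement]:
    """Read repeat annotations, returning Alu/FLAM elements only.

    Dialects: ``rmsk_out`` (RepeatMasker .out, 1-based inclusive, 3 header
    lines, strand 'C' = minus), ``ucsc_rmsk`` (header TSV with
    genoName/genoStart/genoEnd/strand/repName, 0-based half-open), ``bed6``.
    """
    path = Path(path)
    if dialect not in REPEAT_DIALECTS:
        raise AnnotationError(f"unknown repeat dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[RepeatElement] = []
    if dialect == "rmsk_out":
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                if lineno <= 3 or not line.strip():
                    continue
                fields = line.split()
                try:
                    chrom = fields[4]
                    begin = int(fields[5])  # 1-based inclusive
                    end = int(fields[6])
                    strand = "-" if fields[8] in ("C", "-") else "+"
                    name = fields[9]
                except (IndexError, ValueError) as exc:
                    raise AnnotationError(
                        f"{path}: unparseable rmsk_out line {lineno}"
                    ) from exc
                if not _is_alu_like(name):
                    continue
                start = begin - 1
                records.append(
                    RepeatElement(
                        f"{chrom}:{start}-{end}:{strand}:{name}",
                        chrom, start, end, strand, name,
                    )
                )
    elif dialect == "ucsc_rmsk":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise AnnotationError(f"{path}: cannot parse ucsc_rmsk table") from exc
        needed = {"genoName", "genoStart", "genoEnd", "strand", "repName"}
        if not needed.issubset(df.columns):
            raise AnnotationError(
                f"{path}: ucsc_rmsk table missing columns {sorted(needed - set(df.columns))}"
            )
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            name = str(getattr(row, "repName"))
            if not _is_alu_like(name):
                continue
            chrom = str(getattr(row, "genoName"))
            try:
                start = int(getattr(row, "genoStart"))
                end = int(getattr(row, "genoEnd"))
            except (TypeError, ValueError) as exc:
                raise AnnotationError(f"{path}: unparseable line {lineno}") from exc
            strand = "-" if str(getattr(row, "strand")) in ("C", "-") else "+"
            records.append(
                RepeatElement(
                    f"{chrom}:{start}-{end}:{strand}:{name}",
                    chrom, start, end, strand, name,
                )
            )
    else:  # bed6
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise AnnotationError(f"{path}: short bed6 line {lineno}")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name, strand = fields[3], fields[5]
                except ValueError as exc:
                    raise AnnotationError(f"{path}: unparseable line {lineno}") from exc
                if strand not in "+-":
                    raise AnnotationError(f"{path}: bad strand on line {lineno}")
                if not _is_alu_like(name):
                    continue
                records.append(
                    RepeatElement(
                        f"{chrom}:{start}-{end}:{strand}:{name}",
                        chrom, start, end, strand, name,
                    )
                )
    return _unique_ids(records)


def write_repeats_bed(repeats: Iterable[RepeatElement], path,
                      genic: dict[str, str] | None = None) -> None:
    """Write elements as BED6+2 (family and gene_id appended)."""
    genic = genic or {}
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}"
                f"\t{r.family}\t{genic.get(r.id, '.')}\n"
            )


def _merge_exons(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def read_gene_models(path, dialect: str) -> list[GeneModel]:
    """Read gene models from refFlat or BED12. Exons are sorted and merged."""
    path = Path(path)
    if dialect not in GENE_DIALECTS:
        raise AnnotationError(f"unknown gene dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    genes: list[GeneModel] = []
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "refflat":
                    gene_id = fields[1] if fields[1] else fields[0]
                    chrom, strand = fields[2], fields[3]
                    tx_start, tx_end = int(fields[4]), int(fields[5])
                    starts = [int(x) for x in fields[9].rstrip(",").split(",")]
                    ends = [int(x) for x in fields[10].rstrip(",").split(",")]
                    exons = list(zip(starts, ends))
                else:  # bed12
                    chrom = fields[0]
                    tx_start, tx_end = int(fields[1]), int(fields[2])
                    gene_id, strand = fields[3], fields[5]
                    nblocks = int(fields[9])
                    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                    offs = [int(x) for x in fields[11].rstrip(",").split(",")]
                    if len(sizes) != nblocks or len(offs) != nblocks:
                        raise AnnotationError(
                            f"{path}: block count mismatch on line {lineno}"
                        )
                    exons = [(tx_start + o, tx_start + o + s)
                             for o, s in zip(offs, sizes)]
            except (IndexError, ValueError) as exc:
                raise AnnotationError(f"{path}: unparseable line {lineno}") from exc
            for s, e in exons:
                if s < tx_start or e > tx_end:
                    raise AnnotationError(
                        f"{path}: exon [{s},{e}) outside transcript on line {lineno}"
                    )
            genes.append(
                GeneModel(gene_id, chrom, strand, tx_start, tx_end,
                          _merge_exons(exons))
            )
    return genes


def select_genic_alus(repeats: Sequence[RepeatElement],
                      genes: Sequence[GeneModel]) -> list[GenicAlu]:
    """Keep repeats fully contained in a gene's transcript span.

    If several genes contain an element, the one with the smallest span wins
    (ties by gene_id).  Reads are attributed to the gene strand, so the
    expressed strand class is polyA when the repeat's annotation strand
    matches the gene strand and polyU otherwise.
    """
    trees: dict[str, IntervalTree] = {}
    by_id = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.tx_start, g.tx_end, g.gene_id)
        by_id[g.gene_id] = g

    out: list[GenicAlu] = []
    for r in repeats:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        containing = [
            by_id[iv.data]
            for iv in tree.overlap(r.start, r.end)
            if iv.begin <= r.start and r.end <= iv.end
        ]
        if not containing:
            continue
        gene = min(containing, key=lambda g: (g.span, g.gene_id))
        cls = "polyA" if r.strand == gene.strand else "polyU"
        out.append(GenicAlu(r, gene.gene_id, gene.strand, cls))
    return out
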