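"""Genomic annotation intervals and BED/GTF input.

Internal coordinates are 0-based half-open throughout the package; GTF's
1-based inclusive coordinates are converted on read and write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class Annotation:
    """A named genomic interval (0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"annotation {self.id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"annotation {self.id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def gtf_interval_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (GTF) -> 0-based half-open."""
    return start - 1, end


def internal_interval_to_gtf(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (GTF)."""
    return start + 1, end


def read_bed(path: str | Path) -> list[Annotation]:
    """Read a BED3+ file; column 4 (name) becomes the annotation id."""
    annotations = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {i}: BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            annotations.append(Annotation(name, chrom, start, end, strand))
    return annotations


def write_bed(annotations: Iterable[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.id}\t0\t{a.strand}\n")


def _gtf_attribute(attributes: str, key: str) -> str | None:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk[len(key) :].strip().strip('"')
    return None


def read_gtf(
    path: str | Path,
    feature: str | None = None,
    id_attribute: str = "gene_id",
) -> list[Annotation]:
    """Read GTF intervals (1-based inclusive, converted to internal coords).

    `feature` restricts to one feature type (e.g. "exon", "gene"); the id is
    taken from `id_attribute` in column 9, falling back to a coordinate id.
    """
    annotations = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}, line {i}: GTF needs 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attributes = fields[:9]
            if feature is not None and ftype != feature:
                continue
            istart, iend = gtf_interval_to_internal(int(start), int(end))
            name = _gtf_attribute(attributes, id_attribute) or f"{chrom}:{istart}-{iend}"
            annotations.append(
                Annotation(name, chrom, istart, iend, strand if strand in "+-" else ".")
            )
    return annotations
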