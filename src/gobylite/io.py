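"""Run tags, read-level QC statistics and small sequence writers."""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

TAG_LENGTH = 7
_LETTERS = string.ascii_uppercase


def make_tag(seed_or_rng: int | np.random.Generator) -> str:
    """Draw a 7-character uppercase run tag (e.g. 'EBGNHJW').

    Tags identify data elements in logs and output file names; the space of
    26^7 tags makes collisions negligible at realistic run counts.
    """
    if isinstance(seed_or_rng, np.random.Generator):
        rng = seed_or_rng
    else:
        rng = np.random.default_rng(seed_or_rng)
    return "".join(_LETTERS[i] for i in rng.integers(0, 26, size=TAG_LENGTH))


@dataclass
class ReadStats:
    """Read-length histogram and per-cycle mean base quality of a FASTQ file."""

    length_histogram: dict[int, int]
    per_cycle_mean_quality: np.ndarray
    total_reads: int


def read_stats(path: str | Path, phred64: bool = False) -> ReadStats:
    """Stream a FASTQ file and collect length/quality statistics.

    Memory is bounded by the maximum read length, not the file size.
    Qualities are decoded as Phred+33 unless `phred64` is set.
    """
    histogram: Counter[int] = Counter()
    quality_sums = np.zeros(0, dtype=np.float64)
    quality_counts = np.zeros(0, dtype=np.int64)
    total = 0
    try:
        with pysam.FastxFile(str(path)) as fx:
            for record in fx:
                seq = record.sequence or ""
                length = len(seq)
                histogram[length] += 1
                total += 1
                quals = record.get_quality_array()
                if quals is not None:
                    q = np.asarray(quals, dtype=np.float64)
                    if phred64:
                        q -= 31.0  # pysam decodes at +33; shift to +64
                    if length > quality_sums.size:
                        quality_sums = np.pad(quality_sums, (0, length - quality_sums.size))
                        quality_counts = np.pad(
                            quality_counts, (0, length - quality_counts.size)
                        )
                    quality_sums[:length] += q
                    quality_counts[:length] += 1
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed FASTQ near record {total + 1} in {path}: {exc}")
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(quality_counts > 0, quality_sums / np.maximum(quality_counts, 1), np.nan)
    return ReadStats(dict(histogram), means, total)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(
    records: Iterable[Sequence[str]], path: str | Path
) -> None:
    """Write (name, sequence, quality) triples as FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a FASTQ file into (name, sequence, quality) triples, in order."""
    out = []
    with pysam.FastxFile(str(path)) as fx:
        for record in fx:
            out.append((record.name, record.sequence or "", record.quality or ""))
    return out
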