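"""Shared fixtures: tiny SAM/FASTQ/FASTA writers for constructed alignments."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest


def write_sam(
    path: Path,
    chrom_lengths: dict[str, int],
    records: list[tuple],
    sort: bool = True,
) -> Path:
    """Write SAM records given as (qname, flag, chrom, pos1, cigar, seq)."""
    if sort:
        order = {c: i for i, c in enumerate(chrom_lengths)}
        records = sorted(records, key=lambda r: (order[r[2]], r[3]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for qname, flag, chrom, pos1, cigar, seq in records:
            qual = "I" * len(seq)
            fh.write(
                f"{qname}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )
    return path


def write_fasta(path: Path, sequences: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def random_fastq(path: Path, n_reads: int, seed: int, read_length: int = 50) -> Path:
    """Write a seeded random FASTQ file with varying name lengths."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for i in range(n_reads):
            length = int(rng.integers(max(1, read_length - 10), read_length + 11))
            seq = bases[rng.integers(0, 4, length)].tobytes().decode()
            qual = "".join(chr(33 + int(q)) for q in rng.integers(2, 41, length))
            fh.write(f"@read_{i}:{int(rng.integers(0, 10**6))}\n{seq}\n+\n{qual}\n")
    return path


@pytest.fixture
def sam_writer(tmp_path):
    def _write(name, chrom_lengths, records, sort=True):
        return write_sam(tmp_path / name, chrom_lengths, records, sort=sort)

    return _write


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(name, sequences):
        return write_fasta(tmp_path / name, sequences)

    return _write
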