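"""Pathogen-contamination screening of unmapped reads.

Reads that fail to align to the study organism's reference are candidate
evidence of viral/bacterial/fungal contamination. The screening pipeline
extracts them, optionally trims sequencing adapters, and (after external
assembly and database search, both out of scope here) filters the resulting
contig-vs-database matches: a match is *annotated* iff it spans more than
150 bp and has an E-value below 1e-6, both thresholds strict. The summary
table reports, per organism, the number of samples with at least one
annotated contig.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .io import write_fastq

MIN_MATCH_BP = 150
MAX_EVALUE = 1e-6
ADAPTER_MIN_OVERLAP = 4  # trim only when the matched suffix exceeds this


def extract_unmapped(
    alignments: str | Path,
    reads: str | Path,
    out: str | Path | None = None,
) -> list[tuple[str, str, str]]:
    """Return (and optionally write) the reads with no aligned record.

    Order follows the reads file. Every read id appearing in the alignment
    file must resolve against the reads file; a mismatch is an error naming
    the first offending id.
    """
    mapped: set[str] = set()
    seen: set[str] = set()
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for record in af.fetch(until_eof=True):
            seen.add(record.query_name)
            if not record.is_unmapped:
                mapped.add(record.query_name)

    out_records: list[tuple[str, str, str]] = []
    read_ids: set[str] = set()
    with pysam.FastxFile(str(reads)) as fx:
        for record in fx:
            read_ids.add(record.name)
            if record.name not in mapped:
                out_records.append(
                    (record.name, record.sequence or "", record.quality or "")
                )
    unresolved = seen - read_ids
    if unresolved:
        raise ValueError(
            f"alignment read id not present in reads file: {sorted(unresolved)[0]!r}"
        )
    if out is not None:
        write_fastq(out_records, out)
    return out_records


def trim_adapter(
    sequence: str,
    adapter: str,
    quality: str | None = None,
    min_overlap: int = ADAPTER_MIN_OVERLAP,
) -> tuple[str, str | None]:
    """Remove a terminal adapter only if the trimmed part exceeds 4 bp.

    The longest suffix of the read exactly matching a prefix of the adapter
    is removed iff its length is strictly greater than `min_overlap`;
    otherwise the read is returned unchanged. The quality string, when
    given, is trimmed in lockstep.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    matched = 0
    for n in range(min(len(sequence), len(adapter)), 0, -1):
        if sequence[-n:] == adapter[:n]:
            matched = n
            break
    if matched > min_overlap:
        sequence = sequence[:-matched]
        if quality is not None:
            quality = quality[:-matched]
    return sequence, quality


@dataclass(frozen=True)
class ContigMatch:
    """One contig-vs-reference-database hit (one HSP of a tabular search)."""

    sample: str
    contig: str
    subject: str
    organism: str
    identity: float
    alignment_length: int
    evalue: float
    bitscore: float


def read_contig_matches(
    path: str | Path,
    sample: str,
    organism_map: Mapping[str, str] | None = None,
) -> list[ContigMatch]:
    """Parse 12-column tabular search output (query, subject, identity,
    alignment length, mismatches, gaps, qstart, qend, sstart, send, evalue,
    bitscore) into ContigMatch records for one sample.

    The organism is looked up from the subject id via `organism_map`,
    defaulting to the subject id itself with underscores read as spaces.
    """
    matches = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}, line {i}: expected 12 tab-delimited columns, got {len(fields)}"
                )
            try:
                identity = float(fields[2])
                alignment_length = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}")
            if alignment_length < 0 or evalue < 0:
                raise ValueError(
                    f"{path}, line {i}: negative alignment length or E-value"
                )
            subject = fields[1]
            organism = (
                organism_map.get(subject, subject.replace("_", " "))
                if organism_map is not None
                else subject.replace("_", " ")
            )
            matches.append(
                ContigMatch(
                    sample=sample,
                    contig=fields[0],
                    subject=subject,
                    organism=organism,
                    identity=identity,
                    alignment_length=alignment_length,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return matches


def annotate_contigs(
    matches: Iterable[ContigMatch],
    min_match_bp: int = MIN_MATCH_BP,
    max_evalue: float = MAX_EVALUE,
) -> list[ContigMatch]:
    """Keep exactly the matches with length > min_match_bp AND evalue < max_evalue.

    Both thresholds are strict: a 150 bp match or an E-value of exactly 1e-6
    is dropped. The filter is order-preserving and idempotent.
    """
    return [
        m
        for m in matches
        if m.alignment_length > min_match_bp and m.evalue < max_evalue
    ]


def species_summary(
    annotated: Iterable[ContigMatch], samples: Sequence[str]
) -> pd.DataFrame:
    """Per-organism sample counts from annotated (already filtered) matches.

    N counts the distinct samples with >=1 annotated contig for the
    organism; per-sample contig counts are retained as extra columns. Rows
    are sorted by N descending, then organism name. Duplicated matches of
    one contig within a sample do not change N.
    """
    annotated = list(annotated)
    known = set(samples)
    for m in annotated:
        if m.sample not in known:
            raise ValueError(f"match sample {m.sample!r} not in the sample list")
    contigs: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for m in annotated:
        contigs[m.organism][m.sample].add(m.contig)
    rows = []
    for organism, by_sample in contigs.items():
        row: dict = {"organism": organism, "N": len(by_sample), "comments": ""}
        for s in samples:
            row[f"contigs:{s}"] = len(by_sample.get(s, ()))
        rows.append(row)
    columns = ["organism", "N", "comments"] + [f"contigs:{s}" for s in samples]
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(
        ["N", "organism"], ascending=[False, True], ignore_index=True
    )
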