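"""Strand-aware per-cytosine methylation analysis of bisulfite alignments.

Bisulfite treatment converts unmethylated cytosine to uracil (sequenced as
T) while methylated cytosine stays C. At a reference cytosine, reads aligned
to the same strand therefore carry C where the cytosine was methylated and T
where it was not; the methylation rate estimate is Cm / (Cm + Cu) with no
pseudocount. Forward-strand cytosines are reference C bases informed by
forward alignments; reverse-strand cytosines are reference G bases informed
by reverse alignments, with G (methylated) / A (converted) read evidence in
the forward representation stored in SAM.

Differential methylation across groups is tested per site (or per region)
with a two-sided Fisher exact test on pooled converted/unconverted counts,
and adjusted per comparison with Benjamini-Hochberg across all sites tested.
"""

from __future__ import annotations

import functools
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .annotations import Annotation
from .design import GroupDesign
from .expression import bh_adjust


@dataclass
class MethylationTable:
    """Per-cytosine converted/unconverted counts for a set of samples.

    sites: DataFrame with columns chrom, pos (1-based cytosine coordinate),
    strand (+/-), context (CpG/CHG/CHH/unknown), then per sample
    "<sample>.Cm" (unconverted, methylated evidence) and "<sample>.Cu"
    (converted). Only positions with at least one informative observation in
    at least one sample are present.
    """

    sites: pd.DataFrame
    samples: list[str]

    def rates(self) -> pd.DataFrame:
        """Per-sample methylation rates; NaN where a sample has no coverage."""
        out = self.sites[["chrom", "pos", "strand", "context"]].copy()
        for s in self.samples:
            cm = self.sites[f"{s}.Cm"].to_numpy(dtype=float)
            cu = self.sites[f"{s}.Cu"].to_numpy(dtype=float)
            depth = cm + cu
            with np.errstate(invalid="ignore", divide="ignore"):
                out[f"{s}.rate"] = np.where(depth > 0, cm / np.maximum(depth, 1), np.nan)
        return out


def methylation_rate(cm: int, cu: int) -> float:
    """Cm / (Cm + Cu); NaN (no call) when the site has no coverage."""
    if cm < 0 or cu < 0:
        raise ValueError("counts must be non-negative")
    depth = cm + cu
    if depth == 0:
        return math.nan
    return cm / depth


def _context_at(ref: np.ndarray, pos: int, strand: str) -> str:
    """CpG/CHG/CHH context of the cytosine at `pos` from the reference only."""
    n = ref.size
    if strand == "+":
        if pos + 1 >= n:
            return "unknown"
        if ref[pos + 1] == b"G":
            return "CpG"
        if pos + 2 >= n:
            return "unknown"
        return "CHG" if ref[pos + 2] == b"G" else "CHH"
    if pos - 1 < 0:
        return "unknown"
    if ref[pos - 1] == b"C":
        return "CpG"
    if pos - 2 < 0:
        return "unknown"
    return "CHG" if ref[pos - 2] == b"C" else "CHH"


def _aligned_positions(read: pysam.AlignedSegment) -> tuple[np.ndarray, np.ndarray]:
    """(query offsets, reference positions) of aligned bases."""
    cig = read.cigartuples
    if cig and len(cig) == 1 and cig[0][0] in (0, 7, 8):  # plain match, no clips
        n = cig[0][1]
        return np.arange(n), np.arange(read.reference_start, read.reference_start + n)
    pairs = read.get_aligned_pairs(matches_only=True)
    if not pairs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    q, r = zip(*pairs)
    return np.asarray(q, dtype=int), np.asarray(r, dtype=int)


def call_methylation_sites(alignments, genome: str | Path) -> MethylationTable:
    """Tally Cm/Cu evidence at every observed reference cytosine.

    `alignments` maps sample name -> SAM/BAM path (or a single path, the
    file stem naming the sample). Forward alignments contribute at reference
    C positions (read C -> Cm, read T -> Cu); reverse alignments at
    reference G positions (read G -> Cm, read A -> Cu); any other read base
    at a cytosine is non-informative and ignored. Sites are emitted only
    where at least one cytosine observation exists.
    """
    if isinstance(alignments, (str, Path)):
        path = Path(alignments)
        samples = {path.stem: path}
    else:
        samples = {name: Path(p) for name, p in dict(alignments).items()}

    fasta = pysam.FastaFile(str(genome))
    refs: dict[str, np.ndarray] = {}

    def ref_array(chrom: str) -> np.ndarray:
        if chrom not in refs:
            if chrom not in fasta.references:
                raise ValueError(
                    f"alignment chromosome {chrom!r} absent from genome FASTA"
                )
            refs[chrom] = np.frombuffer(
                fasta.fetch(chrom).upper().encode(), dtype="S1"
            )
        return refs[chrom]

    # per sample, per chrom: (cm, cu) arrays over the chromosome
    tallies: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {
        s: {} for s in samples
    }
    for sample, path in samples.items():
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                chrom = read.reference_name
                ref = ref_array(chrom)
                if chrom not in tallies[sample]:
                    tallies[sample][chrom] = (
                        np.zeros(ref.size, dtype=np.int64),
                        np.zeros(ref.size, dtype=np.int64),
                    )
                cm, cu = tallies[sample][chrom]
                qpos, rpos = _aligned_positions(read)
                if qpos.size == 0:
                    continue
                seq = np.frombuffer(read.query_sequence.upper().encode(), dtype="S1")
                bases = seq[qpos]
                ref_bases = ref[rpos]
                if not read.is_reverse:
                    at_c = ref_bases == b"C"
                    np.add.at(cm, rpos[at_c & (bases == b"C")], 1)
                    np.add.at(cu, rpos[at_c & (bases == b"T")], 1)
                else:
                    at_g = ref_bases == b"G"
                    np.add.at(cm, rpos[at_g & (bases == b"G")], 1)
                    np.add.at(cu, rpos[at_g & (bases == b"A")], 1)

    # assemble the union of observed sites, sorted by (chrom, pos)
    chroms = sorted({c for t in tallies.values() for c in t})
    rows: dict[str, list] = {
        "chrom": [], "pos": [], "strand": [], "context": [],
    }
    per_sample: dict[str, list[int]] = {}
    for s in samples:
        per_sample[f"{s}.Cm"] = []
        per_sample[f"{s}.Cu"] = []
    for chrom in chroms:
        ref = ref_array(chrom)
        depth = np.zeros(ref.size, dtype=np.int64)
        for s in samples:
            if chrom in tallies[s]:
                cm, cu = tallies[s][chrom]
                depth += cm + cu
        positions = np.nonzero(depth)[0]
        for pos in positions:
            strand = "+" if ref[pos] == b"C" else "-"
            rows["chrom"].append(chrom)
            rows["pos"].append(int(pos) + 1)  # 1-based in the site table
            rows["strand"].append(strand)
            rows["context"].append(_context_at(ref, int(pos), strand))
            for s in samples:
                if chrom in tallies[s]:
                    cm, cu = tallies[s][chrom]
                    per_sample[f"{s}.Cm"].append(int(cm[pos]))
                    per_sample[f"{s}.Cu"].append(int(cu[pos]))
                else:
                    per_sample[f"{s}.Cm"].append(0)
                    per_sample[f"{s}.Cu"].append(0)
    fasta.close()
    sites = pd.DataFrame({**rows, **per_sample})
    return MethylationTable(sites=sites, samples=list(samples))


def aggregate_regions(
    table: MethylationTable, annotations: Sequence[Annotation]
) -> pd.DataFrame:
    """Pool site counts over annotation intervals (count-weighted rates).

    Region counts are sums of member-site counts; the region rate is
    recomputed from the summed counts, not averaged over site rates. Regions
    containing no sites are emitted with zero counts and a NaN (no-call)
    rate.
    """
    sites = table.sites
    out_rows = []
    pos0 = sites["pos"].to_numpy() - 1  # internal 0-based
    for a in annotations:
        mask = (
            (sites["chrom"] == a.chrom).to_numpy()
            & (pos0 >= a.start)
            & (pos0 < a.end)
        )
        row: dict = {"id": a.id, "chrom": a.chrom, "start": a.start, "end": a.end}
        for s in table.samples:
            cm = int(sites.loc[mask, f"{s}.Cm"].sum())
            cu = int(sites.loc[mask, f"{s}.Cu"].sum())
            row[f"{s}.Cm"] = cm
            row[f"{s}.Cu"] = cu
            row[f"{s}.rate"] = methylation_rate(cm, cu)
        out_rows.append(row)
    columns = ["id", "chrom", "start", "end"] + [
        f"{s}.{f}" for s in table.samples for f in ("Cm", "Cu", "rate")
    ]
    return pd.DataFrame(out_rows, columns=columns).set_index("id")


@functools.lru_cache(maxsize=100_000)
def _fisher_2x2(cm1: int, cu1: int, cm2: int, cu2: int) -> float:
    _, p = stats.fisher_exact([[cm1, cu1], [cm2, cu2]], alternative="two-sided")
    return float(p)


def comparison_label(g1: str, g2: str) -> str:
    safe = lambda g: re.sub(r"[^0-9A-Za-z]", "_", g)
    return f"{safe(g1)}_vs_{safe(g2)}"


def diff_methylation(
    data: MethylationTable | pd.DataFrame,
    design: GroupDesign,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Pairwise-group Fisher exact differential methylation with BH.

    For each comparison (g1, g2) of the design, counts are pooled by summing
    member samples within each group, and the two-sided Fisher exact test is
    applied to [[Cm_g1, Cu_g1], [Cm_g2, Cu_g2]]. Sites with pooled coverage
    below `min_coverage` in either group are flagged missing (NaN) and
    excluded from the BH family; adjustment is applied per comparison across
    all sites tested. Accepts a site table or a region table (any frame with
    per-sample .Cm/.Cu columns).
    """
    if isinstance(data, MethylationTable):
        frame, samples = data.sites, data.samples
    else:
        frame = data
        samples = sorted(
            {c[: -len(".Cm")] for c in frame.columns if c.endswith(".Cm")}
        )
    for sample in design.samples:
        if f"{sample}.Cm" not in frame.columns:
            raise ValueError(f"design sample {sample!r} not present in the table")
    if not design.comparisons:
        raise ValueError("design defines no comparisons")

    out = pd.DataFrame(index=frame.index)
    for g1, g2 in design.comparisons:
        label = comparison_label(g1, g2)
        cm1 = sum(frame[f"{s}.Cm"].to_numpy() for s in design.groups[g1])
        cu1 = sum(frame[f"{s}.Cu"].to_numpy() for s in design.groups[g1])
        cm2 = sum(frame[f"{s}.Cm"].to_numpy() for s in design.groups[g2])
        cu2 = sum(frame[f"{s}.Cu"].to_numpy() for s in design.groups[g2])
        cov1, cov2 = cm1 + cu1, cm2 + cu2
        tested = (cov1 >= max(1, min_coverage)) & (cov2 >= max(1, min_coverage))
        with np.errstate(invalid="ignore", divide="ignore"):
            rate1 = np.where(cov1 > 0, cm1 / np.maximum(cov1, 1), np.nan)
            rate2 = np.where(cov2 > 0, cm2 / np.maximum(cov2, 1), np.nan)
        p = np.full(len(frame), np.nan)
        idx = np.nonzero(tested)[0]
        for i in idx:
            p[i] = _fisher_2x2(int(cm1[i]), int(cu1[i]), int(cm2[i]), int(cu2[i]))
        q = np.full(len(frame), np.nan)
        if idx.size:
            q[idx] = bh_adjust(p[idx])
        out[f"{label}.Cm_{g1}"] = cm1
        out[f"{label}.Cu_{g1}"] = cu1
        out[f"{label}.Cm_{g2}"] = cm2
        out[f"{label}.Cu_{g2}"] = cu2
        out[f"{label}.rate_diff"] = rate1 - rate2
        out[f"{label}.fisher_p"] = p
        out[f"{label}.fisher_q"] = q
    return out


# ---------------------------------------------------------------------------
# VCF 4.1 and IGV-track output
# ---------------------------------------------------------------------------

def _check_sorted(sites: pd.DataFrame) -> None:
    last: dict[str, int] = {}
    order: list[str] = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        if chrom not in last:
            if chrom in order[:-1] if order else False:
                raise ValueError("sites not sorted: chromosome blocks interleaved")
            order.append(chrom)
            last[chrom] = pos
        else:
            if order[-1] != chrom:
                raise ValueError(f"sites not sorted: {chrom!r} appears in two blocks")
            if pos < last[chrom]:
                raise ValueError(
                    f"sites not sorted: {chrom}:{pos} after {chrom}:{last[chrom]}"
                )
            last[chrom] = pos


def _fmt_float(x: float) -> str:
    return "." if (x is None or (isinstance(x, float) and math.isnan(x))) else f"{x:.6g}"


def write_methylation_vcf(
    table: MethylationTable,
    path: str | Path,
    dm: pd.DataFrame | None = None,
    design: GroupDesign | None = None,
) -> None:
    """Write one VCF 4.1 record per site with per-sample rates and counts.

    Genotype fields: MR (methylation rate, '.' when uncovered), MC
    (unconverted/methylated count), NC (converted count). INFO carries the
    cytosine strand and context, plus per-comparison Fisher p/q when a
    differential-methylation frame and design are supplied. Sites must
    already be sorted by (chrom, pos); unsorted input is an error, never
    silently reordered.
    """
    sites = table.sites
    _check_sorted(sites)
    labels = []
    if dm is not None:
        if design is None or not design.comparisons:
            raise ValueError("dm given without a design defining comparisons")
        labels = [comparison_label(g1, g2) for g1, g2 in design.comparisons]

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write("##source=gobylite-methylation\n")
        for chrom in dict.fromkeys(sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=STR,Number=1,Type=String,Description="Cytosine strand">\n')
        fh.write(
            '##INFO=<ID=CTX,Number=1,Type=String,Description="Cytosine context (CpG/CHG/CHH)">\n'
        )
        for label in labels:
            fh.write(
                f'##INFO=<ID=P_{label},Number=1,Type=Float,Description='
                f'"Fisher exact p, comparison {label}">\n'
            )
            fh.write(
                f'##INFO=<ID=Q_{label},Number=1,Type=Float,Description='
                f'"BH-adjusted Fisher p, comparison {label}">\n'
            )
        fh.write('##FORMAT=<ID=MR,Number=1,Type=Float,Description="Methylation rate">\n')
        fh.write(
            '##FORMAT=<ID=MC,Number=1,Type=Integer,Description="Unconverted (methylated) cytosine count">\n'
        )
        fh.write(
            '##FORMAT=<ID=NC,Number=1,Type=Integer,Description="Converted cytosine count">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i, (_, row) in enumerate(sites.iterrows()):
            ref_base = "C" if row["strand"] == "+" else "G"
            info = f"STR={row['strand']};CTX={row['context']}"
            for label in labels:
                p = dm.iloc[i][f"{label}.fisher_p"]
                q = dm.iloc[i][f"{label}.fisher_q"]
                info += f";P_{label}={_fmt_float(p)};Q_{label}={_fmt_float(q)}"
            fields = [
                row["chrom"], str(row["pos"]), ".", ref_base, ".", ".", ".",
                info, "MR:MC:NC",
            ]
            for s in table.samples:
                cm, cu = int(row[f"{s}.Cm"]), int(row[f"{s}.Cu"])
                fields.append(f"{_fmt_float(methylation_rate(cm, cu))}:{cm}:{cu}")
            fh.write("\t".join(fields) + "\n")


def read_methylation_vcf(path: str | Path) -> MethylationTable:
    """Parse a VCF written by :func:`write_methylation_vcf` back to a table."""
    samples: list[str] = []
    rows: list[dict] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            row: dict = {
                "chrom": fields[0],
                "pos": int(fields[1]),
                "strand": info.get("STR", "+" if fields[3] == "C" else "-"),
                "context": info.get("CTX", "unknown"),
            }
            fmt_keys = fields[8].split(":")
            for s, value in zip(samples, fields[9:]):
                parts = dict(zip(fmt_keys, value.split(":")))
                row[f"{s}.Cm"] = int(parts["MC"])
                row[f"{s}.Cu"] = int(parts["NC"])
            rows.append(row)
    columns = ["chrom", "pos", "strand", "context"] + [
        f"{s}.{f}" for s in samples for f in ("Cm", "Cu")
    ]
    sites = pd.DataFrame(rows, columns=columns)
    if rows:
        sites["pos"] = sites["pos"].astype(int)
    return MethylationTable(sites=sites, samples=samples)


def write_region_igv(
    regions: pd.DataFrame, path: str | Path, samples: Sequence[str] | None = None
) -> None:
    """Write region rates as a tab-delimited IGV track.

    Columns: Chromosome, Start, End, Feature, then one numeric rate column
    per sample (0-based half-open coordinates, matching the region table).
    """
    if samples is None:
        samples = [c[: -len(".rate")] for c in regions.columns if c.endswith(".rate")]
    with open(path, "w") as fh:
        fh.write("Chromosome\tStart\tEnd\tFeature\t" + "\t".join(samples) + "\n")
        for rid, row in regions.iterrows():
            values = "\t".join(_fmt_float(row[f"{s}.rate"]) for s in samples)
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{rid}\t{values}\n")


def read_region_igv(path: str | Path) -> pd.DataFrame:
    """Parse an IGV track written by :func:`write_region_igv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row = {
                "id": fields[3],
                "chrom": fields[0],
                "start": int(fields[1]),
                "end": int(fields[2]),
            }
            for s, v in zip(samples, fields[4:]):
                row[f"{s}.rate"] = math.nan if v == "." else float(v)
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end"] + [f"{s}.rate" for s in samples]
    ).set_index("id")
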