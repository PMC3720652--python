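"""Gene-expression quantification and two-group differential statistics.

Fragment counts over annotations, junction-spanning counts, RPKM with a +1
pseudocount, total / upper-quartile normalization, heptamer priming-bias
weights, and Fisher-exact / pooled-t statistics with Benjamini-Hochberg
adjustment.

The RPKM of an annotation of length L bases with c overlapping fragments in
a sample normalized by N is

    r = (c + 1) / (L / 1000) / (N / 1e6)

where N is either the total number of aligned fragments in the sample or the
75th percentile of the sample's nonzero annotation counts (upper-quartile
normalization). The pseudocount keeps log2(r) finite at c = 0.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import Annotation
from .design import GroupDesign

ReadWeight = Mapping[str, float]


@dataclass
class CountTable:
    """Per-sample, per-annotation fragment counts.

    counts: DataFrame indexed by annotation id, one column per sample. Values
    are floats to admit heptamer-weighted counts; unweighted counting yields
    integer values.
    totals: per-sample number of primary aligned fragments (always integer,
    unweighted).
    lengths: per-annotation length in bases, for RPKM.
    """

    counts: pd.DataFrame
    totals: pd.Series
    lengths: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def annotations(self) -> list[str]:
        return list(self.counts.index)


def _as_sample_map(alignments) -> dict[str, Path]:
    if isinstance(alignments, (str, Path)):
        path = Path(alignments)
        return {path.stem: path}
    return {name: Path(p) for name, p in dict(alignments).items()}


def _open_sorted(path: Path, require_sorted: bool) -> pysam.AlignmentFile:
    af = pysam.AlignmentFile(str(path), check_sq=False)
    if require_sorted:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            af.close()
            raise ValueError(
                f"{path}: alignments must be coordinate-sorted "
                f"(header SO={so!r}); run `samtools sort` first"
            )
    return af


def _is_primary(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def count_fragments(
    alignments,
    annotations: Sequence[Annotation],
    weights: ReadWeight | None = None,
    stranded: bool = False,
    require_sorted: bool = True,
) -> CountTable:
    """Count primary aligned fragments overlapping each annotation by >=1 base.

    `alignments` is a mapping sample -> SAM/BAM path (or a single path; the
    file stem becomes the sample name). One primary alignment record is one
    fragment; secondary and supplementary records are ignored. A fragment
    overlapping several (possibly overlapping) annotations is counted once in
    each. With `weights`, each fragment contributes its read weight instead
    of 1; totals remain unweighted fragment counts.
    """
    samples = _as_sample_map(alignments)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for a in annotations:
        trees[a.chrom].addi(a.start, a.end, a)

    index = [a.id for a in annotations]
    lengths = pd.Series({a.id: a.length for a in annotations}, dtype=int).reindex(index)
    counts = pd.DataFrame(0.0, index=index, columns=list(samples))
    totals = pd.Series(0, index=list(samples), dtype=int)

    for sample, path in samples.items():
        with _open_sorted(path, require_sorted) as af:
            known = set(af.references)
            for chrom in trees:
                if chrom not in known:
                    warnings.warn(
                        f"{path}: annotation chromosome {chrom!r} absent from "
                        "alignment header; its annotations get zero counts"
                    )
            acc: Counter[str] = Counter()
            total = 0
            for read in af.fetch(until_eof=True):
                if not _is_primary(read):
                    continue
                total += 1
                tree = trees.get(read.reference_name)
                if tree is None:
                    continue
                w = 1.0 if weights is None else float(weights.get(read.query_name, 1.0))
                for hit in tree.overlap(read.reference_start, read.reference_end):
                    annot: Annotation = hit.data
                    if stranded and annot.strand in "+-":
                        read_strand = "-" if read.is_reverse else "+"
                        if read_strand != annot.strand:
                            continue
                    acc[annot.id] += w
            totals[sample] = total
            for annot_id, value in acc.items():
                counts.loc[annot_id, sample] = value
    return CountTable(counts=counts, totals=totals, lengths=lengths)


def count_junction_reads(alignments, require_sorted: bool = True) -> pd.DataFrame:
    """Count reads spanning splice junctions implied by alignment gaps.

    Each N (skip) operation of a primary alignment defines one junction keyed
    by (chrom, intron start, intron end) in 0-based half-open coordinates; a
    read spanning k junctions increments k counts. Returns a DataFrame
    indexed by junction with one column per sample; ungapped input yields an
    empty table.
    """
    samples = _as_sample_map(alignments)
    counts: dict[str, Counter] = {s: Counter() for s in samples}
    for sample, path in samples.items():
        with _open_sorted(path, require_sorted) as af:
            for read in af.fetch(until_eof=True):
                if not _is_primary(read) or not read.cigartuples:
                    continue
                pos = read.reference_start
                for op, length in read.cigartuples:
                    if op == 3:  # N: skipped region = intron
                        counts[sample][(read.reference_name, pos, pos + length)] += 1
                    if op in (0, 2, 3, 7, 8):  # reference-consuming ops
                        pos += length
    junctions = sorted({j for c in counts.values() for j in c})
    table = pd.DataFrame(
        {s: [counts[s].get(j, 0) for j in junctions] for s in samples},
        index=pd.MultiIndex.from_tuples(junctions, names=["chrom", "start", "end"])
        if junctions
        else pd.MultiIndex.from_arrays([[], [], []], names=["chrom", "start", "end"]),
    )
    return table


def rpkm(c, length, norm):
    """(c + 1) / (length/1000) / (norm/1e6); strictly positive for c >= 0."""
    c = np.asarray(c, dtype=float)
    length = np.asarray(length, dtype=float)
    norm = np.asarray(norm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("annotation length must be positive")
    if np.any(norm <= 0):
        raise ValueError("normalization factor must be positive")
    result = (c + 1.0) / (length / 1000.0) / (norm / 1.0e6)
    return float(result) if result.ndim == 0 else result


def upper_quartile(values: Sequence[float]) -> float:
    """Nearest-rank 75th percentile of the nonzero counts."""
    nonzero = sorted(v for v in values if v > 0)
    if not nonzero:
        raise ValueError("upper-quartile normalization undefined: all counts are zero")
    rank = math.ceil(0.75 * len(nonzero))  # 1-based nearest rank
    return float(nonzero[rank - 1])


def normalization_factor(table: CountTable, method: str = "total") -> pd.Series:
    """Per-sample N: 'total' aligned fragments or 'upper-quartile' of counts.

    Upper-quartile uses the nearest-rank 75th percentile restricted to
    annotations with nonzero counts, so that sparse annotation sets do not
    drive N to zero.
    """
    if method == "total":
        n = table.totals.astype(float)
        if (n <= 0).any():
            bad = n.index[n <= 0][0]
            raise ValueError(f"sample {bad!r} has no aligned fragments; N undefined")
        return n
    if method in ("upper-quartile", "uq"):
        return pd.Series(
            {s: upper_quartile(table.counts[s].to_numpy()) for s in table.samples}
        )
    raise ValueError(f"unknown normalization method {method!r}")


def heptamer_weights(
    reads: str | Path,
    k: int = 7,
    distal_window: tuple[int, int] = (24, 30),
) -> dict[str, float]:
    """Priming-bias read weights from heptamer frequency ratios.

    For each read, let h be its first k bases. The weight is the frequency of
    h among heptamers in the distal positional window (1-based start
    positions `distal_window`, inclusive) divided by its frequency among
    read-start heptamers. Heptamers over-represented at read starts (the
    signature of biased random priming) are down-weighted; an unbiased
    library gives weights near 1. Reads too short for the distal window get
    weight 1 with a warning.
    """
    lo, hi = distal_window
    if lo < 1 or hi < lo:
        raise ValueError(f"bad distal window {distal_window}")
    min_len = hi + k - 1
    start_counts: Counter[str] = Counter()
    distal_counts: Counter[str] = Counter()
    read_heptamers: list[tuple[str, str | None]] = []
    with pysam.FastxFile(str(reads)) as fx:
        for record in fx:
            seq = (record.sequence or "").upper()
            if len(seq) < min_len:
                read_heptamers.append((record.name, None))
                continue
            h = seq[:k]
            start_counts[h] += 1
            for p in range(lo - 1, hi):  # 0-based start offsets of the window
                distal_counts[seq[p : p + k]] += 1
            read_heptamers.append((record.name, h))

    n_start = sum(start_counts.values())
    n_distal = sum(distal_counts.values())
    n_short = sum(1 for _, h in read_heptamers if h is None)
    if n_short:
        warnings.warn(
            f"{n_short} reads shorter than {min_len} bp; assigned weight 1.0"
        )
    weights: dict[str, float] = {}
    for name, h in read_heptamers:
        if h is None or n_start == 0 or n_distal == 0:
            weights[name] = 1.0
            continue
        f_start = start_counts[h] / n_start
        f_distal = distal_counts.get(h, 0) / n_distal
        weights[name] = f_distal / f_start if f_start > 0 else 1.0
    return weights


def fisher_exact_de(cA: int, cB: int, TA: int, TB: int) -> float:
    """Two-sided Fisher exact p for the table [[cA, TA-cA], [cB, TB-cB]]."""
    for name, value in (("cA", cA), ("cB", cB), ("TA", TA), ("TB", TB)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value}")
    cA, cB, TA, TB = int(cA), int(cB), int(TA), int(TB)
    if TA < cA or TB < cB:
        raise ValueError(f"margins violated: need TA >= cA and TB >= cB")
    _, p = stats.fisher_exact([[cA, TA - cA], [cB, TB - cB]], alternative="two-sided")
    return float(p)


def ttest_de(groupA: Sequence[float], groupB: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance (classic Student) t on per-sample values.

    Intended for log2(RPKM); with fewer than 2 samples in either group the
    statistic is undefined and (nan, nan) is returned so the caller can flag
    it missing rather than report 0.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if a.size < 2 or b.size < 2:
        return (math.nan, math.nan)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diff_expression(
    table: CountTable,
    design: GroupDesign,
    comparison: tuple[str, str] | None = None,
    norm: str = "total",
    raw_table: CountTable | None = None,
) -> pd.DataFrame:
    """Per-annotation counts, RPKM, log2(RPKM) and two-group DE statistics.

    The Fisher exact test uses pooled *unweighted integer* counts per group
    against the pooled totals (exact tests need integers); pass the
    unweighted table as `raw_table` when `table` holds weighted counts. The
    t-test compares per-sample log2(RPKM) between the groups; it is reported
    as missing (NaN) when a group has fewer than 2 samples.
    """
    if comparison is None:
        if not design.comparisons:
            raise ValueError("no comparison given and design defines none")
        comparison = design.comparisons[0]
    g1, g2 = comparison
    samples1, samples2 = design.groups[g1], design.groups[g2]
    integer_table = raw_table if raw_table is not None else table
    if not np.allclose(integer_table.counts, np.round(integer_table.counts)):
        raise ValueError(
            "Fisher exact DE needs integer counts; pass the unweighted table as raw_table"
        )

    n = normalization_factor(table, norm)
    rpkm_df = pd.DataFrame(
        {
            s: rpkm(table.counts[s].to_numpy(), table.lengths.to_numpy(), n[s])
            for s in table.samples
        },
        index=table.counts.index,
    )
    log2_df = np.log2(rpkm_df)

    out = pd.DataFrame(index=table.counts.index)
    for s in table.samples:
        out[f"count:{s}"] = table.counts[s]
    for s in table.samples:
        out[f"rpkm:{s}"] = rpkm_df[s]
    for s in table.samples:
        out[f"log2rpkm:{s}"] = log2_df[s]
    mean1 = log2_df[samples1].mean(axis=1)
    mean2 = log2_df[samples2].mean(axis=1)
    out[f"mean_log2rpkm:{g1}"] = mean1
    out[f"mean_log2rpkm:{g2}"] = mean2
    out["log2_fold_change"] = mean1 - mean2

    c1 = integer_table.counts[samples1].sum(axis=1).round().astype(int)
    c2 = integer_table.counts[samples2].sum(axis=1).round().astype(int)
    t1 = int(integer_table.totals[samples1].sum())
    t2 = int(integer_table.totals[samples2].sum())
    out["fisher_p"] = [
        fisher_exact_de(a, b, t1, t2) for a, b in zip(c1.to_numpy(), c2.to_numpy())
    ]
    tp = [ttest_de(log2_df.loc[i, samples1], log2_df.loc[i, samples2]) for i in out.index]
    out["ttest_t"] = [t for t, _ in tp]
    out["ttest_p"] = [p for _, p in tp]
    out["fisher_q"] = bh_adjust(out["fisher_p"].to_numpy())
    tmask = out["ttest_p"].notna()
    out["ttest_q"] = np.nan
    if tmask.any():
        out.loc[tmask, "ttest_q"] = bh_adjust(out.loc[tmask, "ttest_p"].to_numpy())
    return out
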