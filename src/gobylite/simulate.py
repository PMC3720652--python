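"""Synthetic fixtures: genomes, methylomes, bisulfite reads, count tables.

Every generator is deterministic under its seed. The bisulfite protocol
follows the validation design for base-level methylation calling: a random
reference region, an independent uniform methylation rate at every cytosine
on both strands, and single-end reads placed uniformly over the region at a
target mean coverage (50X and 250X are the reference conditions). The
simulator records, for every emitted read base at a cytosine, whether it
left the machine converted (T/A) or unconverted (C/G), so downstream
methylation calls can be checked against ground truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .design import GroupDesign
from .expression import CountTable
from .pathogen import ContigMatch

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

DEFAULT_REGION_LENGTH = 100_000  # desk-scale region; full-scale runs use more
DEFAULT_READ_LENGTH = 36


@dataclass
class SimulationConfig:
    """Conditions of a bisulfite simulation run."""

    region_length: int = DEFAULT_REGION_LENGTH
    coverage: float = 50.0
    read_length: int = DEFAULT_READ_LENGTH
    gc_fraction: float = 0.5
    bisulfite_conversion_efficiency: float = 1.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.region_length < self.read_length:
            raise ValueError("region_length must be >= read_length")
        if self.coverage <= 0 or self.read_length <= 0:
            raise ValueError("coverage and read_length must be positive")


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def simulate_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random reference sequence with the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode()


def simulate_methylome(
    genome: str,
    seed: int = 0,
    rate_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> np.ndarray:
    """Independent methylation rate for every cytosine on both strands.

    Returns an array aligned to the genome: positions holding C (forward
    strand cytosine) or G (reverse strand cytosine) get a rate draw
    (uniform on [0, 1] by default); all other positions are NaN.
    """
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.upper().encode(), dtype="S1")
    is_cytosine = (arr == b"C") | (arr == b"G")
    rates = np.full(arr.size, np.nan)
    n = int(is_cytosine.sum())
    draws = rng.uniform(0.0, 1.0, n) if rate_sampler is None else np.asarray(
        rate_sampler(rng, n), dtype=float
    )
    rates[is_cytosine] = draws
    return rates


@dataclass
class BisulfiteSim:
    """Paths and ground truth of one simulated bisulfite sample."""

    sample: str
    chrom: str
    fastq: Path
    sam: Path
    n_reads: int
    read_length: int
    truth_cm: np.ndarray  # per-position emitted unconverted evidence
    truth_cu: np.ndarray  # per-position emitted converted evidence
    rates: np.ndarray  # the true methylome used

    @property
    def truth_depth(self) -> np.ndarray:
        return self.truth_cm + self.truth_cu


def simulate_bisulfite_reads(
    genome: str,
    rates: np.ndarray,
    coverage: float,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
    out_dir: str | Path = ".",
    sample: str = "sim",
    chrom: str = "chr1",
    conversion_efficiency: float = 1.0,
    error_rate: float = 0.0,
    batch_size: int = 100_000,
) -> BisulfiteSim:
    """Simulate bisulfite-converted single-end reads at a mean coverage.

    Read starts are uniform over the region, strands equiprobable. At each
    covered cytosine the emitted base stays unconverted with probability
    equal to the site's methylation rate; an unmethylated cytosine is
    converted with probability `conversion_efficiency`. Reverse-strand
    fragments are simulated on the minus strand but written in forward
    representation (G unconverted / A converted at reference G sites), as
    they appear in SAM. Alignments record the true placements (MAPQ 60,
    ungapped, coordinate-sorted), so methylation calling is testable without
    running an aligner. The truth tallies count emitted informative bases
    exactly as a caller sees them, including any sequencing errors.
    """
    L = len(genome)
    if read_length > L:
        raise ValueError("read_length exceeds region length")
    rng = np.random.default_rng(seed)
    garr = np.frombuffer(genome.upper().encode(), dtype="S1")
    rates = np.asarray(rates, dtype=float)
    n_reads = max(1, int(round(coverage * L / read_length)))
    starts = np.sort(rng.integers(0, L - read_length + 1, size=n_reads))
    reverse = rng.random(n_reads) < 0.5

    truth_cm = np.zeros(L, dtype=np.int64)
    truth_cu = np.zeros(L, dtype=np.int64)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fastq_path = out_dir / f"{sample}.fastq"
    sam_path = out_dir / f"{sample}.sam"
    qual = "I" * read_length

    with open(fastq_path, "w") as fq, open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:coordinate\n")
        sam.write(f"@SQ\tSN:{chrom}\tLN:{L}\n")
        offsets = np.arange(read_length)
        for lo in range(0, n_reads, batch_size):
            hi = min(lo + batch_size, n_reads)
            idx = starts[lo:hi, None] + offsets[None, :]
            bases = garr[idx].copy()
            ref_bases = garr[idx]
            rmat = rates[idx]
            rev = reverse[lo:hi]
            meth = rng.random(bases.shape) < np.where(np.isnan(rmat), 0.0, rmat)
            converted = (~meth) & (rng.random(bases.shape) < conversion_efficiency)
            # forward fragments sample forward-strand cytosines (reference C)
            fwd_c = (ref_bases == b"C") & ~rev[:, None]
            bases[fwd_c & converted] = b"T"
            # reverse fragments sample reverse-strand cytosines (reference G)
            rev_g = (ref_bases == b"G") & rev[:, None]
            bases[rev_g & converted] = b"A"
            if error_rate > 0:
                err = rng.random(bases.shape) < error_rate
                bases[err] = _BASES[rng.integers(0, 4, size=int(err.sum()))]
            # tally exactly what an idealized caller would count
            np.add.at(truth_cm, idx[fwd_c & (bases == b"C")], 1)
            np.add.at(truth_cu, idx[fwd_c & (bases == b"T")], 1)
            np.add.at(truth_cm, idx[rev_g & (bases == b"G")], 1)
            np.add.at(truth_cu, idx[rev_g & (bases == b"A")], 1)

            for i in range(hi - lo):
                name = f"{sample}:r{lo + i}"
                fwd_seq = bases[i].tobytes().decode()
                if rev[i]:
                    fq.write(f"@{name}\n{revcomp(fwd_seq)}\n+\n{qual}\n")
                    flag = 16
                else:
                    fq.write(f"@{name}\n{fwd_seq}\n+\n{qual}\n")
                    flag = 0
                sam.write(
                    f"{name}\t{flag}\t{chrom}\t{starts[lo + i] + 1}\t60\t"
                    f"{read_length}M\t*\t0\t0\t{fwd_seq}\t{qual}\n"
                )
    return BisulfiteSim(
        sample=sample,
        chrom=chrom,
        fastq=fastq_path,
        sam=sam_path,
        n_reads=n_reads,
        read_length=read_length,
        truth_cm=truth_cm,
        truth_cu=truth_cu,
        rates=rates,
    )


def simulate_count_table(
    n_genes: int = 2000,
    group_sizes: Sequence[int] = (3, 3),
    baseline_mean: float = 100.0,
    effect_fold: float = 2.0,
    dispersion: float = 0.0,
    de_fraction: float = 0.1,
    gene_mean_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[CountTable, pd.DataFrame, GroupDesign]:
    """Two-group negative-binomial count table with a planted fold effect.

    Per-gene baseline means are lognormal around `baseline_mean` (log-sd
    `gene_mean_sigma`). With `effect_fold` = 1 no gene is flagged; otherwise
    a `de_fraction` subset carries the fold effect in group B, direction
    random. `dispersion` is the NB overdispersion (variance = m + d*m^2);
    0 gives the Poisson limit of purely technical counting noise, the null
    under which exact count tests are calibrated. Returns the count table,
    a truth frame (is_de, true_log2_fold, per-group means), and the two-group
    design comparing A vs B.
    """
    if len(group_sizes) != 2 or any(g < 2 for g in group_sizes):
        raise ValueError("need two groups of >= 2 samples")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    means = baseline_mean * rng.lognormal(
        -0.5 * gene_mean_sigma**2, gene_mean_sigma, n_genes
    )
    if effect_fold == 1.0:
        is_de = np.zeros(n_genes, dtype=bool)
    else:
        is_de = rng.random(n_genes) < de_fraction
    direction = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    fold = np.where(is_de, effect_fold**direction, 1.0)
    means_b = means * fold

    def draw(mean_vector: np.ndarray) -> np.ndarray:
        if dispersion <= 0:
            return rng.poisson(mean_vector)
        lam = rng.gamma(1.0 / dispersion, mean_vector * dispersion)
        return rng.poisson(lam)

    samples_a = [f"A{i + 1}" for i in range(group_sizes[0])]
    samples_b = [f"B{i + 1}" for i in range(group_sizes[1])]
    counts = pd.DataFrame(index=genes)
    for s in samples_a:
        counts[s] = draw(means)
    for s in samples_b:
        counts[s] = draw(means_b)
    lengths = pd.Series(rng.integers(200, 5001, n_genes), index=genes)
    table = CountTable(
        counts=counts.astype(float),
        totals=counts.sum(axis=0).astype(int),
        lengths=lengths,
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "mean_A": means,
            "mean_B": means_b,
            "is_de": is_de,
            "true_log2_fold": np.log2(fold),
        }
    ).set_index("gene")
    design = GroupDesign({"A": samples_a, "B": samples_b}, [("A", "B")])
    return table, truth, design


_DEFAULT_ORGANISMS = (
    "Human herpesvirus 4 type 1 (EBV)",
    "Macacine herpesvirus 4",
    "Enterobacteria phage phi X 174",
)

#: Alignment lengths and E-values straddling the annotation filter
#: boundaries (length > 150 strict, E < 1e-6 strict).
_LENGTH_POOL = (148, 149, 150, 151, 152, 300, 500)
_EVALUE_POOL = (1e-5, 1e-6, 1e-7, 1e-8)


def simulate_contig_matches(
    n_samples: int = 4,
    organisms: Sequence[str] = _DEFAULT_ORGANISMS,
    matches_per_sample: int = 8,
    seed: int = 0,
) -> tuple[list[ContigMatch], pd.DataFrame, list[str]]:
    """Toy contig-match table with known pass/fail truth at the filter.

    Lengths and E-values are drawn from pools straddling both thresholds, so
    the annotated subset and the per-organism sample counts are fully
    determined and recorded in the truth frame.
    """
    if not organisms:
        raise ValueError("organisms must be non-empty")
    rng = np.random.default_rng(seed)
    samples = [f"sample_{i + 1}" for i in range(n_samples)]
    matches: list[ContigMatch] = []
    rows = []
    for s in samples:
        for j in range(matches_per_sample):
            organism = organisms[rng.integers(0, len(organisms))]
            length = int(_LENGTH_POOL[rng.integers(0, len(_LENGTH_POOL))])
            evalue = float(_EVALUE_POOL[rng.integers(0, len(_EVALUE_POOL))])
            match = ContigMatch(
                sample=s,
                contig=f"{s}_contig{j}",
                subject=organism.replace(" ", "_"),
                organism=organism,
                identity=float(rng.uniform(85, 100)),
                alignment_length=length,
                evalue=evalue,
                bitscore=float(rng.uniform(50, 500)),
            )
            matches.append(match)
            rows.append(
                {
                    "sample": s,
                    "contig": match.contig,
                    "organism": organism,
                    "alignment_length": length,
                    "evalue": evalue,
                    "passes": length > 150 and evalue < 1e-6,
                }
            )
    truth = pd.DataFrame(rows)
    return matches, truth, samples


def expected_species_n(truth: pd.DataFrame) -> pd.Series:
    """Ground-truth N per organism: distinct samples with >=1 passing match."""
    passing = truth[truth["passes"]]
    return passing.groupby("organism")["sample"].nunique()
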