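"""Fragment counting, normalization and differential-expression statistics."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gobylite.annotations import Annotation
from gobylite.design import GroupDesign
from gobylite.expression import (
    CountTable,
    bh_adjust,
    count_fragments,
    count_junction_reads,
    diff_expression,
    fisher_exact_de,
    heptamer_weights,
    normalization_factor,
    rpkm,
    ttest_de,
    upper_quartile,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_by_enumeration(cA, cB, TA, TB):
    """Two-sided Fisher p by summing hypergeometric table probabilities."""
    c = cA + cB

    def prob(x):
        return (
            math.comb(TA, x) * math.comb(TB, c - x) / math.comb(TA + TB, c)
        )

    observed = prob(cA)
    total = 0.0
    for x in range(max(0, c - TB), min(TA, c) + 1):
        p = prob(x)
        if p <= observed * (1 + 1e-9):
            total += p
    return min(1.0, total)


def bh_by_definition(pvals):
    """Step-up definition: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.minimum(1.0, m * ranked / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    out = np.empty(m)
    out[order] = q
    return out


def pooled_t_by_formula(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))


# ---------------------------------------------------------------------------
# fragment counting
# ---------------------------------------------------------------------------

class TestCountFragments:
    def test_single_read_inside_annotation(self, sam_writer):
        path = sam_writer(
            "a.sam", {"chr1": 1000}, [("r1", 0, "chr1", 101, "10M", "A" * 10)]
        )
        table = count_fragments(
            {"s1": path}, [Annotation("gene1", "chr1", 50, 200)]
        )
        assert table.counts.loc["gene1", "s1"] == 1
        assert table.totals["s1"] == 1

    def test_read_in_two_overlapping_annotations_counts_in_each(self, sam_writer):
        path = sam_writer(
            "a.sam", {"chr1": 1000}, [("r1", 0, "chr1", 101, "10M", "A" * 10)]
        )
        annotations = [
            Annotation("geneA", "chr1", 90, 120),
            Annotation("geneB", "chr1", 100, 300),
        ]
        table = count_fragments({"s1": path}, annotations)
        assert table.counts.loc["geneA", "s1"] == 1
        assert table.counts.loc["geneB", "s1"] == 1
        assert table.totals["s1"] == 1  # still one fragment

    def test_no_reads_gives_zero_counts(self, sam_writer):
        path = sam_writer("empty.sam", {"chr1": 1000}, [])
        table = count_fragments({"s1": path}, [Annotation("g", "chr1", 0, 10)])
        assert table.counts.loc["g", "s1"] == 0
        assert table.totals["s1"] == 0

    def test_randomized_counts_match_brute_force_overlap(self, sam_writer):
        rng = np.random.default_rng(42)
        reads = []
        for i in range(150):
            start = int(rng.integers(0, 900))
            length = int(rng.integers(5, 60))
            reads.append((f"r{i}", 0, "chr1", start + 1, f"{length}M", "A" * length))
        annotations = []
        for j in range(25):
            start = int(rng.integers(0, 950))
            end = start + int(rng.integers(10, 120))
            annotations.append(Annotation(f"a{j}", "chr1", start, min(end, 1000)))
        path = sam_writer("rand.sam", {"chr1": 1100}, reads)
        table = count_fragments({"s1": path}, annotations)
        # brute force: >=1 base overlap between read span and annotation
        for a in annotations:
            expected = sum(
                1
                for _, _, _, pos1, cigar, seq in reads
                if max(pos1 - 1, a.start) < min(pos1 - 1 + len(seq), a.end)
            )
            assert table.counts.loc[a.id, "s1"] == expected

    def test_weights_of_one_reproduce_unweighted_counts(self, sam_writer):
        reads = [(f"r{i}", 0, "chr1", 10 * i + 1, "8M", "A" * 8) for i in range(20)]
        path = sam_writer("w.sam", {"chr1": 1000}, reads)
        annotations = [Annotation("g", "chr1", 0, 150)]
        plain = count_fragments({"s1": path}, annotations)
        weighted = count_fragments(
            {"s1": path}, annotations, weights={f"r{i}": 1.0 for i in range(20)}
        )
        pd.testing.assert_frame_equal(plain.counts, weighted.counts)

    def test_unsorted_input_instructs_to_sort(self, tmp_path):
        path = tmp_path / "unsorted.sam"
        path.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100\n"
            "r1\t0\tchr1\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        with pytest.raises(ValueError, match="sort"):
            count_fragments({"s1": path}, [Annotation("g", "chr1", 0, 10)])

    def test_unknown_chromosome_warns_and_counts_zero(self, sam_writer):
        path = sam_writer("a.sam", {"chr1": 100}, [("r1", 0, "chr1", 1, "4M", "ACGT")])
        with pytest.warns(UserWarning, match="chrX"):
            table = count_fragments({"s1": path}, [Annotation("g", "chrX", 0, 10)])
        assert table.counts.loc["g", "s1"] == 0


class TestJunctionCounts:
    def test_gap_structure_defines_junction_counts(self, sam_writer):
        reads = [
            ("r1", 0, "chr1", 101, "10M50N10M", "A" * 20),  # one junction
            ("r2", 0, "chr1", 201, "20M", "A" * 20),  # ungapped
            ("r3", 0, "chr1", 101, "10M50N10M30N10M", "A" * 30),  # two junctions
        ]
        path = sam_writer("j.sam", {"chr1": 10000}, reads)
        table = count_junction_reads({"s1": path})
        # junctions enumerated by hand from the CIGAR strings (0-based introns)
        assert table.loc[("chr1", 110, 160), "s1"] == 2  # r1 and r3
        assert table.loc[("chr1", 170, 200), "s1"] == 1  # r3 only
        assert len(table) == 2

    def test_ungapped_file_yields_empty_table(self, sam_writer):
        path = sam_writer(
            "u.sam", {"chr1": 1000}, [("r1", 0, "chr1", 1, "20M", "A" * 20)]
        )
        assert count_junction_reads({"s1": path}).empty


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestRpkm:
    @pytest.mark.parametrize(
        "c, L, N, expected",
        [(0, 1000, 1e6, 1.0), (9, 500, 2e6, 10.0), (999, 1000, 1e6, 1000.0)],
    )
    def test_closed_form(self, c, L, N, expected):
        assert rpkm(c, L, N) == pytest.approx(expected)

    def test_monotone_in_arguments(self):
        assert rpkm(10, 1000, 1e6) > rpkm(5, 1000, 1e6)
        assert rpkm(10, 500, 1e6) > rpkm(10, 1000, 1e6)
        assert rpkm(10, 1000, 1e6) > rpkm(10, 1000, 2e6)

    def test_log2_always_finite(self):
        assert np.isfinite(np.log2(rpkm(0, 10, 1)))

    @pytest.mark.parametrize("L, N", [(0, 1e6), (-5, 1e6), (1000, 0), (1000, -1)])
    def test_invalid_arguments(self, L, N):
        with pytest.raises(ValueError):
            rpkm(1, L, N)


class TestNormalizationFactor:
    def _table(self, counts_by_sample, totals):
        counts = pd.DataFrame(counts_by_sample, dtype=float)
        return CountTable(
            counts=counts,
            totals=pd.Series(totals),
            lengths=pd.Series(1000, index=counts.index),
        )

    def test_total_is_aligned_fragment_count(self):
        table = self._table({"s1": [1, 2, 3]}, {"s1": 2_000_000})
        n = normalization_factor(table, "total")
        assert n["s1"] == 2_000_000

    def test_upper_quartile_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = rng.integers(0, 500, size=rng.integers(1, 60))
            nonzero = sorted(v for v in values if v > 0)
            if not nonzero:
                continue
            expected = nonzero[math.ceil(0.75 * len(nonzero)) - 1]
            assert upper_quartile(values) == expected

    def test_uq_on_1_to_100(self):
        assert upper_quartile(list(range(1, 101))) == 75  # nearest rank

    def test_single_annotation_uq_equals_that_count(self):
        table = self._table({"s1": [37]}, {"s1": 100})
        assert normalization_factor(table, "upper-quartile")["s1"] == 37

    def test_all_zero_sample_is_an_error(self):
        table = self._table({"s1": [0, 0]}, {"s1": 10})
        with pytest.raises(ValueError):
            normalization_factor(table, "upper-quartile")


class TestHeptamerWeights:
    @staticmethod
    def _write_reads(path, reads):
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        return path

    @staticmethod
    def _read(start_h, distal_base):
        # start heptamer + 16 filler + 13-base distal window (offsets 23-35)
        return start_h + "T" * 16 + distal_base * 13

    def test_matched_start_and_distal_composition_gives_unit_weights(self, tmp_path):
        # each heptamer equally frequent at starts and in the distal window
        reads = [self._read("AAAAAAA", "A"), self._read("CCCCCCC", "C"),
                 self._read("GGGGGGG", "G"), self._read("TTTTTTT", "T")]
        path = self._write_reads(tmp_path / "r.fastq", reads)
        weights = heptamer_weights(path)
        assert all(w == pytest.approx(1.0) for w in weights.values())

    def test_start_overrepresentation_halves_the_weight(self, tmp_path):
        # 'AAAAAAA' starts half the reads but is only a quarter of the
        # distal heptamers: weight = 0.25 / 0.5 = 0.5
        reads = [
            self._read("AAAAAAA", "A"),
            self._read("AAAAAAA", "C"),
            self._read("CCCCCCC", "G"),
            self._read("GGGGGGG", "T"),
        ]
        path = self._write_reads(tmp_path / "r.fastq", reads)
        weights = heptamer_weights(path)
        assert weights["r0"] == pytest.approx(0.5)
        assert weights["r1"] == pytest.approx(0.5)
        # independent closed-form check for the others
        assert weights["r2"] == pytest.approx((7 / 28) / (1 / 4))
        assert weights["r3"] == pytest.approx((7 / 28) / (1 / 4))

    def test_short_reads_get_unit_weight_with_warning(self, tmp_path):
        path = self._write_reads(tmp_path / "r.fastq", ["ACGTACGTAC"])
        with pytest.warns(UserWarning, match="shorter"):
            weights = heptamer_weights(path)
        assert weights["r0"] == 1.0


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_de(5, 5, 100, 100) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        assert fisher_exact_de(10, 0, 10, 10) == pytest.approx(
            fisher_by_enumeration(10, 0, 10, 10), rel=1e-9
        )

    def test_random_tables_match_full_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            TA = int(rng.integers(1, 31))
            TB = int(rng.integers(1, 31))
            cA = int(rng.integers(0, TA + 1))
            cB = int(rng.integers(0, TB + 1))
            assert fisher_exact_de(cA, cB, TA, TB) == pytest.approx(
                fisher_by_enumeration(cA, cB, TA, TB), rel=1e-8, abs=1e-12
            )

    @pytest.mark.parametrize("args", [(-1, 0, 10, 10), (5, 0, 4, 10), (0, 5, 10, 4)])
    def test_violated_margins_are_an_error(self, args):
        with pytest.raises(ValueError):
            fisher_exact_de(*args)


class TestTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        t, p = ttest_de([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_t(self):
        a, b = [4.2, 5.1, 6.3, 5.5], [3.1, 3.9, 4.0]
        t, _ = ttest_de(a, b)
        assert t == pytest.approx(pooled_t_by_formula(a, b), rel=1e-12)

    def test_swapping_groups_negates_t_preserves_p(self):
        a, b = [1.0, 2.0, 4.0], [2.5, 3.5, 5.0]
        t1, p1 = ttest_de(a, b)
        t2, p2 = ttest_de(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_undersized_group_is_flagged_missing(self):
        t, p = ttest_de([1.0], [1.0, 2.0])
        assert math.isnan(t) and math.isnan(p)


class TestBHAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    @given(
        pvals=st.lists(
            st.floats(0, 1, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_definition(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), bh_by_definition(pvals), rtol=1e-10, atol=1e-12
        )

    def test_q_dominates_p_and_equal_ps_are_fixed_points(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        assert (bh_adjust(p) >= p - 1e-12).all()
        np.testing.assert_allclose(bh_adjust([0.3] * 5), [0.3] * 5)

    def test_out_of_range_p_is_an_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestDiffExpression:
    def _setup(self, sam_writer):
        annotations = [
            Annotation("g1", "chr1", 0, 1000),
            Annotation("g2", "chr1", 2000, 2500),
        ]
        samples = {}
        rng = np.random.default_rng(9)
        for s, bias in [("A1", 0), ("A2", 0), ("B1", 30), ("B2", 30)]:
            reads = []
            for i in range(40):
                start = int(rng.integers(0, 900))
                reads.append((f"{s}_r{i}", 0, "chr1", start + 1, "10M", "A" * 10))
            for i in range(10 + bias):
                start = 2000 + int(rng.integers(0, 400))
                reads.append((f"{s}_j{i}", 0, "chr1", start + 1, "10M", "A" * 10))
            samples[s] = sam_writer(f"{s}.sam", {"chr1": 3000}, reads)
        design = GroupDesign({"A": ["A1", "A2"], "B": ["B1", "B2"]}, [("A", "B")])
        return samples, annotations, design

    def test_result_columns_and_statistics(self, sam_writer):
        samples, annotations, design = self._setup(sam_writer)
        table = count_fragments(samples, annotations)
        result = diff_expression(table, design)
        assert {"fisher_p", "ttest_p", "fisher_q", "ttest_q",
                "log2_fold_change"} <= set(result.columns)
        assert ((result["fisher_p"] >= 0) & (result["fisher_p"] <= 1)).all()
        assert (result["fisher_q"] >= result["fisher_p"] - 1e-12).all()
        # the planted 4x effect on g2 produces a negative A-vs-B fold change
        assert result.loc["g2", "log2_fold_change"] < 0
        # fisher_p computed from pooled counts must match the direct call
        c1 = int(table.counts.loc["g2", ["A1", "A2"]].sum())
        c2 = int(table.counts.loc["g2", ["B1", "B2"]].sum())
        t1 = int(table.totals[["A1", "A2"]].sum())
        t2 = int(table.totals[["B1", "B2"]].sum())
        assert result.loc["g2", "fisher_p"] == pytest.approx(
            fisher_exact_de(c1, c2, t1, t2)
        )
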