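"""Interval model, BED I/O and exact set arithmetic against per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakscape.intervals import (
    BedParseError,
    Genome,
    GenomicInterval,
    GenomicIntervalSet,
    intersect,
    jaccard,
    merge,
    read_bed,
    reciprocal_overlap,
    write_bed,
)

from conftest import random_interval_set
from oracles import allpairs_intersect, coverage_bool, jaccard_bool, merged_runs


class TestGenomeAndInterval:
    def test_duplicate_chrom_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Genome([("chr1", 10), ("chr1", 20)])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            Genome([("chr1", 0)])

    @pytest.mark.parametrize("start,end", [(100, 50), (5, 5), (-1, 10)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_summit_must_be_inside(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 100, summit=100)

    def test_summit_defaults_to_midpoint(self):
        assert GenomicInterval("chr1", 10, 21).effective_summit() == 15

    def test_set_rejects_foreign_chromosome(self, tiny_genome):
        with pytest.raises(ValueError, match="not in genome"):
            GenomicIntervalSet(tiny_genome, [GenomicInterval("chrX", 0, 10)])

    def test_set_sorted_regardless_of_input_order(self, tiny_genome):
        a = GenomicInterval("chr1", 50, 150)
        b = GenomicInterval("chr1", 0, 100)
        s = GenomicIntervalSet(tiny_genome, [a, b])
        assert [iv.start for iv in s] == [0, 50]


class TestBedIO:
    def test_read_bed3_sorted(self, tmp_path, tiny_genome):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t50\t150\nchr1\t0\t100\n")
        s = read_bed(p, tiny_genome)
        assert [(iv.start, iv.end) for iv in s] == [(0, 100), (50, 150)]

    def test_narrowpeak_summit_column(self, tmp_path, tiny_genome):
        p = tmp_path / "x.narrowPeak"
        p.write_text("chr1\t100\t300\tpk1\t60\t.\t5.5\t4.4\t3.3\t30\n")
        s = read_bed(p, tiny_genome)
        assert s[0].summit == 30
        assert s[0].effective_summit() == 130

    def test_inverted_coordinates_error_with_line_number(self, tmp_path, tiny_genome):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\nchr1\t100\t50\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p, tiny_genome)

    def test_unknown_chromosome_rejected(self, tmp_path, tiny_genome):
        p = tmp_path / "bad.bed"
        p.write_text("chrZ\t0\t10\n")
        with pytest.raises(BedParseError, match="chrZ"):
            read_bed(p, tiny_genome)

    def test_roundtrip_preserves_coordinates(self, tmp_path, tiny_genome):
        rng = np.random.default_rng(3)
        s = random_interval_set(tiny_genome, rng, n=30)
        p = tmp_path / "rt.bed"
        write_bed(s, p)
        back = read_bed(p, tiny_genome)
        assert [(iv.chrom, iv.start, iv.end) for iv in back] == [
            (iv.chrom, iv.start, iv.end) for iv in s
        ]

    def test_roundtrip_narrowpeak_keeps_summit(self, tmp_path, tiny_genome):
        s = GenomicIntervalSet(
            tiny_genome, [GenomicInterval("chr1", 5, 105, "p", 1.0, "+", 42)]
        )
        p = tmp_path / "rt.narrowPeak"
        write_bed(s, p, narrowpeak=True)
        assert read_bed(p, tiny_genome)[0].summit == 42


class TestMerge:
    def test_empty(self, tiny_genome):
        assert len(merge(GenomicIntervalSet(tiny_genome))) == 0

    def test_overlapping_pair(self, tiny_genome):
        s = GenomicIntervalSet(
            tiny_genome,
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)],
        )
        assert [(iv.start, iv.end) for iv in merge(s)] == [(0, 150)]

    def test_bookended_intervals_merge(self, tiny_genome):
        s = GenomicIntervalSet(
            tiny_genome,
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200)],
        )
        assert [(iv.start, iv.end) for iv in merge(s)] == [(0, 200)]

    def test_matches_boolean_occupancy_oracle(self, tiny_genome):
        rng = np.random.default_rng(5)
        s = random_interval_set(tiny_genome, rng, n=50)
        cov = coverage_bool(s, tiny_genome)
        expected = [
            ("chr1" if c == "chr1" else c, a, b)
            for c in tiny_genome.names
            for a, b in merged_runs(cov[c])
        ]
        got = [(iv.chrom, iv.start, iv.end) for iv in merge(s)]
        assert got == expected

    def test_idempotent(self, tiny_genome):
        rng = np.random.default_rng(9)
        s = random_interval_set(tiny_genome, rng, n=40)
        assert merge(merge(s)) == merge(s)


class TestIntersect:
    def test_simple_pair(self, tiny_genome):
        a = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 0, 100)])
        b = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 50, 150)])
        [(x, y, ov)] = intersect(a, b)
        assert (x.start, y.start, ov) == (0, 50, 50)

    def test_disjoint_sets_empty(self, tiny_genome):
        a = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 0, 100)])
        b = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr2", 0, 100)])
        assert intersect(a, b) == []

    def test_genome_mismatch_errors(self, tiny_genome):
        other = Genome([("chr1", 10_000)])
        a = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 0, 10)])
        b = GenomicIntervalSet(other, [GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError, match="different genomes"):
            intersect(a, b)

    def test_matches_allpairs_bruteforce(self, tiny_genome):
        rng = np.random.default_rng(17)
        a = random_interval_set(tiny_genome, rng, n=100)
        b = random_interval_set(tiny_genome, rng, n=100)
        got = {
            ((x.chrom, x.start, x.end), (y.chrom, y.start, y.end), ov)
            for x, y, ov in intersect(a, b)
        }
        expected = {
            (
                (a[i].chrom, a[i].start, a[i].end),
                (b[j].chrom, b[j].start, b[j].end),
                ov,
            )
            for i, j, ov in allpairs_intersect(list(a), list(b))
        }
        assert got == expected

    def test_symmetric_total_overlap(self, random_sets):
        a, b = random_sets
        tot_ab = sum(ov for *_, ov in intersect(a, b))
        tot_ba = sum(ov for *_, ov in intersect(b, a))
        assert tot_ab == tot_ba


class TestJaccard:
    def test_identical_sets(self, tiny_genome):
        s = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 10, 60)])
        assert jaccard(s, s) == 1.0

    def test_disjoint_sets(self, tiny_genome):
        a = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 0, 50)])
        b = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 100, 150)])
        assert jaccard(a, b) == 0.0

    def test_half_overlap_value(self, tiny_genome):
        a = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 0, 100)])
        b = GenomicIntervalSet(tiny_genome, [GenomicInterval("chr1", 50, 150)])
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_both_empty_convention(self, tiny_genome):
        e = GenomicIntervalSet(tiny_genome)
        assert jaccard(e, e) == 0.0

    def test_matches_boolean_oracle_and_symmetry(self, tiny_genome):
        rng = np.random.default_rng(23)
        for _ in range(10):
            a = random_interval_set(tiny_genome, rng, n=30)
            b = random_interval_set(tiny_genome, rng, n=30)
            expected = jaccard_bool(
                coverage_bool(a, tiny_genome), coverage_bool(b, tiny_genome)
            )
            assert jaccard(a, b) == pytest.approx(expected, abs=1e-12)
            assert jaccard(a, b) == pytest.approx(jaccard(b, a), abs=1e-12)

    def test_agrees_with_bedtools(self, tmp_path, tiny_genome):
        """Independent cross-check against the reference command-line tool."""
        import subprocess

        rng = np.random.default_rng(31)
        a = merge(random_interval_set(tiny_genome, rng, n=25))
        b = merge(random_interval_set(tiny_genome, rng, n=25))
        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(a, pa)
        write_bed(b, pb)
        out = subprocess.run(
            ["bedtools", "jaccard", "-a", str(pa), "-b", str(pb)],
            capture_output=True, text=True, check=True,
        ).stdout.splitlines()
        ref = float(out[1].split("\t")[2])  # printed to 6 decimals
        assert jaccard(a, b) == pytest.approx(ref, abs=1e-6)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "x,y,f,expected",
        [
            ((0, 100), (0, 100), 0.5, True),
            ((0, 100), (50, 150), 0.5, True),  # both exactly 0.5, >= applies
            ((0, 100), (90, 200), 0.5, False),
            ((0, 100), (0, 300), 0.5, False),  # one-sided overlap only
        ],
    )
    def test_threshold_cases(self, x, y, f, expected):
        ivx = GenomicInterval("chr1", *x)
        ivy = GenomicInterval("chr1", *y)
        assert reciprocal_overlap(ivx, ivy, f) is expected

    def test_different_chrom_is_false_not_error(self):
        x = GenomicInterval("chr1", 0, 100)
        y = GenomicInterval("chr2", 0, 100)
        assert reciprocal_overlap(x, y, 0.5) is False

    def test_invalid_fraction_rejected(self):
        x = GenomicInterval("chr1", 0, 100)
        with pytest.raises(ValueError):
            reciprocal_overlap(x, x, 0.0)


@settings(deadline=None, max_examples=50)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 950), st.integers(1, 50)), min_size=0, max_size=40
    )
)
def test_merge_preserves_covered_bases_property(data):
    """Property: merge never changes the covered-base set (random inputs)."""
    genome = Genome([("chr1", 1000)])
    s = GenomicIntervalSet(
        genome, [GenomicInterval("chr1", a, a + l) for a, l in data]
    )
    cov_before = coverage_bool(s, genome)["chr1"]
    m = merge(s)
    cov_after = coverage_bool(m, genome)["chr1"]
    assert np.array_equal(cov_before, cov_after)
    starts_ends = [(iv.start, iv.end) for iv in m]
    assert all(e1 < s2 for (_, e1), (s2, _) in zip(starts_ends, starts_ends[1:]))
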