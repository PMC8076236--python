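"""Signal matrices, meta-profiles, k-means clustering, peak categories."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from peakscape.intervals import Genome, GenomicInterval, GenomicIntervalSet
from peakscape.signals import (
    Gene,
    SignalTrack,
    aggregate_profile,
    build_signal_matrix,
    categorize_peaks,
    category_fractions,
    kmeans_cluster,
    read_bedgraph,
)


@pytest.fixture
def genome():
    return Genome([("chr1", 100_000)])


def constant_track(genome, value):
    return SignalTrack(
        genome,
        {c: (np.array([0]), np.array([L]), np.array([float(value)]))
         for c, L in genome.chromosomes},
    )


class TestSignalTrack:
    def test_negative_values_rejected(self, genome):
        with pytest.raises(ValueError, match=">= 0"):
            SignalTrack(
                genome,
                {"chr1": (np.array([0]), np.array([10]), np.array([-1.0]))},
            )

    def test_bedgraph_roundtrip_and_integral(self, tmp_path, genome):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t100\t2.5\nchr1\t100\t200\t1.0\nchr1\t500\t600\t4\n")
        t = read_bedgraph(p, genome)
        assert t.integral("chr1", 0, 200) == pytest.approx(350.0)
        assert t.integral("chr1", 50, 150) == pytest.approx(175.0)
        assert t.integral("chr1", 300, 400) == 0.0
        assert t.mean("chr1", 400, 700) == pytest.approx(400 / 300)

    def test_negative_bedgraph_rejected(self, tmp_path, genome):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chr1\t0\t10\t-3\n")
        with pytest.raises(Exception, match="negative"):
            read_bedgraph(p, genome)

    def test_window_clipping_zero_pads(self, genome):
        t = constant_track(genome, 2.0)
        # window extends 100 bp past the chromosome start
        assert t.mean("chr1", -100, 100) == pytest.approx(1.0)


class TestBuildSignalMatrix:
    def test_constant_track_fills_matrix(self, genome):
        peaks = GenomicIntervalSet(
            genome, [GenomicInterval("chr1", 10_000, 10_400, "p", None, ".", 200)]
        )
        m = build_signal_matrix(peaks, {"x": constant_track(genome, 3.0)})
        assert m.values.shape == (1, 80)
        assert np.allclose(m.values, 3.0)

    def test_unit_spike_lands_in_central_bin(self, genome):
        peaks = GenomicIntervalSet(
            genome, [GenomicInterval("chr1", 10_000, 10_400, "p", None, ".", 200)]
        )
        summit = 10_200
        spike = SignalTrack(
            genome,
            {"chr1": (np.array([summit]), np.array([summit + 1]), np.array([1.0]))},
        )
        m = build_signal_matrix(peaks, {"x": spike}, flank_bp=2000, bin_bp=50)
        row = m.values[0]
        assert np.count_nonzero(row) == 1
        assert row[40] == pytest.approx(1 / 50)  # first bin right of the anchor

    def test_bin_count_arithmetic(self, genome):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 50_000, 50_200)])
        m = build_signal_matrix(
            peaks, {"a": constant_track(genome, 1), "b": constant_track(genome, 2)},
            flank_bp=2000, bin_bp=50,
        )
        assert m.bins == 80
        assert m.values.shape == (1, 160)

    def test_non_multiple_flank_rejected(self, genome):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError, match="multiple"):
            build_signal_matrix(peaks, {"x": constant_track(genome, 1)},
                                flank_bp=1999, bin_bp=50)

    def test_unknown_anchor_kind_errors(self, genome):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError, match="anchor"):
            build_signal_matrix(peaks, {"x": constant_track(genome, 1)},
                                anchor="nope")

    def test_minus_strand_tss_reverses_bins(self, genome):
        track = SignalTrack(
            genome,
            {"chr1": (np.array([50_000]), np.array([50_100]), np.array([1.0]))},
        )
        plus = GenomicIntervalSet(
            genome, [GenomicInterval("chr1", 49_950, 50_950, strand="+")]
        )
        # '-' TSS at 50150 so the signal sits 50-150 bp downstream of it too
        minus = GenomicIntervalSet(
            genome, [GenomicInterval("chr1", 49_151, 50_151, strand="-")]
        )
        mp = build_signal_matrix(plus, {"x": track}, flank_bp=500, bin_bp=50,
                                 anchor="tss")
        mm = build_signal_matrix(minus, {"x": track}, flank_bp=500, bin_bp=50,
                                 anchor="tss")
        # signal downstream of both TSSs: same bins after strand flip
        assert np.allclose(mp.values, mm.values)

    def test_mass_conservation(self, default_bundle):
        """Sum(bin mean * bin_bp) equals the track integral over the window."""
        b = default_bundle
        peaks = GenomicIntervalSet(b.genome, list(b.truth.true_peaks)[:20])
        track = b.signal_tracks["H3K4me3"]
        m = build_signal_matrix(peaks, {"H3K4me3": track})
        for r, iv in enumerate(peaks):
            s = iv.effective_summit()
            expected = track.integral(iv.chrom, s - 2000, s + 2000)
            got = m.values[r].sum() * m.bin_bp
            assert got == pytest.approx(expected, rel=1e-6)


class TestAggregateProfile:
    def test_single_anchor_profile_is_its_row(self, genome):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 10_000, 10_400)])
        m = build_signal_matrix(peaks, {"x": constant_track(genome, 2.0)})
        assert np.allclose(aggregate_profile(m)["x"], m.values[0])

    def test_two_anchor_mean(self, genome):
        peaks = GenomicIntervalSet(
            genome,
            [GenomicInterval("chr1", 10_000, 10_400),
             GenomicInterval("chr1", 50_000, 50_400)],
        )
        t = SignalTrack(
            genome,
            {"chr1": (np.array([0, 30_000]), np.array([30_000, 100_000]),
                      np.array([1.0, 3.0]))},
        )
        prof = aggregate_profile(build_signal_matrix(peaks, {"x": t}))
        assert np.allclose(prof["x"], 2.0)

    def test_empty_matrix_errors(self, genome):
        m = build_signal_matrix(
            GenomicIntervalSet(genome), {"x": constant_track(genome, 1)}
        )
        with pytest.raises(ValueError, match="empty"):
            aggregate_profile(m)

    def test_promoter_archetype_peaks_atac_centred(self, default_bundle):
        """Planted promoter-like peaks show their ATAC maximum at the centre."""
        b = default_bundle
        c1 = GenomicIntervalSet(
            b.genome,
            [iv for iv in b.truth.true_peaks
             if b.truth.peak_cluster_labels[iv.name] == "C1"],
        )
        prof = aggregate_profile(
            build_signal_matrix(c1, {"ATAC": b.signal_tracks["ATAC"]})
        )["ATAC"]
        center = len(prof) // 2
        assert abs(int(np.argmax(prof)) - center) <= 1


class TestKmeans:
    def test_k1_centroid_is_column_mean(self, default_bundle):
        b = default_bundle
        peaks = GenomicIntervalSet(b.genome, list(b.truth.true_peaks)[:30])
        m = build_signal_matrix(peaks, {"ATAC": b.signal_tracks["ATAC"]})
        a = kmeans_cluster(m, k=1, seed=0, transform=False)
        assert np.allclose(a.centroids[0], m.values.mean(axis=0))
        assert set(a.labels.values()) == {"C1"}

    def test_well_separated_duplicates_each_get_a_cluster(self, genome):
        from peakscape.signals import SignalMatrix

        base = np.zeros((9, 10))
        base[0:3, 0] = 100.0
        base[3:6, 5] = 100.0
        # rows 6-9 stay zero
        m = SignalMatrix(
            [f"p{i}" for i in range(9)],
            [("chr1", 0, ".")] * 9,
            bins=10, bin_bp=50, tracks=["x"], values=base,
        )
        a = kmeans_cluster(m, k=3, seed=0, transform=False)
        groups = {a.labels[f"p{i}"] for i in range(3)}, {
            a.labels[f"p{i}"] for i in range(3, 6)
        }, {a.labels[f"p{i}"] for i in range(6, 9)}
        assert all(len(g) == 1 for g in groups)
        assert len(set().union(*groups)) == 3

    def test_k_larger_than_rows_errors(self, genome):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 0, 100)])
        m = build_signal_matrix(peaks, {"x": constant_track(genome, 1)})
        with pytest.raises(ValueError):
            kmeans_cluster(m, k=5, seed=0)

    def test_deterministic_given_seed(self, default_bundle):
        b = default_bundle
        peaks = GenomicIntervalSet(b.genome, list(b.truth.true_peaks)[:100])
        m = build_signal_matrix(peaks, b.signal_tracks)
        a1 = kmeans_cluster(m, k=5, seed=123)
        a2 = kmeans_cluster(m, k=5, seed=123)
        assert a1.labels == a2.labels

    def test_recovers_planted_archetypes(self, default_bundle):
        """ARI vs planted cluster labels >= 0.9 on the default matrix."""
        b = default_bundle
        m = build_signal_matrix(b.truth.true_peaks, b.signal_tracks)
        truth = [b.truth.peak_cluster_labels[i] for i in m.anchor_ids]
        a = kmeans_cluster(m, k=5, seed=0)
        pred = [a.labels[i] for i in m.anchor_ids]
        assert adjusted_rand_score(truth, pred) >= 0.9


class TestCategorizePeaks:
    @pytest.fixture
    def genes(self):
        return [
            Gene("gA", "chr1", "+", 20_000, 20_000, 40_000),
            Gene("gB", "chr1", "-", 79_999, 60_000, 80_000),
        ]

    def test_peak_at_tss_is_promoter(self, genome, genes):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 19_900, 20_100, "p")])
        assert categorize_peaks(peaks, genes)["p"] == "TSS/promoter"

    def test_peak_mid_gene_is_gene_body(self, genome, genes):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 30_000, 30_200, "p")])
        assert categorize_peaks(peaks, genes)["p"] == "gene body"

    def test_peak_far_away_is_distal(self, genome, genes):
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 95_000, 95_200, "p")])
        assert categorize_peaks(peaks, genes)["p"] == "distal"

    def test_minus_strand_upstream_window(self, genome, genes):
        # 3 kb beyond the '-' gene's TSS (towards larger coordinates) is upstream
        peaks = GenomicIntervalSet(genome, [GenomicInterval("chr1", 82_900, 83_100, "p")])
        assert categorize_peaks(peaks, genes)["p"] == "TSS/promoter"

    def test_matches_bruteforce_window_oracle(self, genome):
        rng = np.random.default_rng(4)
        genes = []
        for i in range(20):
            strand = "+" if rng.uniform() < 0.5 else "-"
            start = int(rng.integers(0, 80_000))
            end = start + int(rng.integers(2_000, 15_000))
            end = min(end, 100_000)
            tss = start if strand == "+" else end - 1
            genes.append(Gene(f"g{i}", "chr1", strand, tss, start, end))
        peaks = GenomicIntervalSet(
            genome,
            [
                GenomicInterval(
                    "chr1", s, s + 200, f"p{i}"
                )
                for i, s in enumerate(rng.integers(0, 99_800, size=100))
            ],
        )
        got = categorize_peaks(peaks, genes)
        for iv in peaks:
            # oracle: explicit base-window checks
            prom = False
            body = False
            for g in genes:
                if g.strand == "+":
                    w = set(range(max(0, g.tss - 5000), g.tss + 500))
                else:
                    w = set(range(max(0, g.tss - 499), g.tss + 5001))
                pk = set(range(iv.start, iv.end))
                if pk & w:
                    prom = True
                if pk & set(range(g.start, g.end)):
                    body = True
            expected = "TSS/promoter" if prom else ("gene body" if body else "distal")
            assert got[iv.name] == expected

    def test_category_fractions_sum_to_one(self, default_bundle):
        b = default_bundle
        cats = categorize_peaks(b.truth.true_peaks, b.genes)
        labels = {
            iv.name: b.truth.peak_cluster_labels[iv.name]
            for iv in b.truth.true_peaks
        }
        fr = category_fractions(cats, labels)
        assert set(fr) == {"C1", "C2", "C3", "C4", "C5"}
        for cluster, d in fr.items():
            assert sum(d.values()) == pytest.approx(1.0, abs=1e-9)
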