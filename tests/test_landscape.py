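"""Landscape statistics: size peaks, bins, chromosome and window tracks."""

import numpy as np
import pytest

from bilecirc.landscape import (compare_length_bins, chromosome_distribution,
                                chromosome_group_tests, count_per_mapped_read,
                                cumulative_size_curve, detect_size_peaks,
                                window_coverage)
from bilecirc.records import EccDNARecord, SampleProfile, Segment
from bilecirc.synthetic import CohortSpec, sample_ecc_sizes, simulate_cohort


def _profile(sid, group, lengths=None, segments=None, reads=1_000):
    recs = []
    if segments is None:
        segments = [("chr1", 1_000 + 10 * i) for i in range(len(lengths or []))]
    for i, ln in enumerate(lengths or []):
        chrom, start = segments[i % len(segments)]
        recs.append(EccDNARecord(f"{sid}:e{i}",
                                 [Segment(chrom, start, start + int(ln))]))
    return SampleProfile(sid, group, mapped_read_count=reads,
                         downsampled_read_count=reads, eccdna=recs)


class TestCountPerMappedRead:
    def test_basic_ratio(self):
        p = _profile("s", "cancer", lengths=[100] * 10, reads=1_000)
        assert count_per_mapped_read(p) == 0.01

    def test_zero_eccdna(self):
        p = _profile("s", "cancer", lengths=[], reads=1_000)
        assert count_per_mapped_read(p) == 0.0

    def test_zero_reads_raises(self):
        p = _profile("s", "cancer", lengths=[], reads=0)
        with pytest.raises(ValueError):
            count_per_mapped_read(p)

    def test_equal_generation_rate_not_significant(self, genome):
        """Same generation rate in both groups: the per-read ratio carries
        no group signal across seeds."""
        from scipy import stats

        rejections = 0
        for seed in range(20):
            spec = CohortSpec(n_cancer=5, n_noncancer=5, circles_mean=500.0,
                              marker_genes=())
            profiles = simulate_cohort(genome, spec, seed=300 + seed)
            ratios = {"cancer": [], "noncancer": []}
            for p in profiles:
                ratios[p.group].append(count_per_mapped_read(p))
            pv = stats.mannwhitneyu(ratios["cancer"], ratios["noncancer"],
                                    alternative="two-sided").pvalue
            rejections += pv < 0.05
        assert rejections <= 4  # expect 1 under the null


class TestSizePeaks:
    def test_six_cancer_peaks_recovered(self):
        lengths = sample_ecc_sizes("cancer", 50_000, seed=7)
        peaks = detect_size_peaks(lengths)
        assert len(peaks) == 6
        for (center, _), expected in zip(peaks, CohortSpec().cancer_centers):
            assert abs(center - expected) <= 30

    def test_unimodal_input_single_peak(self, rng):
        lengths = rng.normal(300, 40, size=10_000)
        peaks = detect_size_peaks(lengths)
        assert len(peaks) == 1
        assert abs(peaks[0][0] - 300) <= 30

    def test_flat_density_no_peaks(self, rng):
        # large n so KDE sampling noise stays below the prominence floor
        lengths = rng.uniform(1, 2_000, size=500_000)
        assert detect_size_peaks(lengths) == []

    def test_too_few_lengths_raises(self):
        with pytest.raises(ValueError):
            detect_size_peaks(np.full(50, 300.0))

    def test_scale_equivariance(self, rng):
        """Scaling lengths, bandwidth and range by c scales peak centers."""
        lengths = np.concatenate([rng.normal(200, 30, 5_000),
                                  rng.normal(700, 30, 5_000)])
        base = detect_size_peaks(lengths, bandwidth_bp=25,
                                 size_range=(0, 1_000))
        c = 2.0
        scaled = detect_size_peaks(lengths * c, bandwidth_bp=25 * c,
                                   size_range=(0, 1_000 * c))
        assert len(base) == len(scaled) == 2
        for (b, _), (s, _) in zip(base, scaled):
            assert abs(s - c * b) <= 5 * c


class TestCumulativeCurve:
    def test_monotone_and_matches_histogram(self, rng):
        lengths = rng.integers(50, 2_500, size=5_000)
        x, y = cumulative_size_curve(lengths, upper=2_000)
        assert np.all(np.diff(y) >= 0)
        assert y[-1] <= 1
        hist, edges = np.histogram(lengths, bins=np.arange(0, 2_050, 50))
        cum_hist = np.cumsum(hist) / len(lengths)
        # numpy's final bin is right-closed; compare it via the inclusive curve
        for edge, mass in zip(edges[1:-1], cum_hist[:-1]):
            assert np.isclose(y[int(edge) - 2], mass)
        assert np.isclose(y[-1], cum_hist[-1])


class TestLengthBins:
    def test_group_direction_matches_profiles(self, default_cohort):
        """Cancer has fewer small (0-250) and more 500-2000 bp circles."""
        _, profiles = default_cohort
        cancer = [p for p in profiles if p.group == "cancer"]
        noncancer = [p for p in profiles if p.group == "noncancer"]
        df = compare_length_bins(cancer, noncancer).set_index("bin")
        assert df.loc["0-250", "cancer_mean"] < df.loc["0-250",
                                                       "noncancer_mean"]
        for b in ("500-1000", "1000-2000"):
            assert df.loc[b, "cancer_mean"] > df.loc[b, "noncancer_mean"]
            assert df.loc[b, "p"] < 0.05

    def test_identical_mixtures_null(self, genome):
        hits = 0
        for seed in range(20):
            spec = CohortSpec(n_cancer=4, n_noncancer=4, circles_mean=800.0,
                              marker_genes=())
            # both groups draw from the same (noncancer) size profile
            spec2 = CohortSpec(
                n_cancer=4, n_noncancer=4, circles_mean=800.0,
                marker_genes=(),
                cancer_centers=(spec.noncancer_center,),
                cancer_sds=(spec.noncancer_sd,),
                cancer_weights=(spec.noncancer_weight,),
                cancer_background_weight=spec.noncancer_background_weight,
                cancer_tail_weight=spec.noncancer_tail_weight)
            profiles = simulate_cohort(genome, spec2, seed=700 + seed)
            df = compare_length_bins(
                [p for p in profiles if p.group == "cancer"],
                [p for p in profiles if p.group == "noncancer"])
            hits += int((df["p"].dropna() < 0.01).any())
        assert hits <= 3

    def test_single_sample_marks_not_applicable(self):
        a = _profile("a", "cancer", lengths=[100, 600, 1_500])
        b = _profile("b", "noncancer", lengths=[120, 130])
        df = compare_length_bins([a], [b])
        assert (df["test"] == "not_applicable").all()
        assert df[["cancer_mean", "noncancer_mean"]].notna().all().all()
        assert df["cancer_mean"].sum() <= 1 + 1e-9

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_length_bins([], [_profile("b", "noncancer", [100])])


class TestChromosomeDistribution:
    def test_all_on_one_chromosome(self):
        p = _profile("s", "cancer", lengths=[100] * 5,
                     segments=[("chr1", 1_000)])
        frac = chromosome_distribution([p], {"chr1": 1_000_000,
                                             "chr2": 1_000_000})
        assert frac.loc["s"].tolist() == [1.0, 0.0]

    def test_fractions_sum_to_one(self, genome, default_cohort):
        _, profiles = default_cohort
        frac = chromosome_distribution(profiles[:5], genome.chrom_lengths)
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_chromosome_raises(self):
        p = _profile("s", "cancer", lengths=[100],
                     segments=[("chrUn", 1_000)])
        with pytest.raises(KeyError):
            chromosome_distribution([p], {"chr1": 1_000_000})

    def test_uniform_origin_density_uniform(self, genome):
        spec = CohortSpec(n_cancer=4, n_noncancer=1, circles_mean=5_000.0,
                          marker_genes=())
        profiles = [p for p in simulate_cohort(genome, spec, seed=13)
                    if p.group == "cancer"]
        frac = chromosome_distribution(profiles, genome.chrom_lengths)
        n = sum(len(p.eccdna) for p in profiles)
        se = np.sqrt(0.5 * 0.5 / n)
        assert np.all(np.abs(frac.mean(axis=0) - 0.5) < 4 * se)

    def test_hotspot_group_flagged(self, genome):
        """Constructed enrichment: noncancer hotspots concentrate density."""
        spec = CohortSpec(n_cancer=6, n_noncancer=6, circles_mean=2_000.0,
                          marker_genes=(), hotspot_loci=3,
                          hotspot_fraction=0.9)
        profiles = simulate_cohort(genome, spec, seed=21)
        frac = chromosome_distribution(profiles, genome.chrom_lengths)
        tests = chromosome_group_tests(frac,
                                       {p.sample_id: p.group
                                        for p in profiles})
        assert (tests["p"] < 0.05).any()


class TestWindowCoverage:
    CHROMS = {"chr1": 5_000_000}

    def test_fully_contained_circle(self):
        p = _profile("s", "cancer", lengths=[1_000],
                     segments=[("chr1", 3_200_000)])
        df = window_coverage([p], self.CHROMS, normalize=False)
        assert df.loc[3, "s"] == 1_000
        assert df["s"].sum() == 1_000

    def test_boundary_split(self):
        p = _profile("s", "cancer", lengths=[1_000],
                     segments=[("chr1", 999_400)])
        df = window_coverage([p], self.CHROMS, normalize=False)
        assert df.loc[0, "s"] == 600
        assert df.loc[1, "s"] == 400

    def test_windows_tile_chromosomes(self, genome):
        df = window_coverage([], genome.chrom_lengths)
        for chrom, ln in genome.chrom_lengths.items():
            sub = df[df["chrom"] == chrom]
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == ln
            assert (sub["start"].iloc[1:].to_numpy()
                    == sub["end"].iloc[:-1].to_numpy()).all()

    def test_uniform_flatter_than_hotspot(self, genome):
        spec_u = CohortSpec(n_cancer=3, n_noncancer=3, circles_mean=3_000.0,
                            marker_genes=(), origin_noncancer="hotspot",
                            hotspot_loci=3, hotspot_fraction=0.9)
        profiles = simulate_cohort(genome, spec_u, seed=17)
        df = window_coverage(profiles, genome.chrom_lengths,
                             window_bp=100_000)

        def median_cv(group):
            cols = [p.sample_id for p in profiles if p.group == group]
            med = df[cols].median(axis=1)
            return med.std() / med.mean()

        assert median_cv("cancer") < median_cv("noncancer")
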