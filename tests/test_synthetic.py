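"""Generator contracts: determinism, mixture fidelity, truth consistency."""

import numpy as np
import pytest
from scipy import stats

from bilecirc.records import EccDNARecord, Segment
from bilecirc.synthetic import (CohortSpec, FeatureDensityError, GenomeSpec,
                                MarkerGeneError, ReadSimParams,
                                random_sequence, sample_ecc_sizes,
                                simulate_cohort, simulate_genome,
                                simulate_rca_reads)


class TestGenome:
    def test_seed_determinism(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=150_000)
        g1 = simulate_genome(spec, seed=1)
        g2 = simulate_genome(spec, seed=1)
        assert g1.chromosomes == g2.chromosomes
        assert [(f.chrom, f.start, f.end, f.id) for f in g1.bundle.genes] == \
            [(f.chrom, f.start, f.end, f.id) for f in g2.bundle.genes]
        g3 = simulate_genome(spec, seed=2)
        assert g3.chromosomes != g1.chromosomes

    def test_infeasible_density_raises(self):
        spec = GenomeSpec(n_chromosomes=1, chrom_length=200_000,
                          genes_per_mb=250, gene_length_range=(5_000, 5_000))
        with pytest.raises(FeatureDensityError):
            simulate_genome(spec, seed=1)

    def test_exons_disjoint_within_gene(self, genome):
        """Brute-force pairwise scan: exons nest in their gene, no overlap."""
        genes = {g.id: g for g in genome.bundle.genes}
        by_gene = {}
        for e in genome.bundle.exons:
            by_gene.setdefault(e.attrs["gene_id"], []).append(e)
        for gid, exons in by_gene.items():
            g = genes[gid]
            for e in exons:
                assert g.start <= e.start < e.end <= g.end
            for a in exons:
                for b in exons:
                    if a is not b:
                        assert a.end <= b.start or b.end <= a.start

    def test_feature_catalog_complete(self, genome):
        b = genome.bundle
        assert len(b.super_enhancers) >= 5
        assert all("closest_gene" in f.attrs for f in b.super_enhancers)
        assert len(b.mirnas) >= 10
        assert len(b.mirna_clusters) >= 2
        for cl in b.mirna_clusters:
            assert len(cl.attrs["members"]) >= 2
            members = {m.id: m for m in b.mirnas}
            for mid in cl.attrs["members"]:
                m = members[mid]
                assert cl.start <= m.start < m.end <= cl.end
        chrom_len = genome.chrom_lengths
        for kind in ("genes", "exons", "introns", "cpg_islands",
                     "super_enhancers", "mirnas", "mirna_clusters"):
            for f in b.features_of(kind):
                assert 0 <= f.start < f.end <= chrom_len[f.chrom]


class TestSizes:
    def test_seed_determinism(self):
        a = sample_ecc_sizes("noncancer", 10, seed=3)
        b = sample_ecc_sizes("noncancer", 10, seed=3)
        assert a.tolist() == b.tolist()

    def test_unknown_group(self):
        with pytest.raises(ValueError):
            sample_ecc_sizes("benign", 10, seed=0)

    def test_minimum_length(self):
        assert sample_ecc_sizes("noncancer", 20_000, seed=1).min() >= 50

    def test_mean_matches_analytic_mixture(self):
        """Empirical mean within 3 SE of the closed-form mixture mean."""
        spec = CohortSpec()
        s = sample_ecc_sizes("cancer", 100_000, spec, seed=7)
        se = s.std() / np.sqrt(len(s))
        # truncation at 50 bp and integer flooring shift the mean < 1 bp
        assert abs(s.mean() - spec.mixture_mean("cancer")) < 3 * se + 1.0

    @pytest.mark.parametrize("group", ["cancer", "noncancer"])
    def test_component_weights_within_3se(self, group):
        spec = CohortSpec()
        weights, _ = spec.mixture(group)
        _, comp = sample_ecc_sizes(group, 100_000, spec, seed=5,
                                   return_components=True)
        for k, w in enumerate(weights):
            emp = (comp == k).mean()
            se = np.sqrt(w * (1 - w) / len(comp))
            assert abs(emp - w) <= 3 * se


class TestCohort:
    def test_emits_all_truth_sets(self, genome):
        spec = CohortSpec(circles_mean=200.0)
        profiles = simulate_cohort(genome, spec, seed=4)
        assert len(profiles) == 28
        assert sum(p.group == "cancer" for p in profiles) == 17
        assert sum(p.group == "noncancer" for p in profiles) == 11
        for p in profiles:
            assert p.serum_cea > 0 and p.serum_ca199 > 0
            for rec in p.eccdna:
                assert rec.length >= 50
                for seg in rec.segments:
                    assert seg.end <= len(genome.chromosomes[seg.chrom])

    def test_missing_marker_gene_raises(self, genome):
        spec = CohortSpec(marker_genes=(("NOT_A_GENE", 8.0),))
        with pytest.raises(MarkerGeneError):
            simulate_cohort(genome, spec, seed=1)

    def test_fold_change_recovered(self, genome, default_cohort):
        """Pooled marker-overlap rates match fold x baseline within their
        binomial sampling bounds (3 SE per group)."""
        spec, profiles = default_cohort
        gene = next(g for g in genome.bundle.genes if g.id == "LINC00598")

        def overlap_counts(group):
            hit = tot = 0
            for p in profiles:
                if p.group != group:
                    continue
                for rec in p.eccdna:
                    tot += 1
                    hit += any(s.chrom == gene.chrom and s.start < gene.end
                               and s.end > gene.start for s in rec.segments)
            return hit, tot

        fold = dict(spec.marker_genes)["LINC00598"]
        for group, expected_rate in (("cancer", fold * spec.marker_baseline),
                                     ("noncancer", spec.marker_baseline)):
            hit, tot = overlap_counts(group)
            se = np.sqrt(expected_rate * (1 - expected_rate) / tot)
            assert abs(hit / tot - expected_rate) <= 3 * se
        # and the point estimate is clearly enriched in cancer
        c_hit, c_tot = overlap_counts("cancer")
        n_hit, n_tot = overlap_counts("noncancer")
        assert (c_hit / c_tot) / (n_hit / n_tot) > fold / 2

    def test_null_fold_change_indistinguishable(self, genome):
        """fold 1 for every marker: proportions carry no group signal."""
        rejections = 0
        for seed in range(20):
            spec = CohortSpec(n_cancer=6, n_noncancer=6, circles_mean=1_000.0,
                              marker_genes=(("LINC00598", 1.0),),
                              marker_baseline=5e-3)
            profiles = simulate_cohort(genome, spec, seed=100 + seed)
            gene = next(g for g in genome.bundle.genes
                        if g.id == "LINC00598")
            props = {"cancer": [], "noncancer": []}
            for p in profiles:
                hit = sum(any(s.chrom == gene.chrom and s.start < gene.end
                              and s.end > gene.start for s in rec.segments)
                          for rec in p.eccdna)
                props[p.group].append(hit / len(p.eccdna))
            pv = stats.mannwhitneyu(props["cancer"], props["noncancer"],
                                    alternative="two-sided").pvalue
            rejections += pv < 0.01
        assert rejections <= 2  # expect 0.2 under the null


class TestReads:
    def test_errorfree_concatenation_identity(self, genome):
        rec = EccDNARecord("c", [Segment("chr1", 10_000, 10_500)])
        params = ReadSimParams(substitution_rate=0, insertion_rate=0,
                               deletion_rate=0, fixed_passes=3,
                               fixed_offset=0, fixed_reads=1)
        rs = simulate_rca_reads([rec], genome, params, seed=1)
        (read,) = rs.reads.values()
        assert len(read) == 1_500
        assert read == genome.circle_sequence(rec) * 3

    def test_two_region_circle_structure(self, genome):
        rec = EccDNARecord("c", [Segment("chr1", 5_000, 5_300),
                                 Segment("chr2", 9_000, 9_200)])
        params = ReadSimParams(substitution_rate=0, insertion_rate=0,
                               deletion_rate=0, fixed_passes=2,
                               fixed_offset=0, fixed_reads=1)
        rs = simulate_rca_reads([rec], genome, params, seed=1)
        (read,) = rs.reads.values()
        unit = genome.circle_sequence(rec)
        assert read == unit * 2
        coords = [(r.tname, r.tstart, r.tend) for r in rs.truth_paf]
        assert coords == [("chr1", 5_000, 5_300), ("chr2", 9_000, 9_200)] * 2

    def test_substitution_rate_within_binomial_bounds(self, genome):
        rec = EccDNARecord("c", [Segment("chr1", 20_000, 20_500)])
        params = ReadSimParams(substitution_rate=0.03, insertion_rate=0,
                               deletion_rate=0, fixed_passes=4,
                               fixed_offset=0, fixed_reads=5)
        rs = simulate_rca_reads([rec], genome, params, seed=5)
        unit = genome.circle_sequence(rec)
        mism = total = 0
        for read in rs.reads.values():
            ref = unit * 4
            assert len(read) == len(ref)
            mism += sum(a != b for a, b in zip(read, ref))
            total += len(ref)
        se = np.sqrt(0.03 * 0.97 / total)
        assert abs(mism / total - 0.03) < 2.58 * se  # 99% bound

    def test_truth_paf_reconstructs_read(self, genome):
        """Error model off: PAF segments re-extracted from the genome
        concatenate to the emitted read exactly."""
        profiles = simulate_cohort(
            genome, CohortSpec(n_cancer=1, n_noncancer=1, circles_mean=30.0),
            seed=6)
        params = ReadSimParams(substitution_rate=0, insertion_rate=0,
                               deletion_rate=0)
        rs = simulate_rca_reads(profiles[0].eccdna, genome, params, seed=2)
        by_read = {}
        for row in rs.truth_paf:
            by_read.setdefault(row.qname, []).append(row)
        for read_id, rows in by_read.items():
            rows.sort(key=lambda r: r.qstart)
            rebuilt = "".join(genome.fetch(r.tname, r.tstart, r.tend, r.strand)
                              for r in rows)
            assert rebuilt == rs.reads[read_id]

    def test_seed_determinism(self, genome):
        rec = EccDNARecord("c", [Segment("chr1", 1_000, 1_400)])
        a = simulate_rca_reads([rec], genome, ReadSimParams(), seed=9)
        b = simulate_rca_reads([rec], genome, ReadSimParams(), seed=9)
        assert a.reads == b.reads
        assert [r.to_line() for r in a.truth_paf] == \
            [r.to_line() for r in b.truth_paf]

    def test_zero_length_circle_rejected(self, genome):
        rec = EccDNARecord("c", [Segment("chr1", 0, 1)])
        rec.segments = []  # force the degenerate state past the constructor
        rec.__dict__["segments"] = []
        with pytest.raises((ValueError, IndexError)):
            simulate_rca_reads([rec], genome, ReadSimParams(), seed=1)


class TestRandomSequence:
    def test_exact_gc_content_and_length(self):
        s = random_sequence(2_500, 0.5, seed=1)
        assert len(s) == 2_500
        assert sum(c in "GC" for c in s) == 1_250

    def test_at_only_boundary(self):
        assert set(random_sequence(4, 0.0, seed=3)) <= {"A", "T"}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            random_sequence(0, 0.5)
        with pytest.raises(ValueError):
            random_sequence(10, 1.5)
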