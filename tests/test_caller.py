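"""Circle-caller behavior: segmentation, unit detection, calling, consensus,
downsampling, and the toy exact aligner."""

import pytest

import edlib

from bilecirc.caller import (AlignmentSegment, SampleReads, align_reads_exact,
                             call_eccdna, consensus_from_passes, detect_unit,
                             downsample_mapped_reads, segment_reads)
from bilecirc.io import PafRecord
from bilecirc.records import EccDNARecord, Segment
from bilecirc.synthetic import (CohortSpec, ReadSimParams, perturb_paf,
                                simulate_cohort, simulate_rca_reads)


def _paf(qname, qstart, qend, tname, tstart, tend, identity=1.0, qlen=10_000,
         tlen=1_000_000):
    alnlen = tend - tstart
    return PafRecord(qname, qlen, qstart, qend, "+", tname, tlen, tstart,
                     tend, int(round(identity * alnlen)), alnlen)


def _aln(read_id, qs, qe, chrom, ts, te, identity=1.0):
    return AlignmentSegment(read_id, qs, qe, chrom, ts, te, "+", identity)


class TestSegmentReads:
    def test_sorted_by_read_start(self):
        rows = [_paf("r", 600, 800, "chr1", 30_600, 30_800),
                _paf("r", 0, 200, "chr1", 30_000, 30_200),
                _paf("r", 400, 600, "chr1", 30_400, 30_600),
                _paf("r", 200, 400, "chr1", 30_200, 30_400)]
        chains = segment_reads(rows)
        assert [s.read_start for s in chains["r"]] == [0, 200, 400, 600]

    def test_same_interval_keeps_higher_identity(self):
        rows = [_paf("r", 0, 200, "chr1", 10_000, 10_200, identity=0.90),
                _paf("r", 0, 200, "chr2", 50_000, 50_200, identity=0.99)]
        chains = segment_reads(rows)
        assert len(chains["r"]) == 1
        assert chains["r"][0].chrom == "chr2"

    def test_chains_match_simulator_truth(self, genome):
        profiles = simulate_cohort(
            genome, CohortSpec(n_cancer=1, n_noncancer=1, circles_mean=40.0),
            seed=3)
        rs = simulate_rca_reads(profiles[0].eccdna, genome, ReadSimParams(),
                                seed=4)
        chains = segment_reads(rs.truth_paf)
        truth = {}
        for row in rs.truth_paf:
            truth.setdefault(row.qname, []).append(
                (row.qstart, row.qend, row.tname, row.tstart, row.tend))
        assert len(chains) >= 100
        for read_id, chain in chains.items():
            got = [(s.read_start, s.read_end, s.chrom, s.ref_start, s.ref_end)
                   for s in chain]
            assert got == sorted(truth[read_id])


class TestDetectUnit:
    A = ("chr1", 10_000, 10_500)
    B = ("chr2", 40_000, 40_300)

    def _chain(self, pattern):
        chain, pos = [], 0
        for name in pattern:
            chrom, ts, te = {"A": self.A, "B": self.B}[name]
            chain.append(_aln("r", pos, pos + (te - ts), chrom, ts, te))
            pos += te - ts
        return chain

    def test_exact_repetition(self):
        det = detect_unit(self._chain("ABABAB"))
        assert det is not None
        assert len(det.unit) == 2
        assert det.passes == 3
        assert det.unit_length == 800

    def test_single_segment_is_one_pass(self):
        det = detect_unit(self._chain("A"))
        assert det is not None and det.passes == 1

    def test_non_repetitive_chain_rejected(self):
        chain = self._chain("ABA")
        chain.append(_aln("r", 1300, 1500, "chr1", 700_000, 700_200))
        assert detect_unit(chain) is None

    def test_jittered_two_pass_read(self, genome, rng):
        rec = EccDNARecord("c", [Segment("chr1", 50_000, 50_400)])
        params = ReadSimParams(fixed_passes=2, fixed_reads=1, seed=0)
        rs = simulate_rca_reads([rec], genome, params, seed=8)
        paf = perturb_paf(rs.truth_paf, 10, seed=9)
        (chain,) = segment_reads(paf).values()
        det = detect_unit(chain)
        assert det is not None and det.passes == 2
        (seg,) = det.unit
        assert abs(seg.start - 50_000) <= 20 and abs(seg.end - 50_400) <= 20


class TestCallEccdna:
    def _reads_for_passes(self, genome, passes_list, offset=0):
        rec = EccDNARecord("c", [Segment("chr1", 70_000, 70_500)])
        reads, chains = {}, {}
        for i, k in enumerate(passes_list):
            params = ReadSimParams(substitution_rate=0, insertion_rate=0,
                                   deletion_rate=0, fixed_passes=k,
                                   fixed_offset=offset, fixed_reads=1)
            rs = simulate_rca_reads([rec], genome, params, seed=20 + i)
            ((rid, seq),) = rs.reads.items()
            reads[f"{rid}|{i}"] = seq
            for row in rs.truth_paf:
                row.qname = f"{rid}|{i}"
            chains.update(segment_reads(rs.truth_paf))
        return rec, chains, reads

    def test_threshold_excludes_single_pass(self, genome):
        rec, chains, reads = self._reads_for_passes(genome, [1, 2, 3, 4])
        result = call_eccdna(chains, reads)
        assert len(result.records) == 1
        assert result.records[0].n_supporting_reads == 3

    def test_zero_reads(self):
        assert call_eccdna({}, {}).records == []

    def test_rotation_invariance(self, genome):
        recs = []
        for offset in (0, 100, 250, 499):
            _, chains, reads = self._reads_for_passes(genome, [3],
                                                      offset=offset)
            result = call_eccdna(chains, reads)
            assert len(result.records) == 1
            recs.append(result.records[0])
        coords = {tuple((s.chrom, s.start, s.end) for s in r.segments)
                  for r in recs}
        assert coords == {(("chr1", 70_000, 70_500),)}

    def test_errorfree_calls_equal_truth_exactly(self, genome):
        profiles = simulate_cohort(
            genome, CohortSpec(n_cancer=1, n_noncancer=1, circles_mean=60.0,
                               chimera_fraction=0.0),
            seed=7)
        truth = profiles[0].eccdna
        params = ReadSimParams(substitution_rate=0, insertion_rate=0,
                               deletion_rate=0, fixed_passes=3)
        rs = simulate_rca_reads(truth, genome, params, seed=5)
        result = call_eccdna(segment_reads(rs.truth_paf), rs.reads)
        called = {tuple((s.chrom, s.start, s.end) for s in r.segments)
                  for r in result.records}
        expected = {tuple((s.chrom, s.start, s.end) for s in t.segments)
                    for t in truth}
        assert called == expected

    def test_merge_idempotence(self, genome):
        profiles = simulate_cohort(
            genome, CohortSpec(n_cancer=1, n_noncancer=1, circles_mean=50.0),
            seed=9)
        rs = simulate_rca_reads(profiles[0].eccdna, genome, ReadSimParams(),
                                seed=6)
        paf = perturb_paf(rs.truth_paf, 10, seed=1)
        chains = segment_reads(paf)
        first = call_eccdna(chains, rs.reads)
        # feed each merged record back as a clean 2-pass chain
        rechains = {}
        for rec in first.records:
            pos, chain = 0, []
            for _ in range(2):
                for seg in rec.segments:
                    chain.append(_aln(rec.id, pos, pos + seg.length,
                                      seg.chrom, seg.start, seg.end))
                    pos += seg.length
            rechains[rec.id] = chain
        second = call_eccdna(rechains, None)
        assert len(second.records) == len(first.records)
        assert {tuple((s.chrom, s.start, s.end) for s in r.segments)
                for r in second.records} == \
            {tuple((s.chrom, s.start, s.end) for s in r.segments)
             for r in first.records}


class TestConsensus:
    def test_requires_two_passes(self):
        with pytest.raises(ValueError):
            consensus_from_passes(["ACGT"])

    def test_majority_corrects_single_substitution(self):
        ref = "ACGTACGTACGTACGTACGT"
        mutated = ref[:10] + ("A" if ref[10] != "A" else "C") + ref[11:]
        assert consensus_from_passes([ref, mutated, ref]) == ref
        # even when the backbone itself carries the error
        assert consensus_from_passes([mutated, ref, ref]) == ref

    def test_errorfree_consensus_equals_reference(self, genome):
        rec = EccDNARecord("c", [Segment("chr1", 30_000, 30_350)])
        params = ReadSimParams(substitution_rate=0, insertion_rate=0,
                               deletion_rate=0, fixed_passes=3,
                               fixed_offset=120, fixed_reads=1)
        rs = simulate_rca_reads([rec], genome, params, seed=2)
        result = call_eccdna(segment_reads(rs.truth_paf), rs.reads)
        assert result.records[0].consensus == genome.circle_sequence(rec)

    def test_consensus_beats_raw_error_rate(self, genome):
        """Multi-pass voting reduces the error rate vs single passes."""
        profiles = simulate_cohort(
            genome, CohortSpec(n_cancer=1, n_noncancer=1, circles_mean=200.0),
            seed=5)
        truth = profiles[0].eccdna[:200]
        rs = simulate_rca_reads(truth, genome, ReadSimParams(pass_p=0.25),
                                seed=9)
        result = call_eccdna(segment_reads(rs.truth_paf), rs.reads)
        truth_by_id = {t.id: t for t in truth}
        cons_err = cons_n = 0
        for rec in result.records:
            t = next((t for t in truth if rec.same_structure(t, 0.95)), None)
            if t is None or rec.consensus is None:
                continue
            ref = genome.circle_sequence(t)
            cons_err += edlib.align(rec.consensus, ref, mode="NW")["editDistance"]
            cons_n += len(ref)
        raw_err = raw_n = 0
        table = {t["read_id"]: t for t in rs.truth_table}
        for rid, seq in list(rs.reads.items())[:150]:
            info = table[rid]
            ref = genome.circle_sequence(truth_by_id[info["circle_id"]])
            rot = ref[info["start_offset"]:] + ref[:info["start_offset"]]
            raw_err += edlib.align(seq[:len(rot)], rot,
                                   mode="NW")["editDistance"]
            raw_n += len(rot)
        assert cons_n > 10_000 and raw_n > 10_000
        assert cons_err / cons_n < raw_err / raw_n


class TestDownsample:
    def _samples(self):
        def chains(n):
            return {f"r{i}": [_aln(f"r{i}", 0, 100, "chr1", 0, 100)]
                    for i in range(n)}
        return [SampleReads("s1", chains(1_000)), SampleReads("s2", chains(600))]

    def test_min_rule(self):
        out = downsample_mapped_reads(self._samples(), seed=0)
        assert [len(s.chains) for s in out] == [600, 600]
        assert all(s.n_mapped == 600 for s in out)

    def test_determinism(self):
        a = downsample_mapped_reads(self._samples(), seed=4)
        b = downsample_mapped_reads(self._samples(), seed=4)
        assert [sorted(s.chains) for s in a] == [sorted(s.chains) for s in b]

    def test_single_sample_unchanged(self):
        s = self._samples()[0]
        (out,) = downsample_mapped_reads([s], seed=1)
        assert sorted(out.chains) == sorted(s.chains)


class TestToyAligner:
    def test_errorfree_alignment_supports_calling(self, small_genome):
        profiles = simulate_cohort(
            small_genome,
            CohortSpec(n_cancer=1, n_noncancer=1, circles_mean=15.0,
                       chimera_fraction=0.0, origin_cancer="uniform"),
            seed=3)
        truth = [t for t in profiles[0].eccdna if t.length >= 200][:8]
        params = ReadSimParams(substitution_rate=0, insertion_rate=0,
                               deletion_rate=0, fixed_passes=3, fixed_reads=2)
        rs = simulate_rca_reads(truth, small_genome, params, seed=1)
        paf = align_reads_exact(small_genome, rs.reads)
        result = call_eccdna(segment_reads(paf), rs.reads)
        for t in truth:
            assert any(r.same_structure(t, 0.9) for r in result.records)
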