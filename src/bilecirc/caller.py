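"""EccDNA calling from read-to-reference alignments.

A rolling-circle concatemer read aligns as an ordered chain of reference
segments that traverses the same segment cycle repeatedly. The caller
groups PAF records per read, detects the minimal repeating unit with
endpoint tolerance, counts complete traversals (passes), keeps reads with
>= 2 passes (the identification threshold), merges multi-read evidence by
reciprocal overlap, and builds a majority-vote consensus sequence across
passes.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io import PafRecord
from .records import EccDNARecord, Segment
from .synthetic import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned block of a read (PAF row distilled)."""

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start or self.ref_end <= self.ref_start:
            raise ValueError("degenerate alignment segment")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


def paf_to_segments(records: list[PafRecord]) -> list[AlignmentSegment]:
    return [AlignmentSegment(r.qname, r.qstart, r.qend, r.tname, r.tstart,
                             r.tend, r.strand, r.identity) for r in records]


def segment_reads(records: list[PafRecord]
                  ) -> dict[str, list[AlignmentSegment]]:
    """Group alignments per read, sorted by read_start, resolving read-space
    conflicts: when two segments cover substantially the same read interval
    (>50% of the shorter), only the higher-identity one survives."""
    by_read: dict[str, list[AlignmentSegment]] = defaultdict(list)
    for seg in paf_to_segments(records):
        by_read[seg.read_id].append(seg)
    out: dict[str, list[AlignmentSegment]] = {}
    for read_id, segs in by_read.items():
        segs.sort(key=lambda s: (s.read_start, -s.identity, s.read_end))
        kept: list[AlignmentSegment] = []
        for seg in segs:
            if kept:
                prev = kept[-1]
                ov = min(prev.read_end, seg.read_end) - max(prev.read_start,
                                                            seg.read_start)
                shorter = min(prev.read_end - prev.read_start,
                              seg.read_end - seg.read_start)
                if ov > 0.5 * shorter:
                    if seg.identity > prev.identity:
                        kept[-1] = seg
                    continue
            kept.append(seg)
        out[read_id] = kept
    return out


# ------------------------------------------------------------------ unit detection

@dataclass
class UnitDetection:
    """Repeating unit of one read's segment chain.

    ``unit`` is the segment cycle in traversal order starting from the
    chain's first segment; ``pass_windows`` are read-coordinate intervals of
    each complete traversal (all sharing the read's rotation phase);
    ``first_offset`` is how far into unit[0] the chain starts.
    """

    unit: list[Segment]
    passes: int
    total_bp: int
    unit_length: int
    pass_windows: list[tuple[int, int]]
    first_offset: int


def _compatible(seg: AlignmentSegment, ext: list, tol: int) -> bool:
    """Same interval within tolerance, or a truncation of it (containment
    with at least one anchored endpoint) - covers rotation-split segments."""
    chrom, strand, start, end = ext
    if seg.chrom != chrom or seg.strand != strand:
        return False
    ds, de = abs(seg.ref_start - start), abs(seg.ref_end - end)
    if ds <= tol and de <= tol:
        return True
    inside = seg.ref_start >= start - tol and seg.ref_end <= end + tol
    contains = seg.ref_start <= start + tol and seg.ref_end >= end - tol
    return (inside or contains) and (ds <= tol or de <= tol)


def detect_unit(chain: list[AlignmentSegment], tol: int = 20,
                coverage_frac: float = 0.95) -> UnitDetection | None:
    """Find the minimal segment cycle the chain traverses.

    Segments are clustered into unit intervals with ``tol`` bp endpoint
    slack (rotation-truncated copies cluster with their full counterpart);
    the cluster-id sequence must then be periodic with the number of
    clusters as period, otherwise the chain is non-repetitive and ``None``
    is returned. The pass count is the number of complete traversals, a
    traversal being complete once ``coverage_frac`` of the unit length is
    covered in order.
    """
    if not chain:
        raise ValueError("empty chain")
    clusters: list[list] = []  # [chrom, strand, start, end]
    members: list[list[tuple[int, int]]] = []
    order: list[int] = []
    for seg in chain:
        for k, ext in enumerate(clusters):
            if _compatible(seg, ext, tol):
                if seg.ref_length > ext[3] - ext[2]:
                    ext[2], ext[3] = seg.ref_start, seg.ref_end
                members[k].append((seg.ref_start, seg.ref_end))
                order.append(k)
                break
        else:
            clusters.append([seg.chrom, seg.strand, seg.ref_start, seg.ref_end])
            members.append([(seg.ref_start, seg.ref_end)])
            order.append(len(clusters) - 1)

    p = len(clusters)
    if any(order[i + p] != order[i] for i in range(len(order) - p)):
        return None
    if order[:p] != list(range(p)):
        return None

    # extent per cluster: per-endpoint median over full-length members,
    # which de-biases aligner endpoint jitter (max-extent would always
    # grow outward)
    unit = []
    for ext, mem in zip(clusters, members):
        max_len = max(e - s for s, e in mem)
        full = [(s, e) for s, e in mem if e - s >= 0.8 * max_len] or mem
        start = int(np.median([s for s, _ in full]))
        end = int(np.median([e for _, e in full]))
        unit.append(Segment(ext[0], start, max(end, start + 1), ext[1]))
    unit_len = sum(s.length for s in unit)
    matched = [min(seg.ref_length, unit[order[i]].length)
               for i, seg in enumerate(chain)]
    total = int(sum(matched))
    passes = int(np.floor(total / unit_len + (1 - coverage_frac)))

    # read-coordinate boundaries at cumulative multiples of the unit length
    windows: list[tuple[int, int]] = []
    cum = np.concatenate(([0], np.cumsum(matched)))
    boundaries = [chain[0].read_start]
    for j in range(1, passes + 1):
        target = j * unit_len
        i = int(np.searchsorted(cum, target, side="left")) - 1
        i = min(i, len(chain) - 1)
        seg = chain[i]
        frac = (target - cum[i]) / matched[i] if matched[i] else 1.0
        frac = min(max(frac, 0.0), 1.0)
        pos = seg.read_start + int(round(frac * (seg.read_end - seg.read_start)))
        boundaries.append(min(pos, chain[-1].read_end))
    windows = list(zip(boundaries[:-1], boundaries[1:]))

    first = chain[0]
    if first.strand == "+":
        first_offset = max(0, first.ref_start - unit[0].start)
    else:
        first_offset = max(0, unit[0].end - first.ref_end)
    return UnitDetection(unit, passes, total, unit_len, windows, first_offset)


# ------------------------------------------------------------------ consensus

def _parse_cigar(cigar: str):
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _align_to_backbone(backbone: str, other: str):
    """Per-backbone-position base of ``other`` ('-' = deleted), plus
    insertions keyed by the backbone gap they precede."""
    res = edlib.align(other, backbone, task="path", mode="NW")
    votes: list[str] = []
    inserts: dict[int, str] = {}
    bi = oi = 0
    for n, op in _parse_cigar(res["cigar"]):
        if op in "=XM":
            votes.extend(other[oi:oi + n])
            bi += n
            oi += n
        elif op == "D":  # backbone base absent from other
            votes.extend("-" * n)
            bi += n
        else:  # I: other bases absent from backbone
            inserts[bi] = inserts.get(bi, "") + other[oi:oi + n]
            oi += n
    return votes, inserts


def consensus_from_passes(pass_seqs: list[str]) -> str:
    """Majority vote across pass sequences; ties go to the first pass.

    The first pass is the voting backbone; other passes contribute a base
    (or a deletion) per backbone position, and majority insertions recover
    bases the backbone itself dropped.
    """
    if len(pass_seqs) < 2:
        raise ValueError("consensus needs >= 2 passes")
    backbone = pass_seqs[0]
    n = len(pass_seqs)
    votes = [[b] for b in backbone]
    ins_votes: dict[int, list[str]] = defaultdict(list)
    for other in pass_seqs[1:]:
        v, ins = _align_to_backbone(backbone, other)
        for i, b in enumerate(v):
            votes[i].append(b)
        for pos, s in ins.items():
            ins_votes[pos].append(s)
    out: list[str] = []
    for i in range(len(backbone) + 1):
        if i in ins_votes:
            best, cnt = _mode(ins_votes[i])
            if cnt > n / 2:  # absent counts as a vote against
                out.append(best)
        if i == len(backbone):
            break
        best, cnt = _mode(votes[i])
        if cnt * 2 == len(votes[i]) and best != backbone[i]:
            best = backbone[i]  # tie-break toward first pass
        if best != "-":
            out.append(best)
    return "".join(out)


def _mode(items: list[str]) -> tuple[str, int]:
    counts: dict[str, int] = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    best = max(counts, key=lambda k: (counts[k], k))
    return best, counts[best]


def consensus_sequence(read_seq: str, detection: UnitDetection,
                       strand: str = "+") -> str:
    """Rotation-phased consensus of one read (majority over its passes).

    The result starts at the unit's traversal start (unit[0] as seen by the
    chain), i.e. still in the read's rotation phase; callers rotate it to
    the canonical circle start via :func:`rotate_to_canonical`.
    """
    if detection.passes < 2:
        raise ValueError("consensus requires >= 2 passes")
    seqs = [read_seq[a:b] for a, b in detection.pass_windows]
    cons = consensus_from_passes(seqs)
    return revcomp(cons) if strand == "-" else cons


def rotate_to_canonical(cons: str, phase: int, unit_len: int) -> str:
    """Rotate a phase-offset consensus so index 0 is circle position 0."""
    if not cons:
        return cons
    shift = int(round(((unit_len - phase) % unit_len) * len(cons) / unit_len))
    shift %= len(cons)
    return cons[shift:] + cons[:shift]


# ------------------------------------------------------------------ calling

@dataclass
class ReadEvidence:
    """Per-read support for a called record (feeds consensus + variants)."""

    read_id: str
    passes: int
    pass_windows: list[tuple[int, int]]
    phase: int  # circle position (canonical rotation) of window starts
    strand: str
    read_seq: str | None = None


@dataclass
class CallResult:
    records: list[EccDNARecord]
    evidence: dict[str, list[ReadEvidence]] = field(default_factory=dict)


def _normalize_strand(unit: list[Segment]) -> tuple[list[Segment], bool]:
    minus = sum(s.strand == "-" for s in unit)
    if minus * 2 <= len(unit):
        return unit, False
    flipped = [Segment(s.chrom, s.start, s.end, "+" if s.strand == "-" else "-")
               for s in reversed(unit)]
    return flipped, True


def _phase_on(segments: list[Segment], first: Segment, first_offset: int) -> int:
    """Circle position of a traversal start on the canonical segment list."""
    cum = 0
    for seg in segments:
        if (seg.chrom == first.chrom and seg.strand == first.strand
                and abs(seg.start - first.start) <= max(50, 0.1 * seg.length)
                and abs(seg.end - first.end) <= max(50, 0.1 * seg.length)):
            return cum + first_offset
        cum += seg.length
    return first_offset  # single-segment circles and fallbacks


def _median_record(grp: list) -> EccDNARecord:
    """Per-endpoint median record over a merge group's candidates."""
    nseg = len(grp[0][0].segments)
    segs = []
    for si in range(nseg):
        proto = grp[0][0].segments[si]
        start = int(np.median([m[0].segments[si].start for m in grp]))
        end = int(np.median([m[0].segments[si].end for m in grp]))
        segs.append(Segment(proto.chrom, start, max(end, start + 1),
                            proto.strand))
    return EccDNARecord("merged", segs, n_passes=max(m[0].n_passes
                                                     for m in grp))


def call_eccdna(chains: dict[str, list[AlignmentSegment]],
                reads: dict[str, str] | None = None,
                min_passes: int = 2, tol: int = 20,
                coverage_frac: float = 0.95,
                merge_reciprocal: float = 0.9,
                build_consensus: bool = True) -> CallResult:
    """Call eccDNA records from per-read chains.

    One candidate per read with passes >= ``min_passes``; candidates from
    different reads merge when segment counts match and every canonical
    segment pair overlaps reciprocally by ``merge_reciprocal``; merged
    coordinates are per-endpoint medians and supporting reads accumulate.
    """
    candidates = []
    for read_id in sorted(chains):
        chain = chains[read_id]
        if not chain:
            continue
        det = detect_unit(chain, tol=tol, coverage_frac=coverage_frac)
        if det is None or det.passes < min_passes:
            continue
        unit_norm, _ = _normalize_strand(det.unit)
        rec = EccDNARecord(read_id, list(unit_norm), n_passes=det.passes)
        candidates.append((rec, det, chain[0], read_id))

    groups: list[list] = [[c] for c in candidates]
    # iterate to a fixpoint: medians move after each merge round
    changed = True
    while changed:
        changed = False
        merged: list[list] = []
        reps: list[EccDNARecord] = []
        for grp in groups:
            rep = _median_record(grp)
            for gi, other_rep in enumerate(reps):
                if other_rep.same_structure(rep, merge_reciprocal, tol=tol):
                    merged[gi].extend(grp)
                    reps[gi] = _median_record(merged[gi])
                    changed = True
                    break
            else:
                merged.append(list(grp))
                reps.append(rep)
        groups = merged

    records: list[EccDNARecord] = []
    evidence: dict[str, list[ReadEvidence]] = {}
    for gi, grp in enumerate(groups):
        proto = _median_record(grp)
        rec_id = f"ecc{gi:05d}"
        rec = EccDNARecord(rec_id, proto.segments,
                           n_passes=max(m[0].n_passes for m in grp),
                           n_supporting_reads=len(grp))
        ev = []
        for cand_rec, det, first_seg, read_id in grp:
            first = Segment(first_seg.chrom, first_seg.ref_start,
                            first_seg.ref_end, first_seg.strand)
            phase = _phase_on(rec.segments, first, det.first_offset)
            ev.append(ReadEvidence(read_id, det.passes, det.pass_windows,
                                   phase, first_seg.strand,
                                   reads.get(read_id) if reads else None))
        evidence[rec_id] = ev
        if build_consensus and reads is not None:
            best = max((e for e in ev if e.read_seq is not None),
                       key=lambda e: e.passes, default=None)
            if best is not None and best.passes >= 2:
                det_best = next(d for cr, d, fs, rid in grp
                                if rid == best.read_id)
                cons = consensus_sequence(best.read_seq, det_best, best.strand)
                rec.consensus = rotate_to_canonical(cons, best.phase,
                                                    rec.length)
        records.append(rec)
    return CallResult(records, evidence)


# ------------------------------------------------------------------ downsampling

@dataclass
class SampleReads:
    """Alignment-level view of one sample before calling."""

    sample_id: str
    chains: dict[str, list[AlignmentSegment]]
    reads: dict[str, str] | None = None
    mapped_read_count: int | None = None

    @property
    def n_mapped(self) -> int:
        return self.mapped_read_count if self.mapped_read_count is not None \
            else len(self.chains)


def downsample_mapped_reads(samples: list[SampleReads],
                            seed: int = 0) -> list[SampleReads]:
    """Downsample every sample to the cohort minimum mapped-read count.

    Sampling is without replacement over sorted read ids, seeded, so the
    retained set is reproducible; eccDNA must be re-called from the
    retained chains afterwards.
    """
    if not samples:
        raise ValueError("no samples")
    target = min(s.n_mapped for s in samples)
    rng = np.random.default_rng(seed)
    out = []
    for s in sorted(samples, key=lambda s: s.sample_id):
        ids = sorted(s.chains)
        if len(ids) > target:
            keep = set(np.asarray(ids, dtype=object)[
                rng.choice(len(ids), size=target, replace=False)])
        else:
            keep = set(ids)
        out.append(SampleReads(
            s.sample_id,
            {rid: s.chains[rid] for rid in sorted(keep)},
            {rid: s.reads[rid] for rid in sorted(keep)} if s.reads else None,
            target))
    return out


# ------------------------------------------------------------------ toy aligner

def align_reads_exact(genome, reads: dict[str, str], k: int = 15,
                      max_hits: int = 4) -> list[PafRecord]:
    """Exact k-mer seed aligner for error-free synthetic reads.

    Indexes the genome's forward strand, chains seeds on a common diagonal
    into maximal segments, and emits PAF. Intended for small synthetic
    genomes and error-free tests only - it is not a long-read aligner.
    """
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome.chromosomes.items():
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]].append((chrom, i))
    chrom_lens = genome.chrom_lengths
    out: list[PafRecord] = []
    for read_id, seq in reads.items():
        hits = []
        for i in range(len(seq) - k + 1):
            locs = index.get(seq[i:i + k], ())
            if 0 < len(locs) <= max_hits:
                for chrom, j in locs:
                    hits.append((i, chrom, j))
        # group by diagonal and chain consecutive seeds
        by_diag: dict[tuple[str, int], list[int]] = defaultdict(list)
        for i, chrom, j in hits:
            by_diag[(chrom, j - i)].append(i)
        segs = []
        for (chrom, diag), positions in by_diag.items():
            positions.sort()
            run_start = prev = positions[0]
            for pos in positions[1:] + [None]:
                if pos is not None and pos <= prev + k:
                    prev = pos
                    continue
                rs, re_ = run_start, prev + k
                segs.append((rs, re_, chrom, rs + diag, re_ + diag))
                if pos is not None:
                    run_start = prev = pos
        segs.sort()
        for rs, re_, chrom, ts, te in segs:
            out.append(PafRecord(read_id, len(seq), rs, re_, "+", chrom,
                                 chrom_lens[chrom], ts, te, re_ - rs,
                                 re_ - rs, 60))
    return out
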