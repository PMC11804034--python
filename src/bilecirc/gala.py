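"""In-silico Gibson-assembly design for large multi-region circles (GALA).

A target circle of one or more genomic segments is partitioned into PCR
fragments that carry the same 20-bp ends as their cyclically adjacent
fragment, so isothermal assembly reconstitutes the circle in order. From
the assembled circle, two linear dsDNA molecules that complement each
other in a split-reversed way (rotations split at 0 and L/2) are designed
for the ligation step, and assembled junctions are verified against the
designed cross-segment sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import Segment


class AmbiguousAssemblyError(ValueError):
    """A 20-bp homology end occurs more than once among fragment ends."""


@dataclass
class Fragment:
    sequence: str
    left_overlap: str
    right_overlap: str
    source: Segment

    @property
    def core(self) -> str:
        """Fragment sequence without the appended downstream overlap."""
        return self.sequence[:-len(self.right_overlap)]


@dataclass
class AssemblyDesign:
    segments: list[Segment]
    fragments: list[Fragment]
    expected_circle: str
    junctions: list[int]  # circle coordinate of each segment boundary
    split_reversed_pair: tuple[str, str]
    overlap_bp: int = 20


def design_fragments(genome, segments: list[Segment],
                     overlap_bp: int = 20) -> AssemblyDesign:
    """Design the GALA fragment set for a target segment chain.

    Fragment i spans segment i plus the first ``overlap_bp`` bases of
    segment i+1 (cyclic), so its right end equals the next fragment's left
    end; a single-segment target self-overlaps. Segments must each be at
    least twice the overlap. Fails loudly when any homology end is
    ambiguous (occurs at more than one junction).
    """
    if not segments:
        raise ValueError("need at least one target segment")
    for seg in segments:
        if seg.length < 2 * overlap_bp:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} shorter than "
                f"2 x overlap ({2 * overlap_bp} bp)")
    seqs = [genome.fetch(s.chrom, s.start, s.end, s.strand) for s in segments]
    circle = "".join(seqs)
    n = len(segments)
    fragments = []
    for i in range(n):
        nxt = seqs[(i + 1) % n]
        frag_seq = seqs[i] + nxt[:overlap_bp]
        fragments.append(Fragment(frag_seq, seqs[i][:overlap_bp],
                                  nxt[:overlap_bp], segments[i]))
    ends = [f.right_overlap for f in fragments]
    if len(set(ends)) != len(ends):
        raise AmbiguousAssemblyError("duplicate 20-bp homology end; "
                                     "assembly order would be ambiguous")
    junctions = [0]
    for s in seqs[:-1]:
        junctions.append(junctions[-1] + len(s))
    return AssemblyDesign(list(segments), fragments, circle, junctions,
                          design_split_reversed(circle), overlap_bp)


def assemble_fragments(fragments: list[Fragment],
                       overlap_bp: int | None = None) -> str:
    """Greedy in-silico assembly joining exact homology ends.

    Starts from the first fragment and repeatedly appends the unique
    fragment whose left end matches the growing molecule's right end;
    closing the circle trims the final overlap. Returns the assembled
    circle (a rotation of the designed one).
    """
    if not fragments:
        raise ValueError("nothing to assemble")
    k = overlap_bp if overlap_bp is not None else len(fragments[0].right_overlap)
    remaining = list(fragments[1:])
    current = fragments[0]
    seq = current.sequence
    while remaining:
        tail = seq[-k:]
        matches = [f for f in remaining if f.left_overlap == tail]
        if len(matches) != 1:
            raise AmbiguousAssemblyError(
                f"{len(matches)} fragments share the end {tail!r}")
        nxt = matches[0]
        remaining.remove(nxt)
        seq = seq[:-k] + nxt.sequence
    if seq[-k:] != fragments[0].left_overlap:
        raise AmbiguousAssemblyError("assembly does not close into a circle")
    return seq[:-k]


def design_split_reversed(circle: str) -> tuple[str, str]:
    """The two linear dsDNA molecules for the ligation step.

    Both are full-length rotations of the circle, split at offset 0 and at
    floor(L/2): each molecule's ends anneal to the other's interior, so
    ligating the pair reconstitutes the circle.
    """
    L = len(circle)
    if L < 4:
        raise ValueError("circle too short to split")
    half = L // 2
    return circle, circle[half:] + circle[:half]


def anneal_check(pair: tuple[str, str], k: int | None = None) -> bool:
    """Each end k-mer of one molecule occurs in the other's interior."""
    a, b = pair
    k = k if k is not None else max(1, min(20, len(a) // 4))
    for mol, other in ((a, b), (b, a)):
        for end in (mol[:k], mol[-k:]):
            if end not in other[1:-1]:
                return False
    return True


def recircularize(pair: tuple[str, str]) -> str:
    """Reconstitute the circle from the split-reversed pair.

    Joins the molecules on their shared halves and returns a rotation of
    the original circle; raises if the pair is inconsistent.
    """
    a, b = pair
    if len(a) != len(b):
        raise ValueError("pair length mismatch")
    half = len(a) // 2
    tail = a[half:]
    if not b.startswith(tail) or not b.endswith(a[:half]):
        raise ValueError("molecules do not complement in a split-reversed way")
    return a


def is_rotation(a: str, b: str) -> bool:
    return len(a) == len(b) and a in b + b


@dataclass
class JunctionReport:
    junction: int
    expected_window: str
    observed_window: str | None
    matches: bool


def verify_junctions(assembled: str, design: AssemblyDesign,
                     window: int = 40) -> list[JunctionReport]:
    """Compare every junction-spanning window of the assembly to the design.

    The assembly may be any rotation of the designed circle: the rotation
    offset is anchored on segment-interior probes (doubled-string search),
    then each junction's ``window`` bp (centered on the breakpoint) is
    compared exactly.
    """
    exp = design.expected_circle
    L = len(exp)
    exp_dbl = exp + exp
    asm_dbl = assembled + assembled
    half = window // 2
    # anchor the rotation on a probe away from every junction
    offset = None
    for seg_i, seg in enumerate(design.segments):
        j = design.junctions[seg_i]
        probe_start = (j + seg.length // 2) % L
        probe = exp_dbl[probe_start:probe_start + min(30, seg.length // 2)]
        if not probe:
            continue
        i = asm_dbl.find(probe)
        if i >= 0 and asm_dbl.find(probe, i + 1) >= len(assembled):
            offset = (i - probe_start) % len(assembled)
            break
    reports = []
    for j in design.junctions:
        expected = exp_dbl[(j - half) % L:(j - half) % L + window]
        if offset is None or len(assembled) < window:
            reports.append(JunctionReport(j, expected, None, False))
            continue
        a0 = (j - half + offset) % len(assembled)
        observed = asm_dbl[a0:a0 + window]
        reports.append(JunctionReport(j, expected, observed,
                                      observed == expected))
    return reports
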