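"""SNV detection on called circles and COSMIC-like tiering.

The caller exposes, per supporting read, the read-coordinate windows of
each pass. Every pass is aligned (edlib, global) against the
rotation-phased reference unit sequence, giving a per-pass base at each
reference position. A site is called when at least ``min_reads``
supporting reads each show the same alternative base in at least
``min_pass_fraction`` of their passes - exploiting the internal
redundancy of rolling-circle reads the way a dedicated long-read SNV
caller would use multiple reads. Substitutions only; positions are
0-based internally and 1-based in VCF and descriptors.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

from .caller import CallResult, _align_to_backbone
from .records import EccDNARecord

CANCER_TIERS = {"1", "2", "3"}
_DESCRIPTOR_RE = re.compile(r"^g\.([ACGT])(\d+)([ACGT])$")


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    supporting_passes: int
    total_passes: int
    supporting_reads: int
    ecc_id: str
    tier: str | None = None
    cosmic_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if not 0 < self.supporting_passes <= self.total_passes:
            raise ValueError("bad pass support")

    @property
    def cancer_related(self) -> bool:
        return self.tier in CANCER_TIERS

    @property
    def descriptor(self) -> str:
        return format_variant_descriptor(self.pos, self.ref, self.alt)


def _circle_position_map(record: EccDNARecord) -> list[tuple[str, int]]:
    """Circle coordinate -> (chrom, genomic 0-based position)."""
    out = []
    for seg in record.segments:
        if seg.strand == "+":
            out.extend((seg.chrom, p) for p in range(seg.start, seg.end))
        else:
            out.extend((seg.chrom, p) for p in range(seg.end - 1,
                                                     seg.start - 1, -1))
    return out


def call_variants(result: CallResult, genome, min_reads: int = 2,
                  min_pass_fraction: float = 0.8,
                  length_tolerance: float = 0.1) -> list[VariantRecord]:
    """Multi-pass consensus SNV calling over all records of a call result.

    ``genome`` must provide ``circle_sequence(record)``. Reads whose
    length is inconsistent with the unit beyond ``length_tolerance`` are
    skipped. Calling is rotation-invariant: per-read phases map every
    pass back to the same genomic coordinates.
    """
    variants: list[VariantRecord] = []
    for rec in result.records:
        ref_seq = genome.circle_sequence(rec)
        L = len(ref_seq)
        pos_map = _circle_position_map(rec)
        # (circle pos, alt) -> list of (alt passes, total passes) per read
        support: dict[tuple[int, str], list[tuple[int, int]]] = defaultdict(list)
        for ev in result.evidence.get(rec.id, []):
            if ev.read_seq is None or ev.passes < 2:
                continue
            phase = ev.phase % L
            ref_rot = ref_seq[phase:] + ref_seq[:phase]
            counts: dict[int, dict[str, int]] = defaultdict(
                lambda: defaultdict(int))
            n_pass = 0
            for a, b in ev.pass_windows:
                pass_seq = ev.read_seq[a:b]
                if abs(len(pass_seq) - L) > length_tolerance * L:
                    continue
                n_pass += 1
                votes, _ = _align_to_backbone(ref_rot, pass_seq)
                for j, base in enumerate(votes):
                    if base in "ACGT" and base != ref_rot[j]:
                        counts[(j + phase) % L][base] += 1
            if n_pass < 2:
                continue
            for cpos, alts in counts.items():
                alt, n_alt = max(alts.items(), key=lambda kv: (kv[1], kv[0]))
                if n_alt >= min_pass_fraction * n_pass:
                    support[(cpos, alt)].append((n_alt, n_pass))
        for (cpos, alt), reads in support.items():
            if len(reads) < min_reads:
                continue
            chrom, gpos = pos_map[cpos]
            variants.append(VariantRecord(
                chrom, gpos + 1, ref_seq[cpos], alt,
                supporting_passes=sum(a for a, _ in reads),
                total_passes=sum(t for _, t in reads),
                supporting_reads=len(reads), ecc_id=rec.id))
    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt, v.ecc_id))
    return variants


# ------------------------------------------------------------------ descriptors

def parse_variant_descriptor(text: str) -> tuple[int, str, str]:
    """Parse ``g.<REF><pos><ALT>`` (e.g. ``g.T42981054C``) -> (pos, ref, alt)."""
    m = _DESCRIPTOR_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed variant descriptor: {text!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref == alt:
        raise ValueError(f"descriptor ref equals alt: {text!r}")
    return pos, ref, alt


def format_variant_descriptor(pos: int, ref: str, alt: str) -> str:
    return f"g.{ref}{pos}{alt}"


# ------------------------------------------------------------------ tiers

def load_cosmic_table(rows) -> dict[tuple[str, int, str, str], tuple[str, float]]:
    """(chrom, pos 1-based, ref, alt) -> (tier, frequency); duplicate keys
    with conflicting payloads raise."""
    table: dict[tuple[str, int, str, str], tuple[str, float]] = {}
    for chrom, pos, ref, alt, tier, freq in rows:
        key = (str(chrom), int(pos), str(ref), str(alt))
        val = (str(tier), float(freq))
        if key in table and table[key] != val:
            raise ValueError(f"conflicting COSMIC rows for {key}")
        table[key] = val
    return table


def annotate_tiers(variants: list[VariantRecord], cosmic_table: dict
                   ) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Assign tier/frequency by exact key join; unmatched stay 'unknown'.

    Returns (all variants, the cancer-related subset: tiers 1-3 only;
    'other'/'unknown' never count).
    """
    for v in variants:
        hit = cosmic_table.get((v.chrom, v.pos, v.ref, v.alt))
        if hit is None:
            v.tier = "unknown"
            v.cosmic_frequency = None
        else:
            v.tier, v.cosmic_frequency = hit
    return variants, [v for v in variants if v.cancer_related]


def primer_window(genome, chrom: str, pos: int, flank: int = 150) -> str:
    """Reference window of +/- ``flank`` bp around a 1-based site, for
    outward-PCR/Sanger export; no thermodynamic primer design."""
    seq = genome.chromosomes[chrom]
    lo = max(0, pos - 1 - flank)
    return seq[lo:min(len(seq), pos + flank)]
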