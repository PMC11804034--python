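"""Readers and writers for the plain-text formats the pipeline speaks.

PAF is the caller's alignment input (minimap2-style 12 mandatory columns
plus SAM-like typed tags). FASTA/FASTQ go through Biopython where parsing
matters; writing is plain text. SAM input is converted to PAF-equivalent
segments through pysam. All intervals on disk follow the native convention
of each format (BED/PAF 0-based half-open, GFF3/VCF 1-based).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .annotation import AnnotationBundle, Feature

log = logging.getLogger("bilecirc")


# ---------------------------------------------------------------- PAF

@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int = 60
    tags: dict = field(default_factory=dict)

    @property
    def identity(self) -> float:
        return self.nmatch / self.alnlen if self.alnlen else 0.0

    def to_line(self) -> str:
        cols = [self.qname, self.qlen, self.qstart, self.qend, self.strand,
                self.tname, self.tlen, self.tstart, self.tend,
                self.nmatch, self.alnlen, self.mapq]
        for key, val in self.tags.items():
            code = "f" if isinstance(val, float) else (
                "i" if isinstance(val, int) else "Z")
            cols.append(f"{key}:{code}:{val}")
        return "\t".join(str(c) for c in cols)


def parse_paf_line(line: str) -> PafRecord:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"PAF line has {len(f)} columns, expected >= 12")
    tags = {}
    for tag in f[12:]:
        key, code, val = tag.split(":", 2)
        tags[key] = {"i": int, "f": float}.get(code, str)(val)
    rec = PafRecord(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[6]), int(f[7]), int(f[8]),
                    int(f[9]), int(f[10]), int(f[11]), tags)
    if rec.strand not in "+-" or rec.qend <= rec.qstart or rec.tend <= rec.tstart:
        raise ValueError("malformed PAF coordinates/strand")
    return rec


def read_paf(source: str | Path | Iterable[str]) -> tuple[list[PafRecord], int]:
    """Parse PAF; malformed lines are skipped with a logged warning.

    Returns (records, number of skipped lines).
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    records, skipped = [], 0
    for line in lines:
        if not line.strip():
            continue
        try:
            records.append(parse_paf_line(line))
        except (ValueError, IndexError) as exc:
            skipped += 1
            log.warning("skipping malformed PAF line: %s", exc)
    if skipped:
        log.warning("%d malformed PAF lines skipped", skipped)
    return records, skipped


def write_paf(records: Iterable[PafRecord], path: str | Path) -> None:
    Path(path).write_text("".join(r.to_line() + "\n" for r in records))


def sam_to_paf(path: str | Path) -> list[PafRecord]:
    """Convert SAM alignments to PAF-equivalent records (read-only support)."""
    import pysam

    out: list[PafRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            qlen = aln.infer_read_length() or aln.query_length
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            alnlen = aln.query_alignment_length
            out.append(PafRecord(
                aln.query_name, qlen,
                aln.query_alignment_start, aln.query_alignment_end,
                "-" if aln.is_reverse else "+",
                aln.reference_name, sam.get_reference_length(aln.reference_name),
                aln.reference_start, aln.reference_end,
                max(alnlen - nm, 0), alnlen, aln.mapping_quality))
    return out


# ---------------------------------------------------------------- FASTA / FASTQ

def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: dict[str, str], path: str | Path, qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads.items():
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_fastq(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


# ---------------------------------------------------------------- BED / GFF3

def write_bed(rows: Iterable[tuple], path: str | Path) -> None:
    """Write BED-like rows (tuples of arbitrary width >= 3)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def read_bed(path: str | Path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.strip() and not line.startswith(("#", "track", "browser")):
            rows.append(line.split("\t"))
    return rows


def bed_to_features(path: str | Path, attr_cols: dict[int, str] | None = None
                    ) -> list[Feature]:
    """BED rows to Feature objects; column 3 is the id, ``attr_cols`` maps
    extra 0-based column indices to attribute names."""
    feats = []
    for row in read_bed(path):
        attrs = {}
        for idx, name in (attr_cols or {}).items():
            if idx < len(row):
                val = row[idx]
                attrs[name] = val.split(",") if name == "members" else val
        feats.append(Feature(row[0], int(row[1]), int(row[2]),
                             row[3] if len(row) > 3 else f"{row[0]}:{row[1]}",
                             attrs))
    return feats


def write_gff3(bundle: AnnotationBundle, path: str | Path) -> None:
    """Gene models (gene/exon) as GFF3; introns are implied by exon gaps."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes:
            strand = g.attrs.get("strand", "+")
            fh.write(f"{g.chrom}\tbilecirc\tgene\t{g.start + 1}\t{g.end}\t."
                     f"\t{strand}\t.\tID={g.id}\n")
        for e in bundle.exons:
            strand = e.attrs.get("strand", "+")
            fh.write(f"{e.chrom}\tbilecirc\texon\t{e.start + 1}\t{e.end}\t."
                     f"\t{strand}\t.\tID={e.id};Parent={e.attrs['gene_id']}\n")


def read_gff3_genes(path: str | Path) -> tuple[list[Feature], list[Feature], list[Feature]]:
    """Parse gene/exon records; derive introns as within-gene exon gaps."""
    genes, exons = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        feat = Feature(f[0], int(f[3]) - 1, int(f[4]), attrs.get("ID", "."),
                       {"strand": f[6]})
        if f[2] == "gene":
            genes.append(feat)
        elif f[2] == "exon":
            feat.attrs["gene_id"] = attrs.get("Parent", ".")
            exons.append(feat)
    introns = derive_introns(genes, exons)
    return genes, exons, introns


def derive_introns(genes: list[Feature], exons: list[Feature]) -> list[Feature]:
    introns = []
    by_gene: dict[str, list[Feature]] = {}
    for e in exons:
        by_gene.setdefault(e.attrs["gene_id"], []).append(e)
    for g in genes:
        exs = sorted(by_gene.get(g.id, []), key=lambda e: e.start)
        for i in range(len(exs) - 1):
            if exs[i + 1].start > exs[i].end:
                introns.append(Feature(g.chrom, exs[i].end, exs[i + 1].start,
                                       f"intron:{g.id}.{i + 1}",
                                       {"gene_id": g.id}))
    return introns


# ---------------------------------------------------------------- TSV / JSON

def write_tsv(rows: Iterable[Iterable], path: str | Path,
              header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------- VCF 4.2

VCF_HEADER = """##fileformat=VCFv4.2
##source=bilecirc
##INFO=<ID=ECC,Number=1,Type=String,Description="eccDNA record id">
##INFO=<ID=PASSES,Number=1,Type=String,Description="supporting passes/total passes">
##INFO=<ID=READS,Number=1,Type=Integer,Description="supporting reads">
##INFO=<ID=TIER,Number=1,Type=String,Description="COSMIC-like tier">
##INFO=<ID=COSMIC_FREQ,Number=1,Type=Float,Description="frequency in the lookup table">
"""


def write_vcf(variants: Iterable, path: str | Path,
              contigs: dict[str, int] | None = None) -> None:
    """``variants`` are VariantRecord objects from the variants module."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = (f"ECC={v.ecc_id};PASSES={v.supporting_passes}/"
                    f"{v.total_passes};READS={v.supporting_reads}")
            if v.tier is not None:
                info += f";TIER={v.tier}"
            if v.cosmic_frequency is not None:
                info += f";COSMIC_FREQ={v.cosmic_frequency}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path) -> Iterator[dict]:
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
        yield {"chrom": f[0], "pos": int(f[1]), "ref": f[3], "alt": f[4],
               "info": info}
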