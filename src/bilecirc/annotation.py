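"""Class annotation of eccDNA records.

Implements the paper-derived eccDNA classes: element labels by priority,
eccGene (overlap with exon/intron), eccEnhancer / eccMIR / eccMIR-cluster
(intact-feature containment), group-specific feature sets, and cancer-gene
flags. Interval lookups use interval trees; tests compare against a
quadratic brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .records import EccDNARecord, Segment

DEFAULT_PRIORITY = ("promoter", "exon", "intron", "UTR", "CpG", "intergenic")


@dataclass(frozen=True)
class Feature:
    """A named genomic interval with optional attributes.

    ``attrs`` carries class-specific extras, e.g. ``gene_id`` for exons and
    introns, ``closest_gene`` for super-enhancers, ``members`` for miRNA
    clusters.
    """

    chrom: str
    start: int
    end: int
    id: str
    attrs: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationBundle:
    """All interval features consumed by the annotation stage."""

    genes: list[Feature] = field(default_factory=list)
    exons: list[Feature] = field(default_factory=list)
    introns: list[Feature] = field(default_factory=list)
    promoters: list[Feature] = field(default_factory=list)
    utrs: list[Feature] = field(default_factory=list)
    cpg_islands: list[Feature] = field(default_factory=list)
    super_enhancers: list[Feature] = field(default_factory=list)
    mirnas: list[Feature] = field(default_factory=list)
    mirna_clusters: list[Feature] = field(default_factory=list)
    cancer_genes: dict[str, str] = field(default_factory=dict)  # id -> role

    def __post_init__(self) -> None:
        self._trees: dict[str, dict[str, IntervalTree]] = {}

    def derive_promoters(self, flank: int = 1000) -> None:
        """Fallback when no promoter track is supplied: TSS +/- ``flank``."""
        if self.promoters:
            return
        proms = []
        for g in self.genes:
            tss = g.start if g.attrs.get("strand", "+") == "+" else g.end
            proms.append(
                Feature(g.chrom, max(0, tss - flank), tss + flank,
                        f"promoter:{g.id}", {"gene_id": g.id})
            )
        self.promoters = proms
        self._trees.pop("promoters", None)

    def features_of(self, kind: str) -> list[Feature]:
        return getattr(self, kind)

    def tree(self, kind: str) -> dict[str, IntervalTree]:
        """Per-chromosome interval tree for one feature class (cached)."""
        if kind not in self._trees:
            per_chrom: dict[str, IntervalTree] = {}
            for f in self.features_of(kind):
                per_chrom.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
            self._trees[kind] = per_chrom
        return self._trees[kind]

    def overlapping(self, kind: str, seg: Segment) -> list[Feature]:
        tree = self.tree(kind).get(seg.chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(seg.start, seg.end)),
                      key=lambda f: (f.start, f.end, f.id))


@dataclass
class EccAnnotation:
    """Per-record class assignment."""

    ecc_id: str
    element_label: str
    is_eccgene: bool = False
    gene_ids: list[str] = field(default_factory=list)
    is_eccenhancer: bool = False
    enhancer_ids: list[str] = field(default_factory=list)
    enhancer_target_genes: list[str] = field(default_factory=list)
    is_eccmir: bool = False
    mirna_ids: list[str] = field(default_factory=list)
    is_eccmir_cluster: bool = False
    cluster_ids: list[str] = field(default_factory=list)
    cancer_gene_hits: dict[str, str] = field(default_factory=dict)


_ELEMENT_KIND = {
    "promoter": "promoters",
    "exon": "exons",
    "intron": "introns",
    "UTR": "utrs",
    "CpG": "cpg_islands",
}


def annotate_element(record: EccDNARecord, bundle: AnnotationBundle,
                     priority: tuple[str, ...] = DEFAULT_PRIORITY) -> str:
    """Highest-priority element class overlapping any segment by >= 1 bp.

    ``intergenic`` is the fall-through when nothing overlaps; it must be the
    last entry of the priority order.
    """
    for label in priority:
        if label == "intergenic":
            continue
        kind = _ELEMENT_KIND[label]
        if any(bundle.overlapping(kind, seg) for seg in record.segments):
            return label
    return "intergenic"


def find_eccgenes(records: list[EccDNARecord],
                  bundle: AnnotationBundle) -> dict[str, list[str]]:
    """eccGene flags: >= 1 bp overlap with any exon or intron.

    Returns ecc id -> sorted gene ids (empty list means not an eccGene).
    Promoter-only overlap does not qualify.
    """
    out: dict[str, list[str]] = {}
    for rec in records:
        hits: set[str] = set()
        for seg in rec.segments:
            for kind in ("exons", "introns"):
                for f in bundle.overlapping(kind, seg):
                    hits.add(f.attrs.get("gene_id", f.id))
        out[rec.id] = sorted(hits)
    return out


def find_intact_features(records: list[EccDNARecord], features: list[Feature],
                         allow_junction_spanning: bool = False) -> dict[str, list[str]]:
    """Features fully contained within the record.

    Default ("intact") rule: the entire feature interval lies inside a single
    segment. With ``allow_junction_spanning`` a feature may instead be
    reconstituted across the circular junction of two adjacent segments that
    are reference-contiguous.
    """
    tree: dict[str, IntervalTree] = {}
    for f in features:
        tree.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    out: dict[str, list[str]] = {}
    for rec in records:
        hits: set[str] = set()
        for seg in rec.segments:
            t = tree.get(seg.chrom)
            if t is None:
                continue
            for iv in t.overlap(seg.start, seg.end):
                f = iv.data
                if seg.start <= f.start and f.end <= seg.end:
                    hits.add(f.id)
        if allow_junction_spanning:
            for a, b in rec.junctions:
                if a.chrom != b.chrom or a is b:
                    continue
                # reference-adjacent pair forming one contiguous interval
                if a.end == b.start:
                    joined = Segment(a.chrom, a.start, b.end, a.strand)
                elif b.end == a.start:
                    joined = Segment(a.chrom, b.start, a.end, a.strand)
                else:
                    continue
                t = tree.get(joined.chrom)
                if t is None:
                    continue
                for iv in t.overlap(joined.start, joined.end):
                    f = iv.data
                    if joined.start <= f.start and f.end <= joined.end:
                        hits.add(f.id)
        out[rec.id] = sorted(hits)
    return out


def annotate_records(records: list[EccDNARecord], bundle: AnnotationBundle,
                     priority: tuple[str, ...] = DEFAULT_PRIORITY,
                     allow_junction_spanning: bool = False) -> dict[str, EccAnnotation]:
    """Full per-record annotation across all classes."""
    eccgene = find_eccgenes(records, bundle)
    enh = find_intact_features(records, bundle.super_enhancers,
                               allow_junction_spanning)
    mir = find_intact_features(records, bundle.mirnas, allow_junction_spanning)
    clus = find_intact_features(records, bundle.mirna_clusters,
                                allow_junction_spanning)
    enh_by_id = {f.id: f for f in bundle.super_enhancers}
    out: dict[str, EccAnnotation] = {}
    for rec in records:
        genes = eccgene[rec.id]
        ann = EccAnnotation(
            ecc_id=rec.id,
            element_label=annotate_element(rec, bundle, priority),
            is_eccgene=bool(genes),
            gene_ids=genes,
            is_eccenhancer=bool(enh[rec.id]),
            enhancer_ids=enh[rec.id],
            enhancer_target_genes=sorted(
                {enh_by_id[e].attrs.get("closest_gene", "") for e in enh[rec.id]}
                - {""}
            ),
            is_eccmir=bool(mir[rec.id]),
            mirna_ids=mir[rec.id],
            is_eccmir_cluster=bool(clus[rec.id]),
            cluster_ids=clus[rec.id],
            cancer_gene_hits={g: bundle.cancer_genes[g] for g in genes
                              if g in bundle.cancer_genes},
        )
        out[rec.id] = ann
    return out


def group_specific_features(cancer_hits: list[set[str]],
                            noncancer_hits: list[set[str]]) -> dict[str, object]:
    """Partition feature ids into shared / cancer-specific / noncancer-specific.

    Each argument is a list of per-sample sets of detected feature ids for
    one class (e.g. intact super-enhancer ids per sample). A feature is
    group-specific iff seen in >= 1 sample of that group and in none of the
    other group.
    """
    in_cancer = set().union(*cancer_hits) if cancer_hits else set()
    in_noncancer = set().union(*noncancer_hits) if noncancer_hits else set()
    union = in_cancer | in_noncancer
    shared = in_cancer & in_noncancer
    return {
        "shared": sorted(shared),
        "cancer_specific": sorted(in_cancer - in_noncancer),
        "noncancer_specific": sorted(in_noncancer - in_cancer),
        "shared_fraction": (len(shared) / len(union)) if union else 0.0,
    }


def annotate_cancer_genes(gene_hits: dict[str, list[str]],
                          table: dict[str, str]) -> dict[str, dict[str, str]]:
    """Join eccGene hits against the cancer-gene role table.

    ``table`` maps gene id -> role (oncogene | tumor suppressor). Returns
    ecc id -> {gene id: role} for the listed genes only.
    """
    return {
        ecc_id: {g: table[g] for g in genes if g in table}
        for ecc_id, genes in gene_hits.items()
    }


def load_cancer_gene_table(rows: list[tuple[str, str]]) -> dict[str, str]:
    """Build the gene->role lookup, rejecting conflicting duplicates."""
    table: dict[str, str] = {}
    for gene, role in rows:
        if gene in table and table[gene] != role:
            raise ValueError(f"conflicting roles for {gene}: "
                             f"{table[gene]!r} vs {role!r}")
        table[gene] = role
    return table
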