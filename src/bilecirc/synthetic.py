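"""Synthetic reference world, eccDNA cohorts and rolling-circle reads.

The generator emulates the descriptive structure reported for bile
cell-free eccDNA: a cancer size mixture with six Gaussian peaks
(~200/380/560/740/950/1150 bp), a small-size-skewed noncancer profile,
~99% of circles under 2 kb, whole-genome origin in cancer versus locus
preference in noncancer, marker-gene proportion enrichment in cancer, and
phi29-style concatemer reads whose pass count is >= 1 with substitution
and indel errors. Everything is driven by numpy Generators seeded
explicitly, so repeat calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .annotation import AnnotationBundle, Feature
from .records import EccDNARecord, SampleProfile, Segment
from . import io as bio

_COMPL = str.maketrans("ACGT", "TGCA")
_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_IDX[ord(_b)] = _i
_IDX_TO_BASE = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


class FeatureDensityError(ValueError):
    """Requested feature footprint does not fit the genome."""


class MarkerGeneError(KeyError):
    """A marker gene named in the cohort spec is absent from the genome."""


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ------------------------------------------------------------------ genome

@dataclass
class GenomeSpec:
    """Desk-scale stand-in for a reference genome plus feature catalog."""

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.41
    genes_per_mb: int = 40
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    exons_per_gene: tuple[int, int] = (2, 6)
    cpg_per_mb: int = 20
    cpg_length_range: tuple[int, int] = (300, 1_500)
    enhancers_per_mb: int = 4
    enhancer_length_range: tuple[int, int] = (5_000, 15_000)
    mirnas_per_mb: int = 12
    mirna_length_range: tuple[int, int] = (80, 120)
    clusters_per_genome: int = 2
    cluster_size_range: tuple[int, int] = (2, 4)
    named_genes: tuple[str, ...] = ("LINC00598", "CELF2", "NELL1", "PODXL", "ZBED1")
    n_cancer_genes: int = 10
    n_cosmic_sites: int = 30
    promoter_flank: int = 1_000
    utr_length: int = 150

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if not (100_000 <= self.chrom_length <= 5_000_000):
            raise ValueError("chromosome length must be in [100 kb, 5 Mb]")


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    bundle: AnnotationBundle
    cosmic_rows: list[tuple]  # (chrom, pos 1-based, ref, alt, tier, frequency)
    config: dict

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.chromosomes[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)

    def circle_sequence(self, record: EccDNARecord) -> str:
        return "".join(self.fetch(s.chrom, s.start, s.end, s.strand)
                       for s in record.segments)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bio.write_fasta(self.chromosomes, outdir / "genome.fa")
        bio.write_gff3(self.bundle, outdir / "genes.gff3")
        b = self.bundle
        bio.write_bed(((f.chrom, f.start, f.end, f.id) for f in b.promoters),
                      outdir / "promoters.bed")
        bio.write_bed(((f.chrom, f.start, f.end, f.id) for f in b.cpg_islands),
                      outdir / "cpg.bed")
        bio.write_bed(((f.chrom, f.start, f.end, f.id, 0, "+",
                        f.attrs["closest_gene"]) for f in b.super_enhancers),
                      outdir / "super_enhancers.bed")
        bio.write_bed(((f.chrom, f.start, f.end, f.id) for f in b.mirnas),
                      outdir / "mirnas.bed")
        bio.write_bed(((f.chrom, f.start, f.end, f.id, 0, "+",
                        ",".join(f.attrs["members"])) for f in b.mirna_clusters),
                      outdir / "mirna_clusters.bed")
        bio.write_tsv(sorted(b.cancer_genes.items()), outdir / "cancer_genes.tsv",
                      header=["gene_id", "role"])
        bio.write_tsv(self.cosmic_rows, outdir / "cosmic_tiers.tsv",
                      header=["chrom", "pos", "ref", "alt", "tier", "frequency"])
        bio.write_json(self.config, outdir / "genome_config.json")


def _place_nonoverlapping(rng: np.random.Generator, span: int,
                          lengths: np.ndarray, offset: int = 0) -> np.ndarray:
    """Random non-overlapping starts for ``lengths`` inside [offset, offset+span)."""
    total = int(lengths.sum())
    free = span - total
    if free < max(1, int(0.05 * span)):
        raise FeatureDensityError(
            f"{len(lengths)} features totalling {total} bp do not fit in "
            f"{span} bp with breathing room")
    gaps = rng.multinomial(free, np.full(len(lengths) + 1, 1.0 / (len(lengths) + 1)))
    starts = offset + np.cumsum(gaps[:-1]) + np.concatenate(([0], np.cumsum(lengths[:-1])))
    return starts.astype(int)


def simulate_genome(spec: GenomeSpec | None = None, seed: int = 1) -> SyntheticGenome:
    """Build the toy genome: sequence plus a full feature catalog.

    Gene models carry exons spanning the gene (introns implied), UTRs at
    both gene ends, promoters at TSS +/- flank, and independent CpG,
    super-enhancer and miRNA tracks (miRNAs partly organised in clusters).
    Raises :class:`FeatureDensityError` when the request cannot fit.
    """
    spec = spec or GenomeSpec()
    rng = _rng(seed)
    mb = spec.chrom_length / 1e6
    p = np.array([(1 - spec.gc_fraction) / 2, spec.gc_fraction / 2,
                  spec.gc_fraction / 2, (1 - spec.gc_fraction) / 2])

    chromosomes: dict[str, str] = {}
    bundle = AnnotationBundle()
    mir_counter = 0
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        idx = rng.choice(4, size=spec.chrom_length, p=p)
        chromosomes[chrom] = "".join(_IDX_TO_BASE[idx])

        # --- genes with exons/introns/UTRs
        n_genes = max(1, int(round(spec.genes_per_mb * mb)))
        glens = rng.integers(*spec.gene_length_range, size=n_genes,
                             endpoint=True)
        gstarts = _place_nonoverlapping(rng, spec.chrom_length, glens)
        for gi, (gs, gl) in enumerate(zip(gstarts, glens)):
            gid = f"GENE_{chrom}_{gi:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            gene = Feature(chrom, int(gs), int(gs + gl), gid, {"strand": strand})
            bundle.genes.append(gene)
            n_ex = int(rng.integers(*spec.exons_per_gene, endpoint=True))
            ex_total = int(min(gl * 0.6, n_ex * 400))
            ex_lens = np.maximum(50, rng.multinomial(
                ex_total, np.full(n_ex, 1.0 / n_ex)))
            inner = int(gl) - int(ex_lens.sum())
            # exons anchored at both gene ends; gaps only between exons
            if n_ex > 1:
                igaps = rng.multinomial(inner, np.full(n_ex - 1, 1.0 / (n_ex - 1)))
            else:
                igaps = np.array([], dtype=int)
            pos = int(gs)
            for ei, el in enumerate(ex_lens):
                bundle.exons.append(Feature(chrom, pos, pos + int(el),
                                            f"{gid}.exon{ei + 1}",
                                            {"gene_id": gid, "strand": strand}))
                pos += int(el) + (int(igaps[ei]) if ei < len(igaps) else 0)
            ul = min(spec.utr_length, int(ex_lens[0]))
            bundle.utrs.append(Feature(chrom, int(gs), int(gs) + ul,
                                       f"{gid}.5utr", {"gene_id": gid}))
            ul = min(spec.utr_length, int(ex_lens[-1]))
            bundle.utrs.append(Feature(chrom, int(gs + gl) - ul, int(gs + gl),
                                       f"{gid}.3utr", {"gene_id": gid}))

        # --- CpG islands (independent of genes, as in real annotation)
        n_cpg = int(round(spec.cpg_per_mb * mb))
        for k, (s, ln) in enumerate(zip(
                rng.integers(0, spec.chrom_length - spec.cpg_length_range[1],
                             size=n_cpg),
                rng.integers(*spec.cpg_length_range, size=n_cpg, endpoint=True))):
            bundle.cpg_islands.append(
                Feature(chrom, int(s), int(s + ln), f"CpG_{chrom}_{k:03d}"))

        # --- super-enhancers with a closest active gene
        n_se = int(round(spec.enhancers_per_mb * mb))
        for k, (s, ln) in enumerate(zip(
                rng.integers(0, spec.chrom_length - spec.enhancer_length_range[1],
                             size=n_se),
                rng.integers(*spec.enhancer_length_range, size=n_se,
                             endpoint=True))):
            mid = int(s + ln // 2)
            chrom_genes = [g for g in bundle.genes if g.chrom == chrom]
            closest = min(chrom_genes,
                          key=lambda g: abs((g.start + g.end) // 2 - mid))
            bundle.super_enhancers.append(
                Feature(chrom, int(s), int(s + ln), f"SE_{chrom}_{k:03d}",
                        {"closest_gene": closest.id}))

        # --- miRNAs: clustered first, then singletons
        n_mir = int(round(spec.mirnas_per_mb * mb))
        n_clusters = spec.clusters_per_genome if ci == 0 else 0
        placed = 0
        for k in range(n_clusters):
            size = int(rng.integers(*spec.cluster_size_range, endpoint=True))
            mlens = rng.integers(*spec.mirna_length_range, size=size,
                                 endpoint=True)
            span = int(mlens.sum() + size * 500)
            cs = int(rng.integers(0, spec.chrom_length - span))
            mstarts = _place_nonoverlapping(rng, span, mlens, offset=cs)
            members = []
            for ms, ml in zip(mstarts, mlens):
                mid_ = f"MIR{mir_counter:03d}"
                mir_counter += 1
                bundle.mirnas.append(Feature(chrom, int(ms), int(ms + ml), mid_))
                members.append(mid_)
            bundle.mirna_clusters.append(
                Feature(chrom, cs, cs + span, f"MIRCLUSTER_{chrom}_{k}",
                        {"members": members}))
            placed += size
        for _ in range(max(0, n_mir - placed)):
            ml = int(rng.integers(*spec.mirna_length_range, endpoint=True))
            ms = int(rng.integers(0, spec.chrom_length - ml))
            bundle.mirnas.append(Feature(chrom, ms, ms + ml,
                                         f"MIR{mir_counter:03d}"))
            mir_counter += 1

    # rename the first genes of chr1 to the requested marker/gene symbols
    for name, gene in zip(spec.named_genes, bundle.genes):
        _rename_gene(bundle, gene.id, name)

    bundle.introns = bio.derive_introns(bundle.genes, bundle.exons)
    bundle.derive_promoters(spec.promoter_flank)

    # cancer-gene roles over a deterministic gene subset
    pick = rng.choice(len(bundle.genes),
                      size=min(spec.n_cancer_genes, len(bundle.genes)),
                      replace=False)
    for j, gi in enumerate(sorted(pick)):
        role = "oncogene" if j % 2 == 0 else "tumor suppressor"
        bundle.cancer_genes[bundle.genes[gi].id] = role

    # COSMIC-like tier table anchored on real genomic bases
    cosmic_rows: list[tuple] = []
    tiers = ["1", "2", "3", "other"]
    for _ in range(spec.n_cosmic_sites):
        g = bundle.genes[int(rng.integers(len(bundle.genes)))]
        pos0 = int(rng.integers(g.start, g.end))
        ref = chromosomes[g.chrom][pos0]
        alt = _IDX_TO_BASE[(int(_BASE_TO_IDX[ord(ref)]) + 1
                            + int(rng.integers(3))) % 4]
        cosmic_rows.append((g.chrom, pos0 + 1, ref, str(alt),
                            tiers[int(rng.integers(len(tiers)))],
                            round(float(rng.uniform(0.01, 0.1)), 3)))

    cfg = asdict(spec)
    cfg["seed"] = int(seed) if not isinstance(seed, np.random.Generator) else None
    return SyntheticGenome(chromosomes, bundle, cosmic_rows, cfg)


def _rename_gene(bundle: AnnotationBundle, old: str, new: str) -> None:
    def swap(feats: list[Feature]) -> None:
        for i, f in enumerate(feats):
            attrs = dict(f.attrs)
            fid = f.id.replace(old, new) if old in f.id else f.id
            if attrs.get("gene_id") == old:
                attrs["gene_id"] = new
            if fid != f.id or attrs != f.attrs:
                feats[i] = Feature(f.chrom, f.start, f.end, fid, attrs)

    for lst in (bundle.genes, bundle.exons, bundle.introns, bundle.utrs,
                bundle.promoters):
        swap(lst)


# ------------------------------------------------------------------ sizes

@dataclass
class CohortSpec:
    """Study conditions for the two-group cohort simulation.

    Size mixtures follow the reported group profiles: the cancer group is a
    six-peak Gaussian mixture plus a uniform background on (50, 2000] and a
    1% tail above 2 kb; the noncancer group is a single small-size Gaussian
    with the same background/tail structure. Marker enrichment is expressed
    as a fold change over an explicit noncancer baseline proportion.
    """

    n_cancer: int = 17
    n_noncancer: int = 11
    cancer_centers: tuple[float, ...] = (200, 380, 560, 740, 950, 1150)
    cancer_sds: tuple[float, ...] = (40,) * 6
    cancer_weights: tuple[float, ...] = (0.30, 0.22, 0.16, 0.12, 0.08, 0.05)
    cancer_background_weight: float = 0.06
    cancer_tail_weight: float = 0.01
    noncancer_center: float = 170.0
    noncancer_sd: float = 60.0
    noncancer_weight: float = 0.92
    noncancer_background_weight: float = 0.07
    noncancer_tail_weight: float = 0.01
    tail_max: int = 10_000
    min_length: int = 50
    origin_cancer: str = "uniform"
    origin_noncancer: str = "hotspot"
    hotspot_loci: int = 20
    hotspot_fraction: float = 0.6
    hotspot_spread: float = 5_000.0
    marker_genes: tuple[tuple[str, float], ...] = (("LINC00598", 8.0),
                                                   ("CELF2", 8.0))
    marker_baseline: float = 1e-4  # noncancer fraction of circles per marker
    circles_mean: float = 10_000.0
    circles_dispersion: float = 0.05
    chimera_fraction: float = 0.05
    read_rate: float = 20.0  # mapped reads per circle (Poisson mean)
    # serum markers: weakly separating lognormals (AUC ~ 0.6 each)
    cea_lognorm: tuple[tuple[float, float], tuple[float, float]] = (
        (0.916, 1.0), (1.274, 1.0))  # (mu, sigma): noncancer, cancer
    ca199_lognorm: tuple[tuple[float, float], tuple[float, float]] = (
        (3.40, 1.2), (3.83, 1.2))
    seed: int = 11

    def __post_init__(self) -> None:
        for group in ("cancer", "noncancer"):
            w = sum(self.mixture(group)[0])
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"{group} mixture weights sum to {w}, not 1")
        if any(fc <= 0 for _, fc in self.marker_genes):
            raise ValueError("marker fold changes must be positive")

    def mixture(self, group: str):
        """(weights, components); a component is ("normal", mu, sd) or
        ("uniform", lo, hi)."""
        if group == "cancer":
            weights = list(self.cancer_weights) + [self.cancer_background_weight,
                                                   self.cancer_tail_weight]
            comps = [("normal", c, s) for c, s in
                     zip(self.cancer_centers, self.cancer_sds)]
        elif group == "noncancer":
            weights = [self.noncancer_weight, self.noncancer_background_weight,
                       self.noncancer_tail_weight]
            comps = [("normal", self.noncancer_center, self.noncancer_sd)]
        else:
            raise ValueError(f"unknown group {group!r}")
        comps += [("uniform", self.min_length, 2_000),
                  ("uniform", 2_000, self.tail_max)]
        return weights, comps

    def mixture_mean(self, group: str) -> float:
        """Closed-form mean of the (untruncated) size mixture."""
        weights, comps = self.mixture(group)
        mean = 0.0
        for w, comp in zip(weights, comps):
            if comp[0] == "normal":
                mean += w * comp[1]
            else:
                mean += w * (comp[1] + comp[2]) / 2.0
        return mean

    def to_config(self) -> dict:
        return asdict(self)


def sample_ecc_sizes(group: str, n: int, spec: CohortSpec | None = None,
                     seed: int | np.random.Generator = 0,
                     return_components: bool = False):
    """Draw circle lengths (bp) from the group mixture, truncated at >= 50.

    Lengths below the bead cutoff are redrawn within their component, so
    component weights are preserved exactly. With ``return_components``
    also returns each draw's mixture-component index.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    spec = spec or CohortSpec()
    rng = _rng(seed)
    weights, comps = spec.mixture(group)
    comp_idx = rng.choice(len(comps), size=n, p=np.asarray(weights))
    out = np.empty(n, dtype=np.int64)
    for k, comp in enumerate(comps):
        mask = comp_idx == k
        m = int(mask.sum())
        if m == 0:
            continue
        if comp[0] == "normal":
            draws = rng.normal(comp[1], comp[2], size=m)
            bad = draws < spec.min_length
            while bad.any():
                draws[bad] = rng.normal(comp[1], comp[2], size=int(bad.sum()))
                bad = draws < spec.min_length
        else:
            draws = rng.uniform(comp[1], comp[2], size=m)
        out[mask] = np.floor(draws).astype(np.int64)
    out = np.maximum(out, spec.min_length)
    return (out, comp_idx) if return_components else out


# ------------------------------------------------------------------ cohorts

def simulate_cohort(genome: SyntheticGenome, spec: CohortSpec | None = None,
                    seed: int | None = None) -> list[SampleProfile]:
    """Simulate per-sample truth eccDNA sets for both groups.

    Cancer circles are placed uniformly over the genome; noncancer circles
    prefer a fixed set of hotspot loci. Per marker gene, the expected
    fraction of circles overlapping the gene is ``marker_baseline`` in
    noncancer and ``fold_change x marker_baseline`` in cancer (non-marker
    circles are redrawn away from marker genes, making the proportion
    exact in expectation). Serum CEA/CA19-9 come from weakly separated
    lognormals.
    """
    spec = spec or CohortSpec()
    rng = _rng(spec.seed if seed is None else seed)
    genes_by_id = {g.id: g for g in genome.bundle.genes}
    markers = []
    for name, fold in spec.marker_genes:
        if name not in genes_by_id:
            raise MarkerGeneError(f"marker gene {name!r} not in genome")
        markers.append((genes_by_id[name], float(fold)))

    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([len(genome.chromosomes[c]) for c in chrom_names],
                          dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    # hotspot loci shared across the noncancer group
    hs_chrom = rng.choice(len(chrom_names), size=spec.hotspot_loci, p=chrom_p)
    hs_pos = np.array([rng.integers(0, chrom_lens[c]) for c in hs_chrom])

    profiles: list[SampleProfile] = []
    plan = ([("cancer", f"C{i + 1:02d}") for i in range(spec.n_cancer)]
            + [("noncancer", f"NC{i + 1:02d}") for i in range(spec.n_noncancer)])
    for group, sid in plan:
        r = 1.0 / max(spec.circles_dispersion, 1e-9)
        n = int(max(1, rng.negative_binomial(r, r / (r + spec.circles_mean))))
        lengths = sample_ecc_sizes(group, n, spec, rng)

        probs = np.array([spec.marker_baseline * (fold if group == "cancer" else 1.0)
                          for _, fold in markers])
        assign = rng.choice(len(markers) + 1, size=n,
                            p=np.concatenate((probs, [1 - probs.sum()])))

        records: list[EccDNARecord] = []
        for i in range(n):
            ln = int(lengths[i])
            if assign[i] < len(markers):
                gene = markers[assign[i]][0]
                segs = [_segment_overlapping(rng, genome, gene, ln)]
            else:
                segs = _place_circle(rng, genome, group, spec, ln,
                                     chrom_names, chrom_p, hs_chrom, hs_pos,
                                     [g for g, _ in markers])
            records.append(EccDNARecord(f"{sid}:ecc{i:05d}", segs, n_passes=2))

        mapped = int(rng.poisson(spec.read_rate * n))
        cea = float(rng.lognormal(*spec.cea_lognorm[group == "cancer"]))
        ca199 = float(rng.lognormal(*spec.ca199_lognorm[group == "cancer"]))
        profiles.append(SampleProfile(sid, group, mapped_read_count=mapped,
                                      downsampled_read_count=mapped,
                                      eccdna=records, serum_cea=cea,
                                      serum_ca199=ca199))
    return profiles


def _segment_overlapping(rng, genome, gene: Feature, length: int) -> Segment:
    chrom_len = len(genome.chromosomes[gene.chrom])
    lo = max(0, gene.start - length + 1)
    hi = min(chrom_len - length, gene.end - 1)
    start = int(rng.integers(lo, max(lo + 1, hi + 1)))
    return Segment(gene.chrom, start, start + length)


def _place_circle(rng, genome, group, spec, length, chrom_names, chrom_p,
                  hs_chrom, hs_pos, avoid_genes) -> list[Segment]:
    chimera = rng.random() < spec.chimera_fraction and length >= 100
    if chimera:
        cut = int(rng.integers(50, length - 49))
        parts = [cut, length - cut]
    else:
        parts = [length]
    origin = spec.origin_cancer if group == "cancer" else spec.origin_noncancer
    segs = []
    for plen in parts:
        for _ in range(20):  # rejection loop away from marker genes
            if origin == "hotspot" and rng.random() < spec.hotspot_fraction:
                k = int(rng.integers(len(hs_pos)))
                ci = int(hs_chrom[k])
                start = int(hs_pos[k] + round(rng.normal(0, spec.hotspot_spread)))
            else:
                ci = int(rng.choice(len(chrom_names), p=chrom_p))
                start = int(rng.integers(0, len(genome.chromosomes[chrom_names[ci]])))
            chrom = chrom_names[ci]
            start = int(np.clip(start, 0, len(genome.chromosomes[chrom]) - plen))
            hit = any(g.chrom == chrom and start < g.end and start + plen > g.start
                      for g in avoid_genes)
            if not hit:
                break
        segs.append(Segment(chrom, start, start + plen))
    return segs


# ------------------------------------------------------------------ reads

@dataclass
class ReadSimParams:
    """Rolling-circle concatemer read model.

    Pass counts follow a shifted geometric on {1, 2, ...} with success
    probability ``pass_p`` (mean 1/pass_p). Errors are context-free and
    applied independently per base and per pass.
    """

    pass_p: float = 0.4
    substitution_rate: float = 0.03
    insertion_rate: float = 0.01
    deletion_rate: float = 0.01
    mean_extra_reads: float = 5.0  # reads per circle = 1 + Poisson(this)
    fixed_passes: int | None = None  # overrides the pass distribution
    fixed_offset: int | None = None  # overrides the uniform start offset
    fixed_reads: int | None = None  # overrides the reads-per-circle draw
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate,
                  self.deletion_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")
        if not 0 < self.pass_p <= 1:
            raise ValueError("pass_p must be in (0, 1]")


@dataclass
class ReadSet:
    reads: dict[str, str]
    truth_paf: list[bio.PafRecord]
    truth_table: list[dict]

    def write(self, outdir: str | Path, prefix: str = "reads") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bio.write_fastq(self.reads, outdir / f"{prefix}.fastq")
        bio.write_paf(self.truth_paf, outdir / f"{prefix}.truth.paf")
        bio.write_tsv(
            ([t["read_id"], t["circle_id"], t["n_passes"], t["start_offset"],
              t["circle_length"]] for t in self.truth_table),
            outdir / f"{prefix}.truth.tsv",
            header=["read_id", "circle_id", "n_passes", "start_offset",
                    "circle_length"])


def apply_errors(seq: str, rng: np.random.Generator, sub: float, ins: float,
                 dele: float) -> tuple[str, int, int, int]:
    """Apply per-base substitutions/indels; returns (seq, n_sub, n_ins, n_del)."""
    if sub == ins == dele == 0 or not seq:
        return seq, 0, 0, 0
    idx = _BASE_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = idx.size
    r = rng.random(n)
    sub_mask = r < sub
    del_mask = (r >= sub) & (r < sub + dele)
    shifted = (idx + 1 + rng.integers(0, 3, size=n).astype(np.uint8)) % 4
    out_idx = np.where(sub_mask, shifted, idx)
    ins_mask = rng.random(n) < ins
    ins_base = rng.integers(0, 4, size=n)
    chars = _IDX_TO_BASE[out_idx].copy()
    chars[del_mask] = ""
    extra = np.where(ins_mask, _IDX_TO_BASE[ins_base], "")
    merged = np.char.add(chars.astype("U2"), extra)
    kept_sub = int((sub_mask & ~del_mask).sum())
    return "".join(merged.tolist()), kept_sub, int(ins_mask.sum()), int(del_mask.sum())


def _rotated_parts(record: EccDNARecord, offset: int) -> list[Segment]:
    """Reference intervals of one traversal starting ``offset`` bp into the
    canonical circle."""
    segs = record.segments
    cum = np.concatenate(([0], np.cumsum([s.length for s in segs])))
    L = int(cum[-1])
    offset %= L
    j = int(np.searchsorted(cum, offset, side="right") - 1)
    within = offset - int(cum[j])
    parts: list[Segment] = []
    first = segs[j]
    if within:
        if first.strand == "+":
            parts.append(Segment(first.chrom, first.start + within, first.end,
                                 first.strand))
        else:
            parts.append(Segment(first.chrom, first.start, first.end - within,
                                 first.strand))
    else:
        parts.append(first)
    parts.extend(segs[j + 1:])
    parts.extend(segs[:j])
    if within:
        if first.strand == "+":
            parts.append(Segment(first.chrom, first.start, first.start + within,
                                 first.strand))
        else:
            parts.append(Segment(first.chrom, first.end - within, first.end,
                                 first.strand))
    return parts


def simulate_rca_reads(circles: list[EccDNARecord], genome: SyntheticGenome,
                       params: ReadSimParams | None = None,
                       seed: int | np.random.Generator | None = None) -> ReadSet:
    """Emit concatemer reads, an exact truth PAF and a per-read truth table.

    Each read is ``passes`` rotated copies of the circle with errors applied
    independently per base; the truth PAF records the error-free alignment
    segments of every pass with exact read coordinates (error application is
    tracked per reference part, so indel-shifted boundaries stay exact).
    """
    params = params or ReadSimParams()
    rng = _rng(params.seed if seed is None else seed)
    chrom_lens = genome.chrom_lengths
    reads: dict[str, str] = {}
    truth_paf: list[bio.PafRecord] = []
    truth_table: list[dict] = []
    for rec in circles:
        if rec.length == 0:
            raise ValueError(f"zero-length circle {rec.id}")
        circle_seq = genome.circle_sequence(rec)
        n_reads = params.fixed_reads if params.fixed_reads is not None \
            else 1 + int(rng.poisson(params.mean_extra_reads))
        for ri in range(n_reads):
            read_id = f"{rec.id}|read{ri}"
            passes = params.fixed_passes if params.fixed_passes is not None \
                else int(rng.geometric(params.pass_p))
            offset = params.fixed_offset if params.fixed_offset is not None \
                else int(rng.integers(0, rec.length))
            offset %= rec.length
            parts = _rotated_parts(rec, offset)
            part_seqs = [genome.fetch(p.chrom, p.start, p.end, p.strand)
                         for p in parts]
            chunks: list[str] = []
            paf_rows: list[bio.PafRecord] = []
            qpos = 0
            for pi in range(passes):
                for part, pseq in zip(parts, part_seqs):
                    err_seq, ns, ni, nd = apply_errors(
                        pseq, rng, params.substitution_rate,
                        params.insertion_rate, params.deletion_rate)
                    chunks.append(err_seq)
                    alnlen = part.length
                    paf_rows.append(bio.PafRecord(
                        read_id, 0, qpos, qpos + len(err_seq), part.strand,
                        part.chrom, chrom_lens[part.chrom], part.start,
                        part.end, max(alnlen - ns - nd, 0), alnlen, 60,
                        {"tp": f"pass{pi}"}))
                    qpos += len(err_seq)
            read_seq = "".join(chunks)
            paf_rows = _merge_contiguous(paf_rows)
            for row in paf_rows:
                row.qlen = len(read_seq)
            reads[read_id] = read_seq
            truth_paf.extend(paf_rows)
            truth_table.append({"read_id": read_id, "circle_id": rec.id,
                                "n_passes": passes, "start_offset": offset,
                                "circle_length": rec.length})
    return ReadSet(reads, truth_paf, truth_table)


def _merge_contiguous(rows: list[bio.PafRecord]) -> list[bio.PafRecord]:
    """Merge consecutive truth blocks that are contiguous on both read and
    reference - the rotation split re-joins across pass boundaries, giving
    the segment chains an aligner would report."""
    merged: list[bio.PafRecord] = []
    for row in rows:
        if merged:
            prev = merged[-1]
            joinable = (prev.tname == row.tname and prev.strand == row.strand
                        and prev.qend == row.qstart)
            if joinable and ((row.strand == "+" and prev.tend == row.tstart)
                             or (row.strand == "-"
                                 and prev.tstart == row.tend)):
                prev.qend = row.qend
                if row.strand == "+":
                    prev.tend = row.tend
                else:
                    prev.tstart = row.tstart
                prev.nmatch += row.nmatch
                prev.alnlen += row.alnlen
                continue
        merged.append(row)
    return merged


def perturb_paf(records: list[bio.PafRecord], max_jitter: int = 10,
                seed: int | np.random.Generator = 0) -> list[bio.PafRecord]:
    """Aligner-style endpoint jitter on reference coordinates (<= max_jitter bp)."""
    rng = _rng(seed)
    out = []
    for r in records:
        js = int(rng.integers(-max_jitter, max_jitter + 1))
        je = int(rng.integers(-max_jitter, max_jitter + 1))
        ts = max(0, r.tstart + js)
        te = min(r.tlen, r.tend + je)
        if te <= ts:
            ts, te = r.tstart, r.tend
        out.append(bio.PafRecord(r.qname, r.qlen, r.qstart, r.qend, r.strand,
                                 r.tname, r.tlen, ts, te, r.nmatch, r.alnlen,
                                 r.mapq, dict(r.tags)))
    return out


# ------------------------------------------------------------------ misc

def random_sequence(length: int, gc_fraction: float,
                    seed: int | np.random.Generator = 0) -> str:
    """Random DNA with an *exact* base composition.

    ``round(length * gc_fraction)`` positions carry G or C; the arrangement
    is a seeded shuffle. Used for the eccRandom assembly control (2.5 kb at
    50% GC).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = _rng(seed)
    n_gc = int(round(length * gc_fraction))
    bases = np.concatenate((
        rng.choice(["G", "C"], size=n_gc),
        rng.choice(["A", "T"], size=length - n_gc)))
    return "".join(bases[rng.permutation(length)])
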