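"""Pipeline orchestration: simulate -> call -> landscape -> annotate ->
diff -> diagnose -> variants.

Every run writes a frozen JSON config snapshot and a per-stage manifest
(input hash + output file hashes). Re-running with the same config and
seed reproduces every output byte-for-byte; a stage whose input hash is
unchanged is marked up-to-date and its files are not rewritten. All
randomness flows from named seeds in the config - there is no global
seed state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation, caller, diagnostics, differential, io as bio
from . import landscape as lsc
from . import synthetic, variants as var

log = logging.getLogger("bilecirc")

ALL_STAGES = ("simulate", "call", "landscape", "annotate", "diff",
              "diagnose", "variants")


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "bilecirc_out"
    seed: int = 11
    mode: str = "synthetic"  # synthetic | real
    truth_mode: bool = True  # skip read simulation/calling, use truth circles
    stages: tuple[str, ...] = ALL_STAGES
    genome: dict = field(default_factory=dict)  # GenomeSpec overrides
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    read_sim: dict = field(default_factory=dict)  # ReadSimParams overrides
    validation: dict = field(default_factory=lambda: {"n_cancer": 9,
                                                      "n_noncancer": 3})
    markers: tuple[str, ...] = ("LINC00598", "CELF2")
    bootstrap_B: int = 2000
    caller_tol: int = 20
    caller_coverage: float = 0.95
    min_passes: int = 2
    paf_jitter: int = 5
    fc_threshold: float = 2.0
    padj_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "markers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["markers"] = list(self.markers)
        return d


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True,
                                     default=str).encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.dir = outdir / "manifests"
        self.dir.mkdir(parents=True, exist_ok=True)

    def up_to_date(self, stage: str, input_hash: str) -> bool:
        path = self.dir / f"{stage}.json"
        if not path.exists():
            return False
        m = json.loads(path.read_text())
        return m.get("input_hash") == input_hash and all(
            Path(p).exists() for p in m.get("outputs", {}))

    def record(self, stage: str, input_hash: str, outputs: list[Path],
               elapsed: float) -> str:
        payload = {"stage": stage, "input_hash": input_hash,
                   "elapsed_s": round(elapsed, 3),
                   "outputs": {str(p): _hash_file(p) for p in sorted(outputs)}}
        (self.dir / f"{stage}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return _hash_obj(payload["outputs"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the in-memory results keyed by stage. Raises
    :class:`StageError` when a stage needs a disabled upstream stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bio.write_json(config.to_dict(), out / "config.snapshot.json")
    manifest = _Manifest(out)
    state: dict = {"config": config}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        input_hash = _hash_obj([config.to_dict(), stage,
                                state.get("_chain_hash", "")])
        skipped = manifest.up_to_date(stage, input_hash)
        outputs = _STAGES[stage](config, state, out, write=not skipped)
        if not skipped:
            chain = manifest.record(stage, input_hash, outputs,
                                    time.time() - t0)
        else:
            chain = json.loads(
                (manifest.dir / f"{stage}.json").read_text())["input_hash"]
            log.info("stage %s up to date; outputs kept", stage)
        state["_chain_hash"] = chain
        log.info("stage %-9s done in %.2fs%s", stage, time.time() - t0,
                 " (up to date)" if skipped else "")
    return state


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise StageError(f"stage {needed_by!r} requires output of "
                         f"stage {stage!r}, which did not run")
    return state[key]


def _stage_simulate(config: PipelineConfig, state: dict, out: Path,
                    write: bool) -> list[Path]:
    gspec = synthetic.GenomeSpec(**config.genome)
    genome = synthetic.simulate_genome(gspec, seed=config.seed)
    cspec = synthetic.CohortSpec(**{"seed": config.seed, **config.cohort})
    train = synthetic.simulate_cohort(genome, cspec, seed=cspec.seed)
    vspec = dataclasses.replace(cspec, **config.validation)
    validation = synthetic.simulate_cohort(genome, vspec,
                                           seed=cspec.seed + 1)
    for i, p in enumerate(validation):
        validation[i] = dataclasses.replace(p, sample_id="V" + p.sample_id)
        for rec in validation[i].eccdna:
            rec.id = "V" + rec.id
    state.update(genome=genome, train=train, validation=validation,
                 cohort_spec=cspec)
    files: list[Path] = []
    gdir = out / "genome"
    if write:
        genome.write(gdir)
    files.extend(sorted(gdir.glob("*")))
    bed = out / "truth_circles.bed"
    if write:
        rows = []
        for p in train + validation:
            for rec in p.eccdna:
                for seg in rec.segments:
                    rows.append((seg.chrom, seg.start, seg.end, rec.id, 0,
                                 seg.strand, p.sample_id, p.group))
        bio.write_bed(rows, bed)
    files.append(bed)
    if not config.truth_mode:
        rparams = synthetic.ReadSimParams(**{"seed": config.seed,
                                             **config.read_sim})
        readsets = {}
        for p in train + validation:
            stable = int(hashlib.sha256(
                f"{config.seed}:{p.sample_id}".encode()).hexdigest()[:8], 16)
            rs = synthetic.simulate_rca_reads(p.eccdna, genome, rparams,
                                              seed=stable % (2 ** 31))
            readsets[p.sample_id] = rs
            if write:
                rs.write(out / "reads", prefix=p.sample_id)
        state["readsets"] = readsets
        files.extend(sorted((out / "reads").glob("*")))
    return files


def _stage_call(config: PipelineConfig, state: dict, out: Path,
                write: bool) -> list[Path]:
    genome = _require(state, "genome", "simulate", "call")
    files: list[Path] = []
    if config.truth_mode:
        # truth-set mode: the simulated circles are taken as the call set
        state["profiles"] = state["train"]
        state["val_profiles"] = state["validation"]
        state["evidence"] = {}
        return files
    readsets = _require(state, "readsets", "simulate", "call")
    samples = []
    for sid, rs in sorted(readsets.items()):
        paf = synthetic.perturb_paf(rs.truth_paf, config.paf_jitter,
                                    seed=config.seed + 17)
        chains = caller.segment_reads(paf)
        samples.append(caller.SampleReads(sid, chains, rs.reads))
    samples = caller.downsample_mapped_reads(samples, seed=config.seed)
    prof_by_id = {p.sample_id: p for p in state["train"] + state["validation"]}
    profiles, val_profiles = [], []
    evidence = {}
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    for s in samples:
        result = caller.call_eccdna(s.chains, s.reads,
                                    min_passes=config.min_passes,
                                    tol=config.caller_tol,
                                    coverage_frac=config.caller_coverage)
        truth = prof_by_id[s.sample_id]
        prof = dataclasses.replace(
            truth, eccdna=result.records, mapped_read_count=s.n_mapped,
            downsampled_read_count=s.n_mapped)
        for rec in prof.eccdna:
            rec.id = f"{s.sample_id}:{rec.id}"
        evidence[s.sample_id] = result
        (val_profiles if s.sample_id.startswith("V") else profiles).append(prof)
        bed = calls_dir / f"{s.sample_id}.bed"
        if write:
            rows = []
            for rec in prof.eccdna:
                for seg in rec.segments:
                    rows.append((seg.chrom, seg.start, seg.end, rec.id,
                                 rec.n_passes, seg.strand, rec.length,
                                 rec.n_supporting_reads))
            bio.write_bed(rows, bed)
            cons = {r.id: r.consensus for r in prof.eccdna if r.consensus}
            if cons:
                bio.write_fasta(cons, calls_dir / f"{s.sample_id}.consensus.fa")
        files.append(bed)
        if (calls_dir / f"{s.sample_id}.consensus.fa").exists():
            files.append(calls_dir / f"{s.sample_id}.consensus.fa")
    state.update(profiles=profiles, val_profiles=val_profiles,
                 evidence=evidence)
    return files


def _stage_landscape(config: PipelineConfig, state: dict, out: Path,
                     write: bool) -> list[Path]:
    profiles = state.get("profiles") or _require(state, "train", "simulate",
                                                 "landscape")
    genome = _require(state, "genome", "simulate", "landscape")
    files = []
    cancer = [p for p in profiles if p.group == "cancer"]
    noncancer = [p for p in profiles if p.group == "noncancer"]
    bins = lsc.compare_length_bins(cancer, noncancer)
    dist = lsc.genome_distribution(profiles, genome.chrom_lengths)
    peaks = {}
    for group, profs in (("cancer", cancer), ("noncancer", noncancer)):
        lens = np.concatenate([[r.length for r in p.eccdna] for p in profs])
        try:
            peaks[group] = lsc.detect_size_peaks(lens)
        except ValueError:
            peaks[group] = []
    counts = {p.sample_id: lsc.count_per_mapped_read(p) for p in profiles}
    state["landscape"] = {"bins": bins, "distribution": dist, "peaks": peaks,
                          "count_per_read": counts}
    ldir = out / "landscape"
    ldir.mkdir(exist_ok=True)
    paths = [ldir / "length_bins.tsv", ldir / "chrom_fractions.tsv",
             ldir / "window_median.bedgraph", ldir / "peaks.json",
             ldir / "count_per_read.json"]
    if write:
        bins.to_csv(paths[0], sep="\t")
        dist.chrom_fractions.to_csv(paths[1], sep="\t")
        bio.write_bed(dist.window_median.itertuples(index=False), paths[2])
        bio.write_json(peaks, paths[3])
        bio.write_json(counts, paths[4])
    return paths


def _stage_annotate(config: PipelineConfig, state: dict, out: Path,
                    write: bool) -> list[Path]:
    genome = _require(state, "genome", "simulate", "annotate")
    profiles = state.get("profiles") or _require(state, "train", "simulate",
                                                 "annotate")
    val_profiles = state.get("val_profiles", state.get("validation", []))
    anns = {}
    for p in profiles + list(val_profiles):
        anns[p.sample_id] = annotation.annotate_records(p.eccdna,
                                                        genome.bundle)
    state["annotations"] = anns
    groups = {}
    for cls, attr in (("eccEnhancer", "enhancer_ids"),
                      ("eccMIR", "mirna_ids"),
                      ("eccMIR_cluster", "cluster_ids")):
        cancer_hits = [set().union(*(getattr(a, attr) for a in anns[p.sample_id]
                                     .values())) if anns[p.sample_id] else set()
                       for p in profiles if p.group == "cancer"]
        noncancer_hits = [set().union(*(getattr(a, attr)
                                        for a in anns[p.sample_id].values()))
                          if anns[p.sample_id] else set()
                          for p in profiles if p.group == "noncancer"]
        cancer_hits = [set(h) for h in cancer_hits]
        groups[cls] = annotation.group_specific_features(cancer_hits,
                                                         noncancer_hits)
    state["group_specific"] = groups
    adir = out / "annotation"
    adir.mkdir(exist_ok=True)
    paths = [adir / "annotations.tsv", adir / "group_specific.json"]
    if write:
        rows = []
        for sid, per in sorted(anns.items()):
            for ann in per.values():
                rows.append((sid, ann.ecc_id, ann.element_label,
                             int(ann.is_eccgene), ",".join(ann.gene_ids),
                             int(ann.is_eccenhancer), int(ann.is_eccmir),
                             int(ann.is_eccmir_cluster)))
        bio.write_tsv(rows, paths[0],
                      header=["sample", "ecc_id", "element", "eccGene",
                              "genes", "eccEnhancer", "eccMIR",
                              "eccMIR_cluster"])
        bio.write_json(groups, paths[1])
    return paths


def _gene_hits(state: dict, sample_ids) -> dict[str, dict[str, list[str]]]:
    anns = state["annotations"]
    return {sid: {eid: a.gene_ids for eid, a in anns[sid].items()}
            for sid in sample_ids if sid in anns}


def _stage_diff(config: PipelineConfig, state: dict, out: Path,
                write: bool) -> list[Path]:
    profiles = state.get("profiles") or _require(state, "train", "simulate",
                                                 "diff")
    _require(state, "annotations", "annotate", "diff")
    hits = _gene_hits(state, [p.sample_id for p in profiles])
    matrix = differential.build_count_matrix(profiles, hits)
    groups = {p.sample_id: p.group for p in profiles}
    results = differential.nb_exact_test(
        matrix, groups, lib_sizes=differential.library_sizes(matrix, profiles))
    results = differential.filter_differential(results, config.fc_threshold,
                                               config.padj_threshold)
    state["diff"] = {"matrix": matrix, "results": results}
    ddir = out / "differential"
    ddir.mkdir(exist_ok=True)
    paths = [ddir / "count_matrix.tsv", ddir / "results.tsv"]
    if write:
        matrix.to_csv(paths[0], sep="\t")
        results.to_csv(paths[1], sep="\t")
    return paths


def _stage_diagnose(config: PipelineConfig, state: dict, out: Path,
                    write: bool) -> list[Path]:
    profiles = state.get("profiles") or _require(state, "train", "simulate",
                                                 "diagnose")
    val_profiles = state.get("val_profiles", state.get("validation", []))
    _require(state, "annotations", "annotate", "diagnose")
    hits = _gene_hits(state, [p.sample_id for p in
                              list(profiles) + list(val_profiles)])
    results = {}
    score_vectors = []
    labels = [p.group for p in profiles]
    for marker in config.markers:
        tr = [diagnostics.marker_proportion(p, marker, hits[p.sample_id])
              for p in profiles]
        va = [diagnostics.marker_proportion(p, marker, hits[p.sample_id])
              for p in val_profiles] if val_profiles else None
        res = diagnostics.evaluate_marker(
            marker, tr, labels, va,
            [p.group for p in val_profiles] if val_profiles else None,
            B=config.bootstrap_B, seed=config.seed)
        results[marker] = res
        score_vectors.append(np.asarray(tr))
    combo = None
    if len(score_vectors) >= 2:
        model, combined = diagnostics.combine_markers(score_vectors, labels)
        combo = {"method": model.method,
                 "auc": diagnostics.roc_auc(combined, labels)}
    state["diagnostics"] = {"markers": results, "combined": combo}
    ddir = out / "diagnostics"
    ddir.mkdir(exist_ok=True)
    paths = [ddir / "report.json"]
    if write:
        payload = {m: r.to_dict() for m, r in results.items()}
        if combo:
            payload["combined"] = combo
        bio.write_json(payload, paths[0])
        for m, r in results.items():
            p = ddir / f"roc_{m}.tsv"
            bio.write_tsv(r.roc.tolist(), p, header=["fpr", "tpr"])
            paths.append(p)
    else:
        paths.extend(sorted(ddir.glob("roc_*.tsv")))
    return paths


def _stage_variants(config: PipelineConfig, state: dict, out: Path,
                    write: bool) -> list[Path]:
    genome = _require(state, "genome", "simulate", "variants")
    vdir = out / "variants"
    vdir.mkdir(exist_ok=True)
    path = vdir / "variants.vcf"
    if config.truth_mode or not state.get("evidence"):
        # no read-level evidence without the caller; emit an empty VCF
        if write:
            bio.write_vcf([], path, genome.chrom_lengths)
        state["variants"] = []
        return [path]
    table = var.load_cosmic_table(genome.cosmic_rows)
    all_variants = []
    for sid, result in sorted(state["evidence"].items()):
        vs = var.call_variants(result, genome)
        var.annotate_tiers(vs, table)
        all_variants.extend(vs)
    state["variants"] = all_variants
    if write:
        bio.write_vcf(all_variants, path, genome.chrom_lengths)
    return [path]


_STAGES = {"simulate": _stage_simulate, "call": _stage_call,
           "landscape": _stage_landscape, "annotate": _stage_annotate,
           "diff": _stage_diff, "diagnose": _stage_diagnose,
           "variants": _stage_variants}
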