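"""Pipeline orchestration: simulate -> call -> annotate -> longread from one
declarative YAML config, with seed propagation, per-stage idempotency and a
combined per-sample report joining short-read and long-read outputs.

The report mirrors the layout of a per-sample gene-therapy-outcome table:
an ITR-seq block (unique sites, per-100-genome frequency, clonal-expansion
summary), an annotation block (category fold changes, cancer-gene hits) and
a long-read block (cohort summary). Identical config + seed reproduces a
byte-identical report.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .annotate import (
    annotate_sites,
    enrichment,
    random_loci,
    read_gff3_genes,
    write_annotation,
)
from .itrseq import (
    CallerParams,
    ReadLayout,
    call_observations,
    collapse_and_count,
    expansion_summary,
    normalize_per_100_genomes,
    write_callset,
)
from .longread import (
    LongReadParams,
    annotate_read,
    build_index,
    junction_bed,
    summarize_cohort,
    write_cohort_summary,
    write_structures,
)
from .models import HostGenome, VectorModel
from .simulate import SimConfig, simulate_to_dir

log = logging.getLogger("aavint")


class ConfigError(ValueError):
    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        super().__init__("; ".join(f"{p}: {m}" for p, m in errors))


@dataclass
class RunConfig:
    sample_id: str = "sample"
    seed: int = 7
    out_dir: str = "aavint_out"
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "itrseq": True, "annotation": True, "longread": True})
    sim: dict = field(default_factory=dict)       # SimConfig overrides
    itrseq: dict = field(default_factory=lambda: {
        "input_dna_ng": 100.0, "genome_mass_pg": 6.6, "window": 0,
        "dup_pos_tolerance": 0})
    annotation: dict = field(default_factory=lambda: {
        "n_random": 10_000, "flank_bp": 0})
    longread: dict = field(default_factory=lambda: {
        "min_flank": 50, "max_gap": 50, "min_segment": 50, "min_itr": 30})
    inputs: dict = field(default_factory=dict)    # external paths when simulate=False


_SIM_FIELDS = {f.name for f in fields(SimConfig)}

_SCHEMA: dict[str, dict] = {
    "sample_id": {"type": str},
    "seed": {"type": int, "min": 0},
    "out_dir": {"type": str},
    "stages": {"keys": {"simulate", "itrseq", "annotation", "longread"},
               "type_of_values": bool},
    "sim": {"keys": _SIM_FIELDS},
    "itrseq": {"keys": {"input_dna_ng", "genome_mass_pg", "window",
                        "dup_pos_tolerance"}},
    "annotation": {"keys": {"n_random", "flank_bp"}},
    "longread": {"keys": {"min_flank", "max_gap", "min_segment", "min_itr"}},
    "inputs": {"keys": {"host_fasta", "vector_fasta", "vector_components",
                        "itrseq_r1", "itrseq_r2", "longreads", "genes_gff3",
                        "expression_tsv", "hcc_list", "mouse_hcc_list",
                        "itr_anchor", "itr_residual"}},
}

_RANGES = {
    ("sim", "n_events"): lambda v: v >= 0,
    ("sim", "n_long_reads"): lambda v: v >= 0,
    ("sim", "substitution_error_rate"): lambda v: 0 <= v <= 1,
    ("itrseq", "input_dna_ng"): lambda v: v > 0,
    ("itrseq", "genome_mass_pg"): lambda v: v > 0,
    ("itrseq", "window"): lambda v: v >= 0,
    ("annotation", "n_random"): lambda v: v >= 1,
}


def validate_config(text: str) -> RunConfig:
    """Parse + validate YAML config text; raises ConfigError listing every
    violation (unknown keys, type and range errors, missing inputs)."""
    raw = yaml.safe_load(text) or {}
    errors: list[tuple[str, str]] = []
    if not isinstance(raw, dict):
        raise ConfigError([("", "config must be a mapping")])
    for key in raw:
        if key not in _SCHEMA:
            errors.append((key, "unknown key"))
    cfg = RunConfig()
    for key, spec in _SCHEMA.items():
        if key not in raw:
            continue
        value = raw[key]
        if "type" in spec and not isinstance(value, spec["type"]):
            errors.append((key, f"expected {spec['type'].__name__}"))
            continue
        if "min" in spec and isinstance(value, (int, float)) and value < spec["min"]:
            errors.append((key, f"must be >= {spec['min']}"))
        if "keys" in spec:
            if not isinstance(value, dict):
                errors.append((key, "expected a mapping"))
                continue
            for sub in value:
                if sub not in spec["keys"]:
                    errors.append((f"{key}.{sub}", "unknown key"))
            if "type_of_values" in spec:
                for sub, v in value.items():
                    if not isinstance(v, spec["type_of_values"]):
                        errors.append((f"{key}.{sub}", "expected a boolean"))
            merged = dict(getattr(cfg, key))
            merged.update({k: v for k, v in value.items() if k in spec["keys"]})
            setattr(cfg, key, merged)
        else:
            setattr(cfg, key, value)
    for (section, name), ok in _RANGES.items():
        v = getattr(cfg, section).get(name) if section != "sim" else cfg.sim.get(name)
        if v is not None and not ok(v):
            errors.append((f"{section}.{name}", "out of range"))
    if not cfg.stages.get("simulate", True):
        needed = ["host_fasta"]
        if cfg.stages.get("itrseq", True):
            needed += ["itrseq_r1", "itrseq_r2", "itr_anchor", "itr_residual"]
        if cfg.stages.get("longread", True):
            needed += ["vector_fasta", "vector_components", "longreads"]
        for key in needed:
            if key not in cfg.inputs:
                errors.append((f"inputs.{key}",
                               "required when simulate stage is disabled"))
    if errors:
        raise ConfigError(sorted(errors))
    return cfg


# ---------------------------------------------------------------------------
# Reference loading


def load_host(path) -> HostGenome:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return HostGenome(records)


def load_vector(fasta_path, components_path) -> VectorModel:
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    seq = str(rec.seq).upper()
    comp = pd.read_csv(components_path, sep="\t")
    components = [(row.label, (int(row.start), int(row.end)),
                   seq[int(row.start):int(row.end)])
                  for row in comp.itertuples()]
    itr_len = components[0][1][1] - components[0][1][0]
    return VectorModel(components, itr_canonical_length=itr_len)


def read_fastq_pairs(r1_path, r2_path):
    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            yield rec1.id, str(rec1.seq), str(rec2.seq)


def read_fastx(path):
    p = str(path)
    fmt = "fastq" if ".fastq" in p or ".fq" in p else "fasta"
    opener = gzip.open(p, "rt") if p.endswith(".gz") else open(p)
    with opener as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


# ---------------------------------------------------------------------------
# Stages


def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not outputs or not all(p.exists() for p in outputs):
        return False
    newest_in = max((p.stat().st_mtime for p in inputs if p.exists()), default=0.0)
    return min(p.stat().st_mtime for p in outputs) >= newest_in


def run_pipeline(config: RunConfig, force: bool = False,
                 only_stage: str | None = None) -> dict:
    """Execute enabled stages in dependency order and write report.json /
    report.tsv under ``config.out_dir``. Returns the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "sample_id": config.sample_id,
        "provenance": {
            "aavint_version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        },
    }
    timings: dict[str, float] = {}

    def enabled(stage: str) -> bool:
        if only_stage is not None and stage != only_stage:
            return False
        return bool(config.stages.get(stage, True))

    sim_dir = out / "sim"
    paths = dict(config.inputs)
    if config.stages.get("simulate", True):
        paths.setdefault("host_fasta", str(sim_dir / "host.fa"))
        paths.setdefault("vector_fasta", str(sim_dir / "vector.fa"))
        paths.setdefault("vector_components", str(sim_dir / "vector_components.tsv"))
        paths.setdefault("itrseq_r1", str(sim_dir / "itrseq_R1.fastq.gz"))
        paths.setdefault("itrseq_r2", str(sim_dir / "itrseq_R2.fastq.gz"))
        paths.setdefault("longreads", str(sim_dir / "longreads.fastq.gz"))
        paths.setdefault("genes_gff3", str(sim_dir / "genes.gff3"))
        paths.setdefault("expression_tsv", str(sim_dir / "expression.tsv"))
        paths.setdefault("hcc_list", str(sim_dir / "hcc_genes.txt"))
        paths.setdefault("mouse_hcc_list", str(sim_dir / "mouse_hcc_genes.txt"))

    if enabled("simulate"):
        t0 = time.perf_counter()
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        outputs = [sim_dir / "manifest.json", sim_dir / "host.fa"]
        if force or not _fresh(outputs, []):
            log.info("stage simulate: running")
            simulate_to_dir(sim_cfg, sim_dir)
        else:
            log.info("stage simulate: up to date, skipped")
        timings["simulate"] = time.perf_counter() - t0

    host = vector = None

    def get_host() -> HostGenome:
        nonlocal host
        if host is None:
            host = load_host(paths["host_fasta"])
        return host

    def get_vector() -> VectorModel:
        nonlocal vector
        if vector is None:
            vector = load_vector(paths["vector_fasta"], paths["vector_components"])
        return vector

    itr_dir = out / "itrseq"
    if enabled("itrseq"):
        t0 = time.perf_counter()
        itr_dir.mkdir(exist_ok=True)
        outputs = [itr_dir / "sites.tsv", itr_dir / "sites.bed",
                   itr_dir / "summary.json"]
        inputs = [Path(paths["itrseq_r1"]), Path(paths["itrseq_r2"])]
        if force or not _fresh(outputs, inputs):
            log.info("stage itrseq: running")
            if "itr_anchor" in paths:
                anchor, residual = paths["itr_anchor"], paths["itr_residual"]
            else:
                manifest = json.loads((sim_dir / "manifest.json").read_text())
                anchor, residual = manifest["itr_anchor"], manifest["itr_residual"]
            layout = ReadLayout(anchor=anchor, residual=residual)
            params = CallerParams(
                window=int(config.itrseq.get("window", 0)),
                dup_pos_tolerance=int(config.itrseq.get("dup_pos_tolerance", 0)))
            obs, rejected = call_observations(
                read_fastq_pairs(paths["itrseq_r1"], paths["itrseq_r2"]),
                get_host(), layout, params)
            callset = collapse_and_count(obs, params, config.sample_id)
            callset.n_rejected = rejected
            normalize_per_100_genomes(
                callset, float(config.itrseq.get("input_dna_ng", 100.0)),
                float(config.itrseq.get("genome_mass_pg", 6.6)))
            write_callset(callset, itr_dir / "sites.bed", itr_dir / "sites.tsv")
            exp = expansion_summary(callset)
            summary = {
                "n_observations": len(obs), "n_rejected": rejected,
                "unique_sites": len(callset.sites),
                "genome_equivalents": callset.genome_equivalents,
                "per_100_genomes": callset.per_100_genomes,
                "percent_expanded": exp.percent_expanded,
                "mean_clone_size_of_expanded": exp.mean_clone_size_of_expanded,
                "largest_clone": exp.largest_clone,
            }
            (itr_dir / "summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n")
        timings["itrseq"] = time.perf_counter() - t0
    if (itr_dir / "summary.json").exists():
        report["itrseq"] = json.loads((itr_dir / "summary.json").read_text())

    ann_dir = out / "annotation"
    if enabled("annotation"):
        t0 = time.perf_counter()
        ann_dir.mkdir(exist_ok=True)
        outputs = [ann_dir / "annotated_sites.tsv", ann_dir / "enrichment.json"]
        inputs = [itr_dir / "sites.tsv"]
        if force or not _fresh(outputs, inputs):
            log.info("stage annotation: running")
            sites = pd.read_csv(itr_dir / "sites.tsv", sep="\t")
            genes = read_gff3_genes(paths["genes_gff3"])
            expr_df = pd.read_csv(paths["expression_tsv"], sep="\t")
            expr = dict(zip(expr_df.gene_id, expr_df.nx))
            hcc = Path(paths["hcc_list"]).read_text().split()
            mouse = Path(paths["mouse_hcc_list"]).read_text().split()
            site_tuples = list(zip(sites.chrom, sites.coord))
            annotated = annotate_sites(site_tuples, genes, expr, hcc, mouse,
                                       int(config.annotation.get("flank_bp", 0)))
            n_random = int(config.annotation.get("n_random", 10_000))
            bg = random_loci(get_host(), n_random, seed=config.seed + 1000)
            bg_annotated = annotate_sites(bg, genes, expr, hcc, mouse,
                                          int(config.annotation.get("flank_bp", 0)))
            report_enr = enrichment(annotated, bg_annotated, seed=config.seed + 1000)
            write_annotation(annotated, report_enr,
                             ann_dir / "annotated_sites.tsv",
                             ann_dir / "enrichment.json")
        timings["annotation"] = time.perf_counter() - t0
    if (ann_dir / "enrichment.json").exists():
        enr = json.loads((ann_dir / "enrichment.json").read_text())
        ann = pd.read_csv(ann_dir / "annotated_sites.tsv", sep="\t")
        report["annotation"] = {
            "enrichment": enr,
            "hcc_hits": int(ann.hcc_hit.sum()) if len(ann) else 0,
            "mouse_hcc_hits": int(ann.mouse_hcc_hit.sum()) if len(ann) else 0,
        }

    lr_dir = out / "longread"
    if enabled("longread"):
        t0 = time.perf_counter()
        lr_dir.mkdir(exist_ok=True)
        outputs = [lr_dir / "structures.jsonl", lr_dir / "cohort_summary.tsv",
                   lr_dir / "cohort_summary.json"]
        inputs = [Path(paths["longreads"])]
        if force or not _fresh(outputs, inputs):
            log.info("stage longread: running")
            params = LongReadParams(
                min_flank=int(config.longread.get("min_flank", 50)),
                max_gap=int(config.longread.get("max_gap", 50)),
                min_segment=int(config.longread.get("min_segment", 50)),
                min_itr=int(config.longread.get("min_itr", 30)))
            vec = get_vector()
            idx = build_index(vec, get_host())
            structures = [annotate_read(rid, seq, idx, vec, params)
                          for rid, seq in read_fastx(paths["longreads"])]
            write_structures(structures, lr_dir / "structures.jsonl")
            summary = summarize_cohort(structures)
            write_cohort_summary(summary, lr_dir / "cohort_summary.tsv")
            (lr_dir / "cohort_summary.json").write_text(
                json.dumps(asdict(summary), indent=2, sort_keys=True) + "\n")
            junction_bed(structures, lr_dir / "junctions.bed")
        timings["longread"] = time.perf_counter() - t0
    if (lr_dir / "cohort_summary.json").exists():
        report["longread"] = json.loads((lr_dir / "cohort_summary.json").read_text())

    for stage, dt in timings.items():
        log.info("stage %s: %.1f s", stage, dt)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_report_tsv(report, out / "report.tsv")
    return report


def _write_report_tsv(report: dict, path: Path) -> None:
    rows: list[tuple[str, object]] = [("Sample", report["sample_id"])]
    itr = report.get("itrseq")
    if itr:
        rows += [("Unique integration sites", itr["unique_sites"]),
                 ("Integrations per 100 genomes", itr["per_100_genomes"]),
                 ("% sites clonally expanded", itr["percent_expanded"]),
                 ("Mean clone size (expanded sites)",
                  itr["mean_clone_size_of_expanded"]),
                 ("Largest clone", itr["largest_clone"])]
    ann = report.get("annotation")
    if ann:
        rows += [("HCC gene hits", ann["hcc_hits"]),
                 ("Mouse HCC gene hits", ann["mouse_hcc_hits"])]
        for cat, d in ann["enrichment"]["categories"].items():
            rows.append((f"Fold change over random ({cat})", d["fold_change"]))
    lr = report.get("longread")
    if lr:
        rows += [("Total", lr["total_reads"]),
                 ("Vector", lr["vector_reads"]),
                 ("Vector + flank (confirmed integrated)", lr["vector_plus_flank"]),
                 ("Average no. ITRs per read", lr["mean_itrs_per_flanked_read"]),
                 ("Functional cDNA", lr["functional_cdna"]),
                 ("cDNA + flank (confirmed integrated)", lr["cdna_plus_flank"]),
                 ("% intact ITRs", lr["pct_intact_itrs"]),
                 ("Mean ITR length (bp)", lr["mean_itr_length"]),
                 ("Flank match %", lr["flank_match_pct"])]
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{'' if value is None else value}\n")
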