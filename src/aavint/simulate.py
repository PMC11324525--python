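"""Synthetic data with planted ground truth.

Forges a toy host genome and an annotated ITR-to-ITR vector genome, plants
integration events with clonal expansion, and emits both anchored-PCR short
read pairs (ITR primer anchor on R1, barcode+UMI Y-adapter prefix on R2) and
CCS-like long reads containing episomal or integrated vector concatemers in
head-to-tail / head-to-head / tail-to-tail configurations with
heterogeneously truncated ITRs. Every read is accompanied by complete truth:
downstream stages are tested against these tables, no download needed.

Conventions
-----------
* ITR3 is the reverse complement of ITR5 (a true inverted terminal repeat),
  but the ITR itself is non-palindromic random sequence; the B-B' loop
  exists as a coordinate window in which truncation break points fall.
* ITR truncation retains the payload-proximal portion; ``retained_length``
  bases survive and equal the recorded breakpoint offset.
* Truth segment boundaries are left-normalized exactly like the annotator's
  output (see aavint._align), so truth and calls compare exactly.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._align import extend_left_exact, extend_right_exact, normalize_boundaries
from .models import (
    DEFAULT_MIN_ITR,
    GeneModel,
    HostGenome,
    IntegrationTruth,
    ItrRecord,
    ReadStructure,
    SegmentAnnotation,
    VectorCopy,
    VectorModel,
    revcomp,
    valid_umi,
)

_BASES = np.array(list("ACGT"))

ANCHOR_LEN = 20      # ITR primer anchor at the start of R1
RESIDUAL_LEN = 30    # residual ITR between primer 3' end and the junction
BARCODE = "ACGTACGT"  # fixed 8-mer sample barcode on R2
UMI_LEN = 8


@dataclass
class SimConfig:
    """Simulation parameters. Defaults are the study conditions exercised by
    the test suite: 200 events, clone counts 1-5, 0-3 PCR duplicates per
    clone, substitution-only errors (default rate 0), 500 long reads mixing
    episomes and 1-5-copy concatemers."""

    seed: int = 7
    # references
    n_chromosomes: int = 4
    chrom_length: int = 150_000
    # events
    n_events: int = 200
    min_event_spacing: int = 1_500
    clone_count_distribution: tuple = ("uniform_range", 1, 5)
    # short reads
    n_pcr_duplicates_per_read: tuple = ("uniform_range", 0, 3)
    substitution_error_rate: float = 0.0
    read_length: int = 150
    fragment_mean: float = 500.0
    fragment_sd: float = 100.0
    fragment_min: int = 200
    fragment_max: int = 1_400
    # long reads
    n_long_reads: int = 500
    concatemer_copy_distribution: tuple = ("uniform_range", 1, 5)
    episome_fraction: float = 0.4
    host_only_fraction: float = 0.02
    capture_both_prob: float = 0.5
    flank_len_min: int = 200
    flank_len_max: int = 1_500
    itr_intact_prob: float = 0.1
    partial_copy_prob: float = 0.15
    same_orientation_prob: float = 0.7
    flank_deletion_prob: float = 0.0
    flank_insertion_prob: float = 0.0
    flank_indel_max: int = 10
    # normalization defaults echoed into downstream configs
    input_dna_ng: float = 100.0
    genome_mass_pg: float = 6.6

    def __post_init__(self) -> None:
        for name in ("substitution_error_rate", "episome_fraction",
                     "host_only_fraction", "capture_both_prob",
                     "itr_intact_prob", "partial_copy_prob",
                     "same_orientation_prob", "flank_deletion_prob",
                     "flank_insertion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.chrom_length < 10_000:
            raise ValueError("chromosome length must be >= 10 kb")


def _draw(dist: tuple, rng: np.random.Generator) -> int:
    kind = dist[0]
    if kind == "constant":
        return int(dist[1])
    if kind == "uniform_range":
        return int(rng.integers(dist[1], dist[2] + 1))
    if kind == "categorical":
        values, probs = zip(*dist[1].items())
        return int(rng.choice(values, p=np.asarray(probs) / sum(probs)))
    raise ValueError(f"unknown distribution kind {kind!r}")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        cur = arr[i].decode()
        alternatives = [b for b in "ACGT" if b != cur]
        arr[i] = rng.choice(alternatives).encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# References


def forge_references(config: SimConfig) -> tuple[HostGenome, VectorModel]:
    """Deterministically forge the toy host genome and vector model."""
    rng = np.random.default_rng(config.seed)
    chroms = [(f"chr{i + 1}", _random_dna(rng, config.chrom_length))
              for i in range(config.n_chromosomes)]
    host = HostGenome(chroms)

    itr = _random_dna(rng, 169)
    parts = {
        "ITR5": itr,
        "enhancer": _random_dna(rng, 400),
        "promoter": _random_dna(rng, 460),
        "intron": _random_dna(rng, 550),
        "cdna": _random_dna(rng, 2550),
        "polyA": _random_dna(rng, 225),
        "ITR3": revcomp(itr),
    }
    components, pos = [], 0
    for label, seq in parts.items():
        components.append((label, (pos, pos + len(seq)), seq))
        pos += len(seq)
    vector = VectorModel(components, itr_canonical_length=169)
    return host, vector


def itr_anchor(vector: VectorModel) -> tuple[str, str]:
    """(primer anchor, expected residual ITR) as they appear at the start of
    R1: the outer 50 bp of the junction-side ITR read outward."""
    seq = vector.sequence
    full = vector.full_length
    outer = seq[full - ANCHOR_LEN - RESIDUAL_LEN:full]
    return outer[:ANCHOR_LEN], outer[ANCHOR_LEN:]


def forge_gene_models(host: HostGenome, config: SimConfig,
                      n_genes: int = 60) -> tuple[list[GeneModel], dict[str, float]]:
    """Toy gene models tiling ~40% of each chromosome plus a lognormal
    liver-expression table; a handful of genes carry HCC-screen names."""
    rng = np.random.default_rng(config.seed + 101)
    hcc_names = ["TP53", "TERT", "CTNNB1", "AXIN1", "ARID1A"]
    mouse_names = ["DLK1", "TAX1BP1", "HRAS", "SOS1", "MEG8"]
    genes: list[GeneModel] = []
    expr: dict[str, float] = {}
    gi = 0
    per_chrom = max(1, n_genes // len(host.chromosomes))
    for name, seq in host.chromosomes:
        pos = int(rng.integers(500, 3_000))
        for _ in range(per_chrom):
            length = int(rng.integers(2_000, 8_000))
            if pos + length > len(seq) - 500:
                break
            if gi < len(hcc_names):
                gid = hcc_names[gi]
            elif gi < len(hcc_names) + len(mouse_names):
                gid = mouse_names[gi - len(hcc_names)]
            else:
                gid = f"GENE{gi:04d}"
            genes.append(GeneModel(gid, name, pos, pos + length))
            expr[gid] = float(np.round(rng.lognormal(mean=1.5, sigma=2.0), 3))
            gi += 1
            pos += length + int(rng.integers(1_000, 5_000))
    return genes, expr


# ---------------------------------------------------------------------------
# Events


def _draw_copy(vector: VectorModel, rng: np.random.Generator,
               config: SimConfig, orientation: str) -> VectorCopy:
    L = vector.full_length
    k = vector.itr_canonical_length
    prom = vector.interval("promoter")
    cdna = vector.interval("cdna")

    def retained() -> int:
        if rng.random() < config.itr_intact_prob:
            return k
        lo, hi = vector.bb_loop_interval
        return int(rng.integers(lo, hi))

    if rng.random() < config.partial_copy_prob:
        if rng.random() < 0.5:  # promoter (and 5' ITR) lost, cDNA intact
            start = int(rng.integers(prom[1] + 20, cdna[0] - 120))
            r3 = retained()
            return VectorCopy(start, L - k + r3, orientation, None, r3)
        # cDNA disrupted
        r5 = retained()
        end = int(rng.integers(cdna[0] + 100, cdna[1] - 100))
        return VectorCopy(k - r5, end, orientation, r5, None)
    r5, r3 = retained(), retained()
    return VectorCopy(k - r5, L - k + r3, orientation, r5, r3)


def _draw_concatemer(vector: VectorModel, rng: np.random.Generator,
                     config: SimConfig) -> list[VectorCopy]:
    n = max(1, _draw(config.concatemer_copy_distribution, rng))
    orientation = "+" if rng.random() < 0.5 else "-"
    copies = [_draw_copy(vector, rng, config, orientation)]
    for _ in range(n - 1):
        if rng.random() >= config.same_orientation_prob:
            orientation = "-" if orientation == "+" else "+"
        copies.append(_draw_copy(vector, rng, config, orientation))
    return copies


def plant_events(host: HostGenome, vector: VectorModel,
                 config: SimConfig) -> list[IntegrationTruth]:
    """Place integration events uniformly over the host with a minimum
    pairwise spacing, each with a planted concatemer and clone count."""
    rng = np.random.default_rng(config.seed + 1)
    margin = max(config.fragment_max, config.flank_len_max) + 100
    lengths = np.array([len(s) for _, s in host.chromosomes], dtype=float)
    usable = lengths - 2 * margin
    if (usable <= 0).any():
        raise ValueError("chromosomes too short for event placement")
    probs = usable / usable.sum()
    placed: dict[str, list[int]] = {n: [] for n in host.names}
    events: list[IntegrationTruth] = []
    attempts = 0
    while len(events) < config.n_events:
        attempts += 1
        if attempts > 200 * config.n_events:
            raise RuntimeError("cannot place events with required spacing")
        ci = int(rng.choice(len(lengths), p=probs))
        name, seq = host.chromosomes[ci]
        pos = int(rng.integers(margin, len(seq) - margin))
        if seq[pos] == "N":
            continue
        if any(abs(pos - q) < config.min_event_spacing for q in placed[name]):
            continue
        placed[name].append(pos)
        copies = _draw_concatemer(vector, rng, config)
        events.append(IntegrationTruth(
            event_id=f"ev{len(events):04d}", chrom=name, position=pos,
            orientation=copies[0].orientation, copies=copies,
            clone_count=max(1, _draw(config.clone_count_distribution, rng))))
    events.sort(key=lambda e: (e.chrom, e.position))
    return events


def events_table(events: list[IntegrationTruth]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "event_id": e.event_id, "chrom": e.chrom, "position": e.position,
            "orientation": e.orientation, "clone_count": e.clone_count,
            "n_copies": len(e.copies),
            "copies": json.dumps([asdict(c) for c in e.copies]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Short anchored-PCR reads


@dataclass
class ReadPair:
    read_id: str
    r1: str
    r2: str


def make_umi(rng: np.random.Generator) -> str:
    bases = [str(rng.choice(list("ACGT"))) for _ in range(UMI_LEN)]
    bases[2] = str(rng.choice(list("AT")))
    bases[5] = str(rng.choice(list("AT")))
    umi = "".join(bases)
    if not valid_umi(umi):  # pragma: no cover - internal consistency
        raise AssertionError("generated UMI violates NNWNNWNN")
    return umi


def make_itrseq_reads(events: list[IntegrationTruth], host: HostGenome,
                      vector: VectorModel, config: SimConfig
                      ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Emit anchored-PCR read pairs plus the per-read truth table.

    Each clone of each event gets a distinct (adapter shear position, UMI)
    template; PCR duplicates re-emit the template verbatim (before errors).
    Clones at one site are guaranteed pairwise distinct in BOTH shear
    position and UMI — the evidence the clone definition requires.
    """
    rng = np.random.default_rng(config.seed + 2)
    anchor, residual = itr_anchor(vector)
    pairs: list[ReadPair] = []
    rows = []
    host_seqs = dict(host.chromosomes)
    r2_host_len = config.read_length - len(BARCODE) - UMI_LEN
    r1_host_len = config.read_length - ANCHOR_LEN - RESIDUAL_LEN
    for ev in events:
        seq = host_seqs[ev.chrom]
        used_shears: set[int] = set()
        used_umis: set[str] = set()
        for clone in range(ev.clone_count):
            while True:
                frag = int(np.clip(rng.normal(config.fragment_mean,
                                              config.fragment_sd),
                                   config.fragment_min, config.fragment_max))
                shear = ev.position + frag
                if shear not in used_shears:
                    break
            while True:
                umi = make_umi(rng)
                if umi not in used_umis:
                    break
            used_shears.add(shear)
            used_umis.add(umi)
            r1 = anchor + residual + seq[ev.position:ev.position + r1_host_len]
            r2 = BARCODE + umi + revcomp(seq[shear - r2_host_len:shear])
            n_dup = _draw(config.n_pcr_duplicates_per_read, rng)
            for dup in range(1 + n_dup):
                rid = f"{ev.event_id}|cl{clone}|d{dup}"
                pairs.append(ReadPair(
                    rid,
                    apply_substitutions(r1, config.substitution_error_rate, rng),
                    apply_substitutions(r2, config.substitution_error_rate, rng)))
                rows.append({"read_id": rid, "event_id": ev.event_id,
                             "chrom": ev.chrom, "position": ev.position,
                             "clone": clone, "duplicate": dup,
                             "adapter_coord": shear, "umi": umi})
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Long reads


@dataclass
class LongRead:
    read_id: str
    sequence: str
    truth: ReadStructure
    event_id: Optional[str] = None


def _copy_segments(copies: list[VectorCopy], vector: VectorModel,
                   read_pos: int) -> tuple[str, list[SegmentAnnotation]]:
    vseq = vector.sequence
    seq_parts: list[str] = []
    segs: list[SegmentAnnotation] = []
    pos = read_pos
    for c in copies:
        part = vseq[c.start_offset:c.end_offset]
        if c.orientation == "-":
            part = revcomp(part)
        segs.append(SegmentAnnotation(
            read_start=pos, read_end=pos + len(part), kind="vector",
            ref_name="vector", ref_start=c.start_offset,
            ref_end=c.end_offset, orientation=c.orientation))
        seq_parts.append(part)
        pos += len(part)
    return "".join(seq_parts), segs


def _truth_junctions(copies: list[VectorCopy]) -> list[str]:
    out = []
    for a, b in zip(copies, copies[1:]):
        if a.orientation == b.orientation:
            out.append("head_to_tail")
        elif (a.orientation, b.orientation) == ("+", "-"):
            out.append("tail_to_tail")
        else:
            out.append("head_to_head")
    return out


def _truth_itrs(segments: list[SegmentAnnotation], vector: VectorModel,
                min_itr: int = DEFAULT_MIN_ITR) -> list[ItrRecord]:
    """ITR records from canonical truth segments, by plain interval
    arithmetic on the vector coordinates (independent of the annotator's
    alignment-driven derivation)."""
    i5 = vector.itr5_interval
    i3 = vector.itr3_interval
    records: list[ItrRecord] = []
    copy_index = -1
    for seg in segments:
        if seg.kind != "vector":
            continue
        copy_index += 1
        found = []
        ref_lo, ref_hi = seg.max_ref_interval
        for end_label, (lo, hi) in (("5p", i5), ("3p", i3)):
            a = max(ref_lo, lo)
            b = min(ref_hi, hi)
            if b - a >= min_itr:
                intact = vector.itr_intact(b - a)
                found.append((lo, ItrRecord(copy_index, end_label, b - a, intact,
                                            None if intact else b - a)))
        found.sort(key=lambda t: t[0], reverse=(seg.orientation == "-"))
        records.extend(r for _, r in found)
    return records


def _plant_flank_indels(flank: str, rng: np.random.Generator,
                        config: SimConfig) -> tuple[str, int, int]:
    """Optionally plant one deletion and/or one insertion in a host flank
    (well inside it, away from the chimeric boundary). Returns the mutated
    flank and the planted (deleted, inserted) base counts."""
    deleted = inserted = 0
    margin = 40
    if len(flank) > 4 * margin and rng.random() < config.flank_deletion_prob:
        size = int(rng.integers(1, config.flank_indel_max + 1))
        at = int(rng.integers(margin, len(flank) - margin - size))
        flank = flank[:at] + flank[at + size:]
        deleted = size
    if len(flank) > 4 * margin and rng.random() < config.flank_insertion_prob:
        size = int(rng.integers(1, config.flank_indel_max + 1))
        at = int(rng.integers(margin, len(flank) - margin))
        flank = flank[:at] + _random_dna(rng, size) + flank[at:]
        inserted = size
    return flank, deleted, inserted


def _canonicalize(read: str, segs: list[SegmentAnnotation],
                  refs: dict[str, str]) -> list[SegmentAnnotation]:
    """Put construction-coordinate truth segments into the shared boundary
    normal form: maximal exact extension at both ends, then left-trim."""
    for seg in segs:
        ref = refs[seg.ref_name]
        seg.read_start, seg.ref_start, seg.ref_end = extend_left_exact(
            read, ref, seg.read_start, seg.ref_start, seg.ref_end,
            seg.orientation)
        seg.read_end, seg.ref_start, seg.ref_end = extend_right_exact(
            read, ref, seg.read_end, seg.ref_start, seg.ref_end,
            seg.orientation)
        seg.max_ref_start, seg.max_ref_end = seg.ref_start, seg.ref_end
    return normalize_boundaries(segs, refs.get)


def make_long_reads(events: list[IntegrationTruth], host: HostGenome,
                    vector: VectorModel, config: SimConfig
                    ) -> list[LongRead]:
    """Emit CCS-like long reads: host-only fragments, episomal concatemers,
    and integrated concatemers with one or two host flanks, each with an
    exact truth ReadStructure."""
    rng = np.random.default_rng(config.seed + 3)
    host_seqs = dict(host.chromosomes)
    refs = {"vector": vector.sequence, **host_seqs}
    reads: list[LongRead] = []
    for i in range(config.n_long_reads):
        rid = f"lr{i:05d}"
        roll = rng.random()
        if roll < config.host_only_fraction:
            name = host.names[int(rng.integers(0, len(host.names)))]
            seq = host_seqs[name]
            length = int(rng.integers(1_000, 4_000))
            start = int(rng.integers(0, len(seq) - length))
            read = seq[start:start + length]
            segs = [SegmentAnnotation(0, length, "host", name, start,
                                      start + length, "+")]
            truth = ReadStructure(rid, _canonicalize(read, segs, refs), [],
                                  [], 0, False, False, False, False,
                                  "host_only")
            reads.append(LongRead(rid, apply_substitutions(
                read, config.substitution_error_rate, rng), truth))
            continue

        if roll < config.host_only_fraction + config.episome_fraction or not events:
            copies = _draw_concatemer(vector, rng, config)
            event = None
            flank_left = flank_right = False
        else:
            event = events[int(rng.integers(0, len(events)))]
            copies = event.copies
            if rng.random() < config.capture_both_prob:
                flank_left = flank_right = True
            else:
                flank_left = rng.random() < 0.5
                flank_right = not flank_left

        parts: list[str] = []
        segs: list[SegmentAnnotation] = []
        pos = 0
        if event is not None and flank_left:
            L1 = int(rng.integers(config.flank_len_min, config.flank_len_max))
            flank = host_seqs[event.chrom][event.position - L1:event.position]
            flank, _, _ = _plant_flank_indels(flank, rng, config)
            segs.append(SegmentAnnotation(0, len(flank), "host", event.chrom,
                                          event.position - L1, event.position,
                                          "+"))
            parts.append(flank)
            pos = len(flank)
        vec_seq, vec_segs = _copy_segments(copies, vector, pos)
        parts.append(vec_seq)
        segs.extend(vec_segs)
        pos += len(vec_seq)
        if event is not None and flank_right:
            L2 = int(rng.integers(config.flank_len_min, config.flank_len_max))
            flank = host_seqs[event.chrom][event.position:event.position + L2]
            flank, _, _ = _plant_flank_indels(flank, rng, config)
            segs.append(SegmentAnnotation(pos, pos + len(flank), "host",
                                          event.chrom, event.position,
                                          event.position + L2, "+"))
            parts.append(flank)
        read = "".join(parts)

        functional = any(c.start_offset <= vector.interval("cdna")[0]
                         and c.end_offset >= vector.interval("cdna")[1]
                         for c in copies)
        promoter_up = any(c.start_offset <= vector.interval("promoter")[0]
                          and c.end_offset >= vector.interval("cdna")[1]
                          for c in copies)
        has_flank = event is not None and (flank_left or flank_right)
        canonical = _canonicalize(read, segs, refs)
        truth = ReadStructure(
            rid, canonical, _truth_junctions(copies),
            _truth_itrs(canonical, vector),
            n_itrs=len(_truth_itrs(canonical, vector)),
            has_flank=has_flank,
            both_flanks=bool(event is not None and flank_left and flank_right),
            functional_cdna=functional, promoter_upstream=promoter_up,
            classification="vector_plus_flank" if has_flank else "vector_only")
        reads.append(LongRead(rid, apply_substitutions(
            read, config.substitution_error_rate, rng), truth,
            event.event_id if event else None))
    return reads


def longreads_table(reads: list[LongRead]) -> pd.DataFrame:
    rows = []
    for r in reads:
        t = r.truth
        rows.append({
            "read_id": r.read_id, "event_id": r.event_id or "",
            "classification": t.classification,
            "both_flanks": t.both_flanks, "n_itrs": t.n_itrs,
            "functional_cdna": t.functional_cdna,
            "promoter_upstream": t.promoter_upstream,
            "junctions": json.dumps(t.junctions),
            "itrs": json.dumps([asdict(x) for x in t.itrs]),
            "segments": json.dumps([asdict(s) for s in t.segments]),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vector-prep reads (long-read QC)

PREP_REF_LENGTHS = {"plasmid_backbone": 2_500, "helper_or_trans": 3_500,
                    "producer_host": 5_000, "lambda_spike": 3_000}

DEFAULT_PREP_COMPOSITION = {"vector_full": 0.70, "vector_truncated": 0.20,
                            "plasmid_backbone": 0.05, "producer_host": 0.03,
                            "lambda_spike": 0.02}


def forge_prep_references(config: SimConfig) -> dict[str, str]:
    """Synthetic stand-ins for the non-vector references of a vector-prep QC
    run (plasmid backbone, helper/trans plasmid, producer-cell DNA, lambda
    spike-in)."""
    rng = np.random.default_rng(config.seed + 4)
    return {name: _random_dna(rng, n) for name, n in PREP_REF_LENGTHS.items()}


def make_prep_reads(vector: VectorModel, prep_refs: dict[str, str],
                    config: SimConfig, n_reads: int = 1_000,
                    composition: dict[str, float] | None = None
                    ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a vector-prep long-read run with a planted composition.

    ``composition`` maps {vector_full, vector_truncated, plasmid_backbone,
    producer_host, lambda_spike} (helper optional) to fractions summing to 1.
    """
    comp = dict(DEFAULT_PREP_COMPOSITION if composition is None else composition)
    rng = np.random.default_rng(config.seed + 5)
    labels = list(comp)
    probs = np.array([comp[k] for k in labels], dtype=float)
    probs /= probs.sum()
    vseq = vector.sequence
    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(n_reads):
        label = labels[int(rng.choice(len(labels), p=probs))]
        if label == "vector_full":
            seq = vseq
            source, truncated = "vector_genome", False
        elif label == "vector_truncated":
            # lose >=50 bp from at least one end
            start = int(rng.integers(50, len(vseq) // 3))
            end = int(rng.integers(2 * len(vseq) // 3, len(vseq) - 50))
            seq = vseq[start:end]
            source, truncated = "vector_genome", True
        else:
            ref = prep_refs[label]
            length = int(rng.integers(500, min(2_000, len(ref))))
            start = int(rng.integers(0, len(ref) - length + 1))
            seq = ref[start:start + length]
            source, truncated = label, None
        if rng.random() < 0.5:
            seq = revcomp(seq)
        rid = f"prep{i:05d}"
        reads.append((rid, apply_substitutions(
            seq, config.substitution_error_rate, rng)))
        rows.append({"read_id": rid, "source": source,
                     "truncated": truncated})
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers (text formats; gzip members carry fixed mtime for byte determinism)


def _write_gz(path: Path, text: str) -> None:
    buf = io.BytesIO()
    with gzip.GzipFile(filename="", mode="wb", fileobj=buf, mtime=0) as gz:
        gz.write(text.encode())
    path.write_bytes(buf.getvalue())


def write_fasta(path: Path, records: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq_gz(path: Path, records: list[tuple[str, str]], qual: str = "I") -> None:
    chunks = [f"@{rid}\n{seq}\n+\n{qual * len(seq)}\n" for rid, seq in records]
    _write_gz(path, "".join(chunks))


def write_gff3(path: Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\ttoy\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n")


def simulate_to_dir(config: SimConfig, out_dir: Path) -> dict:
    """Run the full simulation and write every artifact; returns a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    host, vector = forge_references(config)
    write_fasta(out_dir / "host.fa", host.chromosomes)
    write_fasta(out_dir / "vector.fa", [("vector", vector.sequence)])
    comp_rows = [{"label": lab, "start": iv[0], "end": iv[1]}
                 for lab, iv, _ in vector.components]
    pd.DataFrame(comp_rows).to_csv(out_dir / "vector_components.tsv",
                                   sep="\t", index=False)
    genes, expr = forge_gene_models(host, config)
    write_gff3(out_dir / "genes.gff3", genes)
    pd.DataFrame({"gene_id": list(expr), "nx": list(expr.values())}
                 ).to_csv(out_dir / "expression.tsv", sep="\t", index=False)
    (out_dir / "hcc_genes.txt").write_text(
        "\n".join(["TP53", "TERT", "CTNNB1", "AXIN1", "ARID1A"]) + "\n")
    (out_dir / "mouse_hcc_genes.txt").write_text(
        "\n".join(["DLK1", "TAX1BP1", "HRAS", "SOS1", "MEG8"]) + "\n")

    events = plant_events(host, vector, config)
    events_table(events).to_csv(out_dir / "events.tsv", sep="\t", index=False)
    pairs, reads_truth = make_itrseq_reads(events, host, vector, config)
    write_fastq_gz(out_dir / "itrseq_R1.fastq.gz",
                   [(p.read_id, p.r1) for p in pairs])
    write_fastq_gz(out_dir / "itrseq_R2.fastq.gz",
                   [(p.read_id, p.r2) for p in pairs])
    reads_truth.to_csv(out_dir / "reads_truth.tsv", sep="\t", index=False)
    long_reads = make_long_reads(events, host, vector, config)
    write_fastq_gz(out_dir / "longreads.fastq.gz",
                   [(r.read_id, r.sequence) for r in long_reads])
    longreads_table(long_reads).to_csv(out_dir / "longreads_truth.tsv",
                                       sep="\t", index=False)
    anchor, residual = itr_anchor(vector)
    manifest = {
        "seed": config.seed, "n_events": config.n_events,
        "n_read_pairs": len(pairs), "n_long_reads": len(long_reads),
        "itr_anchor": anchor, "itr_residual": residual,
        "barcode": BARCODE,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    return manifest
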