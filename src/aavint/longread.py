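"""Long-read (CCS-like) structural annotation of vector concatemers.

Each read is decomposed into vector-component and host segments by seeded
local alignment and weighted-interval chaining, then classified: concatemer
junction types (head-to-tail / head-to-head / tail-to-tail), ITR presence,
length and intactness (intact = observed length within the 165-173 bp
window), functional-cassette content (intact transgene cDNA, promoter
upstream in the same copy), integration status (vector + flank = host
sequence adjoining vector sequence) and flank integrity from alignment
operations. A cohort of reads is summarized in the layout of a
gene-therapy-outcome table; vector-prep reads are classified per source
reference for QC (including the lambda spike-in check).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from ._align import (
    ReferenceIndex,
    annotate_segment_alignment,
    chain_candidates,
    find_candidates,
    normalize_boundaries,
    _cand_to_segment,
)
from .models import (
    CohortSummary,
    DEFAULT_MIN_ITR,
    HostGenome,
    ItrRecord,
    PrepReadClass,
    ReadStructure,
    SegmentAnnotation,
    VectorModel,
    revcomp,
)


@dataclass
class LongReadParams:
    min_segment: int = 50
    min_identity: float = 0.90
    max_gap: int = 50            # max unaligned gap between adjoining segments
    min_flank: int = 50          # min host segment length to call integration
    min_itr: int = DEFAULT_MIN_ITR
    cdna_coverage: float = 0.99
    cdna_identity: float = 0.98
    promoter_gap: int = 10
    seed_stride: int = 5


def build_index(vector: VectorModel, host: HostGenome, k: int = 15
                ) -> ReferenceIndex:
    refs = [("vector", "vector", vector.sequence)]
    refs += [("host", name, seq) for name, seq in host.chromosomes]
    return ReferenceIndex(refs, k=k)


# ---------------------------------------------------------------------------
# Decomposition


def decompose_read(read: str, idx: ReferenceIndex,
                   params: LongReadParams | None = None
                   ) -> list[SegmentAnnotation]:
    """Greedy chaining of seeded local alignments to vector and host:
    the highest-scoring non-overlapping candidate set covering the read,
    boundaries left-normalized, segments below length/identity dropped."""
    params = params or LongReadParams()
    cands = find_candidates(read, idx, stride=params.seed_stride,
                            min_len=params.min_segment)
    chosen = chain_candidates(cands)
    segs = [_cand_to_segment(c, idx) for c in chosen]
    segs = normalize_boundaries(segs, None)
    out = []
    for seg in segs:
        if seg.read_end - seg.read_start < params.min_segment:
            continue
        annotate_segment_alignment(read, seg, idx.forward_seq(seg.ref_name))
        if seg.identity >= params.min_identity:
            out.append(seg)
    return out


# ---------------------------------------------------------------------------
# Junctions


def junction_types(segments: Sequence[SegmentAnnotation],
                   max_gap: int = 50) -> list[str]:
    """Label junctions between adjacent vector segments.

    Same orientation -> head_to_tail; (+,-) meet at the vector 3' ends ->
    tail_to_tail; (-,+) meet at the 5' ends -> head_to_head. A host segment
    (or a larger-than-max_gap hole) between two vector segments suppresses
    the junction.
    """
    out: list[str] = []
    for a, b in zip(segments, segments[1:]):
        if a.kind != "vector" or b.kind != "vector":
            continue
        if b.read_start - a.read_end > max_gap:
            continue
        if a.orientation == b.orientation:
            out.append("head_to_tail")
        elif (a.orientation, b.orientation) == ("+", "-"):
            out.append("tail_to_tail")
        else:
            out.append("head_to_head")
    return out


# ---------------------------------------------------------------------------
# ITR metrics


def itr_records(segments: Sequence[SegmentAnnotation], vector: VectorModel,
                min_itr: int = DEFAULT_MIN_ITR) -> list[ItrRecord]:
    """One record per maximal ITR-overlapping run of each vector copy.

    ``observed_length`` is the overlap of the copy's maximal exact-extension
    interval with the ITR interval — boundary-trim independent, so identical
    for a read and its reverse complement; intact means within the vector's
    intact window; truncated records carry ``breakpoint_offset`` equal to
    the observed (retained) length.
    """
    i5, i3 = vector.itr5_interval, vector.itr3_interval
    records: list[ItrRecord] = []
    copy_index = -1
    for seg in segments:
        if seg.kind != "vector":
            continue
        copy_index += 1
        found: list[tuple[int, ItrRecord]] = []
        ref_lo, ref_hi = seg.max_ref_interval
        for end_label, (lo, hi) in (("5p", i5), ("3p", i3)):
            a, b = max(ref_lo, lo), min(ref_hi, hi)
            if b - a >= min_itr:
                intact = vector.itr_intact(b - a)
                found.append((lo, ItrRecord(copy_index, end_label, b - a,
                                            intact,
                                            None if intact else b - a)))
        # read order: 5p first on a forward copy, 3p first on a reverse copy
        found.sort(key=lambda t: t[0], reverse=(seg.orientation == "-"))
        records.extend(r for _, r in found)
    return records


@dataclass
class ItrAggregates:
    count: int
    mean_length: Optional[float]
    pct_intact: Optional[float]
    max_within_read_length_diff: Optional[int]


def itr_aggregates(records: Sequence[ItrRecord]) -> ItrAggregates:
    if not records:
        return ItrAggregates(0, None, None, None)
    lengths = [r.observed_length for r in records]
    return ItrAggregates(
        count=len(records),
        mean_length=sum(lengths) / len(lengths),
        pct_intact=100.0 * sum(r.intact for r in records) / len(records),
        max_within_read_length_diff=max(lengths) - min(lengths))


# ---------------------------------------------------------------------------
# Functional cassette


def functional_cassette(segments: Sequence[SegmentAnnotation],
                        vector: VectorModel,
                        params: LongReadParams | None = None
                        ) -> tuple[bool, bool]:
    """(functional_cdna, promoter_upstream).

    functional_cdna: some vector copy covers the cDNA end-to-end (coverage
    and identity thresholds) with no rearrangement break inside it — a
    single chained segment spanning the cDNA guarantees that. The promoter
    is "upstream" when the same copy contiguously covers promoter through
    cDNA in one orientation (coverage shortfall up to promoter_gap).
    """
    params = params or LongReadParams()
    cdna = vector.interval("cdna")
    prom = vector.interval("promoter")
    cdna_len = cdna[1] - cdna[0]
    functional = promoter_up = False
    for seg in segments:
        if seg.kind != "vector" or seg.identity < params.cdna_identity:
            continue
        covered = min(seg.ref_end, cdna[1]) - max(seg.ref_start, cdna[0])
        if covered < params.cdna_coverage * cdna_len:
            continue
        functional = True
        if (seg.ref_start <= prom[0] + params.promoter_gap
                and seg.ref_end >= cdna[1]):
            promoter_up = True
    return functional, promoter_up


# ---------------------------------------------------------------------------
# Classification and flank integrity


def classify_read(segments: Sequence[SegmentAnnotation],
                  params: LongReadParams | None = None
                  ) -> tuple[str, bool, bool]:
    """(classification, has_flank, both_flanks).

    vector_plus_flank: a host segment of at least min_flank adjoins a vector
    segment within max_gap (integration evidence); both_flanks: host
    segments flank the vector run on both sides (complete capture of an
    integration, two chromosomal junctions).
    """
    params = params or LongReadParams()
    vec = [s for s in segments if s.kind == "vector"]
    hostseg = [s for s in segments
               if s.kind == "host"
               and s.read_end - s.read_start >= params.min_flank]
    if not segments:
        return "ambiguous", False, False
    if not vec:
        return ("host_only", False, False) if hostseg else ("ambiguous", False, False)
    has_flank = False
    for h in hostseg:
        for v in vec:
            gap = max(v.read_start - h.read_end, h.read_start - v.read_end)
            if gap <= params.max_gap:
                has_flank = True
    first_v = min(s.read_start for s in vec)
    last_v = max(s.read_end for s in vec)
    left = any(h.read_end <= first_v + params.max_gap for h in hostseg)
    right = any(h.read_start >= last_v - params.max_gap for h in hostseg)
    both = has_flank and left and right
    return ("vector_plus_flank" if has_flank else "vector_only"), has_flank, both


@dataclass
class FlankIntegrity:
    match_pct: float
    insertion_pct: float
    deletion_pct: float
    aligned_bases: int  # alignment columns pooled over host segments


def flank_integrity(host_segments: Sequence[SegmentAnnotation]
                    ) -> Optional[FlankIntegrity]:
    """Pooled match/insertion/deletion percentages over all host-flank
    alignment columns (match+mismatch+insertion+deletion)."""
    counts = {"match": 0, "mismatch": 0, "insertion": 0, "deletion": 0}
    for seg in host_segments:
        if seg.kind != "host":
            continue
        for op, length in seg.alignment_ops:
            counts[op] += length
    total = sum(counts.values())
    if total == 0:
        return None
    return FlankIntegrity(
        match_pct=100.0 * counts["match"] / total,
        insertion_pct=100.0 * counts["insertion"] / total,
        deletion_pct=100.0 * counts["deletion"] / total,
        aligned_bases=total)


# ---------------------------------------------------------------------------
# Per-read driver and cohort summary


def annotate_read(read_id: str, read: str, idx: ReferenceIndex,
                  vector: VectorModel,
                  params: LongReadParams | None = None) -> ReadStructure:
    params = params or LongReadParams()
    segments = decompose_read(read, idx, params)
    junctions = junction_types(segments, params.max_gap)
    itrs = itr_records(segments, vector, params.min_itr)
    functional, promoter_up = functional_cassette(segments, vector, params)
    classification, has_flank, both = classify_read(segments, params)
    return ReadStructure(
        read_id=read_id, segments=segments, junctions=junctions, itrs=itrs,
        n_itrs=len(itrs), has_flank=has_flank, both_flanks=both,
        functional_cdna=functional, promoter_upstream=promoter_up,
        classification=classification)


def summarize_cohort(structures: Sequence[ReadStructure]) -> CohortSummary:
    """Cohort roll-up in the layout of a per-sample outcome table."""
    s = CohortSummary(total_reads=len(structures))
    flanked = [st for st in structures if st.classification == "vector_plus_flank"]
    s.vector_reads = sum(st.classification in ("vector_only", "vector_plus_flank")
                         for st in structures)
    s.vector_plus_flank = len(flanked)
    s.host_only = sum(st.classification == "host_only" for st in structures)
    s.ambiguous = sum(st.classification == "ambiguous" for st in structures)
    s.functional_cdna = sum(st.functional_cdna for st in structures)
    s.cdna_plus_flank = sum(st.functional_cdna for st in flanked)
    if flanked:
        s.mean_itrs_per_flanked_read = sum(st.n_itrs for st in flanked) / len(flanked)
        s.pct_flanked_with_ge1_itr = 100.0 * sum(st.n_itrs >= 1 for st in flanked) / len(flanked)
        s.pct_flanked_with_ge2_itr = 100.0 * sum(st.n_itrs >= 2 for st in flanked) / len(flanked)
        itrs = [r for st in flanked for r in st.itrs]
        if itrs:
            s.pct_intact_itrs = 100.0 * sum(r.intact for r in itrs) / len(itrs)
            s.mean_itr_length = sum(r.observed_length for r in itrs) / len(itrs)
        fi = flank_integrity([seg for st in flanked for seg in st.segments])
        if fi is not None:
            s.flank_match_pct = fi.match_pct
            s.flank_insertion_pct = fi.insertion_pct
            s.flank_deletion_pct = fi.deletion_pct
    return s


# ---------------------------------------------------------------------------
# Vector-prep QC


@dataclass
class PrepParams:
    # semi-global (full-query) alignment enforces read coverage; identity
    # absorbs both mismatch and unaligned slack
    min_identity: float = 0.85
    end_slack: int = 10


def classify_prep_read(read_id: str, read: str, refs: dict[str, str],
                       vector: VectorModel,
                       params: PrepParams | None = None) -> PrepReadClass:
    """Assign a vector-prep read to its best-matching source reference.

    ``refs`` maps {plasmid_backbone, helper_or_trans, producer_host,
    lambda_spike} to sequences; the vector genome is taken from ``vector``.
    Vector reads are truncated when the covered ITR-to-ITR interval misses
    either terminus by more than end_slack.
    """
    params = params or PrepParams()
    all_refs = {"vector_genome": vector.sequence, **refs}
    best: tuple[float, str, Optional[tuple[int, int]]] = (-1.0, "unclassified", None)
    for source, ref in sorted(all_refs.items()):
        for query in (read, revcomp(read)):
            res = edlib.align(query, ref, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            identity = 1.0 - res["editDistance"] / len(query)
            if identity < params.min_identity:
                continue
            loc = res["locations"][0]
            interval = (loc[0], loc[1] + 1)
            if identity > best[0]:
                best = (identity, source, interval)
    if best[1] == "unclassified":
        return PrepReadClass(read_id, "unclassified")
    identity, source, interval = best
    if source != "vector_genome":
        return PrepReadClass(read_id, source)
    full = vector.full_length
    truncated = not (interval[0] <= params.end_slack
                     and interval[1] >= full - params.end_slack)
    return PrepReadClass(read_id, source, truncated=truncated,
                         covered_vector_interval=interval)


# ---------------------------------------------------------------------------
# Disk I/O


def write_structures(structures: Sequence[ReadStructure], jsonl_path) -> None:
    import json
    from dataclasses import asdict

    with open(jsonl_path, "w") as fh:
        for st in structures:
            fh.write(json.dumps(asdict(st), sort_keys=True) + "\n")


def write_cohort_summary(summary: CohortSummary, tsv_path) -> None:
    rows = [
        ("Total", summary.total_reads),
        ("Vector", summary.vector_reads),
        ("Vector + flank (confirmed integrated)", summary.vector_plus_flank),
        ("Average no. ITRs per read", summary.mean_itrs_per_flanked_read),
        ("Functional cDNA", summary.functional_cdna),
        ("cDNA + flank (confirmed integrated)", summary.cdna_plus_flank),
        ("% flanked reads with >=1 ITR", summary.pct_flanked_with_ge1_itr),
        ("% flanked reads with >=2 ITRs", summary.pct_flanked_with_ge2_itr),
        ("% intact ITRs", summary.pct_intact_itrs),
        ("Mean ITR length (bp)", summary.mean_itr_length),
        ("Flank match %", summary.flank_match_pct),
        ("Flank insertion %", summary.flank_insertion_pct),
        ("Flank deletion %", summary.flank_deletion_pct),
    ]
    with open(tsv_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{'' if value is None else value}\n")


def junction_bed(structures: Sequence[ReadStructure], bed_path) -> None:
    """Host-side junction coordinates of integrated reads."""
    with open(bed_path, "w") as fh:
        for st in structures:
            if st.classification != "vector_plus_flank":
                continue
            for a, b in zip(st.segments, st.segments[1:]):
                pair = {a.kind, b.kind}
                if pair != {"host", "vector"}:
                    continue
                h = a if a.kind == "host" else b
                coord = h.ref_end if h is a else h.ref_start
                fh.write(f"{h.ref_name}\t{coord}\t{coord + 1}\t{st.read_id}\t0\t.\n")
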