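"""ITR-seq integration-site calling.

Anchored-PCR read pairs are parsed (ITR primer anchor on R1, barcode+UMI on
R2), their host parts placed on the genome, and observations collapsed into
unique vector-genome junctions. Reads at one junction are separated into
cell clones versus PCR duplicates: a PCR duplicate shares the junction AND
the adapter shear position and/or the UMI with another read, so clones are
the connected components of the same-adapter-or-same-UMI relation within a
junction group. Unique-site counts are normalized to integrations per 100
genomes from the input DNA mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from ._align import ReferenceIndex, map_short
from .models import (
    CallSet,
    DEFAULT_GENOME_MASS_PG,
    HostGenome,
    IntegrationSiteCall,
    JunctionObservation,
    valid_umi,
)


@dataclass
class ReadLayout:
    """Library architecture: fixed primer anchor + expected residual ITR on
    R1; fixed-length barcode and UMI prefix on R2."""

    anchor: str
    residual: str
    barcode_len: int = 8
    umi_len: int = 8
    anchor_max_mismatch: int = 2
    residual_max_mismatch: int = 3


@dataclass
class CallerParams:
    min_host_len: int = 25
    min_identity: float = 0.90
    max_fragment: int = 2_000
    window: int = 0              # junction grouping window (bp)
    dup_pos_tolerance: int = 0   # adapter-position tolerance for duplicates
    umi_mismatch_tolerance: int = 0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ParsedPair:
    umi: str
    barcode: str
    itr_part: str
    host_part_r1: str
    host_part_r2: str


def parse_read_pair(r1: str, r2: str, layout: ReadLayout
                    ) -> tuple[Optional[ParsedPair], str]:
    """Split a read pair into its anchored-PCR parts.

    Returns (parsed, status); status "ok", "no_itr_anchor", "umi_invalid"
    or "too_short".
    """
    min_r1 = len(layout.anchor) + len(layout.residual) + 1
    min_r2 = layout.barcode_len + layout.umi_len + 1
    if len(r1) < min_r1 or len(r2) < min_r2:
        return None, "too_short"
    if _hamming(r1[:len(layout.anchor)], layout.anchor) > layout.anchor_max_mismatch:
        return None, "no_itr_anchor"
    itr_part = r1[len(layout.anchor):len(layout.anchor) + len(layout.residual)]
    if _hamming(itr_part, layout.residual) > layout.residual_max_mismatch:
        return None, "no_itr_anchor"
    umi = r2[layout.barcode_len:layout.barcode_len + layout.umi_len]
    if not valid_umi(umi):
        return None, "umi_invalid"
    return ParsedPair(
        umi=umi,
        barcode=r2[:layout.barcode_len],
        itr_part=itr_part,
        host_part_r1=r1[len(layout.anchor) + len(layout.residual):],
        host_part_r2=r2[layout.barcode_len + layout.umi_len:],
    ), "ok"


def build_host_index(host: HostGenome, k: int = 15) -> ReferenceIndex:
    return ReferenceIndex([("host", name, seq)
                           for name, seq in host.chromosomes], k=k)


def locate_junction(read_id: str, parsed: ParsedPair, idx: ReferenceIndex,
                    params: CallerParams
                    ) -> tuple[Optional[JunctionObservation], str]:
    """Place both host parts and derive the junction/adapter coordinates.

    R1's host part starts at the first host base adjacent to the ITR
    remnant: mapped forward, the junction is its leftmost coordinate and the
    host lies right of the vector; mapped reverse, the rightmost, host left.
    R2's host part runs from the adapter shear point back toward the
    junction on the opposite strand.
    """
    hit1, status = map_short(parsed.host_part_r1, idx, params.min_host_len,
                             params.min_identity)
    if hit1 is None:
        return None, status
    hit2, status = map_short(parsed.host_part_r2, idx, params.min_host_len,
                             params.min_identity)
    if hit2 is None:
        return None, status
    if hit1.chrom != hit2.chrom or hit1.strand == hit2.strand:
        return None, "inconsistent_pair"
    # extrapolate through any unaligned (errored) query prefix so an edge
    # substitution does not shift the inferred junction/shear coordinate
    if hit1.strand == "+":
        side = "right"
        coord = hit1.start - hit1.query_start
        adapter = hit2.end + hit2.query_start
        if not (coord <= adapter <= coord + params.max_fragment):
            return None, "inconsistent_pair"
    else:
        side = "left"
        coord = hit1.end + hit1.query_start
        adapter = hit2.start - hit2.query_start
        if not (coord - params.max_fragment <= adapter <= coord):
            return None, "inconsistent_pair"
    return JunctionObservation(read_id, hit1.chrom, coord, side, adapter,
                               parsed.umi, len(parsed.itr_part)), "ok"


def call_observations(pairs: Iterable[tuple[str, str, str]],
                      host: HostGenome, layout: ReadLayout,
                      params: CallerParams | None = None,
                      idx: ReferenceIndex | None = None
                      ) -> tuple[list[JunctionObservation], dict[str, int]]:
    """Parse and place an iterable of (read_id, r1, r2); returns accepted
    observations and a rejection-reason tally."""
    params = params or CallerParams()
    idx = idx or build_host_index(host)
    observations: list[JunctionObservation] = []
    rejected: dict[str, int] = {}
    for read_id, r1, r2 in pairs:
        parsed, status = parse_read_pair(r1, r2, layout)
        if parsed is None:
            rejected[status] = rejected.get(status, 0) + 1
            continue
        obs, status = locate_junction(read_id, parsed, idx, params)
        if obs is None:
            rejected[status] = rejected.get(status, 0) + 1
            continue
        observations.append(obs)
    return observations, rejected


# ---------------------------------------------------------------------------
# Collapse: clones vs PCR duplicates


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def n_components(self) -> int:
        return len({self.find(i) for i in range(len(self.parent))})


def count_clones(group: list[JunctionObservation],
                 dup_pos_tolerance: int = 0,
                 umi_mismatch_tolerance: int = 0) -> int:
    """Number of connected components of the duplicate-of relation (same
    adapter position OR same UMI) among observations at one junction."""
    n = len(group)
    uf = _UnionFind(n)
    if dup_pos_tolerance == 0 and umi_mismatch_tolerance == 0:
        by_adapter: dict[int, int] = {}
        by_umi: dict[str, int] = {}
        for i, obs in enumerate(group):
            if obs.adapter_coord in by_adapter:
                uf.union(by_adapter[obs.adapter_coord], i)
            else:
                by_adapter[obs.adapter_coord] = i
            if obs.umi in by_umi:
                uf.union(by_umi[obs.umi], i)
            else:
                by_umi[obs.umi] = i
    else:
        for i in range(n):
            for j in range(i + 1, n):
                same_adapter = abs(group[i].adapter_coord -
                                   group[j].adapter_coord) <= dup_pos_tolerance
                same_umi = _hamming(group[i].umi, group[j].umi) <= umi_mismatch_tolerance
                if same_adapter or same_umi:
                    uf.union(i, j)
    return uf.n_components()


def collapse_and_count(observations: list[JunctionObservation],
                       params: CallerParams | None = None,
                       sample_id: str = "sample") -> CallSet:
    """Group observations into unique junctions (within ±window bp) and
    count clones per junction."""
    params = params or CallerParams()
    groups: dict[tuple, list[JunctionObservation]] = {}
    if params.window == 0:
        for obs in observations:
            groups.setdefault((obs.chrom, obs.side, obs.coord), []).append(obs)
    else:
        by_track: dict[tuple, list[JunctionObservation]] = {}
        for obs in observations:
            by_track.setdefault((obs.chrom, obs.side), []).append(obs)
        for (chrom, side), track in by_track.items():
            track.sort(key=lambda o: o.coord)
            current: list[JunctionObservation] = []
            for obs in track:
                if current and obs.coord - current[-1].coord > params.window:
                    groups[(chrom, side, current[0].coord)] = current
                    current = []
                current.append(obs)
            if current:
                groups[(chrom, side, current[0].coord)] = current
    callset = CallSet(sample_id=sample_id,
                      params={"window": params.window,
                              "dup_pos_tolerance": params.dup_pos_tolerance})
    for (chrom, side, coord), group in groups.items():
        callset.sites.append(IntegrationSiteCall(
            chrom=chrom, coord=coord, side=side, n_reads=len(group),
            n_clones=count_clones(group, params.dup_pos_tolerance,
                                  params.umi_mismatch_tolerance)))
    callset.sort()
    return callset


# ---------------------------------------------------------------------------
# Normalization and expansion summary


def normalize_per_100_genomes(callset: CallSet, input_dna_ng: float,
                              genome_mass_pg: float = DEFAULT_GENOME_MASS_PG
                              ) -> CallSet:
    """Attach genome equivalents and per-100-genome unique-site frequency.

    genome_equivalents = input_ng * 1000 / genome_mass_pg; the sample
    frequency is unique sites * 100 / genome equivalents, and each site
    carries its own 100 / genome-equivalents contribution.
    """
    if input_dna_ng <= 0 or genome_mass_pg <= 0:
        raise ValueError("input mass and genome mass must be positive")
    ge = input_dna_ng * 1_000.0 / genome_mass_pg
    callset.genome_equivalents = ge
    callset.per_100_genomes = len(callset.sites) * 100.0 / ge
    for site in callset.sites:
        site.per_100_genomes = 100.0 / ge
    callset.params.update({"input_dna_ng": input_dna_ng,
                           "genome_mass_pg": genome_mass_pg})
    return callset


@dataclass
class ExpansionSummary:
    percent_expanded: Optional[float]
    mean_clone_size_of_expanded: Optional[float]
    largest_clone: Optional[int]
    n_sites: int = 0


def expansion_summary(callset: CallSet) -> ExpansionSummary:
    """Clonal expansion: a site is expanded when two or more clones share
    its junction. Mean clone size is averaged over expanded sites only."""
    sites = callset.sites
    if not sites:
        return ExpansionSummary(None, None, None, 0)
    expanded = [s for s in sites if s.n_clones >= 2]
    return ExpansionSummary(
        percent_expanded=100.0 * len(expanded) / len(sites),
        mean_clone_size_of_expanded=(
            sum(s.n_clones for s in expanded) / len(expanded) if expanded else None),
        largest_clone=max(s.n_clones for s in sites),
        n_sites=len(sites))


# ---------------------------------------------------------------------------
# Disk I/O


def write_callset(callset: CallSet, bed_path, tsv_path) -> None:
    """BED6+ (score = n_clones, strand encodes host side) and a full TSV."""
    import pandas as pd

    with open(bed_path, "w") as fh:
        for i, s in enumerate(callset.sites):
            strand = "+" if s.side == "right" else "-"
            fh.write(f"{s.chrom}\t{s.coord}\t{s.coord + 1}\tsite{i:05d}\t"
                     f"{s.n_clones}\t{strand}\n")
    pd.DataFrame([{
        "chrom": s.chrom, "coord": s.coord, "side": s.side,
        "n_reads": s.n_reads, "n_clones": s.n_clones,
        "per_100_genomes": s.per_100_genomes,
    } for s in callset.sites]).to_csv(tsv_path, sep="\t", index=False)
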