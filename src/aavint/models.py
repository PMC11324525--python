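"""Shared domain types for the AAV integration-analysis pipeline.

Coordinates are 0-based half-open throughout; intervals on disk use BED
conventions. DNA sequences are uppercase A/C/G/T/N strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: UMI pattern on the Y-adapter: 8-mer with fixed A/T ("weak") bases at
#: positions 3 and 6 (1-based), free A/C/G/T elsewhere.
UMI_RE = re.compile(r"^[ACGT]{2}[AT][ACGT]{2}[AT][ACGT]{2}$")

#: ITR length window (bp) within which an observed ITR counts as intact.
DEFAULT_ITR_INTACT_WINDOW = (165, 173)

#: Mass of one diploid genome in picograms, used to convert input DNA mass
#: into genome equivalents.
DEFAULT_GENOME_MASS_PG = 6.6

#: Minimum aligned ITR length (bp) that counts as one ITR record.
DEFAULT_MIN_ITR = 30

VECTOR_COMPONENT_ORDER = (
    "ITR5", "enhancer", "promoter", "intron", "cdna", "polyA", "ITR3",
)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def valid_umi(seq: str) -> bool:
    return bool(UMI_RE.match(seq))


# ---------------------------------------------------------------------------
# References


@dataclass
class HostGenome:
    """A (toy) host reference genome: ordered named chromosomes."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if set(seq) - set("ACGTN"):
                raise ValueError(f"{name}: sequence contains non-ACGTN characters")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]


@dataclass
class VectorModel:
    """ITR-to-ITR vector genome annotated by component.

    ``components`` tile the vector sequence in order without gaps:
    ITR5, enhancer, promoter, intron, cdna, polyA, ITR3.
    """

    components: list[tuple[str, tuple[int, int], str]]
    itr_canonical_length: int
    itr_intact_window: tuple[int, int] = DEFAULT_ITR_INTACT_WINDOW
    bb_loop_interval: tuple[int, int] = (64, 126)

    def __post_init__(self) -> None:
        labels = [c[0] for c in self.components]
        if tuple(labels) != VECTOR_COMPONENT_ORDER:
            raise ValueError(f"components must be {VECTOR_COMPONENT_ORDER} in order")
        pos = 0
        for label, (start, end), seq in self.components:
            if start != pos or end - start != len(seq) or end <= start:
                raise ValueError(f"component {label} does not tile the vector")
            pos = end
        lo, hi = self.itr_intact_window
        if not lo <= self.itr_canonical_length <= hi:
            raise ValueError("itr_intact_window must contain itr_canonical_length")
        if not 0 <= self.bb_loop_interval[0] < self.bb_loop_interval[1] <= self.itr_canonical_length:
            raise ValueError("bb_loop_interval must lie within the ITR")

    @property
    def sequence(self) -> str:
        return "".join(seq for _, _, seq in self.components)

    @property
    def full_length(self) -> int:
        return self.components[-1][1][1]

    def interval(self, label: str) -> tuple[int, int]:
        for lab, iv, _ in self.components:
            if lab == label:
                return iv
        raise KeyError(label)

    @property
    def itr5_interval(self) -> tuple[int, int]:
        return self.interval("ITR5")

    @property
    def itr3_interval(self) -> tuple[int, int]:
        return self.interval("ITR3")

    def itr_intact(self, observed_length: int) -> bool:
        lo, hi = self.itr_intact_window
        return lo <= observed_length <= hi


# ---------------------------------------------------------------------------
# Simulation truth


@dataclass
class VectorCopy:
    """One vector copy inside a planted concatemer."""

    start_offset: int
    end_offset: int
    orientation: str  # "+" or "-"
    itr5_retained: Optional[int] = None  # None = ITR absent (partial copy)
    itr3_retained: Optional[int] = None


@dataclass
class IntegrationTruth:
    event_id: str
    chrom: str
    position: int
    orientation: str
    copies: list[VectorCopy]
    clone_count: int

    def __post_init__(self) -> None:
        if self.clone_count < 1:
            raise ValueError("clone_count must be >= 1")
        if not self.copies:
            raise ValueError("copies must be non-empty")


# ---------------------------------------------------------------------------
# Short-read calling


@dataclass(frozen=True)
class JunctionObservation:
    """Evidence from one read pair: where the vector meets the genome, where
    the adapter was ligated (shear point) and which UMI the molecule carried."""

    read_id: str
    chrom: str
    coord: int
    side: str  # host sequence "left" or "right" of the vector
    adapter_coord: int
    umi: str
    itr_residual_length: int = 0


@dataclass
class IntegrationSiteCall:
    chrom: str
    coord: int
    side: str
    n_reads: int
    n_clones: int
    per_100_genomes: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_clones <= self.n_reads:
            raise ValueError("need 1 <= n_clones <= n_reads")


@dataclass
class CallSet:
    sample_id: str
    sites: list[IntegrationSiteCall] = field(default_factory=list)
    genome_equivalents: Optional[float] = None
    per_100_genomes: Optional[float] = None
    n_rejected: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def sort(self) -> None:
        self.sites.sort(key=lambda s: (s.chrom, s.coord, s.side))


# ---------------------------------------------------------------------------
# Annotation


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gene interval must be non-empty")


EXPRESSION_CATEGORIES = ("not_expressed", "low", "medium", "high")


def expression_category(nx: float) -> str:
    """Bin a liver normalized-expression value into the four categories:
    not expressed (nx<1), low [1,10), medium [10,100), high (>=100)."""
    if nx < 1:
        return "not_expressed"
    if nx < 10:
        return "low"
    if nx < 100:
        return "medium"
    return "high"


@dataclass
class AnnotatedSite:
    chrom: str
    coord: int
    genic: bool
    gene_id: Optional[str] = None
    category: Optional[str] = None
    hcc_hit: bool = False
    mouse_hcc_hit: bool = False


@dataclass
class EnrichmentReport:
    categories: dict[str, dict]  # name -> {observed_fraction, background_fraction, fold_change}
    n_sites: int
    n_random: int
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Long-read structures


@dataclass
class SegmentAnnotation:
    """One aligned block of a long read: read interval plus its source
    (vector or a host chromosome), orientation and alignment bookkeeping."""

    read_start: int
    read_end: int
    kind: str  # "vector" or "host"
    ref_name: str  # "vector" or chromosome name
    ref_start: int
    ref_end: int
    orientation: str  # "+" or "-"
    identity: float = 1.0
    alignment_ops: list[tuple[str, int]] = field(default_factory=list)
    #: maximal exact-extension reference interval, before adjacent-segment
    #: boundary trimming; orientation-symmetric, used for ITR bookkeeping
    max_ref_start: Optional[int] = None
    max_ref_end: Optional[int] = None

    @property
    def read_interval(self) -> tuple[int, int]:
        return (self.read_start, self.read_end)

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)

    @property
    def max_ref_interval(self) -> tuple[int, int]:
        if self.max_ref_start is None or self.max_ref_end is None:
            return (self.ref_start, self.ref_end)
        return (self.max_ref_start, self.max_ref_end)

    def key(self) -> tuple:
        return (self.read_start, self.read_end, self.kind, self.ref_name,
                self.ref_start, self.ref_end, self.orientation)


@dataclass
class ItrRecord:
    copy_index: int
    end: str  # "5p" or "3p"
    observed_length: int
    intact: bool
    breakpoint_offset: Optional[int] = None  # = observed_length when truncated


@dataclass
class ReadStructure:
    read_id: str
    segments: list[SegmentAnnotation]
    junctions: list[str]
    itrs: list[ItrRecord]
    n_itrs: int
    has_flank: bool
    both_flanks: bool
    functional_cdna: bool
    promoter_upstream: bool
    classification: str  # vector_only | vector_plus_flank | host_only | ambiguous


@dataclass
class CohortSummary:
    total_reads: int = 0
    vector_reads: int = 0
    vector_plus_flank: int = 0
    host_only: int = 0
    ambiguous: int = 0
    mean_itrs_per_flanked_read: Optional[float] = None
    functional_cdna: int = 0
    cdna_plus_flank: int = 0
    pct_flanked_with_ge1_itr: Optional[float] = None
    pct_flanked_with_ge2_itr: Optional[float] = None
    pct_intact_itrs: Optional[float] = None
    mean_itr_length: Optional[float] = None
    flank_match_pct: Optional[float] = None
    flank_insertion_pct: Optional[float] = None
    flank_deletion_pct: Optional[float] = None


PREP_SOURCES = ("vector_genome", "plasmid_backbone", "helper_or_trans",
                "producer_host", "lambda_spike", "unclassified")


@dataclass
class PrepReadClass:
    read_id: str
    source: str
    truncated: Optional[bool] = None  # defined only for vector_genome reads
    covered_vector_interval: Optional[tuple[int, int]] = None
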