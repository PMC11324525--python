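# Methods

This note documents the models, conventions and parameter choices behind
`aavint`, what the synthetic-data generator does and does not emulate, and
the numerical decisions that make truth comparison exact.

## 1. The measurement problem

Recombinant AAV genomes are single-stranded DNA bounded by two inverted
terminal repeats (ITRs). In transduced tissue they persist mainly as
circularized/concatemerized episomes; a small fraction integrates into host
chromosomes, almost always via the ITR. Two questions follow:

1. *Where and how often does the vector integrate, and do integrated clones
   expand?* — answered from anchored-PCR short reads (ITR-seq).
2. *What is the structure of the persisting vector DNA — concatemer
   configuration, ITR integrity, functional cassette content, flank
   integrity?* — answered from long consensus (CCS-like) reads.

Neither question can be answered from public data at desk scale, so the
package carries a simulator whose outputs are the test fixtures: every read
comes with complete planted truth, and the callers are held to exact
agreement with it on error-free data.

## 2. Synthetic references

* **Host genome**: 4 chromosomes × 150 kb of uniform random A/C/G/T
  (seeded). Random sequence is the hardest case for a k-mer mapper in the
  sense of having no systematic repeats, while remaining small enough for
  exhaustive testing; it does not model repeat families, GC skew or N gaps
  (N handling is implemented and tested separately).
* **Vector model**: ITR5 (169 bp), enhancer (400), promoter (460), intron
  (550), transgene cDNA (2,550), polyA (225), ITR3 (169); 4,523 bp total,
  in the size range of a real single-stranded AAV genome. ITR3 is the exact
  reverse complement of ITR5 — a true inverted terminal repeat, which is
  what makes a single ITR primer read outward across either junction.
* **ITR internal structure**: real ITRs contain internal palindromic arms
  (the B–B′ / C–C′ hairpins). The synthetic ITR is deliberately
  *non-palindromic* random sequence: internal self-similarity would make
  the base-level boundary of a truncated-ITR junction mathematically
  ambiguous and exact truth comparison impossible. The B–B′ region is
  retained as a coordinate window (default bases 64–126 of the ITR) in
  which truncation break points are drawn, reproducing the observation that
  truncations cluster near the palindromic loop with retained lengths far
  below the intact window.
* An ITR is **intact** iff its observed length lies in [165, 173] bp.
  Truncated ITR records carry `breakpoint_offset = observed_length` (the
  retained length defines where the break sits).

## 3. Planted events and short reads

Integration events are placed uniformly (length-proportional across
chromosomes) with ≥ 1.5 kb pairwise spacing — enough to keep every junction
coordinate unambiguous; 200 events is the default study scale. Each event
carries a concatemer (1–5 copies; each subsequent copy keeps the previous
orientation with probability 0.7) and a clone count drawn uniformly from
1–5.

Read layout (the real library's primer/barcode architecture is not public;
this is the package's documented stand-in):

* R1 = 20 bp ITR primer anchor + 30 bp residual ITR + host flank, reading
  outward across the junction. Anchor and residual are the outer 50 bp of
  the junction-side ITR; because ITR3 = revcomp(ITR5), the same primer
  serves both orientations, and the simulator emits the right-hand junction
  for every event.
* R2 = 8 bp sample barcode + 8 bp UMI (`NNWNNWNN`, W ∈ {A,T}) + host
  sequence reading from the adapter shear point back toward the junction.
  Shear points are Normal(500, 100) bp from the junction, clipped to
  [200, 1400].

Each clone of an event is one template with its own (shear, UMI) pair; PCR
duplicates re-emit the template verbatim before errors. Clones at one site
are guaranteed pairwise distinct in *both* shear position and UMI. This is
not a convenience: the clone definition (different adapter position *and*
different UMI) makes colliding clones indistinguishable from duplicates in
principle, so the generator enforces the identifiability its consumers are
tested against; collision probability in practice is small (UMI space
4^6·2^2, shear space ~1,200).

Errors are substitutions only (CCS/Illumina-consensus regime; indel knobs
exist for flanks, default 0). Default error rate 0 — the oracle condition;
tests also run at 0.5–1%.

## 4. Short-read calling

`parse_read_pair` verifies the anchor (≤ 2 mismatches over 20 bp) and
residual (≤ 3 over 30 bp), validates the UMI against `NNWNNWNN`, and splits
off the host parts. `locate_junction` places each host part with the k-mer
engine (below) and requires a unique best placement; equally scoring
placements at distinct loci are rejected as ambiguous, unmapped or
inconsistent pairs are tallied by reason. The junction coordinate is the
first host base adjacent to the ITR remnant; the adapter coordinate is the
shear point recovered from R2. Both coordinates are extrapolated through
any unaligned query prefix so an edge substitution cannot shift them.

Clone counting is the connected-components closure of the pairwise
duplicate rule (same adapter position and/or same UMI). Components are the
unique order-independent closure of that rule, which is why read order and
added duplicates can never change a clone count (property-tested, and
verified against a brute-force transitive-closure oracle). Junction
grouping window, adapter-position tolerance and UMI mismatch tolerance all
default to 0 (exact matching) and are exposed as parameters.

Normalization: genome equivalents = input ng × 1000 / 6.6 pg per diploid
genome (the constant is configurable); the per-sample frequency is
sites × 100 / GE, and each site carries its own 100/GE contribution.

## 5. Long-read decomposition

The annotator finds, per read, the highest-scoring set of non-overlapping
segments against the vector and host references:

1. **Seeding**: exact 15-mers (2-bit packed), both strands indexed; read
   k-mers sampled at stride 5.
2. **Clustering**: hits grouped per target into diagonal bands (band 32 bp,
   absorbing small indels), then split at read-position gaps > 200 bp.
3. **Extension**: from the outermost seeds, per-base extension; a mismatch
   is absorbed when ≥ 8 of the following 10 bases match (isolated
   sequencing errors pass; random cross-junction sequence fails with
   probability ≈ 4×10⁻⁴).
4. **Canonical ends**: each end is retracted to the nearest 12-base exact
   run and then extended by exact matches only — dropping any
   mismatch-absorbing overhang.
5. **Chaining**: weighted interval scheduling maximizing covered read bases
   (overlaps debited), ties broken by fewer segments, then leftmost;
   candidates strictly contained in longer ones are dropped first.
6. **Per-segment alignment**: edlib (global) supplies the
   match/mismatch/insertion/deletion operations and identity; segments
   below 50 bp or 90% identity are discarded.

**Boundary normal form.** At a chimeric junction the terminal read base(s)
match both adjacent references with probability ~1/4 per base, so "the"
boundary is not unique and exact truth comparison would be ill-posed. Both
the annotator and the generator's truth therefore left-normalize: each
segment's start is its maximal exact leftward extension, and the left
neighbour is trimmed to it — the segment-level analogue of indel
left-alignment. ITR lengths are *not* read off these trimmed boundaries but
off each segment's maximal exact-extension interval, which is
orientation-symmetric; this makes ITR metrics identical for a read and its
reverse complement, and equal between truth and call.

**Junction labels** come from adjacent vector-segment orientation patterns:
same → head-to-tail; (+,−) → tail-to-tail (3′ ends meet); (−,+) →
head-to-head. These patterns are invariant under reverse complement (order
reverses, orientations flip, the pattern is preserved): a 3′–3′ junction
joins the same two 3′ ends no matter which strand is read. The test suite
asserts full label preservation under RC.

**Classification**: vector + flank (integrated) needs ≥ 50 bp of host
adjoining vector within a 50 bp gap; both-flanks needs host on both sides
of the vector run. Functional cDNA: one copy covering the cDNA ≥ 99% at
≥ 98% identity (a single chained segment excludes internal rearrangement);
promoter upstream: the same copy covers promoter through cDNA contiguously.
The vector has an intron between promoter and cDNA, so "upstream" is
defined by contiguous copy coverage of the promoter→cDNA span, with the
10 bp `promoter_gap` tolerating coverage shortfall at the promoter edge —
not by genomic adjacency. Coverage/identity thresholds are not published
anywhere authoritative; they are exposed parameters with these defaults.

**Flank integrity** pools match/insertion/deletion alignment columns over
host segments: e.g. a 5-base deletion inside a 100-base flank gives
5/105 ≈ 4.76% deletion. A planted 5 bp deletion + 7 bp insertion fixture is
checked for exact per-operation totals.

**Prep QC** aligns each read semi-globally (edlib HW, both strands) to the
vector genome and the backbone/helper/producer/lambda references, assigns
the best identity ≥ 0.85, and marks vector reads truncated when the covered
ITR-to-ITR interval misses either terminus by > 10 bp. The planted default
composition is 70% full vector / 20% truncated / 5% backbone / 3% producer
host / 2% lambda spike; recovery is held to 3 binomial SD and zero lambda
escapes at error 0.

## 6. What the simulator does not emulate

PCR chimeras and amplification bias; quality-score structure (constant Q);
indel sequencing errors by default; nanopore signal artifacts; repeat
families and segmental duplications in the host; ITR secondary-structure
palindromes (see §2); multi-sample barcode demultiplexing. Passing tests
therefore demonstrate correctness of the junction/clone/structure logic
under the stated read model, not robustness to every artifact of real
libraries.

## 7. Problem sizes and determinism

Default scales — 4×150 kb host, 200 events, ~1,500 read pairs, 500 long
reads (~6 Mb), 10,000 background loci, 1,000 prep reads — were chosen so
that exhaustive truth comparison over every read remains comfortable on a
single CPU while keeping per-category counts large enough for the 3-SD/3-SE
statistical checks to be meaningful. All randomness flows from
`numpy.random.default_rng` seeded from one config seed (derived stage seeds:
+1 events, +2 short reads, +3 long reads, +4/+5 prep, +1000/+2000
background/site draws); a fixed seed reproduces byte-identical FASTQ/TSV
artifacts (gzip members are written with zero mtime) and byte-identical
pipeline reports.

## 8. Known limitations

* Segment decomposition assumes references small enough for an in-memory
  exact k-mer index (~megabases); it is not a general-purpose long-read
  mapper.
* The clone-collapse rule with nonzero adapter-position tolerance is not
  transitive; connected components remain well-defined, but a tolerance > 0
  can chain distinct clones (documented knob, default 0).
* At sequencing error > 0, truth comparison is statistical (classification
  and junction labels), since canonical boundaries on a noisy read can
  shift by up to the local error spacing.
* Left/right junction sides are called but the simulator exercises only
  right-hand junctions (one primed junction per event); merging left/right
  evidence at one locus is off by default.
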