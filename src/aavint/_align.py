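"""Seed-and-extend alignment engine for chimeric-read decomposition.

The references involved here are tiny (a few hundred kb of host plus a ~4.5 kb
vector), so segments are found with an exact k-mer index, diagonal clustering
and mismatch-tolerant extension; per-segment alignment operations and
identities come from edlib. Chaining of candidate segments over a read is
weighted interval scheduling on matched bases.

Boundary normal form: at a chimeric junction the terminal read base(s) can by
chance match both flanking references, so segment boundaries are
left-normalized (each segment's start is its maximal exact leftward
extension; the left neighbour is trimmed to it), the segment analogue of
indel left-alignment. The simulator applies the same normal form to its
truth, making exact truth/call comparison well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

from .models import SegmentAnnotation, revcomp

_BASE2BITS = {"A": 0, "C": 1, "G": 2, "T": 3}

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in _BASE2BITS.items():
    _CODE_LUT[ord(_b)] = _v


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Vector of 2-bit-packed k-mer codes for every position of ``seq``
    (-1 where the window contains a non-ACGT base)."""
    arr = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    bad = (windows == 255).any(axis=1)
    powers = (np.uint64(1) << (2 * np.arange(k - 1, -1, -1, dtype=np.uint64)))
    codes = (windows.astype(np.uint64) * powers).sum(axis=1).astype(np.int64)
    codes[bad] = -1
    return codes


@dataclass(frozen=True)
class Target:
    """One indexed reference strand."""

    kind: str       # "vector" or "host" (or "prep" for QC references)
    name: str       # reference name ("vector", chromosome, prep ref)
    strand: str     # "+" or "-"
    seq: str        # oriented sequence actually indexed
    length: int     # forward reference length


def _kmer_codes(seq: str, k: int, stride: int = 1):
    """Yield (pos, code) for exact-ACGT k-mers of ``seq`` at the stride."""
    codes = _encode_kmers(seq, k)
    for i in range(0, len(codes), stride):
        if codes[i] >= 0:
            yield i, int(codes[i])


class ReferenceIndex:
    """Exact k-mer index over a set of named references, both strands.

    The index maps each k-mer code to a packed int64 array of hits
    (target_id << 40 | position).
    """

    def __init__(self, references: list[tuple[str, str, str]], k: int = 15):
        """``references``: list of (kind, name, forward_sequence)."""
        self.k = k
        self.targets: list[Target] = []
        packed_parts: list[np.ndarray] = []
        code_parts: list[np.ndarray] = []
        for kind, name, seq in references:
            for strand in ("+", "-"):
                oriented = seq if strand == "+" else revcomp(seq)
                tid = len(self.targets)
                self.targets.append(Target(kind, name, strand, oriented, len(seq)))
                codes = _encode_kmers(oriented, k)
                valid = np.nonzero(codes >= 0)[0]
                code_parts.append(codes[valid])
                packed_parts.append((np.int64(tid) << 40) | valid.astype(np.int64))
        codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.int64)
        packed = np.concatenate(packed_parts) if packed_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        codes, packed = codes[order], packed[order]
        uniq, starts = np.unique(codes, return_index=True)
        bounds = np.append(starts, len(codes))
        self.index: dict[int, np.ndarray] = {
            int(c): packed[bounds[i]:bounds[i + 1]] for i, c in enumerate(uniq)}

    def hits(self, code: int):
        """Iterate (target_id, position) hits for a k-mer code."""
        arr = self.index.get(code)
        if arr is None:
            return
        for v in arr:
            yield int(v) >> 40, int(v) & ((1 << 40) - 1)

    def forward_seq(self, name: str) -> str:
        for t in self.targets:
            if t.name == name and t.strand == "+":
                return t.seq
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Extension

_RUN = 12  # exact-match run length anchoring canonical ends


def _extend_right(read: str, ref: str, i: int, j: int,
                  tolerant: bool) -> tuple[int, int]:
    """Extend a match ending at read[i)/ref[j) rightward.

    Exact matches always extend. With ``tolerant`` a single mismatch is
    absorbed when at least 8 of the following 10 bases match (isolated
    sequencing errors), which random cross-junction sequence virtually
    never satisfies.
    """
    n, m = len(read), len(ref)
    while i < n and j < m:
        if read[i] == ref[j]:
            i += 1
            j += 1
            continue
        if not tolerant:
            break
        look = sum(1 for d in range(1, 11)
                   if i + d < n and j + d < m and read[i + d] == ref[j + d])
        if look >= 8:
            i += 1
            j += 1
            continue
        break
    return i, j


def _extend_left(read: str, ref: str, i: int, j: int,
                 tolerant: bool) -> tuple[int, int]:
    while i > 0 and j > 0:
        if read[i - 1] == ref[j - 1]:
            i -= 1
            j -= 1
            continue
        if not tolerant:
            break
        look = sum(1 for d in range(2, 12)
                   if i - d >= 0 and j - d >= 0 and read[i - d] == ref[j - d])
        if look >= 8:
            i -= 1
            j -= 1
            continue
        break
    return i, j


def _retract_to_run(read: str, ref: str, i: int, j: int, left_end: bool) -> tuple[int, int]:
    """Pull an end back to the nearest exact _RUN-mer, dropping any
    mismatch-absorbing overhang, so canonical ends restart from certain
    ground."""
    if left_end:
        while True:
            if read[i:i + _RUN] == ref[j:j + _RUN]:
                return i, j
            if read[i] == ref[j]:
                i += 1
                j += 1
            else:
                i += 1
                j += 1
            if i >= len(read) or j >= len(ref):
                return i, j
    else:
        while i > 0 and j > 0:
            if read[i - _RUN:i] == ref[j - _RUN:j] and i >= _RUN and j >= _RUN:
                return i, j
            i -= 1
            j -= 1
        return i, j


@dataclass
class Candidate:
    tid: int
    read_start: int
    read_end: int
    t_start: int  # coordinates on the oriented target sequence
    t_end: int

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


def find_candidates(read: str, idx: ReferenceIndex, stride: int = 5,
                    min_len: int = 50, diag_band: int = 32,
                    read_gap: int = 200, tolerant: bool = True) -> list[Candidate]:
    """Seed, cluster by (target, diagonal band, read gap), and extend."""
    k = idx.k
    hits: list[tuple[int, int, int]] = []  # (tid, diag, read_pos)
    for i, code in _kmer_codes(read, k, stride):
        for tid, pos in idx.hits(code):
            hits.append((tid, pos - i, i))
    if not hits:
        return []
    hits.sort()
    # group into diagonal bands per target (indels shift the diagonal by
    # their size), then split each band at read-position gaps
    bands: list[list[tuple[int, int, int]]] = []
    for h in hits:
        if bands and bands[-1][-1][0] == h[0] \
                and h[1] - bands[-1][-1][1] <= diag_band:
            bands[-1].append(h)
        else:
            bands.append([h])
    clusters: list[list[tuple[int, int, int]]] = []
    for band in bands:
        band.sort(key=lambda h: h[2])
        current = [band[0]]
        for h in band[1:]:
            if h[2] - current[-1][2] <= read_gap:
                current.append(h)
            else:
                clusters.append(current)
                current = [h]
        clusters.append(current)
    out: list[Candidate] = []
    seen: set[tuple] = set()
    for cl in clusters:
        tid = cl[0][0]
        ref = idx.targets[tid].seq
        # leftmost / rightmost seeds anchor the extension
        left = min(cl, key=lambda h: h[2])
        right = max(cl, key=lambda h: h[2])
        li, lj = _extend_left(read, ref, left[2], left[2] + left[1], tolerant)
        ri, rj = _extend_right(read, ref, right[2] + k, right[2] + right[1] + k, tolerant)
        # canonical ends: retract to solid ground, then exact-extend
        li, lj = _retract_to_run(read, ref, li, lj, left_end=True)
        li, lj = _extend_left(read, ref, li, lj, tolerant=False)
        ri, rj = _retract_to_run(read, ref, ri, rj, left_end=False)
        ri, rj = _extend_right(read, ref, ri, rj, tolerant=False)
        if ri - li < min_len:
            continue
        key = (tid, li, ri, lj, rj)
        if key not in seen:
            seen.add(key)
            out.append(Candidate(tid, li, ri, lj, rj))
    return out


# ---------------------------------------------------------------------------
# Chaining

_MAX_OVERLAP = 200


def chain_candidates(cands: list[Candidate]) -> list[Candidate]:
    """Weighted interval scheduling over candidates: maximize covered read
    bases (overlaps debited), tie-break fewer segments then leftmost."""
    if not cands:
        return []
    cands = sorted(cands, key=lambda c: (c.read_start, c.read_end))
    # drop candidates strictly contained in a longer one
    keep = []
    for c in cands:
        if any(d.read_start <= c.read_start and c.read_end <= d.read_end
               and d.length > c.length for d in cands):
            continue
        keep.append(c)
    cands = keep
    n = len(cands)
    best: list[tuple[float, int, int]] = [(0.0, 0, -1)] * n  # (score, -count, prev)
    for i, c in enumerate(cands):
        score, count, prev = float(c.length), -1, -1
        for j in range(i):
            cj = cands[j]
            overlap = cj.read_end - c.read_start
            if overlap > min(_MAX_OVERLAP, c.length // 2, cj.length // 2):
                continue
            s = best[j][0] + c.length - max(0, overlap)
            cnt = best[j][1] - 1
            if (s, cnt) > (score, count):
                score, count, prev = s, cnt, j
        best[i] = (score, count, prev)
    end = max(range(n), key=lambda i: (best[i][0], best[i][1], -cands[i].read_start))
    chosen = []
    while end != -1:
        chosen.append(cands[end])
        end = best[end][2]
    chosen.reverse()
    return chosen


# ---------------------------------------------------------------------------
# Conversion to segments + boundary normal form + alignment ops


def _cand_to_segment(c: Candidate, idx: ReferenceIndex) -> SegmentAnnotation:
    t = idx.targets[c.tid]
    if t.strand == "+":
        ref_start, ref_end = c.t_start, c.t_end
    else:
        ref_start, ref_end = t.length - c.t_end, t.length - c.t_start
    return SegmentAnnotation(
        read_start=c.read_start, read_end=c.read_end, kind=t.kind,
        ref_name=t.name, ref_start=ref_start, ref_end=ref_end,
        orientation=t.strand, max_ref_start=ref_start, max_ref_end=ref_end)


def normalize_boundaries(segs: list[SegmentAnnotation],
                         get_ref) -> list[SegmentAnnotation]:
    """Left-normalize boundaries of read-ordered segments.

    Each segment's start is already maximal-exact-left from candidate
    construction; here the left neighbour is trimmed so adjacent segments
    do not overlap, giving contested junction bases to the right segment.
    ``get_ref(seg) -> forward reference string``.
    """
    segs = sorted(segs, key=lambda s: (s.read_start, s.read_end))
    out: list[SegmentAnnotation] = []
    for seg in segs:
        if out:
            prev = out[-1]
            if prev.read_end > seg.read_start:
                trim = prev.read_end - seg.read_start
                if trim >= prev.read_end - prev.read_start:
                    continue  # fully shadowed
                prev.read_end -= trim
                if prev.orientation == "+":
                    prev.ref_end -= trim
                else:
                    prev.ref_start += trim
        out.append(seg)
    return [s for s in out if s.read_end > s.read_start]


def extend_left_exact(read: str, ref: str, read_start: int, ref_start: int,
                      ref_end: int, orientation: str) -> tuple[int, int, int]:
    """Maximal exact leftward extension of a segment start on the read.

    Returns (read_start, ref_start, ref_end) updated. Used by the simulator
    to put its truth segments into the same normal form the caller emits.
    """
    if orientation == "+":
        i, j = read_start, ref_start
        while i > 0 and j > 0 and read[i - 1] == ref[j - 1]:
            i -= 1
            j -= 1
        return i, j, ref_end
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    i, j = read_start, ref_end
    while i > 0 and j < len(ref) and read[i - 1] == comp[ref[j]]:
        i -= 1
        j += 1
    return i, ref_start, j


def extend_right_exact(read: str, ref: str, read_end: int, ref_start: int,
                       ref_end: int, orientation: str) -> tuple[int, int, int]:
    if orientation == "+":
        i, j = read_end, ref_end
        while i < len(read) and j < len(ref) and read[i] == ref[j]:
            i += 1
            j += 1
        return i, ref_start, j
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    i, j = read_end, ref_start
    while i < len(read) and j > 0 and read[i] == comp[ref[j - 1]]:
        i += 1
        j -= 1
    return i, j, ref_end


_CIGAR_OP = {"=": "match", "X": "mismatch", "I": "insertion", "D": "deletion"}


def alignment_ops(read_part: str, ref_part: str) -> tuple[list[tuple[str, int]], float]:
    """Global-align a read segment to its reference span with edlib.

    Returns (ops, identity) where ops is a run-length list over
    match/mismatch/insertion/deletion (insertion = base present in the read,
    absent from the reference) and identity = matches / alignment columns.
    """
    if not read_part or not ref_part:
        return [], 0.0
    res = edlib.align(read_part, ref_part, mode="NW", task="path")
    cigar = res["cigar"] or ""
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            op = _CIGAR_OP[ch]
            length = int(num)
            num = ""
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + length)
            else:
                ops.append((op, length))
    cols = sum(l for _, l in ops)
    matches = sum(l for op, l in ops if op == "match")
    return ops, (matches / cols if cols else 0.0)


def annotate_segment_alignment(read: str, seg: SegmentAnnotation,
                               forward_ref: str) -> None:
    """Fill ``alignment_ops`` and ``identity`` of a segment in place."""
    part = read[seg.read_start:seg.read_end]
    ref_part = forward_ref[seg.ref_start:seg.ref_end]
    if seg.orientation == "-":
        ref_part = revcomp(ref_part)
    seg.alignment_ops, seg.identity = alignment_ops(part, ref_part)


# ---------------------------------------------------------------------------
# Unique mapping of short host fragments


@dataclass
class ShortHit:
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    #: aligned query interval (query bases outside it are unaligned clip)
    query_start: int = 0
    query_end: int = 0


def map_short(seq: str, idx: ReferenceIndex, min_len: int = 25,
              min_identity: float = 0.9) -> tuple[Optional[ShortHit], str]:
    """Place a short fragment uniquely on the host.

    Returns (hit, status); status is "ok", "unmappable" or "ambiguous"
    (two equally scoring placements at different loci).
    """
    if len(seq) < min_len:
        return None, "unmappable"
    cands = find_candidates(seq, idx, stride=5, min_len=min(min_len, len(seq)),
                            tolerant=True)
    scored: list[tuple[float, Candidate]] = []
    for c in cands:
        t = idx.targets[c.tid]
        # require the candidate to cover nearly the whole fragment
        if c.length < 0.9 * len(seq):
            continue
        _, ident = alignment_ops(seq[c.read_start:c.read_end],
                                 t.seq[c.t_start:c.t_end])
        if ident >= min_identity:
            scored.append((c.length * ident, c))
    if not scored:
        return None, "unmappable"
    scored.sort(key=lambda x: -x[0])
    if len(scored) > 1 and abs(scored[0][0] - scored[1][0]) < 1e-9:
        a, b = scored[0][1], scored[1][1]
        if (a.tid, a.t_start) != (b.tid, b.t_start):
            return None, "ambiguous"
    best = scored[0][1]
    t = idx.targets[best.tid]
    if t.strand == "+":
        start, end = best.t_start, best.t_end
    else:
        start, end = t.length - best.t_end, t.length - best.t_start
    _, ident = alignment_ops(seq[best.read_start:best.read_end],
                             t.seq[best.t_start:best.t_end])
    return ShortHit(t.name, start, end, t.strand, ident,
                    best.read_start, best.read_end), "ok"
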