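"""Long-read structural annotation: segment decomposition against planted
truth, junction labeling, ITR intactness, functional-cassette calls, flank
integrity bookkeeping and prep-read classification."""

import numpy as np
import pytest

from aavint import longread as lr
from aavint import simulate as sim
from aavint.models import (
    ItrRecord,
    SegmentAnnotation,
    VectorCopy,
    revcomp,
)


def structure_fields(st):
    return (st.classification, st.both_flanks, st.functional_cdna,
            st.promoter_upstream, st.junctions, st.n_itrs,
            [(r.end, r.observed_length, r.intact) for r in st.itrs],
            [s.key() for s in st.segments])


def test_structures_match_truth_exactly(long_reads, longread_index, vector):
    for r in long_reads:
        st = lr.annotate_read(r.read_id, r.sequence, longread_index, vector)
        assert structure_fields(st) == structure_fields(r.truth), r.read_id


def test_segments_ordered_nonoverlapping(long_reads, longread_index, vector):
    for r in long_reads[:20]:
        st = lr.annotate_read(r.read_id, r.sequence, longread_index, vector)
        for a, b in zip(st.segments, st.segments[1:]):
            assert a.read_end <= b.read_start
        covered = sum(s.read_end - s.read_start for s in st.segments)
        assert covered >= 0.98 * len(r.sequence)


def test_pure_host_read_is_host_only(host, longread_index, vector):
    seq = host.chromosomes[0][1][10_000:13_000]
    st = lr.annotate_read("h", seq, longread_index, vector)
    assert st.classification == "host_only"
    assert len(st.segments) == 1 and st.segments[0].kind == "host"
    assert st.n_itrs == 0 and not st.functional_cdna


def test_unalignable_read_is_ambiguous(longread_index, vector):
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    st = lr.annotate_read("x", seq, longread_index, vector)
    assert st.classification == "ambiguous"


# ---------------------------------------------------------------------------
# Junction typing


def _vseg(start, end, orientation, read_start=0):
    return SegmentAnnotation(read_start, read_start + (end - start), "vector",
                             "vector", start, end, orientation)


def test_junction_type_definitions(vector):
    L = vector.full_length
    pp = [_vseg(0, L, "+"), _vseg(0, L, "+", L)]
    assert lr.junction_types(pp) == ["head_to_tail"]
    mm = [_vseg(0, L, "-"), _vseg(0, L, "-", L)]
    assert lr.junction_types(mm) == ["head_to_tail"]
    pm = [_vseg(0, L, "+"), _vseg(0, L, "-", L)]
    assert lr.junction_types(pm) == ["tail_to_tail"]
    mp = [_vseg(0, L, "-"), _vseg(0, L, "+", L)]
    assert lr.junction_types(mp) == ["head_to_head"]
    # a host segment between vector copies suppresses the junction
    interrupted = [_vseg(0, L, "+"),
                   SegmentAnnotation(L, L + 500, "host", "chr1", 0, 500, "+"),
                   _vseg(0, L, "+", L + 500)]
    assert lr.junction_types(interrupted) == []


def test_reverse_complement_invariance(long_reads, longread_index, vector):
    """Classification, ITR metrics and junction labels are preserved when a
    read is annotated from the opposite strand (junction order reverses)."""
    for r in long_reads:
        a = lr.annotate_read(r.read_id, r.sequence, longread_index, vector)
        b = lr.annotate_read(r.read_id, revcomp(r.sequence), longread_index,
                             vector)
        assert a.classification == b.classification
        assert a.both_flanks == b.both_flanks
        assert a.functional_cdna == b.functional_cdna
        assert a.promoter_upstream == b.promoter_upstream
        assert a.n_itrs == b.n_itrs
        assert [(x.end, x.observed_length, x.intact) for x in a.itrs] == \
               [(x.end, x.observed_length, x.intact) for x in reversed(b.itrs)]
        assert a.junctions == list(reversed(b.junctions))


# ---------------------------------------------------------------------------
# ITR metrics


def test_itr_intact_window_rule(vector):
    """Planted retained lengths {102,145,164,165,169,173,174} map to intact
    flags {F,F,F,T,T,T,F} under the 165-173 bp window."""
    L = vector.full_length
    k = vector.itr_canonical_length
    expected = {102: False, 145: False, 164: False, 165: True,
                169: True, 173: True, 174: False}
    # the window rule itself, including an over-long observation (174)
    for length, want_intact in expected.items():
        assert vector.itr_intact(length) == want_intact, length
    # lengths realizable as retained ITR portions of a 169 bp canonical ITR
    for retained, want_intact in expected.items():
        if retained > k:
            continue
        seg = _vseg(k - retained, L, "+")
        records = lr.itr_records([seg], vector)
        rec5 = [r for r in records if r.end == "5p"][0]
        assert rec5.observed_length == retained
        assert rec5.intact == want_intact, retained
        if not rec5.intact:
            assert rec5.breakpoint_offset == rec5.observed_length
        else:
            assert rec5.breakpoint_offset is None


def test_itr_records_per_copy_and_aggregates(vector):
    L = vector.full_length
    k = vector.itr_canonical_length
    segs = [_vseg(k - 102, L, "+"), _vseg(0, L, "+", L)]
    records = lr.itr_records(segs, vector)
    assert [(r.copy_index, r.end, r.observed_length) for r in records] == \
        [(0, "5p", 102), (0, "3p", k), (1, "5p", k), (1, "3p", k)]
    agg = lr.itr_aggregates(records)
    assert agg.count == 4
    assert agg.pct_intact == pytest.approx(75.0)
    assert agg.max_within_read_length_diff == k - 102
    # equal truncations -> zero homogeneity difference
    equal = lr.itr_records([_vseg(k - 120, L - k + 120, "+")] * 2, vector)
    assert lr.itr_aggregates(equal).max_within_read_length_diff == 0
    # reverse-orientation copy lists its 3' ITR first in read order
    rev = lr.itr_records([_vseg(0, L, "-")], vector)
    assert [r.end for r in rev] == ["3p", "5p"]


def test_short_itr_fragment_below_min_is_not_counted(vector):
    L = vector.full_length
    seg = _vseg(vector.itr_canonical_length - 20, L, "+")  # 20 bp of 5' ITR
    records = lr.itr_records([seg], vector)
    assert [r.end for r in records] == ["3p"]


# ---------------------------------------------------------------------------
# Functional cassette


def test_functional_cassette_calls(vector):
    L = vector.full_length
    cdna = vector.interval("cdna")
    prom = vector.interval("promoter")
    full = _vseg(0, L, "+")
    assert lr.functional_cassette([full], vector) == (True, True)
    cut = _vseg(0, cdna[0] + 500, "+")  # truncated inside the cDNA
    assert lr.functional_cassette([cut], vector) == (False, False)
    no_prom = _vseg(prom[1] + 30, L, "+")  # promoter deleted, cDNA intact
    assert lr.functional_cassette([no_prom], vector) == (True, False)
    low_identity = _vseg(0, L, "+")
    low_identity.identity = 0.90
    assert lr.functional_cassette([low_identity], vector) == (False, False)


# ---------------------------------------------------------------------------
# Classification and flank integrity


def test_classification_rules(vector):
    L = vector.full_length
    vec = _vseg(0, L, "+", 600)
    left = SegmentAnnotation(0, 600, "host", "chr1", 5_000, 5_600, "+")
    right = SegmentAnnotation(600 + L, 600 + L + 400, "host", "chr1",
                              5_600, 6_000, "+")
    assert lr.classify_read([vec]) == ("vector_only", False, False)
    assert lr.classify_read([left, vec]) == ("vector_plus_flank", True, False)
    assert lr.classify_read([left, vec, right]) == ("vector_plus_flank", True, True)
    assert lr.classify_read([left]) == ("host_only", False, False)
    assert lr.classify_read([]) == ("ambiguous", False, False)
    # a sub-min_flank host fragment does not qualify as integration evidence
    stub = SegmentAnnotation(570, 600, "host", "chr1", 5_570, 5_600, "+")
    assert lr.classify_read([stub, vec])[0] == "vector_only"


def test_min_flank_monotonicity(long_reads, longread_index, vector):
    """Raising min_flank never increases the vector_plus_flank count."""
    counts = []
    for min_flank in (50, 300, 1_000):
        params = lr.LongReadParams(min_flank=min_flank)
        n = sum(lr.annotate_read(r.read_id, r.sequence, longread_index,
                                 vector, params).classification
                == "vector_plus_flank" for r in long_reads[:30])
        counts.append(n)
    assert counts[0] >= counts[1] >= counts[2]


def _host_seg(ops):
    seg = SegmentAnnotation(0, 100, "host", "chr1", 0, 100, "+")
    seg.alignment_ops = ops
    return seg


def test_flank_integrity_bookkeeping():
    perfect = lr.flank_integrity([_host_seg([("match", 100)])])
    assert (perfect.match_pct, perfect.insertion_pct,
            perfect.deletion_pct) == (100.0, 0.0, 0.0)
    # planted 5-base deletion inside a 100-base flank: 105 alignment columns
    deleted = lr.flank_integrity(
        [_host_seg([("match", 60), ("deletion", 5), ("match", 40)])])
    assert deleted.deletion_pct == pytest.approx(100 * 5 / 105)
    assert deleted.match_pct == pytest.approx(100 * 100 / 105)
    # pooling equals column-weighted mean of per-flank values
    pooled = lr.flank_integrity(
        [_host_seg([("match", 100)]),
         _host_seg([("match", 60), ("deletion", 5), ("match", 40)])])
    assert pooled.deletion_pct == pytest.approx(100 * 5 / 205)
    assert lr.flank_integrity([]) is None


def test_planted_flank_indels_recovered(references, longread_index, vector):
    """Flank indels planted by the simulator come back through the aligner's
    operation lists with matching pooled percentages."""
    host, _ = references
    cfg = sim.SimConfig(seed=21, n_events=10, n_long_reads=25,
                        episome_fraction=0.0, host_only_fraction=0.0,
                        flank_deletion_prob=0.6, flank_insertion_prob=0.4)
    events = sim.plant_events(host, vector, cfg)
    reads = sim.make_long_reads(events, host, vector, cfg)
    any_indel = False
    for r in reads:
        st = lr.annotate_read(r.read_id, r.sequence, longread_index, vector)
        got = lr.flank_integrity(st.segments)
        assert got is not None
        if got.insertion_pct or got.deletion_pct:
            any_indel = True
        # host segments must still be single blocks spanning each flank
        hosts = [s for s in st.segments if s.kind == "host"]
        truth_hosts = [s for s in r.truth.segments if s.kind == "host"]
        assert len(hosts) == len(truth_hosts)
        for a, b in zip(hosts, truth_hosts):
            assert a.ref_name == b.ref_name
            assert abs(a.read_start - b.read_start) <= 15
            assert abs(a.read_end - b.read_end) <= 15
    assert any_indel


# ---------------------------------------------------------------------------
# Cohort summary


def test_summarize_cohort_matches_truth(long_reads, longread_index, vector):
    structures = [lr.annotate_read(r.read_id, r.sequence, longread_index,
                                   vector) for r in long_reads]
    truth = [r.truth for r in long_reads]
    got = lr.summarize_cohort(structures)
    want = lr.summarize_cohort(truth)
    # truth records carry no alignment ops, so flank-integrity fields are
    # checked separately: error-free flanks must be 100% match
    for name in ("total_reads", "vector_reads", "vector_plus_flank",
                 "host_only", "ambiguous", "mean_itrs_per_flanked_read",
                 "functional_cdna", "cdna_plus_flank",
                 "pct_flanked_with_ge1_itr", "pct_flanked_with_ge2_itr",
                 "pct_intact_itrs", "mean_itr_length"):
        assert getattr(got, name) == getattr(want, name), name
    assert got.flank_match_pct == pytest.approx(100.0)
    assert got.flank_insertion_pct == 0.0 and got.flank_deletion_pct == 0.0
    assert got.vector_plus_flank <= got.vector_reads <= got.total_reads
    assert got.cdna_plus_flank <= got.functional_cdna
    flanked = [t for t in truth if t.classification == "vector_plus_flank"]
    assert got.mean_itrs_per_flanked_read == pytest.approx(
        sum(t.n_itrs for t in flanked) / len(flanked))


def test_summarize_cohort_edge_cases():
    s = lr.summarize_cohort([])
    assert s.total_reads == 0 and s.mean_itrs_per_flanked_read is None
    episomes = [lr.ReadStructure(f"r{i}", [], [], [], 2, False, False,
                                 True, True, "vector_only") for i in range(3)]
    s2 = lr.summarize_cohort(episomes)
    assert s2.vector_plus_flank == 0 and s2.cdna_plus_flank == 0
    assert s2.functional_cdna == 3
    # two flanked reads with 2 and 3 ITRs -> mean 2.5
    fl = [lr.ReadStructure("a", [], [], [], 2, True, False, False, False,
                           "vector_plus_flank"),
          lr.ReadStructure("b", [], [], [], 3, True, False, False, False,
                           "vector_plus_flank")]
    assert lr.summarize_cohort(fl).mean_itrs_per_flanked_read == pytest.approx(2.5)


# ---------------------------------------------------------------------------
# Prep-read QC


def test_classify_prep_reads(vector, small_config):
    refs = sim.forge_prep_references(small_config)
    full = lr.classify_prep_read("r1", vector.sequence, refs, vector)
    assert full.source == "vector_genome" and full.truncated is False
    trunc = lr.classify_prep_read("r2", vector.sequence[400:3_000], refs, vector)
    assert trunc.source == "vector_genome" and trunc.truncated is True
    lam = lr.classify_prep_read("r3", refs["lambda_spike"][100:1_200], refs, vector)
    assert lam.source == "lambda_spike"
    rc = lr.classify_prep_read(
        "r4", revcomp(refs["plasmid_backbone"][0:900]), refs, vector)
    assert rc.source == "plasmid_backbone"
    rng = np.random.default_rng(9)
    junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
    assert lr.classify_prep_read("r5", junk, refs, vector).source == "unclassified"


def test_prep_composition_recovery(vector, small_config):
    refs = sim.forge_prep_references(small_config)
    reads, truth = sim.make_prep_reads(vector, refs, small_config, n_reads=300)
    t = truth.set_index("read_id")
    correct = 0
    lambda_escapes = 0
    for rid, seq in reads:
        c = lr.classify_prep_read(rid, seq, refs, vector)
        row = t.loc[rid]
        if c.source == row.source:
            correct += 1
            if row.source == "vector_genome":
                assert c.truncated == row.truncated
        if row.source == "lambda_spike" and c.source != "lambda_spike":
            lambda_escapes += 1
    assert lambda_escapes == 0
    assert correct == len(reads)
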