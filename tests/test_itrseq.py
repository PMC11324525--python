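"""ITR-seq caller: read parsing, junction placement, clone-vs-duplicate
collapse (connected components of the same-adapter-or-same-UMI relation),
normalization arithmetic and expansion summary."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from aavint import itrseq
from aavint import simulate as sim
from aavint.models import JunctionObservation


# ---------------------------------------------------------------------------
# Parsing


def test_parse_accepts_valid_pair(layout):
    r1 = layout.anchor + layout.residual + "ACGT" * 20
    r2 = "ACGTACGT" + "ACTGGTAA" + "TTGGCCAA" * 10
    parsed, status = itrseq.parse_read_pair(r1, r2, layout)
    assert status == "ok"
    assert parsed.umi == "ACTGGTAA"  # positions 3 and 6 are A/T: valid
    assert parsed.host_part_r1 == "ACGT" * 20
    assert parsed.host_part_r2 == "TTGGCCAA" * 10


def test_parse_rejects_bad_umi(layout):
    r1 = layout.anchor + layout.residual + "ACGT" * 20
    r2 = "ACGTACGT" + "ACGGGCAA" + "A" * 50  # position 3 is G
    parsed, status = itrseq.parse_read_pair(r1, r2, layout)
    assert parsed is None and status == "umi_invalid"


def test_parse_rejects_missing_anchor(layout):
    r1 = "T" * 150  # random host read without the ITR primer
    r2 = "ACGTACGT" + "ACTGGTAA" + "A" * 50
    parsed, status = itrseq.parse_read_pair(r1, r2, layout)
    assert parsed is None and status == "no_itr_anchor"


def test_parse_tolerates_anchor_mismatches(layout):
    mutated = ("G" if layout.anchor[0] != "G" else "C") + layout.anchor[1:]
    r1 = mutated + layout.residual + "ACGT" * 20
    r2 = "ACGTACGT" + "ACTGGTAA" + "TTGGCCAA" * 10
    _, status = itrseq.parse_read_pair(r1, r2, layout)
    assert status == "ok"


# ---------------------------------------------------------------------------
# Junction placement


def test_error_free_pairs_recover_exact_coordinates(short_reads, host_index,
                                                    layout, events):
    pairs, truth = short_reads
    obs, rejected = itrseq.call_observations(
        [(p.read_id, p.r1, p.r2) for p in pairs[:100]], None, layout,
        idx=host_index)
    assert not rejected
    t = truth.set_index("read_id")
    for o in obs:
        row = t.loc[o.read_id]
        assert (o.chrom, o.coord) == (row.chrom, row.position)
        assert o.adapter_coord == row.adapter_coord
        assert o.umi == row.umi
        assert o.side == "right"


def test_errored_pairs_still_place(references, layout, host_index):
    host, vector = references
    cfg = sim.SimConfig(seed=13, n_events=10, substitution_error_rate=0.01)
    ev = sim.plant_events(host, vector, cfg)
    pairs, truth = sim.make_itrseq_reads(ev, host, vector, cfg)
    obs, rejected = itrseq.call_observations(
        [(p.read_id, p.r1, p.r2) for p in pairs], None, layout, idx=host_index)
    t = truth.set_index("read_id")
    placed = sum((o.chrom, o.coord) == (t.loc[o.read_id].chrom,
                                        t.loc[o.read_id].position)
                 for o in obs)
    assert placed / len(pairs) > 0.9


def test_ambiguous_multimapper_rejected():
    """A host part matching two identical planted segments is ambiguous."""
    from aavint._align import ReferenceIndex, map_short
    import numpy as np

    rng = np.random.default_rng(0)
    unique = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
    segment = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    chrom = unique[:1000] + segment + unique[1000:3000] + segment + unique[3000:]
    idx = ReferenceIndex([("host", "chrA", chrom)])
    hit, status = map_short(segment[50:150], idx)
    assert hit is None and status == "ambiguous"
    hit, status = map_short(unique[100:200], idx)
    assert status == "ok" and (hit.start, hit.end) == (100, 200)


# ---------------------------------------------------------------------------
# Collapse: clones vs PCR duplicates


def _obs(coord, adapter, umi, rid="r"):
    return JunctionObservation(rid, "chr1", coord, "right", adapter, umi)


def _brute_force_clones(group):
    """Independent oracle: transitive closure of the pairwise duplicate
    relation by fixpoint iteration over observation sets."""
    sets = [{i} for i in range(len(group))]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(sets)), 2):
            gi, gj = sets[i], sets[j]
            if any(group[a].adapter_coord == group[b].adapter_coord
                   or group[a].umi == group[b].umi
                   for a in gi for b in gj):
                sets[i] = gi | gj
                del sets[j]
                changed = True
                break
    return len(sets)


def test_collapse_chained_duplicates_matches_brute_force():
    # {(1200,U1),(1200,U2),(1350,U1),(1500,U3)}: U1 chains reads 1-3 -> 2 clones
    group = [_obs(500, 1200, "AATAATAA"), _obs(500, 1200, "CCTCCTCC"),
             _obs(500, 1350, "AATAATAA"), _obs(500, 1500, "GGTGGTGG")]
    assert _brute_force_clones(group) == 2
    assert itrseq.count_clones(group) == 2


@settings(max_examples=200, deadline=None)
@given(st.lists(st.tuples(st.integers(1000, 1005), st.integers(0, 5)),
                min_size=1, max_size=12))
def test_collapse_matches_brute_force_random(pairs):
    umis = ["AATAATAA", "CCTCCTCC", "GGTGGTGG", "TTATTATT",
            "ACTACTAC", "GCTGCTGC"]
    group = [_obs(500, a, umis[u]) for a, u in pairs]
    assert itrseq.count_clones(group) == _brute_force_clones(group)


def test_all_shared_is_one_clone():
    group = [_obs(500, 1200, "AATAATAA") for _ in range(5)]
    assert itrseq.count_clones(group) == 1


@settings(max_examples=50, deadline=None)
@given(st.data())
def test_adding_pcr_duplicates_never_changes_clone_count(data):
    """Re-emitting any existing observation (same junction, adapter and UMI)
    leaves n_clones of every site unchanged; so does read order."""
    umis = ["AATAATAA", "CCTCCTCC", "GGTGGTGG", "TTATTATT"]
    base = data.draw(st.lists(
        st.tuples(st.sampled_from([100, 200]), st.integers(1000, 1004),
                  st.integers(0, 3)), min_size=1, max_size=10))
    obs = [_obs(c, a, umis[u], rid=f"r{i}") for i, (c, a, u) in enumerate(base)]
    before = {(s.chrom, s.coord): s.n_clones
              for s in itrseq.collapse_and_count(obs).sites}
    dup_of = data.draw(st.integers(0, len(obs) - 1))
    src = obs[dup_of]
    obs_plus = obs + [JunctionObservation("dup", src.chrom, src.coord,
                                          src.side, src.adapter_coord, src.umi)]
    perm = data.draw(st.permutations(obs_plus))
    after = {(s.chrom, s.coord): s.n_clones
             for s in itrseq.collapse_and_count(list(perm)).sites}
    assert before == after


def test_collapse_on_simulated_sample_matches_truth(short_reads, host_index,
                                                    layout, events):
    pairs, _ = short_reads
    obs, _ = itrseq.call_observations(
        [(p.read_id, p.r1, p.r2) for p in pairs], None, layout, idx=host_index)
    callset = itrseq.collapse_and_count(obs)
    called = {(s.chrom, s.coord): s.n_clones for s in callset.sites}
    planted = {(e.chrom, e.position): e.clone_count for e in events}
    assert called == planted


def test_grouping_window():
    obs = [_obs(100, 1000, "AATAATAA"), _obs(102, 2000, "CCTCCTCC")]
    assert len(itrseq.collapse_and_count(obs).sites) == 2
    wide = itrseq.CallerParams(window=5)
    merged = itrseq.collapse_and_count(obs, wide)
    assert len(merged.sites) == 1
    assert merged.sites[0].n_clones == 2


# ---------------------------------------------------------------------------
# Normalization and expansion


def _callset(clones):
    cs = itrseq.CallSet(sample_id="s")
    for i, n in enumerate(clones):
        cs.sites.append(itrseq.IntegrationSiteCall("chr1", 100 * i, "right",
                                                   n_reads=n, n_clones=n))
    return cs


def test_normalization_closed_form():
    cs = _callset([1] * 30)
    itrseq.normalize_per_100_genomes(cs, input_dna_ng=100.0, genome_mass_pg=6.6)
    assert cs.genome_equivalents == pytest.approx(15151.515, abs=0.01)
    assert cs.per_100_genomes == pytest.approx(30 * 100 / 15151.515, rel=1e-4)
    assert cs.per_100_genomes == pytest.approx(0.198, abs=0.0005)


def test_normalization_scaling_grid():
    for n_sites in (1, 10, 50):
        for ng in (25.0, 100.0, 400.0):
            cs = _callset([1] * n_sites)
            itrseq.normalize_per_100_genomes(cs, ng, 6.6)
            expected = n_sites * 100.0 * 6.6 / (ng * 1000.0)
            assert cs.per_100_genomes == pytest.approx(expected, rel=1e-9)
    # doubling mass halves the frequency
    a, b = _callset([1] * 10), _callset([1] * 10)
    itrseq.normalize_per_100_genomes(a, 100.0, 6.6)
    itrseq.normalize_per_100_genomes(b, 200.0, 6.6)
    assert a.per_100_genomes == pytest.approx(2 * b.per_100_genomes)


def test_normalization_rejects_nonpositive_mass():
    with pytest.raises(ValueError):
        itrseq.normalize_per_100_genomes(_callset([1]), 0.0, 6.6)
    with pytest.raises(ValueError):
        itrseq.normalize_per_100_genomes(_callset([1]), 10.0, -1.0)


def test_zero_sites_zero_frequency():
    cs = itrseq.CallSet(sample_id="s")
    itrseq.normalize_per_100_genomes(cs, 100.0, 6.6)
    assert cs.per_100_genomes == 0.0


def test_expansion_summary_examples():
    s = itrseq.expansion_summary(_callset([1, 1, 2, 3]))
    assert s.percent_expanded == pytest.approx(50.0)
    assert s.mean_clone_size_of_expanded == pytest.approx(2.5)
    assert s.largest_clone == 3
    s0 = itrseq.expansion_summary(_callset([1, 1, 1]))
    assert s0.percent_expanded == 0.0
    assert s0.mean_clone_size_of_expanded is None
    assert s0.largest_clone == 1
    empty = itrseq.expansion_summary(itrseq.CallSet(sample_id="s"))
    assert empty.percent_expanded is None and empty.largest_clone is None
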