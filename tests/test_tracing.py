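import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedtrace.iomodel import (
    ALT_HOM,
    GeneticMap,
    GenotypeMatrix,
    HET,
    MISSING_CALL,
    OriginMatrix,
    Pedigree,
    PedigreeRecord,
    REF_HOM,
)
from pedtrace.labels import CONFLICT, MISSING, ambiguous, source
from pedtrace.segments import compile_all_segments, count_recombinations
from pedtrace.tracing import (
    assign_anchor_markers,
    impute_from_flanks,
    singleton_report,
    smooth_singletons,
    trace_generation,
)

S1, S2 = source("p1"), source("p2")
AMB = ambiguous("p1", "p2")


def _assign(prog, p1, p2):
    return assign_anchor_markers(
        np.array(prog, dtype=np.int8),
        np.array(p1, dtype=np.int8),
        np.array(p2, dtype=np.int8),
        "p1",
        "p2",
    )


# ---------------------------------------------------------------------------
# assign_anchor_markers
# ---------------------------------------------------------------------------

def test_anchor_match_gives_source():
    # progeny A, p1 A, p2 B
    assert _assign([REF_HOM], [REF_HOM], [ALT_HOM])[0] == S1
    assert _assign([ALT_HOM], [REF_HOM], [ALT_HOM])[0] == S2


def test_identical_parents_give_ambiguous():
    assert _assign([REF_HOM], [REF_HOM], [REF_HOM])[0] == AMB


def test_nonparental_allele_gives_conflict():
    # progeny B, p1 A, p2 A
    assert _assign([ALT_HOM], [REF_HOM], [REF_HOM])[0] == CONFLICT


def test_het_or_missing_progeny_gives_missing():
    assert _assign([HET], [REF_HOM], [ALT_HOM])[0] == MISSING
    assert _assign([MISSING_CALL], [REF_HOM], [ALT_HOM])[0] == MISSING


def test_het_parent_gives_ambiguous_not_conflict():
    # p2 het carries the progeny allele, so no conflict
    assert _assign([ALT_HOM], [REF_HOM], [HET])[0] == AMB


def test_row_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        _assign([0, 0], [0], [2])


calls = st.sampled_from([REF_HOM, HET, ALT_HOM, MISSING_CALL])


@given(st.lists(st.tuples(calls, calls, calls), min_size=1, max_size=40))
def test_never_source_when_parents_equal(rows):
    prog, p1, p2 = (np.array(x, dtype=np.int8) for x in zip(*rows))
    out = assign_anchor_markers(prog, p1, p2, "p1", "p2")
    for lab, a, b in zip(out, p1, p2):
        if a == b:
            assert not lab.is_source


# ---------------------------------------------------------------------------
# impute_from_flanks
# ---------------------------------------------------------------------------

def _map_one_chrom(n):
    return GeneticMap([f"m{i}" for i in range(n)], ["c1"] * n, list(range(n)))


def test_impute_fills_agreeing_run():
    row = np.array([S1, AMB, AMB, S1], dtype=object)
    out = impute_from_flanks(row, _map_one_chrom(4))
    assert list(out) == [S1, S1, S1, S1]


def test_impute_leaves_disagreeing_run():
    row = np.array([S1, AMB, S2], dtype=object)
    out = impute_from_flanks(row, _map_one_chrom(3))
    assert list(out) == [S1, AMB, S2]


def test_impute_leaves_chromosome_end_run():
    row = np.array([AMB, S1, S1], dtype=object)
    out = impute_from_flanks(row, _map_one_chrom(3))
    assert out[0] == AMB


def test_impute_fills_conflict_only_inside_agreeing_run():
    row = np.array([S1, CONFLICT, S1, CONFLICT, S2], dtype=object)
    out = impute_from_flanks(row, _map_one_chrom(5))
    assert list(out) == [S1, S1, S1, CONFLICT, S2]


def test_impute_does_not_cross_chromosomes():
    gmap = GeneticMap(["a", "b", "c", "d"], ["c1", "c1", "c2", "c2"], [0, 1, 0, 1])
    row = np.array([S1, AMB, AMB, S1], dtype=object)
    out = impute_from_flanks(row, gmap)
    assert list(out) == [S1, AMB, AMB, S1]


labels_strategy = st.sampled_from([S1, S2, AMB, CONFLICT, MISSING])


def _brute_force_impute(row, gmap):
    """Independent oracle: per-position nearest SOURCE anchor on each side."""
    out = row.copy()
    for _, sl in gmap.chromosome_slices():
        chunk = row[sl]
        for i, lab in enumerate(chunk):
            if lab.is_source:
                continue
            left = next((chunk[j] for j in range(i - 1, -1, -1) if chunk[j].is_source), None)
            right = next((chunk[j] for j in range(i + 1, len(chunk)) if chunk[j].is_source), None)
            if left is not None and right is not None and left == right:
                out[sl.start + i] = left
    return out


@settings(max_examples=200, deadline=None)
@given(st.lists(labels_strategy, min_size=1, max_size=30), st.integers(1, 3))
def test_impute_matches_brute_force_oracle(labs, n_chrom):
    n = len(labs)
    chroms = [f"c{min(i * n_chrom // n, n_chrom - 1)}" for i in range(n)]
    gmap = GeneticMap([f"m{i}" for i in range(n)], chroms, list(range(n)))
    row = np.array(labs, dtype=object)
    assert list(impute_from_flanks(row, gmap)) == list(_brute_force_impute(row, gmap))


@settings(max_examples=100, deadline=None)
@given(st.lists(labels_strategy, min_size=1, max_size=30))
def test_impute_idempotent_and_preserves_sources(labs):
    gmap = _map_one_chrom(len(labs))
    row = np.array(labs, dtype=object)
    once = impute_from_flanks(row, gmap)
    assert list(impute_from_flanks(once, gmap)) == list(once)
    for before, after in zip(row, once):
        if before.is_source:
            assert after == before


# ---------------------------------------------------------------------------
# trace_generation
# ---------------------------------------------------------------------------

def test_progeny_identical_to_p1_all_source_p1(two_chrom_map, trio_pedigree):
    n = len(two_chrom_map)
    p1 = np.full(n, REF_HOM, dtype=np.int8)
    p2 = np.full(n, ALT_HOM, dtype=np.int8)
    gm = GenotypeMatrix(["p1", "p2", "kid"], two_chrom_map.marker_ids,
                        np.stack([p1, p2, p1]))
    origins, summary = trace_generation(gm, trio_pedigree, two_chrom_map)
    assert all(lab == S1 for lab in origins.row("kid"))
    segs = compile_all_segments(origins, two_chrom_map)
    assert count_recombinations(segs) == 0
    assert summary.loc[0, "fraction_unassigned"] == 0.0


def test_line_with_ungenotyped_parent_skipped(two_chrom_map, caplog):
    ped = Pedigree([
        PedigreeRecord("p1"), PedigreeRecord("p2"), PedigreeRecord("p3"),
        PedigreeRecord("ok", "p1", "p2"), PedigreeRecord("orphan", "p1", "p3"),
    ])
    n = len(two_chrom_map)
    gm = GenotypeMatrix(
        ["p1", "p2", "ok", "orphan"],
        two_chrom_map.marker_ids,
        np.stack([np.full(n, REF_HOM, np.int8), np.full(n, ALT_HOM, np.int8),
                  np.full(n, REF_HOM, np.int8), np.full(n, REF_HOM, np.int8)]),
    )
    with caplog.at_level(logging.WARNING):
        origins, _ = trace_generation(gm, ped, two_chrom_map)
    assert origins.line_ids == ["ok"]
    assert any("orphan" in rec.message for rec in caplog.records)


def test_no_traceable_line_is_error(two_chrom_map):
    ped = Pedigree([PedigreeRecord("solo")])
    n = len(two_chrom_map)
    gm = GenotypeMatrix(["solo"], two_chrom_map.marker_ids,
                        np.full((1, n), REF_HOM, np.int8))
    with pytest.raises(ValueError, match="no requested line"):
        trace_generation(gm, ped, two_chrom_map, lines=["solo"])


def test_traced_origins_match_simulator_truth(sim_result, sim_traced):
    """Ground-truth oracle: at markers outside breakpoint uncertainty
    intervals every SOURCE label equals the simulated truth."""
    origins, _ = sim_traced
    truth = sim_result.truth.origins
    ped = sim_result.pedigree
    geno = sim_result.genotypes
    agree = total = 0
    for line in origins.line_ids:
        p1, p2 = ped.parents_of(line)
        anchors = assign_anchor_markers(
            geno.row(line), geno.row(p1), geno.row(p2), p1, p2
        )
        src_idx = np.array([i for i, lab in enumerate(anchors) if lab.is_source])
        excluded = np.zeros(len(anchors), dtype=bool)
        for _, left, right in sim_result.truth.breakpoints[line]:
            lo = src_idx[src_idx <= left].max() if (src_idx <= left).any() else 0
            hi = (src_idx[src_idx >= right].min() if (src_idx >= right).any()
                  else len(anchors) - 1)
            excluded[lo + 1:hi] = True
        t_row, o_row = truth.row(line), origins.row(line)
        for j in range(len(anchors)):
            if o_row[j].is_source and not excluded[j]:
                total += 1
                agree += o_row[j] == t_row[j]
    assert total > 1000
    assert agree / total >= 0.99


def test_unassigned_fraction_lower_bound():
    # k of m markers with identical parents must stay unassigned pre-imputation
    m, k = 10, 4
    p1 = np.array([REF_HOM] * m, dtype=np.int8)
    p2 = np.array([ALT_HOM] * (m - k) + [REF_HOM] * k, dtype=np.int8)
    prog = p1.copy()
    out = assign_anchor_markers(prog, p1, p2, "p1", "p2")
    unassigned = sum(1 for lab in out if not lab.is_source)
    assert unassigned / m >= k / m


# ---------------------------------------------------------------------------
# singletons
# ---------------------------------------------------------------------------

def test_singleton_detected():
    gmap = _map_one_chrom(3)
    om = OriginMatrix(["L"], gmap.marker_ids,
                      np.array([[S1, S2, S1]], dtype=object))
    rep = singleton_report(om, gmap)
    assert len(rep) == 1
    assert rep.loc[0, "marker"] == "m1"
    assert rep.loc[0, "source"] == "p2"


def test_no_singleton_in_uniform_row():
    gmap = _map_one_chrom(3)
    om = OriginMatrix(["L"], gmap.marker_ids,
                      np.array([[S1, S1, S1]], dtype=object))
    assert len(singleton_report(om, gmap)) == 0


def test_forced_double_crossover_reported_as_singleton():
    """Scripted crossovers either side of one marker -> exactly that marker."""
    from pedtrace.simulate import simulate_gamete

    n = 9
    gmap = _map_one_chrom(n)
    hap = np.stack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    rng = np.random.default_rng(0)
    k = 4
    gam = simulate_gamete(hap, gmap, rng,
                          forced_crossovers={"c1": [k - 0.5, k + 0.5]})
    row = np.array([S2 if v else S1 for v in gam], dtype=object)
    om = OriginMatrix(["L"], gmap.marker_ids, row.reshape(1, -1))
    rep = singleton_report(om, gmap)
    assert list(rep["marker"]) == [f"m{k}"]


def test_smooth_singletons_relabels_ambiguous():
    gmap = _map_one_chrom(3)
    om = OriginMatrix(["L"], gmap.marker_ids,
                      np.array([[S1, S2, S1]], dtype=object))
    smoothed = smooth_singletons(om, gmap)
    assert smoothed.row("L")[1] == AMB
    # original untouched
    assert om.row("L")[1] == S2
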