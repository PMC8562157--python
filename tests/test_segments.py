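import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedtrace.iomodel import GeneticMap, OriginMatrix
from pedtrace.labels import CONFLICT, MISSING, ambiguous, source
from pedtrace.segments import (
    IBDSegment,
    RecombinationEvent,
    call_allele_by_flanks,
    compile_all_segments,
    compile_segments,
    count_recombinations,
    export_segments_bed,
    find_recombination_events,
    intact_chromosome_stats,
    read_segments_bed,
)
from pedtrace.simulate import simulate_meiosis

S1, S2 = source("p1"), source("p2")
AMB = ambiguous("p1", "p2")


def _map(n, chrom="c1"):
    return GeneticMap([f"{chrom}_m{i}" for i in range(n)], [chrom] * n,
                      list(range(n)))


def row(*labels):
    return np.array(labels, dtype=object)


# ---------------------------------------------------------------------------
# compile_segments
# ---------------------------------------------------------------------------

def test_compile_two_segments():
    segs = compile_segments(row(S1, S1, S2), _map(3), "L")
    assert [(s.source, s.n_markers) for s in segs] == [(S1, 2), (S2, 1)]
    assert segs[0].start_index == 0 and segs[0].end_index == 1


def test_all_ambiguous_chromosome_single_segment():
    segs = compile_segments(row(AMB, AMB, AMB), _map(3), "L")
    assert len(segs) == 1 and segs[0].source == AMB


labels_strategy = st.sampled_from([S1, S2, AMB, CONFLICT, MISSING])


@settings(max_examples=100, deadline=None)
@given(st.lists(labels_strategy, min_size=1, max_size=30))
def test_segment_coverage_and_maximality(labs):
    gmap = _map(len(labs))
    segs = compile_segments(np.array(labs, dtype=object), gmap, "L")
    assert sum(s.n_markers for s in segs) == len(labs)
    for a, b in zip(segs, segs[1:]):
        assert a.source != b.source
        assert b.start_index == a.end_index + 1


# ---------------------------------------------------------------------------
# recombination counting
# ---------------------------------------------------------------------------

def test_count_simple_switches():
    segs = compile_segments(row(S1, S1, S2, S2, S1), _map(5), "L")
    assert count_recombinations(segs) == 2


def test_ambiguous_run_spans_one_event():
    segs = compile_segments(row(S1, AMB, S2), _map(3), "L")
    assert count_recombinations(segs) == 1
    ev = find_recombination_events(segs)[0]
    assert (ev.left_anchor_index, ev.right_anchor_index) == (0, 2)
    assert ev.source_left == S1 and ev.source_right == S2


def test_ambiguous_between_same_source_counts_zero():
    segs = compile_segments(row(S1, AMB, S1), _map(3), "L")
    assert count_recombinations(segs) == 0


def _brute_force_count(labs):
    """Oracle: pairwise scan over the SOURCE subsequence."""
    sources = [lab for lab in labs if lab.is_source]
    return sum(1 for a, b in zip(sources, sources[1:]) if a != b)


@settings(max_examples=150, deadline=None)
@given(st.lists(labels_strategy, min_size=1, max_size=40))
def test_count_matches_brute_force(labs):
    segs = compile_segments(np.array(labs, dtype=object), _map(len(labs)), "L")
    assert count_recombinations(segs) == _brute_force_count(labs)


def test_event_invariants():
    with pytest.raises(ValueError, match="different sources"):
        RecombinationEvent("L", "c", 0, 1, S1, S1)
    with pytest.raises(ValueError, match="precede"):
        RecombinationEvent("L", "c", 2, 1, S1, S2)


# ---------------------------------------------------------------------------
# intact chromosomes
# ---------------------------------------------------------------------------

def test_all_source_p1_everywhere_intact():
    gmap = GeneticMap(["a", "b", "c", "d"], ["c1", "c1", "c2", "c2"], [0, 1, 0, 1])
    om = OriginMatrix(["L"], gmap.marker_ids,
                      row(S1, S1, S1, S1).reshape(1, -1))
    stats = intact_chromosome_stats(om, gmap)
    assert stats.per_line.loc["L"] == 2
    assert stats.fraction == 1.0
    assert stats.lines_with_intact == 1


def test_flanked_ambiguous_chromosome_is_intact():
    gmap = _map(3)
    om = OriginMatrix(["L"], gmap.marker_ids, row(S1, AMB, S1).reshape(1, -1))
    assert intact_chromosome_stats(om, gmap).per_line.loc["L"] == 1


@settings(max_examples=100, deadline=None)
@given(st.lists(labels_strategy, min_size=1, max_size=25))
def test_intact_iff_one_source_and_zero_recombinations(labs):
    gmap = _map(len(labs))
    om = OriginMatrix(["L"], gmap.marker_ids,
                      np.array(labs, dtype=object).reshape(1, -1))
    stats = intact_chromosome_stats(om, gmap)
    segs = compile_segments(np.array(labs, dtype=object), gmap, "L")
    distinct = {lab for lab in labs if lab.is_source}
    expected = int(len(distinct) == 1 and count_recombinations(segs) == 0)
    assert stats.per_line.loc["L"] == expected


def test_simulated_fraction_matches_truth_oracle(sim_result):
    """Fraction of intact chromosomes in the truth origins equals the value
    implied by the recorded true breakpoints."""
    truth = sim_result.truth.origins
    gmap = sim_result.gmap
    stats = intact_chromosome_stats(truth, gmap)
    chrom_slices = gmap.chromosome_slices()
    expected = 0
    for line in truth.line_ids:
        bp_chroms = {c for c, _, _ in sim_result.truth.breakpoints[line]}
        expected += sum(1 for c, _ in chrom_slices if c not in bp_chroms)
    assert stats.n_intact == expected


def test_mean_recombinations_match_haldane_waddington_limit():
    """Selfed-to-fixation RILs show ~2 origin switches per Morgan."""
    rng = np.random.default_rng(21)
    n, L = 200, 100.0  # 1 Morgan, dense markers
    gmap = GeneticMap([f"m{i}" for i in range(n)], ["c1"] * n,
                      [L * i / (n - 1) for i in range(n)])
    p1 = np.full(n, 0, dtype=np.int8)
    p2 = np.full(n, 2, dtype=np.int8)
    counts = []
    for _ in range(300):
        _, _, _, bps = simulate_meiosis("p1", "p2", p1, p2, gmap, 20, rng)
        counts.append(len(bps))
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean - 2.0) <= 3 * se + 0.05


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def test_bed_record_coordinates(tmp_path):
    gmap = GeneticMap(["m1", "m2"], ["chr1", "chr1"], [100, 200], unit="bp")
    seg = IBDSegment("L1", "chr1", 0, 1, S1)
    out = tmp_path / "segs.bed"
    export_segments_bed([seg], gmap, out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("track")
    assert lines[1] == "chr1\t100\t201\tL1:p1"


def test_bed_empty_list_header_only(tmp_path):
    gmap = GeneticMap(["m1"], ["chr1"], [0], unit="bp")
    out = tmp_path / "empty.bed"
    export_segments_bed([], gmap, out)
    content = out.read_text().splitlines()
    assert len(content) == 1 and content[0].startswith("track")


def test_bed_roundtrip(tmp_path):
    gmap = GeneticMap(["m1", "m2", "m3"], ["chr1"] * 3, [10, 20, 30], unit="bp")
    segs = [IBDSegment("L1", "chr1", 0, 1, S1), IBDSegment("L1", "chr1", 2, 2, S2)]
    out = tmp_path / "segs.bed"
    export_segments_bed(segs, gmap, out)
    df = read_segments_bed(out)
    assert list(df["start"]) == [10, 30]
    assert list(df["end"]) == [21, 31]
    assert list(df["source"]) == [S1, S2]


def test_bed_cm_map_uses_index_coordinates(tmp_path):
    gmap = _map(3)  # cM unit
    out = tmp_path / "segs.bed"
    export_segments_bed([IBDSegment("L1", "c1", 1, 2, S1)], gmap, out)
    lines = out.read_text().splitlines()
    assert "marker_index" in lines[0]
    assert lines[1].split("\t")[1:3] == ["1", "3"]


# ---------------------------------------------------------------------------
# allele calling by flanks
# ---------------------------------------------------------------------------

def test_flank_call_agreeing_sources():
    gmap = _map(2)
    om = OriginMatrix(["L1", "L2"], gmap.marker_ids,
                      np.array([[S1, S1], [S1, S2]], dtype=object))
    calls = call_allele_by_flanks(om, ("c1", "c1_m0", "c1_m1"))
    assert calls.loc["L1"] == "p1"
    assert calls.loc["L2"] is None


def test_flank_call_missing_marker_rejected():
    gmap = _map(2)
    om = OriginMatrix(["L1"], gmap.marker_ids,
                      np.array([[S1, S1]], dtype=object))
    with pytest.raises(ValueError, match="flanking marker"):
        call_allele_by_flanks(om, ("c1", "c1_m0", "nope"))


def test_flank_call_concordance_on_simulated_gene():
    """A scripted qualitative locus between two 1 cM flanks: descent-based
    calls agree with the true origin at the gene in >= 90% of lines."""
    rng = np.random.default_rng(9)
    n = 101
    gmap = GeneticMap([f"m{i}" for i in range(n)], ["c1"] * n,
                      [float(i) for i in range(n)])  # 1 cM spacing
    p1 = np.full(n, 0, dtype=np.int8)
    p2 = np.full(n, 2, dtype=np.int8)
    gene_idx = 50
    lines, rows, true_allele = [], [], {}
    for i in range(800):
        _, origin, _, _ = simulate_meiosis("p1", "p2", p1, p2, gmap, 5, rng)
        lid = f"L{i:03d}"
        lines.append(lid)
        rows.append(origin)
        true_allele[lid] = origin[gene_idx].source_id
    om = OriginMatrix(lines, gmap.marker_ids, np.stack(rows))
    calls = call_allele_by_flanks(om, ("c1", f"m{gene_idx - 1}", f"m{gene_idx + 1}"))
    called = calls[calls.notna()]
    assert len(called) > 400
    concordance = np.mean([called.loc[l] == true_allele[l] for l in called.index])
    assert concordance >= 0.9


def test_compile_all_segments_covers_matrix(sim_traced, sim_result):
    origins, _ = sim_traced
    segs = compile_all_segments(origins, sim_result.gmap)
    total = sum(s.n_markers for s in segs)
    assert total == len(origins.line_ids) * len(sim_result.gmap)
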