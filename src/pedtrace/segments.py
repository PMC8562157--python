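"""IBD segment compilation, recombination events, and summary statistics.

Segments are maximal same-label runs per chromosome (run-length encoding
of an origin row).  A recombination event is an ordered pair of adjacent
SOURCE segments with different sources; any intervening ambiguous/
conflict/missing run is the breakpoint *uncertainty interval* — the
crossover happened somewhere inside it but cannot be delimited between
two adjacent markers.  Breakpoints are therefore always reported as
intervals, never point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .iomodel import GeneticMap, OriginMatrix
from .labels import OriginLabel

__all__ = [
    "IBDSegment",
    "RecombinationEvent",
    "compile_segments",
    "compile_all_segments",
    "count_recombinations",
    "find_recombination_events",
    "IntactStats",
    "intact_chromosome_stats",
    "export_segments_bed",
    "read_segments_bed",
    "call_allele_by_flanks",
    "paint_segments",
]


@dataclass(frozen=True)
class IBDSegment:
    """Maximal same-label run; indices are 0-based inclusive positions
    *within the chromosome*."""

    line_id: str
    chromosome: str
    start_index: int
    end_index: int
    source: OriginLabel

    @property
    def n_markers(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class RecombinationEvent:
    """Breakpoint between two differently-sourced segments.  The anchors
    are the within-chromosome indices of the nearest SOURCE markers on each
    side; the crossover lies in the open interval between them."""

    line_id: str
    chromosome: str
    left_anchor_index: int
    right_anchor_index: int
    source_left: OriginLabel
    source_right: OriginLabel

    def __post_init__(self) -> None:
        if self.source_left == self.source_right:
            raise ValueError("recombination event requires two different sources")
        if not self.left_anchor_index < self.right_anchor_index:
            raise ValueError("left anchor must precede right anchor")


def compile_segments(
    origin_row: np.ndarray, gmap: GeneticMap, line_id: str = ""
) -> list[IBDSegment]:
    """Run-length encode an origin row per chromosome."""
    origin_row = np.asarray(origin_row, dtype=object)
    if origin_row.shape != (len(gmap),):
        raise ValueError("origin row length does not match map")
    segments: list[IBDSegment] = []
    for chrom, sl in gmap.chromosome_slices():
        chunk = origin_row[sl]
        start = 0
        for i in range(1, len(chunk) + 1):
            if i == len(chunk) or chunk[i] != chunk[start]:
                segments.append(IBDSegment(line_id, chrom, start, i - 1, chunk[start]))
                start = i
    return segments


def compile_all_segments(origins: OriginMatrix, gmap: GeneticMap) -> list[IBDSegment]:
    if origins.marker_ids != gmap.marker_ids:
        gmap = gmap.subset(origins.marker_ids)
    out: list[IBDSegment] = []
    for line_id in origins.line_ids:
        out.extend(compile_segments(origins.row(line_id), gmap, line_id))
    return out


def count_recombinations(segments: Sequence[IBDSegment]) -> int:
    """Number of source changes between consecutive SOURCE segments, per
    chromosome, summed.  An intervening non-SOURCE run between two
    different sources counts as exactly one event; between two identical
    sources it counts as zero (the run is transparent)."""
    return len(find_recombination_events(segments))


def find_recombination_events(
    segments: Sequence[IBDSegment],
) -> list[RecombinationEvent]:
    """Adjacent differently-sourced SOURCE segments, with the breakpoint
    uncertainty interval spanning any intervening non-SOURCE run."""
    events: list[RecombinationEvent] = []
    by_chrom: dict[tuple[str, str], list[IBDSegment]] = {}
    for seg in segments:
        by_chrom.setdefault((seg.line_id, seg.chromosome), []).append(seg)
    for (line_id, chrom), segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start_index)
        src = [s for s in segs if s.source.is_source]
        for left, right in zip(src, src[1:]):
            if left.source != right.source:
                events.append(
                    RecombinationEvent(
                        line_id,
                        chrom,
                        left.end_index,
                        right.start_index,
                        left.source,
                        right.source,
                    )
                )
    return events


@dataclass
class IntactStats:
    """Chromosomes inherited whole from a single source."""

    per_line: pd.Series  # line id -> number of intact chromosomes
    n_intact: int
    n_total: int  # lines x chromosomes
    fraction: float
    lines_with_intact: int  # lines with >= 1 intact chromosome


def intact_chromosome_stats(origins: OriginMatrix, gmap: GeneticMap) -> IntactStats:
    """A chromosome is *intact* for a line iff exactly one distinct SOURCE
    is present on it and no recombination event occurs — ambiguous,
    conflict and missing labels are transparent."""
    if origins.marker_ids != gmap.marker_ids:
        gmap = gmap.subset(origins.marker_ids)
    chrom_slices = gmap.chromosome_slices()
    counts: dict[str, int] = {}
    for line_id in origins.line_ids:
        row = origins.row(line_id)
        n = 0
        for _, sl in chrom_slices:
            sources = {lab for lab in row[sl] if lab.is_source}
            if len(sources) == 1:
                n += 1
        counts[line_id] = n
    per_line = pd.Series(counts, name="n_intact")
    n_total = len(origins.line_ids) * len(chrom_slices)
    n_intact = int(per_line.sum())
    return IntactStats(
        per_line=per_line,
        n_intact=n_intact,
        n_total=n_total,
        fraction=n_intact / n_total if n_total else 0.0,
        lines_with_intact=int((per_line > 0).sum()),
    )


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def export_segments_bed(
    segments: Sequence[IBDSegment], gmap: GeneticMap, path: str | Path
) -> None:
    """Write BED4 records: chrom, start (position of first marker, 0-based),
    end (position after last marker, half-open), name = ``line:source``.

    Maps in cM export marker *index* coordinates instead of positions; a
    header note records which convention is in force.
    """
    chrom_start = {c: sl.start for c, sl in gmap.chromosome_slices()}
    use_positions = gmap.unit == "bp"
    note = "coord=bp" if use_positions else "coord=marker_index (map unit is cM)"
    with open(path, "w") as fh:
        fh.write(f'track name=ibd_segments description="{note}"\n')
        for seg in segments:
            if use_positions:
                base = chrom_start[seg.chromosome]
                start = int(gmap.positions[base + seg.start_index])
                end = int(gmap.positions[base + seg.end_index]) + 1
            else:
                start = seg.start_index
                end = seg.end_index + 1
            fh.write(
                f"{seg.chromosome}\t{start}\t{end}\t{seg.line_id}:{seg.source.encode()}\n"
            )


def read_segments_bed(path: str | Path) -> pd.DataFrame:
    """Read back a BED file written by :func:`export_segments_bed`."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("track") or not raw.strip():
                continue
            chrom, start, end, name = raw.rstrip("\n").split("\t")
            line_id, src = name.rsplit(":", 1)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "line": line_id,
                    "source": OriginLabel.decode(src),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "line", "source"])


# ---------------------------------------------------------------------------
# Allele calling by flanking markers
# ---------------------------------------------------------------------------

def call_allele_by_flanks(
    origins: OriginMatrix, locus: tuple[str, str, str]
) -> pd.Series:
    """Genotype an untyped gene by descent: for each line, return the
    source id when both immediate flanking markers carry the same SOURCE,
    else ``None`` (no call).

    ``locus`` is (chromosome, left marker id, right marker id).
    """
    chrom, left_marker, right_marker = locus
    try:
        jl = origins.marker_ids.index(left_marker)
        jr = origins.marker_ids.index(right_marker)
    except ValueError as exc:
        raise ValueError(f"flanking marker not found: {exc}") from None
    calls: dict[str, str | None] = {}
    for line_id in origins.line_ids:
        row = origins.row(line_id)
        a, b = row[jl], row[jr]
        calls[line_id] = a.source_id if (a.is_source and a == b) else None
    return pd.Series(calls, name=f"{chrom}:{left_marker}-{right_marker}")


# ---------------------------------------------------------------------------
# Painting
# ---------------------------------------------------------------------------

def paint_segments(
    origins: OriginMatrix,
    gmap: GeneticMap,
    lines: Sequence[str] | None = None,
    path: str | Path | None = None,
):
    """Minimal per-line chromosome scatter of origin labels (one panel per
    line; x = chromosome, y = marker position, colour = source)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if origins.marker_ids != gmap.marker_ids:
        gmap = gmap.subset(origins.marker_ids)
    if lines is None:
        lines = origins.line_ids
    all_labels = sorted(
        {lab.encode() for l in lines for lab in origins.row(l)}
    )
    cmap = plt.get_cmap("tab10")
    colors = {lab: cmap(i % 10) for i, lab in enumerate(all_labels)}
    chrom_slices = gmap.chromosome_slices()
    chrom_x = {c: x for x, (c, _) in enumerate(chrom_slices)}

    fig, axes = plt.subplots(
        1, len(lines), figsize=(3 * len(lines), 4), squeeze=False, sharey=True
    )
    for ax, line_id in zip(axes[0], lines):
        row = origins.row(line_id)
        for chrom, sl in chrom_slices:
            xs = np.full(sl.stop - sl.start, chrom_x[chrom], dtype=float)
            ys = gmap.positions[sl]
            cs = [colors[lab.encode()] for lab in row[sl]]
            ax.scatter(xs, ys, c=cs, s=8, marker="s")
        ax.set_title(line_id)
        ax.set_xticks(list(chrom_x.values()))
        ax.set_xticklabels(list(chrom_x.keys()), rotation=90, fontsize=6)
    axes[0][0].set_ylabel(f"position ({gmap.unit})")
    handles = [
        plt.Line2D([], [], marker="s", linestyle="", color=colors[lab], label=lab)
        for lab in all_labels
    ]
    fig.legend(handles=handles, loc="upper right", fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
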