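"""Single-generation parental-origin assignment.

Two deterministic passes per progeny line:

1. :func:`assign_anchor_markers` — a marker is an *anchor* when the two
   parents carry different homozygous calls; the progeny's homozygous call
   then identifies its parental source unambiguously.
2. :func:`impute_from_flanks` — runs of non-anchor labels are filled with a
   source when the nearest anchors on BOTH sides (same chromosome, any
   distance) agree; runs whose flanking anchors disagree are left as the
   ambiguous recombination-containing region.

No probabilistic inference: the rule set is intentionally deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iomodel import (
    ALT_HOM,
    GeneticMap,
    GenotypeMatrix,
    HET,
    MISSING_CALL,
    OriginMatrix,
    Pedigree,
    REF_HOM,
    UNKNOWN,
)
from .labels import CONFLICT, MISSING, OriginLabel, ambiguous, source

log = logging.getLogger(__name__)

__all__ = [
    "assign_anchor_markers",
    "impute_from_flanks",
    "trace_generation",
    "singleton_report",
    "smooth_singletons",
    "TraceSummary",
]


@dataclass
class TraceSummary:
    """Per-line label counts after tracing."""

    line_id: str
    n_source: int
    n_ambiguous: int
    n_conflict: int
    n_missing: int

    @property
    def n_markers(self) -> int:
        return self.n_source + self.n_ambiguous + self.n_conflict + self.n_missing

    @property
    def fraction_unassigned(self) -> float:
        return 1.0 - self.n_source / self.n_markers if self.n_markers else 0.0


def assign_anchor_markers(
    progeny_row: np.ndarray,
    p1_row: np.ndarray,
    p2_row: np.ndarray,
    p1_id: str,
    p2_id: str,
) -> np.ndarray:
    """Label each marker of a progeny line against its two parents.

    Per marker:

    * progeny heterozygous or missing -> ``MISSING`` (uninformative in
      inbred material);
    * parents carry different homozygous calls (anchor) and progeny is
      homozygous -> ``SOURCE`` of the matching parent;
    * progeny homozygous for an allele neither parent carries ->
      ``CONFLICT``;
    * otherwise (parents identical, or a parent heterozygous/missing) ->
      ``AMBIGUOUS``.
    """
    progeny_row = np.asarray(progeny_row, dtype=np.int8)
    p1_row = np.asarray(p1_row, dtype=np.int8)
    p2_row = np.asarray(p2_row, dtype=np.int8)
    if not (progeny_row.shape == p1_row.shape == p2_row.shape):
        raise ValueError("progeny and parent rows have different lengths")

    s1, s2 = source(p1_id), source(p2_id)
    amb = ambiguous(p1_id, p2_id)

    prog_hom = (progeny_row == REF_HOM) | (progeny_row == ALT_HOM)
    parents_hom = np.isin(p1_row, (REF_HOM, ALT_HOM)) & np.isin(p2_row, (REF_HOM, ALT_HOM))
    anchor = parents_hom & (p1_row != p2_row)

    # a parent can carry the progeny allele if it is het, missing, or the
    # matching homozygote
    p1_carries = (p1_row == HET) | (p1_row == MISSING_CALL) | (p1_row == progeny_row)
    p2_carries = (p2_row == HET) | (p2_row == MISSING_CALL) | (p2_row == progeny_row)

    out = np.empty(progeny_row.shape, dtype=object)
    out[:] = amb
    out[prog_hom & anchor & (progeny_row == p1_row)] = s1
    out[prog_hom & anchor & (progeny_row == p2_row)] = s2
    out[prog_hom & ~anchor & ~p1_carries & ~p2_carries] = CONFLICT
    out[~prog_hom] = MISSING
    return out


def impute_from_flanks(origin_row: np.ndarray, gmap: GeneticMap) -> np.ndarray:
    """Fill non-SOURCE runs whose nearest SOURCE anchors on both sides agree.

    The search goes arbitrarily far along the chromosome but never crosses
    a chromosome boundary.  Runs whose flanking anchors disagree, and runs
    at chromosome ends (one-sided anchors), are left unchanged — they
    encode the ambiguous recombination-containing region.  CONFLICT labels
    never act as anchors; they are overwritten only inside an agreeing run.
    Existing SOURCE labels are never modified, so the pass is idempotent.
    """
    origin_row = np.asarray(origin_row, dtype=object)
    if origin_row.shape != (len(gmap),):
        raise ValueError("origin row length does not match map")
    out = origin_row.copy()
    for _, sl in gmap.chromosome_slices():
        chunk = out[sl]
        anchor_idx = [i for i, lab in enumerate(chunk) if lab.is_source]
        for left, right in zip(anchor_idx, anchor_idx[1:]):
            if right - left > 1 and chunk[left] == chunk[right]:
                chunk[left + 1:right] = chunk[left]
        out[sl] = chunk
    return out


def trace_generation(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    gmap: GeneticMap,
    lines: list[str] | None = None,
    smooth: bool = False,
) -> tuple[OriginMatrix, pd.DataFrame]:
    """Trace every requested line against its two pedigree parents.

    A line is traceable when it is genotyped and both its parents are known
    and genotyped; untraceable requested lines are skipped with a warning.
    Returns the traced :class:`OriginMatrix` (marker order = map order) and
    a per-line summary table (label counts, fraction unassigned).

    ``smooth=True`` additionally relabels singleton source calls (see
    :func:`smooth_singletons`) as AMBIGUOUS for sensitivity analysis.
    """
    if genotypes.marker_ids != gmap.marker_ids:
        gmap = gmap.subset(genotypes.marker_ids)

    if lines is None:
        lines = [l for l in genotypes.line_ids if l in pedigree
                 and not pedigree.record(l).is_founder]

    traced_ids: list[str] = []
    rows: list[np.ndarray] = []
    summaries: list[TraceSummary] = []
    for line_id in lines:
        reason = _untraceable_reason(line_id, genotypes, pedigree)
        if reason:
            log.warning("skipping line %s: %s", line_id, reason)
            continue
        p1, p2 = pedigree.parents_of(line_id)
        row = assign_anchor_markers(
            genotypes.row(line_id), genotypes.row(p1), genotypes.row(p2), p1, p2
        )
        row = impute_from_flanks(row, gmap)
        traced_ids.append(line_id)
        rows.append(row)
        summaries.append(_summarize(line_id, row))

    if not traced_ids:
        raise ValueError("no requested line could be traced")

    origins = OriginMatrix(traced_ids, gmap.marker_ids, np.stack(rows))
    if smooth:
        origins = smooth_singletons(origins, gmap)
        summaries = [_summarize(l, origins.row(l)) for l in traced_ids]
    summary = pd.DataFrame(
        [
            {
                "line": s.line_id,
                "n_source": s.n_source,
                "n_ambiguous": s.n_ambiguous,
                "n_conflict": s.n_conflict,
                "n_missing": s.n_missing,
                "fraction_unassigned": s.fraction_unassigned,
            }
            for s in summaries
        ]
    )
    return origins, summary


def _untraceable_reason(line_id: str, genotypes: GenotypeMatrix,
                        pedigree: Pedigree) -> str | None:
    if line_id not in genotypes:
        return "line not genotyped"
    if line_id not in pedigree:
        return "line not in pedigree"
    p1, p2 = pedigree.parents_of(line_id)
    if UNKNOWN in (p1, p2):
        return "a parent is unknown"
    missing = [p for p in (p1, p2) if p not in genotypes]
    if missing:
        return f"parent(s) not genotyped: {', '.join(missing)}"
    return None


def _summarize(line_id: str, row: np.ndarray) -> TraceSummary:
    kinds = pd.Series([lab.kind for lab in row])
    counts = kinds.value_counts()
    return TraceSummary(
        line_id,
        int(counts.get("source", 0)),
        int(counts.get("ambiguous", 0)),
        int(counts.get("conflict", 0)),
        int(counts.get("missing", 0)),
    )


def singleton_report(origins: OriginMatrix, gmap: GeneticMap) -> pd.DataFrame:
    """List length-1 source islands: SOURCE calls whose nearest SOURCE
    neighbours on both sides (same chromosome) carry a different source.

    Singletons are reported, never altered; they flag either genuine double
    recombination between adjacent markers or marker-order problems.
    """
    if origins.marker_ids != gmap.marker_ids:
        gmap = gmap.subset(origins.marker_ids)
    records = []
    for line_id in origins.line_ids:
        row = origins.row(line_id)
        for chrom, sl in gmap.chromosome_slices():
            chunk = row[sl]
            src_idx = [i for i, lab in enumerate(chunk) if lab.is_source]
            for prev_i, mid_i, next_i in zip(src_idx, src_idx[1:], src_idx[2:]):
                mid = chunk[mid_i]
                if chunk[prev_i] != mid and chunk[next_i] != mid:
                    records.append(
                        {
                            "line": line_id,
                            "chrom": chrom,
                            "marker": gmap.marker_ids[sl.start + mid_i],
                            "source": mid.source_id,
                            "left_source": chunk[prev_i].source_id,
                            "right_source": chunk[next_i].source_id,
                        }
                    )
    return pd.DataFrame(
        records,
        columns=["line", "chrom", "marker", "source", "left_source", "right_source"],
    )


def smooth_singletons(origins: OriginMatrix, gmap: GeneticMap) -> OriginMatrix:
    """Relabel each singleton whose two flanking sources agree with each
    other as AMBIGUOUS(singleton source, flanking source)."""
    if origins.marker_ids != gmap.marker_ids:
        gmap = gmap.subset(origins.marker_ids)
    labels = origins.labels.copy()
    report = singleton_report(origins, gmap)
    marker_pos = {m: j for j, m in enumerate(origins.marker_ids)}
    line_pos = {l: i for i, l in enumerate(origins.line_ids)}
    for _, rec in report.iterrows():
        if rec["left_source"] == rec["right_source"] and rec["left_source"] != rec["source"]:
            labels[line_pos[rec["line"]], marker_pos[rec["marker"]]] = ambiguous(
                rec["source"], rec["left_source"]
            )
    return OriginMatrix(origins.line_ids, origins.marker_ids, labels)
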