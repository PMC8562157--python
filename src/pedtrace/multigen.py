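"""Multi-generation origin composition.

Single-generation labels name a line's immediate parents.  Composition
pushes each SOURCE label up the pedigree so a marker is attributed to the
most distal traceable ancestor: a child's SOURCE(parent) becomes the
parent's own label at that marker whenever the parent's label is itself a
SOURCE; otherwise the parent becomes its own ancestral class ("self
class") — the child genuinely inherited that physical segment from the
parent even if the parent's own provenance at that marker is unresolved.
"""

from __future__ import annotations

import numpy as np

from .iomodel import OriginMatrix, Pedigree
from .labels import source

__all__ = ["compose_origins", "assign_self_classes", "trace_to_founders"]


def compose_origins(
    child_row: np.ndarray,
    parent_origin_rows: dict[str, np.ndarray],
) -> np.ndarray:
    """One composition step of a traced child row against its parents' rows.

    For each marker labelled ``SOURCE(p)`` with ``p`` in
    ``parent_origin_rows``: if the parent's label at that marker is a
    SOURCE it replaces the child's; any other parent label (ambiguous,
    conflict, missing) collapses to the parent's self class ``SOURCE(p)``,
    i.e. the label is unchanged.  Non-SOURCE child labels and labels
    naming untraced parents pass through.
    """
    child_row = np.asarray(child_row, dtype=object)
    for parent_row in parent_origin_rows.values():
        if np.asarray(parent_row).shape != child_row.shape:
            raise ValueError("child and parent origin rows cover different markers")
    out = child_row.copy()
    for j, lab in enumerate(child_row):
        if not lab.is_source:
            continue
        parent_row = parent_origin_rows.get(lab.source_id)
        if parent_row is None:
            continue
        parent_lab = parent_row[j]
        if parent_lab.is_source:
            out[j] = parent_lab
    return out


def assign_self_classes(line_origin_row: np.ndarray, line_id: str) -> np.ndarray:
    """Rewrite a line's AMBIGUOUS labels as ``SOURCE(line_id)``.

    Used only when the line serves as a parent downstream: unassignable
    regions become a new ancestral class named after the line itself.  The
    original row (used for predicting the line's own performance) is left
    untouched — a new row is returned.
    """
    out = np.asarray(line_origin_row, dtype=object).copy()
    for j, lab in enumerate(out):
        if lab.is_ambiguous:
            out[j] = source(line_id)
    return out


def trace_to_founders(
    pedigree: Pedigree,
    origins: OriginMatrix,
    max_depth: int | None = None,
    lines: list[str] | None = None,
) -> OriginMatrix:
    """Compose origin rows up the pedigree, ancestors first.

    ``origins`` holds the single-generation traced rows of every traced
    line (intermediate ancestors included).  ``max_depth`` limits how many
    generations are composed (``1`` returns the single-generation rows
    unchanged; ``None`` composes to founders/untraced ancestors).  Output
    labels are founder ids, intermediate-line self classes, AMBIGUOUS,
    CONFLICT, or MISSING.
    """
    if max_depth is not None and max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if lines is None:
        lines = origins.line_ids

    memo: dict[tuple[str, int | None], np.ndarray] = {}

    def composed(line_id: str, depth: int | None) -> np.ndarray | None:
        """Composed row for ``line_id`` at the given remaining depth, or
        None when the line is untraced (terminal label)."""
        if line_id not in origins:
            return None
        key = (line_id, depth)
        if key in memo:
            return memo[key]
        row = origins.row(line_id)
        if depth is None or depth > 1:
            next_depth = None if depth is None else depth - 1
            parent_rows = {}
            if line_id in pedigree:
                for p in pedigree.record(line_id).known_parents:
                    if p == line_id:
                        continue
                    prow = composed(p, next_depth)
                    if prow is not None:
                        parent_rows[p] = prow
            if parent_rows:
                row = compose_origins(row, parent_rows)
        memo[key] = row
        return row

    rows = []
    for line_id in lines:
        row = composed(line_id, max_depth)
        if row is None:
            raise ValueError(f"line {line_id!r} has no traced origin row")
        rows.append(row)
    return OriginMatrix(list(lines), origins.marker_ids, np.stack(rows))
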