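"""Domain types, file readers/writers, and pedigree normalisation.

All downstream stages consume the types defined here: :class:`Pedigree`,
:class:`GeneticMap`, :class:`GenotypeMatrix`, :class:`PhenotypeTable` and
:class:`OriginMatrix`.

Genotype calls use a fixed four-code alphabet stored as ``int8``:
``0`` REF homozygote, ``1`` heterozygote, ``2`` ALT homozygote, ``-1``
missing.  Heterozygotes are retained in the matrix but the tracer treats
them as uninformative (the target material is inbred).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .labels import OriginLabel, validate_identifier

log = logging.getLogger(__name__)

__all__ = [
    "UNKNOWN",
    "PedigreeRecord",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "normalize_backcrosses",
    "GeneticMap",
    "read_map",
    "write_map",
    "REF_HOM",
    "HET",
    "ALT_HOM",
    "MISSING_CALL",
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "PhenotypeTable",
    "read_phenotypes",
    "write_phenotypes",
    "preprocess_phenotypes",
    "OriginMatrix",
    "read_origins",
    "write_origins",
]

#: sentinel for an unrecorded parent
UNKNOWN = "UNKNOWN"

# genotype call codes
REF_HOM = np.int8(0)
HET = np.int8(1)
ALT_HOM = np.int8(2)
MISSING_CALL = np.int8(-1)

_MATRIX_CODE_IN = {
    "A": REF_HOM, "H": HET, "B": ALT_HOM, "NA": MISSING_CALL,
    "0": REF_HOM, "1": HET, "2": ALT_HOM,
    "N": MISSING_CALL, "-": MISSING_CALL, ".": MISSING_CALL, "": MISSING_CALL,
}
_MATRIX_CODE_OUT = {int(REF_HOM): "A", int(HET): "H", int(ALT_HOM): "B",
                    int(MISSING_CALL): "NA"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeRecord:
    """One line and its two (possibly unknown) parents."""

    line_id: str
    parent1_id: str = UNKNOWN
    parent2_id: str = UNKNOWN

    def __post_init__(self) -> None:
        validate_identifier(self.line_id)
        for p in (self.parent1_id, self.parent2_id):
            if p != UNKNOWN:
                validate_identifier(p)
        if self.line_id in (self.parent1_id, self.parent2_id):
            raise PedigreeError(f"line {self.line_id!r} lists itself as a parent")

    @property
    def parents(self) -> tuple[str, str]:
        return (self.parent1_id, self.parent2_id)

    @property
    def known_parents(self) -> tuple[str, ...]:
        return tuple(p for p in self.parents if p != UNKNOWN)

    @property
    def is_founder(self) -> bool:
        return not self.known_parents


class Pedigree:
    """An ordered, validated collection of :class:`PedigreeRecord`.

    Validation enforces unique line ids and an acyclic parent relation.
    Parents referenced without a record of their own are treated as
    terminal founders.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        self.records: list[PedigreeRecord] = list(records)
        self._by_id: dict[str, PedigreeRecord] = {}
        for rec in self.records:
            if rec.line_id in self._by_id:
                raise PedigreeError(f"duplicate line id {rec.line_id!r}")
            self._by_id[rec.line_id] = rec
        cycle = self._find_cycle()
        if cycle:
            raise PedigreeError("pedigree contains a cycle: " + " -> ".join(cycle))

    # -- structure -------------------------------------------------------
    def __contains__(self, line_id: str) -> bool:
        return line_id in self._by_id

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self.records == other.records

    def record(self, line_id: str) -> PedigreeRecord:
        return self._by_id[line_id]

    def parents_of(self, line_id: str) -> tuple[str, str]:
        return self._by_id[line_id].parents

    @property
    def line_ids(self) -> list[str]:
        return [r.line_id for r in self.records]

    def founders(self) -> list[str]:
        """Line ids with no known parents, plus parents lacking a record."""
        ids = [r.line_id for r in self.records if r.is_founder]
        seen = set(self._by_id)
        for r in self.records:
            for p in r.known_parents:
                if p not in seen:
                    ids.append(p)
                    seen.add(p)
        return ids

    def ancestors(self, line_id: str) -> set[str]:
        """All (transitive) known ancestors of ``line_id``."""
        out: set[str] = set()
        stack = [line_id]
        while stack:
            cur = stack.pop()
            rec = self._by_id.get(cur)
            if rec is None:
                continue
            for p in rec.known_parents:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def topological_order(self) -> list[str]:
        """Recorded line ids, ancestors before descendants."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 2 or node not in self._by_id:
                return
            state[node] = 1
            for p in self._by_id[node].known_parents:
                visit(p)
            state[node] = 2
            order.append(node)

        for rec in self.records:
            visit(rec.line_id)
        return order

    def _find_cycle(self) -> list[str] | None:
        state: dict[str, int] = {}
        parent_edge: dict[str, str] = {}

        def visit(node: str) -> list[str] | None:
            state[node] = 1
            rec = self._by_id.get(node)
            if rec is not None:
                for p in rec.known_parents:
                    if state.get(p) == 1:
                        # unwind the cycle
                        cyc = [p, node]
                        cur = node
                        while parent_edge.get(cur) and cur != p:
                            cur = parent_edge[cur]
                            cyc.append(cur)
                        return cyc
                    if state.get(p, 0) == 0:
                        parent_edge[p] = node
                        found = visit(p)
                        if found:
                            return found
            state[node] = 2
            return None

        for rec in self.records:
            if state.get(rec.line_id, 0) == 0:
                found = visit(rec.line_id)
                if found:
                    return found
        return None


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV with header ``line,parent1,parent2``.

    ``-`` or an empty field encodes an unknown parent.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"line", "parent1", "parent2"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")

    def norm(v: str) -> str:
        v = v.strip()
        return UNKNOWN if v in ("", "-", UNKNOWN) else v

    records = [
        PedigreeRecord(row["line"].strip(), norm(row["parent1"]), norm(row["parent2"]))
        for _, row in df.iterrows()
    ]
    return Pedigree(records)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["line", "parent1", "parent2"])
        for rec in pedigree.records:
            w.writerow([
                rec.line_id,
                "-" if rec.parent1_id == UNKNOWN else rec.parent1_id,
                "-" if rec.parent2_id == UNKNOWN else rec.parent2_id,
            ])


def normalize_backcrosses(pedigree: Pedigree) -> Pedigree:
    """Collapse backcross chains so a derived line is coded as a single
    cross of the original donor by the recurrent parent.

    For a record ``L = X × R`` where ``X`` itself is a cross involving
    ``R`` (i.e. a backcross onto recurrent parent ``R``), the chain is
    followed upward through repeated crosses to ``R`` and ``L`` is
    re-coded ``donor × R``.  All other records are left untouched, so the
    operation is a no-op on pedigrees without backcross patterns and is
    idempotent.
    """
    new_records = []
    for rec in pedigree.records:
        p1, p2 = rec.parents
        rewritten = None
        for cross_parent, recurrent in ((p1, p2), (p2, p1)):
            if recurrent == UNKNOWN or cross_parent == UNKNOWN:
                continue
            if cross_parent not in pedigree:
                continue
            if recurrent not in pedigree.record(cross_parent).parents:
                continue
            # walk up the chain of crosses to the same recurrent parent
            donor = cross_parent
            while donor in pedigree and recurrent in pedigree.record(donor).parents:
                others = [p for p in pedigree.record(donor).parents if p != recurrent]
                donor = others[0] if others else UNKNOWN
                if donor == UNKNOWN:
                    break
            if donor != UNKNOWN and donor != rec.line_id:
                # keep the recurrent parent in its original slot
                if recurrent == p2:
                    rewritten = PedigreeRecord(rec.line_id, donor, recurrent)
                else:
                    rewritten = PedigreeRecord(rec.line_id, recurrent, donor)
            break
        new_records.append(rewritten if rewritten is not None else rec)
    return Pedigree(new_records)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Ordered marker map.  List order is authoritative; positions within a
    chromosome must be non-decreasing.  The tracer uses only marker ORDER,
    so the position unit (cM or bp) is metadata."""

    def __init__(
        self,
        marker_ids: Sequence[str],
        chromosomes: Sequence[str],
        positions: Sequence[float],
        unit: str = "cM",
    ):
        if not (len(marker_ids) == len(chromosomes) == len(positions)):
            raise ValueError("marker_ids, chromosomes, positions length mismatch")
        if len(set(marker_ids)) != len(marker_ids):
            dup = pd.Series(marker_ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r} in map")
        if unit not in ("cM", "bp"):
            raise ValueError("unit must be 'cM' or 'bp'")
        self.marker_ids = list(marker_ids)
        self.chromosomes = list(chromosomes)
        self.positions = np.asarray(positions, dtype=float)
        self.unit = unit
        self._index = {m: i for i, m in enumerate(self.marker_ids)}
        # contiguity + monotonicity check per chromosome
        seen_done: set[str] = set()
        prev_chrom: str | None = None
        for i, c in enumerate(self.chromosomes):
            if c != prev_chrom:
                if c in seen_done:
                    raise ValueError(f"chromosome {c!r} markers are not contiguous in map")
                if prev_chrom is not None:
                    seen_done.add(prev_chrom)
                prev_chrom = c
            elif i > 0 and self.positions[i] < self.positions[i - 1]:
                raise ValueError(
                    f"positions decrease within chromosome {c!r} at marker "
                    f"{self.marker_ids[i]!r}"
                )

    def __len__(self) -> int:
        return len(self.marker_ids)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GeneticMap)
            and self.marker_ids == other.marker_ids
            and self.chromosomes == other.chromosomes
            and np.array_equal(self.positions, other.positions)
            and self.unit == other.unit
        )

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """(chromosome, slice into marker order) in map order."""
        out: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(self.chromosomes) + 1):
            if i == len(self.chromosomes) or self.chromosomes[i] != self.chromosomes[start]:
                out.append((self.chromosomes[start], slice(start, i)))
                start = i
        return out

    def subset(self, marker_ids: Sequence[str]) -> "GeneticMap":
        """Restrict to ``marker_ids``; relative map order must be preserved."""
        idx = [self._index[m] for m in marker_ids]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("subset marker order disagrees with map order")
        return GeneticMap(
            [self.marker_ids[i] for i in idx],
            [self.chromosomes[i] for i in idx],
            self.positions[idx],
            self.unit,
        )


def read_map(path: str | Path, unit: str = "cM") -> GeneticMap:
    """Read a map CSV with header ``marker,chrom,pos``."""
    df = pd.read_csv(path, dtype={"marker": str, "chrom": str})
    if not {"marker", "chrom", "pos"}.issubset(df.columns):
        raise ValueError("map file must have columns marker,chrom,pos")
    return GeneticMap(df["marker"].tolist(), df["chrom"].tolist(),
                      df["pos"].to_numpy(float), unit=unit)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    pd.DataFrame(
        {"marker": gmap.marker_ids, "chrom": gmap.chromosomes, "pos": gmap.positions}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Lines x markers call matrix on the four-code alphabet."""

    def __init__(self, line_ids: Sequence[str], marker_ids: Sequence[str],
                 calls: np.ndarray, flagged_lines: Sequence[str] = ()):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(line_ids), len(marker_ids)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(line_ids)} lines x {len(marker_ids)} markers"
            )
        bad = ~np.isin(calls, (REF_HOM, HET, ALT_HOM, MISSING_CALL))
        if bad.any():
            raise ValueError("calls contain values outside {-1, 0, 1, 2}")
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("duplicate line ids in genotype matrix")
        self.line_ids = list(line_ids)
        self.marker_ids = list(marker_ids)
        self.calls = calls
        #: lines present in the file but absent from the pedigree (informational)
        self.flagged_lines = list(flagged_lines)
        self._row_index = {l: i for i, l in enumerate(self.line_ids)}

    def __contains__(self, line_id: str) -> bool:
        return line_id in self._row_index

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def row(self, line_id: str) -> np.ndarray:
        return self.calls[self._row_index[line_id]]

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._row_index[l] for l in line_ids]
        return GenotypeMatrix(list(line_ids), self.marker_ids, self.calls[idx])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )


def _reorder_to_map(line_ids, marker_ids, calls, gmap: GeneticMap,
                    flagged: Sequence[str]) -> GenotypeMatrix:
    keep = [(gmap.index_of(m), j) for j, m in enumerate(marker_ids) if m in gmap._index]
    dropped = len(marker_ids) - len(keep)
    if dropped:
        log.info("dropped %d markers absent from the genetic map", dropped)
    keep.sort()
    cols = [j for _, j in keep]
    kept_ids = [marker_ids[j] for j in cols]
    return GenotypeMatrix(line_ids, kept_ids, calls[:, cols], flagged_lines=flagged)


def read_genotypes(
    path: str | Path,
    gmap: GeneticMap,
    format: str = "matrix",
    pedigree: Pedigree | None = None,
) -> GenotypeMatrix:
    """Read genotype calls and reorder markers to match the map.

    ``format="matrix"``: TSV with rows = lines, columns = markers, cells in
    ``{A,B,H,NA}`` or ``{0,1,2,NA}``.  ``format="vcf"``: VCF 4.x, biallelic
    SNP records only (multi-allelic records are skipped with a warning).

    Markers absent from the map are dropped (count logged).  Lines absent
    from ``pedigree`` (when given) are retained but flagged.
    """
    if format == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        line_ids = [str(l) for l in df.index]
        marker_ids = [str(m) for m in df.columns]
        calls = np.empty(df.shape, dtype=np.int8)
        values = df.to_numpy(dtype=str)
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                token = values[i, j].strip()
                try:
                    calls[i, j] = _MATRIX_CODE_IN[token]
                except KeyError:
                    raise ValueError(
                        f"unrecognised genotype code {token!r} at line "
                        f"{line_ids[i]!r}, marker {marker_ids[j]!r}"
                    ) from None
    elif format == "vcf":
        line_ids, marker_ids, calls = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    flagged = []
    if pedigree is not None:
        flagged = [l for l in line_ids if l not in pedigree]
        if flagged:
            log.warning("%d genotyped lines absent from pedigree: %s",
                        len(flagged), ", ".join(flagged[:5]))
    return _reorder_to_map(line_ids, marker_ids, calls, gmap, flagged)


def _read_vcf(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            warnings.warn(
                f"skipping non-biallelic-SNP record at {variant.CHROM}:{variant.POS}",
                stacklevel=2,
            )
            continue
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = np.asarray(variant.gt_types)
        code = np.full(gt.shape, MISSING_CALL, dtype=np.int8)
        code[gt == 0] = REF_HOM
        code[gt == 1] = HET
        code[gt == 3] = ALT_HOM
        rows.append(code)
    vcf.close()
    calls = (np.stack(rows, axis=1) if rows
             else np.empty((len(line_ids), 0), dtype=np.int8))
    return line_ids, marker_ids, calls


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the A/B/H/NA TSV form (round-trips with ``read_genotypes``)."""
    with open(path, "w") as fh:
        fh.write("line\t" + "\t".join(genotypes.marker_ids) + "\n")
        for i, line_id in enumerate(genotypes.line_ids):
            tokens = [_MATRIX_CODE_OUT[int(c)] for c in genotypes.calls[i]]
            fh.write(line_id + "\t" + "\t".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

class PhenotypeTable:
    """Tidy (line, env, trait, value) records."""

    COLUMNS = ["line", "env", "trait", "value"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = values.isna() & df["value"].notna()
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"non-numeric phenotype value {row['value']!r} for line "
                f"{row['line']!r} ({row['env']}, {row['trait']})"
            )
        df["value"] = values
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PhenotypeTable) and self.df.equals(other.df)

    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    def environments(self) -> list[str]:
        return sorted(self.df["env"].unique())

    def values_for(self, trait: str, env: str) -> pd.Series:
        """Series of phenotype values indexed by line for one (trait, env)."""
        sub = self.df[(self.df["trait"] == trait) & (self.df["env"] == env)]
        if sub["line"].duplicated().any():
            raise ValueError(
                f"replicated entries remain for ({trait}, {env}); "
                "run preprocess_phenotypes first"
            )
        return sub.set_index("line")["value"]


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, dtype={"line": str, "env": str, "trait": str}))


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def preprocess_phenotypes(raw: PhenotypeTable, mode: str = "mean") -> PhenotypeTable:
    """Collapse replicated (line, env, trait) entries to one value each.

    ``mode="mean"``: arithmetic mean of replicates.  ``mode="shrunken"``:
    replicate means are shrunk toward the environment mean with factor
    ``s2g / (s2g + s2e / r)`` from a one-way random-effects decomposition
    over the replicated lines of that (env, trait); unreplicated entries
    pass through at their raw value under both modes.
    """
    if mode not in ("mean", "shrunken"):
        raise ValueError("mode must be 'mean' or 'shrunken'")
    out_rows: list[pd.DataFrame] = []
    for (env, trait), group in raw.df.groupby(["env", "trait"], sort=False):
        counts = group.groupby("line")["value"].agg(["mean", "count"])
        if mode == "mean":
            collapsed = counts["mean"]
        else:
            collapsed = _shrink_one_way(group, counts)
        block = collapsed.rename("value").reset_index()
        block["env"] = env
        block["trait"] = trait
        out_rows.append(block[PhenotypeTable.COLUMNS])
    df = (pd.concat(out_rows, ignore_index=True)
          if out_rows else pd.DataFrame(columns=PhenotypeTable.COLUMNS))
    return PhenotypeTable(df)


def _shrink_one_way(group: pd.DataFrame, counts: pd.DataFrame) -> pd.Series:
    """One-way random-effects shrinkage of replicate means toward the
    environment mean (method-of-moments variance components over the
    replicated lines; unbalanced designs use the n0 correction)."""
    rep = counts[counts["count"] >= 2]
    result = counts["mean"].copy()
    if len(rep) < 2:
        return result  # not enough replicated lines to estimate components
    rep_values = group[group["line"].isin(rep.index)]
    n_total = len(rep_values)
    k = len(rep)
    grand = rep_values["value"].mean()
    ss_within = float(
        ((rep_values["value"] - rep_values.groupby("line")["value"].transform("mean")) ** 2).sum()
    )
    df_within = n_total - k
    if df_within <= 0:
        return result
    ms_within = ss_within / df_within
    ss_between = float((rep["count"] * (rep["mean"] - grand) ** 2).sum())
    ms_between = ss_between / (k - 1)
    n0 = (n_total - float((rep["count"] ** 2).sum()) / n_total) / (k - 1)
    s2e = ms_within
    s2g = max(0.0, (ms_between - ms_within) / n0)
    env_mean = grand
    for line_id, row in rep.iterrows():
        denom = s2g + s2e / row["count"]
        b = s2g / denom if denom > 0 else 0.0
        result.loc[line_id] = env_mean + b * (row["mean"] - env_mean)
    return result


# ---------------------------------------------------------------------------
# Origin matrices
# ---------------------------------------------------------------------------

class OriginMatrix:
    """Lines x markers matrix of :class:`~pedtrace.labels.OriginLabel`."""

    def __init__(self, line_ids: Sequence[str], marker_ids: Sequence[str],
                 labels: np.ndarray):
        labels = np.asarray(labels, dtype=object)
        if labels.shape != (len(line_ids), len(marker_ids)):
            raise ValueError("labels shape does not match line/marker ids")
        if len(set(line_ids)) != len(line_ids):
            raise ValueError("duplicate line ids in origin matrix")
        self.line_ids = list(line_ids)
        self.marker_ids = list(marker_ids)
        self.labels = labels
        self._row_index = {l: i for i, l in enumerate(self.line_ids)}

    def __contains__(self, line_id: str) -> bool:
        return line_id in self._row_index

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def row(self, line_id: str) -> np.ndarray:
        return self.labels[self._row_index[line_id]]

    def subset_lines(self, line_ids: Sequence[str]) -> "OriginMatrix":
        idx = [self._row_index[l] for l in line_ids]
        return OriginMatrix(list(line_ids), self.marker_ids, self.labels[idx])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, OriginMatrix)
            and self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and bool(np.all(self.labels == other.labels))
        )


def write_origins(origins: OriginMatrix, path: str | Path) -> None:
    """TSV with rows = lines, columns = markers; cells are the label tokens
    (parent id, ``id1|id2``, ``!`` conflict, ``.`` missing)."""
    with open(path, "w") as fh:
        fh.write("line\t" + "\t".join(origins.marker_ids) + "\n")
        for i, line_id in enumerate(origins.line_ids):
            tokens = [lab.encode() for lab in origins.labels[i]]
            fh.write(line_id + "\t" + "\t".join(tokens) + "\n")


def read_origins(path: str | Path) -> OriginMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    labels = np.empty(df.shape, dtype=object)
    values = df.to_numpy(dtype=str)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            labels[i, j] = OriginLabel.decode(values[i, j])
    return OriginMatrix([str(l) for l in df.index], [str(m) for m in df.columns], labels)
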