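"""Allele-effect estimation: convert origin labels to trait-scale numbers.

For one (trait, environment): ``mu`` is the mean phenotype of the training
lines; for each marker and each parental source observed there, ``alpha``
is the mean phenotype of the training lines carrying that source minus
``mu``.  Alphas are raw class-mean deviations — deliberately NOT shrunk or
regressed toward the mean.  The resulting numeric matrix replaces the raw
0/1/2 marker codes as input to ridge-regression prediction:

* ``SOURCE(j)``        -> ``alpha_j`` (0 when source j was unseen in training)
* ``AMBIGUOUS(j, k)``  -> ``(alpha_j + alpha_k) / 2``
* ``MISSING/CONFLICT`` -> 0 (the neutral deviation, defaulting toward mu)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iomodel import OriginMatrix, PhenotypeTable

__all__ = [
    "AlleleEffect",
    "AlleleEffectTable",
    "AEEMatrix",
    "fit_aee",
    "build_aee_matrix",
    "aee_pipeline",
    "write_aee_table",
    "write_aee_matrix",
    "read_aee_matrix",
]


@dataclass(frozen=True)
class AlleleEffect:
    alpha: float
    n: int


@dataclass
class AlleleEffectTable:
    """Per-marker, per-source deviations from the training mean."""

    trait: str
    environment: str
    mu: float
    effects: dict[str, dict[str, AlleleEffect]] = field(default_factory=dict)

    def alpha(self, marker_id: str, source_id: str) -> float:
        """alpha for a source at a marker; 0 for sources unseen in training."""
        eff = self.effects.get(marker_id, {}).get(source_id)
        return eff.alpha if eff is not None else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker": m, "source": s, "n": e.n, "alpha": e.alpha, "mu": self.mu}
            for m, per_source in self.effects.items()
            for s, e in sorted(per_source.items())
        ]
        return pd.DataFrame(rows, columns=["marker", "source", "n", "alpha", "mu"])


@dataclass
class AEEMatrix:
    """Numeric lines x markers matrix in trait units."""

    line_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray
    trait: str = ""
    environment: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("values shape does not match line/marker ids")
        if not np.isfinite(self.values).all():
            raise ValueError("AEE matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)


def fit_aee(
    origins: OriginMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    environment: str,
    n_min: int = 1,
) -> AlleleEffectTable:
    """Fit per-marker, per-source allele effects on the training lines.

    Training lines are the traced lines with a phenotype for
    ``(trait, environment)``.  Sources observed in fewer than ``n_min``
    training lines at a marker have their alpha forced to 0 (default 1:
    no thresholding).  Only SOURCE labels contribute; a marker with no
    SOURCE label in training gets an empty effect map.
    """
    pheno = phenotypes.values_for(trait, environment)
    train_lines = [l for l in origins.line_ids if l in pheno.index]
    if not train_lines:
        raise ValueError(
            f"no phenotyped training lines for trait {trait!r} in {environment!r}"
        )
    y = pheno.loc[train_lines].to_numpy(float)
    mu = float(y.mean())

    sub = origins.subset_lines(train_lines)
    table = AlleleEffectTable(trait=trait, environment=environment, mu=mu)
    for j, marker_id in enumerate(sub.marker_ids):
        groups: dict[str, list[float]] = {}
        col = sub.labels[:, j]
        for yi, lab in zip(y, col):
            if lab.is_source:
                groups.setdefault(lab.source_id, []).append(yi)
        per_source = {
            src: AlleleEffect(
                alpha=(float(np.mean(vals)) - mu) if len(vals) >= n_min else 0.0,
                n=len(vals),
            )
            for src, vals in groups.items()
        }
        table.effects[marker_id] = per_source
    return table


def build_aee_matrix(origins: OriginMatrix, table: AlleleEffectTable) -> AEEMatrix:
    """Replace every origin label with its numeric allele effect.

    Works for training and test lines alike; test-line sources unseen in
    training fall back to 0 (the deviation of an unknown source from the
    mean), so predictions degrade gracefully toward mu.
    """
    values = np.zeros(origins.shape, dtype=float)
    for j, marker_id in enumerate(origins.marker_ids):
        col = origins.labels[:, j]
        for i, lab in enumerate(col):
            if lab.is_source:
                values[i, j] = table.alpha(marker_id, lab.source_id)
            elif lab.is_ambiguous:
                a, b = lab.ids
                values[i, j] = 0.5 * (
                    table.alpha(marker_id, a) + table.alpha(marker_id, b)
                )
            # conflict/missing stay 0
    return AEEMatrix(
        list(origins.line_ids),
        list(origins.marker_ids),
        values,
        trait=table.trait,
        environment=table.environment,
    )


def aee_pipeline(
    origins: OriginMatrix,
    phenotypes: PhenotypeTable,
    traits: list[str] | None = None,
    environments: list[str] | None = None,
    n_min: int = 1,
) -> dict[tuple[str, str], AEEMatrix]:
    """One AEE matrix per (trait, environment) from a single traced
    origin matrix — tracing is never repeated per trait."""
    traits = traits if traits is not None else phenotypes.traits()
    environments = environments if environments is not None else phenotypes.environments()
    out: dict[tuple[str, str], AEEMatrix] = {}
    for trait in traits:
        for env in environments:
            sub = phenotypes.df[
                (phenotypes.df["trait"] == trait) & (phenotypes.df["env"] == env)
            ]
            if sub.empty:
                continue
            table = fit_aee(origins, phenotypes, trait, env, n_min=n_min)
            out[(trait, env)] = build_aee_matrix(origins, table)
    return out


def write_aee_table(table: AlleleEffectTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_aee_matrix(matrix: AEEMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="line")


def read_aee_matrix(path: str | Path) -> AEEMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AEEMatrix([str(l) for l in df.index], [str(m) for m in df.columns],
                     df.to_numpy(float))
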