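"""Fixture generator: pedigreed populations with ground-truth origins.

Meiosis uses the Haldane (no-interference) model: crossovers per
chromosome are Poisson with mean equal to the map length in Morgans,
positions uniform.  Lines are produced by a cross followed by the
configured number of selfing generations; residual heterozygous runs are
resolved to one haplotype at output time so downstream modules always see
homozygous inbreds.

Phenotypes can carry *founder-specific* QTL alleles — the same SNP allele
tagging different causal effects depending on which founder contributed
the segment — which is exactly the confounding that origin-aware
prediction is designed to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .iomodel import (
    ALT_HOM,
    GeneticMap,
    GenotypeMatrix,
    OriginMatrix,
    Pedigree,
    PedigreeRecord,
    PhenotypeTable,
    REF_HOM,
    write_genotypes,
    write_map,
    write_origins,
    write_pedigree,
    write_phenotypes,
)
from .labels import source

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_founders",
    "simulate_gamete",
    "simulate_meiosis",
    "simulate_phenotypes",
    "simulate_population",
    "TwoLocusSelectionResult",
    "simulate_two_locus_selection",
    "TWO_LOCUS_FREQUENCIES",
]


@dataclass
class SimConfig:
    """Knobs for one simulated population."""

    n_founders: int = 5
    design: str = "nam"  # "nam" (hub x others) or "biparental"
    n_families: int | None = None
    lines_per_family: int = 25
    n_chromosomes: int = 3
    markers_per_chromosome: int = 50
    chrom_length_cM: float = 100.0
    selfing_generations: int = 5
    maf: tuple[float, float] = (0.2, 0.5)  # per-marker ALT-frequency range
    n_qtl: int = 10
    qtl_allele_mode: str = "founder-specific"  # or "biallelic"
    #: in founder-specific mode, the marker window (this many markers each
    #: side of a QTL) is made identical across founders: ancestors share
    #: the haplotype around the gene without sharing the causal allele
    qtl_shared_window: int = 2
    h2_target: float = 0.5
    genotype_error_rate: float = 0.0
    trait: str = "trait1"
    environment: str = "env1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("nam", "biparental"):
            raise ValueError("design must be 'nam' or 'biparental'")
        if self.qtl_allele_mode not in ("founder-specific", "biallelic"):
            raise ValueError("qtl_allele_mode must be 'founder-specific' or 'biallelic'")
        for name in ("n_founders", "lines_per_family", "n_chromosomes",
                     "markers_per_chromosome", "n_qtl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError("h2_target must be in (0, 1)")
        if self.n_families is None:
            self.n_families = (self.n_founders - 1 if self.design == "nam"
                               else self.n_founders // 2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "maf" in data and isinstance(data["maf"], list):
            data["maf"] = tuple(data["maf"])
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth carried next to the simulated data."""

    origins: OriginMatrix  # founder-of-origin label per line x marker
    breakpoints: dict[str, list[tuple[str, int, int]]]  # line -> (chrom, left, right) global marker indices
    genetic_values: pd.Series
    qtl: pd.DataFrame  # marker, chrom, mode, and effect columns


@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    gmap: GeneticMap
    genotypes: GenotypeMatrix  # founders and lines
    phenotypes: PhenotypeTable
    truth: SimTruth

    @property
    def line_ids(self) -> list[str]:
        return self.truth.origins.line_ids

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.pedigree, out / "pedigree.csv")
        write_map(self.gmap, out / "map.csv")
        write_genotypes(self.genotypes, out / "genotypes.tsv")
        write_phenotypes(self.phenotypes, out / "phenotypes.csv")
        write_origins(self.truth.origins, out / "truth_origins.tsv")
        self.truth.qtl.to_csv(out / "truth_qtl.tsv", sep="\t", index=False)


def _default_map(config: SimConfig) -> GeneticMap:
    ids, chroms, pos = [], [], []
    m = config.markers_per_chromosome
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        for j in range(m):
            ids.append(f"{chrom}_m{j + 1:03d}")
            chroms.append(chrom)
            # spread markers over the full length, ends included
            pos.append(config.chrom_length_cM * j / max(m - 1, 1))
    return GeneticMap(ids, chroms, pos, unit="cM")


def simulate_founders(config: SimConfig, rng: np.random.Generator,
                      gmap: GeneticMap | None = None) -> GenotypeMatrix:
    """Independent homozygous founder genotypes; the per-marker ALT allele
    frequency is drawn uniformly from the configured range."""
    gmap = gmap or _default_map(config)
    n_markers = len(gmap)
    lo, hi = (config.maf, config.maf) if np.isscalar(config.maf) else config.maf
    freq = rng.uniform(lo, hi, size=n_markers)
    alt = rng.random((config.n_founders, n_markers)) < freq
    calls = np.where(alt, ALT_HOM, REF_HOM).astype(np.int8)
    founder_ids = [f"P{i + 1:02d}" for i in range(config.n_founders)]
    return GenotypeMatrix(founder_ids, gmap.marker_ids, calls)


def simulate_gamete(
    hap_pair: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    forced_crossovers: dict[str, list[float]] | None = None,
    return_crossovers: bool = False,
):
    """One recombinant gamete from a pair of haplotypes.

    ``hap_pair`` is a (2, n_markers) array of arbitrary per-marker values
    (founder indices, labels...).  Crossover counts are Poisson with mean
    = chromosome length in Morgans unless ``forced_crossovers`` supplies
    explicit positions per chromosome (in map units, assumed cM).  With
    ``return_crossovers`` the realised positions are returned as a
    ``{chromosome: positions}`` dict alongside the gamete.
    """
    hap_pair = np.asarray(hap_pair)
    out = np.empty(hap_pair.shape[1], dtype=hap_pair.dtype)
    realised: dict[str, np.ndarray] = {}
    for chrom, sl in gmap.chromosome_slices():
        pos = gmap.positions[sl]
        length = float(pos[-1] - pos[0]) if len(pos) > 1 else 0.0
        if forced_crossovers is not None:
            xpos = np.sort(np.asarray(forced_crossovers.get(chrom, []), dtype=float))
        else:
            n_x = rng.poisson(length / 100.0)
            xpos = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
        realised[chrom] = xpos
        phase0 = int(rng.integers(2))
        switches = np.searchsorted(xpos, pos, side="left")
        phase = (phase0 + switches) % 2
        out[sl] = hap_pair[:, sl][phase, np.arange(sl.stop - sl.start)]
    if return_crossovers:
        return out, realised
    return out


def _resolve_heterozygosity(
    hap_pair: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Force homozygosity: each maximal residual heterozygous run (per
    chromosome) is resolved to one haplotype by a single fair coin, so no
    spurious origin switches are introduced inside the run."""
    choice = hap_pair[0].copy()
    het = hap_pair[0] != hap_pair[1]
    for _, sl in gmap.chromosome_slices():
        idx = np.flatnonzero(het[sl]) + sl.start
        if idx.size == 0:
            continue
        run_start = 0
        for i in range(1, idx.size + 1):
            if i == idx.size or idx[i] != idx[i - 1] + 1:
                run = idx[run_start:i]
                if rng.integers(2):
                    choice[run] = hap_pair[1][run]
                run_start = i
    return choice


def simulate_meiosis(
    p1_id: str,
    p2_id: str,
    p1_genotype: np.ndarray,
    p2_genotype: np.ndarray,
    gmap: GeneticMap,
    selfing_generations: int,
    rng: np.random.Generator,
    p1_truth: np.ndarray | None = None,
    p2_truth: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[str, int, int]]]:
    """Derive one inbred line from a cross of two (inbred) parents.

    Returns ``(genotype_row, origin_row, founder_truth_row, breakpoints)``
    where ``origin_row`` labels each marker with the contributing
    immediate parent, ``founder_truth_row`` pushes that through the
    parents' own truth rows (when supplied), and ``breakpoints`` is the
    list of (chromosome, left, right) global marker-index intervals where
    the parental origin switches.
    """
    n = len(gmap)
    if p1_genotype.shape != (n,) or p2_genotype.shape != (n,):
        raise ValueError("parent genotype rows do not match map")
    # haplotype content = index of contributing parent (0 or 1)
    hap = np.stack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    for _ in range(selfing_generations):
        hap = np.stack([simulate_gamete(hap, gmap, rng),
                        simulate_gamete(hap, gmap, rng)])
    origin_idx = _resolve_heterozygosity(hap, gmap, rng)

    parent_geno = np.stack([p1_genotype, p2_genotype])
    genotype_row = parent_geno[origin_idx, np.arange(n)]
    ids = (p1_id, p2_id)
    origin_row = np.array([source(ids[i]) for i in origin_idx], dtype=object)
    if p1_truth is not None and p2_truth is not None:
        parent_truth = np.stack([np.asarray(p1_truth, dtype=object),
                                 np.asarray(p2_truth, dtype=object)])
        founder_truth = parent_truth[origin_idx, np.arange(n)]
    else:
        founder_truth = origin_row.copy()

    breakpoints: list[tuple[str, int, int]] = []
    for chrom, sl in gmap.chromosome_slices():
        o = origin_idx[sl]
        for i in np.flatnonzero(o[1:] != o[:-1]):
            breakpoints.append((chrom, sl.start + int(i), sl.start + int(i) + 1))
    return genotype_row, origin_row, founder_truth, breakpoints


def choose_qtl(config: SimConfig, gmap: GeneticMap,
               rng: np.random.Generator) -> np.ndarray:
    """Sorted marker indices hosting the causal loci."""
    return np.sort(rng.choice(len(gmap), size=min(config.n_qtl, len(gmap)),
                              replace=False))


def share_qtl_haplotypes(
    founders: GenotypeMatrix,
    gmap: GeneticMap,
    qtl_idx: np.ndarray,
    window: int,
) -> GenotypeMatrix:
    """Copy the first founder's alleles to all founders inside the window
    around each QTL, so the local haplotype is identical by state while the
    causal alleles (assigned per founder) still differ."""
    calls = founders.calls.copy()
    chrom_of = {i: c for c, sl in gmap.chromosome_slices()
                for i in range(sl.start, sl.stop)}
    for j in qtl_idx:
        lo, hi = max(0, j - window), min(len(gmap) - 1, j + window)
        cols = [i for i in range(lo, hi + 1) if chrom_of[i] == chrom_of[j]]
        calls[:, cols] = calls[0, cols]
    return GenotypeMatrix(founders.line_ids, founders.marker_ids, calls)


def simulate_phenotypes(
    truth_origins: OriginMatrix,
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator,
    qtl_idx: np.ndarray | None = None,
) -> tuple[PhenotypeTable, pd.DataFrame, pd.Series]:
    """Genetic values from QTL effects plus calibrated residual noise.

    ``founder-specific`` mode assigns each QTL a separate effect per
    founder origin (drawn N(0,1)); ``biallelic`` mode assigns one additive
    effect to the ALT allele.  Residual noise is scaled so the realised
    heritability approximates ``h2_target``.
    """
    line_ids = truth_origins.line_ids
    if qtl_idx is None:
        qtl_idx = choose_qtl(config, gmap, rng)
    founder_ids = sorted(
        {lab.source_id for row in truth_origins.labels for lab in row if lab.is_source}
    )

    g = np.zeros(len(line_ids))
    qtl_rows = []
    if config.qtl_allele_mode == "founder-specific":
        for j in qtl_idx:
            effects = {f: float(rng.normal()) for f in founder_ids}
            col = truth_origins.labels[:, j]
            g += np.array([effects.get(lab.source_id, 0.0) if lab.is_source else 0.0
                           for lab in col])
            row = {"marker": gmap.marker_ids[j], "chrom": gmap.chromosomes[j],
                   "mode": "founder-specific"}
            row.update({f"effect_{f}": e for f, e in effects.items()})
            qtl_rows.append(row)
    else:
        sub = genotypes.subset_lines(line_ids)
        for j in qtl_idx:
            effect = float(rng.normal())
            dosage = sub.calls[:, j].astype(float) / 2.0  # hom ALT = 1
            g += effect * dosage
            qtl_rows.append({"marker": gmap.marker_ids[j],
                             "chrom": gmap.chromosomes[j],
                             "mode": "biallelic", "effect": effect})

    var_g = float(np.var(g))
    noise_sd = (np.sqrt(var_g * (1.0 - config.h2_target) / config.h2_target)
                if var_g > 0 else 1.0)
    y = g + rng.normal(0.0, noise_sd, size=len(line_ids))
    table = PhenotypeTable(pd.DataFrame({
        "line": line_ids,
        "env": config.environment,
        "trait": config.trait,
        "value": y,
    }))
    genetic_values = pd.Series(g, index=line_ids, name="genetic_value")
    return table, pd.DataFrame(qtl_rows), genetic_values


def _family_pairs(config: SimConfig, founder_ids: list[str]) -> list[tuple[str, str]]:
    if config.design == "nam":
        if config.n_families > len(founder_ids) - 1:
            raise ValueError("nam design needs n_families <= n_founders - 1")
        hub = founder_ids[0]
        return [(hub, founder_ids[i + 1]) for i in range(config.n_families)]
    if config.n_families > len(founder_ids) // 2:
        raise ValueError("biparental design needs n_families <= n_founders // 2")
    return [(founder_ids[2 * i], founder_ids[2 * i + 1])
            for i in range(config.n_families)]


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate a full pedigreed population from one seed."""
    rng = np.random.default_rng(config.seed)
    gmap = _default_map(config)
    founders = simulate_founders(config, rng, gmap)
    qtl_idx = choose_qtl(config, gmap, rng)
    if config.qtl_allele_mode == "founder-specific" and config.qtl_shared_window >= 0:
        founders = share_qtl_haplotypes(founders, gmap, qtl_idx,
                                        config.qtl_shared_window)
    pairs = _family_pairs(config, founders.line_ids)

    records = [PedigreeRecord(f) for f in founders.line_ids]
    line_ids: list[str] = []
    geno_rows: list[np.ndarray] = []
    origin_rows: list[np.ndarray] = []
    breakpoints: dict[str, list[tuple[str, int, int]]] = {}
    for fam, (p1, p2) in enumerate(pairs):
        for k in range(config.lines_per_family):
            line_id = f"fam{fam + 1:02d}_L{k + 1:03d}"
            geno, origin, _, bps = simulate_meiosis(
                p1, p2, founders.row(p1), founders.row(p2), gmap,
                config.selfing_generations, rng,
            )
            records.append(PedigreeRecord(line_id, p1, p2))
            line_ids.append(line_id)
            geno_rows.append(geno)
            origin_rows.append(origin)
            breakpoints[line_id] = bps

    geno_calls = np.stack(geno_rows)
    if config.genotype_error_rate > 0:
        flip = rng.random(geno_calls.shape) < config.genotype_error_rate
        flipped = np.where(geno_calls == REF_HOM, ALT_HOM, REF_HOM).astype(np.int8)
        geno_calls = np.where(flip, flipped, geno_calls).astype(np.int8)

    genotypes = GenotypeMatrix(
        founders.line_ids + line_ids,
        gmap.marker_ids,
        np.vstack([founders.calls, geno_calls]),
    )
    truth_origins = OriginMatrix(line_ids, gmap.marker_ids, np.stack(origin_rows))
    phenotypes, qtl, genetic_values = simulate_phenotypes(
        truth_origins, genotypes, gmap, config, rng, qtl_idx=qtl_idx
    )
    truth = SimTruth(origins=truth_origins, breakpoints=breakpoints,
                     genetic_values=genetic_values, qtl=qtl)
    return SimResult(
        config=config,
        pedigree=Pedigree(records),
        gmap=gmap,
        genotypes=genotypes,
        phenotypes=phenotypes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Analytic two-locus worked example
# ---------------------------------------------------------------------------

#: population fractions of marker-allele / gene-allele haplotypes
TWO_LOCUS_FREQUENCIES: dict[tuple[str, str], float] = {
    ("A", "desired"): 0.30,
    ("A", "wild"): 0.20,
    ("G", "desired"): 0.20,
    ("G", "wild"): 0.30,
}


@dataclass(frozen=True)
class TwoLocusSelectionResult:
    base_expected: float  # expected phenotype in the base population
    selected_fraction: float  # fraction retained when selecting marker allele
    selected_expected: float  # expected phenotype of the marker-selected group
    intermated_expected: float  # after intermating with origin-tracked segments


def simulate_two_locus_selection(
    frequencies: dict[tuple[str, str], float] | None = None,
    effect: float = 1.0,
    marker_allele: str = "A",
    desired_allele: str = "desired",
    recombination_fraction: float = 0.01,
) -> TwoLocusSelectionResult:
    """Expected outcomes of marker selection vs origin-tracked selection
    when marker and gene are in incomplete linkage.

    The base expectation is the marginal desired-allele frequency times the
    effect; marker selection keeps the carriers of ``marker_allele`` and
    achieves the conditional desired-allele frequency; tracking the
    parental origin of the marker-gene segment keeps the gene with
    probability ``1 - c`` through one meiosis of the intermating cycle.
    """
    freqs = frequencies if frequencies is not None else TWO_LOCUS_FREQUENCIES
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("haplotype frequencies must sum to a positive value")
    base = sum(f for (m, gene), f in freqs.items() if gene == desired_allele) / total
    marker_frac = sum(f for (m, gene), f in freqs.items() if m == marker_allele) / total
    if marker_frac == 0:
        raise ValueError(f"no haplotype carries marker allele {marker_allele!r}")
    both = freqs.get((marker_allele, desired_allele), 0.0) / total
    selected = both / marker_frac
    return TwoLocusSelectionResult(
        base_expected=base * effect,
        selected_fraction=marker_frac,
        selected_expected=selected * effect,
        intermated_expected=(1.0 - recombination_fraction) * effect,
    )
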