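# pedtrace

Pedigree-aware parental-origin tracing and origin-aware genomic prediction
for inbred crop populations.

Given a pedigree, a biallelic SNP genotype matrix (TSV or VCF), and a
genetic map, `pedtrace`:

1. **traces** the parental origin of every marker in every progeny line
   (anchor markers where the parents carry different homozygous alleles,
   then flanking-marker imputation of the ambiguous runs);
2. **composes** origins through multiple generations so segments are
   attributed to the most distal traceable ancestor (with self classes for
   a line's own unassignable regions);
3. **compiles** maximal identity-by-descent segments, recombination
   breakpoint intervals, intact-chromosome statistics, BED exports and
   chromosome paintings;
4. **converts** origin labels into allele-effect estimates — per-locus,
   per-source deviations of carrier-line mean phenotype from the
   population mean — and builds the numeric matrix that replaces raw
   0/1/2 marker codes;
5. **predicts** phenotypes by ridge-regression BLUP (REML variance
   components via the eigenvalue spectrum) with either matrix, under a
   seeded 80/20 split or k-fold cross-validation, reporting accuracy,
   top-fraction selection statistics and marker-based heritability.

A bundled simulator generates pedigreed RIL populations (Haldane meiosis,
configurable selfing depth, NAM-hub or biparental designs) with
ground-truth origins, crossovers and founder-specific QTL phenotypes, so
the whole pipeline is testable without external data.

## Test

```sh
python -m pytest -q tests/
```

One acceptance test (`test_acceptance.py::test_c6_null_case_ratio_ci_covers_one`)
is expected to fail: it asserts exact statistical equivalence of the two
prediction arms under a null simulation, and the allele-effect encoding
has a small but resolvable finite-sample cost there (accuracy ratio
~0.98, CI excluding 1). The assertion is kept as specified rather than
loosened.

## CLI

All stages are subcommands of one entry point (`pedtrace --help`):

```sh
pedtrace simulate --out-dir sim/ --seed 7            # synthetic dataset
pedtrace trace --genotypes sim/genotypes.tsv --pedigree sim/pedigree.csv \
    --map sim/map.csv --out origins.tsv
pedtrace multitrace --origins origins.tsv --pedigree sim/pedigree.csv \
    --out founders.tsv
pedtrace segments --origins origins.tsv --map sim/map.csv --out-prefix seg --bed
pedtrace aee --origins origins.tsv --phenotypes sim/phenotypes.csv \
    --trait trait1 --env env1 --out aee.tsv
pedtrace predict --matrix aee --aee-matrix aee.tsv \
    --phenotypes sim/phenotypes.csv --trait trait1 --env env1 \
    --mode cv --seed 17 --out report.json
pedtrace compare --origins origins.tsv --genotypes sim/genotypes.tsv \
    --map sim/map.csv --phenotypes sim/phenotypes.csv \
    --trait trait1 --env env1 --mode cv --seed 17 --out compare.json
pedtrace paint --origins origins.tsv --map sim/map.csv --out paint.png
```

Every run writes a provenance JSON (inputs, seed, version) beside its
outputs; reruns with the same inputs and seed are byte-identical.

### File formats

- pedigree: CSV `line,parent1,parent2` (`-` or empty = unknown parent)
- genotypes: TSV matrix (rows = lines, cells `A/B/H/NA` or `0/1/2/NA`) or
  VCF 4.x (biallelic SNPs, GT field)
- map: CSV `marker,chrom,pos` (cM or bp; the tracer uses order only)
- phenotypes: CSV `line,env,trait,value`
- origins: TSV of label tokens — parent id, `id1|id2` (ambiguous), `!`
  (conflict), `.` (missing)

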