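# alleletally

Tools for reasoning about per-population variant tallies built from
allele-count summary tables (gnomAD-style AC/AN data), with a focus on the
sample-size discovery artifact: populations sampled more deeply reveal more
of their rare variants, so raw per-population tallies of "variants found"
track sample size even when the underlying variant pools are identical.

The package provides:

- **Core data model** (`alleletally.core`): variant records with per-population
  allele counts/numbers, inheritance-mode annotation, karyotype-aware
  population specs, and table validation. "Absent" always requires a nonzero
  allele number — no data is not absence.
- **Synthetic tables** (`alleletally.synth`): configurable true-frequency
  spectra (point mass, log-uniform, rare-skewed) sampled binomially at the
  allele numbers implied by each population's XX/XY composition.
- **Tallies and through-origin regression** (`alleletally.tally`):
  per-population counts of shortlisted variants present, max-AN effective
  sample sizes, and origin-rooted least squares with the uncentered
  r² = (Σxy)²/(Σx²·Σy²).
- **Absence confidence** (`alleletally.absence`): the smallest number of
  sampled alleles n with 1−(1−p)ⁿ ≥ c — how much more data you need before a
  variant's absence from a sample says it is truly rare.
- **Carrier-free estimation** (`alleletally.carriers`): probability that a
  random individual carries none of a variant set, as a product of
  (1−p)^copies with chromosome-appropriate copy numbers (X-linked: 1 for XY,
  2 for XX), averaged over a configurable XX/XY mix.
- **Discovery simulation** (`alleletally.discovery`): end-to-end experiments
  showing that identical variant pools plus lopsided sample sizes produce
  tallies almost proportional to sample size, with analytic expected tallies
  Σ(1−(1−p)ⁿ) for cross-checking.
- **I/O and CLI** (`alleletally.tableio`, `alleletally.cli`): long-format TSV
  interchange and a convenience reader for VCFs with per-population
  `AC_<pop>`/`AN_<pop>` INFO keys (requires `cyvcf2`).

## Test

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and independent oracles:
grid-search minimization for the through-origin slope, Monte-Carlo
individual-level simulation for carrier-free probabilities, and analytic
binomial expectations for discovery tallies.

## CLI

The console script `alleletally` exposes:

```sh
alleletally simulate --seed 1 --out table.tsv          # synthetic fixture table
alleletally tally --table table.tsv --gene TMPRSS2LIKE # per-population tallies
alleletally regress --table table.tsv --gene TMPRSS2LIKE --out fit.json
alleletally absence --p 1e-4 --confidence 0.9          # alleles needed to detect
alleletally carrierfree --table table.tsv              # % carrying none
alleletally discover --seed 1 --out summary.tsv        # artifact experiment
alleletally demo --seed 1 --out demo_report            # end-to-end report
```

`simulate` and `discover` also accept YAML configs (spectrum, variant count,
populations); see `tests/test_cli.py` for examples. Exclusion lists
(`--exclude`) let record corrections be expressed as configuration.

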