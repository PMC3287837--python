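# rareqtl

Gene-based rare-variant association testing for quantitative traits.

`rareqtl` implements and evaluates nine gene-level association tests formed
by crossing three rare-variant collapsing scores with three strategies for
handling the common variants in the same gene region:

| | no common variants | CMC | LASSO |
|---|---|---|---|
| **indicator** | rare score alone | score + all commons | score + selected commons |
| **count** | " | " | " |
| **data-adaptive** | " | " | " |

- **indicator** — 1 if a subject carries any rare minor allele in the gene.
- **count** — total rare minor alleles per subject (equivalent to the
  rare-allele proportion method when no genotypes are missing).
- **data-adaptive** — count score after flipping a variant to major-allele
  counting when its covariate-adjusted marginal coefficient is negative with
  p ≤ 0.1. Because the flip uses the outcome, this method needs an
  empirical or permutation null for valid inference (both provided).
- **CMC** — the rare score plus every common variant as additive terms,
  tested jointly.
- **LASSO** — an L1 path with the covariates and the rare score forced in
  (zero penalty) selects which common variants to keep; λ is chosen by
  10-fold cross-validation with the 1-SE rule; the selected model is refit
  by OLS and tested. The resulting post-selection type-I-error inflation is
  a *property under study*, not corrected.

Association is tested with a nested-model F-test (covariates + genetic
terms vs. covariates only), adjusting for sex, age, smoking and population
group. Rare variants are defined by MAF < 0.005, 0.01 or 0.05 (strict).

The `evaluation` module pools null-trait p-values over genes × replicates
into an empirical null, computes type I error at the nominal level,
derives empirical significance thresholds, per-gene power, and a
Freedman–Lane residual-permutation p-value that re-runs the entire
adaptive procedure on each permuted trait.

The `simdata` module generates the full study synthetically: 697 subjects
from 7 populations (logit-scale allele-frequency jitter induces real
stratification), haplotypes with tunable adjacent-variant LD via a latent
AR(1) Gaussian, covariate effects, one associated and one pure-null
quantitative trait panel (genotypes fixed, noise redrawn across the 200
replicates), plus presets for nine risk-gene architectures and for
pure-null calibration studies.

## CLI

```bash
# simulate a study (default design: 697 subjects, 200 replicates)
rareqtl simulate --config config.yaml --out data/ --seed 1

# run all 9 method combinations at all cutoffs on the null trait
rareqtl test --data data/ --trait trait_q4like.tsv --out null.tsv --seed 1

# same on the associated trait
rareqtl test --data data/ --trait trait_q1like.tsv --out alt.tsv --seed 1

# type I error table, empirical thresholds, per-gene power
rareqtl evaluate --null null.tsv --alt alt.tsv --alpha 0.05 --out-prefix eval
```

All tabular inputs/outputs are tab-delimited; every run writes a JSON
manifest (seed, versions, outputs) for reproducibility. Exit codes:
0 success, 2 input error, 1 internal error.

## Layout

```
src/rareqtl/
  io.py          genotype/covariate/trait I/O, MAF, rare-common partitions
  collapse.py    indicator, count, data-adaptive scores
  assoc.py       nested F-test, CMC, penalized selection + refit
  evaluation.py  empirical null, thresholds, type I error, power, permutation
  simdata.py     synthetic genotypes, covariates, trait replicates, presets
  study.py       gene x method x cutoff x replicate driver
  cli.py         simulate / test / evaluate subcommands
```
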