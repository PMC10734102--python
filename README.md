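# platedesign

Plate design for GC/LC-MS sample preparation: stratified inter-batch
balancing, (optimized) block randomization of the run order, 96/384-well
plate layout decoupled from injection order, even QC interleaving, and
instrument-ready worksheet export.

## Why

In mass-spectrometry metabolomics and proteomics, samples processed on the
same plate or in the same run share systematic measurement error (batch
effects, machine drift). If a biological factor — treatment arm, sex, age
group — clusters within a batch or within a stretch of the run, that factor
becomes confounded with the instrument. Two standard countermeasures are:

1. **Inter-batch balancing.** Partition the cohort into plates so each
   stratum (joint covariate category) is represented as evenly as possible:
   a stratum with *c* samples contributes ⌊c/B⌋ samples to each of *B*
   batches; the pooled remainders ("tail samples") are dealt round-robin.
2. **Intra-batch block randomization.** Fill the run order with blocks of
   size *b* (a multiple of the number of categories *d*, default *b = d*),
   each block a uniform draw from the b!/((b/d)!)^d balanced arrangements —
   e.g. d = 2, b = 4 gives the 6 blocks AABB, ABAB, ABBA, BAAB, BABA, BBAA.
   With *b = d* no category can ever appear 3 times in a row.

Classic block randomization needs equal category counts. Real cohorts are
unbalanced, so the package also implements an **optimized block
randomization**: categories are sorted by ascending count and sliced into
*nested groups* with internally equal counts (counts {A:2, B:5, C:9} →
{A,B,C}×2, {B,C}×3, {C}×4); each multi-category group is block randomized,
the single-category remainder completely randomized, and the groups'
blocks interspersed at a stride of ⌊len(base)/len(insert)⌋ so scarce
categories stay spread across the whole run.

Finally, because modern autosamplers inject in any user-defined order, the
**well position is designed separately from the injection order**: QC
samples sit together in a predefined plate region (say, column 1) for easy
pipetting, while their injections are spread evenly through the run — QC
*j* of *m* is injected after experimental sample ⌊j·n/m⌋ of *n*, so gaps
differ by at most one.

The audience is anyone preparing large LC/GC-MS sample batches: core
facilities, clinical metabolomics studies, or method developers who need a
scriptable, seeded, reproducible alternative to spreadsheet randomization.

## Worked example

```sh
platedesign simulate-cohort --seed 1 --dest cohort.csv
# wrote 1300 samples to cohort.csv
```

The built-in demonstration cohort has 1300 samples with fixed marginals:
gender 615 Male / 434 Female / 251 Unknown, treatment 650 / placebo 650,
age 169 Kids / 351 Teenager / 481 Middle-Aged / 299 Older.

With a design config (`config.yaml`):

```yaml
sample_table: cohort.csv
plate: "96"
qc:
  types:
    - {name: Blank, count: 1}
    - {name: LTR, count: 2}
  region: first_column
stratify_covariates: [gender, treatment, age]
randomize_covariate: treatment
algorithm: optimized_block
seed: 42
```

```sh
platedesign -v design --config config.yaml --out-dir out
# design: 1300 samples, capacity 93/plate -> 14 plates (seed 42)
# plate 1: 93 experimental + 3 QC injections
# ...
# wrote out/project.json, out/worksheet.csv (1342 injections on 14 plates)
```

Three QC wells are reserved per 96-well plate, so 93 experimental samples
fit each plate and ⌈1300/93⌉ = 14 plates are needed; the worksheet has
1300 + 14·3 = 1342 rows. `out/sequence_summary.csv` reports, per plate,
the longest same-arm run in the randomized order:

```
plate,n_injections,n_experimental,longest_run,runs_ge_3
1,96,93,2,0
2,96,93,2,0
...
```

— never three consecutive samples of the same treatment arm. The balance
report `out/balance_gender.csv` shows each plate's category percentages;
for this design the worst plate deviates 4.3 percentage points from the
cohort-wide gender proportions:

```
,Male,Female,Unknown,max_abs_deviation_pct
Plate 1,46.24,34.41,19.35,4.31
Plate 2,48.39,32.26,19.35,4.31
```

The same pipeline is available as a library (`platedesign.cli.run_design`,
or the individual operations in `platedesign.stratify`,
`platedesign.blockrand`, `platedesign.plate_layout`,
`platedesign.injection_sequence`, `platedesign.worksheet`).

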