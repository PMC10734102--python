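# Methods

## Inter-batch balancing

Samples are stratified by the joint category combination of the chosen
covariates (the cross-product of their category sets; empty strata are
skipped). For a stratum with count *c* and *B* batches, every batch
receives ⌊c/B⌋ samples of that stratum; which samples fill which slot is
decided by a seeded shuffle. The per-stratum remainders (*c* mod *B*
samples each, so at most *B* − 1 per stratum) are pooled and dealt
round-robin in one continuous pass starting from a seeded-random batch.

Two details of the tail deal matter:

- **The starting batch is random.** A deal that always starts at batch 1
  would make the first batches systematically larger across projects.
- **Each stratum's tail samples stay contiguous in the deal** (the strata
  themselves are taken in seeded-random order). Because a stratum has at
  most *B* − 1 tail samples, consecutive dealing necessarily places them in
  distinct batches, which preserves the guarantee that per-stratum
  per-batch counts differ by at most 1 even when many strata have tails.
  Fully shuffling the pooled tail would break this guarantee whenever the
  pooled tail exceeds *B* — two tail samples of one stratum could land in
  the same batch — so the package deliberately shuffles *within* strata and
  *across* strata, but not across the pool as a whole. Total batch sizes
  still differ by at most 1 because the deal is one continuous round-robin.

`allocate_balanced` accepts an optional `capacity`; if the balanced
allocation would overflow it, a `CapacityError` is raised rather than
silently adding a batch — callers should recompute
`n_batches_for_capacity(n, capacity)` (= ⌈n/capacity⌉). The completely
random allocator (`allocate_complete_random`) is offered as a deliberate
no-stratification baseline.

## Block randomization (balanced counts)

A block factor is (dim size *d*, block size *b*) with *b* a multiple of
*d*. The b!/((b/d)!)^d distinct balanced blocks are enumerated
lexicographically (via `sympy`'s multiset permutations; the closed form is
cross-checked against brute-force enumeration in the tests). The sequence
is built by drawing, per block, a uniform index into that list (with
replacement — no balanced-Latin constraint across blocks) and substituting
randomly chosen samples of each category. The default `block_size="auto"`
uses *b = d*: larger blocks approach complete randomization, while *b = d*
is maximally balanced and guarantees no category ever runs 3 in a row.

When the total is not a multiple of *b*, the trailing partial block is a
uniform shuffle of the leftover category multiset (uniform over distinct
label sequences), which keeps the no-3-run property at the boundary.
Enumeration is refused above 500 000 permutations; block sizes that large
are statistically pointless and the error says to shrink the block.

## Optimized block randomization (unbalanced counts)

Categories are sorted by ascending count c(1) ≤ … ≤ c(k); with c(0) = 0,
nested group *i* contains categories *i..k*, each contributing
c(i) − c(i−1) samples (zero-contribution groups dropped). Every
multi-category group has equal internal counts and is block randomized at
*b = d*; the final single-category group is completely randomized — its
internal order carries no information, but the samples are still shuffled
for traceability — and contributes single-sample blocks so it can be
spread thin.

Groups are folded together from most-dimensional to least. At each fold
the side with more *blocks* is the backbone; the other side's blocks are
inserted every `max(1, ⌊n_base_blocks / n_insert_blocks⌋)` backbone
blocks. Insert blocks left over when the backbone runs out are assigned by
cycling over the insertion slots again from the sequence start, which
avoids clustering leftovers at the end. Design choices made where the
construction was genuinely open:

- **Stride counted in blocks, not samples.** The merge operates on blocks;
  a sample-count stride would split blocks and destroy their internal
  balance.
- **Backbone = the side with more blocks.** Usually that is the
  accumulated sequence; for extreme skews (e.g. counts {A:1, B:100}) the
  next group can be longer, and inserting the long side into the short one
  would pile it up at the ends.
- The fold order (densest group first) makes the most uniform sequence the
  backbone that everything else is spread into.

The windowed-balance tests quantify the benefit: over 200 seeds on the
1300-sample demonstration cohort's age covariate (counts 169/351/481/299),
the mean worst-100-sample-window deviation of the optimized randomizer is
strictly below that of complete randomization.

## Position design and QC interleaving

Plate geometry is an explicit spec (axis sizes + label alphabets);
built-ins are the standard 96-well (12×8, columns 1–12, rows a–h) and
384-well (24×16, columns 1–24, rows a–p) templates. Well labels are
y-label followed by x-label ("a1"), parsed case-insensitively with
longest-y-label-first matching so multi-character alphabets stay
unambiguous.

Layout and run order are decoupled: `assign_positions` puts QC samples in
the predefined region (first column, last column, or an explicit well
list), grouped by QC type in plan order, and fills experimental samples
into the remaining wells in row-major ("horizontal") or column-major
("vertical") order. The layout is a function of the batch *membership*
only, never of the injection order.

QC injections are interleaved by the circular rule: QC *j* (1-based) of
*m* goes after experimental sample ⌊j·n/m⌋ of *n*. Gaps between
consecutive QC differ by at most one, and the run always ends on a QC
injection, matching the common practice of closing a batch with QC. An
optional `qc_lead_in: k` moves the first *k* scheduled QC injections to
the very start (column conditioning); it defaults to 0. If *m* > *n*, one
QC follows each experimental sample and the surplus is appended at the end
with a logged warning. QC IDs are synthesized deterministically as
`<type>_<plate>_<ordinal>`, and types are scheduled round-robin in plan
order so no QC type clusters.

## Worksheets and persistence

Export goes through a field map (ordered internal-field → header pairs;
`sample_id` and `injection_order` are mandatory, headers must be unique).
Only a "generic" preset is built in; vendor header sets are user
configuration. CSV is UTF-8 with LF endings (the reader tolerates CRLF);
XLSX uses a single sheet named "worksheet". `injection_order` restarts per
plate and `global_order` numbers the whole run, since instruments differ
on which they want. Projects persist to schema-versioned JSON
(`schema_version: 1`); save→load and reload→re-export are byte-stable, so
long-running studies can be reopened months later.

## Determinism

Every randomized operation takes an explicit seed and uses an
independently constructed `numpy` generator; the pipeline derives one
sub-seed per stage and per batch from the config seed, so a (config, seed)
pair fully determines every output byte.

## Synthetic demonstration cohort

`generate_case_study_cohort` emulates a large clinical metabolomics
cohort: 1300 samples with exact marginals — gender 615/434/251 (the 251
"Unknown" standing for missing demographic data), treatment 650/650, age
169/351/481/299. Each covariate column is an independent seeded shuffle of
its fixed multiset, then the columns are zipped; the marginals are
therefore exact for every seed while the joint distribution is random.
Real cohorts have correlated covariates (age and treatment are rarely
independent); none of the balancing or randomization guarantees tested
here depend on the joint structure, but effect sizes seen on real data
will differ. The generator produces no QC rows — QC samples are created by
the design step, not uploaded.

## Problem sizes in the test suite

Tests run the worked examples at their natural sizes (105-sample
balancing over 1000 seeds, 1300-sample randomization over 100–200 seeds,
QC interleaving for all 1 ≤ m ≤ n ≤ 500); the whole suite completes in
well under a minute on one CPU.

## Known limitations

- Continuous covariates must be pre-binned into categories; there is no
  binning logic.
- One batch = one plate; multi-plate batches and cross-plate coordinates
  are out of scope.
- A single even QC interleave per plan — no per-type spacing rules
  (e.g. solvent blank every 5, reference standard every 20).
- No optimization-solver or correlation-minimizing layout search; the
  algorithms here are constructive and O(n log n).
- With many categories in one covariate, the nested-group construction can
  leave mild local clustering for some count distributions, since later
  (sparser) groups are interspersed at coarse strides.
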