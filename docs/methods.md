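# Methods

## The pair statistic

MB-MDR scores a SNP pair by partitioning its genotype cells into
high-risk (H), low-risk (L) and no-evidence (O) classes and testing the
partition against the trait.

**Binary trait.** For cell `(m, n)` of the `C_l × C_r` genotype grid, let
`a = A_mn` and `b = U_mn` be the affected/unaffected counts inside the
cell and `c = N_A − a`, `d = N_U − b` the counts outside. The cell test is
the 1-df statistic `(ad − bc)²(a+b+c+d) / [(a+b)(c+d)(b+d)(a+c)]`, which
equals the Pearson χ² of the 2×2 table whenever all margins are positive;
a zero margin returns the no-evidence sentinel 0. A cell is O when
`a+b < min_cell_total`, or `c+d < min_cell_total`, or the test does not
exceed the χ²(1) upper-α quantile; otherwise H if `ad − bc > 0`, L if
negative. (A significant test with `ad − bc = 0` is impossible since the
statistic is then 0; if a user sets `cell_alpha = 1`, the zero-difference
cell stays O.) The pair statistic is
`T = max(χ²_H-vs-rest, χ²_L-vs-rest)`; an empty partition contributes the
sentinel 0, so a fully-O grid gives `T = 0`.

**Continuous trait.** The per-cell test is the two-group one-way F
statistic of the cell's subjects against all others, computed from group
sizes and sums (`F = SSB·(N−2)/SSW` with 1 and `N−2` degrees of freedom),
gated by the same minimum cell size and by the F(1, N−2) quantile at α.
H/L follows the sign of cell mean minus complement mean, and the final
`T` is the larger of the two-group F for H-members-vs-rest and
L-members-vs-rest. A perfectly separating split (zero within-group
variance, positive between-group contrast) yields `T = +inf`, which the
permutation machinery handles through ordinary comparisons; a
zero-variance trait yields `T = 0` with a warning. The cell-vs-rest
construction (rather than a full one-way ANOVA across all cells) was a
deliberate choice for symmetry with the binary path; it is isolated
behind one routine so alternatives can be swapped in.

### Parameters

| parameter        | default | meaning                                                                   |
|------------------|---------|---------------------------------------------------------------------------|
| `min_cell_total` | 10      | minimum subjects in a cell *and* in its complement for the cell to be tested |
| `cell_alpha`     | 0.1     | liberal significance level of the per-cell gate (quantile-based, any level works) |
| `-n`             | 1000    | number of top pairs for which adjusted p-values are computed              |
| `-p`             | 999     | trait permutations B; the smallest attainable p-value is `1/(B+1)`        |

The gate uses the distribution quantile (χ²(1) or F(1, N−2)) computed at
run time, so `cell_alpha` is genuinely tunable; at the default it is
~2.705543 for the binary path.

## maxT and the top-n reformulation

Classical maxT: sort observed statistics descending (ties broken by
ascending pair index, via a stable sort); per permutation, recompute all
statistics in that order and force row monotonicity right-to-left
(running maximum); exceedance counts start at 1 because the observed data
is one of the `B+1` samples, and `T_i,j ≥ T_0,j` uses exact floating
comparison — permuted and observed statistics come from the same finite
computation, so no epsilon is warranted; finally `p_j = a_j/(B+1)` with
left-to-right monotonicity. Counting is done on the fly, one permutation
row in memory at a time (O(m), never O(B·m)).

Top-n variant: since the monotone row at ranks `1..n` depends on ranks
`> n` only through their maximum `M_i`, it suffices to keep the n
statistics of the top pairs plus `M_i`, replace `T_i,n` by `M_i` when
larger, and continue the monotone pass from rank `n−1`. The resulting
p-values equal the classical ones bit for bit (asserted over randomized
instances in the test suite, including `n = m`, where `M_i` is the empty
maximum and the replacement is skipped). Boundary ties in the observed
top-n selection keep the earlier-enumerated pair, matching the stable
classical sort, so membership — not value — decides routing when a
non-top pair ties the cut.

### Determinism contract

Permutation `i` (1-based, global across the run) draws from
`PCG64(SeedSequence(base_seed, spawn_key=(i,)))` and shuffles the trait
with `Generator.permutation` (Fisher–Yates). Child seeds depend only on
`(base_seed, i)`, so the classical, top-n, in-process parallel and
file-based multi-machine paths all see identical permutations and their
outputs are byte-identical. The synthetic-data module uses a separate
spawn key so dataset generation never interacts with the permutation
stream.

### Parallel workflow

Permutations split homogeneously over Z chunks (sizes differ by at most
one). Worker vectors accumulate exceedances from **zero**; the observed
data's `+1` is added at merge time. This keeps chunk files pure integer
counts whose sum reproduces the sequential `a` exactly — the merge
involves no floating-point accumulation. The merge refuses permfiles
whose lengths disagree with the topfile or whose chunk sizes do not sum
to B.

## Vectorized engine and the memory instrumentation

Statistics stream in enumeration order (row-major over `l < r`) in blocks
of ~`block_pairs` pairs (default 4096; a block never splits a row, so it
holds at most `max(block_pairs, S−1)` pairs). Within a block, the
affected and unaffected count matrices of all pairs come from one-hot
genotype matrix products; counts are accumulated in float32 products
(exact for counts below 2^24) and promoted to float64 before any test
arithmetic, so the blocked and scalar binary paths agree bit for bit.
Continuous-trait cell sums accumulate in a different order in the two
paths, so they agree to ~1e−12 relative rather than exactly; all
exactness guarantees between the classical and top-n procedures hold
because both consume the same engine. Per-pair genotype-count totals are
permutation-invariant and cached when `S ≤ 4096`; above that they are
recomputed per pass so memory stays independent of the pair count.

The `MemoryTracker` counts statistic values simultaneously held in the
pass's data structures: the n-slot buffer (top list or permutation
vector, with the rest-maximum folded into one running slot) plus the
backlog of computed-but-unconsumed block values. With `block_pairs = 1`
— the literal pair-at-a-time algorithm — the peak is `n + 1`; with
blocking it is `n + block`, still independent of m.

## Synthetic data

The generator reproduces the validation design of the method's power
study:

- one functional pair at positions 5 and 10 (1-based), minor allele
  frequency fixed at 0.5; disease probability given the joint genotype is
  the checkerboard penetrance table
  `[[0, .1, 0], [.1, 0, .1], [0, .1, 0]]` — a purely epistatic model with
  no marginal effects;
- non-functional SNPs draw a MAF once per SNP, uniform on [0.05, 0.5],
  and genotypes follow Hardy–Weinberg proportions, all loci independent;
- balanced cases/controls are collected by rejection-to-quota sampling
  (the sampler itself is our choice; a 10^7-draw budget guards degenerate
  tables). Kept subjects are shuffled so case status is not encoded in
  row order.

The continuous-trait generator is an explicit surrogate:
`trait = effect_size · penetrance/max(penetrance) + N(0, noise_sd)` with
defaults `effect_size = 1`, `noise_sd = 0.5` — a mean-shift encoding of
the same epistatic structure, with parameters exposed for other designs.
A pure-null generator (trait permuted independently of all genotypes)
feeds the family-wise error rate study.

What the generator does **not** emulate: linkage disequilibrium between
markers, genotyping error or missingness, population structure, or main
effects. Passing tests therefore demonstrate correctness of the
algorithmic machinery and calibration under idealized sampling, not
robustness to the confounders of real genotype data.

## Problem sizes in the validation suite

The exactness property is asserted over 50 randomized instances
(6–20 SNPs, 50–200 subjects, B ∈ {9, 99, 199}, n ∈ {1, 3, m}); power over
20 replicates of the planted-pair design (100 SNPs, 500/500 subjects,
B = 999, n = 1000); FWER over 200 null datasets (20 SNPs, 500 subjects,
B = 199), with the rejection fraction required to fall in the exact
binomial 95% band around 0.05. The acceptance script runs scaled
versions of the same computations (10 power replicates, 100 null
datasets, 15 exactness instances) chosen as comfortable desk-scale runs.

## Known limitations

- Survival/censored traits and the log-rank cell test are out of scope,
  as are main-effects-corrected screens and covariate adjustment.
- Missing genotypes are rejected at parse time; the count matrices assume
  complete data.
- The classical implementation is an oracle for small instances; only the
  top-n path is meant for large S.
- The dataset text dialect (whitespace-delimited, mandatory `Trait`
  header) is this package's documented convention; the trait scale is
  always set by the caller/flag, never sniffed from the file.
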