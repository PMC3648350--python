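# mbmdr

Exhaustive SNP×SNP epistasis screening with exact, memory-bounded
permutation-adjusted p-values.

`mbmdr` is for statistical geneticists who want to test every pair of
genetic markers for joint association with a trait — binary
(case/control) or continuous — while controlling the family-wise error
rate across all `m = S(S−1)/2` correlated tests. It implements the
Model-Based Multifactor Dimensionality Reduction (MB-MDR) pair statistic
together with a reformulation of the maxT step-down permutation procedure
whose memory use depends only on the number of reported pairs `n`, not on
`m` — the quantity that otherwise grows quadratically in the number of
SNPs and makes genome-scale interaction screens infeasible.

## The statistic

For a pair of SNPs and a binary trait, subjects are cross-tabulated into
affected counts `A_mn` and unaffected counts `U_mn` over the genotype
combinations `(m, n)`. Each cell is labelled

- **H** (high risk) or **L** (low risk) by the sign of `ad − bc` in the
  2×2 table *cell vs. rest* (`a = A_mn`, `b = U_mn`, `c = N_A − A_mn`,
  `d = N_U − U_mn`), when the 1-df test

  `χ² = (ad − bc)² (a+b+c+d) / [(a+b)(c+d)(b+d)(a+c)]`

  exceeds the χ²(1) quantile at a liberal level α = 0.1;
- **O** (no evidence) when `a+b` or `c+d` falls below a minimum cell size
  (default 10) or the test is not significant.

The pair statistic `T` is the maximum of two further 1-df χ² tests:
H cells against the rest, and L cells against the rest. For a continuous
trait the per-cell and final tests are two-group one-way F tests and H/L
follows the sign of the mean difference.

## maxT in O(n) memory

Significance comes from `B` permutations of the trait column. Classical
maxT sorts the observed statistics `T_0,1 ≥ … ≥ T_0,m`, recomputes all
statistics per permutation in that order, forces row monotonicity
right-to-left, counts exceedances `a_j = #{i : T_i,j ≥ T_0,j}` (the
observed data counts once), and reports `p_j = a_j/(B+1)` after a final
left-to-right monotonicity pass.

Because the monotone row is a running maximum, ranks `1..n` only ever see
the top-n statistics and the single maximum `M_i` of the remaining
`m − n` pairs. Keeping just those `n + 1` numbers per permutation yields
**bit-for-bit identical** p-values for the top n pairs in O(n) memory.
The permutations are also embarrassingly parallel: a topfile/permfile
protocol lets chunks run on separate machines and merge exactly
(`mbmdr top` / `chunk` / `merge`).

## Worked example

Simulate 400 subjects × 20 SNPs with a planted epistatic pair at
(SNP5, SNP10) — disease risk depends only on the joint genotype through a
3×3 penetrance table with no marginal effects — then screen all 190 pairs
with 999 permutations:

```sh
mbmdr simulate --model binary -S 20 --cases 200 --controls 200 --seed 7 demo.txt
mbmdr analyze --binary -n 5 -p 999 --seed 1 demo.txt results.txt
cat results.txt
```

```
SNP_l	SNP_r	T	p
SNP5	SNP10	142.373	0.001
SNP15	SNP16	17.8708	0.065
SNP12	SNP16	14.5642	0.282
SNP10	SNP16	14.3817	0.298
SNP2	SNP14	11.7056	0.657
```

The planted pair is ranked first with the smallest attainable adjusted
p-value, `1/(B+1) = 0.001`: none of the 999 permutations produced a
statistic anywhere reaching `T = 142.4`. Every other pair is noise; its
adjusted p-value reflects how often a permutation's (monotonicity-
corrected) statistic at that rank met the observed one. The same run via
the library:

```python
import mbmdr as mb

model = mb.PenetranceModel()            # checkerboard two-locus penetrance
ds = mb.simulate_binary_trait(model, n_snps=20, n_cases=200, n_controls=200, seed=7)
res = mb.maxt_topn(ds, n=5, n_permutations=999, seed=1)
print(res.pairs[0], res.p[0])           # PairId(l=4, r=9, j=...) 0.001
```

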