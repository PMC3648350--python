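"""Classical maxT over all pairs — the correctness oracle for the top-n path.

Steps of the step-down procedure:

1. compute the statistic for every pair and sort descending (T_0,1 >= ... >=
   T_0,m; ties broken by ascending pair index);
2. for each of B trait permutations, recompute all statistics in the sorted
   observed order and force row monotonicity right-to-left;
3. count, per rank j, how many rows (including the observed data itself)
   reach T_0,j — the exceedance count a_j, initialized at 1;
4. p_j = a_j / (B+1), then force monotonicity left-to-right.

Exceedance counting happens on the fly, so memory is O(m) (one permutation
row at a time), never O(B·m).  This module is meant for small instances; the
production path is :func:`mbmdr.topn.maxt_topn`.
"""

from __future__ import annotations

import numpy as np

from .data import Dataset, MaxTResult, PairId, iter_pairs, pair_from_index
from .engine import DEFAULT_BLOCK_PAIRS, EngineProvider, PairStatsEngine
from .stats import StatParams
from .topn import enforce_monotonicity, finalize_pvalues

__all__ = ["all_pair_statistics", "maxt_classical"]


def all_pair_statistics(dataset: Dataset, trait: np.ndarray | None = None,
                        params: StatParams | None = None,
                        block_pairs: int = DEFAULT_BLOCK_PAIRS) -> list[tuple[PairId, float]]:
    """Statistic for every unordered pair, in fixed enumeration order.

    ``trait`` defaults to the dataset's own trait; pass a permuted copy to
    score a permutation round.
    """
    if dataset.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    engine = PairStatsEngine(dataset, params, block_pairs)
    t = dataset.trait if trait is None else trait
    stats = engine.all_stats(t)
    return [(pid, float(stats[pid.j])) for pid in iter_pairs(dataset.n_snps)]


def maxt_classical(dataset: Dataset | None, n_permutations: int, seed: int = 0,
                   params: StatParams | None = None, *,
                   block_pairs: int = DEFAULT_BLOCK_PAIRS,
                   provider=None) -> MaxTResult:
    """Exact maxT-adjusted p-values for *all* m pairs.

    ``provider`` may replace the dataset-backed statistic stream (used to
    drive the bookkeeping with fixed numbers in tests).
    """
    if n_permutations < 0:
        raise ValueError("number of permutations must be >= 0")
    if provider is None:
        if dataset is None:
            raise ValueError("either a dataset or a provider is required")
        provider = EngineProvider(dataset, params, seed, block_pairs)
    m = provider.m
    t0_all = np.empty(m, dtype=np.float64)
    for j0, block in provider.real_blocks():
        t0_all[j0:j0 + len(block)] = block
    # stable sort on the negated statistics: ties keep ascending pair index
    order = np.argsort(-t0_all, kind="stable")
    t0_sorted = t0_all[order]
    a = np.ones(m, dtype=np.int64)
    ti = np.empty(m, dtype=np.float64)
    for i in range(1, n_permutations + 1):
        for j0, block in provider.perm_blocks(i):
            ti[j0:j0 + len(block)] = block
        ti_sorted = enforce_monotonicity(ti[order])
        a += ti_sorted >= t0_sorted
    p = finalize_pvalues(a, n_permutations)
    pairs = [pair_from_index(int(j), provider.n_snps) for j in order]
    return MaxTResult(pairs=pairs, t0=t0_sorted, a=a, p=p,
                      n_permutations=n_permutations)
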