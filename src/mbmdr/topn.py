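"""Memory-bounded maxT: exact adjusted p-values for the n best pairs.

The classical procedure keeps a statistic per pair (O(m) memory, quadratic
in the number of SNPs).  This variant keeps only

* the n best observed pairs and their statistics (the top list),
* per permutation, the n statistics of those pairs plus the single maximum
  M_i over the remaining m−n pairs.

Because row monotonicity is a right-to-left running maximum, replacing the
n-th entry by max(T_i,n, M_i) propagates exactly the same values into ranks
1..n as the full-row enforcement would, so the first n adjusted p-values are
*identical* to the classical ones — not an approximation.  Memory is O(n),
independent of m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .data import Dataset, MaxTResult, PairId, TopList, pair_from_index
from .engine import DEFAULT_BLOCK_PAIRS, EngineProvider
from .stats import StatParams

__all__ = [
    "MemoryTracker",
    "PermPass",
    "select_top_n",
    "permutation_pass",
    "enforce_monotonicity",
    "update_counts",
    "finalize_pvalues",
    "maxt_topn",
]


@dataclass
class MemoryTracker:
    """Peak count of simultaneously retained statistic values.

    Accounting: the persistent buffers of a pass hold n statistics (the top
    list or the Permutation_i vector, with the rest-maximum folded into one
    of its slots), plus the backlog of computed-but-unconsumed block values.
    With ``block_pairs=1`` the peak is therefore n+1: the n-slot buffer and
    the single incoming statistic.
    """

    peak: int = 0

    def observe(self, count: int) -> None:
        if count > self.peak:
            self.peak = count


@dataclass
class PermPass:
    """One permutation sweep: the top-pair statistics and the rest maximum.

    ``rest_max`` is −inf when the top list covers every pair (n = m); the
    boundary replacement is then a no-op.
    """

    top_stats: np.ndarray
    rest_max: float


# ---------------------------------------------------------------------------
# step 1: bounded-memory top-n selection
# ---------------------------------------------------------------------------

def select_top_n(stream: Iterable[tuple[PairId, float]], n: int,
                 tracker: MemoryTracker | None = None) -> TopList:
    """Keep the n best (pair, statistic) entries of a statistic stream.

    Sorting-by-insertion: a sorted buffer of at most n entries; a statistic
    no better than the current minimum is discarded, anything better evicts
    the minimum.  Boundary ties keep the earlier-enumerated pair.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    buf: list[tuple[float, int, PairId]] = []  # descending by (T, -j)... kept manually
    seen = 0
    for pid, t in stream:
        seen += 1
        if tracker is not None:
            tracker.observe(len(buf) + 1)
        if len(buf) < n:
            _insert_desc(buf, (float(t), pid.j, pid))
        elif t > buf[-1][0]:
            buf.pop()
            _insert_desc(buf, (float(t), pid.j, pid))
    if seen == 0:
        raise ValueError("empty statistic stream")
    pairs = [e[2] for e in buf]
    t0 = np.array([e[0] for e in buf])
    return TopList(pairs=pairs, t0=t0)


def _insert_desc(buf: list, entry: tuple) -> None:
    """Insert keeping the buffer sorted by descending T, ascending j."""
    t, j, _ = entry
    lo, hi = 0, len(buf)
    while lo < hi:
        mid = (lo + hi) // 2
        mt, mj, _ = buf[mid]
        if (mt > t) or (mt == t and mj < j):
            lo = mid + 1
        else:
            hi = mid
    buf.insert(lo, entry)


def _toplist_from_blocks(blocks: Iterator[tuple[int, np.ndarray]], n: int,
                         n_snps: int, tracker: MemoryTracker | None = None) -> TopList:
    """Blocked top-n selection: merge each block into the running buffer."""
    cur_t = np.empty(0, dtype=np.float64)
    cur_j = np.empty(0, dtype=np.int64)
    seen = 0
    for j0, block in blocks:
        b = len(block)
        seen += b
        if tracker is not None:
            tracker.observe(len(cur_t) + b)
        all_t = np.concatenate([cur_t, block])
        all_j = np.concatenate([cur_j, np.arange(j0, j0 + b, dtype=np.int64)])
        order = np.lexsort((all_j, -all_t))[:n]
        cur_t, cur_j = all_t[order], all_j[order]
    if seen == 0:
        raise ValueError("empty statistic stream")
    pairs = [pair_from_index(int(j), n_snps) for j in cur_j]
    return TopList(pairs=pairs, t0=cur_t)


# ---------------------------------------------------------------------------
# step 3: one permutation sweep
# ---------------------------------------------------------------------------

def _pass_blocks(blocks: Iterator[tuple[int, np.ndarray]], toplist: TopList,
                 tracker: MemoryTracker | None = None) -> PermPass:
    n = len(toplist)
    top_stats = np.full(n, -np.inf)
    rest_max = -np.inf
    for j0, block in blocks:
        b = len(block)
        if tracker is not None:
            tracker.observe(n + b)
        pos, js = toplist.positions_in_range(j0, j0 + b)
        if len(pos):
            top_stats[pos] = block[js - j0]
        if len(pos) < b:
            if len(pos):
                mask = np.ones(b, dtype=bool)
                mask[js - j0] = False
                blk_max = block[mask].max()
            else:
                blk_max = block.max()
            if blk_max > rest_max:
                rest_max = float(blk_max)
    return PermPass(top_stats=top_stats, rest_max=rest_max)


def permutation_pass(dataset: Dataset, permuted_trait: np.ndarray, toplist: TopList,
                     params: StatParams | None = None,
                     block_pairs: int = DEFAULT_BLOCK_PAIRS) -> PermPass:
    """Score one permuted trait: one sweep over all pairs, each statistic
    computed exactly once and routed to the top list (membership hit) or
    folded into the rest maximum (miss)."""
    from .engine import PairStatsEngine

    engine = PairStatsEngine(dataset, params, block_pairs)
    return _pass_blocks(engine.stat_blocks(permuted_trait), toplist)


# ---------------------------------------------------------------------------
# steps 3(d)-(f) and 4: bookkeeping
# ---------------------------------------------------------------------------

def enforce_monotonicity(v: np.ndarray) -> np.ndarray:
    """Right-to-left running maximum: output[j] = max(v[j:]).  Idempotent."""
    v = np.asarray(v, dtype=np.float64)
    if len(v) == 0:
        raise ValueError("empty vector")
    return np.maximum.accumulate(v[::-1])[::-1]


def update_counts(a: np.ndarray, perm_pass: PermPass, toplist: TopList) -> np.ndarray:
    """Fold one permutation into the exceedance counts (in place).

    Boundary replacement (T_i,n <- M_i if larger), then monotonicity over
    the n-vector, then a_j += 1 wherever T_i,j >= T_0,j — ties count, and
    the comparison is exact floating equality: permuted and observed
    statistics come from the same finite computation, so no epsilon is
    introduced.
    """
    n = len(toplist)
    if len(a) != n or len(perm_pass.top_stats) != n:
        raise ValueError("count/toplist length mismatch")
    v = perm_pass.top_stats.copy()
    if perm_pass.rest_max > v[-1]:
        v[-1] = perm_pass.rest_max
    v = enforce_monotonicity(v)
    a += v >= toplist.t0
    return a


def finalize_pvalues(a: np.ndarray, n_permutations: int) -> np.ndarray:
    """p_j = a_j/(B+1), then left-to-right running maximum."""
    a = np.asarray(a)
    if len(a) and (a.min() < 1 or a.max() > n_permutations + 1):
        raise ValueError("exceedance counts must lie in [1, B+1]")
    p = a / (n_permutations + 1)
    return np.maximum.accumulate(p)


# ---------------------------------------------------------------------------
# the full procedure
# ---------------------------------------------------------------------------

def maxt_topn(dataset: Dataset | None, n: int, n_permutations: int, seed: int = 0,
              params: StatParams | None = None, *,
              block_pairs: int = DEFAULT_BLOCK_PAIRS,
              tracker: MemoryTracker | None = None,
              provider=None) -> MaxTResult:
    """Adjusted p-values for the n best pairs in O(n) memory.

    Produces bit-for-bit the first n entries of :func:`mbmdr.reference.
    maxt_classical` for the same seed, B and parameters.  ``tracker``
    records the peak retained-statistic count (see :class:`MemoryTracker`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_permutations < 0:
        raise ValueError("number of permutations must be >= 0")
    if provider is None:
        if dataset is None:
            raise ValueError("either a dataset or a provider is required")
        provider = EngineProvider(dataset, params, seed, block_pairs)
    m = provider.m
    if n > m:
        warnings.warn(f"n={n} exceeds the number of pairs m={m}; clamping to m",
                      stacklevel=2)
        n = m
    toplist = _toplist_from_blocks(provider.real_blocks(), n, provider.n_snps, tracker)
    a = np.ones(n, dtype=np.int64)
    for i in range(1, n_permutations + 1):
        perm_pass = _pass_blocks(provider.perm_blocks(i), toplist, tracker)
        update_counts(a, perm_pass, toplist)
    p = finalize_pvalues(a, n_permutations)
    return MaxTResult(pairs=toplist.pairs, t0=toplist.t0, a=a, p=p,
                      n_permutations=n_permutations,
                      peak_retained=None if tracker is None else tracker.peak)


def chunk_exceedance_counts(provider, toplist: TopList, perm_indices: Iterable[int],
                            tracker: MemoryTracker | None = None) -> np.ndarray:
    """Exceedance counts for a subset of global permutation indices.

    Starts from zero — the observed data's +1 is added when chunks are
    merged — so that summing chunk vectors reproduces the sequential counts
    exactly (integer arithmetic throughout).
    """
    n = len(toplist)
    counts = np.zeros(n, dtype=np.int64)
    for i in perm_indices:
        perm_pass = _pass_blocks(provider.perm_blocks(i), toplist, tracker)
        update_counts(counts, perm_pass, toplist)
    return counts
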