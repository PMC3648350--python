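"""Streaming computation of the pair statistic over all SNP pairs.

The maxT procedures never need all statistics at once — only the observed
top-n and, per permutation, the running maximum of the rest.  The engine
therefore yields statistics in fixed enumeration order as contiguous
*blocks* of pairs.  Within a block the cross-counts of every pair are
obtained with a handful of one-hot matrix products, so the per-pair cost is
a few floating-point operations instead of a pass over the subjects.

``block_pairs`` bounds how many statistics exist at the same time: memory is
O(n + block_pairs), independent of the number of pairs.  With
``block_pairs=1`` the engine degenerates to the literal pair-at-a-time
algorithm (using the scalar routines of :mod:`mbmdr.stats`), which is what
the memory-contract instrumentation measures.

Count matrices are accumulated in float32 matrix products (exact for counts
below 2^24) and promoted to float64 before any test arithmetic, so the
blocked and scalar binary paths produce bit-identical statistics.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from .data import Dataset
from .stats import (
    StatParams,
    _binary_T_from_counts,
    _continuous_T_from_sums,
    chi2_critical,
    f_critical,
    pair_statistic_binary,
    pair_statistic_continuous,
)

__all__ = ["PairStatsEngine", "EngineProvider", "FixedStatsProvider", "DEFAULT_BLOCK_PAIRS"]

DEFAULT_BLOCK_PAIRS = 4096


def _row_blocks(n_snps: int, block_pairs: int) -> Iterator[tuple[int, int]]:
    """Partition the rows l = 0..S-2 into runs of at most ``block_pairs``
    pairs (a single row may exceed the target, so a block holds at most
    ``max(block_pairs, S-1)`` pairs)."""
    l = 0
    while l < n_snps - 1:
        l2, count = l, 0
        while l2 < n_snps - 1:
            row = n_snps - 1 - l2
            if count and count + row > block_pairs:
                break
            count += row
            l2 += 1
        yield l, l2
        l = l2


class PairStatsEngine:
    """Computes the MB-MDR statistic for every pair, in enumeration order.

    One engine is built per dataset; ``stat_blocks(trait)`` is then called
    once per (real or permuted) trait vector and yields ``(j0, values)``
    with ``values`` covering pairs ``j0 .. j0+len(values)-1``.
    """

    def __init__(self, dataset: Dataset, params: StatParams | None = None,
                 block_pairs: int = DEFAULT_BLOCK_PAIRS) -> None:
        if dataset.n_snps < 2:
            raise ValueError("need at least 2 SNPs to enumerate pairs")
        if block_pairs < 1:
            raise ValueError("block_pairs must be >= 1")
        self.dataset = dataset
        self.params = params or StatParams()
        self.block_pairs = block_pairs
        self.c_max = int(dataset.n_categories.max())
        # one-hot genotype indicators, float32: exact 0/1 values, fast sgemm
        g = dataset.genotypes
        self._onehot = [(g == m).astype(np.float32) for m in range(self.c_max)]
        self._binary = dataset.trait_kind == "binary"
        if self._binary:
            self._fcrit = None
        else:
            self._fcrit = f_critical(self.params.cell_alpha, dataset.n_subjects - 2)
        # upper-triangle masks are cheap to rebuild; totals per block are
        # permutation-invariant and cached for small S (re-derived otherwise,
        # keeping per-pass memory independent of the pair count)
        self._totals_cache: dict[tuple[int, int], np.ndarray] | None = (
            {} if dataset.n_snps <= 4096 else None
        )

    @property
    def m(self) -> int:
        return self.dataset.n_pairs

    # -- scalar fallback ----------------------------------------------------

    def _scalar_blocks(self, trait: np.ndarray) -> Iterator[tuple[int, np.ndarray]]:
        g = self.dataset.genotypes
        stat = pair_statistic_binary if self._binary else pair_statistic_continuous
        j = 0
        for l in range(self.dataset.n_snps - 1):
            for r in range(l + 1, self.dataset.n_snps):
                t = stat(trait, g[:, l], g[:, r], self.params)
                yield j, np.array([t], dtype=np.float64)
                j += 1

    # -- blocked vectorized path ---------------------------------------------

    def _pair_totals(self, l0: int, l1: int) -> np.ndarray:
        """Per-cell subject totals N_mn for pairs (l in [l0,l1), all r),
        shape (C, C, l1-l0, S).  Permutation-invariant."""
        if self._totals_cache is not None and (l0, l1) in self._totals_cache:
            return self._totals_cache[(l0, l1)]
        C = self.c_max
        S = self.dataset.n_snps
        tot = np.empty((C, C, l1 - l0, S), dtype=np.float64)
        for mm in range(C):
            left = self._onehot[mm][:, l0:l1].T
            for nn in range(C):
                tot[mm, nn] = left @ self._onehot[nn]
        if self._totals_cache is not None:
            self._totals_cache[(l0, l1)] = tot
        return tot

    def _block_values_binary(self, trait, l0, l1):
        C = self.c_max
        aff = trait == 1
        n_aff = int(aff.sum())
        n_un = len(trait) - n_aff
        A = np.empty((C, C, l1 - l0, self.dataset.n_snps), dtype=np.float64)
        case_oh = [x[aff] for x in self._onehot]
        for mm in range(C):
            left = case_oh[mm][:, l0:l1].T
            for nn in range(C):
                A[mm, nn] = left @ case_oh[nn]
        U = self._pair_totals(l0, l1) - A
        # cell axes last so the shared helpers apply unchanged
        A = np.moveaxis(A, (0, 1), (-2, -1))
        U = np.moveaxis(U, (0, 1), (-2, -1))
        t_grid, _ = _binary_T_from_counts(A, U, n_aff, n_un, self.params)
        return t_grid  # (l1-l0, S)

    def _block_values_continuous(self, trait, l0, l1, s_total, ss_total):
        C = self.c_max
        n_total = len(trait)
        n_cell = self._pair_totals(l0, l1)
        s_cell = np.empty_like(n_cell)
        weighted = [trait[:, None] * x for x in self._onehot]
        for mm in range(C):
            left = weighted[mm][:, l0:l1].T
            for nn in range(C):
                s_cell[mm, nn] = left @ self._onehot[nn]
        n_cell = np.moveaxis(n_cell, (0, 1), (-2, -1))
        s_cell = np.moveaxis(s_cell, (0, 1), (-2, -1))
        t_grid, _ = _continuous_T_from_sums(
            n_cell, s_cell, n_total, s_total, ss_total, self._fcrit, self.params
        )
        return t_grid

    def stat_blocks(self, trait: np.ndarray) -> Iterator[tuple[int, np.ndarray]]:
        """Yield ``(j0, statistics)`` blocks covering all pairs in order."""
        if self.block_pairs == 1:
            yield from self._scalar_blocks(trait)
            return
        S = self.dataset.n_snps
        if self._binary:
            make = lambda l0, l1: self._block_values_binary(trait, l0, l1)
        else:
            t = np.asarray(trait, dtype=np.float64)
            s_total = float(t.sum())
            ss_total = float(t @ t) - s_total ** 2 / len(t)
            if ss_total <= 0:
                # zero-variance trait: every statistic is the 0 sentinel
                j0 = 0
                for l0, l1 in _row_blocks(S, self.block_pairs):
                    count = sum(S - 1 - l for l in range(l0, l1))
                    yield j0, np.zeros(count, dtype=np.float64)
                    j0 += count
                return
            make = lambda l0, l1: self._block_values_continuous(trait, l0, l1, s_total, ss_total)
        j0 = 0
        for l0, l1 in _row_blocks(S, self.block_pairs):
            grid = make(l0, l1)  # (l1-l0, S): statistic for (l, r) at [l-l0, r]
            parts = [grid[l - l0, l + 1:] for l in range(l0, l1)]
            block = np.concatenate(parts) if len(parts) > 1 else parts[0].copy()
            yield j0, block
            j0 += len(block)

    def all_stats(self, trait: np.ndarray) -> np.ndarray:
        """All m statistics as one array (reference path; O(m) memory)."""
        out = np.empty(self.m, dtype=np.float64)
        for j0, block in self.stat_blocks(trait):
            out[j0:j0 + len(block)] = block
        return out


class EngineProvider:
    """Binds an engine to the permutation contract of :mod:`mbmdr.rngs`.

    ``real_blocks()`` streams the observed-trait statistics; ``perm_blocks(i)``
    streams the statistics of global permutation ``i`` (1-based).  Both the
    classical and the top-n procedure consume providers, so swapping in a
    fixed-statistics stub exercises the bookkeeping in isolation.
    """

    def __init__(self, dataset: Dataset, params: StatParams | None = None,
                 base_seed: int = 0, block_pairs: int = DEFAULT_BLOCK_PAIRS) -> None:
        from .rngs import permute_trait  # local import to avoid cycles

        self._permute = permute_trait
        self.engine = PairStatsEngine(dataset, params, block_pairs)
        self.dataset = dataset
        self.base_seed = int(base_seed)

    @property
    def m(self) -> int:
        return self.engine.m

    @property
    def n_snps(self) -> int:
        return self.dataset.n_snps

    def real_blocks(self) -> Iterator[tuple[int, np.ndarray]]:
        return self.engine.stat_blocks(self.dataset.trait)

    def perm_blocks(self, i: int) -> Iterator[tuple[int, np.ndarray]]:
        trait = self._permute(self.dataset.trait, self.base_seed, i)
        return self.engine.stat_blocks(trait)


class FixedStatsProvider:
    """Provider serving pre-specified statistic vectors (enumeration order).

    Used to drive the maxT bookkeeping with hand-enumerable numbers.
    """

    def __init__(self, real: Sequence[float], perm_rows: Sequence[Sequence[float]],
                 n_snps: int | None = None, block_pairs: int = DEFAULT_BLOCK_PAIRS) -> None:
        self.real = np.asarray(real, dtype=np.float64)
        self.rows = [np.asarray(r, dtype=np.float64) for r in perm_rows]
        for r in self.rows:
            if len(r) != len(self.real):
                raise ValueError("permutation rows must match the real vector length")
        self.m = len(self.real)
        self.block_pairs = block_pairs
        if n_snps is None:
            # smallest S with S(S-1)/2 >= m, for PairId bookkeeping only
            s = 2
            while s * (s - 1) // 2 < self.m:
                s += 1
            n_snps = s
        self.n_snps = n_snps

    def _blocks(self, vec: np.ndarray) -> Iterator[tuple[int, np.ndarray]]:
        for j0 in range(0, len(vec), self.block_pairs):
            yield j0, vec[j0:j0 + self.block_pairs]

    def real_blocks(self) -> Iterator[tuple[int, np.ndarray]]:
        return self._blocks(self.real)

    def perm_blocks(self, i: int) -> Iterator[tuple[int, np.ndarray]]:
        return self._blocks(self.rows[i - 1])
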