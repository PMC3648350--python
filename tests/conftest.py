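import numpy as np
import pytest

from mbmdr import FixedStatsProvider, simulate_binary_null


# hand-enumerable 3-pair instance: real statistics (enumeration order)
# p0=5, p1=9, p2=3; two permutation rows p0/p1/p2 = 6/4/2 and 1/10/7.
TOY_REAL = [5.0, 9.0, 3.0]
TOY_ROWS = [[6.0, 4.0, 2.0], [1.0, 10.0, 7.0]]


@pytest.fixture
def toy_provider():
    return FixedStatsProvider(TOY_REAL, TOY_ROWS)


def toy_provider_factory(block_pairs=4096):
    return FixedStatsProvider(TOY_REAL, TOY_ROWS, block_pairs=block_pairs)


@pytest.fixture
def small_binary_dataset():
    """Null case-control dataset small enough for brute-force oracles."""
    return simulate_binary_null(8, 60, 60, seed=11)


def random_binary_dataset(seed, n_snps=10, n_cases=60, n_controls=60):
    return simulate_binary_null(n_snps, n_cases, n_controls, seed=seed)


def naive_maxt_pvalues(stat_matrix):
    """Brute-force maxT on a full (B+1) x m statistic matrix.

    Row 0 is the observed data.  Returns (column order, p-values in sorted
    order).  Keeps the whole matrix in memory — the thing the package
    avoids — which makes it a structurally independent oracle for the
    step-down bookkeeping.
    """
    stat_matrix = np.asarray(stat_matrix, dtype=np.float64)
    t0 = stat_matrix[0]
    order = np.argsort(-t0, kind="stable")
    sorted_rows = stat_matrix[:, order]
    perm = sorted_rows[1:]
    mono = np.maximum.accumulate(perm[:, ::-1], axis=1)[:, ::-1]
    t0s = sorted_rows[0]
    a = 1 + (mono >= t0s[None, :]).sum(axis=0)
    p = a / stat_matrix.shape[0]
    return order, np.maximum.accumulate(p)
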