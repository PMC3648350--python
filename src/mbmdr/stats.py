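"""The MB-MDR association statistic for one SNP pair.

For a pair of markers and a binary trait the statistic is computed in three
steps:

1. cross-count the subjects into an affected matrix ``A`` and an unaffected
   matrix ``U`` over the C_l × C_r genotype combinations;
2. label every genotype cell H (high risk), L (low risk) or O (no evidence)
   from a per-cell 1-df chi-squared test of that cell against the rest,
   gated by a minimum cell size (default 10) and a liberal significance
   level (default 0.1);
3. run two 1-df chi-squared tests — H cells against the rest, and L cells
   against the rest — and return the maximum of the two.

For a continuous trait the per-cell and final tests are two-group one-way
F tests (cell members versus all other subjects) and H/L is decided by the
sign of the cell-mean minus complement-mean difference.

All arithmetic helpers operate elementwise on arrays so the vectorized
all-pairs engine and the scalar per-pair path share the exact same
floating-point operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatParams",
    "CrossCounts",
    "HLOMatrix",
    "build_cross_counts",
    "cell_chi2",
    "classify_cells",
    "pair_statistic_binary",
    "pair_statistic_continuous",
    "chi2_critical",
    "f_critical",
]

H, L, O = 1, -1, 0  # HLO cell codes
_LABELS = {H: "H", L: "L", O: "O"}


@dataclass(frozen=True)
class StatParams:
    """Tunable knobs of the per-cell association tests.

    ``min_cell_total``: a cell (or its complement) with fewer subjects than
    this is never tested and is labelled O (default 10).
    ``cell_alpha``: liberal significance level of the per-cell test
    (default 0.1); the gate is applied through the distribution quantile so
    any level is supported.
    """

    min_cell_total: int = 10
    cell_alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.min_cell_total < 0:
            raise ValueError("min_cell_total must be >= 0")
        if not 0 < self.cell_alpha <= 1:
            raise ValueError("cell_alpha must be in (0, 1]")


@lru_cache(maxsize=32)
def chi2_critical(alpha: float) -> float:
    """Upper-``alpha`` quantile of chi-squared with 1 df."""
    return float(sps.chi2.ppf(1.0 - alpha, df=1))


@lru_cache(maxsize=128)
def f_critical(alpha: float, df2: int) -> float:
    """Upper-``alpha`` quantile of F(1, df2)."""
    return float(sps.f.ppf(1.0 - alpha, dfn=1, dfd=df2))


@dataclass
class CrossCounts:
    """Affected/unaffected genotype-combination counts for one pair."""

    A: np.ndarray  # (C_l, C_r) affected counts
    U: np.ndarray  # (C_l, C_r) unaffected counts
    n_affected: int
    n_unaffected: int

    def __post_init__(self) -> None:
        if self.A.shape != self.U.shape:
            raise ValueError("A and U must have the same shape")
        if int(self.A.sum()) != self.n_affected or int(self.U.sum()) != self.n_unaffected:
            raise ValueError("totals inconsistent with count matrices")


@dataclass
class HLOMatrix:
    """Per-cell risk labels for one pair; codes: H=+1, L=-1, O=0."""

    codes: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        out = np.empty(self.codes.shape, dtype="<U1")
        for code, lab in _LABELS.items():
            out[self.codes == code] = lab
        return out


# ---------------------------------------------------------------------------
# shared elementwise arithmetic
# ---------------------------------------------------------------------------

def _chi2_formula(a, b, c, d):
    """(ad-bc)^2 (a+b+c+d) / [(a+b)(c+d)(b+d)(a+c)], elementwise.

    Any zero factor in the denominator (an empty margin) yields the
    no-evidence sentinel 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    num = (a * d - b * c) ** 2 * (a + b + c + d)
    den = (a + b) * (c + d) * (b + d) * (a + c)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _two_group_f(n1, s1, n_total, s_total, ss_total):
    """Two-group one-way F statistic from group size/sum summaries.

    Group 1 has ``n1`` members summing to ``s1``; group 2 is the complement.
    ``ss_total`` is the total (mean-centred) sum of squares of the trait.
    Empty groups give the sentinel 0; zero within-group variance with a
    nonzero between-group contrast gives +inf (a perfectly separating
    split); df2 = n_total - 2.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    s1 = np.asarray(s1, dtype=np.float64)
    n2 = n_total - n1
    valid = (n1 > 0) & (n2 > 0)
    safe_n1 = np.where(n1 > 0, n1, 1.0)
    safe_n2 = np.where(n2 > 0, n2, 1.0)
    gm = s_total / n_total
    m1 = s1 / safe_n1
    m2 = (s_total - s1) / safe_n2
    ssb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
    ssw = ss_total - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ssw > 0, ssb * (n_total - 2) / np.where(ssw > 0, ssw, 1.0), np.inf)
    f = np.where(ssb > 0, f, 0.0)
    return np.where(valid, f, 0.0)


# ---------------------------------------------------------------------------
# scalar (per-pair) path
# ---------------------------------------------------------------------------

def build_cross_counts(trait: np.ndarray, g_l: np.ndarray, g_r: np.ndarray,
                       shape: tuple[int, int] | None = None) -> CrossCounts:
    """Cross-tabulate affected and unaffected subjects over genotype cells.

    One pass over the subjects; inputs are taken by value (never mutated).
    """
    trait = np.asarray(trait)
    g_l = np.asarray(g_l)
    g_r = np.asarray(g_r)
    if not (len(trait) == len(g_l) == len(g_r)):
        raise ValueError("trait and genotype columns must have equal length")
    if shape is None:
        shape = (int(g_l.max()) + 1, int(g_r.max()) + 1)
    cl, cr = shape
    cell = g_l.astype(np.int64) * cr + g_r.astype(np.int64)
    aff = trait == 1
    A = np.bincount(cell[aff], minlength=cl * cr).reshape(cl, cr)
    U = np.bincount(cell[~aff], minlength=cl * cr).reshape(cl, cr)
    return CrossCounts(A=A, U=U, n_affected=int(aff.sum()), n_unaffected=int((~aff).sum()))


def cell_chi2(a: float, b: float, c: float, d: float) -> float:
    """1-df chi-squared of one genotype cell against the rest.

    ``a, b`` are affected/unaffected counts inside the cell, ``c, d``
    outside.  Equals the standard Pearson chi-squared of the 2x2 table when
    all margins are positive; a degenerate margin returns 0 (no evidence).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    return float(_chi2_formula(a, b, c, d))


def classify_cells(counts: CrossCounts, params: StatParams | None = None) -> HLOMatrix:
    """Assign H/L/O to every genotype cell of a pair (binary trait)."""
    params = params or StatParams()
    A = counts.A.astype(np.float64)
    U = counts.U.astype(np.float64)
    codes = _classify_binary(A, U, counts.n_affected, counts.n_unaffected, params)
    return HLOMatrix(codes=codes)


def _classify_binary(A, U, n_aff, n_un, params: StatParams) -> np.ndarray:
    a, b = A, U
    c, d = n_aff - A, n_un - U
    chi2 = _chi2_formula(a, b, c, d)
    small = (a + b < params.min_cell_total) | (c + d < params.min_cell_total)
    sig = ~small & (chi2 > chi2_critical(params.cell_alpha))
    delta = a * d - b * c
    codes = np.zeros(A.shape, dtype=np.int8)
    codes[sig & (delta > 0)] = H
    codes[sig & (delta < 0)] = L
    return codes


def _binary_T_from_counts(A, U, n_aff, n_un, params: StatParams):
    """Final statistic from count matrices; works on (..., C_l, C_r) stacks
    with the cell axes last two.  Shared by the scalar and vectorized paths."""
    codes = _classify_binary(A, U, n_aff, n_un, params)
    hmask = (codes == H).astype(np.float64)
    lmask = (codes == L).astype(np.float64)
    aH = (A * hmask).sum(axis=(-2, -1))
    bH = (U * hmask).sum(axis=(-2, -1))
    aL = (A * lmask).sum(axis=(-2, -1))
    bL = (U * lmask).sum(axis=(-2, -1))
    t_h = _chi2_formula(aH, bH, n_aff - aH, n_un - bH)
    t_l = _chi2_formula(aL, bL, n_aff - aL, n_un - bL)
    return np.maximum(t_h, t_l), codes


def pair_statistic_binary(trait: np.ndarray, g_l: np.ndarray, g_r: np.ndarray,
                          params: StatParams | None = None) -> float:
    """MB-MDR statistic T for one pair and a binary trait.

    T = max of the H-versus-rest and L-versus-rest 1-df chi-squared tests;
    an empty partition contributes 0, so a fully-O matrix gives T = 0.
    """
    params = params or StatParams()
    trait = np.asarray(trait)
    uniq = np.unique(trait)
    if not np.isin(uniq, [0, 1]).all() or len(uniq) < 2:
        raise ValueError("binary trait must contain both 0 and 1")
    counts = build_cross_counts(trait, g_l, g_r)
    t, _ = _binary_T_from_counts(
        counts.A.astype(np.float64), counts.U.astype(np.float64),
        counts.n_affected, counts.n_unaffected, params,
    )
    return float(t)


# ---------------------------------------------------------------------------
# continuous-trait path
# ---------------------------------------------------------------------------

def _classify_continuous(n_cell, s_cell, n_total, s_total, ss_total, fcrit,
                         params: StatParams) -> np.ndarray:
    f = _two_group_f(n_cell, s_cell, n_total, s_total, ss_total)
    n2 = n_total - n_cell
    small = (n_cell < params.min_cell_total) | (n2 < params.min_cell_total)
    sig = ~small & (f > fcrit) & (n_cell > 0) & (n2 > 0)
    safe_n1 = np.where(n_cell > 0, n_cell, 1.0)
    safe_n2 = np.where(n2 > 0, n2, 1.0)
    diff = s_cell / safe_n1 - (s_total - s_cell) / safe_n2
    codes = np.zeros(np.shape(n_cell), dtype=np.int8)
    codes[sig & (diff > 0)] = H
    codes[sig & (diff < 0)] = L
    return codes


def _continuous_T_from_sums(n_cell, s_cell, n_total, s_total, ss_total, fcrit,
                            params: StatParams):
    """Final continuous-trait statistic from per-cell size/sum summaries."""
    codes = _classify_continuous(n_cell, s_cell, n_total, s_total, ss_total,
                                 fcrit, params)
    hmask = (codes == H).astype(np.float64)
    lmask = (codes == L).astype(np.float64)
    nH = (n_cell * hmask).sum(axis=(-2, -1))
    sH = (s_cell * hmask).sum(axis=(-2, -1))
    nL = (n_cell * lmask).sum(axis=(-2, -1))
    sL = (s_cell * lmask).sum(axis=(-2, -1))
    t_h = _two_group_f(nH, sH, n_total, s_total, ss_total)
    t_l = _two_group_f(nL, sL, n_total, s_total, ss_total)
    return np.maximum(t_h, t_l), codes


def pair_statistic_continuous(trait: np.ndarray, g_l: np.ndarray, g_r: np.ndarray,
                              params: StatParams | None = None) -> float:
    """MB-MDR statistic T for one pair and a continuous trait.

    Per-cell test: two-group one-way F (cell versus all other subjects);
    H/L by the sign of the mean difference; final T = max of the two-group
    F for H-members-versus-rest and L-members-versus-rest.
    """
    params = params or StatParams()
    trait = np.asarray(trait, dtype=np.float64)
    g_l = np.asarray(g_l)
    g_r = np.asarray(g_r)
    if not (len(trait) == len(g_l) == len(g_r)):
        raise ValueError("trait and genotype columns must have equal length")
    n_total = len(trait)
    s_total = float(trait.sum())
    ss_total = float(trait @ trait) - s_total ** 2 / n_total
    if ss_total <= 0:
        warnings.warn("trait has zero variance; statistic is 0", stacklevel=2)
        return 0.0
    cl, cr = int(g_l.max()) + 1, int(g_r.max()) + 1
    cell = g_l.astype(np.int64) * cr + g_r.astype(np.int64)
    n_cell = np.bincount(cell, minlength=cl * cr).reshape(cl, cr).astype(np.float64)
    s_cell = np.bincount(cell, weights=trait, minlength=cl * cr).reshape(cl, cr)
    fcrit = f_critical(params.cell_alpha, n_total - 2)
    t, _ = _continuous_T_from_sums(n_cell, s_cell, n_total, s_total, ss_total,
                                   fcrit, params)
    return float(t)
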