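"""Core data containers and text I/O.

The native dataset format is a whitespace-delimited text file: a header line
``Trait SNP1 SNP2 ...`` followed by one line per subject, the trait value
first and then one genotype per SNP coded ``0..C-1`` (``0/1/2`` for
bi-allelic markers: homozygous first allele / heterozygous / homozygous
second allele).  Whether the trait column is binary or continuous is decided
by the caller, never inferred from the file.

This module also owns the two intermediate artifacts of the parallel
workflow: the *topfile* (the n best pairs with their observed statistics)
and the *permfile* (a chunk's exceedance-count vector).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "DataFormatError",
    "TraitError",
    "Dataset",
    "PairId",
    "TopList",
    "MaxTResult",
    "pair_count",
    "pair_index",
    "pair_from_index",
    "iter_pairs",
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_results",
    "save_topfile",
    "load_topfile",
    "save_permfile",
    "load_permfile",
]


class DataFormatError(ValueError):
    """Malformed dataset, topfile or permfile."""


class TraitError(DataFormatError):
    """Trait column violates the declared trait scale."""


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

class PairId(NamedTuple):
    """An unordered SNP pair ``(l, r)`` with its linear rank ``j``.

    Pairs are enumerated row-major over ``l < r``:
    ``(0,1), (0,2), ..., (0,S-1), (1,2), ...`` so that the linear index is
    reproducible across runs and machines.
    """

    l: int
    r: int
    j: int


def pair_count(n_snps: int) -> int:
    """Number of unordered SNP pairs, ``m = S(S-1)/2``."""
    return n_snps * (n_snps - 1) // 2


def pair_index(l: int, r: int, n_snps: int) -> int:
    """Linear index of pair ``(l, r)``, ``l < r``, in enumeration order."""
    if not 0 <= l < r < n_snps:
        raise ValueError(f"invalid pair ({l},{r}) for S={n_snps}")
    return l * n_snps - l * (l + 1) // 2 + (r - l - 1)


def pair_from_index(j: int, n_snps: int) -> PairId:
    """Inverse of :func:`pair_index`."""
    m = pair_count(n_snps)
    if not 0 <= j < m:
        raise ValueError(f"pair index {j} out of range for S={n_snps}")
    # smallest l with cumulative pair count > j
    l = int((2 * n_snps - 1 - math.sqrt((2 * n_snps - 1) ** 2 - 8 * j)) // 2)
    while pair_index(l, n_snps - 1, n_snps) < j:
        l += 1
    while l > 0 and pair_index(l, l + 1, n_snps) > j:
        l -= 1
    r = j - (l * n_snps - l * (l + 1) // 2) + l + 1
    return PairId(l, r, j)


def iter_pairs(n_snps: int) -> Iterator[PairId]:
    """Yield all pairs in enumeration order."""
    j = 0
    for l in range(n_snps - 1):
        for r in range(l + 1, n_snps):
            yield PairId(l, r, j)
            j += 1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A trait vector plus a subjects × S genotype matrix.

    ``n_categories[b]`` is the number of genotype categories of SNP ``b``,
    inferred from the data as ``1 + max(genotypes[:, b])`` so that
    multi-allelic markers and categorical exposures coded ``0..C-1`` are
    handled transparently.
    """

    trait: np.ndarray
    genotypes: np.ndarray
    snp_labels: list[str]
    trait_kind: str  # "binary" | "continuous"
    n_categories: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait)
        self.genotypes = np.asarray(self.genotypes)
        if self.trait_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown trait kind {self.trait_kind!r}")
        if self.genotypes.ndim != 2:
            raise DataFormatError("genotypes must be a 2-D matrix")
        n_subj, n_snps = self.genotypes.shape
        if self.trait.shape != (n_subj,):
            raise DataFormatError("trait length does not match genotype rows")
        if n_subj < 2:
            raise DataFormatError("need at least 2 subjects")
        if len(self.snp_labels) != n_snps:
            raise DataFormatError("label count does not match SNP columns")
        if not np.issubdtype(self.genotypes.dtype, np.integer):
            raise DataFormatError("genotypes must be integers")
        if self.genotypes.size and self.genotypes.min() < 0:
            raise DataFormatError("negative genotype code")
        if self.trait_kind == "binary":
            vals = np.unique(self.trait)
            if not np.isin(vals, [0, 1]).all():
                raise TraitError("binary trait must contain only 0 and 1")
            if len(vals) < 2:
                raise TraitError("binary trait needs both cases and controls")
            self.trait = self.trait.astype(np.int64)
        else:
            self.trait = self.trait.astype(np.float64)
        if self.n_categories is None:
            self.n_categories = self.genotypes.max(axis=0).astype(np.int64) + 1
        else:
            self.n_categories = np.asarray(self.n_categories, dtype=np.int64)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_pairs(self) -> int:
        return pair_count(self.n_snps)


@dataclass
class TopList:
    """The ``n`` best pairs of the observed data, sorted by descending T.

    Ties in T are broken by ascending pair index, matching the stable
    descending sort of the reference algorithm.  ``positions_in_range``
    gives constant-time membership routing for the streaming permutation
    pass: which retained pairs fall in a contiguous block of linear indices.
    """

    pairs: list[PairId]
    t0: np.ndarray
    _j_sorted: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _pos_sorted: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t0 = np.asarray(self.t0, dtype=np.float64)
        if len(self.pairs) != len(self.t0):
            raise ValueError("pairs/t0 length mismatch")
        if np.any(np.diff(self.t0) > 0):
            raise ValueError("t0 must be non-increasing")
        js = np.array([p.j for p in self.pairs], dtype=np.int64)
        order = np.argsort(js)
        self._j_sorted = js[order]
        self._pos_sorted = order.astype(np.int64)

    def __len__(self) -> int:
        return len(self.pairs)

    def positions_in_range(self, j0: int, j1: int) -> tuple[np.ndarray, np.ndarray]:
        """(list positions, linear indices) of retained pairs with j in [j0, j1)."""
        lo = np.searchsorted(self._j_sorted, j0, side="left")
        hi = np.searchsorted(self._j_sorted, j1, side="left")
        return self._pos_sorted[lo:hi], self._j_sorted[lo:hi]

    def position_of(self, j: int) -> int:
        """List position of pair index ``j`` or -1 if not retained."""
        k = np.searchsorted(self._j_sorted, j)
        if k < len(self._j_sorted) and self._j_sorted[k] == j:
            return int(self._pos_sorted[k])
        return -1


@dataclass
class MaxTResult:
    """maxT output: pairs, observed statistics, exceedance counts, p-values.

    Pairs are in descending-T order; ``p`` is non-decreasing; every p-value
    is a multiple of ``1/(B+1)``; ``a[j] >= 1`` because the observed data
    counts as one of the ``B+1`` samples.
    """

    pairs: list[PairId]
    t0: np.ndarray
    a: np.ndarray
    p: np.ndarray
    n_permutations: int
    peak_retained: int | None = None

    def __post_init__(self) -> None:
        self.t0 = np.asarray(self.t0, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if not (len(self.pairs) == len(self.t0) == len(self.a) == len(self.p)):
            raise ValueError("field length mismatch")
        if np.any(np.diff(self.t0) > 0):
            raise ValueError("t0 must be non-increasing")
        if np.any(np.diff(self.p) < 0):
            raise ValueError("p must be non-decreasing")
        if len(self.a) and (self.a.min() < 1 or self.a.max() > self.n_permutations + 1):
            raise ValueError("exceedance counts out of [1, B+1]")


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def read_dataset(path, trait_kind: str) -> Dataset:
    """Parse a native-format text file into a :class:`Dataset`.

    Raises :class:`DataFormatError` (naming line and column) on non-integer
    or negative genotypes, ragged rows, or a binary trait value outside
    {0, 1}.  Missing genotypes are not supported: the count matrices of the
    association statistic assume complete data.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().split()
        if not header or header[0].lower() != "trait":
            raise DataFormatError(f"{path}: first header token must be 'Trait'")
        labels = header[1:]
        n_snps = len(labels)
        if n_snps == 0:
            raise DataFormatError(f"{path}: no SNP columns in header")
        traits: list[float] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != n_snps + 1:
                raise DataFormatError(
                    f"{path}:{lineno}: expected {n_snps + 1} columns, got {len(tokens)}"
                )
            try:
                tval = float(tokens[0])
            except ValueError:
                raise TraitError(f"{path}:{lineno}: bad trait value {tokens[0]!r}") from None
            if trait_kind == "binary" and tval not in (0.0, 1.0):
                raise TraitError(f"{path}:{lineno}: binary trait value {tokens[0]!r} not in {{0,1}}")
            row = []
            for col, tok in enumerate(tokens[1:], start=2):
                try:
                    g = int(tok)
                except ValueError:
                    raise DataFormatError(
                        f"{path}:{lineno}: column {col}: non-integer genotype {tok!r}"
                    ) from None
                if g < 0:
                    raise DataFormatError(
                        f"{path}:{lineno}: column {col}: negative genotype {g}"
                    )
                row.append(g)
            traits.append(tval)
            rows.append(row)
    if len(rows) < 2:
        raise DataFormatError(f"{path}: need at least 2 subjects")
    genotypes = np.array(rows, dtype=np.int64)
    trait = np.array(traits)
    return Dataset(trait=trait, genotypes=genotypes, snp_labels=labels, trait_kind=trait_kind)


def write_dataset(dataset: Dataset, path) -> None:
    """Serialize a dataset back to the native text format."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("Trait " + " ".join(dataset.snp_labels) + "\n")
        binary = dataset.trait_kind == "binary"
        for t, row in zip(dataset.trait, dataset.genotypes):
            tstr = str(int(t)) if binary else repr(float(t))
            fh.write(tstr + " " + " ".join(str(int(g)) for g in row) + "\n")


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def write_results(result: MaxTResult, labels: Sequence[str], path) -> None:
    """Write the final report: one tab-separated line per top pair.

    Lines are ordered by ascending adjusted p-value, ties broken by
    descending statistic and then by pair enumeration order — which is
    exactly the order the result already carries.  Output is byte-
    deterministic for a fixed result.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("SNP_l\tSNP_r\tT\tp\n")
        for pid, t, p in zip(result.pairs, result.t0, result.p):
            fh.write(f"{labels[pid.l]}\t{labels[pid.r]}\t{t:.6g}\t{p:.6g}\n")


def read_results(path) -> list[tuple[str, str, float, float]]:
    """Read back a results file (label, label, T, p) at printed precision."""
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("SNP_l"):
            raise DataFormatError(f"{path}: not a results file")
        for line in fh:
            tok = line.split("\t")
            if len(tok) != 4:
                raise DataFormatError(f"{path}: malformed results line")
            out.append((tok[0], tok[1], float(tok[2]), float(tok[3])))
    return out


# ---------------------------------------------------------------------------
# parallel-workflow artifacts
# ---------------------------------------------------------------------------

def save_topfile(toplist: TopList, n_permutations_planned: int, path) -> None:
    """Persist the top list: header ``n B_planned`` then ``l r T`` per line.

    Statistics are written with shortest round-tripping decimals so that a
    load reproduces them bit-for-bit and the chunk merge stays exact.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{len(toplist)} {n_permutations_planned}\n")
        for pid, t in zip(toplist.pairs, toplist.t0):
            fh.write(f"{pid.l} {pid.r} {_full_precision(t)}\n")


def load_topfile(path, n_snps: int) -> tuple[TopList, int]:
    """Inverse of :func:`save_topfile`; returns (toplist, planned B)."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise DataFormatError(f"{path}: bad topfile header")
        try:
            n, b_planned = int(header[0]), int(header[1])
        except ValueError:
            raise DataFormatError(f"{path}: bad topfile header") from None
        pairs: list[PairId] = []
        t0: list[float] = []
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 3:
                raise DataFormatError(f"{path}: malformed topfile record")
            l, r = int(tok[0]), int(tok[1])
            pairs.append(PairId(l, r, pair_index(l, r, n_snps)))
            t0.append(float(tok[2]))
    if len(pairs) != n:
        raise DataFormatError(f"{path}: truncated topfile ({len(pairs)} of {n} records)")
    return TopList(pairs=pairs, t0=np.array(t0)), b_planned


def save_permfile(counts: np.ndarray, chunk_size: int, path) -> None:
    """Persist one chunk's exceedance counts: header ``chunk_size`` then one
    integer per top pair."""
    counts = np.asarray(counts)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{int(chunk_size)}\n")
        for c in counts:
            fh.write(f"{int(c)}\n")


def load_permfile(path, expected_n: int | None = None) -> tuple[np.ndarray, int]:
    """Inverse of :func:`save_permfile`; returns (counts, chunk size)."""
    with open(path, "rt", encoding="utf-8") as fh:
        try:
            chunk_size = int(fh.readline().split()[0])
        except (ValueError, IndexError):
            raise DataFormatError(f"{path}: bad permfile header") from None
        try:
            counts = np.array([int(line.split()[0]) for line in fh if line.strip()],
                              dtype=np.int64)
        except ValueError:
            raise DataFormatError(f"{path}: non-integer count") from None
    if expected_n is not None and len(counts) != expected_n:
        raise DataFormatError(
            f"{path}: {len(counts)} counts but topfile has {expected_n} pairs"
        )
    return counts, chunk_size


def _full_precision(x: float) -> str:
    if np.isinf(x):
        return "inf" if x > 0 else "-inf"
    return repr(float(x))
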