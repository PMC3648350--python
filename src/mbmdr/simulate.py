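"""Synthetic datasets for power and type-I-error studies.

The default design plants one purely epistatic functional pair: disease
probability depends only on the joint genotype of two SNPs through a 3×3
penetrance table whose rows/columns have no marginal effect
(the checkerboard table below), while every other SNP is independent noise.

* Functional SNPs sit at positions 5 and 10 (1-based) with minor allele
  frequency 0.5.
* Non-functional minor allele frequencies are drawn once per SNP, uniform
  on [0.05, 0.5].
* Genotypes follow Hardy–Weinberg proportions [(1−q)², 2q(1−q), q²],
  coded 0/1/2.
* Case/control balance is achieved by rejection-to-quota sampling: subjects
  are drawn, assigned disease status with the penetrance of their
  functional genotype, and kept until both quotas are filled.

A continuous-trait surrogate and a pure-null generator (trait independent
of all genotypes) are included for F-test screening and family-wise error
rate studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .rngs import simulation_generator

__all__ = [
    "PenetranceModel",
    "simulate_genotypes",
    "simulate_binary_trait",
    "simulate_continuous_trait",
    "simulate_binary_null",
]

#: Checkerboard two-locus penetrance: pure epistasis, no marginal effects.
DEFAULT_PENETRANCE = np.array([
    [0.0, 0.1, 0.0],
    [0.1, 0.0, 0.1],
    [0.0, 0.1, 0.0],
])


@dataclass(frozen=True)
class PenetranceModel:
    """Two-locus disease model: P(affected | g_l, g_r) = table[g_l, g_r]."""

    table: np.ndarray = field(default_factory=lambda: DEFAULT_PENETRANCE.copy())
    functional_indices: tuple[int, int] = (4, 9)  # 0-based: SNP5 and SNP10
    maf_functional: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.float64)
        if t.shape != (3, 3) or t.min() < 0 or t.max() > 1:
            raise ValueError("penetrance table must be 3x3 with entries in [0,1]")
        object.__setattr__(self, "table", t)
        l, r = self.functional_indices
        if l == r or l < 0 or r < 0:
            raise ValueError("functional indices must be two distinct SNP positions")


def _hwe_sample(rng: np.random.Generator, mafs: np.ndarray, n_subjects: int) -> np.ndarray:
    """Hardy–Weinberg genotypes, one column per SNP, coded 0/1/2."""
    q = np.asarray(mafs, dtype=np.float64)
    p0 = (1 - q) ** 2
    p01 = p0 + 2 * q * (1 - q)
    u = rng.random((n_subjects, len(q)))
    return ((u >= p0).astype(np.int64) + (u >= p01)).astype(np.int64)


def simulate_genotypes(n_snps: int, n_subjects: int, mafs, seed: int = 0) -> np.ndarray:
    """Independent HWE genotype matrix for given per-SNP allele frequencies."""
    mafs = np.asarray(mafs, dtype=np.float64)
    if mafs.shape != (n_snps,):
        raise ValueError("need one MAF per SNP")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = simulation_generator(seed)
    return _hwe_sample(rng, mafs, n_subjects)


def _draw_mafs(rng: np.random.Generator, model: PenetranceModel, n_snps: int) -> np.ndarray:
    lo, hi = model.maf_range
    mafs = rng.uniform(lo, hi, size=n_snps)
    l, r = model.functional_indices
    if max(l, r) >= n_snps:
        raise ValueError(f"functional indices {model.functional_indices} need S > {max(l, r)}")
    mafs[[l, r]] = model.maf_functional
    return mafs


def _snp_labels(n_snps: int) -> list[str]:
    return [f"SNP{b}" for b in range(1, n_snps + 1)]


def simulate_binary_trait(model: PenetranceModel, n_snps: int,
                          n_cases: int = 500, n_controls: int = 500,
                          seed: int = 0, max_draws: int = 10 ** 7) -> Dataset:
    """Balanced case-control dataset driven by the penetrance table.

    Rejection-to-quota sampling; ``max_draws`` bounds the attempt budget so
    a degenerate table (e.g. all zeros with cases requested) fails cleanly
    instead of looping forever.
    """
    rng = simulation_generator(seed)
    mafs = _draw_mafs(rng, model, n_snps)
    l, r = model.functional_indices
    case_rows, control_rows = [], []
    need_cases, need_controls = n_cases, n_controls
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"could not fill case/control quotas within {max_draws} draws; "
                "is the penetrance table degenerate?"
            )
        batch = min(8192, max_draws - drawn)
        drawn += batch
        g = _hwe_sample(rng, mafs, batch)
        pen = model.table[g[:, l], g[:, r]]
        affected = rng.random(batch) < pen
        if need_cases > 0:
            take = g[affected][:need_cases]
            case_rows.append(take)
            need_cases -= len(take)
        if need_controls > 0:
            take = g[~affected][:need_controls]
            control_rows.append(take)
            need_controls -= len(take)
    genotypes = np.vstack(case_rows + control_rows)
    trait = np.concatenate([np.ones(n_cases, dtype=np.int64),
                            np.zeros(n_controls, dtype=np.int64)])
    # shuffle subject order so case status is not encoded in row position
    order = rng.permutation(n_cases + n_controls)
    return Dataset(trait=trait[order], genotypes=genotypes[order],
                   snp_labels=_snp_labels(n_snps), trait_kind="binary")


def simulate_continuous_trait(model: PenetranceModel, n_snps: int, n_subjects: int,
                              effect_size: float = 1.0, noise_sd: float = 0.5,
                              seed: int = 0) -> Dataset:
    """Continuous-trait surrogate of the epistasis design.

    trait = effect_size · table[g_l, g_r] / max(table) + N(0, noise_sd).
    This generator is a documented stand-in: it keeps the same functional
    pair and genotype model but expresses the signal as a mean shift.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = simulation_generator(seed)
    mafs = _draw_mafs(rng, model, n_snps)
    genotypes = _hwe_sample(rng, mafs, n_subjects)
    l, r = model.functional_indices
    peak = model.table.max()
    base = model.table[genotypes[:, l], genotypes[:, r]] / peak if peak > 0 else 0.0
    trait = effect_size * base + rng.normal(0.0, noise_sd, size=n_subjects)
    return Dataset(trait=trait, genotypes=genotypes,
                   snp_labels=_snp_labels(n_snps), trait_kind="continuous")


def simulate_binary_null(n_snps: int, n_cases: int = 250, n_controls: int = 250,
                         seed: int = 0,
                         maf_range: tuple[float, float] = (0.05, 0.5)) -> Dataset:
    """Pure-null dataset: trait assigned independently of every genotype."""
    rng = simulation_generator(seed)
    mafs = rng.uniform(*maf_range, size=n_snps)
    genotypes = _hwe_sample(rng, mafs, n_cases + n_controls)
    trait = np.concatenate([np.ones(n_cases, dtype=np.int64),
                            np.zeros(n_controls, dtype=np.int64)])
    trait = rng.permutation(trait)
    return Dataset(trait=trait, genotypes=genotypes,
                   snp_labels=_snp_labels(n_snps), trait_kind="binary")
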