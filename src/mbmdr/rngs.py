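"""Deterministic random-number contracts shared by every analysis path.

The permutation test, the top-n algorithm and the chunked parallel workflow
must all see *exactly* the same sequence of trait permutations for a given
base seed, otherwise their results could not be compared bit-for-bit.  The
contract is:

* permutation ``i`` (1-based, global over the whole run) is drawn from a
  ``numpy`` PCG64 generator seeded with ``SeedSequence(base_seed,
  spawn_key=(i,))``;
* the permutation itself is ``Generator.permutation`` (a Fisher–Yates
  shuffle).

Because the child seed depends only on ``(base_seed, i)``, splitting the
permutations across processes or machines cannot change which permutations
are generated.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "permutation_generator",
    "permute_trait",
    "simulation_generator",
]


def permutation_generator(base_seed: int, perm_index: int) -> np.random.Generator:
    """Generator for the ``perm_index``-th trait permutation of a run."""
    if perm_index < 1:
        raise ValueError("permutation indices are 1-based")
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(perm_index),))
    return np.random.Generator(np.random.PCG64(ss))


def permute_trait(trait: np.ndarray, base_seed: int, perm_index: int) -> np.ndarray:
    """Return the ``perm_index``-th permutation of ``trait`` (a new array)."""
    rng = permutation_generator(base_seed, perm_index)
    return rng.permutation(trait)


def simulation_generator(seed: int) -> np.random.Generator:
    """Generator used by the synthetic-data module (separate stream family)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(0xD5,))
    return np.random.Generator(np.random.PCG64(ss))
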