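"""Chunked parallel permutation workflow.

The B permutations split homogeneously into Z chunks that can run in
separate processes — or on separate machines, through the file-based
protocol:

1. one invocation computes the top list and writes ``topfile.txt``;
2. each worker z reads the topfile, runs its share of the permutations with
   exceedance counts starting at zero, and writes ``permutation_z.txt``;
3. the merge sums the count vectors, adds the observed data's +1, and
   derives the final p-values.

Per-permutation seeds derive from the *global* permutation index, so the
chunking never changes which permutations are generated and the merged
result is identical — bit for bit — to the sequential run.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np

from .data import (
    DataFormatError,
    Dataset,
    MaxTResult,
    TopList,
    load_permfile,
    load_topfile,
    save_permfile,
    save_topfile,
)
from .engine import DEFAULT_BLOCK_PAIRS, EngineProvider
from .stats import StatParams
from .topn import chunk_exceedance_counts, finalize_pvalues, _toplist_from_blocks

__all__ = ["ChunkSpec", "plan_chunks", "run_chunk", "merge_chunks", "maxt_topn_parallel"]


@dataclass(frozen=True)
class ChunkSpec:
    """One worker's share: global permutation indices start+1 .. start+size."""

    chunk_id: int
    start: int
    size: int
    base_seed: int

    @property
    def perm_indices(self) -> range:
        return range(self.start + 1, self.start + self.size + 1)


def plan_chunks(n_permutations: int, n_workers: int, seed: int) -> list[ChunkSpec]:
    """Split B permutations over Z workers; sizes differ by at most one.

    Surplus workers (Z > B) receive empty chunks.  Chunks carry the base
    seed, not private seeds: each permutation's generator is derived from
    (base seed, global index), so the plan cannot alter the permutations.
    """
    if n_permutations < 0:
        raise ValueError("number of permutations must be >= 0")
    if n_workers < 1:
        raise ValueError("need at least one worker")
    base, extra = divmod(n_permutations, n_workers)
    specs = []
    start = 0
    for z in range(n_workers):
        size = base + (1 if z < extra else 0)
        specs.append(ChunkSpec(chunk_id=z + 1, start=start, size=size,
                               base_seed=int(seed)))
        start += size
    return specs


def run_chunk(dataset: Dataset, topfile_path, spec: ChunkSpec, out_path,
              params: StatParams | None = None,
              block_pairs: int = DEFAULT_BLOCK_PAIRS):
    """Execute one chunk's permutations and write its permfile.

    Counts start at zero; the observed-data contribution is added at merge
    time.  Raises :class:`DataFormatError` if the topfile is inconsistent
    with the dataset.
    """
    toplist, b_planned = load_topfile(topfile_path, dataset.n_snps)
    if spec.start + spec.size > b_planned:
        raise DataFormatError(
            f"chunk covers permutations up to {spec.start + spec.size} "
            f"but the topfile plans only {b_planned}"
        )
    provider = EngineProvider(dataset, params, spec.base_seed, block_pairs)
    if len(toplist) > provider.m:
        raise DataFormatError("topfile has more pairs than the dataset")
    counts = chunk_exceedance_counts(provider, toplist, spec.perm_indices)
    save_permfile(counts, spec.size, out_path)
    return out_path


def merge_chunks(permfile_paths, n_permutations: int, topfile_path, n_snps: int) -> MaxTResult:
    """Sum the chunk count vectors and finish step 4.

    Refuses to merge if the chunk sizes do not sum to B or any count vector
    disagrees with the topfile length.  Summation is exact integer
    arithmetic, so the result equals the sequential run bit for bit.
    """
    toplist, _ = load_topfile(topfile_path, n_snps)
    n = len(toplist)
    total = np.zeros(n, dtype=np.int64)
    covered = 0
    for path in permfile_paths:
        counts, chunk_size = load_permfile(path, expected_n=n)
        total += counts
        covered += chunk_size
    if covered != n_permutations:
        raise DataFormatError(
            f"chunks cover {covered} permutations, expected {n_permutations}"
        )
    a = 1 + total
    p = finalize_pvalues(a, n_permutations)
    return MaxTResult(pairs=toplist.pairs, t0=toplist.t0, a=a, p=p,
                      n_permutations=n_permutations)


def _run_chunk_task(dataset, topfile_path, spec, out_path, params, block_pairs):
    return run_chunk(dataset, topfile_path, spec, out_path, params, block_pairs)


def maxt_topn_parallel(dataset: Dataset, n: int, n_permutations: int, seed: int = 0,
                       params: StatParams | None = None, n_workers: int = 1,
                       workdir=None, block_pairs: int = DEFAULT_BLOCK_PAIRS) -> MaxTResult:
    """Run the full top-n procedure with the permutations split over a
    process pool; equals the sequential :func:`mbmdr.topn.maxt_topn`."""
    n = min(n, dataset.n_pairs)
    provider = EngineProvider(dataset, params, seed, block_pairs)
    toplist = _toplist_from_blocks(provider.real_blocks(), n, dataset.n_snps)
    with tempfile.TemporaryDirectory() if workdir is None else _keep(workdir) as wd:
        topfile = os.path.join(wd, "topfile.txt")
        save_topfile(toplist, n_permutations, topfile)
        specs = plan_chunks(n_permutations, n_workers, seed)
        outs = [os.path.join(wd, f"permutation_{s.chunk_id}.txt") for s in specs]
        if n_workers > 1:
            from joblib import Parallel, delayed

            Parallel(n_jobs=n_workers)(
                delayed(_run_chunk_task)(dataset, topfile, s, o, params, block_pairs)
                for s, o in zip(specs, outs)
            )
        else:
            for s, o in zip(specs, outs):
                run_chunk(dataset, topfile, s, o, params, block_pairs)
        return merge_chunks(outs, n_permutations, topfile, dataset.n_snps)


class _keep:
    """Context manager that passes through an existing directory."""

    def __init__(self, path):
        self.path = str(path)

    def __enter__(self):
        os.makedirs(self.path, exist_ok=True)
        return self.path

    def __exit__(self, *exc):
        return False
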