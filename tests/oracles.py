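"""Independent brute-force oracles used to validate the pipeline.

Each oracle re-derives an expected result from first principles (explicit
scans, per-bp bitmaps, exhaustive enumeration) without sharing code with
the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from ctcnt.types import DONOR, MISSING, RECIPIENT


def brute_force_runs(
    positions,
    states,
    genome_length: int,
    circular: bool,
    min_seed: int = 2,
    min_length: int = 500,
):
    """Enumerate maximal donor runs by an explicit per-site scan.

    Returns (start, end, length, n_support) tuples sorted by start;
    start > end denotes an origin-wrapping run on a circular genome.
    """
    sites = [(int(p), int(s)) for p, s in zip(positions, states) if s != MISSING]
    runs: list[list[int]] = []
    current: list[int] = []
    for pos, state in sites:
        if state == DONOR:
            current.append(pos)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    if (
        circular
        and len(runs) >= 2
        and sites
        and sites[0][1] == DONOR
        and sites[-1][1] == DONOR
    ):
        runs = [runs[-1] + runs[0]] + runs[1:-1]
    out = []
    for run in runs:
        start, end = run[0], run[-1]
        if start <= end:
            length = end - start + 1
        else:
            length = genome_length - start + 1 + end
        if len(run) >= min_seed and length > min_length:
            out.append((start, end, length, len(run)))
    return sorted(out)


def bitmap_union(clones_intervals, genome_length: int) -> int:
    """Union length via an explicit per-bp occupancy bitmap (wrap-aware)."""
    covered = np.zeros(genome_length, dtype=bool)
    for clone in clones_intervals:
        for s, e in clone:
            if s <= e:
                covered[s - 1 : e] = True
            else:
                covered[s - 1 :] = True
                covered[:e] = True
    return int(covered.sum())


def feasible_partitions(
    intervals: list[tuple[int, int]],
    max_gap: int,
    min_occupancy: float,
    max_span: int,
):
    """All partitions of sorted disjoint segments into contiguous feasible blocks.

    A block is feasible when every adjacent gap is < max_gap and every
    prefix of the block (the state of a growing tract at each append)
    keeps span < max_span and occupancy >= min_occupancy. Singleton
    blocks are always feasible.
    """
    n = len(intervals)

    def block_ok(block: list[tuple[int, int]]) -> bool:
        for k in range(1, len(block)):
            gap = block[k][0] - block[k - 1][1] - 1
            if gap >= max_gap:
                return False
            span = block[k][1] - block[0][0] + 1
            if span >= max_span:
                return False
            occupied = sum(e - s + 1 for s, e in block[: k + 1])
            if occupied / span < min_occupancy:
                return False
        return True

    results = []
    for cuts in itertools.product([False, True], repeat=n - 1):
        blocks, start = [], 0
        for i, cut in enumerate(cuts, start=1):
            if cut:
                blocks.append(intervals[start:i])
                start = i
        blocks.append(intervals[start:])
        if all(block_ok(b) for b in blocks):
            results.append(tuple(tuple(b) for b in blocks))
    return results


def point_coverage_mc(
    rng: np.random.Generator,
    n_trials: int,
    loci: np.ndarray,
    lam: float,
    mean_length: float,
    genome_length: int,
) -> np.ndarray:
    """Monte-Carlo coverage indicator of fixed loci by random segments.

    Draws, for each trial, Poisson(lam) segments with uniform starts on
    the circle and exponential lengths, and records whether each locus is
    covered — a direct simulation of the generative law, independent of
    the cohort simulator's code path.
    """
    loci = np.asarray(loci, dtype=np.int64)
    counts = rng.poisson(lam, size=n_trials)
    total = int(counts.sum())
    trial_idx = np.repeat(np.arange(n_trials), counts)
    starts = rng.integers(1, genome_length + 1, size=total)
    lengths = np.minimum(
        np.maximum(1, np.rint(rng.exponential(mean_length, size=total)).astype(np.int64)),
        genome_length,
    )
    ends = starts + lengths - 1  # may exceed G: wrapped
    covered = np.zeros((n_trials, loci.size), dtype=bool)
    for j, locus in enumerate(loci):
        hit = ((starts <= locus) & (locus <= ends)) | (ends > genome_length) & (
            locus <= ends - genome_length
        )
        col = np.zeros(n_trials, dtype=bool)
        np.logical_or.at(col, trial_idx, hit)
        covered[:, j] = col
    return covered
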