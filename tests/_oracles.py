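"""Independent brute-force oracles for the grouping heuristics.

Both pipeline heuristics partition a sorted sequence into contiguous groups
with a greedy single pass.  The oracles here instead *enumerate* every
contiguous partition whose groups individually satisfy the admissibility
rules, then select the partition whose group sizes are lexicographically
maximal (first group as long as possible, then the second, ...).  Because
admissible groups are closed under taking prefixes, that selection is what
a left-to-right greedy scan must produce — computed by exhaustive search
rather than by a scan.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence


def enumerate_partitions(n: int):
    """All ways to cut range(n) into contiguous non-empty runs."""
    if n == 0:
        yield []
        return
    for mask in itertools.product((False, True), repeat=n - 1):
        bounds = [0] + [i + 1 for i, cut in enumerate(mask) if cut] + [n]
        yield [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


def best_partition(n: int, valid: Callable[[int, int], bool]) -> list[tuple[int, int]]:
    """Lexicographically size-maximal partition into valid contiguous runs."""
    best = None
    best_sizes = None
    for parts in enumerate_partitions(n):
        if all(valid(i, j) for i, j in parts):
            sizes = tuple(j - i for i, j in parts)
            if best_sizes is None or sizes > best_sizes:
                best, best_sizes = parts, sizes
    assert best is not None, "the all-singletons partition is always valid"
    return best


# -- isotopic joining ------------------------------------------------------

def envelope_admissible(abundances: Sequence[float], first_mz: float,
                        crossover: float) -> bool:
    """Re-statement of the envelope shape rule for the oracle."""
    n = len(abundances)
    if n == 1:
        return True
    if first_mz <= crossover:
        maxima = [0]
    else:
        maxima = [0, 1]
    for m in maxima:
        ok = all(abundances[k] > abundances[k + 1] for k in range(m, n - 1))
        if m == 1:
            ok = ok and abundances[1] > abundances[0]
        if ok:
            return True
    return False


def join_oracle(peaks, params):
    """Partition of a peak list into isotopic groups, by enumeration."""
    def valid(i: int, j: int) -> bool:
        if j - i > params.max_isotopic_peaks:
            return False
        for k in range(i + 1, j):
            spacing = peaks[k].mz - peaks[k - 1].mz
            if not (1 - params.iso_delta) <= spacing <= (1 + params.iso_delta):
                return False
            if not envelope_admissible(
                [p.abundance for p in peaks[i:k + 1]],
                peaks[i].mz, params.crossover_mass,
            ):
                return False
        return True

    return [peaks[i:j] for i, j in best_partition(len(peaks), valid)]


# -- cross-spectrum grouping ----------------------------------------------

def group_oracle(peak_lists, delta):
    """Partition of the pooled, sorted peaks into m/z groups, by enumeration.

    A run of the sorted pool is a valid group when, walking it in order,
    each peak stays within ``delta`` of the mean of the peaks before it in
    the run and no spectrum contributes twice.
    """
    pool = sorted(
        ((peak, idx) for idx, peaks in enumerate(peak_lists) for peak in peaks),
        key=lambda t: (t[0].mz, t[1]),
    )

    def valid(i: int, j: int) -> bool:
        seen = set()
        mzs: list[float] = []
        for k in range(i, j):
            peak, idx = pool[k]
            if mzs:
                if idx in seen:
                    return False
                if abs(peak.mz - sum(mzs) / len(mzs)) > delta:
                    return False
            mzs.append(peak.mz)
            seen.add(idx)
        return True

    return [
        [(idx, peak) for peak, idx in pool[i:j]]
        for i, j in best_partition(len(pool), valid)
    ]
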