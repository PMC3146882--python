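"""Shared helpers: errors, interval arithmetic, rounding, RNG plumbing."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger("utrindel")


class DataError(Exception):
    """Malformed or inconsistent input data (exit code 3 in the CLI)."""


class ConfigError(Exception):
    """Invalid run configuration (exit code 2 in the CLI)."""


Interval = tuple[int, int]  # 0-based, half-open


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, non-overlapping list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total overlap length between two interval sets (need not be merged)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    total = i = j = 0
    while i < len(am) and j < len(bm):
        lo = max(am[i][0], bm[j][0])
        hi = min(am[i][1], bm[j][1])
        if hi > lo:
            total += hi - lo
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return total


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intervals_overlap(a: Sequence[Interval], b: Sequence[Interval]) -> bool:
    return intersect_length(a, b) > 0


def round_half_up(x: float) -> int:
    """Round to nearest integer with exact halves going up (not banker's)."""
    return int(np.floor(x + 0.5))


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent, reproducible generators derived from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
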