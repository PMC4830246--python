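"""Quality- and length-based read filtering.

Trimming follows the modified-Mott scheme used by common workbench
trimmers: each base contributes ``quality_limit - p_err`` where
``p_err = 10**(-Q/10)``, and the retained region is the contiguous
maximal-scoring subsequence.  Bases better than the limit contribute
positively, worse bases negatively; a read of uniformly bad bases trims
to nothing.  Ties are broken leftmost-then-longest so results are
deterministic.  This is the documented equivalent of the proprietary
workbench algorithm and is flagged as an approximation of it.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .io_formats import Read

__all__ = ["trim_read", "filter_reads", "trim_and_filter"]


def _mott_interval(scores: np.ndarray) -> tuple[int, int]:
    """Maximal-scoring contiguous interval [start, end) of ``scores``.

    Ties broken by leftmost start, then by longest extent.  Returns (0, 0)
    when every prefix sum is non-positive (empty result).
    """
    best_sum = 0.0
    best = (0, 0)
    run_sum = 0.0
    run_start = 0
    for i, s in enumerate(scores):
        # Reset only on strictly negative running sums: zero-sum prefixes may
        # extend an equal-scoring, longer interval, which the tie rule prefers.
        if run_sum < 0:
            run_sum = 0.0
            run_start = i
        run_sum += s
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, i + 1)
        elif run_sum == best_sum and best_sum > 0:
            # Equal score: prefer the earlier start, then the longer interval.
            if run_start < best[0] or (run_start == best[0] and i + 1 > best[1]):
                best = (run_start, i + 1)
    return best


def trim_read(read: Read, quality_limit: float = 0.05) -> Optional[Read]:
    """End-trim a read on quality; returns the trimmed read or None if empty.

    Requires per-base qualities.  The retained region is always a
    contiguous substring of the input, and trimming is idempotent.
    """
    if read.quals is None:
        raise ValueError(f"read {read.id}: trimming requested but no qualities present")
    if not 0 < quality_limit < 1:
        raise ValueError("quality_limit must be in (0, 1)")
    q = np.asarray(read.quals, dtype=float)
    scores = quality_limit - np.power(10.0, -q / 10.0)
    start, end = _mott_interval(scores)
    if end <= start:
        return None
    if (start, end) == (0, len(read)):
        return read
    return Read(
        id=read.id,
        seq=read.seq[start:end],
        quals=read.quals[start:end],
        truth=read.truth,
    )


def filter_reads(
    reads: Iterable[Read], min_length: int = 100, max_ambiguous: int = 2
) -> list[Read]:
    """Keep exactly the reads with length >= min_length and <= max_ambiguous N's.

    Both boundaries are inclusive (a 100 bp read with 2 N's is kept).
    """
    kept = []
    for r in reads:
        if len(r) >= min_length and r.seq.count("N") <= max_ambiguous:
            kept.append(r)
    return kept


def trim_and_filter(
    reads: Iterable[Read],
    quality_limit: float = 0.05,
    min_length: int = 100,
    max_ambiguous: int = 2,
) -> list[Read]:
    """Trim each read then apply the length/ambiguity filter."""
    trimmed = []
    for r in reads:
        t = trim_read(r, quality_limit) if r.quals is not None else r
        if t is not None:
            trimmed.append(t)
    return filter_reads(trimmed, min_length=min_length, max_ambiguous=max_ambiguous)
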