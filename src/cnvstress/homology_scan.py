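"""Detection of long high-identity stretches between two sequence windows.

The scan asks whether the two breakpoint-flank windows of a CNV contain a
contiguous alignment of at least ``min_len`` bases at greater than
``min_ident`` identity — the in-silico criterion for segmental homology
capable of supporting homologous recombination.  The algorithm is k-mer
seeded, ungapped (identity over a stretch is the stated criterion; indels
are out of scope), and scans both orientations of the second window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HomologyHit", "find_homologous_stretches", "reverse_complement"]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class HomologyHit:
    """One qualifying ungapped stretch between the two windows.

    Offsets are 0-based within each window (``offset_b`` always refers to the
    forward strand of window b); ``orientation`` is "+" for direct and "-"
    for reverse-complement matches.
    """

    offset_a: int
    offset_b: int
    length: int
    identity: float
    orientation: str = "+"


def _max_scoring(matches: np.ndarray, min_len: int, min_ident: float):
    """Maximum-scoring ungapped segment (match +1, mismatch -r with
    r = min_ident / (1 - min_ident), so any positive-score segment has
    identity > min_ident).  Returns (start, length, identity) if the best
    segment reaches ``min_len``, else None."""
    r = min_ident / (1.0 - min_ident)
    s = np.where(matches, 1.0, -r)
    best_sum = 0.0
    best = None
    run_sum = 0.0
    run_start = 0
    for i, v in enumerate(s):
        if run_sum <= 0:
            run_sum = v
            run_start = i
        else:
            run_sum += v
        if run_sum > best_sum:
            best_sum = run_sum
            best = (run_start, i + 1)
    if best is None or best[1] - best[0] < min_len:
        return None
    start, end = best
    return start, end - start, float(matches[start:end].mean())


def _longest_qualifying(matches: np.ndarray, min_len: int, min_ident: float):
    """Longest contiguous stretch with identity strictly > min_ident and
    length >= min_len.  Returns (start, length, identity) or None.

    Reduction: with t_i = match_i - min_ident, a stretch qualifies iff its
    t-sum is positive; the longest positive-sum subarray is found with the
    prefix-sum / suffix-max two-pointer sweep.
    """
    n = matches.size
    if n < min_len:
        return None
    t = matches.astype(float) - min_ident
    prefix = np.concatenate(([0.0], np.cumsum(t)))
    # rmax[j] = max(prefix[j:]) — if rmax[j] > prefix[i], some end >= j works
    rmax = np.maximum.accumulate(prefix[::-1])[::-1]
    best_len = 0
    best = None
    i = 0
    j = 0
    eps = 1e-9
    while j <= n and i <= n:
        if rmax[j] > prefix[i] + eps:
            if j - i > best_len:
                best_len = j - i
                best = (i, j)
            j += 1
        else:
            i += 1
            j = max(j, i)
    if best is None or best_len < min_len:
        return None
    start, end = best
    # the recorded j is the largest end with prefix[end] > prefix[start]
    # within the sweep; re-derive the exact end achieving the max length
    ends = np.flatnonzero(prefix[start + 1 :] > prefix[start] + eps) + start + 1
    end = int(ends.max())
    length = end - start
    if length < min_len:
        return None
    identity = float(matches[start:end].mean())
    return start, length, identity


def _scan_orientation(
    a: np.ndarray, b: np.ndarray, a_str: str, b_str: str,
    min_len: int, min_ident: float, seed_k: int,
) -> list[tuple[int, int, int, float]]:
    """Candidate diagonals from k-mer seeding, then per-diagonal extension.

    Returns (offset_a, offset_b, length, identity) tuples.
    """
    index: dict[str, list[int]] = {}
    for i in range(0, len(a_str) - seed_k + 1):
        index.setdefault(a_str[i : i + seed_k], []).append(i)
    diagonals: set[int] = set()
    for j in range(0, len(b_str) - seed_k + 1):
        for i in index.get(b_str[j : j + seed_k], ()):
            diagonals.add(i - j)
    hits = []
    for d in sorted(diagonals):
        # overlap of the two windows along diagonal d (a index = b index + d)
        b_lo = max(0, -d)
        b_hi = min(len(b_str), len(a_str) - d)
        if b_hi - b_lo < min_len:
            continue
        seg = a[b_lo + d : b_hi + d] == b[b_lo:b_hi]
        # prefer the highest-scoring segment (sharp boundaries); fall back to
        # the longest qualifying stretch so detection is never lost
        found = _max_scoring(seg, min_len, min_ident)
        if found is None:
            found = _longest_qualifying(seg, min_len, min_ident)
        if found is not None:
            start, length, identity = found
            hits.append((b_lo + d + start, b_lo + start, length, identity))
    return hits


def find_homologous_stretches(
    window_a: str,
    window_b: str,
    min_len: int = 1_000,
    min_ident: float = 0.90,
    seed_k: int = 16,
) -> list[HomologyHit]:
    """All maximal ungapped stretches of length >= ``min_len`` at identity
    > ``min_ident`` between the two windows, in both orientations."""
    if not window_a or not window_b:
        raise ValueError("windows must be non-empty")
    if min_len < seed_k:
        raise ValueError(f"min_len {min_len} < seed k-mer size {seed_k}: cannot seed")
    if min_len > len(window_a) or min_len > len(window_b):
        raise ValueError("min_len exceeds a window length")
    window_a = window_a.upper()
    window_b = window_b.upper()
    a = np.frombuffer(window_a.encode(), dtype=np.uint8)
    b = np.frombuffer(window_b.encode(), dtype=np.uint8)

    results: list[HomologyHit] = []
    for off_a, off_b, length, ident in _scan_orientation(
        a, b, window_a, window_b, min_len, min_ident, seed_k
    ):
        results.append(HomologyHit(off_a, off_b, length, ident, "+"))

    b_rc_str = reverse_complement(window_b)
    b_rc = np.frombuffer(b_rc_str.encode(), dtype=np.uint8)
    for off_a, off_rc, length, ident in _scan_orientation(
        a, b_rc, window_a, b_rc_str, min_len, min_ident, seed_k
    ):
        # map back to forward-strand coordinates of window b
        off_b = len(window_b) - (off_rc + length)
        results.append(HomologyHit(off_a, off_b, length, ident, "-"))
    results.sort(key=lambda h: (-h.length, h.offset_a, h.offset_b))
    return results
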