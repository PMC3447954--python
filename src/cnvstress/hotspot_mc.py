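"""CNV hotspot delineation and its Monte Carlo random-placement null.

The genome is tiled into non-overlapping windows (default 10 kb); every
window's distinct-CNV overlap count is computed, and maximal runs of
consecutive windows with at least ``min_count`` overlapping CNVs (default 5)
are merged into hotspot regions.  The null asks how often intervals of the
observed sizes, placed uniformly at random on the genome, produce at least
one such region; the empirical probability over (default) 10,000 iterations
is the hotspot p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import CnvCall, Genome

__all__ = [
    "HotspotRegion",
    "McNullResult",
    "window_coverage",
    "find_hotspots",
    "assert_distinct_boundaries",
    "hotspot_null_pvalue",
]


@dataclass(frozen=True)
class HotspotRegion:
    chrom: str
    start: int
    end: int
    cnv_count: int
    clone_frequency: float
    cnvs_per_treated_clone: float = float("nan")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hotspot region must be non-empty")

    def overlaps(self, cnv: CnvCall) -> bool:
        return cnv.chrom == self.chrom and cnv.start < self.end and self.start < cnv.end


@dataclass(frozen=True)
class McNullResult:
    n_iter: int
    min_count: int
    hits: int
    p_empirical: float
    seed: int


def window_coverage(
    cnvs: Sequence[CnvCall], genome: Genome, window: int = 10_000
) -> dict[str, np.ndarray]:
    """Distinct-CNV overlap count for each tiled window of each chromosome.

    Windows are half-open ``[i*window, (i+1)*window)``; a CNV contributes 1 to
    every window it intersects (half-open intersection).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows = {
        c: -(-genome.chrom_lengths[c] // window) for c in genome.chrom_names
    }
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in n_windows.items()}
    for cnv in cnvs:
        if cnv.chrom not in diffs:
            raise ValueError(f"CNV on unknown chromosome {cnv.chrom!r}")
        first = cnv.start // window
        last = (cnv.end - 1) // window
        diffs[cnv.chrom][first] += 1
        diffs[cnv.chrom][last + 1] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def find_hotspots(
    cnvs: Sequence[CnvCall],
    genome: Genome,
    window: int = 10_000,
    min_count: int = 5,
    treated_clones: Iterable[str] | None = None,
) -> list[HotspotRegion]:
    """Maximal runs of consecutive windows with >= ``min_count`` overlapping
    CNVs, merged into regions.

    ``cnv_count`` is the number of distinct CNVs overlapping the merged
    region.  When ``treated_clones`` is given, ``clone_frequency`` is the
    fraction of those clones carrying at least one overlapping CNV, and
    ``cnvs_per_treated_clone`` is cnv_count divided by the roster size.
    """
    coverage = window_coverage(cnvs, genome, window)
    treated = list(treated_clones) if treated_clones is not None else None
    regions: list[HotspotRegion] = []
    for chrom in genome.chrom_names:
        counts = coverage[chrom]
        above = counts >= min_count
        if not above.any():
            continue
        # run boundaries of the boolean mask
        padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for ws, we in zip(starts, ends):
            start = int(ws) * window
            end = min(int(we) * window, genome.chrom_lengths[chrom])
            members = [c for c in cnvs if c.overlaps(chrom, start, end)]
            clone_freq = float("nan")
            per_clone = float("nan")
            if treated is not None and treated:
                carriers = {c.clone_id for c in members} & set(treated)
                clone_freq = len(carriers) / len(treated)
                per_clone = len(members) / len(treated)
            regions.append(
                HotspotRegion(chrom, start, end, len(members), clone_freq, per_clone)
            )
    return regions


def assert_distinct_boundaries(
    cnvs: Sequence[CnvCall],
) -> tuple[bool, list[tuple[CnvCall, CnvCall]]]:
    """True iff no two CNVs share both start and end (i.e. each arose
    independently); offending pairs returned alongside."""
    seen: dict[tuple[str, int, int], CnvCall] = {}
    offending: list[tuple[CnvCall, CnvCall]] = []
    for c in cnvs:
        key = (c.chrom, c.start, c.end)
        if key in seen:
            offending.append((seen[key], c))
        else:
            seen[key] = c
    return not offending, offending


def hotspot_null_pvalue(
    sizes: Sequence[int],
    genome: Genome,
    n_iter: int = 10_000,
    window: int = 10_000,
    min_count: int = 5,
    seed: int = 0,
    per_chromosome: Sequence[str] | None = None,
) -> McNullResult:
    """Monte Carlo null for hotspot existence.

    Each iteration places intervals of the observed ``sizes`` uniformly at
    random — chromosome chosen with probability proportional to length among
    chromosomes long enough, start uniform over valid positions (or, with
    ``per_chromosome``, each interval is kept on its observed chromosome) —
    and scores whether any window accumulates >= ``min_count`` distinct
    overlapping intervals.  ``p_empirical`` is the qualifying fraction.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    chroms = list(genome.chrom_names)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    if sizes.max() > lengths.max():
        raise ValueError("an interval size exceeds every chromosome")
    # cumulative window offsets give a single global window index space
    n_win = -(-lengths // window)
    win_offset = np.concatenate(([0], np.cumsum(n_win)))

    rng = np.random.default_rng(seed)
    n = sizes.size
    if per_chromosome is not None:
        if len(per_chromosome) != len(sizes):
            raise ValueError("per_chromosome must parallel sizes")
        fixed_ci = np.array([chroms.index(c) for c in per_chromosome])

    # eligibility depends only on the interval size; group sizes into
    # eligibility classes once so chromosome draws vectorise over iterations
    classes: dict[tuple[int, ...], np.ndarray] = {}
    for idx, s in enumerate(sizes):
        key = tuple(np.flatnonzero(lengths >= s))
        classes.setdefault(key, []).append(idx)  # type: ignore[arg-type]
    class_items = [
        (np.array(eligible), np.asarray(members)) for eligible, members in classes.items()
    ]

    hits = 0
    chunk = 2_000
    for lo in range(0, n_iter, chunk):
        m = min(chunk, n_iter - lo)
        ci = np.empty((m, n), dtype=np.int64)
        if per_chromosome is None:
            for eligible, members in class_items:
                p = lengths[eligible].astype(float)
                p /= p.sum()
                draw = rng.choice(eligible.size, size=(m, members.size), p=p)
                ci[:, members] = eligible[draw]
        else:
            ci[:] = fixed_ci
        starts = (rng.random((m, n)) * (lengths[ci] - sizes[None, :] + 1)).astype(
            np.int64
        )
        first = win_offset[ci] + starts // window
        last = win_offset[ci] + (starts + sizes[None, :] - 1) // window
        # max window depth via endpoint sweep over snapped window ranges;
        # at equal coordinates closings sort before openings (even < odd key)
        keys = np.concatenate((first * 2 + 1, (last + 1) * 2), axis=1)
        order = np.argsort(keys, axis=1, kind="stable")
        delta = np.where(order < n, 1, -1)
        depth = np.cumsum(delta, axis=1)
        hits += int((depth.max(axis=1) >= min_count).sum())
    return McNullResult(n_iter, min_count, hits, hits / n_iter, seed)
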