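"""Breakpoint-junction calling, microhomology statistics and the
random-usage null, and complex/chromothripsis-like event grouping.

A junction-spanning read is aligned to its two flank windows by maximal
exact prefix/suffix extension.  If the extensions overlap, the overlapped
read bases are the junction microhomology (the deletion placement is
ambiguous over that tract; the leftmost placement is reported).  A gap
between the extensions is an untemplated insertion; no overlap and no gap is
a blunt junction.

The null model for microhomology under random sequence: extension on either
side of the junction point is geometric with per-base match probability
``m = sum(p_i^2)``, and the two directions are independent, giving

    P(K = k) = (k + 1) * (1 - m)^2 * m^k

(the ``k+1`` counts the ways k matched bases split around the junction).
Its mean is ``2m / (1 - m)`` — 2/3 bp for uniform base composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_io import CnvCall, Genome, JunctionRecord
from .homology_scan import find_homologous_stretches

__all__ = [
    "MhNullPmf",
    "ComplexEvent",
    "MicrohomologySummary",
    "NullComparison",
    "FlankHomologyResult",
    "call_junction",
    "summarize_microhomology",
    "microhomology_null_pmf",
    "simulate_microhomology_null",
    "compare_to_null",
    "group_complex_events",
    "flank_homology_fraction",
]


# ---------------------------------------------------------------------------
# junction calling
# ---------------------------------------------------------------------------

def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def call_junction(
    read: str,
    left_flank: str,
    left_flank_start: int,
    right_flank: str,
    right_flank_start: int,
    min_anchor: int = 20,
    clone_id: str = "",
    genotype: str = "WT",
    cnv_type: str = "deletion",
    chrom: str = "",
) -> JunctionRecord:
    """Call breakpoints, microhomology and insertion from a junction read.

    ``left_flank`` is reference sequence starting at genomic position
    ``left_flank_start`` and extending past the expected left breakpoint;
    ``right_flank`` likewise spans the right breakpoint.  Breakpoints are
    0-based: ``left_bp`` is the first deleted base, ``right_bp`` the first
    retained base on the right, at the leftmost consistent placement.
    """
    read = read.upper()
    left_flank = left_flank.upper()
    right_flank = right_flank.upper()
    if len(read) < 2 * min_anchor:
        raise ValueError("read shorter than the two anchors")
    p = _common_prefix(read, left_flank)
    s = _common_prefix(read[::-1], right_flank[::-1])
    if p < min_anchor or s < min_anchor:
        raise ValueError(
            f"anchor match too short (prefix {p}, suffix {s}; need {min_anchor})"
        )
    if left_flank.count(read[:min_anchor]) != 1:
        raise ValueError("left anchor ambiguous: multiple placements")
    if right_flank.count(read[-min_anchor:]) != 1:
        raise ValueError("right anchor ambiguous: multiple placements")

    overlap = p + s - len(read)
    junction_read_pos = len(read) - s  # leftmost placement
    if overlap > 0:
        homology = read[junction_read_pos : junction_read_pos + overlap]
        insertion = ""
        hl = overlap
        left_bp = left_flank_start + junction_read_pos
    elif overlap < 0:
        homology = ""
        insertion = read[p : len(read) - s]
        hl = 0
        left_bp = left_flank_start + p
    else:
        homology = ""
        insertion = ""
        hl = 0
        left_bp = left_flank_start + p
    right_bp = right_flank_start + len(right_flank) - s
    return JunctionRecord(
        clone_id=clone_id,
        genotype=genotype,
        cnv_type=cnv_type,
        chrom=chrom,
        left_bp=left_bp,
        right_bp=right_bp,
        homology_len=hl,
        homology_seq=homology,
        insertion_seq=insertion,
    )


# ---------------------------------------------------------------------------
# microhomology statistics and null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrohomologySummary:
    n: int
    mean: float
    median: float
    max: int
    histogram: dict[int, int]


def summarize_microhomology(
    records: Iterable[JunctionRecord], exclude_insertions: bool = True
) -> MicrohomologySummary:
    """Mean/median/max homology length and the length histogram.

    Insertion junctions are excluded by default: their homology length is 0
    by definition, and the convention keeps the homology statistics a
    property of end-alignment rather than of untemplated synthesis.
    """
    lens = [
        r.homology_len
        for r in records
        if not (exclude_insertions and r.insertion_seq)
    ]
    if not lens:
        raise ValueError("no junctions left after filtering")
    arr = np.asarray(lens)
    hist = {int(k): int((arr == k).sum()) for k in np.unique(arr)}
    return MicrohomologySummary(
        n=len(lens),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        max=int(arr.max()),
        histogram=hist,
    )


@dataclass(frozen=True)
class MhNullPmf:
    """Microhomology-length pmf under random sequence usage."""

    match_prob: float
    pmf: np.ndarray  # P(K = k) for k = 0..k_max
    tail: float  # P(K > k_max)

    @property
    def k_max(self) -> int:
        return len(self.pmf) - 1

    @property
    def mean(self) -> float:
        m = self.match_prob
        return 2.0 * m / (1.0 - m)


def microhomology_null_pmf(
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    k_max: int = 10,
) -> MhNullPmf:
    """Analytic null pmf ``(k+1)(1-m)^2 m^k`` with ``m = sum(p_i^2)``."""
    comp = np.asarray(base_composition, dtype=float)
    if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("base composition must be probabilities summing to 1")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    m = float((comp**2).sum())
    if m >= 1.0 - 1e-12:
        raise ValueError("degenerate composition: every base pair matches")
    k = np.arange(k_max + 1)
    pmf = (k + 1) * (1.0 - m) ** 2 * m**k
    # P(K > k_max) for K = sum of two geometrics: closed-form complement
    tail = 1.0 - float(pmf.sum())
    return MhNullPmf(m, pmf, tail)


def simulate_microhomology_null(
    n_pairs: int,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    max_extension: int = 64,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Monte Carlo homology lengths at junctions of random flank pairs.

    For each pair, two independent random sequences are compared outward from
    the junction point in both directions; the homology length is the sum of
    the two maximal exact extensions.  Returns the array of lengths.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = np.asarray(base_composition, dtype=float)
    # matches are Bernoulli(m) i.i.d. per offset; simulate match indicators
    m = float((comp**2).sum())
    def _first_mismatch(matches: np.ndarray) -> np.ndarray:
        # length of leading True run per row
        any_false = ~matches.all(axis=1)
        first = np.where(any_false, np.argmin(matches, axis=1), matches.shape[1])
        return first
    right = _first_mismatch(rng.random((n_pairs, max_extension)) < m)
    left = _first_mismatch(rng.random((n_pairs, max_extension)) < m)
    return right + left


@dataclass(frozen=True)
class NullComparison:
    observed_mean: float
    null_mean: float
    right_shifted: bool


def compare_to_null(
    records: Iterable[JunctionRecord],
    null: MhNullPmf | None = None,
    exclude_insertions: bool = True,
) -> NullComparison:
    """Flag whether observed microhomology is right-shifted versus the null."""
    null = microhomology_null_pmf() if null is None else null
    summary = summarize_microhomology(records, exclude_insertions)
    return NullComparison(
        observed_mean=summary.mean,
        null_mean=null.mean,
        right_shifted=summary.mean > null.mean,
    )


# ---------------------------------------------------------------------------
# complex / chromothripsis-like event grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexEvent:
    clone_id: str
    chrom: str
    junctions: tuple[JunctionRecord, ...]
    span: int
    event_class: str  # "complex" | "chromothripsis_like"

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


def group_complex_events(
    records: Sequence[JunctionRecord],
    max_span: int = 5_000_000,
    chromothripsis_min_junctions: int = 8,
) -> list[ComplexEvent]:
    """Cluster junctions of the same clone and chromosome by breakpoint
    proximity (single linkage, gap <= ``max_span``); clusters of >= 2 are
    complex events, and clusters with >= ``chromothripsis_min_junctions``
    deletion-type members are flagged chromothripsis-like."""
    groups: dict[tuple[str, str], list[JunctionRecord]] = {}
    for r in records:
        groups.setdefault((r.clone_id, r.chrom), []).append(r)

    events: list[ComplexEvent] = []
    for (clone, chrom), members in sorted(groups.items()):
        members = sorted(members, key=lambda r: (min(r.left_bp, r.right_bp),
                                                 max(r.left_bp, r.right_bp)))
        cluster: list[JunctionRecord] = []
        cluster_max = -1

        def _flush() -> None:
            if len(cluster) < 2:
                return
            lo = min(min(r.left_bp, r.right_bp) for r in cluster)
            hi = max(max(r.left_bp, r.right_bp) for r in cluster)
            n_del = sum(1 for r in cluster if r.cnv_type == "deletion")
            klass = (
                "chromothripsis_like"
                if n_del >= chromothripsis_min_junctions
                else "complex"
            )
            events.append(ComplexEvent(clone, chrom, tuple(cluster), hi - lo, klass))

        for r in members:
            lo = min(r.left_bp, r.right_bp)
            if cluster and lo - cluster_max > max_span:
                _flush()
                cluster = []
                cluster_max = -1
            cluster.append(r)
            cluster_max = max(cluster_max, max(r.left_bp, r.right_bp))
        _flush()
    return events


# ---------------------------------------------------------------------------
# breakpoint-flank homology fraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankHomologyResult:
    fraction: float
    ci_low: float
    ci_high: float
    flags: tuple[bool, ...]


def flank_homology_fraction(
    cnvs: Sequence[CnvCall],
    genome: Genome,
    window: int = 10_000,
    min_len: int = 1_000,
    min_ident: float = 0.90,
    seed_k: int = 16,
) -> FlankHomologyResult:
    """Fraction of CNVs whose two breakpoint-flank windows share a stretch of
    >= ``min_len`` bases at > ``min_ident`` identity (a proxy for
    recombination-capable segmental homology), with an exact binomial CI."""
    if min_len > window:
        raise ValueError("min_len larger than the flank window")
    if genome.sequence is None:
        raise ValueError("genome sequence required")
    flags: list[bool] = []
    half = window // 2
    for cnv in cnvs:
        chrom_len = genome.chrom_lengths[cnv.chrom]
        a_lo, a_hi = max(0, cnv.start - half), min(chrom_len, cnv.start + half)
        b_lo, b_hi = max(0, cnv.end - half), min(chrom_len, cnv.end + half)
        if a_hi - a_lo < window or b_hi - b_lo < window:
            import warnings

            warnings.warn(
                f"flank window clipped at chromosome bound for {cnv.clone_id}",
                stacklevel=2,
            )
        win_a = genome.fetch(cnv.chrom, a_lo, a_hi)
        win_b = genome.fetch(cnv.chrom, b_lo, b_hi)
        hits = find_homologous_stretches(
            win_a, win_b, min_len=min_len, min_ident=min_ident, seed_k=seed_k
        )
        flags.append(bool(hits))
    k = sum(flags)
    n = len(flags)
    if n == 0:
        raise ValueError("no CNVs supplied")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return FlankHomologyResult(k / n, lo, hi, tuple(flags))
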