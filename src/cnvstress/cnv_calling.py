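"""Segmentation of probe-level log2-ratio tracks and CNV calling.

A documented least-squares binary segmentation stands in for the array
vendor's proprietary segmentation: segments are split recursively at the
change-point with the largest residual-sum-of-squares reduction, and a split
is kept only if that reduction exceeds ``penalty`` and both children keep at
least ``min_probes`` probes.  Segment boundaries fall midway between
adjacent probes.

By default the penalty is set adaptively to ``2 * sigma^2 * ln(n)`` (a
BIC-like cost), with ``sigma`` estimated robustly from successive probe
differences so that change points do not inflate it.  At ~3.6 kb probe
spacing and probe noise sd ~0.2 this detects events >= 20 kb routinely
while flat tracks produce no calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import CnvCall, ProbeTrack

__all__ = ["SegmentCall", "segment_track", "call_cnvs", "estimate_noise_sd"]

DEFAULT_LOSS_THRESHOLD = -0.5
DEFAULT_GAIN_THRESHOLD = 0.3


def estimate_noise_sd(log2r: np.ndarray) -> float:
    """Robust probe-noise sd from the median absolute successive difference
    (for Gaussian noise, median |y[i+1]-y[i]| = 0.6745 * sqrt(2) * sigma)."""
    y = np.asarray(log2r, dtype=float)
    if y.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(y))) / (0.6745 * np.sqrt(2.0)))


@dataclass(frozen=True)
class SegmentCall:
    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log2r: float
    state: str  # "loss" | "neutral" | "gain"

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("a segment must contain at least one probe")
        if self.state not in ("loss", "neutral", "gain"):
            raise ValueError(f"unknown state {self.state!r}")


def _best_split(csum: np.ndarray, csum2: np.ndarray, lo: int, hi: int, min_probes: int):
    """Best single change point in probes [lo, hi); returns (gain, t) with the
    RSS reduction of splitting before probe index t."""
    n = hi - lo
    if n < 2 * min_probes:
        return 0.0, -1
    total = csum[hi] - csum[lo]
    total2 = csum2[hi] - csum2[lo]
    cost_parent = total2 - total * total / n
    t = np.arange(lo + min_probes, hi - min_probes + 1)
    left_n = t - lo
    right_n = hi - t
    left_sum = csum[t] - csum[lo]
    right_sum = total - left_sum
    left2 = csum2[t] - csum2[lo]
    right2 = total2 - left2
    cost_children = (
        left2 - left_sum**2 / left_n + right2 - right_sum**2 / right_n
    )
    gains = cost_parent - cost_children
    i = int(np.argmax(gains))
    return float(gains[i]), int(t[i])


def segment_track(
    track: ProbeTrack,
    penalty: float | None = None,
    min_probes: int = 2,
) -> list[SegmentCall]:
    """Recursive least-squares binary segmentation of one probe track.

    ``penalty=None`` selects ``2 * sigma_hat^2 * ln(n)`` with the robust
    noise estimate of :func:`estimate_noise_sd`.
    """
    n = track.n_probes
    if n == 0:
        raise ValueError("empty probe track")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    y = track.log2r
    pos = track.positions
    if penalty is None:
        penalty = max(2.0 * estimate_noise_sd(y) ** 2 * np.log(max(n, 2)), 1e-9)
    csum = np.concatenate(([0.0], np.cumsum(y)))
    csum2 = np.concatenate(([0.0], np.cumsum(y * y)))

    breakpoints: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        gain, t = _best_split(csum, csum2, lo, hi, min_probes)
        if t >= 0 and gain > penalty:
            breakpoints.append(t)
            stack.append((lo, t))
            stack.append((t, hi))
    bounds = [0] + sorted(breakpoints) + [n]

    # boundary polish: each internal boundary is re-optimised between its
    # neighbouring boundaries (no segments created or removed); corrects
    # off-by-one placements inherited from higher-level splits
    for _ in range(5):
        moved = False
        for i in range(1, len(bounds) - 1):
            lo, hi = bounds[i - 1], bounds[i + 1]
            _, t = _best_split(csum, csum2, lo, hi, 1)
            if t > 0 and t != bounds[i]:
                bounds[i] = t
                moved = True
        if not moved:
            break

    segments: list[SegmentCall] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        start = int(pos[lo]) if lo == 0 else int((pos[lo - 1] + pos[lo] + 1) // 2)
        end = int(pos[hi - 1]) + 1 if hi == n else int((pos[hi - 1] + pos[hi] + 1) // 2)
        mean = float((csum[hi] - csum[lo]) / (hi - lo))
        segments.append(SegmentCall(track.chrom, start, end, hi - lo, mean, "neutral"))
    return segments


def call_cnvs(
    segments: Sequence[SegmentCall],
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    min_size: int = 1_000,
    clone_id: str = "",
    genotype: str = "WT",
    aph_dose: float = 0.0,
) -> list[CnvCall]:
    """Threshold segment means into loss/neutral/gain and emit CNV calls.

    Adjacent same-state non-neutral segments are merged; calls smaller than
    ``min_size`` are dropped.
    """
    if loss_threshold >= gain_threshold:
        raise ValueError("loss threshold must be below the gain threshold")

    def _state(mean: float) -> str:
        if mean <= loss_threshold:
            return "loss"
        if mean >= gain_threshold:
            return "gain"
        return "neutral"

    calls: list[CnvCall] = []
    run: list[SegmentCall] = []
    run_state = "neutral"

    def _flush() -> None:
        if not run or run_state == "neutral":
            return
        start, end = run[0].start, run[-1].end
        if end - start >= min_size:
            calls.append(
                CnvCall(
                    clone_id=clone_id,
                    genotype=genotype,
                    aph_dose=aph_dose,
                    chrom=run[0].chrom,
                    start=start,
                    end=end,
                    cnv_type="deletion" if run_state == "loss" else "duplication",
                )
            )

    for seg in segments:
        state = _state(seg.mean_log2r)
        if state == run_state and run and seg.chrom == run[-1].chrom:
            run.append(seg)
        else:
            _flush()
            run = [seg]
            run_state = state
    _flush()
    return calls
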