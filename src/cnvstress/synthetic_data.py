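"""Synthetic clones, CNV cohorts, probe tracks, reference sequence and
junction-spanning reads.

Two generators live here:

* a *stochastic* simulator (:class:`SimulationConfig` plus the ``simulate_*``
  functions) producing Poisson clone counts, hotspot-mixture CNV placement,
  log-normal sizes, noisy aCGH-like probe tracks and junction reads with
  planted microhomology — every downstream stage can be exercised against
  known truth;
* a *deterministic* reference cohort (:func:`synthetic_cohort`) that rebuilds,
  from its printed marginal statistics, a stand-in for the study's per-CNV
  supplementary list: 143 wild-type and 234 Xrcc4-null de novo CNVs over 85
  clones (55 aphidicolin-treated), 13 CNV hotspots with the observed
  per-region counts, deletion fractions of 90.9%/83.3% (98.5% inside
  hotspots), and median sizes of exactly 59 kb (WT), 63 kb (Xrcc4-null),
  89.8 kb (hotspot) and 46.3 kb (non-hotspot).  The original per-CNV table is
  not public, so this catalog is synthetic; only its cohort-level statistics
  are faithful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    CloneSummary,
    CnvCall,
    Genome,
    JunctionRecord,
    ProbeTrack,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimulatedJunction",
    "MOUSE_HOTSPOT_CATALOG",
    "simulate_clone_counts",
    "place_cnvs",
    "simulate_probe_track",
    "simulate_reference",
    "simulate_junction_sequence",
    "simulate_truth_set",
    "synthetic_cohort",
]

BASES = "ACGT"

#: CNV hotspot regions observed in aphidicolin-treated mouse ES cells
#: (chrom, start, end, associated gene, observed CNV count).  Used both as
#: the default hotspot mixture of the simulator and by the reference cohort.
MOUSE_HOTSPOT_CATALOG: tuple[tuple[str, int, int, str, int], ...] = (
    ("chr2", 67_227_959, 67_873_163, "Xirp2", 15),
    ("chr2", 140_550_331, 141_557_233, "Macrod2", 9),
    ("chr2", 161_777_721, 162_229_484, "Ptprt", 8),
    ("chr5", 4_957_925, 5_164_013, "Cdk14", 5),
    ("chr5", 132_196_231, 132_935_046, "Auts2", 32),
    ("chr6", 21_333_255, 21_447_908, "Kcnd2", 6),
    ("chr8", 117_160_242, 117_608_147, "Wwox", 14),
    ("chr12", 35_023_371, 35_455_164, "Hdac9", 10),
    ("chr12", 38_642_601, 39_183_139, "Dgkb", 5),
    ("chr14", 10_761_778, 10_964_749, "Fhit", 5),
    ("chr14", 117_568_872, 117_958_464, "Gpc6", 10),
    ("chr17", 50_995_219, 51_146_542, "Tbc1d5", 7),
    ("chr17", 90_801_260, 91_269_143, "Nrxn1", 7),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the stochastic cohort simulator.

    Default per-clone CNV rates are the four observed arm frequencies
    (untreated/treated x wild-type/Xrcc4-null); per-arm clone counts were not
    published, so the default of 20 clones per arm is a free choice at the
    scale of one experiment.
    """

    #: (genotype, aphidicolin dose uM) -> number of clones in the arm
    n_clones: Mapping[tuple[str, float], int] = field(
        default_factory=lambda: {
            ("WT", 0.0): 20,
            ("WT", 0.6): 20,
            ("Xrcc4_null", 0.0): 20,
            ("Xrcc4_null", 0.6): 20,
        }
    )
    #: (genotype, dose) -> Poisson CNV rate per clone
    cnv_rate: Mapping[tuple[str, float], float] = field(
        default_factory=lambda: {
            ("WT", 0.0): 0.43,
            ("WT", 0.6): 5.19,
            ("Xrcc4_null", 0.0): 1.31,
            ("Xrcc4_null", 0.6): 7.34,
        }
    )
    #: genotype -> probability a CNV is a deletion (observed 130/143, 195/234)
    deletion_prob: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.909, "Xrcc4_null": 0.833}
    )
    size_median_bp: float = 60_000.0
    size_log_sd: float = 1.0
    min_size_bp: int = 1_000
    #: (chrom, start, end, weight); defaults to the observed hotspot catalog
    hotspot_regions: tuple[tuple[str, int, int, float], ...] = field(
        default_factory=lambda: tuple(
            (c, s, e, float(n)) for c, s, e, _, n in MOUSE_HOTSPOT_CATALOG
        )
    )
    #: fraction of CNVs routed into hotspot regions (observed ~0.35)
    hotspot_mass: float = 0.35
    probe_spacing: int = 3_600
    probe_noise_sd: float = 0.2
    #: expected log2 ratio over a clonal hemizygous deletion, log2(1/2)
    log2r_shift_deletion: float = -1.0
    #: expected log2 ratio over a clonal single-copy gain, log2(3/2)
    log2r_shift_duplication: float = 0.585
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, lam in self.cnv_rate.items():
            if lam < 0:
                raise ValueError(f"negative CNV rate for arm {arm}")
        for g, p in self.deletion_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"deletion_prob out of [0,1] for {g}")
        if not 0.0 <= self.hotspot_mass <= 1.0:
            raise ValueError("hotspot_mass must be in [0,1]")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.size != 4 or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


@dataclass(frozen=True)
class TruthSet:
    cnvs: tuple[CnvCall, ...]
    junctions: tuple[JunctionRecord, ...]
    clones: tuple[CloneSummary, ...]

    def __post_init__(self) -> None:
        clone_ids = {c.clone_id for c in self.clones}
        for cnv in self.cnvs:
            if cnv.clone_id not in clone_ids:
                raise ValueError(f"CNV clone {cnv.clone_id!r} not in clone table")


# ---------------------------------------------------------------------------
# stochastic simulator
# ---------------------------------------------------------------------------

def simulate_clone_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CloneSummary]:
    """Draw per-clone CNV counts, independently Poisson within each arm."""
    rng = config.rng(1) if rng is None else rng
    clones: list[CloneSummary] = []
    for (genotype, dose), n in sorted(config.n_clones.items()):
        lam = config.cnv_rate.get((genotype, dose), 0.0)
        counts = rng.poisson(lam, size=n)
        tag = f"{'W' if genotype == 'WT' else 'X'}{dose:g}"
        for i, k in enumerate(counts):
            clones.append(
                CloneSummary(f"{tag}-{i + 1:03d}", genotype, dose, int(k))
            )
    return clones


def _sample_size(config: SimulationConfig, rng: np.random.Generator, max_bp: int) -> int:
    mu = np.log(config.size_median_bp)
    for _ in range(1000):
        size = int(round(np.exp(rng.normal(mu, config.size_log_sd))))
        if config.min_size_bp <= size <= max_bp:
            return size
    # heavy truncation: fall back to clamping
    return int(min(max_bp, max(config.min_size_bp, config.size_median_bp)))


def place_cnvs(
    clone_summaries: Sequence[CloneSummary],
    genome: Genome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[CnvCall]:
    """Place each clone's CNVs on the genome.

    With probability ``hotspot_mass`` a CNV is drawn to overlap a
    weight-sampled hotspot region; otherwise it is placed uniformly
    (chromosome chosen proportional to length among those long enough).
    Sizes are log-normal, truncated to the chromosome; all boundaries are
    distinct across the cohort.
    """
    rng = config.rng(2) if rng is None else rng
    hot = [h for h in config.hotspot_regions if h[0] in genome]
    hot_w = np.array([h[3] for h in hot], dtype=float)
    if hot_w.size:
        hot_w = hot_w / hot_w.sum()
    chroms = list(genome.chrom_names)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    max_len = int(lengths.max())
    if max_len < config.min_size_bp:
        raise ValueError("every chromosome is shorter than the minimum CNV size")

    used_starts: set[tuple[str, int]] = set()
    calls: list[CnvCall] = []
    for clone in clone_summaries:
        p_del = config.deletion_prob.get(clone.genotype, 0.85)
        for _ in range(clone.n_cnvs):
            use_hotspot = bool(hot) and rng.random() < config.hotspot_mass
            for _attempt in range(1000):
                if use_hotspot:
                    j = rng.choice(len(hot), p=hot_w)
                    chrom, rs, re_, _w = hot[j]
                    chrom_len = genome.chrom_lengths[chrom]
                    size = _sample_size(config, rng, chrom_len)
                    anchor = int(rng.integers(rs, re_))
                    start = anchor - int(rng.integers(0, size))
                    start = max(0, min(start, chrom_len - size))
                else:
                    ok = lengths >= config.min_size_bp
                    ci = rng.choice(len(chroms), p=(lengths * ok) / (lengths * ok).sum())
                    chrom = chroms[ci]
                    chrom_len = genome.chrom_lengths[chrom]
                    size = _sample_size(config, rng, chrom_len)
                    start = int(rng.integers(0, chrom_len - size + 1))
                if (chrom, start) not in used_starts:
                    used_starts.add((chrom, start))
                    break
            cnv_type = "deletion" if rng.random() < p_del else "duplication"
            calls.append(
                CnvCall(
                    clone_id=clone.clone_id,
                    genotype=clone.genotype,
                    aph_dose=clone.aph_dose,
                    chrom=chrom,
                    start=start,
                    end=start + size,
                    cnv_type=cnv_type,
                )
            )
    return calls


def simulate_probe_track(
    cnvs: Sequence[CnvCall],
    genome: Genome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    chroms: Sequence[str] | None = None,
) -> dict[str, ProbeTrack]:
    """aCGH-like probe tracks for one clone: baseline 0, shifted means over
    its CNVs, Gaussian noise.  Overlapping CNVs are merged with a warning."""
    rng = config.rng(3) if rng is None else rng
    chroms = list(genome.chrom_names) if chroms is None else list(chroms)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
    for c in cnvs:
        if c.chrom not in by_chrom:
            continue
        shift = (
            config.log2r_shift_deletion
            if c.cnv_type == "deletion"
            else config.log2r_shift_duplication
        )
        by_chrom[c.chrom].append((c.start, c.end, shift))

    tracks: dict[str, ProbeTrack] = {}
    for chrom in chroms:
        length = genome.chrom_lengths[chrom]
        if config.probe_spacing > length:
            raise ValueError(f"probe spacing exceeds length of {chrom}")
        positions = np.arange(config.probe_spacing // 2, length, config.probe_spacing)
        values = np.zeros(positions.size, dtype=float)
        intervals = sorted(by_chrom[chrom])
        merged: list[tuple[int, int, float]] = []
        for start, end, shift in intervals:
            if merged and start < merged[-1][1]:
                warnings.warn(
                    f"overlapping CNVs merged on {chrom} at {start}", stacklevel=2
                )
                ps, pe, psh = merged[-1]
                merged[-1] = (ps, max(pe, end), psh)
            else:
                merged.append((start, end, shift))
        for start, end, shift in merged:
            inside = (positions >= start) & (positions < end)
            values[inside] = shift
        if config.probe_noise_sd > 0:
            values = values + rng.normal(0.0, config.probe_noise_sd, positions.size)
        tracks[chrom] = ProbeTrack(chrom, positions, values)
    return tracks


def simulate_reference(
    chrom_lengths: Mapping[str, int] | Genome,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
) -> Genome:
    """Genome with i.i.d. random sequence of the given base composition."""
    comp = np.asarray(base_composition, dtype=float)
    if comp.size != 4 or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("base_composition must be 4 probabilities summing to 1")
    if isinstance(chrom_lengths, Genome):
        lengths = {c: chrom_lengths.chrom_lengths[c] for c in chrom_lengths.chrom_names}
        names = chrom_lengths.chrom_names
    else:
        lengths = dict(chrom_lengths)
        names = tuple(lengths)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphabet = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seqs = {}
    for name in names:
        idx = rng.choice(4, size=lengths[name], p=comp)
        seqs[name] = alphabet[idx].tobytes().decode()
    return Genome(tuple(names), lengths, seqs)


@dataclass(frozen=True)
class SimulatedJunction:
    """A junction-spanning read with its flank windows and planted truth."""

    read: str
    left_flank: str
    left_flank_start: int
    right_flank: str
    right_flank_start: int
    truth: JunctionRecord


def _pick_other(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in BASES if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def simulate_junction_sequence(
    genome: Genome,
    cnv: CnvCall,
    mh_len: int,
    insertion: str = "",
    flank: int = 120,
    pad: int = 60,
    rng: np.random.Generator | None = None,
) -> SimulatedJunction:
    """Plant an exact microhomology (or insertion) at a deletion junction.

    The reference around the two breakpoints is locally edited so that the
    bases following the left and right breakpoints share exactly ``mh_len``
    identical bases and mismatch immediately beyond in both directions; the
    returned read spans left flank + optional insertion + right flank.
    Guarantees exact truth labels by construction.
    """
    if mh_len < 0:
        raise ValueError("mh_len must be >= 0")
    if mh_len > 0 and insertion:
        raise ValueError("a junction cannot have both microhomology and an insertion")
    if genome.sequence is None:
        raise ValueError("genome sequence required")
    insertion = insertion.upper()
    if any(b not in BASES for b in insertion):
        raise ValueError(f"invalid insertion sequence {insertion!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    left, right = cnv.start, cnv.end
    chrom_len = genome.chrom_lengths[cnv.chrom]
    if left - flank < 1 or right + max(flank, mh_len + 1) + 1 > chrom_len:
        raise ValueError("breakpoints too close to the chromosome end")
    if right - left <= mh_len + 1:
        raise ValueError("deleted interval too short to edit")

    seq = bytearray(genome.sequence[cnv.chrom], "ascii")

    def get(i: int) -> str:
        return chr(seq[i])

    def put(i: int, b: str) -> None:
        seq[i] = ord(b)

    if mh_len > 0:
        for j in range(mh_len):
            put(right + j, get(left + j))  # create the shared tract
        if get(left + mh_len) == get(right + mh_len):
            put(left + mh_len, _pick_other(rng, get(right + mh_len)))
        if get(left - 1) == get(right - 1):
            put(right - 1, _pick_other(rng, get(left - 1)))
    elif insertion:
        if insertion[0] == get(right):
            put(right, _pick_other(rng, insertion[0]))
        # first deleted base must differ from the first inserted base, or the
        # junction would be left-shiftable into the reference
        if get(left) == insertion[0]:
            put(left, _pick_other(rng, insertion[0]))
        if insertion[-1] == get(left - 1):
            put(left - 1, _pick_other(rng, insertion[-1]))
        if get(right - 1) == insertion[-1]:
            put(right - 1, _pick_other(rng, insertion[-1]))
    else:  # blunt
        if get(left) == get(right):
            put(left, _pick_other(rng, get(right)))
        if get(left - 1) == get(right - 1):
            put(right - 1, _pick_other(rng, get(left - 1)))

    edited = seq.decode()
    read = edited[left - flank : left] + insertion + edited[right : right + flank]
    left_flank_start = left - flank
    right_flank_start = right - pad
    truth = JunctionRecord(
        clone_id=cnv.clone_id,
        genotype=cnv.genotype,
        cnv_type=cnv.cnv_type,
        chrom=cnv.chrom,
        left_bp=left,
        right_bp=right,
        homology_len=mh_len,
        homology_seq=edited[left : left + mh_len],
        insertion_seq=insertion,
    )
    return SimulatedJunction(
        read=read,
        left_flank=edited[left_flank_start : left + pad],
        left_flank_start=left_flank_start,
        right_flank=edited[right_flank_start : right + flank],
        right_flank_start=right_flank_start,
        truth=truth,
    )


def simulate_truth_set(
    config: SimulationConfig,
    genome: Genome,
    rng: np.random.Generator | None = None,
    max_junctions: int = 0,
) -> TruthSet:
    """End-to-end cohort: clone counts, placed CNVs and (optionally, when the
    genome carries sequence) planted junction truths for simple deletions."""
    rng = config.rng(4) if rng is None else rng
    clones = simulate_clone_counts(config, rng)
    cnvs = place_cnvs(clones, genome, config, rng)
    junctions: list[JunctionRecord] = []
    if max_junctions and genome.sequence is not None:
        for cnv in cnvs:
            if len(junctions) >= max_junctions or cnv.cnv_type != "deletion":
                continue
            mh = int(rng.integers(0, 6))
            try:
                sim = simulate_junction_sequence(genome, cnv, mh, rng=rng)
            except ValueError:
                continue
            junctions.append(sim.truth)
    return TruthSet(tuple(cnvs), tuple(junctions), tuple(clones))


# ---------------------------------------------------------------------------
# deterministic reference cohort
# ---------------------------------------------------------------------------
# Size pools are built per (genotype x hotspot-status) cell as geometric grids
# inside intervals bounded by the four printed median pivots (46.3 kb
# non-hotspot, 59 kb WT, 63 kb Xrcc4-null, 89.8 kb hotspot).  The per-cell
# interval counts below make all four cohort medians land exactly on their
# pivot order statistic simultaneously.

_P46, _P59, _P63, _P89 = 46_300, 59_000, 63_000, 89_800

# each entry: (lo, hi, n) grids plus optional exact pivot repeats
_WT_HS_GRID = [(12_000, 46_000, 2), (47_000, 58_500, 3), (60_000, 62_500, 1),
               (64_000, 89_000, 16), (91_000, 1_400_000, 28)]
_X4_HS_GRID = [(13_000, 45_800, 4), (46_800, 58_800, 5), (59_500, 62_800, 2),
               (63_200, 89_500, 33), (90_500, 1_350_000, 38)]
_X4_HS_PIVOTS = [_P89]
_WT_NON_GRID = [(11_600, 46_200, 46), (46_500, 58_900, 20), (59_200, 62_900, 4),
                (63_100, 89_700, 12), (90_000, 1_390_000, 10)]
_WT_NON_PIVOTS = [_P59]
_X4_NON_GRID = [(7_700, 46_250, 75), (46_400, 58_950, 20), (59_100, 62_950, 8),
                (63_300, 89_600, 30), (90_200, 26_200_000, 14)]
_X4_NON_PIVOTS = [_P46, _P46, _P63, _P63]


def _grid_sizes(spec: list[tuple[int, int, int]], pivots: list[int]) -> list[int]:
    out: list[int] = []
    for lo, hi, n in spec:
        if n == 1:
            out.append(int(round(np.sqrt(lo * hi))))
        else:
            out.extend(int(round(v)) for v in np.geomspace(lo, hi, n))
    out.extend(pivots)
    return sorted(out)


def _largest_remainder(counts: Sequence[int], total: int) -> list[int]:
    """Apportion ``total`` across items proportionally to ``counts``."""
    counts = np.asarray(counts, dtype=float)
    quota = counts * total / counts.sum()
    out = np.floor(quota).astype(int)
    rem = total - int(out.sum())
    order = np.argsort(-(quota - out), kind="stable")
    for i in order[:rem]:
        out[i] += 1
    return out.tolist()


def _spread_flags(n: int, n_true: int) -> list[bool]:
    """n booleans with n_true Trues spread evenly (deterministic)."""
    flags = [False] * n
    if n_true == 0:
        return flags
    for i in range(n_true):
        flags[(i * n) // n_true] = True
    # stride collisions can only lose Trues; repair deterministically
    deficit = n_true - sum(flags)
    for i in range(n):
        if deficit == 0:
            break
        if not flags[i]:
            flags[i] = True
            deficit -= 1
    return flags


def synthetic_cohort(genome: Genome | None = None) -> TruthSet:
    """Deterministic stand-in for the study's per-CNV supplementary list.

    Returns 377 CNVs (143 WT / 234 Xrcc4-null) across 85 clones, reproducing
    the printed cohort statistics exactly (see module docstring).  Purely
    arithmetic: no random state is involved.
    """
    if genome is None:
        from .datasets import load_mouse_genome

        genome = load_mouse_genome()

    window = 10_000
    wt_treated = [f"WT6-{i + 1:02d}" for i in range(26)]
    x4_treated = [f"X6-{i + 1:02d}" for i in range(29)]
    wt_untreated = [f"WTU-{i + 1:02d}" for i in range(12)]
    x4_untreated = [f"X4U-{i + 1:02d}" for i in range(18)]

    calls: list[CnvCall] = []

    # --- hotspot CNVs: all members of a region share the core 10-kb window
    hs_counts = [n for *_x, n in MOUSE_HOTSPOT_CATALOG]
    wt_per_region = _largest_remainder(hs_counts, 50)
    wt_hs_sizes = _grid_sizes(_WT_HS_GRID, [])
    x4_hs_sizes = _grid_sizes(_X4_HS_GRID, _X4_HS_PIVOTS)
    assert len(wt_hs_sizes) == 50 and len(x4_hs_sizes) == 83

    # deal sorted sizes round-robin across regions so each region spans scales
    def _deal(sizes: list[int], per_region: list[int]) -> list[list[int]]:
        pools: list[list[int]] = [[] for _ in per_region]
        j = 0
        for s in sizes:
            for _ in range(len(per_region)):
                if len(pools[j]) < per_region[j]:
                    pools[j].append(s)
                    j = (j + 1) % len(per_region)
                    break
                j = (j + 1) % len(per_region)
        return pools

    wt_pools = _deal(wt_hs_sizes, wt_per_region)
    x4_per_region = [c - w for c, w in zip(hs_counts, wt_per_region)]
    x4_pools = _deal(x4_hs_sizes, x4_per_region)

    wt_clone_cycle = 0
    x4_clone_cycle = 0
    for r, (chrom, rs, re_, gene, count) in enumerate(MOUSE_HOTSPOT_CATALOG):
        core_mid = ((rs + re_) // 2 // window) * window + window // 2
        members: list[tuple[str, int]] = [("WT", s) for s in wt_pools[r]]
        members += [("Xrcc4_null", s) for s in x4_pools[r]]
        for i, (genotype, size) in enumerate(members):
            u = (i + 1) / (len(members) + 1)
            start = core_mid - int(round(u * size))
            end = start + size
            # one duplication in each genotype's hotspot set, rest deletions
            if genotype == "WT" and gene == "Auts2" and i == 0:
                cnv_type = "duplication"
            elif genotype == "Xrcc4_null" and gene == "Wwox" and i == len(members) - 1:
                cnv_type = "duplication"
            else:
                cnv_type = "deletion"
            if genotype == "WT":
                clone = wt_treated[wt_clone_cycle % len(wt_treated)]
                wt_clone_cycle += 1
            else:
                clone = x4_treated[x4_clone_cycle % len(x4_treated)]
                x4_clone_cycle += 1
            calls.append(
                CnvCall(clone, genotype, 0.6, chrom, start, end, cnv_type)
            )

    # --- non-hotspot CNVs: isolated placements outside hotspot neighbourhoods
    margin = 2_000_000
    gap = 500_000
    blocked: dict[str, list[tuple[int, int]]] = {}
    for chrom, rs, re_, _g, _n in MOUSE_HOTSPOT_CATALOG:
        blocked.setdefault(chrom, []).append((rs - margin, re_ + margin))

    wt_non_sizes = _grid_sizes(_WT_NON_GRID, _WT_NON_PIVOTS)
    x4_non_sizes = _grid_sizes(_X4_NON_GRID, _X4_NON_PIVOTS)
    assert len(wt_non_sizes) == 93 and len(x4_non_sizes) == 151

    wt_dup = _spread_flags(93, 12)
    x4_dup = _spread_flags(151, 38)
    wt_untx = _spread_flags(93, 5)
    x4_untx = _spread_flags(151, 24)

    queue: list[tuple[str, int, bool, bool]] = []
    # interleave genotypes, largest sizes first so they always find room
    wt_items = sorted(
        zip(["WT"] * 93, wt_non_sizes, wt_dup, wt_untx), key=lambda t: -t[1]
    )
    x4_items = sorted(
        zip(["Xrcc4_null"] * 151, x4_non_sizes, x4_dup, x4_untx), key=lambda t: -t[1]
    )
    i = j = 0
    while i < len(wt_items) or j < len(x4_items):
        if j < len(x4_items):
            queue.append(x4_items[j]); j += 1
        if i < len(wt_items):
            queue.append(wt_items[i]); i += 1

    cursors = {c: 3_000_000 for c in genome.chrom_names}
    chrom_order = list(genome.chrom_names)

    def _place(size: int) -> tuple[str, int]:
        for chrom in chrom_order:
            length = genome.chrom_lengths[chrom]
            pos = cursors[chrom]
            while pos + size + margin < length:
                conflict = next(
                    (
                        b
                        for b in blocked.get(chrom, [])
                        if pos < b[1] and b[0] < pos + size
                    ),
                    None,
                )
                if conflict is None:
                    cursors[chrom] = pos + size + gap
                    return chrom, pos
                pos = conflict[1]
            cursors[chrom] = max(cursors[chrom], length)
        raise RuntimeError("no room left for non-hotspot placement")

    counters = {"WT": 0, "Xrcc4_null": 0}
    for genotype, size, is_dup, is_untx in queue:
        chrom, start = _place(size)
        if genotype == "WT":
            pool = wt_untreated if is_untx else wt_treated
        else:
            pool = x4_untreated if is_untx else x4_treated
        clone = pool[counters[genotype] % len(pool)]
        counters[genotype] += 1
        calls.append(
            CnvCall(
                clone,
                genotype,
                0.0 if is_untx else 0.6,
                chrom,
                start,
                start + size,
                "duplication" if is_dup else "deletion",
            )
        )

    roster = (
        [(c, "WT", 0.6) for c in wt_treated]
        + [(c, "WT", 0.0) for c in wt_untreated]
        + [(c, "Xrcc4_null", 0.6) for c in x4_treated]
        + [(c, "Xrcc4_null", 0.0) for c in x4_untreated]
    )
    from .core_io import summarize_clones

    clones = summarize_clones(calls, roster)
    return TruthSet(tuple(calls), (), tuple(clones))
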