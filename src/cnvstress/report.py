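"""Cohort-level summaries and contrasts, and the pipeline orchestrator.

The summary reproduces the descriptive statistics a replication-stress CNV
study reports: per-arm CNV rates with exact Poisson confidence intervals and
one-sided E-test p-values (treated vs untreated), deletion fractions overall
and inside/outside hotspots with a Fisher exact contrast, size medians per
stratum with fold ratios, per-genotype hotspot CNV fractions, and complex
breakpoint-junction event counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core_io import (
    CloneSummary,
    CnvCall,
    Genome,
    JunctionRecord,
    write_cnv_bed,
    write_cnv_table,
)
from .hotspot_mc import HotspotRegion, McNullResult, find_hotspots, hotspot_null_pvalue
from .junction_analysis import (
    ComplexEvent,
    MicrohomologySummary,
    NullComparison,
    compare_to_null,
    group_complex_events,
    summarize_microhomology,
)
from .poisson_stats import ETestResult, RateEstimate, e_test_two_poisson, estimate_rate

__all__ = [
    "ContrastResult",
    "SizeSummary",
    "CohortSummary",
    "PipelineError",
    "deletion_fraction_contrast",
    "size_summary",
    "hotspot_stratifier",
    "cohort_summary",
    "run_pipeline",
]


@dataclass(frozen=True)
class ContrastResult:
    """2x2 deletion-status x hotspot-status table with Fisher exact p."""

    hotspot_deletions: int
    hotspot_other: int
    non_hotspot_deletions: int
    non_hotspot_other: int
    p_value: float

    @property
    def hotspot_deletion_fraction(self) -> float:
        return self.hotspot_deletions / (self.hotspot_deletions + self.hotspot_other)

    @property
    def non_hotspot_deletion_fraction(self) -> float:
        return self.non_hotspot_deletions / (
            self.non_hotspot_deletions + self.non_hotspot_other
        )


def deletion_fraction_contrast(
    cnvs: Sequence[CnvCall], hotspot_regions: Sequence[HotspotRegion]
) -> ContrastResult:
    """Two-sided Fisher exact test of deletion enrichment at hotspots."""
    in_hot = [any(r.overlaps(c) for r in hotspot_regions) for c in cnvs]
    table = np.zeros((2, 2), dtype=int)
    for c, hot in zip(cnvs, in_hot):
        row = 0 if hot else 1
        col = 0 if c.cnv_type == "deletion" else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table (zero margin): {table.tolist()}")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return ContrastResult(
        int(table[0, 0]), int(table[0, 1]), int(table[1, 0]), int(table[1, 1]), float(p)
    )


@dataclass(frozen=True)
class SizeSummary:
    strata: dict[str, tuple[int, float, int, int]]  # label -> (n, median, min, max)
    fold_ratios: dict[tuple[str, str], float]  # (a, b) -> median_a / median_b


def hotspot_stratifier(
    hotspot_regions: Sequence[HotspotRegion],
) -> Callable[[CnvCall], str]:
    def _stratum(c: CnvCall) -> str:
        return "hotspot" if any(r.overlaps(c) for r in hotspot_regions) else "non_hotspot"

    return _stratum


def size_summary(
    cnvs: Sequence[CnvCall],
    strata: str | Callable[[CnvCall], str] = "genotype",
) -> SizeSummary:
    """Median/min/max CNV size per stratum plus fold ratios of medians.

    ``strata`` is either an attribute name (e.g. ``"genotype"``,
    ``"cnv_type"``) or a callable mapping a CNV to a stratum label.
    """
    key = strata if callable(strata) else (lambda c: str(getattr(c, strata)))
    groups: dict[str, list[int]] = {}
    for c in cnvs:
        groups.setdefault(key(c), []).append(c.size)
    if not groups or any(not v for v in groups.values()):
        raise ValueError("every stratum must contain at least one CNV")
    out = {
        label: (len(v), float(np.median(v)), min(v), max(v))
        for label, v in sorted(groups.items())
    }
    ratios = {
        (a, b): out[a][1] / out[b][1]
        for a in out
        for b in out
        if a != b
    }
    return SizeSummary(out, ratios)


@dataclass(frozen=True)
class CohortSummary:
    rates: dict[tuple[str, float], RateEstimate]
    e_tests: dict[str, ETestResult]  # genotype -> treated-vs-untreated
    hotspots: tuple[HotspotRegion, ...]
    deletion_contrast: ContrastResult | None
    sizes_by_genotype: SizeSummary
    sizes_by_hotspot: SizeSummary | None
    hotspot_fraction: dict[str, tuple[int, int]]  # genotype -> (in hotspots, total)
    complex_events: tuple[ComplexEvent, ...]
    mh_by_genotype: dict[str, MicrohomologySummary]
    mh_null_comparison: NullComparison | None
    hotspot_null: McNullResult | None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def cohort_summary(
    cnvs: Sequence[CnvCall],
    clones: Sequence[CloneSummary],
    genome: Genome,
    junctions: Sequence[JunctionRecord] = (),
    window: int = 10_000,
    min_count: int = 5,
    mc_iterations: int = 0,
    seed: int = 0,
) -> CohortSummary:
    """Full descriptive summary of a CNV cohort.

    Set ``mc_iterations`` > 0 to also run the Monte Carlo hotspot null on the
    observed size set.
    """
    arms: dict[tuple[str, float], list[CloneSummary]] = {}
    for cl in clones:
        arms.setdefault((cl.genotype, cl.aph_dose), []).append(cl)
    rates = {arm: estimate_rate(members) for arm, members in sorted(arms.items())}

    e_tests: dict[str, ETestResult] = {}
    for genotype in sorted({g for g, _ in arms}):
        doses = sorted(d for g, d in arms if g == genotype)
        if len(doses) >= 2:
            lo, hi = doses[0], doses[-1]
            r0, r1 = rates[(genotype, lo)], rates[(genotype, hi)]
            e_tests[genotype] = e_test_two_poisson(
                r0.total_events, r0.n_units, r1.total_events, r1.n_units, "greater"
            )

    treated = [cl.clone_id for cl in clones if cl.aph_dose > 0]
    hotspots = tuple(
        find_hotspots(cnvs, genome, window, min_count, treated_clones=treated)
    )

    contrast = None
    sizes_hot = None
    if hotspots:
        strat = hotspot_stratifier(hotspots)
        try:
            contrast = deletion_fraction_contrast(cnvs, hotspots)
        except ValueError:
            contrast = None
        try:
            sizes_hot = size_summary(cnvs, strat)
        except ValueError:
            sizes_hot = None

    hotspot_fraction: dict[str, tuple[int, int]] = {}
    for genotype in sorted({c.genotype for c in cnvs}):
        sub = [c for c in cnvs if c.genotype == genotype]
        k = sum(1 for c in sub if any(r.overlaps(c) for r in hotspots))
        hotspot_fraction[genotype] = (k, len(sub))

    complex_events: tuple[ComplexEvent, ...] = ()
    mh_by_genotype: dict[str, MicrohomologySummary] = {}
    mh_null = None
    if junctions:
        complex_events = tuple(group_complex_events(junctions))
        for genotype in sorted({j.genotype for j in junctions}):
            sub = [j for j in junctions if j.genotype == genotype]
            mh_by_genotype[genotype] = summarize_microhomology(sub)
        mh_null = compare_to_null(junctions)

    hotspot_null = None
    if mc_iterations > 0:
        hotspot_null = hotspot_null_pvalue(
            [c.size for c in cnvs],
            genome,
            n_iter=mc_iterations,
            window=window,
            min_count=min_count,
            seed=seed,
        )

    return CohortSummary(
        rates=rates,
        e_tests=e_tests,
        hotspots=hotspots,
        deletion_contrast=contrast,
        sizes_by_genotype=size_summary(cnvs, "genotype"),
        sizes_by_hotspot=sizes_hot,
        hotspot_fraction=hotspot_fraction,
        complex_events=complex_events,
        mh_by_genotype=mh_by_genotype,
        mh_null_comparison=mh_null,
        hotspot_null=hotspot_null,
    )


def run_pipeline(
    sim_config=None,
    genome: Genome | None = None,
    cnvs: Sequence[CnvCall] | None = None,
    clones: Sequence[CloneSummary] | None = None,
    junctions: Sequence[JunctionRecord] = (),
    outdir: str | Path | None = None,
    mc_iterations: int = 0,
    seed: int = 0,
) -> CohortSummary:
    """Run simulate (optional) -> hotspots -> rates -> junctions -> report.

    Either a :class:`~cnvstress.synthetic_data.SimulationConfig` is given (a
    cohort is simulated) or ``cnvs``+``clones`` are supplied directly.  All
    randomness flows from ``sim_config.seed``/``seed``; outputs are written
    as TSV/BED under ``outdir`` when given.
    """
    from .synthetic_data import SimulationConfig, simulate_clone_counts, place_cnvs

    if genome is None:
        try:
            from .datasets import load_mouse_genome

            genome = load_mouse_genome()
        except Exception as exc:  # pragma: no cover
            raise PipelineError("genome", str(exc)) from exc

    if sim_config is not None:
        try:
            rng = sim_config.rng(17)
            clones = simulate_clone_counts(sim_config, rng)
            cnvs = place_cnvs(clones, genome, sim_config, rng)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
    if cnvs is None or clones is None:
        raise PipelineError("input", "need either sim_config or cnvs+clones")

    try:
        summary = cohort_summary(
            cnvs, clones, genome, junctions, mc_iterations=mc_iterations, seed=seed
        )
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cnv_table(cnvs, outdir / "cnv_calls.tsv")
        write_cnv_bed(cnvs, outdir / "cnv_calls.bed")
        with open(outdir / "hotspots.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tcnv_count\tclone_frequency\n")
            for r in summary.hotspots:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.cnv_count}\t{r.clone_frequency:.4f}\n"
                )
        with open(outdir / "rates.tsv", "w") as fh:
            fh.write("genotype\tdose_uM\tevents\tclones\trate\tci_low\tci_high\n")
            for (g, d), r in summary.rates.items():
                fh.write(
                    f"{g}\t{d:g}\t{r.total_events}\t{r.n_units}\t"
                    f"{r.rate:.4f}\t{r.ci_low:.4f}\t{r.ci_high:.4f}\n"
                )
    return summary
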