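"""Loaders for the small fixtures shipped with the package.

* ``load_mouse_genome`` — mouse-like chromosome lengths (chr1–chr19, chrX),
  the coordinate frame used throughout.
* ``load_junction_catalog`` — the 41 sequenced breakpoint junctions from
  aphidicolin-treated wild-type and Xrcc4-null mouse ES cell clones.
* ``load_cnv_catalog`` — the synthetic reference CNV cohort (377 records,
  85 clones); a deterministic stand-in for the study's unpublished per-CNV
  list, rebuilt from its printed cohort statistics (see
  :func:`cnvstress.synthetic_data.synthetic_cohort`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core_io import (
    CloneSummary,
    CnvCall,
    Genome,
    JunctionRecord,
    read_cnv_table,
    read_genome,
    read_junction_table,
)

__all__ = [
    "load_mouse_genome",
    "load_junction_catalog",
    "load_cnv_catalog",
    "load_clone_roster",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("cnvstress").joinpath("data", name))


def load_mouse_genome() -> Genome:
    return read_genome(_data_path("mouse_chrom_sizes.tsv"))


def load_junction_catalog() -> list[JunctionRecord]:
    return read_junction_table(_data_path("junction_catalog.tsv"))


def load_cnv_catalog(genome: Genome | None = None) -> list[CnvCall]:
    genome = load_mouse_genome() if genome is None else genome
    return read_cnv_table(
        _data_path("cnv_catalog_synthetic.tsv"),
        coordinate_dialect="zero_half_open",
        genome=genome,
    )


def load_clone_roster() -> list[CloneSummary]:
    """Clone table matching the synthetic CNV catalog (85 clones, 55
    aphidicolin-treated)."""
    from .synthetic_data import synthetic_cohort

    return list(synthetic_cohort().clones)
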