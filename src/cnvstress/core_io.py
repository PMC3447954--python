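"""Domain types, coordinate conventions and tabular/sequence readers.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
(the BED convention); report output uses 1-based inclusive coordinates to match
the way CNV tables are conventionally printed.  A CNV's size is ``end - start``.

The central records are :class:`CnvCall` (one de novo copy-number variant
detected in a clonal cell population), :class:`JunctionRecord` (one sequenced
breakpoint junction with its microhomology / insertion annotation) and
:class:`ProbeTrack` (array-CGH log2-ratio intensities along a chromosome).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genome",
    "CnvCall",
    "ProbeTrack",
    "JunctionRecord",
    "CloneSummary",
    "read_genome",
    "read_cnv_table",
    "write_cnv_table",
    "read_junction_table",
    "write_cnv_bed",
    "summarize_clones",
]

Genotype = Literal["WT", "Xrcc4_null"]
CnvType = Literal["deletion", "duplication", "complex"]
JunctionClass = Literal["blunt", "microhomology", "insertion"]

#: accepted spellings for the two genotypes (input is normalised to the key)
_GENOTYPE_ALIASES = {
    "wt": "WT",
    "wild-type": "WT",
    "wildtype": "WT",
    "xrcc4_null": "Xrcc4_null",
    "xrcc4-null": "Xrcc4_null",
    "xrcc4-/-": "Xrcc4_null",
    "xrcc4−/−": "Xrcc4_null",
    "xrcc4–/–": "Xrcc4_null",
}

_CNV_TYPE_ALIASES = {
    "deletion": "deletion",
    "del": "deletion",
    "loss": "deletion",
    "duplication": "duplication",
    "dup": "duplication",
    "gain": "duplication",
    "complex": "complex",
}


def normalize_genotype(token: str) -> str:
    key = str(token).strip().lower()
    if key not in _GENOTYPE_ALIASES:
        raise ValueError(f"unknown genotype token: {token!r}")
    return _GENOTYPE_ALIASES[key]


def normalize_cnv_type(token: str) -> str:
    key = str(token).strip().lower()
    if key not in _CNV_TYPE_ALIASES:
        raise ValueError(f"unknown CNV type token: {token!r}")
    return _CNV_TYPE_ALIASES[key]


@dataclass(frozen=True)
class Genome:
    """Coordinate frame: ordered chromosomes, lengths, optional sequence."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name)
            if length is None or length <= 0:
                raise ValueError(f"non-positive or missing length for {name!r}")
            if self.sequence is not None:
                seq = self.sequence.get(name)
                if seq is None or len(seq) != length:
                    raise ValueError(
                        f"sequence length for {name!r} does not match declared length"
                    )

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the base string for 0-based half-open ``[start, end)``."""
        if self.sequence is None:
            raise ValueError("genome has no sequence")
        if chrom not in self.sequence:
            raise KeyError(chrom)
        if start < 0 or end > self.chrom_lengths[chrom] or start > end:
            raise ValueError(f"interval [{start}, {end}) outside {chrom}")
        return self.sequence[chrom][start:end]


@dataclass(frozen=True)
class CnvCall:
    """One de novo CNV in one clone; coordinates 0-based half-open."""

    clone_id: str
    genotype: str
    aph_dose: float
    chrom: str
    start: int
    end: int
    cnv_type: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) for {self.clone_id}"
            )
        if self.aph_dose < 0:
            raise ValueError("aphidicolin dose must be >= 0")
        object.__setattr__(self, "genotype", normalize_genotype(self.genotype))
        object.__setattr__(self, "cnv_type", normalize_cnv_type(self.cnv_type))

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class ProbeTrack:
    """Sorted probe positions and log2 ratios for one chromosome."""

    chrom: str
    positions: np.ndarray
    log2r: np.ndarray

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        log2r = np.asarray(self.log2r, dtype=float)
        if positions.shape != log2r.shape or positions.ndim != 1:
            raise ValueError("positions and log2r must be 1-D arrays of equal length")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "log2r", log2r)

    @property
    def n_probes(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class JunctionRecord:
    """One sequenced breakpoint junction.

    ``homology_len`` is taken from the numeric annotation and is authoritative;
    ``homology_seq`` may contain ambiguity codes like ``(T/C)`` and is stored
    verbatim.  Classes: ``insertion`` iff ``insertion_seq`` is non-empty,
    ``blunt`` iff no homology and no insertion, else ``microhomology``.
    """

    clone_id: str
    genotype: str
    cnv_type: str
    chrom: str
    left_bp: int
    right_bp: int
    homology_len: int
    homology_seq: str = ""
    insertion_seq: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", normalize_genotype(self.genotype))
        object.__setattr__(self, "cnv_type", normalize_cnv_type(self.cnv_type))
        if self.homology_len < 0:
            raise ValueError("homology length must be >= 0")
        if self.homology_len > 0 and self.insertion_seq:
            raise ValueError("a junction cannot have both homology and an insertion")
        seq = self.homology_seq
        if seq and "(" not in seq and len(seq) != self.homology_len:
            raise ValueError(
                f"homology_len {self.homology_len} != length of {seq!r}"
            )

    @property
    def junction_class(self) -> str:
        if self.insertion_seq:
            return "insertion"
        if self.homology_len == 0:
            return "blunt"
        return "microhomology"


@dataclass(frozen=True)
class CloneSummary:
    clone_id: str
    genotype: str
    aph_dose: float
    n_cnvs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", normalize_genotype(self.genotype))
        if self.n_cnvs < 0:
            raise ValueError("n_cnvs must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> Genome:
    """Read a genome from a UCSC-style chrom-sizes TSV or a FASTA file.

    The format is sniffed from the first non-blank character: ``>`` means
    FASTA (sequence is populated); otherwise a two-column name/length table.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        names: list[str] = []
        lengths: dict[str, int] = {}
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in lengths:
                raise ValueError(f"duplicate chromosome name: {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for {rec.id!r}")
            names.append(rec.id)
            lengths[rec.id] = len(seq)
            seqs[rec.id] = seq
        if not names:
            raise ValueError(f"no FASTA records in {path}")
        return Genome(tuple(names), lengths, seqs)

    names = []
    lengths = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected name<TAB>length")
            name, length_s = fields[0], fields[1]
            if name in lengths:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length_s)
            if length <= 0:
                raise ValueError(f"non-positive length for {name!r}")
            names.append(name)
            lengths[name] = length
    if not names:
        raise ValueError(f"no chromosomes in {path}")
    return Genome(tuple(names), lengths)


#: header used by the CNV table reader/writer
CNV_TABLE_COLUMNS = [
    "clone_id",
    "genotype",
    "aph_dose_uM",
    "chrom",
    "start",
    "end",
    "type",
]


def read_cnv_table(
    path: str | Path,
    coordinate_dialect: str = "one_based_inclusive",
    genome: Genome | None = None,
) -> list[CnvCall]:
    """Read a CNV call table, normalising coordinates to 0-based half-open.

    ``coordinate_dialect`` declares the file's convention:
    ``one_based_inclusive`` (1-based start and end, both included; the form
    printed in publication tables) or ``zero_half_open`` (BED-like).
    """
    if coordinate_dialect not in ("one_based_inclusive", "zero_half_open"):
        raise ValueError(f"unknown coordinate dialect: {coordinate_dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in CNV_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CNV table missing columns: {missing}")
    calls: list[CnvCall] = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        end = int(row.end)
        if coordinate_dialect == "one_based_inclusive":
            start -= 1
        call = CnvCall(
            clone_id=str(row.clone_id),
            genotype=str(row.genotype),
            aph_dose=float(row.aph_dose_uM),
            chrom=str(row.chrom),
            start=start,
            end=end,
            cnv_type=str(row.type),
        )
        if genome is not None:
            if call.chrom not in genome:
                raise ValueError(f"unknown chromosome {call.chrom!r}")
            if call.end > genome.chrom_lengths[call.chrom]:
                raise ValueError(
                    f"CNV [{call.start}, {call.end}) exceeds {call.chrom} length"
                )
        calls.append(call)
    return calls


def write_cnv_table(
    cnvs: Iterable[CnvCall],
    path: str | Path,
    coordinate_dialect: str = "zero_half_open",
) -> None:
    """Write CNV calls as TSV in the declared coordinate dialect."""
    if coordinate_dialect not in ("one_based_inclusive", "zero_half_open"):
        raise ValueError(f"unknown coordinate dialect: {coordinate_dialect!r}")
    rows = []
    for c in cnvs:
        start = c.start + 1 if coordinate_dialect == "one_based_inclusive" else c.start
        rows.append(
            (c.clone_id, c.genotype, c.aph_dose, c.chrom, start, c.end, c.cnv_type)
        )
    pd.DataFrame(rows, columns=CNV_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


JUNCTION_TABLE_COLUMNS = [
    "clone_id",
    "genotype",
    "aph_dose_uM",
    "cnv_type",
    "chrom",
    "left_bp",
    "right_bp",
    "homology_len",
    "homology_seq",
    "insertion_seq",
]


def read_junction_table(path: str | Path) -> list[JunctionRecord]:
    """Read a breakpoint-junction table ("-" denotes an empty sequence field)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in JUNCTION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"junction table missing columns: {missing}")

    def _seq(token: str) -> str:
        token = "" if token is None or token != token else str(token).strip()
        return "" if token in ("-", "") else token

    records = []
    for row in df.itertuples(index=False):
        records.append(
            JunctionRecord(
                clone_id=str(row.clone_id),
                genotype=str(row.genotype),
                cnv_type=str(row.cnv_type),
                chrom=str(row.chrom),
                left_bp=int(str(row.left_bp).replace(",", "")),
                right_bp=int(str(row.right_bp).replace(",", "")),
                homology_len=int(row.homology_len),
                homology_seq=_seq(row.homology_seq),
                insertion_seq=_seq(row.insertion_seq),
            )
        )
    return records


def write_cnv_bed(cnvs: Sequence[CnvCall], path: str | Path) -> None:
    """Write calls as BED4; name field is ``clone|genotype|type``."""
    with open(path, "w") as fh:
        for c in cnvs:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.clone_id}|{c.genotype}|{c.cnv_type}\n")


def summarize_clones(
    cnvs: Iterable[CnvCall],
    clones: Iterable[tuple[str, str, float]] | None = None,
) -> list[CloneSummary]:
    """Per-clone CNV counts.

    ``clones`` optionally supplies the full roster of (clone_id, genotype,
    dose) so that clones with zero CNVs are represented; without it only
    clones appearing in ``cnvs`` are summarised.
    """
    counts: dict[str, int] = {}
    meta: dict[str, tuple[str, float]] = {}
    for c in cnvs:
        counts[c.clone_id] = counts.get(c.clone_id, 0) + 1
        meta.setdefault(c.clone_id, (c.genotype, c.aph_dose))
    if clones is not None:
        for clone_id, genotype, dose in clones:
            counts.setdefault(clone_id, 0)
            meta[clone_id] = (normalize_genotype(genotype), float(dose))
    return [
        CloneSummary(cid, meta[cid][0], meta[cid][1], n)
        for cid, n in sorted(counts.items())
    ]
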