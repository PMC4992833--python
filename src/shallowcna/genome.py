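"""Genome coordinate frame, interval types and readers/writers.

Every other stage of the pipeline works in the coordinate frame defined
here: an ordered list of named chromosomes with lengths (UCSC
``chrom.sizes`` dialect), genomic intervals in 0-based half-open BED
convention, and strand-aware read-start records.  A bundled hg19-style
chromosome-sizes table ships with the package so that window grids match
the reference assembly the method was designed around.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "GenomeModel",
    "CNAInterval",
    "ReadStartRecord",
    "read_chrom_sizes",
    "read_bed_intervals",
    "write_bed_intervals",
    "hg19_genome",
    "average_depth",
]

Direction = Literal["gain", "loss"]


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths; defines genome-wide window order.

    The chromosome order is exactly the input order and is treated as
    authoritative: windows, profiles and segment tables all inherit it.
    Chromosome name matching everywhere in the package is exact text;
    no ``chr`` prefix aliasing is attempted.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome: {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def order(self, chrom: str) -> int:
        """Rank of a chromosome in genome order (0-based)."""
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    def subset(self, keep: Iterable[str]) -> "GenomeModel":
        """Genome restricted to ``keep`` (original order preserved)."""
        keep = set(keep)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"unknown chromosome(s): {sorted(missing)}")
        return GenomeModel(tuple(c for c in self.chromosomes if c[0] in keep))

    def drop(self, names: Iterable[str]) -> "GenomeModel":
        names = set(names)
        return GenomeModel(tuple(c for c in self.chromosomes if c[0] not in names))


@dataclass(frozen=True)
class CNAInterval:
    """A genomic interval with a copy-number direction.

    Coordinates are 0-based half-open (BED native).  ``copy_number`` is
    optional and, when set, overrides the default 1-copy loss / 3-copy
    gain when the interval is rasterized onto a window grid.
    """

    chrom: str
    start: int
    end: int
    direction: Direction
    copy_number: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be 'gain' or 'loss', got {self.direction!r}")

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlap(self, other: "CNAInterval") -> int:
        """Overlap in bp with another interval (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ReadStartRecord:
    """Mapped read start: (chromosome, 0-based position, strand)."""

    chrom: str
    pos: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Parse a two-column UCSC ``chrom.sizes`` TSV into a :class:`GenomeModel`.

    File order is preserved (it defines genome-wide window order).
    Blank lines are ignored; anything else that is not exactly
    ``name<TAB>integer`` is rejected.
    """
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            name, raw_len = parts
            try:
                length = int(raw_len)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer length {raw_len!r}") from None
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name}")
            chroms.append((name, length))
    if not chroms:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeModel(tuple(chroms))


def hg19_genome(include_chrY: bool = True) -> GenomeModel:
    """The bundled hg19-style genome (24 chromosomes, ~3.1 Gb)."""
    ref = importlib.resources.files("shallowcna.data") / "hg19.chrom.sizes"
    with importlib.resources.as_file(ref) as path:
        genome = read_chrom_sizes(path)
    if not include_chrY:
        genome = genome.drop(["chrY"])
    return genome


def _validate_interval(iv: CNAInterval, genome: GenomeModel) -> None:
    if iv.chrom not in genome:
        raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
    if iv.end > genome.length(iv.chrom):
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {genome.length(iv.chrom)}"
        )


def read_bed_intervals(path: str | Path, genome: GenomeModel) -> list[CNAInterval]:
    """Read BED3+ intervals, validate against ``genome``, sort genomically.

    The optional 4th column is parsed as a direction label (``gain`` or
    ``loss``); BED3 lines default to ``gain`` with no copy number.  A
    5th numeric column, when present, is taken as an explicit copy
    number.  Output is sorted by (chromosome order, start).
    """
    intervals: list[CNAInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom, raw_start, raw_end = parts[0], parts[1], parts[2]
            try:
                start, end = int(raw_start), int(raw_end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            direction: Direction = "gain"
            if len(parts) >= 4 and parts[3]:
                label = parts[3].strip().lower()
                if label not in ("gain", "loss"):
                    raise ValueError(
                        f"{path}:{lineno}: direction must be gain/loss, got {parts[3]!r}"
                    )
                direction = label  # type: ignore[assignment]
            copy_number = None
            if len(parts) >= 5 and parts[4] not in ("", "."):
                copy_number = float(parts[4])
            iv = CNAInterval(chrom, start, end, direction, copy_number)
            _validate_interval(iv, genome)
            intervals.append(iv)
    intervals.sort(key=lambda iv: (genome.order(iv.chrom), iv.start, iv.end))
    return intervals


def write_bed_intervals(intervals: Sequence[CNAInterval], path: str | Path) -> None:
    """Write intervals as BED4(+score) — lossless round-trip with the reader."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.direction]
            if iv.copy_number is not None:
                fields.append(repr(iv.copy_number))
            fh.write("\t".join(fields) + "\n")


def average_depth(n_reads: float, read_length: int, genome_length: float) -> float:
    """Haploid average sequencing depth: n_reads * read_length / genome_length.

    For 34 million 75 bp reads on a 3.2 Gb genome this is ~0.8x, the
    shallow (<1x) regime in which window-count CN profiling operates.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return n_reads * read_length / genome_length
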