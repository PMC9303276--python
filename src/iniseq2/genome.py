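"""Genome layout, intervals, read sets and signal tracks.

All coordinates throughout the package are BED-style: 0-based, half-open
``[start, end)``. The length of an interval is ``end - start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """A malformed line in a BED or chrom.sizes file (carries the line number)."""


class BoundsError(ValueError):
    """An interval that does not fit the genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of chromosomes with their lengths in bp."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes.items()))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise BoundsError(f"chromosome {name!r} not in genome layout") from None

    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class Interval:
    """A genomic interval; ``name``, ``score`` and ``strand`` are optional."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def validate(self, layout: GenomeLayout) -> None:
        if self.end > layout.length_of(self.chrom):
            raise BoundsError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {layout.length_of(self.chrom)}"
            )


@dataclass
class GeneRecord(Interval):
    """An interval with a mandatory +/- strand (a transcriptional unit)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name or self.chrom} requires strand '+' or '-'")


def _parse_bed_line(line: str, lineno: int, record: type = Interval) -> Interval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from None
    name = fields[3] if len(fields) > 3 else None
    score: float | None = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-numeric score {fields[4]!r}") from None
    strand = fields[5] if len(fields) > 5 else "."
    try:
        return record(chrom, start, end, name=name, score=score, strand=strand)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from None


def read_bed(
    path: str | Path,
    layout: GenomeLayout | None = None,
    record: type = Interval,
) -> list[Interval]:
    """Read a BED3/BED5/BED6 file, preserving input order.

    Intervals are validated against ``layout`` when one is given; malformed
    lines raise :class:`BedParseError` naming the offending line.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, record)
            if layout is not None:
                iv.validate(layout)
            out.append(iv)
    return out


def read_genes_bed(path: str | Path, layout: GenomeLayout | None = None) -> list[GeneRecord]:
    """Read a stranded BED6 file of genes (strand must be + or -)."""
    return read_bed(path, layout, record=GeneRecord)  # type: ignore[return-value]


def _format_score(x: float) -> str:
    return repr(float(x))  # shortest string that round-trips


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write intervals as BED; emits as many columns as the records carry."""
    intervals = list(intervals)
    n_cols = 3
    if any(iv.strand != "." for iv in intervals):
        n_cols = 6
    elif any(iv.score is not None for iv in intervals):
        n_cols = 5
    elif any(iv.name is not None for iv in intervals):
        n_cols = 4
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if n_cols > 3:
                fields.append(iv.name if iv.name is not None else ".")
            if n_cols > 4:
                fields.append(_format_score(iv.score) if iv.score is not None else "0")
            if n_cols > 5:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column ``name TAB length`` table into a GenomeLayout."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"line {lineno}: expected 'name<TAB>length'")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise BedParseError(f"line {lineno}: non-integer length {fields[1]!r}") from None
            if name in seen:
                raise BedParseError(f"line {lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise BedParseError(f"line {lineno}: non-positive length for {name!r}")
            seen.add(name)
            chroms.append((name, length))
    return GenomeLayout(tuple(chroms))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


class ReadSet:
    """A library of fixed-length single-end reads, stored as 5' start arrays.

    Reads are unstranded in this assay; each read is fully described by its
    chromosome, start coordinate and the common read length.
    """

    def __init__(
        self,
        starts: dict[str, np.ndarray],
        read_length: int,
        layout: GenomeLayout,
    ) -> None:
        if read_length <= 0:
            raise ValueError("read_length must be positive")
        self.read_length = int(read_length)
        self.layout = layout
        self.starts: dict[str, np.ndarray] = {}
        for chrom, arr in starts.items():
            arr = np.asarray(arr, dtype=np.int64)
            L = layout.length_of(chrom)
            if arr.size and (arr.min() < 0 or arr.max() + read_length > L):
                bad = arr[(arr < 0) | (arr + read_length > L)][0]
                raise BoundsError(
                    f"read at {chrom}:{bad} (length {read_length}) outside chromosome of length {L}"
                )
            self.starts[chrom] = np.sort(arr)

    @property
    def total(self) -> int:
        """Number of reads in the library."""
        return int(sum(arr.size for arr in self.starts.values()))

    @classmethod
    def from_intervals(cls, intervals: Sequence[Interval], layout: GenomeLayout) -> "ReadSet":
        if not intervals:
            raise ValueError("empty read list; read length cannot be inferred")
        lengths = {len(iv) for iv in intervals}
        if len(lengths) != 1:
            raise ValueError(f"reads have mixed lengths {sorted(lengths)}; expected one")
        by_chrom: dict[str, list[int]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv.start)
        return cls(
            {c: np.asarray(v) for c, v in by_chrom.items()}, lengths.pop(), layout
        )

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout) -> "ReadSet":
        return cls.from_intervals(read_bed(path, layout), layout)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.layout.names:
                for s in self.starts.get(chrom, ()):
                    fh.write(f"{chrom}\t{s}\t{s + self.read_length}\n")

    def subsample(self, fraction: float, rng: np.random.Generator) -> "ReadSet":
        """Uniform draw of ``round(fraction * total)`` reads without replacement."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if fraction == 1.0:
            return self
        new: dict[str, np.ndarray] = {}
        for chrom, arr in self.starts.items():
            k = int(round(fraction * arr.size))
            new[chrom] = rng.choice(arr, size=k, replace=False)
        return ReadSet(new, self.read_length, self.layout)

    def __iter__(self) -> Iterator[Interval]:
        for chrom in self.layout.names:
            for s in self.starts.get(chrom, ()):
                yield Interval(chrom, int(s), int(s) + self.read_length)


class SignalTrack:
    """A piecewise-constant signal over genomic intervals (zero where uncovered)."""

    def __init__(self, segments: Sequence[tuple[Interval, float]], layout: GenomeLayout | None = None):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in segments:
            if not np.isfinite(value):
                raise ValueError(f"non-finite track value at {iv.chrom}:{iv.start}-{iv.end}")
            if layout is not None:
                iv.validate(layout)
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end, float(value)))
        for chrom, items in grouped.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            values = np.array([v for _, _, v in items], dtype=float)
            self._by_chrom[chrom] = (starts, ends, values)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout | None = None) -> "SignalTrack":
        """Read a bedGraph (4 numeric columns) or BED5 (value in column 5) track."""
        segments: list[tuple[Interval, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise BedParseError(f"line {lineno}: track needs >=4 columns")
                try:
                    value = float(fields[3]) if len(fields) == 4 else float(fields[4])
                except ValueError:
                    raise BedParseError(f"line {lineno}: non-numeric track value") from None
                iv = _parse_bed_line("\t".join(fields[:3]), lineno)
                segments.append((iv, value))
        return cls(segments, layout)

    def mean_over(self, chrom: str, start: float, end: float) -> float:
        """Length-weighted mean signal over ``[start, end)``; uncovered bp count as 0."""
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._by_chrom:
            return 0.0
        starts, ends, values = self._by_chrom[chrom]
        lo = np.maximum(starts, start)
        hi = np.minimum(ends, end)
        overlap = np.clip(hi - lo, 0, None)
        return float(np.dot(overlap, values) / (end - start))
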