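"""Genome and region-set data model plus BED / chrom.sizes I/O.

Coordinates are 0-based, half-open (BED convention) everywhere in this
package.  A :class:`GenomeDef` is the randomization universe: an ordered
list of chromosomes with lengths and an optional mask of excluded
intervals.  A :class:`RegionSet` is a named, sorted collection of
intervals bound to a genome — the unit every statistic consumes.

Strand is ignored throughout: the overlap statistics computed here are
strand-blind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GenomeDef",
    "RegionSet",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
]


class GenomicInterval(NamedTuple):
    """A genomic interval: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge intervals already sorted by start; adjacent intervals merge."""
    if starts.size == 0:
        return starts, ends
    # new merged block starts where a start exceeds the running max end
    run_max_end = np.maximum.accumulate(ends)
    is_break = np.empty(starts.size, dtype=bool)
    is_break[0] = True
    is_break[1:] = starts[1:] > run_max_end[:-1]
    block = np.cumsum(is_break) - 1
    n_blocks = block[-1] + 1
    m_starts = starts[is_break]
    m_ends = np.zeros(n_blocks, dtype=ends.dtype)
    np.maximum.at(m_ends, block, ends)
    return m_starts, m_ends


class GenomeDef:
    """Ordered chromosomes with lengths and an optional exclusion mask.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs; order is preserved and
        defines the canonical chromosome order of every bound RegionSet.
    mask
        Optional iterable of ``(chrom, start, end)`` excluded intervals.
        Masked intervals must lie within their chromosome.
    """

    def __init__(
        self,
        chromosomes: Sequence[tuple[str, int]],
        mask: Iterable[tuple[str, int, int]] | None = None,
    ):
        if len(chromosomes) == 0:
            raise ValueError("empty genome: at least one chromosome required")
        names = [str(n) for n, _ in chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dupes)}")
        lengths = np.asarray([int(l) for _, l in chromosomes], dtype=np.int64)
        if np.any(lengths <= 0):
            bad = names[int(np.argmax(lengths <= 0))]
            raise ValueError(f"non-positive length for chromosome {bad!r}")
        self.names: tuple[str, ...] = tuple(names)
        self.lengths: np.ndarray = lengths
        self._index = {n: i for i, n in enumerate(self.names)}
        # merged mask per chromosome index: (starts, ends)
        self._mask: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        if mask is not None:
            self._set_mask(mask)

    # -- basic queries ------------------------------------------------

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def index(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def length(self, chrom: str) -> int:
        return int(self.lengths[self.index(chrom)])

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    @property
    def has_mask(self) -> bool:
        return bool(self._mask)

    def _set_mask(self, mask: Iterable[tuple[str, int, int]]) -> None:
        per_chrom: dict[int, list[tuple[int, int]]] = {}
        for chrom, start, end in mask:
            ci = self.index(chrom)
            start, end = int(start), int(end)
            if not (0 <= start < end <= self.lengths[ci]):
                raise ValueError(
                    f"mask interval {chrom}:{start}-{end} outside [0, {self.lengths[ci]})"
                )
            per_chrom.setdefault(ci, []).append((start, end))
        for ci, ivals in per_chrom.items():
            arr = np.asarray(sorted(ivals), dtype=np.int64)
            self._mask[ci] = _merge_sorted(arr[:, 0], arr[:, 1])

    def mask_arrays(self, chrom_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Merged mask intervals (starts, ends) on one chromosome."""
        empty = np.empty(0, dtype=np.int64)
        return self._mask.get(chrom_index, (empty, empty))

    def masked_bp(self, chrom_index: int) -> int:
        s, e = self.mask_arrays(chrom_index)
        return int((e - s).sum())

    def effective_length(self, chrom_index: int) -> int:
        """Placeable (unmasked) base pairs on one chromosome."""
        return int(self.lengths[chrom_index]) - self.masked_bp(chrom_index)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenomeDef({len(self)} chromosomes, {self.total_length:,} bp"
            f"{', masked' if self.has_mask else ''})"
        )


class RegionSet:
    """A named, sorted set of genomic intervals bound to a :class:`GenomeDef`.

    Intervals are stored as parallel numpy arrays (chromosome index,
    start, end) sorted by (chromosome order, start, end).  Duplicate
    intervals are permitted — the region *count* is the number of
    records, not merged bases — but flagged via :attr:`has_duplicates`.

    The constructor is the single validation gate: every interval must
    satisfy ``0 <= start < end <= chromosome length``.
    """

    def __init__(
        self,
        name: str,
        genome: GenomeDef,
        intervals: Iterable[tuple[str, int, int]] = (),
    ):
        rows = [(genome.index(c), int(s), int(e)) for c, s, e in intervals]
        if rows:
            arr = np.asarray(rows, dtype=np.int64)
            ci, st, en = arr[:, 0], arr[:, 1], arr[:, 2]
        else:
            ci = st = en = np.empty(0, dtype=np.int64)
        self.name = name
        self.genome = genome
        self._init_from_arrays(ci, st, en, presorted=False, validate=True)

    @classmethod
    def from_arrays(
        cls,
        name: str,
        genome: GenomeDef,
        chrom_idx: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        *,
        presorted: bool = False,
        validate: bool = True,
    ) -> "RegionSet":
        rs = cls.__new__(cls)
        rs.name = name
        rs.genome = genome
        rs._init_from_arrays(
            np.asarray(chrom_idx, dtype=np.int64),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            presorted=presorted,
            validate=validate,
        )
        return rs

    def _init_from_arrays(self, ci, st, en, *, presorted: bool, validate: bool) -> None:
        if not (ci.size == st.size == en.size):
            raise ValueError("chrom/start/end arrays differ in length")
        if validate and ci.size:
            if np.any((ci < 0) | (ci >= len(self.genome))):
                raise ValueError("chromosome index out of range")
            if np.any(st < 0):
                i = int(np.argmax(st < 0))
                raise ValueError(f"negative start: {self._fmt(ci[i], st[i], en[i])}")
            if np.any(st >= en):
                i = int(np.argmax(st >= en))
                raise ValueError(f"start >= end: {self._fmt(ci[i], st[i], en[i])}")
            if np.any(en > self.genome.lengths[ci]):
                i = int(np.argmax(en > self.genome.lengths[ci]))
                raise ValueError(
                    f"end beyond chromosome: {self._fmt(ci[i], st[i], en[i])}"
                )
        if not presorted and ci.size:
            order = np.lexsort((en, st, ci))
            ci, st, en = ci[order], st[order], en[order]
        self.chrom_idx = ci
        self.starts = st
        self.ends = en
        if ci.size > 1:
            same = (ci[1:] == ci[:-1]) & (st[1:] == st[:-1]) & (en[1:] == en[:-1])
            self.has_duplicates = bool(same.any())
            if self.has_duplicates:
                logger.debug("RegionSet %r contains duplicate intervals", self.name)
        else:
            self.has_duplicates = False

    def _fmt(self, ci: int, s: int, e: int) -> str:
        return f"{self.genome.names[int(ci)]}:{int(s)}-{int(e)}"

    # -- container protocol -------------------------------------------

    def __len__(self) -> int:
        return int(self.chrom_idx.size)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for ci, s, e in zip(self.chrom_idx, self.starts, self.ends):
            yield GenomicInterval(self.genome.names[int(ci)], int(s), int(e))

    def __getitem__(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.genome.names[int(self.chrom_idx[i])],
            int(self.starts[i]),
            int(self.ends[i]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return (
            self.genome.names == other.genome.names
            and np.array_equal(self.chrom_idx, other.chrom_idx)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def intervals(self) -> list[GenomicInterval]:
        return list(self)

    def subset(self, keep: np.ndarray, name: str | None = None) -> "RegionSet":
        """Subset by boolean mask or index array, preserving order."""
        return RegionSet.from_arrays(
            name if name is not None else self.name,
            self.genome,
            self.chrom_idx[keep],
            self.starts[keep],
            self.ends[keep],
            presorted=True,
            validate=False,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet({self.name!r}, n={len(self)})"


# ---------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_chrom_sizes(path: str | Path) -> GenomeDef:
    """Read a UCSC chrom.sizes file (two whitespace-delimited columns).

    Chromosome order is the file order.  Malformed lines, non-positive
    lengths and duplicate names raise ``ValueError`` naming the line.
    """
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed line {line.strip()!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name!r}")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeDef(chroms)


def read_bed(
    path: str | Path,
    genome: GenomeDef,
    name: str | None = None,
    *,
    strict: bool = True,
) -> RegionSet:
    """Read a BED3+ file into a :class:`RegionSet`.

    The first three columns are chrom / start / end (0-based, half-open);
    extra columns are ignored; ``track``/``browser``/``#`` lines are
    skipped.  Records on chromosomes absent from *genome* are dropped
    with a logged count.  Invalid coordinates raise in strict mode
    (default) and are dropped with a warning in lenient mode.
    """
    if name is None:
        name = Path(path).stem
    chrom_idx: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    n_unknown = 0
    n_invalid = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if chrom not in genome:
                n_unknown += 1
                continue
            ci = genome.index(chrom)
            problem = None
            if start < 0:
                problem = "negative start"
            elif start >= end:
                problem = "start >= end"
            elif end > genome.lengths[ci]:
                problem = "end beyond chromosome"
            if problem is not None:
                if strict:
                    raise ValueError(
                        f"{path}:{lineno}: {problem} ({chrom}:{start}-{end})"
                    )
                n_invalid += 1
                continue
            chrom_idx.append(ci)
            starts.append(start)
            ends.append(end)
    if n_unknown:
        logger.info(
            "read_bed(%s): dropped %d record(s) on chromosomes absent from genome",
            path,
            n_unknown,
        )
    if n_invalid:
        logger.warning(
            "read_bed(%s): dropped %d invalid record(s) (lenient mode)", path, n_invalid
        )
    return RegionSet.from_arrays(
        name,
        genome,
        np.asarray(chrom_idx, dtype=np.int64),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        presorted=False,
        validate=False,  # validated field-by-field above
    )


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3, one line per interval, in set order.

    ``read_bed(write_bed(X))`` reproduces X exactly (duplicates included).
    """
    with open(path, "w") as fh:
        names = regions.genome.names
        for ci, s, e in zip(regions.chrom_idx, regions.starts, regions.ends):
            fh.write(f"{names[int(ci)]}\t{int(s)}\t{int(e)}\n")
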