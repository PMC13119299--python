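"""Interval algebra and overlap statistics.

The central primitive is count-once overlap counting: the number of
query regions that intersect at least one reference region.  Overlap
means >= 1 shared base under half-open arithmetic — intervals sharing
only a boundary coordinate do not overlap (but they do merge, by the
usual BED convention that adjacent half-open intervals are mergeable).

Query sets are never merged before counting; counts refer to input
records, so a duplicated query interval counts twice.

The hot path used by the permutation machinery works directly on the
numpy arrays of a :class:`~regiondiff.genome.RegionSet`: the reference
is merged once per chromosome, and each query interval is located with
a single ``searchsorted`` against the merged ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .genome import GenomeDef, RegionSet, _merge_sorted

__all__ = [
    "OverlapCount",
    "count_overlaps",
    "overlap_fraction",
    "filter_overlapping",
    "merge_regions",
    "coverage_bp",
    "merged_reference",
    "overlap_flags",
]


@dataclass(frozen=True)
class OverlapCount:
    """Result of counting query regions overlapping a reference set."""

    query_name: str
    reference_name: str
    n_query: int
    n_overlapping: int
    min_overlap_bp: int = 1
    count_mode: Literal["once", "pairwise"] = "once"

    def __post_init__(self):
        if self.count_mode == "once" and not 0 <= self.n_overlapping <= self.n_query:
            raise ValueError("0 <= n_overlapping <= n_query violated")


def _check_same_genome(a: RegionSet, b: RegionSet) -> None:
    if a.genome is not b.genome and a.genome.names != b.genome.names:
        raise ValueError(
            f"region sets {a.name!r} and {b.name!r} are bound to different genomes"
        )


def merged_reference(reference: RegionSet) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Merged (starts, ends) arrays per chromosome index, adjacency merged."""
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    ci = reference.chrom_idx
    if ci.size == 0:
        return out
    # region set is sorted, so chromosome blocks are contiguous
    boundaries = np.flatnonzero(np.diff(ci)) + 1
    for block in np.split(np.arange(ci.size), boundaries):
        c = int(ci[block[0]])
        out[c] = _merge_sorted(reference.starts[block], reference.ends[block])
    return out


def overlap_flags(
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    merged_ref: dict[int, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Boolean flag per query interval: does it share >= 1 bp with the
    merged reference?  Query arrays need not be sorted."""
    flags = np.zeros(chrom_idx.size, dtype=bool)
    for c, (ms, me) in merged_ref.items():
        sel = chrom_idx == c
        if not sel.any():
            continue
        qs, qe = starts[sel], ends[sel]
        # first merged interval whose end is > query start
        pos = np.searchsorted(me, qs, side="right")
        hit = pos < ms.size
        hit[hit] &= ms[pos[hit]] < qe[hit]
        flags[sel] = hit
    return flags


def _overlap_flags_min_bp(
    query: RegionSet,
    reference: RegionSet,
    min_overlap_bp: int,
) -> np.ndarray:
    """Per-query flag: >= min_overlap_bp shared with at least one single
    reference interval (not the merged union).  Cold path, O(n·m) per
    chromosome block — adequate for the non-default min_overlap_bp use."""
    flags = np.zeros(len(query), dtype=bool)
    ref_by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    ci = reference.chrom_idx
    if ci.size:
        boundaries = np.flatnonzero(np.diff(ci)) + 1
        for block in np.split(np.arange(ci.size), boundaries):
            c = int(ci[block[0]])
            ref_by_chrom[c] = (reference.starts[block], reference.ends[block])
    for i in range(len(query)):
        c = int(query.chrom_idx[i])
        if c not in ref_by_chrom:
            continue
        rs, re = ref_by_chrom[c]
        ov = np.minimum(query.ends[i], re) - np.maximum(query.starts[i], rs)
        flags[i] = bool((ov >= min_overlap_bp).any())
    return flags


def _pairwise_count(query: RegionSet, reference: RegionSet, min_overlap_bp: int) -> int:
    """Total number of (query, reference) interval pairs sharing
    >= min_overlap_bp bases."""
    total = 0
    ci = reference.chrom_idx
    ref_by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if ci.size:
        boundaries = np.flatnonzero(np.diff(ci)) + 1
        for block in np.split(np.arange(ci.size), boundaries):
            c = int(ci[block[0]])
            ref_by_chrom[c] = (reference.starts[block], reference.ends[block])
    for i in range(len(query)):
        c = int(query.chrom_idx[i])
        if c not in ref_by_chrom:
            continue
        rs, re = ref_by_chrom[c]
        ov = np.minimum(query.ends[i], re) - np.maximum(query.starts[i], rs)
        total += int((ov >= min_overlap_bp).sum())
    return total


def count_overlaps(
    query: RegionSet,
    reference: RegionSet,
    min_overlap_bp: int = 1,
    count_mode: Literal["once", "pairwise"] = "once",
) -> OverlapCount:
    """Count query regions overlapping the reference set.

    With the default count-once semantics each query interval is counted
    at most once, however many reference intervals it touches; this is
    the observed-overlaps statistic of the permutation tests.  With
    ``count_mode="pairwise"`` every overlapping (query, reference) pair
    counts.
    """
    _check_same_genome(query, reference)
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if count_mode == "pairwise":
        n = _pairwise_count(query, reference, min_overlap_bp)
    elif min_overlap_bp == 1:
        flags = overlap_flags(
            query.chrom_idx, query.starts, query.ends, merged_reference(reference)
        )
        n = int(flags.sum())
    else:
        n = int(_overlap_flags_min_bp(query, reference, min_overlap_bp).sum())
    return OverlapCount(
        query_name=query.name,
        reference_name=reference.name,
        n_query=len(query),
        n_overlapping=n,
        min_overlap_bp=min_overlap_bp,
        count_mode=count_mode,
    )


def overlap_fraction(query: RegionSet, reference: RegionSet) -> float:
    """Fraction of query regions overlapping the reference (count-once)."""
    if len(query) == 0:
        raise ValueError("undefined fraction: empty query set")
    oc = count_overlaps(query, reference)
    return oc.n_overlapping / oc.n_query


def filter_overlapping(
    query: RegionSet,
    reference: RegionSet,
    keep: Literal["overlapping", "non_overlapping"],
) -> RegionSet:
    """Subset query intervals by overlap status against the reference.

    Order is preserved; the two complementary filters partition the
    query exactly.
    """
    _check_same_genome(query, reference)
    if keep not in ("overlapping", "non_overlapping"):
        raise ValueError(f"keep must be 'overlapping' or 'non_overlapping', got {keep!r}")
    flags = overlap_flags(
        query.chrom_idx, query.starts, query.ends, merged_reference(reference)
    )
    if keep == "non_overlapping":
        flags = ~flags
    return query.subset(flags, name=f"{query.name}|{keep}:{reference.name}")


def merge_regions(regions: RegionSet) -> RegionSet:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Adjacent half-open intervals merge; idempotent.
    """
    merged = merged_reference(regions)
    if not merged:
        return RegionSet.from_arrays(
            f"{regions.name}|merged",
            regions.genome,
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            presorted=True,
            validate=False,
        )
    chroms = sorted(merged)
    ci = np.concatenate([np.full(merged[c][0].size, c, dtype=np.int64) for c in chroms])
    st = np.concatenate([merged[c][0] for c in chroms])
    en = np.concatenate([merged[c][1] for c in chroms])
    return RegionSet.from_arrays(
        f"{regions.name}|merged", regions.genome, ci, st, en,
        presorted=True, validate=False,
    )


def coverage_bp(regions: RegionSet) -> int:
    """Total bases covered by the (merged) region set."""
    total = 0
    for ms, me in merged_reference(regions).values():
        total += int((me - ms).sum())
    return total
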