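"""Synthetic genomes and region sets with planted enrichment.

The generator emulates the statistical structure the enrichment tests
assume: a background of peaks placed uniformly over a small genome,
plus a configurable *planted fraction* ``f`` of query regions anchored
to overlap a reference region.  Because planted regions are clipped so
that at least one base of overlap with their anchor is guaranteed,
``f`` is an exact lower bound on the query/reference overlap fraction,
which gives clean analytic expectations for calibration and power
experiments.

Default scale (desk-sized, peak-like): a 2-chromosome genome of
10 Mb + 5 Mb, 500 reference regions, 300 query regions, lengths uniform
in 200–600 bp.  At this scale a background query region overlaps the
reference ~1–5% of the time, so null and enriched scenarios are well
separated without being degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .genome import GenomeDef, RegionSet, write_bed
from .randomize import RandomizationPolicy, _draw_genome_wide

__all__ = [
    "SyntheticConfig",
    "ScenarioBundle",
    "make_genome",
    "sample_lengths",
    "sample_regions",
    "plant_enriched_query",
    "make_scenario",
    "write_bundle",
]

DEFAULT_GENOME: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 5_000_000))

# length_model forms:
#   ("fixed", L) | ("uniform", Lmin, Lmax) | ("lognormal", mu, sigma, Lmin, Lmax)
LengthModel = tuple


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic region-set generator.

    ``planted_fraction`` is the probability each query region is
    anchored onto a uniformly chosen reference region; ``jitter`` is the
    maximum offset (bp) of a planted start from its anchor's start,
    clipped so >= 1 bp of overlap survives.
    """

    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_reference: int = 500
    n_query: int = 300
    length_model: LengthModel = ("uniform", 200, 600)
    planted_fraction: float = 0.0
    jitter: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if self.n_reference < 0 or self.n_query < 0:
            raise ValueError("region counts must be non-negative")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass(frozen=True)
class ScenarioBundle:
    """A reproducible simulation scenario: genome, reference set, one or
    more query sets, and per-query hidden truth vectors (True = planted)."""

    scenario: str
    config: SyntheticConfig
    genome: GenomeDef
    reference: RegionSet
    queries: dict[str, RegionSet]
    truth: dict[str, np.ndarray]


def make_genome(spec: Sequence[tuple[str, int]]) -> GenomeDef:
    """Build an unmasked GenomeDef from (name, length) pairs."""
    return GenomeDef(list(spec))


def sample_lengths(model: LengthModel, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = model[0]
    if kind == "fixed":
        (L,) = model[1:]
        lens = np.full(n, int(L), dtype=np.int64)
    elif kind == "uniform":
        lmin, lmax = model[1:]
        lens = rng.integers(int(lmin), int(lmax) + 1, size=n, dtype=np.int64)
    elif kind == "lognormal":
        mu, sigma, lmin, lmax = model[1:]
        lens = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
        lens = np.clip(lens, int(lmin), int(lmax))
    else:
        raise ValueError(f"unknown length model {kind!r}")
    if n and lens.min() < 1:
        raise ValueError("region lengths must be >= 1")
    return lens


def sample_regions(
    genome: GenomeDef,
    n: int,
    length_model: LengthModel,
    rng: np.random.Generator,
    name: str = "regions",
) -> RegionSet:
    """Place ``n`` background regions: chromosome chosen with probability
    proportional to its placeable span for each region's length, start
    uniform over that span."""
    lens = sample_lengths(length_model, n, rng)
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return RegionSet.from_arrays(name, genome, e, e, e, presorted=True, validate=False)
    if lens.max() > genome.lengths.max():
        raise ValueError("region length exceeds every chromosome")
    policy = RandomizationPolicy()  # placement only; mask honored if present
    ci, st = _draw_genome_wide(lens, genome, policy, rng)
    return RegionSet.from_arrays(
        name, genome, ci, st, st + lens, presorted=False, validate=True
    )


def plant_enriched_query(
    reference: RegionSet,
    config: SyntheticConfig,
    rng: np.random.Generator,
    name: str = "query",
) -> tuple[RegionSet, np.ndarray]:
    """Generate a query set in which each region is planted onto the
    reference with probability ``config.planted_fraction``.

    Planted regions copy their anchor's chromosome and take a start
    jittered around the anchor's start, clipped so the region stays on
    the chromosome and keeps >= 1 bp of overlap with the anchor.
    Background regions are placed as :func:`sample_regions`.

    Returns the sorted RegionSet and the aligned boolean truth vector
    (True = planted), for power accounting.
    """
    genome = reference.genome
    f = config.planted_fraction
    n = config.n_query
    if f > 0 and len(reference) == 0:
        raise ValueError("planted_fraction > 0 requires a nonempty reference")
    lens = sample_lengths(config.length_model, n, rng)
    if n and lens.max() > genome.lengths.max():
        raise ValueError("region length exceeds every chromosome")
    planted = rng.random(n) < f
    ci = np.empty(n, dtype=np.int64)
    st = np.empty(n, dtype=np.int64)

    n_bg = int((~planted).sum())
    if n_bg:
        policy = RandomizationPolicy()
        bg_ci, bg_st = _draw_genome_wide(lens[~planted], genome, policy, rng)
        ci[~planted], st[~planted] = bg_ci, bg_st

    n_pl = int(planted.sum())
    if n_pl:
        anchors = rng.integers(0, len(reference), size=n_pl)
        a_ci = reference.chrom_idx[anchors]
        a_st = reference.starts[anchors]
        a_en = reference.ends[anchors]
        L = lens[planted]
        offset = rng.integers(-config.jitter, config.jitter + 1, size=n_pl)
        s = a_st + offset
        # clip: stay on chromosome and keep >= 1 bp overlap with the anchor
        lo = np.maximum(0, a_st - L + 1)
        hi = np.minimum(genome.lengths[a_ci] - L, a_en - 1)
        s = np.clip(s, lo, hi)
        ci[planted], st[planted] = a_ci, s

    order = np.lexsort((st + lens, st, ci))
    return (
        RegionSet.from_arrays(
            name, genome, ci[order], st[order], (st + lens)[order],
            presorted=True, validate=True,
        ),
        planted[order],
    )


def make_scenario(
    name: Literal["null", "enriched", "differential"],
    config: SyntheticConfig | None = None,
) -> ScenarioBundle:
    """Build a reproducible scenario bundle.

    * ``null`` — two query sets, both pure background (f = 0).
    * ``enriched`` — one query set with the configured planted fraction.
    * ``differential`` — ``query_1`` with the configured planted
      fraction, ``query_2`` pure background, equal sizes.
    """
    if config is None:
        config = SyntheticConfig()
    genome = make_genome(config.genome)
    ref_rng = np.random.default_rng([config.seed, 101])
    reference = sample_regions(
        genome, config.n_reference, config.length_model, ref_rng, name="reference"
    )
    queries: dict[str, RegionSet] = {}
    truth: dict[str, np.ndarray] = {}

    def _query(qname: str, f: float, stream: int) -> None:
        qcfg = SyntheticConfig(
            genome=config.genome,
            n_reference=config.n_reference,
            n_query=config.n_query,
            length_model=config.length_model,
            planted_fraction=f,
            jitter=config.jitter,
            seed=config.seed,
        )
        qrng = np.random.default_rng([config.seed, stream])
        q, t = plant_enriched_query(reference, qcfg, qrng, name=qname)
        queries[qname] = q
        truth[qname] = t

    if name == "null":
        _query("query_1", 0.0, 201)
        _query("query_2", 0.0, 202)
    elif name == "enriched":
        _query("query_1", config.planted_fraction, 201)
    elif name == "differential":
        _query("query_1", config.planted_fraction, 201)
        _query("query_2", 0.0, 202)
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return ScenarioBundle(
        scenario=name,
        config=config,
        genome=genome,
        reference=reference,
        queries=queries,
        truth=truth,
    )


def write_bundle(bundle: ScenarioBundle, out_dir: str | Path) -> None:
    """Write a scenario bundle as chrom.sizes + BED files + truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.chrom.sizes", "w") as fh:
        for name, length in zip(bundle.genome.names, bundle.genome.lengths):
            fh.write(f"{name}\t{int(length)}\n")
    write_bed(bundle.reference, out / "reference.bed")
    for qname, q in bundle.queries.items():
        write_bed(q, out / f"{qname}.bed")
        with open(out / f"{qname}.truth.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tplanted\n")
            for iv, t in zip(q, bundle.truth[qname]):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{int(t)}\n")
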