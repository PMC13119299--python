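"""Manifest-driven orchestration of a full region-set enrichment run.

A YAML manifest declares the genome, the region sets, and four kinds of
jobs: enrichment (single-set permutation tests), differential
(two-set differential permutation tests), colocalization (2x2
contingency + Yates chi-square), and filter chains (sequential overlap
filters with per-step counts).  One manifest-level seed drives every
job through per-job substreams, so a run is reproducible bit-for-bit.

Outputs: ``enrichment.tsv``, ``differential.tsv``,
``colocalization.tsv``, ``filters.tsv``, ``run.json`` and ``run.log``
in the output directory.  Job-level failures are recorded in the report
and the run continues; the CLI exits nonzero if any job failed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeDef, RegionSet, read_bed, read_chrom_sizes
from .overlap import filter_overlapping
from .randomize import RandomizationPolicy
from .stats import (
    bh_adjust,
    colocalization_table,
    diff_perm_test,
    perm_test,
    yates_chi2,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_manifest", "filter_chain"]

_KIND_CODES = {"enrichment": 1, "differential": 2, "colocalization": 3, "filters": 4}


@dataclass
class RunManifest:
    """Declarative description of an analysis run (parsed YAML)."""

    genome: str
    region_sets: dict[str, str]
    mask: str | None = None
    policy: dict[str, Any] = field(default_factory=dict)
    enrichment: list[dict[str, Any]] = field(default_factory=list)
    differential: list[dict[str, Any]] = field(default_factory=list)
    colocalization: list[dict[str, Any]] = field(default_factory=list)
    filters: list[dict[str, Any]] = field(default_factory=list)
    multiple_testing: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown manifest key(s): {', '.join(sorted(unknown))}")
        if "genome" not in raw:
            raise ValueError("manifest missing required key 'genome'")
        return cls(**raw)

    def base_seed(self) -> int:
        return int(self.policy.get("seed", 0))


def _job_seed(base_seed: int, kind: str, index: int) -> int:
    """Deterministic per-job substream seed, < 2^31."""
    ss = np.random.SeedSequence([base_seed, _KIND_CODES[kind], index])
    return int(ss.generate_state(1)[0] % (2**31))


def _job_policy(manifest: RunManifest, kind: str, index: int) -> RandomizationPolicy:
    pol = manifest.policy
    return RandomizationPolicy(
        strategy=pol.get("strategy", "per_chromosome"),
        allow_self_overlap=bool(pol.get("allow_self_overlap", True)),
        respect_mask=bool(pol.get("respect_mask", True)),
        seed=_job_seed(manifest.base_seed(), kind, index),
        max_retries=int(pol.get("max_retries", 1000)),
    )


def filter_chain(
    base: RegionSet,
    steps: Sequence[tuple[str, str]],
    resolve: dict[str, RegionSet],
) -> tuple[RegionSet, list[int]]:
    """Apply an ordered chain of overlap filters.

    ``steps`` is a sequence of ``(reference name, keep)`` pairs with
    ``keep`` in {"overlapping", "non_overlapping"}.  Returns the final
    set and the counts after each stage, starting with the base count;
    counts are monotonically non-increasing.
    """
    counts = [len(base)]
    current = base
    for ref_name, keep in steps:
        if ref_name not in resolve:
            raise KeyError(f"unresolved set {ref_name!r} in filter chain")
        current = filter_overlapping(current, resolve[ref_name], keep)
        counts.append(len(current))
    return current, counts


def _resolve(sets: dict[str, RegionSet], name: str) -> RegionSet:
    if name not in sets:
        raise KeyError(f"unresolved set {name!r}")
    return sets[name]


def run_manifest(manifest: RunManifest, out_dir: str | Path) -> dict[str, Any]:
    """Execute every job in the manifest and write the report bundle.

    Returns the report dict (also serialized to ``run.json``); the
    ``n_failed`` entry counts job-level errors.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    run_logger = logging.getLogger("regiondiff.run")
    run_logger.setLevel(logging.INFO)
    run_logger.addHandler(handler)

    errors: list[dict[str, str]] = []
    try:
        genome = read_chrom_sizes(manifest.genome)
        if manifest.mask:
            mask_rs = read_bed(manifest.mask, genome, name="mask")
            genome = GenomeDef(
                list(zip(genome.names, (int(x) for x in genome.lengths))),
                mask=[(iv.chrom, iv.start, iv.end) for iv in mask_rs],
            )
        sets: dict[str, RegionSet] = {}
        for name, path in manifest.region_sets.items():
            sets[name] = read_bed(path, genome, name=name)
            run_logger.info("loaded %s: %d regions from %s", name, len(sets[name]), path)
    except Exception as exc:
        run_logger.error("manifest setup failed: %s", exc)
        run_logger.removeHandler(handler)
        handler.close()
        raise

    def _policy_echo(policy: RandomizationPolicy) -> dict[str, Any]:
        return {
            "strategy": policy.strategy,
            "policy_seed": policy.seed,
            "allow_self_overlap": policy.allow_self_overlap,
            "respect_mask": policy.respect_mask,
            "version": __version__,
        }

    def _persist_null(vector, kind: str, index: int) -> None:
        """Audit sidecar: the raw null vector of one permutation job."""
        with open(out / f"{kind}_{index}.null.tsv", "w") as fh:
            fh.write("draw\tcount\n")
            for j, v in enumerate(vector):
                fh.write(f"{j}\t{int(v)}\n")

    enrich_rows: list[dict[str, Any]] = []
    for i, job in enumerate(manifest.enrichment):
        policy = _job_policy(manifest, "enrichment", i)
        t0 = time.perf_counter()
        try:
            res = perm_test(
                _resolve(sets, job["query"]),
                _resolve(sets, job["reference"]),
                genome,
                policy,
                n_perm=int(job.get("n_perm", 500)),
                alternative=job.get("alternative", "greater"),
                min_overlap_bp=int(job.get("min_overlap_bp", 1)),
                keep_null=bool(job.get("persist_null", False)),
            )
            if res.null_counts is not None:
                _persist_null(res.null_counts, "enrichment", i)
            enrich_rows.append(
                {
                    "query": res.query_name,
                    "reference": res.reference_name,
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "z": "NA" if res.z is None else res.z,
                    "p_empirical": res.p_empirical,
                    "threshold_count_at_p05": res.threshold_count_at_p05,
                    "n_perm": res.n_perm,
                    "alternative": res.alternative,
                    **_policy_echo(policy),
                }
            )
            run_logger.info(
                "enrichment[%d] %s vs %s: obs=%d z=%s p=%g (%.2fs)",
                i, job["query"], job["reference"], res.observed, res.z,
                res.p_empirical, time.perf_counter() - t0,
            )
        except Exception as exc:
            errors.append({"job": f"enrichment[{i}]", "error": str(exc)})
            run_logger.error("enrichment[%d] failed: %s", i, exc)

    diff_rows: list[dict[str, Any]] = []
    for i, job in enumerate(manifest.differential):
        policy = _job_policy(manifest, "differential", i)
        t0 = time.perf_counter()
        try:
            res = diff_perm_test(
                _resolve(sets, job["query_1"]),
                _resolve(sets, job["query_2"]),
                _resolve(sets, job["reference"]),
                genome,
                policy,
                n_perm=int(job.get("n_perm", 1000)),
                alternative=job.get("alternative", "greater"),
                min_overlap_bp=int(job.get("min_overlap_bp", 1)),
                randomize=job.get("randomize", "both"),
                keep_null=bool(job.get("persist_null", False)),
            )
            if res.null_diffs is not None:
                _persist_null(res.null_diffs, "differential", i)
            diff_rows.append(
                {
                    "query_1": res.query_1_name,
                    "query_2": res.query_2_name,
                    "reference": res.reference_name,
                    "observed_1": res.observed_1,
                    "observed_2": res.observed_2,
                    "observed_diff": res.observed_diff,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "z": "NA" if res.z is None else res.z,
                    "p_empirical": res.p_empirical,
                    "n_perm": res.n_perm,
                    "alternative": res.alternative,
                    "randomize": res.randomize,
                    **_policy_echo(policy),
                }
            )
            run_logger.info(
                "differential[%d] %s-%s vs %s: diff=%d z=%s p=%g (%.2fs)",
                i, job["query_1"], job["query_2"], job["reference"],
                res.observed_diff, res.z, res.p_empirical, time.perf_counter() - t0,
            )
        except Exception as exc:
            errors.append({"job": f"differential[{i}]", "error": str(exc)})
            run_logger.error("differential[%d] failed: %s", i, exc)

    coloc_rows: list[dict[str, Any]] = []
    for i, job in enumerate(manifest.colocalization):
        try:
            companions = [_resolve(sets, c) for c in job["companions"]]
            table = colocalization_table(
                _resolve(sets, job["set_1"]),
                _resolve(sets, job["set_2"]),
                companions,
                mode=job.get("mode", "any"),
            )
            stat, p, df = yates_chi2(table)
            coloc_rows.append(
                {
                    "set_1": job["set_1"],
                    "set_2": job["set_2"],
                    "companions": ",".join(job["companions"]),
                    "mode": job.get("mode", "any"),
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "chi2_yates": stat,
                    "p": p,
                    "df": df,
                    "version": __version__,
                }
            )
            run_logger.info(
                "colocalization[%d] %s vs %s: chi2=%.4f p=%g",
                i, job["set_1"], job["set_2"], stat, p,
            )
        except Exception as exc:
            errors.append({"job": f"colocalization[{i}]", "error": str(exc)})
            run_logger.error("colocalization[%d] failed: %s", i, exc)

    filter_rows: list[dict[str, Any]] = []
    for i, job in enumerate(manifest.filters):
        try:
            base = _resolve(sets, job["base"])
            steps = [(s["reference"], s["keep"]) for s in job.get("steps", [])]
            final, counts = filter_chain(base, steps, sets)
            for stage, count in enumerate(counts):
                filter_rows.append(
                    {
                        "chain": job.get("name", f"chain_{i}"),
                        "stage": stage,
                        "reference": "-" if stage == 0 else steps[stage - 1][0],
                        "keep": "-" if stage == 0 else steps[stage - 1][1],
                        "count": count,
                        "version": __version__,
                    }
                )
            run_logger.info("filters[%d] %s: counts=%s", i, job.get("name", i), counts)
        except Exception as exc:
            errors.append({"job": f"filters[{i}]", "error": str(exc)})
            run_logger.error("filters[%d] failed: %s", i, exc)

    if manifest.multiple_testing:
        all_p = [r["p_empirical"] for r in enrich_rows] + [
            r["p_empirical"] for r in diff_rows
        ]
        adj = bh_adjust(all_p)
        for r, q in zip(enrich_rows + diff_rows, adj):
            r["p_bh"] = float(q)

    def _write_tsv(rows: list[dict[str, Any]], name: str) -> None:
        df = pd.DataFrame(rows)
        df.to_csv(out / name, sep="\t", index=False)

    _write_tsv(enrich_rows, "enrichment.tsv")
    _write_tsv(diff_rows, "differential.tsv")
    _write_tsv(coloc_rows, "colocalization.tsv")
    _write_tsv(filter_rows, "filters.tsv")

    report = {
        "version": __version__,
        "seed": manifest.base_seed(),
        "n_jobs": {
            "enrichment": len(manifest.enrichment),
            "differential": len(manifest.differential),
            "colocalization": len(manifest.colocalization),
            "filters": len(manifest.filters),
        },
        "n_failed": len(errors),
        "errors": errors,
        "enrichment": enrich_rows,
        "differential": diff_rows,
        "colocalization": coloc_rows,
        "filters": filter_rows,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(report, fh, indent=2)
    run_logger.removeHandler(handler)
    handler.close()
    return report
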