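"""End-to-end pipeline: encode -> filter -> subset -> fit -> evaluate ->
rank -> groups, with a run manifest for exact reproducibility.

Each run writes a bundle of delimited-text outputs into one directory:

* ``summary.tsv`` — genotype-class counts by sex;
* ``origin_matrix.tsv`` — filtered origin-score matrix;
* ``excluded.tsv`` — ineligible subjects with reasons;
* ``country_counts.tsv`` — per-country referral counts and retention;
* ``evaluation.txt`` — scheme, per-resample AUCs, mean AUC, skips;
* ``coefficients.tsv`` — per-resample coefficient vectors;
* ``ranking.tsv`` — countries by mean coefficient;
* ``dose_top.tsv`` / ``dose_bottom.tsv`` — prevalence by grandparent dose;
* ``manifest.json`` — command, config, seed, inputs/outputs, version, timings.

Identical inputs and seed give an identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_io import Cohort, read_cohort
from .evaluation import bootstrap_evaluate, kfold_evaluate, rank_countries
from .genotype_summary import modeling_subset, summarize_cohort
from .group_analysis import dose_prevalence, select_groups
from .logistic_model import make_feature_table
from .origin_score import build_matrix, filter_countries

__all__ = ["PipelineResult", "run_pipeline", "parse_variant_target"]


def parse_variant_target(target: str) -> tuple[str, str]:
    """Map a CLI target like ``M694V`` or ``M694V-hmz`` to
    (variant, outcome)."""
    if target.endswith("-hmz"):
        return target[: -len("-hmz")], "homozygous"
    return target, "carrier"


@dataclass
class PipelineResult:
    """In-memory bundle of one pipeline run."""

    summary: object
    matrix_full: pd.DataFrame
    matrix: pd.DataFrame
    country_filter: object
    excluded: dict
    report: object
    ranking: object
    top_group: tuple
    bottom_group: tuple
    dose_top: pd.DataFrame
    dose_bottom: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cohort_path: str | Path | None,
    variant_target: str,
    scheme: str = "kfold",
    out_dir: str | Path | None = None,
    *,
    cohort: Cohort | None = None,
    seed: int = 0,
    k: int = 10,
    B: int = 1000,
    min_referrals: int = 15,
    group_size: int = 4,
    penalty: str = "ridge",
    lam: float = 1.0,
    dose_on_modeling_subset: bool = False,
) -> PipelineResult:
    """Run the full association pipeline for one variant target.

    ``variant_target`` is a variant name, optionally suffixed ``-hmz`` for
    the homozygosity outcome.  Either ``cohort_path`` or a pre-loaded
    ``cohort`` must be given.  When ``out_dir`` is set, the output bundle
    and manifest are written there.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    if cohort is None:
        if cohort_path is None:
            raise ValueError("either cohort_path or cohort is required")
        cohort = read_cohort(cohort_path)
    variant, outcome = parse_variant_target(variant_target)
    timings["load"] = time.perf_counter() - t0

    t = time.perf_counter()
    summary = summarize_cohort(cohort)
    matrix_full, excluded = build_matrix(cohort)
    matrix, cfilter = filter_countries(matrix_full, min_referrals)
    timings["encode"] = time.perf_counter() - t

    t = time.perf_counter()
    subset = modeling_subset(cohort)
    table = make_feature_table(subset, matrix, variant, outcome)
    if scheme == "kfold":
        report = kfold_evaluate(table, k=k, seed=seed, penalty=penalty, lam=lam)
    elif scheme == "bootstrap":
        report = bootstrap_evaluate(table, B=B, seed=seed, penalty=penalty, lam=lam)
    else:
        raise ValueError(f"unknown scheme {scheme!r} (expected 'kfold' or 'bootstrap')")
    ranking = rank_countries(report)
    top, bottom = select_groups(ranking, group_size)
    timings["evaluate"] = time.perf_counter() - t

    t = time.perf_counter()
    dose_cohort = subset if dose_on_modeling_subset else cohort
    dose_matrix = matrix_full.loc[matrix_full.index.intersection(
        [r.subject_id for r in dose_cohort], sort=False
    )]
    dose_top = dose_prevalence(dose_cohort, dose_matrix, top, variant)
    dose_bottom = dose_prevalence(dose_cohort, dose_matrix, bottom, variant)
    timings["groups"] = time.perf_counter() - t

    result = PipelineResult(
        summary=summary,
        matrix_full=matrix_full,
        matrix=matrix,
        country_filter=cfilter,
        excluded=excluded,
        report=report,
        ranking=ranking,
        top_group=top,
        bottom_group=bottom,
        dose_top=dose_top,
        dose_bottom=dose_bottom,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), cohort_path, variant_target, scheme, seed, timings)
    return result


def _write_bundle(
    result: PipelineResult,
    out_dir: Path,
    cohort_path,
    variant_target: str,
    scheme: str,
    seed: int,
    timings: dict,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        outputs[name] = _sha256(path)

    emit("summary.tsv", lambda p: result.summary.to_frame().to_csv(p, sep="\t"))
    emit("origin_matrix.tsv", lambda p: result.matrix.to_csv(p, sep="\t"))
    emit(
        "excluded.tsv",
        lambda p: pd.Series(result.excluded, name="reason")
        .rename_axis("subject_id")
        .to_csv(p, sep="\t"),
    )
    counts = result.country_filter.counts.to_frame()
    counts["retained"] = [c in result.country_filter.retained for c in counts.index]
    emit("country_counts.tsv", lambda p: counts.rename_axis("country").to_csv(p, sep="\t"))

    def write_eval(p: Path) -> None:
        r = result.report
        lines = [
            f"scheme\t{r.scheme}",
            f"params\t{json.dumps(r.params)}",
            f"seed\t{r.seed}",
            f"resamples\t{r.n_resamples}",
            f"skipped\t{r.skipped}",
            f"mean_auc\t{r.mean_auc:.6f}",
            "per_resample_auc\t" + ",".join(f"{a:.6f}" for a in r.aucs),
        ]
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")

    emit("evaluation.txt", write_eval)
    emit("coefficients.tsv", lambda p: result.report.coef.to_csv(p, sep="\t", index_label="resample"))
    emit(
        "ranking.tsv",
        lambda p: result.ranking.to_series().rename_axis("country").to_csv(p, sep="\t"),
    )
    emit("dose_top.tsv", lambda p: result.dose_top.to_csv(p, sep="\t"))
    emit("dose_bottom.tsv", lambda p: result.dose_bottom.to_csv(p, sep="\t"))

    manifest = {
        "command": "run_pipeline",
        "package_version": __version__,
        "variant_target": variant_target,
        "scheme": scheme,
        "seed": seed,
        "input": {
            "cohort_path": str(cohort_path) if cohort_path else None,
            "sha256": _sha256(Path(cohort_path)) if cohort_path else None,
        },
        "top_group": list(result.top_group),
        "bottom_group": list(result.bottom_group),
        "outputs": outputs,
        "timings_seconds": {k: round(v, 4) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    result.manifest = manifest
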