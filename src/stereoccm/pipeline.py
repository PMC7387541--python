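"""End-to-end study pipeline: sample → area → clip → metrics → statistics.

``analyze_cohort`` runs the full stereological pipeline over an in-memory
synthetic cohort; ``run_pipeline`` is the config-file front end used by the
CLI, writing result tables and a provenance manifest.  All randomness flows
from one root seed: per-subject/per-stratum sampling seeds and per-image
nucleator phases are derived deterministically, so re-running a config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    GROUPS,
    METRIC_NAMES,
    SubjectRecord,
    ValidationError,
    write_results,
)
from .focus_area import nucleator_area
from .metrics import adjusted_and_unadjusted, aggregate_subject
from .sampling import SamplingPlan, build_pool, select_images
from .stats import (
    compare_aucs,
    correlate,
    group_compare,
    paired_methods_test,
    roc_analysis,
)
from .synthetic import Cohort, SynthParams, generate_cohort

__all__ = ["analyze_cohort", "run_pipeline", "StudyResult", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


@dataclass
class StudyResult:
    records: list                      # SubjectRecord per subject
    selection: pd.DataFrame            # image-level provenance
    group_tests: list = field(default_factory=list)
    paired_tests: list = field(default_factory=list)
    rocs: dict = field(default_factory=dict)
    auc_comparison: object | None = None
    correlations: dict = field(default_factory=dict)


def _image_rng(root_seed: int, image_id: str) -> np.random.Generator:
    key = zlib.crc32(image_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(key,)))


def analyze_cohort(
    cohort: Cohort,
    plan: SamplingPlan | None = None,
    n_rays: int = 4,
    seed: int = 0,
) -> StudyResult:
    """Run the stereological pipeline over a cohort and the study statistics.

    Per subject: classify the *visible* annotations into orientation strata,
    select images systematically, estimate each selected image's in-focus
    area with the nucleator, clip and compute adjusted/unadjusted metrics,
    and average across the subject's sampled images.  Then compare groups,
    modes and discrimination performance across subjects.
    """
    if plan is None:
        plan = SamplingPlan(seed=seed)
    records: list = []
    sel_rows: list = []
    for subj in cohort.subjects:
        by_id = {im.meta.image_id: im for im in subj.images}
        pool = build_pool(
            subj.subject_id, [(im.meta, im.visible) for im in subj.images]
        )
        if not pool.images:
            continue
        selected = select_images(pool, plan)
        per_image = []
        for sel in selected:
            sim = by_id[sel.meta.image_id]
            rng = _image_rng(seed, sel.meta.image_id)
            region = nucleator_area(sim.region, n_rays=n_rays, seed=rng, meta=sel.meta)
            adj, unadj = adjusted_and_unadjusted(sel.annotation, region, sel.meta)
            per_image.append((adj, unadj))
            sel_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "image_id": sel.meta.image_id,
                    "stratum": sel.stratum,
                    "a_after_um2": region.a_after,
                    "cnfl_adjusted": adj.cnfl,
                    "cnfl_unadjusted": unadj.cnfl,
                }
            )
        records.append(
            aggregate_subject(per_image, subj.subject_id, subj.group, ienfd=subj.ienfd)
        )
    result = StudyResult(records=records, selection=pd.DataFrame(sel_rows))
    _run_statistics(result)
    return result


def _run_statistics(result: StudyResult) -> None:
    records = result.records
    present_groups = {r.group for r in records}
    enough = len(present_groups) >= 2 and all(
        sum(r.group == g for r in records) >= 2 for g in present_groups
    )
    for metric in METRIC_NAMES:
        for mode in ("adjusted", "unadjusted"):
            if enough:
                result.group_tests.append(group_compare(records, metric, mode))
        result.paired_tests.append(paired_methods_test(records, metric))
        try:
            result.rocs[metric] = roc_analysis(records, metric, mode="adjusted")
        except ValidationError:
            pass
        a = np.array([r.metrics_adjusted for r in records])
        adj = np.array([getattr(r.metrics_adjusted, metric) for r in records])
        unadj = np.array([getattr(r.metrics_unadjusted, metric) for r in records])
        try:
            result.correlations[f"{metric}_adjusted_vs_unadjusted"] = correlate(unadj, adj)
        except ValidationError:
            pass
        ienfd = np.array([np.nan if r.ienfd is None else r.ienfd for r in records])
        if not np.any(np.isnan(ienfd)):
            try:
                result.correlations[f"{metric}_adjusted_vs_ienfd"] = correlate(ienfd, adj)
            except ValidationError:
                pass
    if all(r.ienfd is not None for r in records):
        try:
            result.rocs["ienfd"] = roc_analysis(records, "ienfd", mode="adjusted")
        except ValidationError:
            pass
    if len(result.rocs) >= 2:
        try:
            result.auc_comparison = compare_aucs(*result.rocs.values())
        except ValidationError:
            result.auc_comparison = None


# ---------------------------------------------------------------------------
# config-driven front end
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"simulate", "plan", "n_rays", "seed", "out"}
_PLAN_KEYS = {"vertical", "diagonal_left", "diagonal_right"}


def _validate_config(cfg: dict) -> list:
    errors = []
    if not isinstance(cfg, dict):
        return ["config must be a mapping"]
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    if "simulate" not in cfg:
        errors.append("config needs a 'simulate' section (synthetic-cohort parameters)")
    elif not isinstance(cfg["simulate"], dict):
        errors.append("'simulate' must be a mapping of SynthParams fields")
    else:
        valid = set(SynthParams.__dataclass_fields__)
        bad = set(cfg["simulate"]) - valid
        if bad:
            errors.append(f"unknown simulate keys: {sorted(bad)}")
    if "plan" in cfg:
        if not isinstance(cfg["plan"], dict) or set(cfg["plan"]) - _PLAN_KEYS:
            errors.append(f"'plan' must map strata {sorted(_PLAN_KEYS)} to sample sizes")
        elif any(not isinstance(v, int) or v < 0 for v in cfg["plan"].values()):
            errors.append("'plan' sample sizes must be non-negative integers")
    if "n_rays" in cfg and (not isinstance(cfg["n_rays"], int) or cfg["n_rays"] < 1):
        errors.append("'n_rays' must be a positive integer")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        errors.append("'seed' must be an integer")
    return errors


def run_pipeline(config, outdir) -> StudyResult:
    """Execute the full pipeline from a YAML config (path or mapping).

    Validates the whole config before any stage runs (all problems reported
    in one ConfigError), then simulates the cohort, analyzes it, and writes
    ``subjects.csv``, ``selection.csv``, statistical tables and a manifest
    with the config hash and row counts to ``outdir``.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = yaml.safe_load(text) or {}
    else:
        cfg = dict(config)
        text = yaml.safe_dump(cfg, sort_keys=True)
    errors = _validate_config(cfg)
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))

    seed = int(cfg.get("seed", 0))
    sim_kwargs = dict(cfg["simulate"])
    for key in ("group_sizes", "orientation_mix", "group_fiber_effects",
                "group_branch_effects", "ienfd_means"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sim_kwargs.setdefault("seed", seed)
    params = SynthParams(**sim_kwargs)
    plan_cfg = cfg.get("plan", {"vertical": 4, "diagonal_left": 2, "diagonal_right": 2})
    plan = SamplingPlan(
        strata=tuple((k, int(plan_cfg.get(k, 0))) for k in ("vertical", "diagonal_left", "diagonal_right")),
        seed=seed,
    )
    cohort = generate_cohort(params)
    result = analyze_cohort(cohort, plan=plan, n_rays=int(cfg.get("n_rays", 4)), seed=seed)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(result.records, out / "subjects.csv")
    result.selection.to_csv(out / "selection.csv", index=False)
    gt_rows = [
        {
            "metric": g.metric, "mode": g.mode, "test": g.test,
            "statistic": g.statistic, "p_value": g.p_value,
            **{f"mean_{k}": v for k, v in g.group_means.items()},
        }
        for g in result.group_tests
    ]
    pd.DataFrame(gt_rows).to_csv(out / "group_tests.csv", index=False)
    pt_rows = [
        {
            "metric": t.metric, "t": t.t_statistic, "p_value": t.p_value,
            "mean_adjusted": t.mean_a, "mean_unadjusted": t.mean_b,
            "percent_difference": t.percent_difference,
        }
        for t in result.paired_tests
    ]
    pd.DataFrame(pt_rows).to_csv(out / "paired_tests.csv", index=False)
    roc_rows = []
    for name, roc in result.rocs.items():
        for fpr, tpr, thr in zip(roc.fpr, roc.tpr, roc.thresholds):
            roc_rows.append({"metric": name, "fpr": fpr, "tpr": tpr, "threshold": thr,
                             "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high})
    pd.DataFrame(roc_rows).to_csv(out / "roc.csv", index=False)
    manifest = {
        "config_sha256": hashlib.sha256(text.encode("utf-8")).hexdigest(),
        "seed": seed,
        "n_subjects": len(result.records),
        "n_images_selected": int(len(result.selection)),
        "n_group_tests": len(result.group_tests),
        "n_paired_tests": len(result.paired_tests),
        "rocs": {k: v.auc for k, v in result.rocs.items()},
        "auc_comparison": (
            None
            if result.auc_comparison is None
            else {"chi2": result.auc_comparison.chi2, "p": result.auc_comparison.p_value,
                  "df": result.auc_comparison.df}
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
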