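"""End-to-end orchestration from a single declarative config.

A run config (YAML or dict) names a global seed and the stages to execute;
each stage either consumes a synthetic scenario or explicit input files in
the standard formats.  Outputs are written per stage in those same formats
and a ``manifest.json`` records the resolved config, the package version,
and a SHA-256 checksum of every written file, so a rerun with the same
config is bit-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chip import annotate_peaks, binding_enrichment, bound_genes, colocalization
from .ctc import estimate_ctc, fit_calibration
from .enrichment import gsea
from .io import (
    GeneSetCollection,
    read_expression,
    read_gmt,
    read_intervals,
    read_loci,
    read_survival,
    write_gmt,
    write_survival,
)
from .signature import (
    GeneSignature,
    StrataAssignment,
    bin_by_score,
    derive_signature,
    differential_expression,
    read_scores,
    score_samples,
    write_scores,
    write_strata,
)
from .simulate import (
    ChipScenario,
    ExpressionScenario,
    GseaScenario,
    SpikeScenario,
    SurvivalScenario,
    gen_chip_study,
    gen_expression_study,
    gen_gsea_study,
    gen_spikein,
    gen_survival_cohort,
)
from .survival import hazard_ratio, km_estimate, logrank_test, restrict_followup

log = logging.getLogger(__name__)

__all__ = ["load_config", "validate_config", "run_pipeline"]

STAGE_ORDER = ["expression", "survival", "gsea", "chip", "ctc"]
_SCENARIO_TYPES = {
    "expression": ExpressionScenario,
    "survival": SurvivalScenario,
    "gsea": GseaScenario,
    "chip": ChipScenario,
    "ctc": SpikeScenario,
}
_STAGE_INPUTS = {
    "expression": ["expression", "groups"],
    "survival": ["survival", "scores"],
    "gsea": ["expression", "groups", "gene_sets"],
    "chip": ["tf_peaks", "acetyl_peaks", "loci", "signature"],
    "ctc": ["spikein"],
}


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("run config must be a mapping")
    return config


def validate_config(config: dict) -> dict:
    """Light schema check; raises naming the missing or unknown field."""
    if "seed" not in config:
        raise ValueError("run config missing required field 'seed'")
    if not isinstance(config["seed"], int):
        raise ValueError("run config field 'seed' must be an integer")
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ValueError("run config missing required field 'stages'")
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages in config: {sorted(unknown)}")
    for name, spec in stages.items():
        spec = spec or {}
        if "scenario" not in spec:
            missing = [f for f in _STAGE_INPUTS[name] if f not in spec.get("inputs", {})]
            if missing:
                raise ValueError(
                    f"stage '{name}': no scenario given and input field(s) "
                    f"{missing} missing"
                )
    return config


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _scenario_cfg(stage: str, spec: dict, seed: int):
    cls = _SCENARIO_TYPES[stage]
    overrides = dict(spec.get("params", {}))
    return cls(seed=seed, **overrides)


def run_pipeline(config: dict | str | Path, out_dir) -> Path:
    """Execute every configured stage; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    stages = config["stages"]
    written: list[Path] = []
    resolved: dict[str, dict] = {}

    for name in STAGE_ORDER:
        if name not in stages:
            continue
        spec = stages[name] or {}
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        try:
            stage_seed = _stage_seed(seed, name)
            resolved[name] = {"seed": stage_seed, "spec": spec}
            if name == "expression":
                written += _run_expression(spec, stage_seed, stage_dir, resolved[name])
            elif name == "survival":
                written += _run_survival(spec, stage_seed, stage_dir, resolved[name])
            elif name == "gsea":
                written += _run_gsea(spec, stage_seed, stage_dir, resolved[name])
            elif name == "chip":
                written += _run_chip(spec, stage_seed, stage_dir, resolved[name])
            elif name == "ctc":
                written += _run_ctc(spec, stage_seed, stage_dir, resolved[name])
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": {"seed": seed, "stages": {k: v or {} for k, v in stages.items()}},
        "resolved": {
            k: {
                "seed": v["seed"],
                "params": v.get("scenario_params", {}),
            }
            for k, v in resolved.items()
        },
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _record_cfg(resolved: dict, cfg) -> None:
    resolved["scenario_params"] = dataclasses.asdict(cfg)


def _run_expression(spec, seed, stage_dir, resolved) -> list[Path]:
    if "scenario" in spec:
        cfg = _scenario_cfg("expression", spec, seed)
        _record_cfg(resolved, cfg)
        study, truth = gen_expression_study(cfg)
        with open(stage_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    else:
        inputs = spec["inputs"]
        study = read_expression(inputs["expression"], groups=inputs["groups"])
    diff = differential_expression(study, pseudocount=spec.get("pseudocount", 1.0))
    sig = derive_signature(
        diff,
        fc_threshold_log2=spec.get("fc_threshold_log2", 1.0),
        alpha=spec.get("alpha", 0.05),
    )
    diff_path = stage_dir / "differential.tsv"
    diff.table.to_csv(diff_path, sep="\t", index_label="gene_id")
    sig_path = stage_dir / "signature.gmt"
    if len(sig):
        write_gmt(GeneSetCollection(sets={"signature": set(sig.genes)}), sig_path)
    else:
        sig_path.write_text("")
    scores = score_samples(study, sig) if len(sig) else None
    out = [diff_path, sig_path]
    if scores is not None:
        write_scores(scores, stage_dir / "scores.tsv")
        out.append(stage_dir / "scores.tsv")
    if "scenario" in spec:
        out.append(stage_dir / "truth.json")
    return out


def _run_survival(spec, seed, stage_dir, resolved) -> list[Path]:
    if "scenario" in spec:
        cfg = _scenario_cfg("survival", spec, seed)
        _record_cfg(resolved, cfg)
        table, scores, truth = gen_survival_cohort(cfg)
        with open(stage_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    else:
        inputs = spec["inputs"]
        table = read_survival(inputs["survival"])
        scores = read_scores(inputs["scores"])
    strata = bin_by_score(scores, scheme=spec.get("scheme", "tertile"))
    restricted = restrict_followup(table, spec.get("horizon_months", 120.0))
    result = logrank_test(restricted, strata)
    hr = hazard_ratio(restricted, strata)
    curves = []
    for label in ("high", "low"):
        sub = restricted.subset(strata.samples_in(label))
        km = km_estimate(sub)
        curves.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "time": km.times,
                    "survival": km.survival,
                    "n_at_risk": km.n_at_risk,
                    "n_events": km.n_events,
                }
            )
        )
    out = []
    curve_path = stage_dir / "km_curves.tsv"
    pd.concat(curves).to_csv(curve_path, sep="\t", index=False)
    out.append(curve_path)
    write_survival(restricted, stage_dir / "survival_restricted.tsv")
    out.append(stage_dir / "survival_restricted.tsv")
    write_strata(strata, stage_dir / "strata.tsv")
    out.append(stage_dir / "strata.tsv")
    summary = {
        "logrank_statistic": result.statistic,
        "logrank_p": result.p,
        "observed": result.observed,
        "expected": result.expected,
        "hazard_ratio": hr.hr,
        "hr_ci_low": hr.ci_low,
        "hr_ci_high": hr.ci_high,
    }
    with open(stage_dir / "survival_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    out.append(stage_dir / "survival_summary.json")
    if "scenario" in spec:
        out.append(stage_dir / "truth.json")
    return out


def _run_gsea(spec, seed, stage_dir, resolved) -> list[Path]:
    if "scenario" in spec:
        cfg = _scenario_cfg("gsea", spec, seed)
        _record_cfg(resolved, cfg)
        study, collection, truth = gen_gsea_study(cfg)
        with open(stage_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    else:
        inputs = spec["inputs"]
        study = read_expression(inputs["expression"], groups=inputs["groups"])
        collection = read_gmt(inputs["gene_sets"])
    strata = StrataAssignment(labels=study.sample_group, scheme="labels")
    result = gsea(
        study,
        strata,
        collection,
        n_perm=spec.get("n_perm", 1000),
        seed=seed,
    )
    path = stage_dir / "gsea.tsv"
    result.table.to_csv(path, sep="\t")
    out = [path]
    if "scenario" in spec:
        out.append(stage_dir / "truth.json")
    return out


def _run_chip(spec, seed, stage_dir, resolved) -> list[Path]:
    if "scenario" in spec:
        cfg = _scenario_cfg("chip", spec, seed)
        _record_cfg(resolved, cfg)
        tf, acetyl, loci, truth = gen_chip_study(cfg)
        signature = GeneSignature(genes=truth["signature_genes"])
        with open(stage_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    else:
        inputs = spec["inputs"]
        tf = read_intervals(inputs["tf_peaks"])
        acetyl = read_intervals(inputs["acetyl_peaks"])
        loci = read_loci(inputs["loci"])
        gmt = read_gmt(inputs["signature"])
        signature = GeneSignature(genes=sorted(gmt[gmt.names[0]]))
    annotation = annotate_peaks(tf, loci)
    bound = bound_genes(annotation)
    enr = binding_enrichment(signature, bound, loci, p0=spec.get("p0"))
    sig_set = set(signature.genes)
    at_signature = annotation.table["gene"].isin(sig_set) & ~annotation.table["unannotated"]
    summary = {
        "bound_signature_genes": enr.k,
        "signature_size": enr.n,
        "background_rate": enr.p0,
        "binomial_p": enr.p,
    }
    if at_signature.any():
        coloc = colocalization(tf.subset(at_signature.to_numpy()), acetyl)
        summary["signature_peaks"] = coloc.considered
        summary["acetyl_overlapping"] = coloc.overlapping
        summary["acetyl_fraction"] = coloc.fraction
    path = stage_dir / "chip_summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    ann_path = stage_dir / "peak_annotation.tsv"
    annotation.table.to_csv(ann_path, sep="\t", index=False)
    out = [path, ann_path]
    if "scenario" in spec:
        out.append(stage_dir / "truth.json")
    return out


def _run_ctc(spec, seed, stage_dir, resolved) -> list[Path]:
    if "scenario" in spec:
        cfg = _scenario_cfg("ctc", spec, seed)
        _record_cfg(resolved, cfg)
        counts, lum, truth = gen_spikein(cfg)
        with open(stage_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    else:
        df = pd.read_csv(spec["inputs"]["spikein"], sep="\t")
        counts, lum = df["count"].to_numpy(), df["luminescence"].to_numpy()
    fit = fit_calibration(counts, lum)
    summary = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "residual_sd": fit.residual_sd,
        "n_points": fit.n_points,
    }
    readings = spec.get("readings", [])
    if readings:
        estimates = [
            estimate_ctc(r, fit, spec.get("sample_volume_ml", 0.4)) for r in readings
        ]
        summary["estimates"] = [
            {"reading": r, "cells": e.cells, "cells_per_ml": e.cells_per_ml, "clamped": e.clamped}
            for r, e in zip(readings, estimates)
        ]
    path = stage_dir / "ctc_summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    out = [path]
    if "scenario" in spec:
        out.append(stage_dir / "truth.json")
    return out
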