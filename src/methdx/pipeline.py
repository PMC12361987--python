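"""End-to-end discovery pipeline and its report writers.

``run_discovery_pipeline`` executes split -> beta calling -> DMS
discovery -> stability selection -> logistic fit -> evaluation on the
train and validation cohorts, writing a reproducible report bundle
(model JSON, metrics TSV/JSON, DMS table, selection counts, ROC points,
and a log with the config hash and per-stage seeds).  Per-stage seeds
are derived by hashing (master seed, stage name) so stages have
independent but reproducible random streams.  Re-running an identical
config reproduces identical outputs; no stage mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from methdx import calling, diagnostic, dms, selection, simulate


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Flat, fail-fast pipeline configuration (YAML key-value file)."""

    outdir: str = "methdx_run"
    seed: int = 0
    # input: either synthetic design (default) or coverage files on disk
    synthetic: bool = True
    coverage_dir: str | None = None
    metadata_path: str | None = None
    # synthetic design
    n_cases: int = 56
    n_controls: int = 44
    n_sites: int = 2000
    n_dms: int = 6
    delta_target: float = 0.3
    mean_coverage: float = 200.0
    detection_rate: float = 0.9
    # calling
    conversion_efficiency: float = 0.99
    min_coverage: int = 30
    # split
    split_ratio: float = 0.7
    # DMS thresholds
    threshold_preset: str = "tissue"     # tissue | plasma
    max_fdr: float | None = None
    max_p: float | None = None
    min_abs_delta: float | None = None
    min_detect: float = 0.65
    # stability selection
    n_subsamples: int = 500
    subsample_fraction: float = 0.8
    freq_threshold: int = 450
    cv_folds: int = 10
    lambda_rule: str = "one_se"
    # model
    use_covariates: bool = True
    classification_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> dms.DMSThresholds:
        base = dms.DMSThresholds.tissue() if self.threshold_preset == "tissue" else dms.DMSThresholds.plasma()
        return dms.DMSThresholds(
            max_fdr=self.max_fdr if self.max_fdr is not None else base.max_fdr,
            max_p=self.max_p if self.max_p is not None else base.max_p,
            min_abs_delta=self.min_abs_delta if self.min_abs_delta is not None else base.min_abs_delta,
            min_detect=self.min_detect,
        )

    def design(self) -> simulate.SynthDesign:
        return simulate.SynthDesign(
            n_cases=self.n_cases, n_controls=self.n_controls, n_sites=self.n_sites,
            n_dms=self.n_dms, delta_target=self.delta_target,
            mean_coverage=self.mean_coverage, detection_rate=self.detection_rate,
            conversion_efficiency=self.conversion_efficiency,
            seed=stage_seed(self.seed, "simulate"),
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.synthetic:
        counts, metadata, truth = simulate.simulate_cohort(config.design())
        return counts, metadata, truth
    if not config.coverage_dir or not config.metadata_path:
        raise ValueError("non-synthetic run needs coverage_dir and metadata_path")
    metadata = simulate.read_metadata(config.metadata_path)
    paths = [os.path.join(config.coverage_dir, f"{s}.cov.tsv") for s in metadata.index]
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(f"coverage file missing: {p}")
    counts = calling.read_coverage_files(paths, list(metadata.index))
    return counts, metadata, None


def run_discovery_pipeline(config: RunConfig, *, markers: list[str] | None = None) -> dict:
    """Execute the full discovery pipeline and write the report bundle.

    When ``markers`` is given, DMS discovery and stability selection are
    skipped and the supplied panel is fitted directly (used e.g. to
    evaluate a tissue-derived panel on plasma samples).
    """
    os.makedirs(config.outdir, exist_ok=True)
    log: list[str] = [f"config_hash\t{config.config_hash()}"]

    counts, metadata, truth = _load_inputs(config)
    log.append(f"stage_seed\tsimulate\t{stage_seed(config.seed, 'simulate')}")
    log.append(f"samples\t{metadata.shape[0]}")

    matrix = calling.call_betas(counts, e=config.conversion_efficiency,
                                min_coverage=config.min_coverage)
    log.append(f"sites_called\t{matrix.shape[0]}")

    split_sd = stage_seed(config.seed, "split")
    train, validation = diagnostic.split_cohort(list(metadata.index), config.split_ratio, split_sd)
    log.append(f"stage_seed\tsplit\t{split_sd}")
    log.append(f"train_n\t{len(train)}")
    log.append(f"validation_n\t{len(validation)}")

    labels = metadata["class"]
    report: dict = {
        "config_hash": config.config_hash(),
        "train_n": len(train), "validation_n": len(validation),
        "sites_called": int(matrix.shape[0]),
    }

    thresholds = config.thresholds()
    if markers is None:
        records = dms.discover_dms(matrix[train], labels.loc[train], thresholds)
        records.to_csv(os.path.join(config.outdir, "dms.tsv"), sep="\t", index=False)
        log.append(f"sites_detected_{int(100 * thresholds.min_detect)}pct\t{records.attrs.get('n_eligible')}")
        log.append(f"dms_discovered\t{len(records)}")
        report["n_dms_discovered"] = int(len(records))
        candidates = list(records["site_id"]) if len(records) else []

        if candidates:
            sel_cfg = selection.StabilityConfig(
                n_subsamples=config.n_subsamples,
                subsample_fraction=config.subsample_fraction,
                freq_threshold=config.freq_threshold,
                cv_folds=config.cv_folds,
                lambda_rule=config.lambda_rule,
                seed=stage_seed(config.seed, "select"),
            )
            sel = selection.stability_select(matrix.loc[candidates, train], labels.loc[train], sel_cfg)
            sel.counts.to_csv(os.path.join(config.outdir, "selection_counts.tsv"), sep="\t")
            log.append(f"stage_seed\tselect\t{sel_cfg.seed}")
            log.append(f"markers_selected\t{len(sel.selected)}")
            report["lambda"] = sel.lambda_
            report["n_markers_selected"] = len(sel.selected)
            markers = sel.selected
        else:
            markers = []
    else:
        report["n_markers_selected"] = len(markers)
        log.append(f"markers_supplied\t{len(markers)}")

    if not markers:
        report["model"] = None
        report["model_skipped_reason"] = "empty marker set after selection"
        log.append("model\tskipped\tempty marker set after selection")
    else:
        covs = diagnostic.DEFAULT_COVARIATES if config.use_covariates else ()
        model = diagnostic.DiagnosticModel(matrix[train], labels.loc[train], markers,
                                           metadata=metadata.loc[train], covariates=covs)
        results = model.fit(threshold=config.classification_threshold)
        results.to_json(os.path.join(config.outdir, "model.json"))
        report["markers"] = list(markers)
        report["ridge_used"] = results.ridge_used

        metrics_rows = []
        for cohort, ids in [("training", train), ("validation", validation)]:
            if not ids:
                continue
            ev = results.evaluate(matrix, metadata, labels.loc[ids], samples=ids)
            disp = ev["metrics"].display()
            disp["auc"] = round(ev["auc"], 3)
            cm = ev["confusion"]
            report[cohort] = {
                "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
                "metrics": disp,
                "auc": ev["auc"],
            }
            metrics_rows.append({"cohort": cohort, **disp})
            diagnostic.roc_points(ev["scores"], labels.loc[ids]).to_csv(
                os.path.join(config.outdir, f"roc_{cohort}.tsv"), sep="\t", index=False)
            log.append(f"{cohort}_auc\t{ev['auc']:.6f}")
        pd.DataFrame(metrics_rows).to_csv(os.path.join(config.outdir, "metrics.tsv"),
                                          sep="\t", index=False)

    if truth is not None:
        report["planted_sites"] = truth.planted_sites

    with open(os.path.join(config.outdir, "metrics.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
    with open(os.path.join(config.outdir, "log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
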