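"""End-to-end reproducible pipeline: curate -> select -> train -> evaluate -> DOA.

One :class:`PipelineConfig` drives the whole run; every stage writes its
artifact into the run directory (curated table, selection report, scaling
parameters, model bundles, metrics JSON, per-compound residuals, DOA
reports, manifest).  Re-running with the same config and seed reproduces
every file bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curation import curate, read_records_csv
from .evaluation import (compute_metrics, detect_outliers, kfold_cv,
                         leave_out_metrics, residual_table)
from .features import fit_scaling, select_top_k
from .models import MlpConfig, gse_predict, null_fit, save_model, train_mlp
from .domain import doa_report, fit_doa
from .synth import SyntheticConfig, generate_study

log = logging.getLogger("solqspr")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat, JSON-serialisable configuration of one pipeline run."""

    #: input paths; when None, a synthetic study is generated instead
    records_csv: str | None = None
    descriptors_csv: str | None = None
    test_csvs: dict[str, str] = field(default_factory=dict)
    gse_csvs: dict[str, str] = field(default_factory=dict)
    synthetic: SyntheticConfig | None = None

    strategy: str = "mean"
    prune_threshold: float = 0.8
    top_k: int = 10
    mlp: MlpConfig = field(default_factory=MlpConfig)
    cv_k: int = 10
    #: restart seeds; metrics are reported per seed and as mean over seeds
    seeds: list[int] = field(default_factory=lambda: [0])
    run_cv: bool = True
    run_doa: bool = True
    doa_neighbors: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["replicate_histogram"] = {
                str(k): v for k, v in self.synthetic.replicate_histogram.items()}
        return d


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    outdir: Path
    curated: object
    selection: object
    models: dict
    metrics: dict
    doa: dict
    manifest: dict


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.records_csv is not None:
        records = read_records_csv(config.records_csv)
        descriptors = pd.read_csv(config.descriptors_csv, dtype={"compound_id": str})
        tests = {name: pd.read_csv(p, dtype={"compound_id": str})
                 for name, p in config.test_csvs.items()}
        gse = {name: pd.read_csv(p, dtype={"compound_id": str})
               for name, p in config.gse_csvs.items()}
        return records, descriptors, tests, gse
    syn = config.synthetic or SyntheticConfig(seed=config.seed)
    study = generate_study(syn)
    study.write(outdir / "synthetic")
    tests = {"tight": study.test_tight, "loose": study.test_loose}
    gse = {"tight": study.gse_tight, "loose": study.gse_loose}
    return study.records, study.descriptors, tests, gse


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute every stage and persist all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, descriptors, tests, gse_tables = _load_inputs(config, outdir)
    log.info("stage=input records=%d test_sets=%d", len(records), len(tests))

    # --- curation ---------------------------------------------------------
    test_ids: set[str] = set()
    for ts in tests.values():
        test_ids |= set(ts["compound_id"].astype(str))
    curated = curate(records, descriptors, test_ids=test_ids, strategy=config.strategy)
    curated.table.to_csv(outdir / "curated.csv", index=False)
    log.info("stage=curation molecules=%d values=%d interlab_sd=%s",
             curated.summary.n_molecules, curated.summary.n_values,
             curated.summary.mean_interlab_sd)

    # --- feature selection + scaling -------------------------------------
    X, y = curated.X, curated.y.to_numpy()
    selection = select_top_k(X, pd.Series(y), k=min(config.top_k, X.shape[1]),
                             threshold=config.prune_threshold)
    selection.to_frame().to_csv(outdir / "selection.csv", index=False)
    feats = selection.selected
    scaling = fit_scaling(X[feats], y)
    scaling.to_json(outdir / "scaling.json")
    log.info("stage=selection kept=%d top=%s", len(feats), feats[0] if feats else None)

    # --- models -----------------------------------------------------------
    Xs = scaling.transform_features(X[feats])
    ys = scaling.transform_target(y)
    models = {"null": null_fit(y)}
    mlps = {}
    for s in config.seeds:
        cfg = MlpConfig(**{**config.mlp.__dict__, "seed": s})
        mlps[s] = train_mlp(Xs, ys, cfg, scaling=scaling, feature_names=feats)
    primary_seed = config.seeds[0]
    models["mlp"] = mlps[primary_seed]
    save_model(models["mlp"], outdir / "model_mlp.json")
    save_model(models["null"], outdir / "model_null.json")

    # --- evaluation -------------------------------------------------------
    metrics: dict = {"train": {}, "per_seed": {}, "outliers": {}}
    train_pred = models["mlp"].predict(curated.table)
    metrics["train"]["mlp"] = compute_metrics(y, train_pred)
    metrics["train"]["null"] = compute_metrics(y, models["null"].predict(curated.table))
    if config.run_cv and len(curated.table) >= config.cv_k:
        cv_report, cv_table = kfold_cv(X, y, config.mlp, k=config.cv_k,
                                       seed=config.seed, top_k=min(config.top_k, X.shape[1]),
                                       prune_threshold=config.prune_threshold)
        metrics["cv"] = cv_report
        cv_table.to_csv(outdir / "cv_predictions.csv", index=False)
    doa_out: dict = {}
    for name, ts in tests.items():
        y_t = ts["logS0"].to_numpy(dtype=float)
        ids = list(ts["compound_id"].astype(str))
        per_seed_rmse = []
        for s, m in mlps.items():
            rep = compute_metrics(y_t, m.predict(ts))
            metrics["per_seed"].setdefault(name, {})[s] = rep
            per_seed_rmse.append(rep.rmse)
        pred = mlps[primary_seed].predict(ts)
        metrics[name] = {"mlp": compute_metrics(y_t, pred),
                         "null": compute_metrics(y_t, models["null"].predict(ts)),
                         "mlp_rmse_mean_over_seeds": float(np.mean(per_seed_rmse)),
                         "mlp_rmse_sd_over_seeds": float(np.std(per_seed_rmse, ddof=1))
                         if len(per_seed_rmse) > 1 else 0.0}
        if name in gse_tables:
            g = gse_tables[name]
            aligned = ts[["compound_id"]].merge(g, on="compound_id", how="left")
            metrics[name]["gse"] = compute_metrics(
                y_t, gse_predict(aligned["logP"], aligned["Tmp"]))
        out_rep = detect_outliers(y_t, pred, ids)
        metrics["outliers"][name] = out_rep
        removals = [cid for cid, _ in out_rep.outliers]
        metrics[name]["after_outlier_removal"] = leave_out_metrics(
            y_t, pred, ids, removals)[-1] if removals else metrics[name]["mlp"]
        residual_table(ids, y_t, pred).to_csv(outdir / f"residuals_{name}.csv",
                                              index=False)
        log.info("stage=evaluate set=%s %s", name, metrics[name]["mlp"])
        if config.run_doa:
            doa = fit_doa(Xs)
            report = doa_report(doa, scaling.transform_features(ts[feats]), ids,
                                y_t, pred, Xs, y,
                                list(curated.table["compound_id"]),
                                outliers=out_rep, k=config.doa_neighbors)
            report.to_csv(outdir / f"doa_{name}.csv", index=False)
            doa_out[name] = {"model": doa, "report": report}
            log.info("stage=doa set=%s inside=%d/%d pc12_var=%.3f", name,
                     int(report["inside_95"].sum()), len(report),
                     float(doa.explained_variance_ratio[:2].sum()))

    # --- manifest ---------------------------------------------------------
    def _ser(obj):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        if isinstance(obj, dict):
            return {str(k): _ser(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_ser(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    (outdir / "metrics.json").write_text(json.dumps(_ser(metrics), indent=2))
    manifest = {"version": __version__, "config": config.to_dict(),
                "counts": curated.log}
    (outdir / "manifest.json").write_text(json.dumps(_ser(manifest), indent=2))
    return PipelineResult(outdir=outdir, curated=curated, selection=selection,
                          models=models, metrics=metrics, doa=doa_out,
                          manifest=manifest)
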