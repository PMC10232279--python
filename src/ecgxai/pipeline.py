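"""End-to-end pipeline orchestration.

``run_pipeline`` drives the full chain -- train, evaluate, attribute, embed,
cluster, extract decision factors, interpret criteria, categorise -- and
writes every artefact plus a manifest with content hashes and the seeds used,
so a rerun with the same configuration reproduces the deterministic outputs
byte-identically.  ``replay`` reruns the explanation stages with an existing
trained model on a second ("external") dataset: the embedding and clustering
are refitted on the new cohort, as generalisation checks of the criteria
should not inherit the internal cohort's geometry.  ``explain_one`` produces
a single-record report against persisted pipeline artefacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .attribution import BackgroundSpec, compute_attributions
from .classifiers import ModelSpec, TrainedModel, classify, train
from .criteria import categorize, extract_decision_factors, interpret_criteria
from .datamodel import PairedDataset, load_dataset, split_by_patient
from .evalstats import evaluate_predictions
from .geometry import cluster, embed, project_new, select_explanation_cohort
from .schema import ParameterSchema, default_schema


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on, with one global seed."""

    dataset_path: Optional[str] = None      # None -> caller passes a dataset
    schema_path: Optional[str] = None
    output_dir: str = "pipeline_out"
    test_fraction: float = 0.194
    model: ModelSpec = field(default_factory=ModelSpec)
    background: BackgroundSpec = field(default_factory=lambda: BackgroundSpec(size=64))
    pca_dims: int = 20
    umap_params: dict = field(default_factory=dict)
    K_max: int = 10
    min_cluster_size: int = 10
    cutoff: float = 0.5
    min_effect_sd: float = 0.2
    bootstrap_B: int = 10_000
    seed: int = 0

    def resolved_schema(self) -> ParameterSchema:
        if self.schema_path:
            return ParameterSchema.from_json(self.schema_path)
        return default_schema()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _factors_frame(factors) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cluster": f.cluster, "parameter": f.parameter,
          "median_shap": f.median_shap, "threshold": f.threshold_used}
         for f in factors],
        columns=["cluster", "parameter", "median_shap", "threshold"])


def _explain(cfg: PipelineConfig, model: TrainedModel, cohort: PairedDataset,
             reference: PairedDataset, train_values: np.ndarray, out: Path,
             manifest: dict) -> dict:
    """Attribution -> embedding -> clustering -> criteria, with artefacts."""
    attr = compute_attributions(model, cohort, cfg.background, train_values)
    attr.to_csv(out / "attributions.csv", sidecar=out / "attributions.json",
                meta={"background": vars(cfg.background)})

    emb = embed(attr, pca_dims=cfg.pca_dims, umap_params=cfg.umap_params,
                seed=cfg.seed)
    ca = cluster(emb, K_max=cfg.K_max, min_cluster_size=cfg.min_cluster_size,
                 seed=cfg.seed)
    pd.DataFrame({
        "record_id": cohort.record_ids, "x": emb.coords[:, 0],
        "y": emb.coords[:, 1], "cluster": ca.labels,
    }).to_csv(out / "embedding.csv", index=False, float_format="%.17g")

    factors = extract_decision_factors(attr, ca)
    _factors_frame(factors).to_csv(out / "decision_factors.csv", index=False,
                                   float_format="%.17g")
    crits = interpret_criteria(factors, cohort.values, ca.labels,
                               reference.values, cohort.schema,
                               min_effect_sd=cfg.min_effect_sd)
    cats = categorize(crits)
    payload = {
        "criteria": [{"cluster": c.cluster, "finding": c.finding,
                      "leads": c.leads, "direction": c.direction}
                     for c in crits],
        "categories": [cats[k].to_dict() for k in sorted(cats)],
        "unexplained_clusters": ca.unexplained,
        "effective_K": ca.effective_K,
    }
    with open(out / "criteria.json", "w") as fh:
        json.dump(payload, fh, indent=1)

    joblib.dump({"embedding": emb, "clusters": ca,
                 "background": cfg.background.draw(train_values)},
                out / "explain_state.joblib")
    for name in ["attributions.csv", "attributions.json", "embedding.csv",
                 "decision_factors.csv", "criteria.json"]:
        manifest["artifacts"][name] = _sha256(out / name)
    return payload


def run_pipeline(cfg: PipelineConfig, dataset: Optional[PairedDataset] = None) -> dict:
    """Run the full pipeline; returns the output manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "artifacts": {}}
    stage = "load"
    try:
        schema = cfg.resolved_schema()
        if dataset is None:
            if cfg.dataset_path is None:
                raise ValueError("config names no dataset and none was passed")
            dataset = load_dataset(cfg.dataset_path, schema)
        stage = "split"
        train_ds, test_ds = split_by_patient(dataset, cfg.test_fraction, cfg.seed)

        stage = "train"
        model = train(train_ds, cfg.model)
        model.save(out / "model.joblib")

        stage = "evaluate"
        probs = model.predict_proba(test_ds)
        calls = classify(probs, cfg.cutoff)
        report = evaluate_predictions(probs, calls, test_ds.reduced,
                                      B=cfg.bootstrap_B, seed=cfg.seed)
        with open(out / "metrics.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)

        stage = "attribute/cluster/criteria"
        cohort_idx = select_explanation_cohort(test_ds, probs, cfg.cutoff)
        cohort = test_ds.subset(cohort_idx)
        pd.DataFrame({"record_id": test_ds.record_ids, "probability": probs,
                      "call": calls}).to_csv(out / "predictions.csv", index=False,
                                             float_format="%.17g")
        summary = _explain(cfg, model, cohort, test_ds, train_ds.values, out,
                           manifest)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    for name in ["model.joblib", "metrics.json", "predictions.csv"]:
        manifest["artifacts"][name] = _sha256(out / name)
    manifest["cohort_size"] = len(cohort)
    manifest["effective_K"] = summary["effective_K"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def replay(cfg: PipelineConfig, model_path: str,
           dataset: Optional[PairedDataset] = None) -> dict:
    """Replay the explanation stages on an external dataset with a fitted model.

    The embedding and clustering are refitted on the external cohort; the
    trained classifier is reused unchanged.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = cfg.resolved_schema()
    if dataset is None:
        if cfg.dataset_path is None:
            raise ValueError("config names no dataset and none was passed")
        dataset = load_dataset(cfg.dataset_path, schema)
    model = TrainedModel.load(model_path)
    probs = model.predict_proba(dataset)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "mode": "external_replay", "artifacts": {}}
    cohort_idx = select_explanation_cohort(dataset, probs, cfg.cutoff)
    cohort = dataset.subset(cohort_idx, split_tag="external")
    summary = _explain(cfg, model, cohort, dataset, dataset.values, out, manifest)
    manifest["cohort_size"] = len(cohort)
    manifest["effective_K"] = summary["effective_K"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def explain_one(output_dir: str, record_values: np.ndarray,
                paced: bool = False, cutoff: float = 0.5) -> dict:
    """Single-record report against persisted pipeline artefacts.

    Returns predicted probability, the binary call, the attribution vector,
    projected 2-D coordinates, the nearest cluster and that cluster's
    decision criteria.  Paced or predicted-negative records get probability
    and attributions but no cluster membership (the explanation cohort holds
    predicted-positive, non-paced records only).
    """
    out = Path(output_dir)
    needed = ["model.joblib", "explain_state.joblib", "criteria.json",
              "attributions.json"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"pipeline artefacts missing ({missing}); run the pipeline first")
    model = TrainedModel.load(out / "model.joblib")
    state = joblib.load(out / "explain_state.joblib")
    with open(out / "criteria.json") as fh:
        crit_payload = json.load(fh)

    x = np.asarray(record_values, dtype=float).ravel()
    prob = float(model.predict_proba(x[None, :])[0])
    call = bool(prob > cutoff)
    report = {"probability": prob, "call": call, "paced": bool(paced)}

    if not call:
        report["cluster"] = None
        report["note"] = "predicted negative: no explanation cohort membership"
        return report
    if paced:
        report["cluster"] = None
        report["note"] = "paced rhythm: excluded from explanation clustering"
        return report

    attr = compute_attributions(model, x[None, :],
                                BackgroundSpec(source="full", size=1),
                                state["background"])
    row = attr.values[0]
    coords, label, resp = project_new(state["embedding"], row, state["clusters"])
    cluster_criteria = [c for c in crit_payload["criteria"] if c["cluster"] == label]
    report.update({
        "attributions": dict(zip(model.feature_names, row.tolist())),
        "coords": [float(coords[0]), float(coords[1])],
        "cluster": label,
        "responsibility": resp,
        "criteria": cluster_criteria,
    })
    return report
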