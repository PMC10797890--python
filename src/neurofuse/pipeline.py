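"""End-to-end orchestration: synthesize -> EEG features -> microstates ->
omics statistics -> fusion classification, with a manifest of every output."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import FeatureTable, write_eeg_binary
from .errors import ConfigError
from .microstate import MicrostateSegmenter, compute_gfp, microstate_metrics
from .ml import CVScheme, PipelineConfig, cv_evaluate, fuse_modalities, \
    fisher_score, minmax_normalize, select_top_k, top_contributors, train_linear_svm
from .omics import alpha_diversity, bray_curtis, differential_filter, fb_ratio, \
    relative_abundance, DifferentialCriteria
from .spectral import band_power, preprocess, roi_summary
from .synthetic import CohortConfig, EEGSimConfig, gen_cohort_features, \
    gen_microstate_eeg, gen_taxa_counts, write_ground_truth

log = logging.getLogger("neurofuse")

STAGES = ("synth", "eeg", "microstate", "omics", "classify")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "synth": {"n_group_a": 19, "n_group_b": 22, "effect_size": 1.5,
              "n_features": {"microbiome": 500, "metabolome": 300, "eeg": 400},
              "n_discriminative": {"microbiome": 10, "metabolome": 10, "eeg": 10},
              "taxa": {"n_taxa": 80, "depth": 20000},
              "eeg_sim": {"n_channels": 64, "fs": 500.0, "duration": 60.0,
                          "k_states": 4, "snr": 4.0, "mean_dwell": 80.0}},
    "eeg": {"method": "welch"},
    "microstate": {"k_min": 2, "k_max": 8, "n_peaks": 1000},
    "omics": {"fc_hi": 2.0, "fc_lo": 0.5, "p_max": 0.05},
    "classify": {"cv": "loocv", "top_k": 100, "final_k": 10, "scope": "global",
                 "tune": True},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def validate_config(config: dict) -> dict:
    config = _merge(DEFAULT_CONFIG, config or {})
    stages = config.get("stages")
    if not stages:
        raise ConfigError("missing required block 'stages'")
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
        if s not in config:
            raise ConfigError(f"missing required block {s!r}")
    if "seed" not in config:
        raise ConfigError("missing required block 'seed'")
    return config


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: dict[str, str] = {}

    def add(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path.relative_to(self.out_dir))] = digest

    def write(self, meta: dict) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps({"meta": meta, "files": self.files}, indent=1))
        return path


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Every written file is listed in ``manifest.json`` with a sha256 checksum;
    the manifest metadata records the seed, the parameter hash and the
    package version so identical configs give byte-identical numeric outputs.
    """
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir)
    param_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    log.info("run start: seed=%s params=%s", config["seed"], param_hash)
    t0 = time.time()
    state: dict = {"seed": int(config["seed"])}

    runners = {"synth": _stage_synth, "eeg": _stage_eeg,
               "microstate": _stage_microstate, "omics": _stage_omics,
               "classify": _stage_classify}
    for stage in config["stages"]:
        log.info("stage %s", stage)
        try:
            runners[stage](config[stage], state, out_dir, manifest)
        except Exception as exc:  # abort with stage name; keep partial outputs
            manifest.write({"seed": state["seed"], "param_hash": param_hash,
                            "version": __version__, "failed_stage": stage,
                            "error": str(exc)})
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest.write({"seed": state["seed"], "param_hash": param_hash,
                    "version": __version__,
                    "elapsed_s": round(time.time() - t0, 2)})
    return out_dir


def _save_df(df: pd.DataFrame, path: Path, manifest: _Manifest, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)
    manifest.add(path)


def _stage_synth(params, state, out_dir, manifest):
    seed = state["seed"]
    cfg = CohortConfig(
        n_group_a=params["n_group_a"], n_group_b=params["n_group_b"],
        n_features_per_modality=params["n_features"],
        n_discriminative=params["n_discriminative"],
        effect_size=params["effect_size"], seed=seed)
    table, truth = gen_cohort_features(cfg)
    table.to_tsv(out_dir / "features.tsv")
    manifest.add(out_dir / "features.tsv")
    write_ground_truth(truth, out_dir / "ground_truth.json")
    manifest.add(out_dir / "ground_truth.json")
    state["features"] = table

    taxa = gen_taxa_counts(
        n_samples=cfg.n_group_a + cfg.n_group_b,
        n_taxa=params["taxa"]["n_taxa"], depth=params["taxa"]["depth"],
        seed=seed + 1)
    taxa.to_tsv(out_dir / "taxa_counts.tsv")
    manifest.add(out_dir / "taxa_counts.tsv")
    manifest.add(out_dir / "taxa_counts.tsv.taxonomy")
    state["taxa"] = taxa

    sim = EEGSimConfig(seed=seed + 2, **params["eeg_sim"])
    rec, eeg_truth = gen_microstate_eeg(sim)
    raw, sidecar = write_eeg_binary(rec, out_dir / "eeg_demo")
    manifest.add(raw)
    manifest.add(sidecar)
    state["eeg"] = rec
    state["eeg_truth"] = eeg_truth


def _stage_eeg(params, state, out_dir, manifest):
    rec = state["eeg"]
    bp = band_power(preprocess(rec), method=params["method"])
    _save_df(bp.relative, out_dir / "band_power_relative.tsv", manifest,
             index_label="channel")
    _save_df(bp.absolute, out_dir / "band_power_absolute.tsv", manifest,
             index_label="channel")
    _save_df(roi_summary(bp), out_dir / "roi_band_power.tsv", manifest)


def _stage_microstate(params, state, out_dir, manifest):
    rec = state["eeg"]
    seg_model = MicrostateSegmenter(k_min=params["k_min"], k_max=params["k_max"],
                                    n_peaks=params["n_peaks"]).fit(rec)
    seg = seg_model.transform(rec)
    metrics = microstate_metrics(seg, compute_gfp(rec))
    (out_dir / "microstate_prototypes.json").write_text(json.dumps({
        "k_selected": seg_model.k_,
        "criteria": seg_model.criteria_.to_dict(orient="index"),
        "prototypes": seg_model.prototypes_.maps.tolist()}))
    manifest.add(out_dir / "microstate_prototypes.json")
    # run-length encoded segmentation: state, start sample, length
    rle = []
    labels = seg.labels
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            rle.append((int(labels[start]), start, i - start))
            start = i
    pd.DataFrame(rle, columns=["state", "start", "length"]).to_csv(
        out_dir / "segmentation_rle.tsv", sep="\t", index=False)
    manifest.add(out_dir / "segmentation_rle.tsv")
    _save_df(metrics.per_state, out_dir / "microstate_metrics.tsv", manifest,
             index_label="state")
    _save_df(metrics.transitions, out_dir / "microstate_transitions.tsv", manifest,
             index_label="from")


def _stage_omics(params, state, out_dir, manifest):
    taxa = state["taxa"]
    rel = relative_abundance(taxa)
    alpha = alpha_diversity(taxa)
    _save_df(alpha, out_dir / "alpha_diversity.tsv", manifest, index_label="sample")
    _save_df(bray_curtis(rel), out_dir / "bray_curtis.tsv", manifest,
             index_label="sample")
    _save_df(fb_ratio(rel).to_frame(), out_dir / "fb_ratio.tsv", manifest,
             index_label="sample")
    features: FeatureTable = state["features"]
    meta = features.modality("metabolome")
    crit = DifferentialCriteria(fc_hi=params["fc_hi"], fc_lo=params["fc_lo"],
                                p_max=params["p_max"])
    diff = differential_filter(np.exp(meta), features.groups.to_numpy(),
                               criteria=crit)
    _save_df(diff, out_dir / "differential_metabolites.tsv", manifest,
             index_label="feature")


def _stage_classify(params, state, out_dir, manifest):
    features: FeatureTable = state["features"]
    y = features.groups.to_numpy()
    scheme = ({"loocv": CVScheme("loocv")}.get(params["cv"])
              or CVScheme("kfold", k=int(params["cv"].lstrip("k")), seed=state["seed"]))
    grid = tuple(2.0**k for k in range(-5, 6)) if params["tune"] else None
    results = {}
    per_modality_top = []
    Xall = features.data.to_numpy(dtype=float)
    cols = list(features.data.columns)
    for mod in features.modalities:
        idx = np.array([i for i, c in enumerate(cols)
                        if c.split("__", 1)[0] == mod])
        res = cv_evaluate(Xall[:, idx], y,
                          PipelineConfig(scope=params["scope"], top_k=params["top_k"],
                                         final_k=params["final_k"], tune_grid=grid,
                                         positive_label="NA"),
                          scheme)
        results[mod] = res["report"].as_dict()
        Xn = minmax_normalize(Xall[:, idx])
        _, order = fisher_score(Xn, y)
        sel = select_top_k(order, min(params["top_k"], len(idx)))
        model = train_linear_svm(Xn, y, feature_idx=sel, positive_label="NA")
        per_modality_top.append(idx[top_contributors(model, params["final_k"])])
    Xn_all = minmax_normalize(Xall)
    _, fused_final = fuse_modalities(per_modality_top, Xn_all, y,
                                     final_k=params["final_k"], positive_label="NA")
    res = cv_evaluate(Xall[:, fused_final], y,
                      PipelineConfig(scope=params["scope"], top_k=len(fused_final),
                                     final_k=len(fused_final), tune_grid=grid,
                                     positive_label="NA"),
                      scheme)
    results["fused"] = res["report"].as_dict()
    results["fused"]["features"] = [cols[i] for i in fused_final]
    (out_dir / "classification_report.json").write_text(
        json.dumps(results, indent=1, default=float))
    manifest.add(out_dir / "classification_report.json")
    state["classification"] = results
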