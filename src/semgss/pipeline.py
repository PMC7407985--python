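"""End-to-end orchestration: simulate -> preprocess -> spectrogram ->
featurize -> train -> evaluate.

Every stage persists its artifact in the run directory and the run manifest
(JSON) records seeds, stage parameters and artifact hashes, so a rerun with
the same configuration reproduces the same confusion matrices and a rerun
with ``resume=True`` skips stages whose artifacts already exist, leaving
those files byte-identical.

Problem sizes default to a desk-scale study: 3 word classes, 150 samples per
class, 2 s per sample at 1000 Hz on 6 channels, with a correspondingly
shortened training schedule (the architecture and per-family hyperparameters
are unchanged).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .conditioning import FilterConfig, QVRConfig, preprocess_recording
from .decoders import (
    DecoderConfig,
    SplitSpec,
    TrainingSchedule,
    build_decoder,
    bundles_to_arrays,
    predict_batch,
    save_decoder,
    split_indices,
    train,
)
from .evaluation import EvaluationReport
from .features import ExtractorSpec, FeatureBundle, Standardizer, featurize_dataset
from .io import load_features, load_recordings, save_features, save_recordings
from .spectrogram import SpectrogramParams
from .synthetic import NoiseSpec, default_class_specs, generate_dataset

logger = logging.getLogger("semgss")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Full run configuration; every stage's knobs plus the run seed."""

    out_dir: str = "semgss_run"
    seed: int = 0
    n_classes: int = 3
    n_per_class: int = 150
    duration_s: float = 2.0
    fs: float = 1000.0
    n_channels: int = 6
    families: tuple[str, ...] = ("mlp", "cnn", "blstm")
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    qvr_cfg: QVRConfig = field(default_factory=QVRConfig)
    sp_params: SpectrogramParams = field(default_factory=SpectrogramParams)
    split: SplitSpec | None = None
    schedule: TrainingSchedule = field(
        default_factory=lambda: TrainingSchedule(
            lr_patience=8, early_stop_patience=15, max_epochs=25
        )
    )
    standardize: bool = True
    resume: bool = False
    skip_stages: tuple[str, ...] = ()

    def path(self, name: str) -> str:
        return os.path.join(self.out_dir, name)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        """Build a config from a YAML file; keyword overrides win.

        Top-level keys mirror the dataclass fields; the nested sections
        ``noise``, ``filter``, ``qvr``, ``spectrogram``, ``split`` and
        ``schedule`` map onto the corresponding config types.
        """
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        nested = {
            "noise": NoiseSpec,
            "filter_cfg": FilterConfig,
            "qvr_cfg": QVRConfig,
            "sp_params": SpectrogramParams,
            "split": SplitSpec,
            "schedule": TrainingSchedule,
        }
        aliases = {"filter": "filter_cfg", "qvr": "qvr_cfg", "spectrogram": "sp_params"}
        kwargs: dict = {}
        for key, value in raw.items():
            key = aliases.get(key, key)
            if key in nested:
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        if "families" in kwargs:
            kwargs["families"] = tuple(kwargs["families"])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    reports: dict[str, EvaluationReport]
    manifest: dict

    @property
    def accuracies(self) -> dict[str, float]:
        return {fam: rep.accuracy for fam, rep in self.reports.items()}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and return the per-family evaluation."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "artifacts": {}}

    def stage_done(name: str, artifact: str | None = None) -> None:
        manifest["stages"][name] = "done"
        if artifact and os.path.exists(artifact):
            manifest["artifacts"][os.path.basename(artifact)] = _sha256(artifact)
        logger.info("stage %s complete", name)

    def should_run(name: str, artifact: str) -> bool:
        if name in cfg.skip_stages:
            return False
        if cfg.resume and os.path.exists(artifact):
            logger.info("stage %s: resuming from existing artifact %s", name, artifact)
            return False
        return True

    # -- simulate ----------------------------------------------------------
    raw_path = cfg.path("raw.h5")
    if should_run("simulate", raw_path):
        specs = default_class_specs(cfg.n_classes, cfg.n_channels, cfg.duration_s)
        recs = generate_dataset(
            specs, cfg.n_per_class, cfg.noise, cfg.duration_s, cfg.fs, seed=cfg.seed
        )
        save_recordings(raw_path, recs)
    else:
        recs = load_recordings(raw_path)
    stage_done("simulate", raw_path)

    # -- preprocess --------------------------------------------------------
    cond_path = cfg.path("conditioned.h5")
    if should_run("preprocess", cond_path):
        conditioned = [preprocess_recording(r, cfg.filter_cfg, cfg.qvr_cfg) for r in recs]
        save_recordings(cond_path, conditioned)
    else:
        conditioned = load_recordings(cond_path)
    stage_done("preprocess", cond_path)

    # -- spectrogram + featurize ------------------------------------------
    feat_path = cfg.path("features.h5")
    ext_spec = ExtractorSpec(seed=cfg.seed + 4)
    if should_run("featurize", feat_path):
        bundles = featurize_dataset(conditioned, cfg.sp_params, ext_spec)
        save_features(feat_path, bundles, backend=ext_spec.backend, seed=ext_spec.seed)
    else:
        bundles = load_features(feat_path)
    stage_done("featurize", feat_path)

    # -- split + standardize ----------------------------------------------
    split = cfg.split or SplitSpec(seed=cfg.seed + 1)
    labels = np.array([b.label for b in bundles])
    tr_idx, va_idx, te_idx = split_indices(labels, split)
    seqs = np.stack([b.sequence for b in bundles])
    if cfg.standardize:
        n, c, d = seqs.shape
        scaler = Standardizer().fit(seqs[tr_idx].reshape(len(tr_idx) * c, d))
        seqs = scaler.transform(seqs.reshape(n * c, d)).reshape(n, c, d)
    std_bundles = [FeatureBundle(sequence=s, label=int(l)) for s, l in zip(seqs, labels)]
    manifest["split"] = {
        "ratios": list(split.fractions),
        "sizes": [len(tr_idx), len(va_idx), len(te_idx)],
        "seed": split.seed,
    }

    # -- train + evaluate --------------------------------------------------
    reports: dict[str, EvaluationReport] = {}
    for fam in cfg.families:
        dec_cfg = DecoderConfig(family=fam, n_classes=cfg.n_classes, seed=cfg.seed + 2)
        model = build_decoder(dec_cfg)
        view = model.input_view
        x_tr, y_tr = bundles_to_arrays([std_bundles[i] for i in tr_idx], view)
        x_va, y_va = bundles_to_arrays([std_bundles[i] for i in va_idx], view)
        rep = train(model, (x_tr, y_tr), (x_va, y_va), cfg.schedule, seed=cfg.seed + 3)
        curve_path = cfg.path(f"training_{fam}.csv")
        rep.to_frame().to_csv(curve_path, index=False)
        save_decoder(model, cfg.path(f"decoder_{fam}"))

        test_bundles = [std_bundles[i] for i in te_idx]
        preds = predict_batch(model, test_bundles)
        truth = labels[te_idx]
        ereport = EvaluationReport.from_predictions(fam, preds, truth, cfg.n_classes)
        ereport.manifest_ref = cfg.path("manifest.json")
        ereport.validate()
        reports[fam] = ereport
        manifest["stages"][f"train_{fam}"] = {
            "stop_epoch": rep.stop_epoch,
            "stop_reason": rep.stop_reason,
            "best_val_loss": float(rep.best_val_loss),
        }
        manifest["artifacts"][os.path.basename(curve_path)] = _sha256(curve_path)
        logger.info("family %s: test accuracy %.3f", fam, ereport.accuracy)

    eval_path = cfg.path("evaluation.json")
    with open(eval_path, "w") as f:
        json.dump({fam: rep.to_dict() for fam, rep in reports.items()}, f, indent=2)
    manifest["artifacts"]["evaluation.json"] = _sha256(eval_path)

    with open(cfg.path("manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return PipelineResult(reports=reports, manifest=manifest)
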