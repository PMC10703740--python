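"""End-to-end pipeline: phantoms -> artifacts -> split -> train -> apply ->
evaluate, with per-stage logging and full reproducibility.

Every artifact on disk is a pure function of (config, seed, toolkit
version); the metric tables of a rerun with the same seed are
byte-identical.  Stage failures abort with the stage name; partial outputs
stay on disk for inspection.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .artifact import SimConfig
from .attenuation import filtered_kramers_spectrum
from .config import RunConfig, config_dict
from .core import PairedSample
from .datasets import make_paired_dataset
from .io import DatasetManifest, build_manifest, load_manifest_samples, \
    read_ct, write_ct
from .metrics import build_report, write_report
from .model import (AugmentToggles, TrainConfig, apply_mar, load_model,
                    save_model, train_cyclemar)
from .phantom import LABELS, PhantomSpec, TransducerSpec

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("ctmar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seed(seed: int, ordinal: int) -> int:
    """Derived per-stage seed: default_rng([seed, ordinal]) -> int < 2^31."""
    return int(np.random.default_rng([seed, ordinal]).integers(0, 2 ** 31 - 1))


def _setup_logging(out_dir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG)
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if verbose and not any(isinstance(h, logging.StreamHandler)
                           and not isinstance(h, logging.FileHandler)
                           for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def _sim_config(cfg: RunConfig) -> SimConfig:
    s = cfg.simulation
    n_views = s.n_views or max(90, int(720 * cfg.phantom.image_size / 512))
    return SimConfig(
        n_views=n_views,
        spectrum=filtered_kramers_spectrum(kvp=s.kvp, i0=s.i0),
        noise=s.noise, lung_max=s.lung_max_hu, bone_min=s.bone_min_hu,
        metal_min=s.metal_min_hu, e_eff_keV=s.e_eff_keV)


def run_pipeline(cfg: RunConfig, out_dir, verbose: bool = False) -> Path:
    """Execute the configured workflow; returns the report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, verbose)
    cfg_yaml = yaml.safe_dump(config_dict(cfg), sort_keys=True)
    (out / "config.yaml").write_text(cfg_yaml)
    cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]
    log.info("run start: toolkit %s, config %s, seed %d", __version__,
             cfg_hash, cfg.seed)

    data_dir = out / "data"
    data_dir.mkdir(exist_ok=True)
    stage = "phantom+simulate"
    t0 = time.time()
    try:
        samples = _generate(cfg, data_dir)
        log.info("stage %s done in %.1fs (%d patients)", stage,
                 time.time() - t0, len(samples))

        stage = "split"
        manifest = build_manifest(data_dir, cfg.split.test_fraction,
                                  cfg.split.folds,
                                  seed=_stage_seed(cfg.seed, 1))
        manifest.to_tsv(data_dir / "manifest.tsv")
        log.info("stage split done: %d train / %d test patients",
                 len(manifest.patients("train")),
                 len(manifest.patients("test")))

        model = None
        if cfg.training.enabled:
            stage = "train"
            t0 = time.time()
            model = _train(cfg, data_dir, manifest)
            save_model(model, out / "model.ckpt")
            log.info("stage train done in %.1fs (%d epochs)",
                     time.time() - t0, cfg.training.epochs)

            stage = "apply"
            for rec in manifest.records:
                if rec["split"] != "test":
                    continue
                art = read_ct(data_dir / rec["art"])
                cor = apply_mar(model, art)
                cor_path = data_dir / f"{rec['slice']}_cor.npy"
                write_ct(cor, cor_path)
                rec["cor"] = cor_path.name
            manifest.to_tsv(data_dir / "manifest.tsv")

        stage = "evaluate"
        report_dir = out / "report"
        test = load_manifest_samples(data_dir, manifest, split="test")
        region_masks = _region_masks(data_dir, test)
        algorithms = ("art", "cor") if model is not None else ("art",)
        rep = build_report(test, region_masks, algorithms=algorithms)
        write_report(rep, report_dir)
        log.info("run complete: report at %s", report_dir)
        return report_dir
    except Exception as exc:  # noqa: BLE001 - stage context matters more
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc


def _generate(cfg: RunConfig, data_dir: Path) -> list[PairedSample]:
    p = cfg.phantom
    spec = PhantomSpec.default(p.image_size,
                               texture_sigma_hu=p.texture_sigma_hu,
                               edge_sigma_px=p.edge_sigma_px,
                               jitter_frac=p.jitter_frac)
    tspec = TransducerSpec(metal_hu=p.transducer_metal_hu)
    samples = make_paired_dataset(
        p.n_patients, image_size=p.image_size,
        seed=_stage_seed(cfg.seed, 0), sim_cfg=_sim_config(cfg),
        phantom_spec=spec,
        transducer_spec=tspec if p.with_transducer else None)
    for s in samples:
        write_ct(s.ref, data_dir / f"{s.patient_id}_s0_ref.npy")
        write_ct(s.art, data_dir / f"{s.patient_id}_s0_art.npy")
        np.save(data_dir / f"{s.patient_id}_s0_labels.npy",
                s.provenance["label_map"])
    return samples


def _train(cfg: RunConfig, data_dir: Path, manifest: DatasetManifest):
    t = cfg.training
    pairs = load_manifest_samples(data_dir, manifest, split="train")
    tc = TrainConfig(
        lambda_cycle=t.lambda_cycle, lambda_identity=t.lambda_identity,
        lambda_paired=t.lambda_paired, epochs=t.epochs, lr=t.lr,
        folds=cfg.split.folds, seed=_stage_seed(cfg.seed, 2),
        image_size=cfg.phantom.image_size, ngf=t.ngf, ndf=t.ndf,
        n_blocks=t.n_blocks, replay_buffer=t.replay_buffer,
        augment=AugmentToggles(
            rotation=t.augment_rotation,
            horizontal_flip=t.augment_horizontal_flip,
            resized_crop=t.augment_resized_crop,
            perspective=t.augment_perspective))
    return train_cyclemar(pairs, tc)


def _region_masks(data_dir: Path, samples: list[PairedSample]) -> dict:
    masks = {}
    for s in samples:
        lbl_path = data_dir / f"{s.slice_id}_labels.npy"
        if not lbl_path.exists():
            continue
        lbl = np.load(lbl_path)
        masks[s.slice_id] = {"heart": lbl == LABELS["heart"],
                             "lung": lbl == LABELS["lung"],
                             "bone": lbl == LABELS["bone"]}
    return masks
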