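"""Run configuration: nested, strictly validated, YAML round-trippable.

Unknown keys are rejected (typos never pass silently) and a config written
to YAML reads back identically.  All randomness of a run flows from the
single ``seed``: each pipeline stage derives its own generator as
``default_rng([seed, stage_ordinal])``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PhantomSection", "SimulationSection", "SplitSection",
           "TrainingSection", "EvaluationSection", "RunConfig",
           "load_config", "save_config", "demo_profile"]


@dataclass
class PhantomSection:
    n_patients: int = 20
    image_size: int = 64
    texture_sigma_hu: float = 10.0
    edge_sigma_px: float = 0.8
    jitter_frac: float = 0.03
    with_transducer: bool = True
    transducer_metal_hu: float = 3000.0


@dataclass
class SimulationSection:
    n_views: int | None = None        # None -> scaled to image size
    kvp: float = 120.0
    i0: float = 2.0e5
    noise: bool = True
    lung_max_hu: float = -300.0
    bone_min_hu: float = 150.0
    metal_min_hu: float = 2000.0
    e_eff_keV: float | None = None    # None -> water-calibrated


@dataclass
class SplitSection:
    test_fraction: float = 0.15
    folds: int = 5


@dataclass
class TrainingSection:
    enabled: bool = True
    epochs: int = 10
    lambda_cycle: float = 10.0
    lambda_identity: float = 15.0
    lambda_paired: float = 10.0
    lr: float = 2e-4
    ngf: int = 8
    ndf: int = 8
    n_blocks: int = 3
    replay_buffer: int = 50
    augment_rotation: bool = False
    augment_horizontal_flip: bool = True
    augment_resized_crop: bool = False
    augment_perspective: bool = False


@dataclass
class EvaluationSection:
    data_range_hu: float = 2000.0
    regions: tuple = ("heart", "lung", "bone")


@dataclass
class RunConfig:
    seed: int = 0
    phantom: PhantomSection = field(default_factory=PhantomSection)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    split: SplitSection = field(default_factory=SplitSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)


def _from_dict(cls, d: dict):
    if not isinstance(d, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys in {cls.__name__}: "
                         + ", ".join(sorted(unknown)))
    kwargs = {}
    for k, v in d.items():
        f = names[k]
        if dataclasses.is_dataclass(f.type) or (
                isinstance(f.default_factory, type)
                and dataclasses.is_dataclass(f.default_factory)):
            kwargs[k] = _from_dict(f.default_factory, v)
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def _to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            out[f.name] = _to_dict(v)
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


def load_config(path) -> RunConfig:
    """Read a YAML run config; unknown keys raise before any stage runs."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_dict(RunConfig, data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=True))


def config_dict(cfg: RunConfig) -> dict:
    return _to_dict(cfg)


def demo_profile(seed: int = 0) -> RunConfig:
    """The small end-to-end profile: 20 phantoms, 64 px, 10 epochs."""
    return RunConfig(seed=seed)
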