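"""YAML configuration for the pipeline and checkpoint (de)serialization."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .caps import CapsConfig
from .harness import PipelineConfig, PipelineModel, TrainConfig
from .preprocess import AugmentSpec
from .synthio import SynthConfig
from .umst import UmstConfig

__all__ = ["ThermosegConfig", "load_config", "save_config",
           "save_checkpoint", "load_checkpoint"]


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class ThermosegConfig:
    """Top-level configuration: one block per pipeline component."""

    data: SynthConfig = field(default_factory=SynthConfig)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    model: UmstConfig = field(default_factory=UmstConfig)
    caps: CapsConfig = field(default_factory=CapsConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    image_size: int = 64
    n_classes: int = 2
    elm_hidden: int = 64
    elm_C: float = 1e3
    screen_pixels: bool = True
    enhance_histogram: bool = False
    use_augment: bool = False

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(image_size=self.image_size, umst=self.model,
                              caps=self.caps, n_classes=self.n_classes,
                              elm_hidden=self.elm_hidden, elm_C=self.elm_C)

    def to_dict(self) -> dict:
        out = asdict(self)
        for key in ("data", "augment", "model", "caps", "train"):
            for k, v in out[key].items():
                if isinstance(v, tuple):
                    out[key][k] = list(v)
                elif hasattr(v, "value"):
                    out[key][k] = v.value
        return out


_SECTIONS = {"data": SynthConfig, "augment": AugmentSpec, "model": UmstConfig,
             "caps": CapsConfig, "train": TrainConfig}


def load_config(path) -> ThermosegConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value or {})
        else:
            kwargs[key] = value
    return _build(ThermosegConfig, kwargs)


def save_config(cfg: ThermosegConfig, path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# checkpoints: network weights + ELM head + config, one .npz file
# ---------------------------------------------------------------------------

def save_checkpoint(model: PipelineModel, cfg: ThermosegConfig, path):
    arrays = {f"param_{i}": arr for i, arr in enumerate(model.state_dict())}
    if model.elm is not None:
        arrays["elm_weights"] = model.elm.weights
        arrays["elm_biases"] = model.elm.biases
        arrays["elm_beta"] = model.elm.beta
        arrays["elm_meta"] = np.array([model.elm.input_dim, model.elm.L,
                                       model.elm.seed, model.elm.C])
    arrays["config_yaml"] = np.frombuffer(
        yaml.safe_dump(cfg.to_dict()).encode(), dtype=np.uint8)
    arrays["seed"] = np.array([model.seed])
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[PipelineModel, ThermosegConfig]:
    from .elm import ElmModel

    with np.load(path) as data:
        cfg_text = bytes(data["config_yaml"]).decode()
        raw = yaml.safe_load(cfg_text)
        kwargs = {k: (_build(_SECTIONS[k], v) if k in _SECTIONS else v)
                  for k, v in raw.items()}
        cfg = _build(ThermosegConfig, kwargs)
        model = PipelineModel(cfg.pipeline_config(), seed=int(data["seed"][0]))
        n = sum(1 for k in data.files if k.startswith("param_"))
        model.load_state_dict([data[f"param_{i}"] for i in range(n)])
        if "elm_beta" in data.files:
            input_dim, L, seed, C = data["elm_meta"]
            model.elm = ElmModel(
                input_dim=int(input_dim), L=int(L), seed=int(seed),
                weights=data["elm_weights"], biases=data["elm_biases"],
                C=float(C), beta=data["elm_beta"])
    return model, cfg
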