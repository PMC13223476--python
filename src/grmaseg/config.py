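"""Hierarchical run configuration ({data, model, au, consistency, train, eval})
plus the RunManifest written before every command touches disk."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .backbone import NetConfig
from .phantom import PhantomConfig
from .training import TrainConfig


class ConfigError(ValueError):
    """A config file violated the schema; the message names the field."""


_SECTIONS = ("data", "model", "au", "consistency", "train", "eval")

DEFAULT_CONFIG: dict = {
    "data": {
        "shape": [64, 64, 16],
        "n_lesions": 2,
        "radius_range": [3.0, 6.0],
        "contrast": 0.2,
        "blur_sigma": 1.0,
        "noise": 0.05,
        "n_labeled": 4,
        "n_unlabeled": 20,
        "n_val": 2,
        "n_test": 2,
    },
    "model": {
        "base_channels": 16,
        "channel_multiplier": 2,
        "num_classes": 2,
        "figr_layer": 4,
        "figr_node_fraction": 0.25,
    },
    "au": {
        "enabled": True,
        "scales": [1, 2],
        "rank": 10,
        "mc_train": 20,
        "mc_eval": 50,
        "mode": "mean-prob",
    },
    "consistency": {
        "enabled": True,
        "weight": 0.1,
        "ramp_len": 1000,
        "ue_enabled": True,
        "noise_placement": "student",
        "noise_std": 0.1,
        "noise_clip": 0.2,
    },
    "train": {
        "learning_rate": 0.0003,
        "batch_size": 1,
        "epochs": 400,
        "ema_decay": 0.999,
        "seed": 1337,
        "augment": True,
        "augment_noise_std": 0.05,
    },
    "eval": {"tau": 1.0, "model": "student"},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        where = f"{path}.{k}" if path else k
        if k not in base:
            raise ConfigError(f"unknown config field: {where}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[k] = _merge(base[k], v, where)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults overlaid with a YAML file; unknown fields are schema errors."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return cfg
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return _merge(cfg, raw)


def phantom_config(cfg: dict, seed: int = 0) -> PhantomConfig:
    d = cfg["data"]
    try:
        return PhantomConfig(
            shape=tuple(int(s) for s in d["shape"]),
            n_lesions=int(d["n_lesions"]),
            radius_range=tuple(float(r) for r in d["radius_range"]),
            contrast=float(d["contrast"]),
            blur_sigma=float(d["blur_sigma"]),
            noise=float(d["noise"]),
            seed=seed,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"data section invalid: {exc}") from exc


def net_config(cfg: dict) -> NetConfig:
    m, a = cfg["model"], cfg["au"]
    try:
        return NetConfig(
            base_channels=int(m["base_channels"]),
            channel_multiplier=int(m["channel_multiplier"]),
            num_classes=int(m["num_classes"]),
            figr_layer=int(m["figr_layer"]),
            figr_node_fraction=float(m["figr_node_fraction"]),
            au_scales=tuple(int(s) for s in a["scales"]),
            au_rank=int(a["rank"]),
            au_enabled=bool(a["enabled"]),
            seed=int(cfg["train"]["seed"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"model/au section invalid: {exc}") from exc


def train_config(cfg: dict) -> TrainConfig:
    t, c, a = cfg["train"], cfg["consistency"], cfg["au"]
    try:
        return TrainConfig(
            learning_rate=float(t["learning_rate"]),
            batch_size=int(t["batch_size"]),
            epochs=int(t["epochs"]),
            ema_decay=float(t["ema_decay"]),
            consistency_weight=float(c["weight"]),
            ramp_len=int(c["ramp_len"]),
            noise_placement=str(c["noise_placement"]),
            noise_std=float(c["noise_std"]),
            noise_clip=float(c["noise_clip"]),
            seed=int(t["seed"]),
            augment=bool(t["augment"]),
            augment_noise_std=float(t["augment_noise_std"]),
            mc_train=int(a["mc_train"]),
            mc_eval=int(a["mc_eval"]),
            au_mode=str(a["mode"]),
            au_enabled=bool(a["enabled"]),
            ue_enabled=bool(c["ue_enabled"]),
            figr_enabled=cfg["model"]["figr_layer"] != 0,
            consistency_enabled=bool(c["enabled"]),
            eval_model=str(cfg["eval"]["model"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"train/consistency section invalid: {exc}") from exc


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    package_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def start(command: str, config: dict, seed: int) -> "RunManifest":
        return RunManifest(command=command, config=config, seed=seed,
                           started=datetime.now(timezone.utc).isoformat())

    def finish(self, outputs: list[str]) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        self.outputs = [str(o) for o in outputs]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))
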