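"""Run configuration: a schema-validated YAML tree with CLI overrides.

Unknown keys are rejected up front so that typos fail before any work
starts; every run writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out": "runs/default",
    "dataset": {
        "path": None,
        "classes": ["macrosiphum_avenae", "rhopalosiphum_padi"],
        "preset": "paper_like",      # paper_like | easy
        "n_train": 50,
        "n_val": 10,
    },
    "backbone": {
        "name": "resnet50",
        "pretrained": False,
        "freeze_stages": 0,
    },
    "neck": {
        "kind": "tfpn",              # tfpn | fpn
        "variant": "RV",
        "d1": 256,
        "heads": 4,
        "mlp_ratio": 1,
        "reduction": 16,
        "lateral_on_finest": False,
    },
    "head": {
        "num_classes": 2,
        "score_thr": 0.025,
        "nms_iou": 0.5,
        "max_dets": 100,
        "use_sampler": False,
    },
    "train": {
        "total_epochs": 16,
        "base_lr": 0.0025,
        "momentum": 0.9,
        "weight_decay": 1.0e-4,
        "warmup_steps": 100,
        "mtm": True,
        "hflip": True,
        "low_res": [667, 400],
        "high_res": [1333, 800],
    },
    "eval": {
        "resolution": [1333, 800],
    },
}


class RunConfig:
    def __init__(self, tree: dict):
        self.tree = tree

    @classmethod
    def load(cls, path: str | Path | None = None,
             overrides: dict | None = None) -> "RunConfig":
        tree = copy.deepcopy(DEFAULT_CONFIG)
        if path is not None:
            with open(path) as fh:
                user = yaml.safe_load(fh) or {}
            _merge(tree, user, DEFAULT_CONFIG, trail="")
        for dotted, value in (overrides or {}).items():
            _set_dotted(tree, dotted, value)
        return cls(tree)

    def __getitem__(self, key):
        return self.tree[key]

    def dump(self, path: str | Path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.tree, fh, sort_keys=False)


def _merge(base: dict, user: dict, schema: dict, trail: str):
    for key, value in user.items():
        here = f"{trail}{key}"
        if key not in schema:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(schema[key], dict) and schema[key]:
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            _merge(base[key], value, schema[key], trail=here + ".")
        else:
            base[key] = value


def _set_dotted(tree: dict, dotted: str, value):
    parts = dotted.split(".")
    node = tree
    schema = DEFAULT_CONFIG
    for p in parts[:-1]:
        if p not in schema:
            raise ConfigError(f"unknown configuration key: {dotted}")
        node = node[p]
        schema = schema[p]
    if parts[-1] not in schema:
        raise ConfigError(f"unknown configuration key: {dotted}")
    node[parts[-1]] = value
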