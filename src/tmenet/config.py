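"""Run configuration: nested YAML sections, presets, and stable hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The selected architecture optimum on the endometrial cohort.
PUBLISHED_DEFAULTS = {
    "cohort": {"n_patients": 40, "cores_per_patient": 2, "core_size": 512,
               "positive_fraction": 0.5, "seed": 0},
    "preprocessing": {"window": 50, "normalize": "institution"},
    "embedding": {"patch_size": 20, "d": 256, "method": "handcrafted"},
    "model": {"P": 10, "N": 8, "A": 4, "K": 2, "hidden": 64,
              "dropout": 0.1, "lr": 1e-3, "weight_decay": 1e-4,
              "epochs": 100, "patients_per_batch": 8,
              "pooling": "hard-max", "activation": "softmax",
              "confidence_weight": 0.0, "balance_weight": 0.0,
              "warmstart_epochs": 0},
    "evaluation": {"k_folds": 10, "tree_max_depth": 3},
}

#: Small everything, for fast smoke runs.
TEST_SMALL = {
    "cohort": {"n_patients": 8, "cores_per_patient": 2, "core_size": 128,
               "positive_fraction": 0.5, "seed": 0},
    "preprocessing": {"window": 50, "normalize": "institution"},
    "embedding": {"patch_size": 20, "d": 64, "method": "handcrafted"},
    "model": {"P": 3, "N": 2, "A": 2, "K": 2, "hidden": 16,
              "dropout": 0.1, "lr": 1e-3, "weight_decay": 1e-4,
              "epochs": 3, "patients_per_batch": 4,
              "pooling": "hard-max", "activation": "softmax",
              "confidence_weight": 0.05, "balance_weight": 0.0,
              "warmstart_epochs": 1},
    "evaluation": {"k_folds": 4, "tree_max_depth": 3},
}

PRESETS = {"published-defaults": PUBLISHED_DEFAULTS, "test-small": TEST_SMALL}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for key in set(base) | set(override):
        bv, ov = base.get(key), override.get(key)
        if isinstance(bv, dict) and isinstance(ov, dict):
            out[key] = _merge(bv, ov)
        else:
            out[key] = ov if key in override else bv
    return out


@dataclass
class RunConfig:
    """Nested per-stage parameters plus a global seed and output directory.

    The hash is computed over the canonical (key-sorted) JSON encoding, so
    it is stable under key reordering.
    """

    sections: dict = field(default_factory=lambda: json.loads(
        json.dumps(PUBLISHED_DEFAULTS)))
    seed: int = 0
    out_dir: str = "runs"

    @classmethod
    def from_preset(cls, name: str, seed: int = 0,
                    out_dir: str = "runs") -> "RunConfig":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; "
                           f"available: {sorted(PRESETS)}")
        return cls(sections=json.loads(json.dumps(PRESETS[name])), seed=seed,
                   out_dir=out_dir)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        base = json.loads(json.dumps(PUBLISHED_DEFAULTS))
        sections = _merge(base, {k: v for k, v in raw.items()
                                 if k not in ("seed", "out_dir")})
        return cls(sections=sections,
                   seed=raw.get("seed", 0) if seed is None else seed,
                   out_dir=raw.get("out_dir", "runs"))

    def to_yaml(self, path):
        payload = dict(self.sections)
        payload["seed"] = self.seed
        payload["out_dir"] = self.out_dir
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @property
    def hash(self) -> str:
        canon = json.dumps({"sections": self.sections, "seed": self.seed},
                           sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def run_dir(self) -> Path:
        return Path(self.out_dir) / self.hash
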