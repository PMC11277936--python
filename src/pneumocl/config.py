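"""Run-configuration file: schema validation and object builders.

One YAML file drives every pipeline stage; each stage reads its own
section. Unknown sections or keys are rejected up front so a typo fails
before any work starts, and the validated mapping is echoed verbatim into
each run summary.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from . import curriculum as cl
from .pipeline import AblationConfig
from .synthetic import CohortSpec
from .training import TrainConfig

__all__ = [
    "load_config",
    "cohort_spec_from",
    "train_config_from",
    "criteria_from",
    "ablation_config_from",
]

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "outdir"},
    "cohort": {
        "n", "prevalence", "small_share", "exact", "shape",
        "size_threshold_px", "size_min_px", "size_max_px", "c0", "c1", "seed",
    },
    "lexicon": {"path"},
    "curriculum": {
        "increment", "f_cap", "auc_min", "sens_min", "spec_min",
        "patience_epochs",
    },
    "training": {
        "lr0", "lr_factor", "lr_patience", "lr_min", "early_stop_patience",
        "epochs_max", "batch_size", "pos_fraction", "dropout", "l2",
        "rotation_max_deg", "flip_prob", "improve_tol", "eval_threshold",
        "seed",
    },
    "evaluation": {"threshold", "conf"},
    "ablation": {
        "cohort_n", "cohort_seed", "val_fraction", "seeds", "epochs_max",
        "arms", "increment", "f_cap", "backbone",
    },
}


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    for key, value in raw.items():
        if key in _SCHEMA[""]:
            continue
        if key not in _SCHEMA:
            raise ValueError(f"unknown config section {key!r}")
        if not isinstance(value, dict):
            raise ValueError(f"section {key!r} must be a mapping")
        unknown = set(value) - _SCHEMA[key]
        if unknown:
            raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
    return raw


def cohort_spec_from(cfg: dict) -> CohortSpec:
    section = dict(cfg.get("cohort", {}))
    section.setdefault("n", 2000)
    section.setdefault("seed", cfg.get("seed", 0))
    if "shape" in section:
        section["shape"] = tuple(section["shape"])
    return CohortSpec(**section)


def train_config_from(cfg: dict) -> TrainConfig:
    section = dict(cfg.get("training", {}))
    section.setdefault("seed", cfg.get("seed", 0))
    section.setdefault("epochs_max", 30)  # desk-scale default profile
    return TrainConfig(**section)


def criteria_from(cfg: dict) -> cl.TransitionCriteria:
    section = cfg.get("curriculum", {})
    kwargs = {
        k: section[k]
        for k in ("auc_min", "sens_min", "spec_min", "patience_epochs")
        if k in section
    }
    return cl.TransitionCriteria(**kwargs)


def ablation_config_from(cfg: dict) -> AblationConfig:
    section = dict(cfg.get("ablation", {}))
    if "seeds" in section:
        section["seeds"] = tuple(section["seeds"])
    if "arms" in section:
        section["arms"] = tuple(bool(a) for a in section["arms"])
    section.setdefault("cohort_seed", cfg.get("seed", 0))
    return AblationConfig(
        criteria=criteria_from(cfg), train=train_config_from(cfg), **section
    )
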