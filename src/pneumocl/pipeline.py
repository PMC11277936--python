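"""End-to-end orchestration: cohort -> training arms -> evaluation.

The central experiment is the matched-arm ablation: a curriculum arm
(large-lesion-first batches with criteria-gated admission of small
lesions) against a traditional arm (uniform batches over the whole pool),
sharing model initialization and augmentation streams per seed so the
arms differ only in batch composition. The comparison endpoint is final
validation AUC, reported overall and on the hard subset (small positives
vs all negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import curriculum as cl
from .evalstats import auc as auc_of
from .models import ConvBackbone, MlpBackbone
from .synthetic import CohortSpec, ImageSample, generate_cohort
from .training import TrainConfig, TrainHistory, stack, train_model

__all__ = ["AblationConfig", "stratified_split", "run_arms", "run_ablation"]


@dataclass(frozen=True)
class AblationConfig:
    """Desk-scale ablation benchmark settings.

    Defaults: a 2000-image synthetic cohort at the development-cohort
    prevalence/small-share, 70/30 stratified split, 30 training epochs,
    five seeds. Full development-cohort-scale values (n=6445, 400 epochs)
    are valid settings; they just take correspondingly longer on one CPU.
    """

    cohort_n: int = 2000
    cohort_seed: int = 0
    val_fraction: float = 0.3
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    epochs_max: int = 30
    arms: tuple[bool, bool] = (True, False)  # (curriculum?, curriculum?)
    increment: float = 0.05
    f_cap: float | None = None  # None -> empirical small share of train positives
    backbone: str = "conv"  # conv | mlp
    criteria: cl.TransitionCriteria = field(default_factory=cl.TransitionCriteria)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.arms[0] == self.arms[1]:
            raise ValueError(
                "misconfigured ablation: both arms have the same curriculum flag"
            )
        if not self.seeds:
            raise ValueError("at least one seed required")


def stratified_split(
    samples: Sequence[ImageSample], val_fraction: float, seed: int
) -> tuple[list[ImageSample], list[ImageSample]]:
    """Deterministic split stratified by (label, size_class)."""
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, str], list[int]] = {}
    for i, s in enumerate(samples):
        strata.setdefault((s.label, s.size_class), []).append(i)
    train_idx, val_idx = [], []
    for key in sorted(strata):
        idx = strata[key]
        order = rng.permutation(len(idx))
        n_val = int(round(val_fraction * len(idx)))
        val_idx.extend(idx[j] for j in order[:n_val])
        train_idx.extend(idx[j] for j in order[n_val:])
    return [samples[i] for i in sorted(train_idx)], [samples[i] for i in sorted(val_idx)]


def _subset_auc(scores, val_samples, size_class: str) -> float:
    """AUC restricted to {positives of one size class} vs {all negatives}."""
    keep = [
        i for i, s in enumerate(val_samples)
        if s.label == "negative" or s.size_class == size_class
    ]
    y = np.array([1 if val_samples[i].label == "positive" else 0 for i in keep])
    return auc_of(np.asarray(scores)[keep], y)


def run_arms(
    train_samples: Sequence[ImageSample],
    val_samples: Sequence[ImageSample],
    seed: int,
    cfg: AblationConfig,
) -> dict:
    """Train the matched curriculum and traditional arms for one seed."""
    x_val, _ = stack(val_samples)
    if cfg.f_cap is None:
        n_small = sum(s.size_class == "small" for s in train_samples)
        n_pos = sum(s.label == "positive" for s in train_samples)
        f_cap = n_small / max(n_pos, 1)
    else:
        f_cap = cfg.f_cap
    tc = TrainConfig(
        **{
            **cfg.train.__dict__,
            "epochs_max": cfg.epochs_max,
            "seed": seed,
        }
    )
    backbone_cls = {"conv": ConvBackbone, "mlp": MlpBackbone}[cfg.backbone]
    out: dict = {"seed": seed}
    for use_curriculum in cfg.arms:
        arm = "curriculum" if use_curriculum else "traditional"
        model = backbone_cls(
            input_shape=train_samples[0].pixels.shape,
            dropout=tc.dropout, l2=tc.l2, seed=seed,
        )
        state = cl.init_state(cfg.increment, f_cap) if use_curriculum else None
        history = train_model(
            model, train_samples, val_samples, tc,
            curriculum_state=state, criteria=cfg.criteria,
        )
        scores = model.predict_scores(x_val)
        out[arm] = {
            "history": history,
            "final_auc": history.rows[-1]["auc"] if history.rows else float("nan"),
            "best_auc": _overall_auc(scores, val_samples),
            "auc_small": _subset_auc(scores, val_samples, "small"),
            "auc_large": _subset_auc(scores, val_samples, "large"),
            "transitions": state.transitions if state else [],
            "final_f": state.f if state else None,
        }
    return out


def _overall_auc(scores, val_samples) -> float:
    y = np.array([1 if s.label == "positive" else 0 for s in val_samples])
    return auc_of(scores, y)


def run_ablation(cfg: AblationConfig = AblationConfig()) -> dict:
    """Run the full multi-seed ablation and aggregate paired differences.

    Returns per-seed arm results plus the paired mean difference
    (curriculum minus traditional) in final validation AUC, overall and on
    the small-lesion subset.
    """
    spec = CohortSpec(n=cfg.cohort_n, seed=cfg.cohort_seed)
    samples, _ = generate_cohort(spec)
    train_samples, val_samples = stratified_split(
        samples, cfg.val_fraction, seed=cfg.cohort_seed
    )
    per_seed = [run_arms(train_samples, val_samples, s, cfg) for s in cfg.seeds]
    diffs_small = [
        r["curriculum"]["auc_small"] - r["traditional"]["auc_small"]
        for r in per_seed
    ]
    diffs_overall = [
        r["curriculum"]["best_auc"] - r["traditional"]["best_auc"]
        for r in per_seed
    ]
    return {
        "n_train": len(train_samples),
        "n_val": len(val_samples),
        "seeds": list(cfg.seeds),
        "per_seed": per_seed,
        "mean_diff_small": float(np.mean(diffs_small)),
        "mean_diff_overall": float(np.mean(diffs_overall)),
        "mean_auc_small_curriculum": float(
            np.mean([r["curriculum"]["auc_small"] for r in per_seed])
        ),
        "mean_auc_small_traditional": float(
            np.mean([r["traditional"]["auc_small"] for r in per_seed])
        ),
    }
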