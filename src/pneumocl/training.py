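"""Backbone-agnostic training loop with the clinical-model protocol.

Binary cross-entropy objective, Adam at an initial learning rate of 1e-3
reduced tenfold on validation-loss plateaus of more than ``lr_patience``
epochs, early stopping on validation loss with best-snapshot restore, and
rotation/flip augmentation. The loop drives any :class:`ModelContract`;
batch composition is either uniform (traditional training) or delegated to
the curriculum scheduler, and everything else — model init, augmentation
stream, evaluation — is identical between the two given the same seed, so
matched ablation arms differ only in what each batch contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import curriculum as cl
from .evalstats import auc as auc_of
from .evalstats import confusion_counts
from .models import ModelContract, bce_loss
from .synthetic import ImageSample

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "augment",
    "reduce_lr_on_plateau",
    "PlateauScheduler",
    "early_stop_check",
    "train_model",
    "named_streams",
    "stack",
]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.001
    lr_factor: float = 0.1
    lr_patience: int = 10
    lr_min: float = 1e-6
    early_stop_patience: int = 20
    epochs_max: int = 400
    batch_size: int = 32
    pos_fraction: float = 0.5
    dropout: float = 0.5
    l2: float = 1e-4
    rotation_max_deg: float = 30.0
    flip_prob: float = 0.5
    improve_tol: float = 1e-6
    eval_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.epochs_max < 0:
            raise ValueError("epochs_max must be >= 0")


@dataclass
class TrainHistory:
    rows: list = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def named_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named RNG streams derived from one master seed.

    Separate streams for batch composition and augmentation mean two runs
    that differ only in batch composition still draw identical
    augmentation parameters — the matched-arm requirement of the ablation.
    """
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    return {
        "batching": np.random.default_rng(kids[0]),
        "augmentation": np.random.default_rng(kids[1]),
        "misc": np.random.default_rng(kids[2]),
    }


def augment(image: np.ndarray, config: TrainConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Random rotation (uniform up to +/- rotation_max_deg) and horizontal flip.

    The rotation draw and the flip draw are always consumed (even when the
    flip is not applied) so the stream advances identically per image.
    Output is clipped to [0, 1] with the input shape preserved.
    """
    angle = rng.uniform(-config.rotation_max_deg, config.rotation_max_deg)
    do_flip = rng.random() < config.flip_prob
    out = image
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    if do_flip:
        out = out[:, ::-1]
    return np.clip(out, 0.0, 1.0)


class PlateauScheduler:
    """Reduce-on-plateau: lr *= factor after > patience non-improving epochs.

    An improvement is a drop in best validation loss by more than
    ``improve_tol``; the bad-epoch counter resets after each reduction.
    """

    def __init__(self, lr0: float, factor: float = 0.1, patience: int = 10,
                 lr_min: float = 1e-6, improve_tol: float = 1e-6):
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.lr_min = lr_min
        self.tol = improve_tol
        self.best = np.inf
        self.num_bad = 0
        self.events: list[int] = []  # step indices of reductions
        self._step = -1

    def step(self, val_loss: float) -> float:
        self._step += 1
        if val_loss < self.best - self.tol:
            self.best = val_loss
            self.num_bad = 0
        else:
            self.num_bad += 1
        if self.num_bad > self.patience and self.lr > self.lr_min:
            self.lr = max(self.lr * self.factor, self.lr_min)
            self.num_bad = 0
            self.events.append(self._step)
        return self.lr


def reduce_lr_on_plateau(val_loss_history: Sequence[float], lr: float,
                         config: TrainConfig) -> float:
    """Stateless form: replay a validation-loss history from ``lr``.

    Returns the learning rate after applying the plateau rule over the
    whole history (e.g. eleven consecutive non-improving epochs from 1e-3
    yield 1e-4).
    """
    if len(val_loss_history) == 0:
        raise ValueError("empty history")
    sched = PlateauScheduler(lr, config.lr_factor, config.lr_patience,
                             config.lr_min, config.improve_tol)
    for v in val_loss_history:
        out = sched.step(v)
    return out


def early_stop_check(val_loss_history: Sequence[float], patience: int,
                     improve_tol: float = 1e-6) -> bool:
    """True iff best validation loss hasn't improved for > patience epochs."""
    if len(val_loss_history) == 0:
        raise ValueError("empty history")
    losses = np.asarray(val_loss_history, dtype=float)
    best, best_idx = np.inf, 0
    for i, v in enumerate(losses):
        if v < best - improve_tol:
            best, best_idx = v, i
    return (len(losses) - 1 - best_idx) > patience


def stack(samples: Sequence[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (images, binary labels) arrays."""
    x = np.stack([s.pixels for s in samples])
    y = np.array([1 if s.label == "positive" else 0 for s in samples])
    return x, y


def split_pools(samples: Sequence[ImageSample]) -> dict[str, list[int]]:
    """Index pools by curriculum stratum: large_pos / small_pos / neg."""
    pools: dict[str, list[int]] = {"large_pos": [], "small_pos": [], "neg": []}
    for i, s in enumerate(samples):
        if s.label == "negative":
            pools["neg"].append(i)
        elif s.size_class == "small":
            pools["small_pos"].append(i)
        else:  # large and unspecified positives feed the easy pool
            pools["large_pos"].append(i)
    return pools


def _evaluate(model: ModelContract, x_val, y_val, threshold: float):
    scores = model.predict_scores(x_val)
    cc = confusion_counts(scores, y_val, threshold)
    return {
        "val_loss": bce_loss(scores, y_val),
        "auc": auc_of(scores, y_val),
        "sensitivity": cc.sensitivity,
        "specificity": cc.specificity,
    }


def train_model(
    model: ModelContract,
    train_samples: Sequence[ImageSample],
    val_samples: Sequence[ImageSample],
    config: TrainConfig = TrainConfig(),
    curriculum_state: cl.CurriculumState | None = None,
    criteria: cl.TransitionCriteria | None = None,
) -> TrainHistory:
    """Train under the optimization protocol; returns the epoch history.

    With ``curriculum_state`` set, batches are composed by the curriculum
    scheduler and the transition check/advance runs after each validation;
    otherwise batches are uniform draws from the full training pool. Fully
    reproducible given ``config.seed``.

    The transition gate is evaluated on the foundational validation subset
    (negatives plus large-lesion positives): the curriculum advances when
    the model has become proficient on the cases it is currently being
    trained on, not when it already solves the hard cases it has yet to
    see — otherwise the bar could never be cleared and the schedule would
    be stuck at stage 0. History rows always report full-validation
    metrics.
    """
    if len({s.id for s in train_samples} & {s.id for s in val_samples}):
        raise ValueError("train and val splits must be disjoint")
    x_val, y_val = stack(val_samples)
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation split must contain both classes")
    x_train, y_train = stack(train_samples)

    streams = named_streams(config.seed)
    rng_batch, rng_aug = streams["batching"], streams["augmentation"]
    sched = PlateauScheduler(config.lr0, config.lr_factor, config.lr_patience,
                             config.lr_min, config.improve_tol)
    criteria = criteria or cl.TransitionCriteria()
    pools = split_pools(train_samples) if curriculum_state is not None else None
    gate_idx = [
        i for i, s in enumerate(val_samples)
        if s.label == "negative" or s.size_class != "small"
    ]
    x_gate, y_gate = x_val[gate_idx], y_val[gate_idx]

    steps_per_epoch = max(1, len(train_samples) // config.batch_size)
    history = TrainHistory()
    val_losses: list[float] = []
    best_loss, best_snap = np.inf, model.snapshot()
    lr = config.lr0

    for epoch in range(config.epochs_max):
        if curriculum_state is not None:
            samplers = {
                k: cl.EpochSampler(v, rng_batch, name=k)
                for k, v in pools.items() if v
            }
        else:
            order = rng_batch.permutation(len(train_samples))
        epoch_losses = []
        for step in range(steps_per_epoch):
            if curriculum_state is not None:
                idx = cl.compose_batch(
                    pools, curriculum_state, config.batch_size,
                    config.pos_fraction, samplers=samplers,
                )
            else:
                idx = order[step * config.batch_size:(step + 1) * config.batch_size]
            xb = np.stack([augment(x_train[i], config, rng_aug) for i in idx])
            yb = y_train[list(idx)]
            loss = model.train_step(xb, yb, lr)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} step {step}"
                )
            epoch_losses.append(loss)

        metrics = _evaluate(model, x_val, y_val, config.eval_threshold)
        val_losses.append(metrics["val_loss"])
        if metrics["val_loss"] < best_loss - config.improve_tol:
            best_loss = metrics["val_loss"]
            best_snap = model.snapshot()
            history.best_epoch = epoch
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "lr": lr,
            "stage": curriculum_state.stage if curriculum_state else None,
            "f": curriculum_state.f if curriculum_state else None,
            **metrics,
        }
        history.rows.append(row)
        lr = sched.step(metrics["val_loss"])

        if curriculum_state is not None:
            gate = _evaluate(model, x_gate, y_gate, config.eval_threshold)
            curriculum_state.epochs_in_stage += 1
            curriculum_state.metric_history.append(
                {"epoch": epoch, **{k: gate[k] for k in
                                    ("auc", "sensitivity", "specificity")}}
            )
            if cl.check_transition(curriculum_state.metric_history, criteria):
                cl.advance(curriculum_state, epoch=epoch)
                # a fresh stage restarts the consecutive-pass window
                curriculum_state.metric_history = []

        if early_stop_check(val_losses, config.early_stop_patience,
                            config.improve_tol):
            history.stop_reason = "early-stop"
            break
    else:
        history.stop_reason = "epoch-budget" if config.epochs_max else "no-training"

    model.restore(best_snap)
    return history
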