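"""Easy-to-hard batch-composition curriculum for lesion detection.

The scheduler is a small state machine over the fraction ``f`` of positive
batch slots given to hard (small-lesion) cases. Training starts with
``f = 0`` — positives drawn exclusively from the large-lesion pool — and
each time the model clears the transition criteria on the validation set
(AUC > 0.95 and sensitivity and specificity both > 0.80, strict, for a
configurable number of consecutive evaluations), ``f`` advances by a fixed
increment (default 5%), capped at ``f_cap``. ``f`` never decreases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionCriteria",
    "CurriculumState",
    "init_state",
    "compose_batch",
    "check_transition",
    "advance",
    "schedule_trace",
    "EpochSampler",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransitionCriteria:
    """Validation thresholds gating each curriculum advance.

    Defaults mirror the CADt performance-goal regime: AUC above 0.95 with
    sensitivity and specificity both above 0.80. Inequalities are strict.
    ``patience_epochs`` is the number of consecutive passing evaluations
    required before advancing.
    """

    auc_min: float = 0.95
    sens_min: float = 0.80
    spec_min: float = 0.80
    patience_epochs: int = 1

    def __post_init__(self) -> None:
        for name in ("auc_min", "sens_min", "spec_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")


@dataclass
class CurriculumState:
    increment: float = 0.05
    f_cap: float = 1.0
    stage: int = 0
    epochs_in_stage: int = 0
    metric_history: list = field(default_factory=list)
    transitions: list = field(default_factory=list)  # (epoch, new_f) log

    @property
    def small_fraction(self) -> float:
        return min(self.stage * self.increment, self.f_cap)

    # short alias used throughout
    @property
    def f(self) -> float:
        return self.small_fraction


def init_state(increment: float = 0.05, f_cap: float = 1.0) -> CurriculumState:
    """Fresh curriculum: stage 0, no small positives in batches."""
    if not 0 < increment <= 1:
        raise ValueError("increment must be in (0, 1]")
    if not 0 <= f_cap <= 1:
        raise ValueError("f_cap must be in [0, 1]")
    return CurriculumState(increment=increment, f_cap=f_cap)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def batch_quotas(
    batch_size: int, pos_fraction: float, f: float
) -> tuple[int, int, int]:
    """(n_small, n_large, n_neg) slot quotas for one batch.

    Quotas use round-half-away-from-zero, with the guarantee that a
    nonzero ``f`` contributes at least one small case whenever there is at
    least one positive slot — so a 5% inclusion step is never vacuous at
    batch size 32.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    n_pos = _round_half_away(pos_fraction * batch_size)
    n_pos = min(max(n_pos, 0), batch_size)
    n_small = _round_half_away(f * n_pos)
    if f > 0 and n_pos >= 1:
        n_small = max(1, n_small)
    n_small = min(n_small, n_pos)
    return n_small, n_pos - n_small, batch_size - n_pos


class EpochSampler:
    """Uniform without-replacement sampler over one stratum for one epoch.

    When the stratum is exhausted mid-epoch it refills and continues —
    effectively sampling with replacement across refills — and logs the
    fallback once.
    """

    def __init__(self, ids: Sequence, rng: np.random.Generator, name: str = ""):
        if len(ids) == 0:
            raise ValueError(f"empty stratum {name!r}")
        self._ids = list(ids)
        self._rng = rng
        self._name = name
        self._queue: list = []
        self.refills = -1
        self._refill()

    def _refill(self) -> None:
        order = self._rng.permutation(len(self._ids))
        self._queue = [self._ids[i] for i in order]
        self.refills += 1
        if self.refills == 1:
            logger.info("stratum %r exhausted; falling back to with-replacement",
                        self._name)

    def draw(self, k: int) -> list:
        out: list = []
        while len(out) < k:
            if not self._queue:
                self._refill()
            out.append(self._queue.pop())
        return out


def compose_batch(
    pools: Mapping[str, Sequence],
    state: CurriculumState,
    batch_size: int,
    pos_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
    samplers: Mapping[str, EpochSampler] | None = None,
) -> list:
    """Draw one batch of sample ids under the current curriculum stage.

    Positive slots are ``round(pos_fraction * batch_size)``; of these,
    ``round(f * n_pos)`` (at least 1 when f > 0) come from the small-lesion
    pool and the rest from the large pool; negatives fill the remainder.
    Pass ``samplers`` (per-stratum :class:`EpochSampler`) for
    without-replacement draws across an epoch; otherwise a one-off uniform
    without-replacement draw per call is used.
    """
    n_small, n_large, n_neg = batch_quotas(batch_size, pos_fraction, state.f)
    quotas = {"small_pos": n_small, "large_pos": n_large, "neg": n_neg}
    batch: list = []
    for stratum, k in quotas.items():
        if k == 0:
            continue
        pool = pools.get(stratum, ())
        if len(pool) == 0 and (samplers is None or stratum not in samplers):
            raise ValueError(f"stratum {stratum!r} exhausted: quota {k}, pool empty")
        if samplers is not None:
            batch.extend(samplers[stratum].draw(k))
        else:
            rng = rng or np.random.default_rng()
            replace = k > len(pool)
            if replace:
                logger.info("stratum %r smaller than quota; with-replacement", stratum)
            idx = rng.choice(len(pool), size=k, replace=replace)
            batch.extend(pool[i] for i in idx)
    return batch


def check_transition(
    metric_history: Sequence[Mapping[str, float]],
    criteria: TransitionCriteria = TransitionCriteria(),
) -> bool:
    """True iff the last ``patience_epochs`` evaluations all clear the bar.

    Each evaluation must have AUC, sensitivity and specificity strictly
    above their thresholds; equality does not pass.
    """
    if len(metric_history) < criteria.patience_epochs:
        return False
    window = metric_history[-criteria.patience_epochs:]
    for m in window:
        for key in ("auc", "sensitivity", "specificity"):
            if key not in m:
                raise ValueError(f"missing metric {key!r}")
        if not (
            m["auc"] > criteria.auc_min
            and m["sensitivity"] > criteria.sens_min
            and m["specificity"] > criteria.spec_min
        ):
            return False
    return True


def advance(state: CurriculumState, epoch: int | None = None) -> CurriculumState:
    """Advance one stage (f += increment, clipped at f_cap). In place.

    Advancing at the cap is a logged no-op, not an error: the curriculum
    has an absorbing terminal stage.
    """
    if state.f >= state.f_cap:
        logger.info("curriculum at f_cap=%.3f; advance is a no-op", state.f_cap)
        return state
    state.stage += 1
    state.epochs_in_stage = 0
    state.transitions.append((epoch, state.f))
    logger.info("curriculum advanced to stage %d (f=%.3f) at epoch %s",
                state.stage, state.f, epoch)
    return state


def schedule_trace(history) -> pd.DataFrame:
    """Per-epoch curriculum trace (epoch, f, stage, val metrics, lr).

    ``history`` is a TrainHistory or any object with a ``rows`` list of
    per-epoch dicts. The ``f`` column is non-decreasing by construction.
    """
    rows = history.rows if hasattr(history, "rows") else list(history)
    if not rows:
        raise ValueError("empty history")
    cols = ["epoch", "f", "stage", "auc", "sensitivity", "specificity", "lr"]
    return pd.DataFrame([{c: r.get(c) for c in cols} for r in rows])
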