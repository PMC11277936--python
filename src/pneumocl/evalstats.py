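"""Clinical validation statistics for binary lesion detection.

Implements the metrics used to validate computer-assisted triage (CADt)
devices against a multi-reader ground truth: confusion metrics at a fixed
operating threshold, Wilson score intervals for sensitivity/specificity,
AUC with DeLong confidence intervals, one-sample Z tests against
performance goals, chi-square association tests, three-reader majority-vote
adjudication, and subgroup performance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "TestResult",
    "confusion_counts",
    "wilson_ci",
    "auc",
    "delong_variance",
    "delong_ci",
    "one_sample_z",
    "chi_square_test",
    "majority_vote",
    "subgroup_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate with a confidence interval.

    ``method`` records how the interval was obtained (``wilson`` for
    binomial proportions, ``delong`` for AUC); bounds are clipped to [0, 1].
    """

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    conf: float = 0.95
    n_effective: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError(
                f"estimate {self.estimate} outside CI "
                f"({self.ci_low}, {self.ci_high})"
            )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    sided: str
    df: int | None = None


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = (y == "positive").astype(int)
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1 or negative/positive)")
    return y


def confusion_counts(
    scores: Sequence[float], labels: Sequence, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts at an operating threshold; ties call positive.

    A score equal to the threshold is called positive — the
    high-sensitivity convention for triage use.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.size == 0 or s.shape != y.shape:
        raise ValueError("scores and labels must be same non-zero length")
    called = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(called & (y == 1))),
        fp=int(np.sum(called & (y == 0))),
        tn=int(np.sum(~called & (y == 0))),
        fn=int(np.sum(~called & (y == 1))),
    )


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for ``k`` successes in ``n`` trials.

    Preferred over the Wald interval for small samples and extreme rates
    (e.g. a subgroup where every case was detected).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    low, high = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    low = float(np.clip(low, 0.0, 1.0))
    high = float(np.clip(high, 0.0, 1.0))
    # at k=0 / k=n the exact bound is 0 / 1; remove float wobble
    if low < 1e-9:
        low = 0.0
    if high > 1.0 - 1e-9:
        high = 1.0
    return low, high


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(y, s))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Midrank structural components V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)  # midranks over pooled sample
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    theta = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return theta, v10, v01


def delong_variance(scores: Sequence[float], labels: Sequence) -> tuple[float, float]:
    """AUC point estimate and its DeLong variance.

    Nonparametric variance of the Mann-Whitney AUC from the structural
    components of the statistic (midrank formulation).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    m = int(np.sum(y == 1))
    n = int(np.sum(y == 0))
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs >= 2 cases per class")
    theta, v10, v01 = _delong_components(s, y)
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(theta), float(var)


def delong_ci(
    scores: Sequence[float], labels: Sequence, conf: float = 0.95
) -> MetricEstimate:
    """AUC with a DeLong normal-approximation CI, clipped to [0, 1]."""
    theta, var = delong_variance(scores, labels)
    z = stats.norm.ppf(0.5 + conf / 2.0)
    half = z * np.sqrt(var)
    y = _as_binary(labels)
    return MetricEstimate(
        name="auc",
        estimate=theta,
        ci_low=float(np.clip(theta - half, 0.0, 1.0)),
        ci_high=float(np.clip(theta + half, 0.0, 1.0)),
        method="delong",
        conf=conf,
        n_effective=int(len(y)),
    )


def one_sample_z(
    estimate: float,
    p0: float,
    n: int | None = None,
    variance: float | None = None,
    alpha: float = 0.025,
    sided: str = "upper",
) -> TestResult:
    """One-sample Z test of an observed rate or AUC against a goal ``p0``.

    For proportions the null variance p0(1-p0)/n is used; for AUC pass the
    DeLong ``variance`` instead of ``n``. The CADt performance-goal setting
    uses an upper-tail test at alpha 0.025.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if variance is not None:
        if variance <= 0:
            if estimate == p0:
                raise ValueError("zero variance with estimate == p0")
            var = 0.0
        else:
            var = variance
        se = np.sqrt(var) if var > 0 else 0.0
        z = np.inf * np.sign(estimate - p0) if se == 0 else (estimate - p0) / se
    elif n is not None:
        if n <= 0:
            raise ValueError("n must be positive")
        se = np.sqrt(p0 * (1.0 - p0) / n)
        z = (estimate - p0) / se
    else:
        raise ValueError("provide either n or variance")
    if sided == "upper":
        p = float(stats.norm.sf(z))
    elif sided == "two":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("sided must be 'upper' or 'two'")
    return TestResult(
        statistic=float(z), p_value=p, alpha=alpha, reject=bool(p < alpha),
        sided=sided,
    )


def chi_square_test(table, correction: str = "auto") -> TestResult:
    """Pearson chi-square test of independence on an r x c table.

    With ``correction='auto'`` the Yates continuity correction is applied
    to 2x2 tables only (the convention that reproduces the published
    subgroup p-values); larger tables use the plain Pearson statistic.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    is_2x2 = t.shape == (2, 2)
    use_yates = {"auto": is_2x2, "always": True, "never": False}[correction]
    res = stats.chi2_contingency(t, correction=use_yates and is_2x2)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=0.05,
        reject=bool(res.pvalue < 0.05),
        sided="upper",
        df=int(res.dof),
    )


@dataclass(frozen=True)
class GroundTruth:
    present: bool
    size_class: str  # large | small | none
    location: str | None
    size_tie: bool = False
    location_tie: bool = False


def majority_vote(
    presence_calls: Sequence[bool],
    sizes: Sequence[str | None] = (),
    locations: Sequence[str | None] = (),
) -> GroundTruth:
    """Three-reader majority adjudication of presence, size and location.

    Presence is the 2-of-3 majority (no ties possible). Size and location
    are decided by majority among the readers calling the lesion present;
    a 1-1 size split resolves conservatively to ``small`` (the harder,
    higher-risk call) with a tie flag.
    """
    if len(presence_calls) != 3:
        raise ValueError("exactly 3 reader calls required")
    calls = [bool(c) for c in presence_calls]
    present = sum(calls) >= 2
    if not present:
        return GroundTruth(present=False, size_class="none", location=None)

    def _majority(values: list[str]) -> tuple[str | None, bool]:
        if not values:
            return None, False
        uniq, counts = np.unique(values, return_counts=True)
        top = counts.max()
        winners = uniq[counts == top]
        if len(winners) == 1:
            return str(winners[0]), False
        return None, True

    pres_sizes = [s for c, s in zip(calls, sizes) if c and s]
    pres_locs = [l for c, l in zip(calls, locations) if c and l]
    size, size_tie = _majority(pres_sizes)
    if size_tie:
        size = "small"
    loc, loc_tie = _majority(pres_locs)
    return GroundTruth(
        present=True,
        size_class=size or "unspecified",
        location=loc,
        size_tie=size_tie,
        location_tie=loc_tie,
    )


def _stratum_row(
    name: str, value: str, s: np.ndarray, y: np.ndarray, threshold: float,
    conf: float,
) -> dict:
    row: dict = {
        "variable": name, "stratum": value, "n": int(len(y)),
        "n_pos": int(y.sum()), "n_neg": int(len(y) - y.sum()),
        "flag": "",
    }
    if len(y) == 0:
        row["flag"] = "empty"
        return row
    cc = confusion_counts(s, y, threshold)
    if cc.n_positive > 0:
        lo, hi = wilson_ci(cc.tp, cc.n_positive, conf)
        row.update(sensitivity=cc.sensitivity, sens_low=lo, sens_high=hi)
    else:
        row["flag"] = "no-positives"
    if cc.n_negative > 0:
        lo, hi = wilson_ci(cc.tn, cc.n_negative, conf)
        row.update(specificity=cc.specificity, spec_low=lo, spec_high=hi)
    else:
        row["flag"] = (row["flag"] + ";" if row["flag"] else "") + "no-negatives"
    if cc.n_positive >= 2 and cc.n_negative >= 2:
        est = delong_ci(s, y, conf)
        row.update(auc=est.estimate, auc_low=est.ci_low, auc_high=est.ci_high)
    else:
        row["flag"] = (row["flag"] + ";" if row["flag"] else "") + "auc-not-estimable"
    return row


def subgroup_report(
    scores: Sequence[float],
    labels: Sequence,
    metadata: pd.DataFrame,
    threshold: float = 0.5,
    variables: Sequence[str] = (
        "sex", "age_group", "site", "manufacturer", "size_class",
    ),
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-stratum sensitivity/specificity (Wilson CIs) and AUC (DeLong CI).

    One row per level of each stratification variable present in
    ``metadata``, plus an overall row. Strata where a metric is not
    estimable (single class, empty) are flagged rather than erroring.
    For lesion-level variables (size class, location) the stratum keeps all
    negatives, so specificity is shared and sensitivity is size-specific —
    the layout of a clinical subgroup table.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(metadata) != len(y):
        raise ValueError("metadata must align with scores/labels")
    rows = [_stratum_row("overall", "overall", s, y, threshold, conf)]
    lesion_vars = {"size_class", "location"}
    for var in variables:
        if var not in metadata.columns:
            continue
        col = metadata[var].to_numpy()
        for level in pd.unique(col):
            if var in lesion_vars and level in ("none", None, ""):
                continue
            if var in lesion_vars:
                mask = (col == level) | (y == 0)
            else:
                mask = col == level
            rows.append(
                _stratum_row(var, str(level), s[mask], y[mask], threshold, conf)
            )
    return pd.DataFrame(rows)
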