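"""Scoring and statistics for two-alternative observer studies.

Covers the full analysis stack used on the trial records: scored accuracy
tables (correction trials excluded), exact one-tailed binomial tests against
chance with Dunn-Sidak adjustment for families of comparisons, the
"flock-sourcing" ensemble score (per-stimulus sum of positive votes across a
cohort), the empirical ROC over that ordinal score, trapezoidal AUC (equal by
construction to the Mann-Whitney pair statistic with half credit for ties),
and paired AUC comparisons via the DeLong placement-value method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import binomtest

__all__ = [
    "ROCCurve",
    "AUCResult",
    "PairedComparison",
    "accuracy_table",
    "binom_vs_chance",
    "dunn_sidak",
    "flock_scores",
    "roc_from_scores",
    "auc",
    "delong_compare",
    "generalization_gap",
    "wilson_ci",
]


@dataclass(frozen=True)
class ROCCurve:
    """Empirical operating points for an ordinal score.

    ``points`` is an (n, 2) array of (false-positive rate, true-positive
    rate) pairs, sorted and componentwise non-decreasing, anchored at (0, 0)
    and (1, 1).  For a score taking values in {0..K} there are K + 2 points,
    one per threshold of the decision rule "call positive when score >= c".
    """

    points: np.ndarray
    positive_label: str = "positive"

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class AUCResult:
    auc: float
    variance: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class PairedComparison:
    auc_a: float
    auc_b: float
    delta: float
    z_statistic: float
    p_value: float
    method: str = "delong"
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------


def accuracy_table(
    records: pd.DataFrame,
    by: Sequence[str] = ("observer_id", "day"),
) -> pd.DataFrame:
    """Scored accuracy per group, with correction trials excluded.

    Nondifferential (test) trials are scored using their correct/incorrect
    designation like any other first-attempt trial.  Returns one row per
    group with ``n_scored``, ``n_correct`` and ``accuracy``; groups with no
    scored trials are omitted (a warning is raised if nothing remains).
    """
    scored = records.loc[~records["is_correction_trial"].astype(bool)]
    if scored.empty:
        warnings.warn("no scored trials (all records are correction trials)",
                      stacklevel=2)
        return pd.DataFrame(columns=[*by, "n_scored", "n_correct", "accuracy"])
    grouped = scored.groupby(list(by), observed=True)["correct"]
    out = grouped.agg(n_scored="size", n_correct="sum").reset_index()
    out["n_correct"] = out["n_correct"].astype(int)
    out["accuracy"] = out["n_correct"] / out["n_scored"]
    return out


def binom_vs_chance(
    n_correct: int, n: int, p0: float = 0.5, alternative: str = "greater"
) -> float:
    """Exact binomial tail probability of the observed success count.

    The default is the one-tailed test against chance responding used on
    per-condition accuracy: ``P(X >= n_correct | n, p0)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= n_correct <= n):
        raise ValueError("n_correct must be in [0, n]")
    return float(binomtest(n_correct, n, p0, alternative=alternative).pvalue)


def dunn_sidak(p: float, m: int) -> float:
    """Dunn-Sidak adjustment of a p-value for a family of ``m`` tests:
    ``1 - (1 - p)^m``, clipped to [0, 1]."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def wilson_ci(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method="wilson")
    return float(ci.low), float(ci.high)


# ---------------------------------------------------------------------------
# Flock sourcing
# ---------------------------------------------------------------------------


def flock_scores(
    records: pd.DataFrame,
    cohort_ids: Sequence[str] | None = None,
    day: int | None = None,
    positive_label: str = "positive",
) -> pd.DataFrame:
    """Pool a cohort's binary judgments into a per-stimulus ordinal score.

    The flock score of a stimulus is the number of cohort members that
    called it positive (malignant), so for a cohort of K observers it ranges
    over {0..K}: three 'malignant' votes out of four birds give a score of 3.
    By default the earliest day present is used (the convention for full-set
    scoring is the first day of the phase); pass ``day`` to override.

    Every cohort member must contribute exactly one scored response per
    stimulus on the chosen day; missing or duplicated responses raise an
    error naming the offending (observer, stimulus) pairs.

    Returns a table with columns ``stimulus_id``, ``true_label``, ``votes``
    and ``K`` (the cohort size), one row per stimulus.
    """
    scored = records.loc[~records["is_correction_trial"].astype(bool)].copy()
    if day is None:
        day = int(scored["day"].min())
    scored = scored.loc[scored["day"] == day]
    if cohort_ids is None:
        cohort_ids = sorted(scored["observer_id"].unique())
    else:
        cohort_ids = list(cohort_ids)
        scored = scored.loc[scored["observer_id"].isin(cohort_ids)]
    if scored.empty:
        raise ValueError(f"no scored responses on day {day}")

    stimuli = sorted(scored["stimulus_id"].unique())
    counts = scored.groupby(["observer_id", "stimulus_id"], observed=True).size()
    offenders = []
    for oid in cohort_ids:
        for sid in stimuli:
            c = counts.get((oid, sid), 0)
            if c != 1:
                offenders.append((oid, sid, int(c)))
    if offenders:
        raise ValueError(
            "each cohort member needs exactly one scored response per stimulus; "
            f"offending (observer, stimulus, count): {offenders[:10]}"
        )

    is_pos_vote = scored["choice"] == positive_label
    votes = is_pos_vote.groupby(scored["stimulus_id"]).sum().astype(int)
    truth = scored.groupby("stimulus_id", observed=True)["true_label"].agg(
        lambda s: s.iloc[0]
    )
    table = pd.DataFrame(
        {
            "stimulus_id": stimuli,
            "true_label": truth.loc[stimuli].to_numpy(),
            "votes": votes.loc[stimuli].to_numpy(),
            "K": len(cohort_ids),
        }
    )
    return table


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _scores_and_truth(
    scores, truth=None, positive_label: str = "positive"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Normalize flock tables or raw arrays into (scores, truth, K)."""
    if isinstance(scores, pd.DataFrame):
        arr = scores["votes"].to_numpy(dtype=float)
        t = (scores["true_label"] == positive_label).to_numpy()
        k = int(scores["K"].iloc[0]) if "K" in scores else int(arr.max())
        return arr, t, k
    arr = np.asarray(scores, dtype=float)
    if truth is None:
        raise ValueError("truth labels required with raw score arrays")
    t = np.asarray(truth)
    if t.dtype != bool:
        t = t == positive_label
    if arr.shape != t.shape:
        raise ValueError("scores and truth must have the same length")
    return arr, t, int(arr.max())


def roc_from_scores(
    scores,
    truth=None,
    positive_label: str = "positive",
    n_levels: int | None = None,
) -> ROCCurve:
    """Empirical ROC of an ordinal score (flock table or raw arrays).

    Thresholds sweep the rule "score >= c" for c = 0 .. K+1, yielding K + 2
    operating points from (0, 0) to (1, 1).  No smoothing is applied: with an
    ordinal score of a few levels, a binormal or other parametric fit would
    inject assumptions the data cannot check.
    """
    arr, t, k = _scores_and_truth(scores, truth, positive_label)
    if n_levels is not None:
        k = int(n_levels)
    pos, neg = arr[t], arr[~t]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to form an ROC curve")
    pts = []
    for c in range(k + 2):  # c = K+1 gives (0,0); c = 0 gives (1,1)
        pts.append(((neg >= c).mean(), (pos >= c).mean()))
    points = np.array(sorted(pts))
    return ROCCurve(points=points, positive_label=positive_label)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: for each positive, the fraction of negatives
    it beats (ties half), and symmetrically for each negative."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def auc(scores, truth=None, positive_label: str = "positive",
        n_levels: int | None = None) -> AUCResult:
    """Area under the empirical ROC, with DeLong variance.

    The trapezoidal area over the empirical curve equals the Mann-Whitney
    statistic (wins + half-ties over all positive/negative pairs); the
    variance is the DeLong placement-value estimate.  An ``ROCCurve`` may be
    passed directly, in which case only the area is computed (variance NaN —
    the placement values need the raw scores).
    """
    if isinstance(scores, ROCCurve):
        area = float(np.trapezoid(scores.tpr, scores.fpr))
        return AUCResult(auc=area, variance=float("nan"), n_pos=0, n_neg=0)
    arr, t, k = _scores_and_truth(scores, truth, positive_label)
    curve = roc_from_scores(arr, t, n_levels=n_levels if n_levels else k)
    area = float(np.trapezoid(curve.tpr, curve.fpr))
    pos, neg = arr[t], arr[~t]
    v10, v01 = _placements(pos, neg)
    var = 0.0
    if len(pos) > 1:
        var += v10.var(ddof=1) / len(pos)
    if len(neg) > 1:
        var += v01.var(ddof=1) / len(neg)
    return AUCResult(auc=area, variance=float(var), n_pos=len(pos), n_neg=len(neg))


def delong_compare(
    scores_a,
    scores_b,
    truth,
    positive_label: str = "positive",
    paired: bool = True,
) -> PairedComparison:
    """DeLong test for the difference of two AUCs on the same stimuli.

    Placement values give each AUC and, for paired designs, the covariance
    of the two estimates; ``z = delta / sqrt(var(delta))`` is referred to the
    standard Normal (two-sided).  If the variance of the difference is
    numerically zero — identical score vectors, for instance — the
    comparison is flagged degenerate and reported with p = 1 (delta 0) or
    p = 0 (a nonzero delta with no sampling variability).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    t = np.asarray(truth)
    if t.dtype != bool:
        t = t == positive_label
    if paired and a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length score vectors")

    pos_a, neg_a = a[t], a[~t]
    pos_b, neg_b = b[t], b[~t]
    if min(len(pos_a), len(neg_a)) == 0:
        raise ValueError("both classes must be present")
    v10_a, v01_a = _placements(pos_a, neg_a)
    v10_b, v01_b = _placements(pos_b, neg_b)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    delta = auc_a - auc_b

    n_pos, n_neg = len(pos_a), len(neg_a)
    var_a = v10_a.var(ddof=1) / n_pos + v01_a.var(ddof=1) / n_neg
    var_b = v10_b.var(ddof=1) / n_pos + v01_b.var(ddof=1) / n_neg
    if paired:
        cov = (
            np.cov(v10_a, v10_b, ddof=1)[0, 1] / n_pos
            + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n_neg
        )
    else:
        cov = 0.0
    var_delta = var_a + var_b - 2.0 * cov

    if var_delta <= 1e-15:
        return PairedComparison(
            auc_a=auc_a,
            auc_b=auc_b,
            delta=delta,
            z_statistic=0.0 if delta == 0 else float("inf") * np.sign(delta),
            p_value=1.0 if delta == 0 else 0.0,
            degenerate=True,
        )
    z = delta / np.sqrt(var_delta)
    p = float(2.0 * (1.0 - ndtr(abs(z))))
    return PairedComparison(
        auc_a=auc_a, auc_b=auc_b, delta=delta, z_statistic=float(z), p_value=p
    )


# ---------------------------------------------------------------------------
# Generalization gap
# ---------------------------------------------------------------------------


def generalization_gap(
    points: pd.DataFrame,
    familiar: str = "training_familiar",
    novel: str = "test_novel",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Familiar-minus-novel accuracy difference per observer and pooled.

    ``points`` is an accuracy table with a ``condition`` column.  Counts are
    summed over days within each condition.  Each proportion gets a Wilson
    interval; the interval on the difference is the Newcombe score-based
    combination of the two Wilson intervals.  A feature learner's gap is 0 in
    expectation; a memorizer shows a large gap with novel accuracy at chance.
    """
    needed = {familiar, novel}
    if "condition" not in points.columns:
        raise ValueError("points must carry a 'condition' column")
    missing = needed - set(points["condition"].unique())
    if missing:
        raise ValueError(f"missing conditions: {sorted(missing)}")

    rows = []
    groups = [(oid, df) for oid, df in points.groupby("observer_id")]
    groups.append(("pooled", points))
    for oid, df in groups:
        agg = df.groupby("condition", observed=True)[["n_correct", "n_scored"]].sum()
        if not needed <= set(agg.index):
            continue
        kf, nf = int(agg.loc[familiar, "n_correct"]), int(agg.loc[familiar, "n_scored"])
        kn, nn = int(agg.loc[novel, "n_correct"]), int(agg.loc[novel, "n_scored"])
        pf, pn = kf / nf, kn / nn
        lf, uf = wilson_ci(kf, nf, confidence)
        ln, un = wilson_ci(kn, nn, confidence)
        gap = pf - pn
        lo = gap - np.sqrt((pf - lf) ** 2 + (un - pn) ** 2)
        hi = gap + np.sqrt((uf - pf) ** 2 + (pn - ln) ** 2)
        rows.append(
            dict(
                observer_id=oid,
                acc_familiar=pf,
                familiar_lo=lf,
                familiar_hi=uf,
                acc_novel=pn,
                novel_lo=ln,
                novel_hi=un,
                gap=gap,
                gap_lo=lo,
                gap_hi=hi,
            )
        )
    return pd.DataFrame(rows)
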