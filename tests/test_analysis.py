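"""Analysis stack: scored accuracy, exact binomial tests, Dunn-Sidak,
flock scores, empirical ROC/AUC, DeLong comparisons, generalization gaps."""

import subprocess
import textwrap
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockstudy.analysis import (
    ROCCurve,
    accuracy_table,
    auc,
    binom_vs_chance,
    delong_compare,
    dunn_sidak,
    flock_scores,
    generalization_gap,
    roc_from_scores,
)


def record_rows(rows):
    base = dict(
        observer_id="b1",
        day=1,
        trial_index=0,
        attempt=0,
        stimulus_id="s0",
        orientation="r0",
        true_label="positive",
        choice="positive",
        correct=True,
        is_correction_trial=False,
        reinforced=True,
        reinforcement="differential",
        condition="training_familiar",
        compression_ratio=1.0,
    )
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d["trial_index"] = i
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------


class TestAccuracyTable:
    def test_correction_trials_excluded_from_both_counts(self):
        rows = [dict(correct=True)] * 100
        rows += [dict(correct=False)] * 44
        rows += [dict(correct=True, is_correction_trial=True, attempt=1)] * 44
        acc = accuracy_table(record_rows(rows))
        assert acc.loc[0, "n_scored"] == 144
        assert acc.loc[0, "n_correct"] == 100
        assert acc.loc[0, "accuracy"] == pytest.approx(100 / 144)

    def test_all_correction_records_yield_empty_table_with_warning(self):
        rows = [dict(is_correction_trial=True, attempt=1)] * 5
        with pytest.warns(UserWarning, match="no scored trials"):
            acc = accuracy_table(record_rows(rows))
        assert acc.empty

    def test_nondifferential_trials_scored_by_designation(self):
        rows = [
            dict(reinforcement="nondifferential", correct=True, reinforced=True),
            dict(reinforcement="nondifferential", correct=False, reinforced=True),
        ]
        acc = accuracy_table(record_rows(rows))
        assert acc.loc[0, "accuracy"] == 0.5

    def test_grouping_by_condition(self):
        rows = [
            dict(condition="training_familiar", correct=True),
            dict(condition="test_novel", correct=False),
        ]
        acc = accuracy_table(record_rows(rows), by=("observer_id", "condition"))
        assert set(acc["condition"]) == {"training_familiar", "test_novel"}


# ---------------------------------------------------------------------------
# Binomial test and Dunn-Sidak
# ---------------------------------------------------------------------------


class TestBinomVsChance:
    def test_perfect_ten_of_ten(self):
        assert binom_vs_chance(10, 10) == pytest.approx(2**-10, rel=1e-12)

    def test_two_of_four_exact_tail(self):
        # P(X >= 2 | n=4, p=1/2) = (6 + 4 + 1) / 16
        assert binom_vs_chance(2, 4) == pytest.approx(11 / 16, rel=1e-12)

    def test_session_scale_count_clears_reporting_threshold(self):
        assert binom_vs_chance(122, 144) < 0.001

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            binom_vs_chance(0, 0)

    @given(n=st.integers(1, 20), k_frac=st.floats(0, 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_pmf_enumeration(self, n, k_frac):
        """Upper tail equals the brute-force binomial pmf sum for n <= 20."""
        k = int(round(k_frac * n))
        expected = sum(comb(n, j) for j in range(k, n + 1)) / 2**n
        assert binom_vs_chance(k, n) == pytest.approx(expected, rel=1e-12)


class TestDunnSidak:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.05, 1, 0.05), (0.0, 7, 0.0), (0.01, 3, 1 - 0.99**3), (1.0, 2, 1.0)],
    )
    def test_closed_form(self, p, m, expected):
        assert dunn_sidak(p, m) == pytest.approx(expected, rel=1e-12)

    def test_invalid_family_size_rejected(self):
        with pytest.raises(ValueError):
            dunn_sidak(0.05, 0)

    @given(p=st.floats(0, 1), m=st.integers(1, 50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_bonferroni_first_order(self, p, m):
        adj = dunn_sidak(p, m)
        assert adj >= p - 1e-15
        assert adj <= dunn_sidak(min(1.0, p + 0.01), m) + 1e-12
        assert adj <= dunn_sidak(p, m + 1) + 1e-12
        if p < 1e-4:
            assert adj == pytest.approx(m * p, rel=1e-2)


# ---------------------------------------------------------------------------
# Flock scores
# ---------------------------------------------------------------------------


def vote_table(votes_by_stim, cohort=("b1", "b2", "b3", "b4"), truth=None):
    """Records where the first `v` observers vote positive on each stimulus."""
    rows = []
    for i, (sid, v) in enumerate(votes_by_stim.items()):
        for j, oid in enumerate(cohort):
            rows.append(
                dict(
                    observer_id=oid,
                    stimulus_id=sid,
                    trial_index=i,
                    choice="positive" if j < v else "negative",
                    true_label=(truth or {}).get(sid, "positive"),
                    correct=True,
                )
            )
    return record_rows(rows)


class TestFlockScores:
    def test_three_of_four_positive_votes_score_three(self):
        table = flock_scores(vote_table({"s0": 3}))
        assert table.loc[0, "votes"] == 3
        assert table.loc[0, "K"] == 4

    def test_zero_and_unanimous_votes(self):
        truth = {"s0": "positive", "s1": "negative"}
        table = flock_scores(vote_table({"s0": 4, "s1": 0}, truth=truth))
        assert dict(zip(table.stimulus_id, table.votes)) == {"s0": 4, "s1": 0}

    def test_perfect_cohort_separates_scores_by_class(self):
        truth = {f"s{i}": ("positive" if i < 3 else "negative") for i in range(6)}
        votes = {s: (4 if l == "positive" else 0) for s, l in truth.items()}
        table = flock_scores(vote_table(votes, truth=truth))
        pos = table[table.true_label == "positive"]["votes"]
        neg = table[table.true_label == "negative"]["votes"]
        assert set(pos) == {4} and set(neg) == {0}

    def test_missing_response_rejected_with_offender(self):
        df = vote_table({"s0": 2, "s1": 2})
        df = df[~((df.observer_id == "b2") & (df.stimulus_id == "s1"))]
        with pytest.raises(ValueError, match="b2"):
            flock_scores(df)

    def test_duplicate_response_rejected(self):
        df = vote_table({"s0": 2})
        dup = df.iloc[[0]].copy()
        with pytest.raises(ValueError, match="exactly one"):
            flock_scores(pd.concat([df, dup], ignore_index=True))

    def test_correction_trials_never_counted(self):
        df = vote_table({"s0": 3})
        extra = df.iloc[[3]].copy()
        extra["is_correction_trial"] = True
        extra["attempt"] = 1
        extra["choice"] = "positive"
        table = flock_scores(pd.concat([df, extra], ignore_index=True))
        assert table.loc[0, "votes"] == 3


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def brute_force_auc(pos, neg):
    """Exhaustive pair counting, half credit for ties."""
    pos, neg = np.asarray(pos), np.asarray(neg)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_hits_corner(self):
        scores = np.array([4, 4, 3, 1, 0, 0], dtype=float)
        truth = np.array([True, True, True, False, False, False])
        curve = roc_from_scores(scores, truth, n_levels=4)
        assert any(np.allclose(p, (0, 1)) for p in curve.points)
        assert auc(scores, truth, n_levels=4).auc == 1.0

    def test_constant_scores_give_diagonal(self):
        scores = np.full(8, 2.0)
        truth = np.array([True, False] * 4)
        curve = roc_from_scores(scores, truth, n_levels=4)
        res = auc(scores, truth, n_levels=4)
        assert res.auc == pytest.approx(0.5, abs=1e-12)

    def test_point_count_is_levels_plus_two(self):
        scores = np.array([0, 1, 2, 3, 4, 2], dtype=float)
        truth = np.array([False, False, True, True, True, False])
        curve = roc_from_scores(scores, truth, n_levels=4)
        assert curve.points.shape == (6, 2)
        assert np.allclose(curve.points[0], (0, 0))
        assert np.allclose(curve.points[-1], (1, 1))
        assert np.all(np.diff(curve.points, axis=0) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_from_scores(np.array([1.0, 2.0]), np.array([True, True]))

    def test_worked_pair_counting_example(self):
        """Positives {3,4,2} vs negatives {1,2,0}: 8.5 of 9 pairs won."""
        scores = np.array([3, 4, 2, 1, 2, 0], dtype=float)
        truth = np.array([True] * 3 + [False] * 3)
        res = auc(scores, truth, n_levels=4)
        assert res.auc == pytest.approx(8.5 / 9, abs=1e-12)

    def test_label_reversal_symmetry(self, rng):
        scores = rng.integers(0, 5, size=20).astype(float)
        truth = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        a = auc(scores, truth, n_levels=4).auc
        b = auc(scores, ~truth, n_levels=4).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_trapezoid_equals_pair_statistic_on_random_tables(self, rng):
        """The empirical-curve area and the Mann-Whitney statistic coincide."""
        for _ in range(300):
            n_pos = rng.integers(2, 16)
            n_neg = rng.integers(2, 16)
            k = rng.integers(1, 7)
            scores = np.r_[
                rng.integers(0, k + 1, n_pos), rng.integers(0, k + 1, n_neg)
            ].astype(float)
            truth = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            res = auc(scores, truth, n_levels=k)
            assert res.auc == pytest.approx(
                brute_force_auc(scores[truth], scores[~truth]), abs=1e-12
            )

    def test_curve_only_input_gives_area(self):
        curve = ROCCurve(points=np.array([[0, 0], [0, 1], [1, 1]], dtype=float))
        assert auc(curve).auc == 1.0


# ---------------------------------------------------------------------------
# DeLong comparisons
# ---------------------------------------------------------------------------


def simulated_table(rng, n=24, d=1.2, rho=0.6):
    """Two correlated ordinal score vectors over the same stimuli."""
    truth = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
    mu = np.where(truth, d, 0.0)
    shared = rng.normal(size=n)
    a = mu + np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=n)
    b = mu + np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.normal(size=n)
    return np.round(a * 2) / 2, np.round(b * 2) / 2, truth


class TestDeLong:
    def test_identical_scores_degenerate(self):
        scores = np.array([0, 1, 2, 3, 4, 1], dtype=float)
        truth = np.array([True, True, True, False, False, False])
        cmp = delong_compare(scores, scores, truth)
        assert cmp.delta == 0.0
        assert cmp.p_value == 1.0
        assert cmp.degenerate

    def test_placement_auc_equals_pair_statistic(self, rng):
        for _ in range(50):
            a, b, truth = simulated_table(rng)
            cmp = delong_compare(a, b, truth)
            assert cmp.auc_a == pytest.approx(
                brute_force_auc(a[truth], a[~truth]), abs=1e-12
            )
            assert cmp.auc_b == pytest.approx(
                brute_force_auc(b[truth], b[~truth]), abs=1e-12
            )

    def test_variance_matches_paired_bootstrap(self, rng):
        """DeLong variance of the AUC difference vs 2000-resample bootstrap."""
        a, b, truth = simulated_table(rng, n=24)
        cmp = delong_compare(a, b, truth)
        var_delong = (
            (cmp.auc_a - cmp.auc_b - cmp.delta) ** 2  # zero; keep shape obvious
        )
        # reconstruct var(delta) from the reported z statistic
        var_delong = (cmp.delta / cmp.z_statistic) ** 2
        deltas = []
        idx_pos = np.flatnonzero(truth)
        idx_neg = np.flatnonzero(~truth)
        for _ in range(2000):
            rp = rng.choice(idx_pos, size=len(idx_pos), replace=True)
            rn = rng.choice(idx_neg, size=len(idx_neg), replace=True)
            ii = np.r_[rp, rn]
            deltas.append(
                brute_force_auc(a[rp], a[rn]) - brute_force_auc(b[rp], b[rn])
            )
        var_boot = np.var(deltas, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)

    def test_agrees_with_reference_r_implementation(self, tmp_path):
        """Cross-check AUCs and the paired test p-value against pROC."""
        a = np.array([4, 3, 4, 2, 3, 1, 2, 0, 1, 1, 0, 2], dtype=float)
        b = np.array([3, 4, 2, 2, 1, 2, 1, 1, 0, 2, 1, 0], dtype=float)
        truth = np.array([True] * 6 + [False] * 6)
        cmp = delong_compare(a, b, truth)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(pROC))
            truth <- c({','.join(str(int(t)) for t in truth)})
            a <- c({','.join(str(x) for x in a)})
            b <- c({','.join(str(x) for x in b)})
            ra <- roc(truth, a, quiet=TRUE, direction="<")
            rb <- roc(truth, b, quiet=TRUE, direction="<")
            tt <- roc.test(ra, rb, method="delong", paired=TRUE)
            cat(sprintf("%.12f", c(auc(ra), auc(rb), tt$p.value)), sep="\\n")
            """
        )
        f = tmp_path / "delong_check.R"
        f.write_text(script)
        out = subprocess.run(
            ["Rscript", "--vanilla", str(f)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        auc_a_r, auc_b_r, p_r = (float(x) for x in out.stdout.split())
        assert cmp.auc_a == pytest.approx(auc_a_r, abs=1e-9)
        assert cmp.auc_b == pytest.approx(auc_b_r, abs=1e-9)
        assert cmp.p_value == pytest.approx(p_r, abs=1e-6)


# ---------------------------------------------------------------------------
# Generalization gap
# ---------------------------------------------------------------------------


def acc_points(rows):
    return pd.DataFrame(rows)


class TestGeneralizationGap:
    def test_identical_accuracies_give_zero_gap(self):
        pts = acc_points(
            [
                dict(observer_id="b1", day=1, condition="training_familiar",
                     n_scored=100, n_correct=85),
                dict(observer_id="b1", day=1, condition="test_novel",
                     n_scored=100, n_correct=85),
            ]
        )
        out = generalization_gap(pts)
        assert np.allclose(out["gap"], 0.0)
        assert (out["gap_lo"] <= 0).all() and (out["gap_hi"] >= 0).all()

    def test_missing_condition_rejected(self):
        pts = acc_points(
            [dict(observer_id="b1", day=1, condition="training_familiar",
                  n_scored=10, n_correct=9)]
        )
        with pytest.raises(ValueError, match="missing conditions"):
            generalization_gap(pts)

    def test_pooled_row_aggregates_all_observers(self):
        pts = acc_points(
            [
                dict(observer_id=o, day=1, condition=c, n_scored=50,
                     n_correct=40 if c == "training_familiar" else 25)
                for o in ("b1", "b2")
                for c in ("training_familiar", "test_novel")
            ]
        )
        out = generalization_gap(pts).set_index("observer_id")
        assert out.loc["pooled", "acc_familiar"] == pytest.approx(0.8)
        assert out.loc["pooled", "acc_novel"] == pytest.approx(0.5)
        assert out.loc["pooled", "gap"] == pytest.approx(0.3)
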