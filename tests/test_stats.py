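import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retinavasc.stats import (
    compare_groups,
    logistic_screen,
    roc_analysis,
    route_variable,
)


def _table(groups: dict, var="x"):
    rows = []
    for g, vals in groups.items():
        rows += [{"group": g, var: v} for v in vals]
    return pd.DataFrame(rows)


class TestRouteVariable:
    def test_normal_groups_parametric(self):
        # seeded fixture drawn from the null so every group passes the gate
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(0, 1, 50) for i in range(4)}
        assert route_variable(groups) == "anova+lsd"

    def test_lognormal_group_forces_nonparametric(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0, 1, 60),
            "b": np.exp(rng.normal(0, 1, 60)),  # Shapiro-Wilk rejects
        }
        assert sps.shapiro(groups["b"]).pvalue < 0.05  # fixture sanity
        assert route_variable(groups) == "kruskal+mannwhitney"

    def test_unequal_variance_forces_nonparametric(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.normal(0, 1, 80), "b": rng.normal(0, 6, 80)}
        assert route_variable(groups) == "kruskal+mannwhitney"

    def test_categorical_routes_chi_square(self):
        assert route_variable({"a": [0, 1], "b": [1, 1]}, categorical=True) == "chi-square"

    def test_tiny_group_warns_nonparametric(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.normal(0, 1, 30), "b": [1.0, 2.0]}
        assert route_variable(groups) == "kruskal+mannwhitney"


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 60)
        table = _table({g: base for g in ("a", "b", "c", "d")})
        rep = compare_groups(table, "x")
        assert rep.omnibus_p > 0.9
        off_diag = rep.pairwise_p.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off_diag > 0.9).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        table = _table(
            {
                "a": rng.normal(0, 1, 50),
                "b": rng.normal(0, 1, 50),
                "c": rng.normal(3, 1, 50),  # 3 sd shift
            }
        )
        rep = compare_groups(table, "x")
        assert rep.omnibus_p < 0.001
        assert rep.pairwise_p.loc["a", "c"] < 0.001

    def test_pairwise_matrix_symmetric(self):
        rng = np.random.default_rng(6)
        table = _table({g: rng.normal(i, 1, 30) for i, g in enumerate("abc")})
        rep = compare_groups(table, "x")
        pd.testing.assert_frame_equal(rep.pairwise_p, rep.pairwise_p.T)

    def test_descriptive_style_matches_route(self):
        rng = np.random.default_rng(7)
        par = compare_groups(_table({"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40)}), "x")
        assert par.route == "anova+lsd"
        assert "±" in next(iter(par.descriptives.values()))
        nonpar = compare_groups(
            _table({"a": np.exp(rng.normal(0, 1, 40)), "b": rng.normal(0, 1, 40)}), "x"
        )
        assert nonpar.route == "kruskal+mannwhitney"
        assert "(" in next(iter(nonpar.descriptives.values()))

    def test_constant_variable_degenerate(self):
        table = _table({"a": [1.0] * 10, "b": [1.0] * 10})
        with pytest.raises(ValueError):
            compare_groups(table, "x")

    def test_chi_square_route(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {
                "group": ["a"] * 50 + ["b"] * 50,
                "sex": list(rng.choice(["m", "f"], 100)),
            }
        )
        rep = compare_groups(table, "sex", categorical=True)
        assert rep.route == "chi-square"
        assert 0 <= rep.omnibus_p <= 1


class TestLogisticScreen:
    def test_null_predictor_ci_covers_one(self):
        rng = np.random.default_rng(9)
        n = 200
        table = pd.DataFrame(
            {"x": rng.normal(0, 1, n), "outcome": rng.integers(0, 2, n)}
        )
        row = logistic_screen(table, ["x"]).iloc[0]
        assert abs(row["beta"]) < 0.5
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(10)
        n = 300
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(0.2 + 1.5 * x)))
        table = pd.DataFrame({"x": x, "outcome": (rng.random(n) < p).astype(int)})
        row = logistic_screen(table, ["x"]).iloc[0]
        assert row["or"] > 1.0 and row["p"] < 0.05
        assert row["converged"]

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.linspace(-3, -1, 30), np.linspace(1, 3, 30)])
        table = pd.DataFrame({"x": x, "outcome": (x > 0).astype(int)})
        row = logistic_screen(table, ["x"]).iloc[0]
        assert row["separation_flag"]
        assert not np.isfinite(row["beta"]) or np.isnan(row["beta"])

    def test_constant_predictor_rejected(self):
        table = pd.DataFrame({"x": [1.0] * 40, "outcome": [0, 1] * 20})
        with pytest.raises(ValueError):
            logistic_screen(table, ["x"])

    def test_single_class_outcome_rejected(self):
        table = pd.DataFrame({"x": np.arange(20.0), "outcome": [1] * 20})
        with pytest.raises(ValueError):
            logistic_screen(table, ["x"])


class TestRocAnalysis:
    def test_perfect_separation(self):
        res = roc_analysis([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_exhaustive_pair_counting_oracle(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[0] = 0
        labels[1] = 1
        res = roc_analysis(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert res.auc == pytest.approx(max(expected, 1 - expected), abs=1e-12)

    def test_constant_score_auc_half(self):
        res = roc_analysis([0.5] * 20, [0, 1] * 10)
        assert res.auc == pytest.approx(0.5)

    def test_negative_marker_orientation(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, 100)
        scores = -labels * 2.0 + rng.normal(0, 0.5, 100)  # lower score = positive
        res = roc_analysis(scores, labels)
        assert res.auc > 0.9
        assert res.direction == -1

    def test_label_swap_maps_auc(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(0, 1, 80)
        labels = (scores + rng.normal(0, 1, 80) > 0).astype(int)
        from sklearn.metrics import roc_auc_score

        raw = roc_auc_score(labels, scores)
        swapped = roc_auc_score(1 - labels, scores)
        assert swapped == pytest.approx(1 - raw, abs=1e-12)
        # the public analysis reports the orientation-corrected value
        assert roc_analysis(scores, labels).auc == pytest.approx(max(raw, 1 - raw))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])
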