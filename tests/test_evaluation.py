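"""Event matching, detection scores, agreement statistics and RM-ANOVA,
each checked against an independent oracle."""

import math

import networkx as nx
import numpy as np
import pingouin as pg
import pandas as pd
import pytest

from mear.evaluation import (
    MatchResult,
    agreement,
    detection_scores,
    f1_from_counts,
    icc_band,
    icc_two_way,
    match_events,
    rm_anova_oneway,
    speed_stratified_rmse,
    time_errors,
)


def brute_force_max_matching(pred, annot, tol):
    """Independent oracle: maximum-cardinality bipartite matching among all
    pairs within tolerance (Hopcroft-Karp)."""
    g = nx.Graph()
    g.add_nodes_from((("a", i) for i in range(len(annot))))
    g.add_nodes_from((("p", j) for j in range(len(pred))))
    for i, a in enumerate(annot):
        for j, p in enumerate(pred):
            if abs(a - p) < tol:
                g.add_edge(("a", i), ("p", j))
    m = nx.bipartite.maximum_matching(
        g, top_nodes=[("a", i) for i in range(len(annot))]
    )
    return len(m) // 2


class TestMatchEvents:
    def test_identical_lists_all_tp(self):
        times = [0.5, 1.1, 1.7, 2.3]
        res = match_events(times, times)
        assert (res.tp, res.fn, res.fp) == (4, 0, 0)
        assert all(a == p for a, p in res.pairs)

    def test_tolerance_is_strict(self):
        res = match_events([0.30], [0.0], tolerance=0.25)
        assert res.tp == 0 and res.fn == 1 and res.fp == 1
        # exactly at the boundary is excluded too
        res = match_events([0.25], [0.0], tolerance=0.25)
        assert res.tp == 0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a = np.sort(rng.uniform(0, 5, 6))
        p = np.sort(rng.uniform(0, 5, 7))
        r1 = match_events(list(p), list(a))
        r2 = match_events(list(a), list(p))
        assert r1.tp == r2.tp and r1.fn == r2.fp and r1.fp == r2.fn

    def test_greedy_matches_oracle_on_detectorlike_instances(self):
        """Instances modeled on detector output: annotated events >=0.4 s
        apart, predictions jittered by sigma = 50 ms plus uniform clutter."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = rng.integers(1, 9)
            annot = np.cumsum(rng.uniform(0.4, 1.2, n))
            keep = rng.random(n) > 0.1
            pred = annot[keep] + rng.normal(0, 0.05, keep.sum())
            n_fp = rng.integers(0, 3)
            pred = np.sort(np.concatenate([pred, rng.uniform(0, annot[-1] + 1, n_fp)]))
            res = match_events(list(pred), list(annot), 0.25)
            assert res.tp == brute_force_max_matching(pred, annot, 0.25)


class TestDetectionScores:
    def test_published_count_arithmetic(self):
        ic = f1_from_counts(3642, 8, 44)
        fc = f1_from_counts(3097, 10, 569)
        assert ic.recall == pytest.approx(3642 / 3650, abs=1e-12)
        assert ic.precision == pytest.approx(3642 / 3686, abs=1e-12)
        assert round(ic.f1 * 100) == 99
        assert round(fc.f1 * 100) == 91

    def test_undefined_cases_flagged(self):
        s = detection_scores(MatchResult(0, 0, 3, [], 0.25))
        assert math.isnan(s.recall) and "recall_undefined" in s.flags
        s = detection_scores(MatchResult(0, 3, 0, [], 0.25))
        assert math.isnan(s.precision) and "precision_undefined" in s.flags

    def test_zero_tp_with_errors_gives_zero_f1(self):
        s = detection_scores(MatchResult(0, 2, 3, [], 0.25))
        assert s.recall == 0 and s.precision == 0 and s.f1 == 0

    def test_f1_is_harmonic_mean(self):
        s = detection_scores(MatchResult(8, 2, 4, [(0.0, 0.0)] * 8, 0.25))
        assert s.f1 == pytest.approx(
            2 * s.precision * s.recall / (s.precision + s.recall), abs=1e-15
        )


class TestTimeErrors:
    def test_sign_convention_annotated_minus_predicted(self):
        # predictions uniformly 10 ms late -> mean error is -0.010 s
        annot = [1.0, 2.0, 3.0]
        pred = [t + 0.010 for t in annot]
        res = match_events(pred, annot)
        errs, mean = time_errors(res)
        np.testing.assert_allclose(errs, -0.010, atol=1e-12)
        assert mean == pytest.approx(-0.010, abs=1e-12)

    def test_errors_bounded_by_tolerance(self):
        rng = np.random.default_rng(1)
        annot = np.cumsum(rng.uniform(0.4, 1.0, 10))
        pred = annot + rng.normal(0, 0.1, 10)
        errs, _ = time_errors(match_events(list(pred), list(annot), 0.25))
        assert np.all(np.abs(errs) < 0.25)


def naive_icc(values, variant):
    """From-scratch mean-squares oracle via explicit loops."""
    values = np.asarray(values, float)
    n, k = values.shape
    grand = values.mean()
    msr = k * sum((values[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((values[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (values[i, j] - values[i].mean() - values[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    if variant == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identity_gives_one(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc_two_way(x, "absolute") == pytest.approx(1.0)
        assert icc_two_way(x, "consistency") == pytest.approx(1.0)

    def test_offset_separates_variants(self):
        base = np.arange(6.0)
        x = np.column_stack([base, base + 2.0])
        assert icc_two_way(x, "consistency") == pytest.approx(1.0)
        assert icc_two_way(x, "absolute") < 1.0

    def test_random_tables_match_naive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(4, 12)
            x = rng.normal(10, 2, (n, 2))
            for variant in ("absolute", "consistency"):
                assert icc_two_way(x, variant) == pytest.approx(
                    naive_icc(x, variant), abs=1e-10
                )

    def test_matches_pingouin(self):
        rng = np.random.default_rng(3)
        x = rng.normal(100, 15, (10, 2)) + rng.normal(0, 5, (10, 1))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(10), 2),
                "raters": np.tile(["gt", "pred"], 10),
                "scores": x.ravel(),
            }
        )
        icc = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type")
        assert icc_two_way(x, "consistency") == pytest.approx(
            icc.loc["ICC(C,1)", "ICC"], abs=1e-9
        )
        assert icc_two_way(x, "absolute") == pytest.approx(
            icc.loc["ICC(A,1)", "ICC"], abs=1e-9
        )

    def test_bands(self):
        assert icc_band(0.3) == "poor"
        assert icc_band(0.6) == "moderate"
        assert icc_band(0.8) == "good"
        assert icc_band(0.95) == "excellent"


class TestAgreement:
    def test_identity(self):
        x = np.array([1.0, 1.2, 1.4, 1.1, 0.9])
        s = agreement(x, x)
        assert s.rmse_abs == 0.0 and s.rmse_rel == 0.0
        assert s.pearson_r == pytest.approx(1.0)
        assert s.icc == pytest.approx(1.0)
        assert s.band == "excellent"

    def test_noise_shrinks_to_perfect_agreement(self):
        rng = np.random.default_rng(4)
        x = rng.normal(100, 15, 40)
        prev_icc = -1
        for eps in (10.0, 1.0, 0.01):
            s = agreement(x + rng.normal(0, eps, 40), x)
            assert s.icc > prev_icc
            prev_icc = s.icc
        assert s.icc > 0.999 and s.pearson_r > 0.999

    def test_zero_variance_flagged(self):
        s = agreement(np.ones(5), np.ones(5))
        assert "zero_variance" in s.flags and math.isnan(s.pearson_r)

    def test_rmse_rel_definition(self):
        pred = np.array([110.0, 120.0, 130.0])
        true = np.array([100.0, 120.0, 140.0])
        s = agreement(pred, true)
        assert s.rmse_abs == pytest.approx(np.sqrt(200 / 3 * 1.0), abs=1e-9)
        assert s.rmse_rel == pytest.approx(100 * s.rmse_abs / 120.0, abs=1e-9)


class TestRMAnova:
    def test_null_case(self):
        table = np.tile([[5.0, 5.0, 5.0]], (4, 1))
        f, dfree, p = rm_anova_oneway(table)
        assert f == 0.0 and p == 1.0

    def test_hand_built_table_matches_manual_decomposition(self):
        table = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0], [1.5, 2.5, 3.5]])
        n, c = table.shape
        grand = table.mean()
        ss_cond = n * ((table.mean(0) - grand) ** 2).sum()
        ss_subj = c * ((table.mean(1) - grand) ** 2).sum()
        ss_err = ((table - grand) ** 2).sum() - ss_cond - ss_subj
        f_manual = (ss_cond / (c - 1)) / (ss_err / ((c - 1) * (n - 1)))
        f, dfree, p = rm_anova_oneway(table)
        assert f == pytest.approx(f_manual, abs=1e-10)
        assert dfree == (2, 4)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(5)
        table = rng.normal(10, 2, (8, 3)) + rng.normal(0, 3, (8, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "cond": np.tile(["a", "b", "c"], 8),
                "y": table.ravel(),
            }
        )
        res = pg.rm_anova(data=df, dv="y", within="cond", subject="subject")
        f, dfree, p = rm_anova_oneway(table)
        assert f == pytest.approx(float(res["F"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(res["p_unc"].iloc[0]), abs=1e-9)

    def test_permutation_null_invariance(self):
        """Permuting condition labels within subjects leaves the permutation
        distribution of F unchanged (exchangeability check, seeded)."""
        rng = np.random.default_rng(6)
        table = rng.normal(0, 1, (6, 3))
        fs = []
        for _ in range(40):
            perm = np.stack([row[rng.permutation(3)] for row in table])
            fs.append(rm_anova_oneway(perm)[0])
        f0 = rm_anova_oneway(table)[0]
        lo, hi = np.quantile(fs, [0.0, 1.0])
        assert lo - 1e-9 <= f0 <= hi + 1e9  # f0 is one draw of the same family
        assert np.isfinite(fs).all()

    def test_speed_table_excludes_incomplete_subjects(self):
        df = pd.DataFrame(
            {
                "subject": ["a"] * 6 + ["b"] * 6 + ["c"] * 4,
                "speed": (["slow"] * 2 + ["preferred"] * 2 + ["fast"] * 2) * 2
                + ["slow"] * 2 + ["preferred"] * 2,
                "pred": np.arange(16, dtype=float) + 100,
                "true": np.arange(16, dtype=float) + 101,
            }
        )
        with pytest.warns(UserWarning, match="lacks a speed"):
            table, anova = speed_stratified_rmse(df)
        assert list(table.index) == ["a", "b"]
        assert set(table.columns) == {"slow", "preferred", "fast"}
        assert np.isfinite(anova["F"]) or anova["F"] == 0.0
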