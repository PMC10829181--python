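"""Composites, ROI adjustment, correlations, termwise OLS and FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from timeuse import coda, models
from timeuse.models import ILR_COLS, Term


class TestMakeComposite:
    def test_single_test_composite_is_its_zscore(self):
        df = pd.DataFrame({"t1": [1.0, 2.0, 3.0, 4.0]})
        out = models.make_composite(df, {"memory": ["t1"]})
        expected = (df["t1"] - df["t1"].mean()) / df["t1"].std(ddof=1)
        pd.testing.assert_series_equal(out["memory"], expected, check_names=False)

    def test_duplicated_test_equals_single(self):
        df = pd.DataFrame({"t1": [3.0, 1.0, 2.0], "t2": [3.0, 1.0, 2.0]})
        out = models.make_composite(df, {"c": ["t1", "t2"]})
        single = models.make_composite(df, {"c": ["t1"]})
        pd.testing.assert_frame_equal(out, single)

    def test_opposite_ranks_cancel(self):
        df = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [3.0, 2.0, 1.0]})
        out = models.make_composite(df, {"c": ["t1", "t2"]})
        np.testing.assert_allclose(out["c"], 0.0, atol=1e-12)

    def test_missing_scores_averaged_over_available(self):
        df = pd.DataFrame({"t1": [1.0, 2.0, 3.0, np.nan], "t2": [4.0, 3.0, 2.0, 1.0]})
        out = models.make_composite(df, {"c": ["t1", "t2"]})
        z2 = (df["t2"] - df["t2"].mean()) / df["t2"].std(ddof=1)
        assert out["c"].iloc[3] == pytest.approx(z2.iloc[3])

    def test_zero_sd_test_rejected(self):
        df = pd.DataFrame({"t1": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="zero standard deviation"):
            models.make_composite(df, {"c": ["t1"]})


class TestAdjustRoi:
    @pytest.fixture()
    def frame(self, rng):
        n = 200
        return pd.DataFrame({
            "tiv": rng.normal(1550, 140, n),
            "site": rng.choice(["A", "B"], n),
            "distortion": rng.integers(0, 2, n),
            "noise": rng.normal(0, 10, n),
        })

    def test_residual_orthogonal_to_tiv(self, frame):
        vol = pd.Series(0.3 * frame["tiv"] + frame["noise"], name="gm")
        adj = models.adjust_roi(vol, frame["tiv"], frame["site"], frame["distortion"])
        assert abs(np.corrcoef(adj, frame["tiv"])[0, 1]) < 1e-9

    def test_mean_restored(self, frame):
        vol = pd.Series(0.3 * frame["tiv"] + frame["noise"])
        adj = models.adjust_roi(vol, frame["tiv"], frame["site"], frame["distortion"])
        assert adj.mean() == pytest.approx(vol.mean(), abs=1e-9)

    def test_uncorrelated_volume_unchanged(self, rng, frame):
        # orthogonalize the volume against the adjusters in-sample
        import statsmodels.api as sm
        X = sm.add_constant(pd.DataFrame({
            "tiv": frame["tiv"],
            "site": pd.Categorical(frame["site"]).codes.astype(float),
            "dist": frame["distortion"].astype(float),
        }))
        vol = pd.Series(sm.OLS(frame["noise"], X).fit().resid + 600.0)
        adj = models.adjust_roi(vol, frame["tiv"], frame["site"], frame["distortion"])
        np.testing.assert_allclose(adj, vol, atol=1e-9)

    def test_collinear_adjusters_rejected(self, frame):
        with pytest.raises(ValueError, match="collinear"):
            models.adjust_roi(pd.Series(frame["noise"]), frame["tiv"],
                              ["A"] * len(frame), frame["distortion"])


class TestCorrelationTable:
    def test_fisher_z_hand_example(self):
        lo, hi = models.fisher_z_ci(0.5, 28)
        assert (lo, hi) == (pytest.approx(0.156, abs=5e-4), pytest.approx(0.736, abs=5e-4))

    def test_point_biserial_is_pearson_on_binary(self, rng):
        df = pd.DataFrame({"sex": rng.integers(0, 2, 60).astype(float),
                           "y": rng.normal(size=60)})
        [entry] = models.correlation_table(df, ["sex", "y"], composition_cols=())
        assert entry.method == "point_biserial"
        assert entry.r == pytest.approx(np.corrcoef(df["sex"], df["y"])[0, 1])

    def test_perfect_linear_pair_degenerate_ci(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        [entry] = models.correlation_table(df, ["a", "b"], composition_cols=())
        assert entry.r == pytest.approx(1.0)
        assert entry.ci_low == entry.ci_high == pytest.approx(1.0)

    def test_compositional_pair_uses_balance_and_bootstrap(self, cohort):
        entries = models.correlation_table(
            cohort, ["mvpa_min", "sleep_min", "age"], n_boot=200, seed=5)
        by_pair = {(e.var1, e.var2): e for e in entries}
        comp = by_pair[("mvpa_min", "sleep_min")]
        assert comp.method == "symmetric_balance" and comp.ci_method == "bootstrap"
        X = coda.closure(cohort[list(models.COMPOSITION_COLS)].to_numpy())
        assert comp.r == pytest.approx(coda.cor_coda(X, 0, 3))
        assert comp.ci_low <= comp.r <= comp.ci_high
        assert by_pair[("mvpa_min", "age")].method == "pearson"

    def test_constant_variable_rejected(self, rng):
        df = pd.DataFrame({"a": np.ones(20), "b": rng.normal(size=20)})
        with pytest.raises(ValueError, match="constant"):
            models.correlation_table(df, ["a", "b"], composition_cols=())


def _planted_frame(rng, n=378, beta=(0.4, -0.2, 0.1), sd=0.8):
    z = rng.normal(size=(n, 3)) * [0.5, 0.3, 0.2] + [-1.3, -0.6, 0.2]
    comp = coda.ilr_inverse(z)
    df = pd.DataFrame(comp, columns=list(models.COMPOSITION_COLS))
    df["age"] = rng.normal(65, 3, n)
    df["y"] = -0.05 * df["age"] + z @ np.asarray(beta) + rng.normal(0, sd, n)
    return df


class TestFitModel:
    def test_planted_ilr_coefficients_recovered(self, rng):
        beta = (0.4, -0.2, 0.1)
        df = models.add_ilr_columns(_planted_frame(rng, beta=beta))
        fit = models.fit_model("y", [Term("age", ("age",)),
                                     Term("composition", ILR_COLS)], df)
        for k, col in enumerate(ILR_COLS):
            se = np.sqrt(fit.cov_params.loc[col, col])
            assert abs(fit.params[col] - beta[k]) < 3 * se

    def test_fitted_values_invariant_to_pivot_order(self, rng):
        df = _planted_frame(rng, n=120)
        preds = []
        for order in [None, (3, 1, 0, 2)]:
            d = models.add_ilr_columns(df, order=order)
            fit = models.fit_model("y", [Term("age", ("age",)),
                                         Term("composition", ILR_COLS)], d)
            preds.append(fit.X.to_numpy() @ fit.params.to_numpy())
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-8)

    def test_rank_deficiency_names_aliased_column(self, rng):
        df = _planted_frame(rng, n=50)
        df = models.add_ilr_columns(df)
        df["age_copy"] = df["age"]
        with pytest.raises(ValueError, match="age_copy"):
            models.fit_model("y", [Term("age", ("age",)),
                                   Term("age_copy", ("age_copy",))], df)

    def test_null_composition_p_uniform(self):
        """Under a pure-noise outcome the composition-term p is uniform."""
        ps = []
        for s in range(200):
            rng = np.random.default_rng(900 + s)
            df = models.add_ilr_columns(_planted_frame(rng, n=100, beta=(0, 0, 0)))
            df["y"] = rng.normal(size=len(df))
            fit = models.fit_model("y", [Term("age", ("age",)),
                                         Term("composition", ILR_COLS)], df)
            [t] = [t for t in models.type2_tests(fit) if t.term == "composition"]
            ps.append(t.p)
        # rejection rate at alpha=0.05 close to nominal
        assert 0.01 <= np.mean(np.asarray(ps) < 0.05) <= 0.10


def brute_force_type2(fit):
    """Independent oracle: explicit nested refits via raw lstsq calls."""
    out = {}
    y = fit.y.to_numpy()
    for t in fit.terms:
        others = [u for u in fit.terms
                  if u.name == t.name or t.name not in u.name.split(":")]
        cols_full = ["const"] + [c for u in others for c in u.columns]
        cols_red = [c for c in cols_full if c not in t.columns]
        Xf, Xr = fit.X[cols_full].to_numpy(), fit.X[cols_red].to_numpy()
        bf, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_f = ((y - Xf @ bf) ** 2).sum()
        rss_r = ((y - Xr @ br) ** 2).sum()
        df1 = len(t.columns)
        df2 = len(y) - Xf.shape[1]
        out[t.name] = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return out


class TestTypeII:
    def test_matches_brute_force_on_small_fixture(self, rng):
        """Type II F equals explicit nested-RSS refits on a 20-row design."""
        n = 20
        df = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        })
        df["x1:x2"] = df["x1"] * df["x2"]
        df["y"] = df["x1"] - 0.5 * df["x2"] + 0.3 * df["x1:x2"] + rng.normal(0, 0.5, n)
        fit = models.fit_model("y", [Term("x1", ("x1",)), Term("x2", ("x2",)),
                                     Term("x1:x2", ("x1:x2",))], df)
        oracle = brute_force_type2(fit)
        for t in models.type2_tests(fit):
            assert t.F == pytest.approx(oracle[t.term], abs=1e-8)

    def test_balanced_orthogonal_design_equals_sequential(self, rng):
        """With orthogonal balanced factors Type II reduces to Type I SS."""
        a = np.repeat([0.0, 1.0], 20)
        b = np.tile([0.0, 1.0], 20)
        y = 1.0 + 2 * a - b + rng.normal(0, 0.5, 40)
        df = pd.DataFrame({"a": a - a.mean(), "b": b - b.mean(), "y": y})
        fit = models.fit_model("y", [Term("a", ("a",)), Term("b", ("b",))], df)
        tests = {t.term: t for t in models.type2_tests(fit)}
        # sequential (Type I) F for "a" entered first
        X0 = fit.X[["const"]].to_numpy()
        X1 = fit.X[["const", "a"]].to_numpy()
        X2 = fit.X[["const", "a", "b"]].to_numpy()
        y_ = fit.y.to_numpy()

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y_, rcond=None)
            return ((y_ - X @ beta) ** 2).sum()

        f_seq_a = (rss(X0) - rss(X1)) / (rss(X2) / (40 - 3))
        assert tests["a"].F == pytest.approx(f_seq_a, rel=1e-9)

    def test_term_absent_not_reported(self, rng):
        df = _planted_frame(rng, n=60)
        df = models.add_ilr_columns(df)
        fit = models.fit_model("y", [Term("age", ("age",))], df)
        assert {t.term for t in models.type2_tests(fit)} == {"age"}

    def test_composition_f_invariant_to_pivot_order(self, cohort):
        fs = []
        for order in [None, (2, 0, 3, 1), (3, 2, 1, 0)]:
            data = models.add_ilr_columns(cohort, order=order)
            fit = models.fit_model(
                "processing_speed_z",
                [Term("age", ("age",)), Term("sex", ("sex",)),
                 Term("education", ("education",)), Term("composition", ILR_COLS)],
                data)
            [t] = [t for t in models.type2_tests(fit) if t.term == "composition"]
            fs.append(t.F)
        assert max(fs) - min(fs) < 1e-8


class TestQuadraticComparison:
    def test_nesting_never_hurts_rss(self, rng):
        df = models.add_ilr_columns(_planted_frame(rng))
        fit2 = models.fit_model("y", [Term("age", ("age",)),
                                      Term("composition", ILR_COLS)], df)
        _, _, fit3 = models.compare_quadratic(fit2)
        assert fit3.rss <= fit2.rss + 1e-9

    def test_planted_curvature_detected(self, rng):
        df = models.add_ilr_columns(_planted_frame(rng, beta=(0, 0, 0), sd=0.5))
        df["y"] = df["y"] + 0.5 * (df["ilr_1"] - df["ilr_1"].mean()) ** 2
        fit2 = models.fit_model("y", [Term("age", ("age",)),
                                      Term("composition", ILR_COLS)], df)
        F, p, _ = models.compare_quadratic(fit2)
        assert p < 0.05

    def test_linear_truth_not_flagged(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(4000 + s)
            df = models.add_ilr_columns(_planted_frame(rng, n=150))
            fit2 = models.fit_model("y", [Term("age", ("age",)),
                                          Term("composition", ILR_COLS)], df)
            _, p, _ = models.compare_quadratic(fit2)
            ps.append(p)
        assert 0.01 <= np.mean(np.asarray(ps) < 0.05) <= 0.11


class TestInteractionModel:
    def test_planted_interaction_recovered(self, cohort, cohort_ilr):
        fit, _ = models.fit_interaction_model("long_term_memory_z", "frontal_std",
                                              cohort_ilr)
        truth = {"ilr_1": 0.35, "ilr_1:frontal_std": -0.65}
        for col, b in truth.items():
            se = np.sqrt(fit.cov_params.loc[col, col])
            assert abs(fit.params[col] - b) < 3 * se

    def test_interaction_df_and_fdr_monotone(self, cohort_ilr):
        _, tests = models.fit_interaction_model("executive_function_z", "gm_std",
                                                cohort_ilr)
        by_term = {t.term: t for t in tests}
        assert by_term["composition"].df1 == 3
        assert by_term["composition:gm_std"].df1 == 3
        for t in tests:
            assert t.p_adjusted >= t.p - 1e-12

    def test_mean_split_same_rows_different_design(self, cohort_ilr):
        cont, _ = models.fit_interaction_model("long_term_memory_z", "frontal_std",
                                               cohort_ilr, roi_form="continuous")
        split, _ = models.fit_interaction_model("long_term_memory_z", "frontal_std",
                                                cohort_ilr, roi_form="mean_split")
        assert cont.n == split.n
        assert set(cont.X.columns) != set(split.X.columns)

    def test_quartile_interaction_spans_nine_columns(self, cohort_ilr):
        fit, tests = models.fit_interaction_model("long_term_memory_z", "frontal_std",
                                                  cohort_ilr, roi_form="quartiles")
        [t] = [t for t in tests if t.term.startswith("composition:")]
        assert t.df1 == 9


class TestBHAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(models.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert models.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_monotone_and_matches_reference(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 15))
            adj = models.bh_adjust(p)
            assert np.all(adj >= p - 1e-15)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(adj, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            models.bh_adjust([0.2, 1.2])
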