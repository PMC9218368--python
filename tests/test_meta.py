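import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from decompmeta import (
    fit_random_effects,
    flag_outliers,
    meta_regression,
    reml_neg2_restricted_loglik,
    screen_and_refit,
    subgroup_analysis,
)
from decompmeta.errors import RankDeficiencyError

from conftest import make_effects, make_moderators


# ----------------------------------------------------------------------
# independent dense-matrix REML oracle (no Sherman-Morrison shortcut)
# ----------------------------------------------------------------------

def dense_reml_neg2ll(tau2_b, tau2_w, y, X, v, study_ids):
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    codes = pd.factorize(np.asarray(study_ids))[0]
    Z = (codes[:, None] == np.arange(codes.max() + 1)[None, :]).astype(float)
    V = np.diag(np.asarray(v, float) + tau2_w) + tau2_b * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + float(r @ Vi @ r)
    ), float(beta[0])


def grid_search_fit(y, v, study_ids, grid_size=50):
    """Brute-force REML over a dense variance-component grid, with one
    zoomed second pass around the coarse argmax."""
    var_y = max(np.var(y), 1e-6)
    X = np.ones((len(y), 1))

    def scan(tb_grid, tw_grid):
        best = (np.inf, None, None, None)
        for tb in tb_grid:
            for tw in tw_grid:
                val, pooled = dense_reml_neg2ll(tb, tw, y, X, v, study_ids)
                if val < best[0]:
                    best = (val, pooled, tb, tw)
        return best

    coarse = np.concatenate(
        [[0.0], np.geomspace(1e-6 * var_y, 4 * var_y, grid_size - 1)]
    )
    best = scan(coarse, coarse)

    def zoom(t0, factor):
        if t0 == 0.0:
            return np.linspace(0.0, 1e-6 * var_y, grid_size)
        return np.linspace(t0 / factor, t0 * factor, grid_size)

    for factor in (3.0, 1.2):
        _, _, tb0, tw0 = best
        best = scan(zoom(tb0, factor), zoom(tw0, factor))
    return best  # (neg2ll, pooled, tau2_b, tau2_w)


def random_small_dataset(rng):
    n_stud = rng.integers(2, 5)
    rows_y, rows_v, rows_s = [], [], []
    total = 0
    for i in range(n_stud):
        per = rng.integers(1, 4)
        for _ in range(per):
            if total >= 8:
                break
            rows_y.append(0.2 + rng.normal(0, 0.1))
            rows_v.append(rng.uniform(0.001, 0.02))
            rows_s.append(f"S{i}")
            total += 1
    if len(set(rows_s)) < 2:  # need at least 2 studies
        rows_s[-1] = "Sx"
    return np.array(rows_y), np.array(rows_v), np.array(rows_s)


class TestClosedFormPooling:
    def test_inverse_variance_weighted_mean(self):
        table = make_effects([0.1, 0.2, 0.3], [0.01, 0.01, 0.04], ["a", "b", "c"])
        fit = fit_random_effects(table, tau2_between=0.0, tau2_within=0.0)
        w = np.array([100.0, 100.0, 25.0])
        expected = float(w @ [0.1, 0.2, 0.3] / w.sum())
        assert fit.pooled_estimate == pytest.approx(expected, abs=1e-10)
        assert fit.pooled_estimate == pytest.approx(37.5 / 225, abs=1e-10)
        assert fit.se_pooled == pytest.approx(1 / np.sqrt(w.sum()), abs=1e-10)

    def test_identical_effects_zero_heterogeneity(self):
        table = make_effects([0.25] * 6, [0.01] * 6,
                             ["a", "a", "b", "b", "c", "c"])
        fit = fit_random_effects(table)
        assert fit.pooled_estimate == pytest.approx(0.25, abs=1e-8)
        assert fit.tau2_between == pytest.approx(0.0, abs=1e-8)
        assert fit.tau2_within == pytest.approx(0.0, abs=1e-8)

    def test_ci_contains_estimate_and_bounds(self):
        table = make_effects([0.1, 0.3, 0.2, 0.25], [0.01] * 4,
                             ["a", "a", "b", "c"])
        fit = fit_random_effects(table)
        lo, hi = fit.ci95
        assert lo < fit.pooled_estimate < hi
        assert min(0.1, 0.2, 0.25, 0.3) <= fit.pooled_estimate <= 0.3


class TestRemlGridOracle:
    def test_optimizer_beats_grid_on_small_datasets(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            y, v, s = random_small_dataset(rng)
            table = make_effects(y, v, s)
            fit = fit_random_effects(table)
            g_neg2, g_pooled, *_ = grid_search_fit(y, v, s)
            assert -2 * fit.reml_loglik <= g_neg2 + 1e-8
            assert fit.pooled_estimate == pytest.approx(g_pooled, abs=1e-4)

    def test_shermanmorrison_matches_dense_likelihood(self):
        rng = np.random.default_rng(3)
        y, v, s = random_small_dataset(rng)
        X = np.ones((len(y), 1))
        for tb, tw in [(0.0, 0.0), (0.01, 0.0), (0.0, 0.02), (0.013, 0.007)]:
            fast = reml_neg2_restricted_loglik(tb, tw, y, X, v, s)
            dense, _ = dense_reml_neg2ll(tb, tw, y, X, v, s)
            assert fast == pytest.approx(dense, rel=1e-10)

    def test_invariant_to_row_order_and_study_labels(self):
        rng = np.random.default_rng(11)
        y, v, s = random_small_dataset(rng)
        fit = fit_random_effects(make_effects(y, v, s))
        perm = rng.permutation(len(y))
        relabel = {lab: f"study-{lab}" for lab in set(s)}
        fit2 = fit_random_effects(
            make_effects(y[perm], v[perm], [relabel[x] for x in s[perm]])
        )
        assert fit2.pooled_estimate == pytest.approx(fit.pooled_estimate, abs=1e-8)
        assert fit2.tau2_between == pytest.approx(fit.tau2_between, abs=1e-8)

    def test_zero_variances_floored_with_warning(self):
        table = make_effects([0.1, 0.2, 0.3], [0.0, 0.01, 0.01], ["a", "b", "c"])
        with pytest.warns(UserWarning, match="floored"):
            fit = fit_random_effects(table, tau2_between=0.0, tau2_within=0.0)
        assert np.isfinite(fit.pooled_estimate)


class TestMetaforOracle:
    def test_matches_rma_mv_on_frozen_dataset(self, tmp_path):
        """Independent cross-check against R metafor's rma.mv with the
        same nested random-effects structure."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(10):
            u = rng.normal(0, 0.08)
            for j in range(3):
                w = rng.normal(0, 0.05)
                v = rng.uniform(0.001, 0.01)
                rows.append((f"S{i}", j, 0.2 + u + w + rng.normal(0, np.sqrt(v)), v))
        df = pd.DataFrame(rows, columns=["study", "obs", "y", "v"])
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        fit = fit_random_effects(make_effects(df["y"], df["v"], df["study"]))
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            d <- read.csv("{csv}")
            res <- rma.mv(yi=y, V=v, random = ~1 | study/obs, data=d, method="REML")
            cat(sprintf("%.10f %.10f %.10f %.10f", coef(res), res$se,
                res$sigma2[1], res$sigma2[2]))
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        est, se, s2b, s2w = map(float, out.stdout.split())
        assert fit.pooled_estimate == pytest.approx(est, abs=1e-6)
        assert fit.se_pooled == pytest.approx(se, abs=1e-6)
        assert fit.tau2_between == pytest.approx(s2b, abs=1e-6)
        assert fit.tau2_within == pytest.approx(s2w, abs=1e-6)


class TestSubgroups:
    def test_constant_factor_rejected(self):
        table = make_effects([0.1, 0.2], [0.01, 0.01], ["a", "b"])
        mods = make_moderators(["a", "b"])
        with pytest.raises(ValueError, match="level"):
            subgroup_analysis(table, mods, "setting")

    def test_recovers_level_means_with_negligible_noise(self):
        rng = np.random.default_rng(5)
        studies = [f"S{i}" for i in range(20)]
        mods = make_moderators(studies)
        mods.loc[10:, "setting"] = "field"
        truth = {"laboratory": 0.1, "field": 0.4}
        y = [truth[mods.loc[i, "setting"]] + rng.normal(0, 1e-4)
             for i in range(20)]
        table = make_effects(y, [1e-6] * 20, studies)
        sg = subgroup_analysis(table, mods, "setting",
                               tau2_between=0.0, tau2_within=0.0)
        got = dict(zip(sg.per_level["level"], sg.per_level["estimate"]))
        assert got["laboratory"] == pytest.approx(0.1, abs=1e-3)
        assert got["field"] == pytest.approx(0.4, abs=1e-3)
        assert sg.qm_p < 0.001

    def test_omnibus_qm_near_zero_for_identical_levels(self):
        studies = [f"S{i}" for i in range(12)]
        mods = make_moderators(studies)
        mods.loc[6:, "environment"] = "freshwater"
        table = make_effects([0.2] * 12, [0.01] * 12, studies)
        sg = subgroup_analysis(table, mods, "environment")
        assert sg.qm_stat == pytest.approx(0.0, abs=1e-10)
        assert sg.qm_p == pytest.approx(1.0, abs=1e-6)
        assert sg.qm_df == 1

    def test_low_k_levels_flagged(self):
        studies = [f"S{i}" for i in range(5)]
        mods = make_moderators(studies)
        mods.loc[4, "setting"] = "field"
        table = make_effects([0.2, 0.25, 0.22, 0.21, 0.4], [0.01] * 5, studies)
        sg = subgroup_analysis(table, mods, "setting")
        level = sg.per_level.set_index("level")
        assert bool(level.loc["field", "low_k"])
        assert not bool(level.loc["laboratory", "low_k"])


class TestMetaRegression:
    def test_noiseless_limit_equals_ols(self):
        studies = [f"S{i}" for i in range(10)]
        x = np.arange(10, dtype=float)
        y = 0.05 + 0.012 * x
        mods = make_moderators(studies)
        mods["max_richness"] = x
        mods["inoculum_complexity"] = "reduced"
        table = make_effects(y, [1e-4] * 10, studies)
        mr = meta_regression(table, mods, "max_richness",
                             tau2_between=0.0, tau2_within=0.0)
        assert mr.coefficients.loc["max_richness", "beta"] == pytest.approx(
            0.012, abs=1e-10
        )
        assert mr.coefficients.loc["intercept", "beta"] == pytest.approx(
            0.05, abs=1e-10
        )

    def test_effect_level_moderator_time_days(self):
        studies = ["S1", "S1", "S2", "S2"]
        table = make_effects([0.1, 0.2, 0.15, 0.3], [0.01] * 4, studies,
                             time_days=[30.0, 90.0, 30.0, 90.0])
        mr = meta_regression(table, make_moderators(["S1", "S2"]), "time_days")
        assert mr.coefficients.loc["time_days", "beta"] > 0

    def test_constant_x_rank_deficient(self):
        table = make_effects([0.1, 0.2, 0.3], [0.01] * 3, ["a", "b", "c"])
        mods = make_moderators(["a", "b", "c"])
        with pytest.raises(RankDeficiencyError):
            meta_regression(table, mods, "litter_cn")

    def test_all_missing_moderator_rejected(self):
        table = make_effects([0.1, 0.2], [0.01] * 2, ["a", "b"])
        mods = make_moderators(["a", "b"])
        mods["litter_cn"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            meta_regression(table, mods, "litter_cn")

    def test_missing_rows_dropped_listwise(self):
        studies = [f"S{i}" for i in range(6)]
        mods = make_moderators(studies)
        mods.loc[0:1, "litter_cn"] = np.nan
        mods.loc[2:, "litter_cn"] = [20.0, 40.0, 60.0, 80.0]
        table = make_effects([0.1, 0.9, 0.2, 0.22, 0.24, 0.26], [0.01] * 6, studies)
        mr = meta_regression(table, mods, "litter_cn")
        assert mr.k_effects == 4


class TestOutliers:
    def test_injected_outlier_flagged(self):
        rng = np.random.default_rng(1)
        y = list(0.2 + rng.normal(0, 0.02, 19))
        v = [0.0004] * 19
        fit0 = fit_random_effects(
            make_effects(y, v, [f"S{i}" for i in range(19)])
        )
        total_sd = np.sqrt(0.0004 + fit0.tau2_between + fit0.tau2_within)
        y.append(fit0.pooled_estimate + 10 * total_sd)
        v.append(0.0004)
        table = make_effects(y, v, [f"S{i}" for i in range(20)])
        report = flag_outliers(table, threshold=3.0)
        assert report.flagged == [19]

    def test_infinite_threshold_flags_nothing(self):
        table = make_effects([0.1, 0.2, 5.0], [0.01] * 3, ["a", "b", "c"])
        report = flag_outliers(table, threshold=np.inf)
        assert report.flagged == []

    def test_screen_and_refit_drops_flagged(self):
        rng = np.random.default_rng(2)
        y = list(0.2 + rng.normal(0, 0.02, 15)) + [1.0]
        v = [0.0004] * 16
        table = make_effects(y, v, [f"S{i}" for i in range(16)])
        fit, report, kept = screen_and_refit(table)
        assert report.flagged == [15]
        assert len(kept) == 15
        assert fit.pooled_estimate == pytest.approx(0.2, abs=0.02)

    def test_homogeneous_data_rarely_flagged(self):
        rng = np.random.default_rng(17)
        clean = 0
        for _ in range(40):
            y = 0.2 + rng.normal(0, 0.05, 15)
            v = np.full(15, 0.0025)
            table = make_effects(y, v, [f"S{i}" for i in range(15)])
            if not flag_outliers(table, 3.0).flagged:
                clean += 1
        assert clean >= 38  # >= 95% of replicates
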