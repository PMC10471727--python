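import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from proglacial import (
    FitSummary,
    LoggerSeries,
    Standardization,
    WorldConfig,
    aggregate_monthly,
    build_design,
    cluster_stations,
    fit_lmm,
    generate_logger_traces,
    generate_world,
    loo_by_glacier,
    monthly_extremes,
    permutation_importance,
    predict_fixed,
    semi_partial_r2,
    sfd_cutoff_diagnostics,
    validate,
)
from proglacial.soil_model import FIXED_TERMS


def make_trace(values, freq_per_day=24, start="2020-01-01", **meta):
    idx = pd.date_range(start, periods=len(values), freq=f"{24 // freq_per_day}h", tz="UTC")
    defaults = dict(
        station_id="S1", glacier_id="G1", region="Northern", latitude=46.0,
        longitude=8.0, elevation=2500.0, depth_cm=5, nominal_frequency=freq_per_day,
    )
    defaults.update(meta)
    return LoggerSeries(records=pd.Series(values, index=idx), **defaults)


class TestAggregateMonthly:
    def test_complete_month_retained(self):
        tr = make_trace(np.ones(31 * 24))  # January 2020 complete
        out = aggregate_monthly(tr)
        assert len(out) == 1
        assert out.iloc[0]["completeness"] == 1.0

    def test_899_percent_month_dropped(self):
        vals = np.ones(647)  # 647 of 31*24=744 -> 87%; build a 30-day month
        idx = pd.date_range("2020-04-01", periods=647, freq="h", tz="UTC")
        tr = make_trace(np.ones(10))
        tr.records = pd.Series(vals, index=idx)  # 647/720 = 89.9%
        assert aggregate_monthly(tr).empty

    def test_noise_free_world_recovers_truth(self, noise_free_world):
        traces = generate_logger_traces(noise_free_world)
        truth = noise_free_world.truth.monthly
        for tr in traces[:5]:
            agg = aggregate_monthly(tr)
            m = agg.merge(truth, on=["station_id", "year", "month"], suffixes=("", "_t"))
            assert len(m) == noise_free_world.config.n_months
            assert np.allclose(m["soilT"], m["soilT_t"], atol=1e-10)


class TestMonthlyExtremes:
    def test_constant_trace(self):
        tr = make_trace(np.full(31 * 24, 4.2))
        out = monthly_extremes(tr)
        assert np.allclose(out[["t_min", "t_max"]], 4.2)

    def test_quantile_oracle_1_to_100(self):
        tr = make_trace(np.arange(1.0, 101.0))
        out = monthly_extremes(tr)
        assert np.isclose(out.iloc[0]["t_min"], 5.95)  # type-7 interpolation
        assert np.isclose(out.iloc[0]["t_max"], 95.05)

    def test_too_few_records_missing(self):
        tr = make_trace(np.ones(10))
        assert monthly_extremes(tr).empty

    def test_mean_tracks_extremes_on_world(self, small_world):
        traces = generate_logger_traces(small_world)
        means, mins, maxs = [], [], []
        for tr in traces:
            agg = aggregate_monthly(tr)
            ext = monthly_extremes(tr)
            m = agg.merge(ext, on=["station_id", "year", "month"])
            means.extend(m["soilT"])
            mins.extend(m["t_min"])
            maxs.extend(m["t_max"])
        assert np.corrcoef(means, mins)[0, 1] > 0.9
        assert np.corrcoef(means, maxs)[0, 1] > 0.9


class TestBuildDesign:
    def test_standardized_columns(self, small_world):
        d = build_design(small_world.monthly_table)
        for col in ("mT", "rad", "sfd", "dg", "d"):
            assert abs(d.X[col].mean()) < 1e-10
            assert abs(d.X[col].std(ddof=1) - 1.0) < 1e-10

    def test_sqrt_transform_order(self, small_world):
        d = build_design(small_world.monthly_table)
        std = d.standardization
        row = d.raw.iloc[0]
        expected = (np.sqrt(row["dg"]) - std.means["dg"]) / std.sds["dg"]
        assert np.isclose(d.X["dg"].iloc[0], expected)

    def test_sfd_cutoff_is_strict(self, small_world):
        tab = small_world.monthly_table.copy().iloc[:40]
        tab["sfd"] = np.linspace(15.0, 100.0, 40)
        tab.loc[tab.index[0], "sfd"] = 20.0
        tab.loc[tab.index[1], "sfd"] = 20.1
        d = build_design(tab)
        assert 20.0 not in d.raw["sfd"].values
        assert 20.1 in d.raw["sfd"].values

    def test_prediction_invariance_raw_vs_prestandardized(self, small_world):
        d = build_design(small_world.monthly_table)
        fit = fit_lmm(d)
        std_tab = d.standardization.apply(d.raw)
        d2 = build_design(std_tab, standardization=d.standardization, already_standardized=True)
        p1 = predict_fixed(d.X, fit.params)
        p2 = predict_fixed(d2.X, fit.params)
        assert np.allclose(p1, p2)

    def test_missing_covariate_rejected(self, small_world):
        tab = small_world.monthly_table.drop(columns=["rad"])
        with pytest.raises(ValueError, match="rad"):
            build_design(tab)


class TestFitLmm:
    def test_no_group_variance_world(self):
        world = generate_world(
            WorldConfig(n_glaciers=6, stations_per_glacier=4, n_months=12,
                        dem_size=24, seed=21, glacier_intercept_sd=0.0)
        )
        fit = fit_lmm(build_design(world.monthly_table))
        assert fit.r2c - fit.r2m < 0.02
        assert fit.var_glacier < 0.1

    def test_matches_lme4_reference(self, small_world, tmp_path):
        """Cross-check the REML fit against lme4 on the same table."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        d = build_design(small_world.monthly_table)
        fit = fit_lmm(d)
        tab = d.X.drop(columns="intercept").copy()
        tab.columns = [c.replace(":", "_x_") for c in tab.columns]
        tab["soilT"] = d.y.to_numpy()
        tab["gl"] = d.groups.to_numpy()
        csv = tmp_path / "design.csv"
        tab.to_csv(csv, index=False)
        terms = " + ".join(c for c in tab.columns if c not in ("soilT", "gl"))
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(soilT ~ {terms} + (1|gl), data=d, REML=TRUE)
        co <- fixef(m)
        cat(jsonlite::toJSON(as.list(co), auto_unbox=TRUE))
        """
        rfile = tmp_path / "fit.R"
        rfile.write_text(script)
        res = subprocess.run(["Rscript", str(rfile)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = json.loads(res.stdout)
        assert np.isclose(fit.params["intercept"], ref["(Intercept)"], atol=1e-3)
        for term in FIXED_TERMS[1:]:
            assert np.isclose(fit.params[term], ref[term.replace(":", "_x_")], atol=1e-3)

    def test_single_glacier_rejected(self, small_world):
        tab = small_world.monthly_table
        tab1 = tab[tab["glacier_id"] == tab["glacier_id"].iloc[0]]
        with pytest.raises(ValueError):
            fit_lmm(build_design(tab1.reset_index(drop=True)))


def stub_fit(design, params, var_glacier=0.5, var_residual=1.0):
    eta = design.X.to_numpy() @ params.to_numpy()
    vf = float(np.var(eta))
    tot = vf + var_glacier + var_residual
    return FitSummary(
        params=params, bse=params * 0 + 0.1,
        conf_int=pd.DataFrame({"lo": params - 1, "hi": params + 1}),
        var_fixed=vf, var_glacier=var_glacier, var_residual=var_residual,
        r2m=vf / tot, r2c=(vf + var_glacier) / tot, converged=True,
        n_obs=len(design.X), n_glaciers=design.n_glaciers,
    )


def synthetic_design(X: pd.DataFrame, y: np.ndarray, groups) -> "object":
    """Wrap a hand-built design matrix for the partitioning helpers."""
    from proglacial.soil_model import DesignMatrix

    return DesignMatrix(
        X=X, y=pd.Series(y, index=X.index), groups=pd.Series(groups, index=X.index),
        standardization=Standardization(means={"x": 0.0}, sds={"x": 1.0}),
        raw=pd.DataFrame(index=X.index),
        training_ranges=pd.DataFrame({"min": [0.0], "max": [1.0]}, index=["x"]),
    )


class TestVariancePartitioning:
    def test_zero_coefficient_term_has_zero_semi_partial(self, small_world):
        d = build_design(small_world.monthly_table)
        rng = np.random.default_rng(0)
        # response built from mT alone: every other term is pure noise
        y = 5.0 + 2.0 * d.X["mT"].to_numpy() + 0.1 * rng.standard_normal(len(d.X))
        d2 = synthetic_design(d.X, y, d.groups.to_numpy())
        fit = fit_lmm(d2)
        sp = semi_partial_r2(fit, d2, n_bootstrap=10, seed=0).set_index("term")
        assert sp.loc["rad", "semi_partial_r2"] < 0.005
        assert sp.loc["mT", "semi_partial_r2"] > 0.5

    def test_orthogonal_columns_decompose_exactly(self, small_world):
        d = build_design(small_world.monthly_table)
        # QR against a leading constant column: predictors come out zero-mean
        # and mutually orthogonal, so the variance decomposition is exact
        n = len(d.X)
        a = np.column_stack([np.ones(n), np.random.default_rng(1).normal(size=(n, 12))])
        q, _ = np.linalg.qr(a)
        X = pd.DataFrame(q[:, 1:] * np.sqrt(n), columns=list(FIXED_TERMS)[1:], index=d.X.index)
        X.insert(0, "intercept", 1.0)
        beta = pd.Series(np.linspace(0.5, 1.5, 13), index=list(FIXED_TERMS))
        rng = np.random.default_rng(2)
        y = X.to_numpy() @ beta.to_numpy() + 0.02 * rng.standard_normal(len(X))
        d2 = synthetic_design(X, y, d.groups.to_numpy())
        fit = fit_lmm(d2)
        sp = semi_partial_r2(fit, d2, n_bootstrap=0, seed=0)
        assert np.isclose(sp["semi_partial_r2"].sum(), fit.r2m, atol=0.01)

    def test_duplicated_predictor_has_no_unique_variance(self, small_world):
        d = build_design(small_world.monthly_table)
        X = d.X.copy()
        rng = np.random.default_rng(3)
        X["rad"] = X["mT"] + 1e-4 * rng.standard_normal(len(X))  # near-duplicate
        y = 1.0 + X["mT"].to_numpy() + X["rad"].to_numpy() + 0.3 * rng.standard_normal(len(X))
        d2 = synthetic_design(X, y, d.groups.to_numpy())
        fit = fit_lmm(d2)
        sp = semi_partial_r2(fit, d2, n_bootstrap=0, seed=0).set_index("term")
        # the surviving copy absorbs the shared variance on refit
        assert abs(sp.loc["rad", "semi_partial_r2"]) < 0.01
        assert abs(sp.loc["mT", "semi_partial_r2"]) < 0.01


class TestPermutationImportance:
    def test_zero_coefficient_predictor_zero_importance(self, small_world):
        d = build_design(small_world.monthly_table)
        params = pd.Series(0.0, index=list(FIXED_TERMS))
        params["intercept"] = 3.0
        params["mT"] = 1.5
        fit = stub_fit(d, params)
        imp = permutation_importance(fit, d, n_perm=5, seed=0).set_index("predictor")
        assert abs(imp.loc["pf", "importance"]) < 1e-12  # no additive or interactive term
        assert imp.loc["mT", "importance"] > 0.0

    def test_dominant_predictor_ranks_first(self, small_world):
        d = build_design(small_world.monthly_table)
        fit = fit_lmm(d)
        imp = permutation_importance(fit, d, n_perm=20, seed=1).set_index("predictor")
        assert imp["importance"].idxmax() == "mT"


class TestLoo:
    def test_fold_count_and_mean_stability(self, small_world):
        d = build_design(small_world.monthly_table)
        full = fit_lmm(d)
        loo = loo_by_glacier(d)
        assert len(loo.coefficients) == d.n_glaciers
        big = full.params.abs() > 0.5
        rel = (loo.mean_coefficients[big] - full.params[big]).abs() / full.params[big].abs()
        assert (rel < 0.05).all()

    def test_mean_row_predicts_mean_intercept(self, small_world):
        d = build_design(small_world.monthly_table)
        loo = loo_by_glacier(d)
        std = d.standardization
        row = pd.DataFrame(
            {
                "mT": [std.means["mT"]], "rad": [std.means["rad"]],
                "sfd": [std.means["sfd"]], "dg": [std.means["dg"] ** 2],
                "d": [std.means["d"]], "tc": [0.0], "pf": [0.0],
                "glacier_id": ["new"],
            }
        )
        d2 = build_design(row, standardization=std, sfd_cutoff=-np.inf)
        pred = predict_fixed(d2.X, loo.mean_coefficients)
        assert np.isclose(pred[0], loo.mean_coefficients["intercept"])

    def test_validation_wrmse_near_noise_floor(self):
        """Held-out prediction error ~ sqrt(glacier_var + residual_var)."""
        wrmses = []
        for seed in (31, 32, 33):
            world = generate_world(
                WorldConfig(n_glaciers=6, stations_per_glacier=4, n_months=12,
                            dem_size=24, seed=seed, residual_sd=1.5)
            )
            d = build_design(world.monthly_table)
            loo = loo_by_glacier(d)
            stats, _ = validate(
                d.y.to_numpy(), loo.predictions.to_numpy(),
                d.raw["region"], d.raw["glacier_id"], d.raw["sfd"],
            )
            wrmses.append(stats.wrmse)
        floor = np.sqrt(1.0**2 + 1.5**2)  # glacier sd 1.0, residual sd 1.5
        assert 0.6 * floor < np.mean(wrmses) < 1.3 * floor


class TestClustering:
    def test_single_linkage_oracle(self):
        x = np.array([0.0, 500.0, 900.0, 5000.0, 5400.0, 9000.0])
        y = np.zeros(6)
        labels = cluster_stations(x, y, max_distance=1000.0)
        # chain 0-500-900 joins; 5000-5400 joins; 9000 alone
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4]
        assert len({labels[0], labels[3], labels[5]}) == 3


class TestCutoffDiagnostics:
    def test_decoupling_fades_with_cutoff(self, small_world):
        tab = small_world.monthly_table
        diag = sfd_cutoff_diagnostics(tab, cutoffs=(0.0, 20.0), min_rows=50)
        d0 = diag[diag.cutoff == 0.0].iloc[0]
        d20 = diag[diag.cutoff == 20.0].iloc[0]
        # snow-decoupled months leave residual structure (heteroscedasticity)
        # that vanishes once the snowy months are discarded
        assert abs(d20["heteroscedasticity"]) < abs(d0["heteroscedasticity"])
        assert abs(d20["heteroscedasticity"]) < 0.1

    def test_no_snow_world_flat_diagnostics(self):
        world = generate_world(
            WorldConfig(n_glaciers=6, stations_per_glacier=4, n_months=12,
                        dem_size=24, seed=22, base_elevation=500.0, relief=100.0)
        )
        diag = sfd_cutoff_diagnostics(world.monthly_table, cutoffs=(0.0, 10.0, 20.0), min_rows=50)
        assert np.all(np.abs(diag["resid_trend_slope"]) < 0.05)

    def test_impossible_cutoff_skipped(self, small_world):
        diag = sfd_cutoff_diagnostics(small_world.monthly_table, cutoffs=(100.0,))
        assert diag.empty
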