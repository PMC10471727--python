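import numpy as np
import pandas as pd
import pytest

from proglacial import (
    Raster,
    SamplingDesign,
    build_design,
    delta_T,
    extrapolation_audit,
    latitude_band,
    mollweide_xy,
    project_soilT,
    stratified_sample,
    summarize,
    t_bp,
    t_var,
)
from proglacial.projection import TBP_CLASS_LABELS, buffering_records
from proglacial.synthetic import BAND_CLIMATES, _band_index_raster, period_covariate_rasters


@pytest.fixture(scope="module")
def projected(snowgap_world):
    """Closed-loop projection with the generating coefficients."""
    world = snowgap_world
    cov_e = period_covariate_rasters(world, "early")
    cov_l = period_covariate_rasters(world, "late")
    coefs = world.truth.standardized_coefficients
    std = world.truth.standardization
    early = project_soilT(coefs, std, cov_e)
    late = project_soilT(coefs, std, cov_l)
    return world, cov_e, cov_l, early, late


def sample_points(world, cov_l, seed=7):
    design = SamplingDesign(
        cell_size=world.config.dem_size * world.config.cell_size,
        distance_classes=((0.0, 70.0), (90.0, 160.0), (180.0, 250.0),
                          (270.0, 340.0), (360.0, 430.0)),
    )
    return design, stratified_sample(design, cov_l["dg"], seed=seed)


class TestProjectSoilT:
    def test_training_mean_covariates_predict_intercept(self, snowgap_world):
        d = build_design(snowgap_world.monthly_table)
        std = d.standardization
        n = 3
        mk = lambda v: Raster(np.full((n, n), v), origin=(0.0, n * 30.0))
        cov = {
            "months": pd.period_range("2019-01", periods=1, freq="M"),
            "mT": [mk(std.means["mT"])],
            "rad": [mk(std.means["rad"])],
            "sfd": [mk(std.means["sfd"])],
            "dg": mk(std.means["dg"] ** 2),
            "tc": mk(0.0),
            "pf": mk(0.0),
        }
        coefs = snowgap_world.truth.standardized_coefficients
        # depth at the training mean too, so every standardized column is 0
        out = project_soilT(coefs, std, cov, depth_cm=std.means["d"])
        assert np.allclose(out[0].data, coefs["intercept"], atol=1e-10)

    def test_closed_loop_matches_station_truth(self, snowgap_world):
        """Generating coefficients reproduce the stored monthly means."""
        world = snowgap_world
        d = build_design(world.monthly_table)
        from proglacial.soil_model import predict_fixed

        pred = predict_fixed(d.X, world.truth.standardized_coefficients)
        b = d.raw["glacier_id"].map(world.truth.glacier_intercepts).to_numpy()
        assert np.allclose(pred + b, d.y.to_numpy(), atol=1e-8)

    def test_low_sfd_cells_masked(self, projected):
        world, cov_e, _, early, _ = projected
        jan = cov_e["sfd"][0].data
        assert np.all(np.isnan(early[0].data[jan <= 20.0]))
        assert np.all(np.isfinite(early[0].data[jan > 20.0]))

    def test_misaligned_rasters_rejected(self, snowgap_world):
        mk = lambda n: Raster(np.zeros((n, n)), origin=(0.0, n * 30.0))
        cov = {
            "months": pd.period_range("2019-01", periods=1, freq="M"),
            "mT": [mk(4)], "rad": [mk(4)], "sfd": [mk(4)],
            "dg": mk(5), "tc": mk(5), "pf": mk(5),
        }
        with pytest.raises(ValueError, match="misaligned"):
            project_soilT(
                snowgap_world.truth.standardized_coefficients,
                snowgap_world.truth.standardization,
                cov,
            )


class TestStratifiedSample:
    def test_deterministic_under_seed(self, projected):
        world, _, cov_l, _, _ = projected
        _, p1 = sample_points(world, cov_l, seed=9)
        _, p2 = sample_points(world, cov_l, seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_distances_fall_inside_class_bands(self, projected):
        world, _, cov_l, _, _ = projected
        design, pts = sample_points(world, cov_l)
        dist = cov_l["dg"].data
        for _, p in pts.iterrows():
            lo, hi = design.distance_classes[int(p["class_index"])]
            assert lo <= dist[int(p["row"]), int(p["col"])] <= hi

    def test_no_duplicate_cells_within_cell_class(self, projected):
        world, _, cov_l, _, _ = projected
        _, pts = sample_points(world, cov_l)
        dup = pts.duplicated(subset=["cell_id", "class_index", "row", "col"])
        assert not dup.any()

    def test_incomplete_cells_dropped(self, projected):
        world, _, cov_l, _, _ = projected
        design, pts = sample_points(world, cov_l)
        counts = pts.groupby("cell_id").size()
        assert (counts == design.min_points).all()

    def test_unsatisfiable_design_raises(self, projected):
        world, _, cov_l, _, _ = projected
        design = SamplingDesign(
            cell_size=world.config.dem_size * world.config.cell_size,
            distance_classes=tuple((1e7 + k * 2e5, 1e7 + k * 2e5 + 1e5) for k in range(5)),
        )
        with pytest.raises(ValueError):
            stratified_sample(design, cov_l["dg"], seed=1)


class TestDeltaT:
    def test_identical_periods_zero(self, projected):
        world, cov_e, cov_l, early, _ = projected
        _, pts = sample_points(world, cov_l)
        dt = delta_T(pts, early, early, cov_e["months"])
        assert np.allclose(dt.dropna(), 0.0)

    def test_uniform_offset_recovered(self, projected):
        world, cov_e, cov_l, early, _ = projected
        _, pts = sample_points(world, cov_l)
        shifted = [r.like(r.data + 0.75) for r in early]
        dt = delta_T(pts, early, shifted, cov_e["months"])
        assert np.allclose(dt.dropna(), 0.75)

    def test_antisymmetry_under_period_swap(self, projected):
        world, cov_e, cov_l, early, late = projected
        _, pts = sample_points(world, cov_l)
        fwd = delta_T(pts, early, late, cov_e["months"])
        rev = delta_T(pts, late, early, cov_e["months"])
        assert np.allclose(fwd.dropna(), -rev.dropna())

    def test_imposed_trend_recovered(self, projected):
        """Closed loop: 0.5 °C/decade with a 15-year midpoint gap -> +0.75."""
        world, cov_e, cov_l, early, late = projected
        _, pts = sample_points(world, cov_l)
        dt = delta_T(pts, early, late, cov_e["months"])
        assert abs(float(np.nanmean(dt)) - 0.75) < 0.1

    def test_seasonal_subsets(self, projected):
        world, cov_e, cov_l, early, late = projected
        _, pts = sample_points(world, cov_l)
        for season in ("DJF", "MAM", "JJA", "SON"):
            dt = delta_T(pts, early, late, cov_e["months"], season=season)
            assert len(dt) == len(pts)


class TestTvar:
    def make_raster(self, values, cell=30.0):
        values = np.asarray(values, dtype=float)
        return Raster(values, origin=(0.0, values.shape[0] * cell), cell_size=cell)

    def center_point(self, raster):
        xs, ys = raster.cell_centers()
        r, c = raster.shape[0] // 2, raster.shape[1] // 2
        return pd.DataFrame({"row": [r], "col": [c], "x": [xs[r, c]], "y": [ys[r, c]]})

    def test_constant_raster_zero(self):
        r = self.make_raster(np.full((9, 9), 3.0))
        assert t_var(self.center_point(r), r, radius=250.0).iloc[0] == 0.0

    def test_quantile_oracle_1_to_100(self):
        r = self.make_raster(np.arange(1.0, 101.0).reshape(10, 10))
        out = t_var(self.center_point(r), r, radius=1e6)
        assert np.isclose(out.iloc[0], 79.2)  # q90 - q10, type-7

    def test_radius_below_cell_size_gives_zero_spread(self):
        r = self.make_raster(np.arange(1.0, 101.0).reshape(10, 10))
        out = t_var(self.center_point(r), r, radius=10.0)
        assert out.iloc[0] == 0.0

    def test_too_few_cells_missing(self):
        r = self.make_raster(np.arange(1.0, 101.0).reshape(10, 10))
        out = t_var(self.center_point(r), r, radius=31.0)  # host + 4 cardinal = 5 ok
        assert np.isfinite(out.iloc[0])
        out2 = t_var(self.center_point(r), r, radius=31.0, min_cells=6)
        assert np.isnan(out2.iloc[0])


class TestTbp:
    def test_signed_ratio_and_classes(self):
        out = t_bp([2.0, 2.0, 0.5, 25.0], [1.0, -1.0, 1.0, 1.0])
        assert list(out["t_bp"]) == [2.0, -2.0, 0.5, 25.0]
        assert list(out["t_bp_class"]) == ["(1,10]", "(-10,-1]", "(-1,1]", ">10"]

    def test_sign_follows_delta(self):
        rng = np.random.default_rng(1)
        tvar = rng.uniform(0.1, 5.0, 100)
        delta = rng.uniform(-2.0, 2.0, 100)
        delta[np.abs(delta) < 1e-6] = 0.5
        out = t_bp(tvar, delta)
        assert np.all(np.sign(out["t_bp"]) == np.sign(delta))

    def test_scale_invariance_of_class(self):
        out1 = t_bp([3.0], [1.5])
        out2 = t_bp([30.0], [15.0])
        assert out1["t_bp_class"].iloc[0] == out2["t_bp_class"].iloc[0]

    def test_near_zero_delta_sentinel(self):
        out = t_bp([1.0], [1e-9])
        assert np.isinf(out["t_bp"].iloc[0])
        assert out["t_bp_class"].iloc[0] == ">10"

    def test_negative_tvar_rejected(self):
        with pytest.raises(ValueError):
            t_bp([-0.1], [1.0])


class TestSummaries:
    def test_single_record_group(self):
        rec = pd.DataFrame(
            {"band": ["Northern"], "dist_class": ["0-100m"],
             "delta_T_annual": [0.4], "season_change": [3.0],
             "t_bp_class": ["(1,10]"]}
        )
        out = summarize(rec)
        assert out.iloc[0]["delta_T_annual_mean"] == 0.4
        assert np.isnan(out.iloc[0]["delta_T_annual_sd"])

    def test_class_percentages_sum_to_100(self, projected):
        world, cov_e, cov_l, early, late = projected
        _, pts = sample_points(world, cov_l)
        band_idx = _band_index_raster(world.config, world.terrain.elevation)
        names = np.array([b[0] for b in BAND_CLIMATES])
        band = pd.Series(names[band_idx[pts["row"], pts["col"]]], index=pts.index)
        rec = buffering_records(
            pts, early, late, cov_e["months"],
            cov_e["season_duration"], cov_l["season_duration"], band,
        )
        out = summarize(rec, by=("band",))
        pct_cols = [f"pct_{c}" for c in TBP_CLASS_LABELS]
        assert np.allclose(out[pct_cols].sum(axis=1), 100.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())


class TestExtrapolationAudit:
    def ranges(self):
        return pd.DataFrame({"min": {"mT": 0.0, "rad": 0.0}, "max": {"mT": 10.0, "rad": 20.0}})

    def test_all_inside_zero_percent(self):
        vals = pd.DataFrame({"mT": np.linspace(0, 10, 50), "rad": np.linspace(0, 20, 50)})
        out = extrapolation_audit(vals, self.ranges())
        assert (out == 0.0).all()

    def test_five_of_hundred_outside(self):
        v = np.linspace(0, 10, 100)
        v[:5] = 11.0
        out = extrapolation_audit(pd.DataFrame({"mT": v}), self.ranges())
        assert np.isclose(out["mT"], 5.0)


class TestGeo:
    def test_latitude_bands(self):
        assert latitude_band(47.0) == "Northern"
        assert latitude_band(-44.0) == "Southern"
        assert latitude_band(10.0) == "Inter-tropical"
        assert latitude_band(23.44) == "Inter-tropical"

    def test_mollweide_origin_and_symmetry(self):
        x, y = mollweide_xy(0.0, 0.0)
        assert abs(x) < 1e-6 and abs(y) < 1e-6
        x1, y1 = mollweide_xy(10.0, 45.0)
        x2, y2 = mollweide_xy(-10.0, -45.0)
        assert np.isclose(x1, -x2) and np.isclose(y1, -y2)
        assert y1 > 0 and x1 > 0
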