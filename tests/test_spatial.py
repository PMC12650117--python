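"""Stable-ecosystem masking, sampling, zonal profiles, ecosystem ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecovuln.grids import Grid
from ecovuln.model import IndexSeries
from ecovuln.spatial import (bin_profile, compact_letter_display,
                             ecosystem_anova, fit_gradient, multi_year_mean,
                             stable_ecosystem_mask, systematic_sample,
                             EcosystemSample)
from ecovuln.synthetic import LandcoverMaps, generate_landcover


def _series(stack, grid=None):
    stack = np.asarray(stack, dtype=float)
    grid = grid or Grid(stack.shape[1], stack.shape[2])
    years = np.arange(2000, 2000 + stack.shape[0])
    keys = ("EI", "SI", "RI", "VI", "EI_raw", "SI_raw", "T_norm", "P_norm")
    return IndexSeries(years, {k: stack.copy() for k in keys}, grid)


class TestStableMask:
    def test_identical_maps_give_vegetated_extent(self, tiny_config):
        lc = generate_landcover(tiny_config, [1983, 1990, 2000])
        stable, per_class = stable_ecosystem_mask(lc)
        np.testing.assert_array_equal(stable, lc.maps[0] > 0)
        union = np.zeros_like(stable)
        for m in per_class.values():
            union |= m
        np.testing.assert_array_equal(union, stable)

    def test_single_flip_excluded(self):
        maps = np.full((3, 4, 4), 2, dtype=np.int16)  # forest everywhere
        maps[1, 2, 2] = 3  # one pixel spends a year as grassland
        stable, _ = stable_ecosystem_mask(LandcoverMaps([0, 1, 2], maps))
        assert not stable[2, 2]
        assert stable.sum() == 15

    def test_churned_maps_match_generator_log(self, tiny_config):
        cfg = tiny_config.with_(grid_rows=50, grid_cols=50,
                                landcover_change_fraction=0.2,
                                landcover_change_year=1990)
        lc = generate_landcover(cfg, list(range(1983, 1995)))
        stable, _ = stable_ecosystem_mask(lc)
        veg = lc.maps[0] > 0
        frac = stable.sum() / veg.sum()
        assert abs(frac - 0.8) < 0.02
        # generator churn log agrees exactly with the mask
        assert not (stable & lc.changed_mask).any()

    def test_mask_is_monotone_in_years(self, tiny_config):
        cfg = tiny_config.with_(landcover_change_fraction=0.1,
                                landcover_change_year=1990)
        lc_full = generate_landcover(cfg, list(range(1983, 1995)))
        lc_part = LandcoverMaps(lc_full.years[:5], lc_full.maps[:5])
        m_full, _ = stable_ecosystem_mask(lc_full)
        m_part, _ = stable_ecosystem_mask(lc_part)
        assert (m_full <= m_part).all()  # more years can only shrink it

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            stable_ecosystem_mask(LandcoverMaps([0], np.zeros((1, 4, 4),
                                                              dtype=int)))


class TestMultiYearMean:
    def test_single_window_is_identity(self, rng):
        stack = rng.random((1, 5, 5))
        np.testing.assert_array_equal(multi_year_mean(_series(stack)),
                                      stack[0])

    def test_two_window_average(self):
        stack = np.stack([np.full((3, 3), 0.2), np.full((3, 3), 0.4)])
        np.testing.assert_allclose(multi_year_mean(_series(stack)), 0.3)

    def test_commutes_with_spatial_subsetting(self, rng):
        stack = rng.random((6, 8, 8))
        full = multi_year_mean(_series(stack))
        crop = multi_year_mean(_series(stack[:, 2:6, 1:5]))
        np.testing.assert_allclose(full[2:6, 1:5], crop)

    def test_sparse_pixels_masked(self, rng):
        stack = rng.random((10, 2, 2))
        stack[:6, 0, 0] = np.nan  # valid in 40% < 50%
        out = multi_year_mean(_series(stack))
        assert np.isnan(out[0, 0])
        assert np.isfinite(out[1, 1])


class TestSystematicSample:
    def test_full_mask_full_demand_returns_everything(self):
        mask = np.ones((12, 12), dtype=bool)
        pts = systematic_sample(mask, 144, seed=0)
        assert len(pts) == 144

    def test_count_close_to_target_on_uniform_mask(self):
        mask = np.ones((100, 100), dtype=bool)
        pts = systematic_sample(mask, 2088, seed=3)
        assert abs(len(pts) - 2088) / 2088 < 0.25  # integer-spacing granularity

    def test_deterministic_given_seed(self):
        mask = np.ones((40, 40), dtype=bool)
        mask[10:20, 10:20] = False
        assert systematic_sample(mask, 100, seed=5) == \
            systematic_sample(mask, 100, seed=5)

    def test_oversized_request_warns(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0] = True
        with pytest.warns(UserWarning, match="valid pixels"):
            pts = systematic_sample(mask, 100, seed=0)
        assert len(pts) == 5


class TestBinProfile:
    def test_constant_surface(self):
        g = Grid(10, 10, origin_lat=34.0, cell_size=0.2)
        surface = np.full((10, 10), 0.42)
        prof = bin_profile(surface, g.latitude_raster(), 1.0)
        _, means = prof.occupied()
        np.testing.assert_allclose(means, 0.42)

    def test_surface_equal_to_coordinate(self):
        g = Grid(30, 5, origin_lat=35.0, cell_size=0.1)
        lat = g.latitude_raster()
        prof = bin_profile(lat, lat, 1.0)
        has = prof.bin_counts > 0
        for lo, hi, m in zip(prof.bin_edges[:-1][has],
                             prof.bin_edges[1:][has], prof.bin_means[has]):
            assert lo <= m <= hi

    def test_matches_bruteforce_groupby(self, rng):
        g = Grid(25, 25, origin_lat=34.0, cell_size=0.11)
        surface = rng.random((25, 25))
        surface[rng.random((25, 25)) < 0.2] = np.nan
        lat = g.latitude_raster()
        prof = bin_profile(surface, lat, 0.5)
        df = pd.DataFrame({"lat": lat.ravel(), "v": surface.ravel()}).dropna()
        df["bin"] = np.floor(df["lat"] / 0.5) * 0.5
        ref = df.groupby("bin")["v"].mean()
        for b, m in ref.items():
            i = np.searchsorted(prof.bin_edges, b + 1e-9) - 1
            assert prof.bin_means[i] == pytest.approx(m, abs=1e-10)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            bin_profile(np.zeros((2, 2)), np.zeros((2, 2)), 0.0)


class TestGradientFit:
    def _profile(self, x, y):
        edges = np.concatenate([x - 0.5, [x[-1] + 0.5]])
        from ecovuln.spatial import BinnedProfile
        return BinnedProfile(edges, np.asarray(y, float),
                             np.ones(len(x), dtype=int), "latitude", "VI")

    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_gradient(self._profile(x, 2.0 + 0.3 * x), "linear")
        assert fit.slopes[0] == pytest.approx(0.3)
        assert fit.r_squared == pytest.approx(1.0)

    def test_v_shape_breakpoint_located(self):
        x = np.arange(15.0)
        k = 6
        y = np.abs(x - k) * 0.2 + 1.0
        fit = fit_gradient(self._profile(x, y), "piecewise")
        assert abs(fit.breakpoint - k) <= 1
        assert fit.slopes[0] < 0 < fit.slopes[1]

    def test_flat_profile_not_significant(self, rng):
        """Under the null the slope test should rarely reject."""
        rejections = 0
        for _ in range(100):
            y = rng.normal(0.5, 0.05, 12)
            fit = fit_gradient(self._profile(np.arange(12.0), y), "linear")
            rejections += fit.p_value < 0.05
        assert rejections <= 12  # ~5% expected, generous MC margin

    def test_insufficient_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_gradient(self._profile(np.arange(2.0), [0, 1]), "linear")


def _samples(class_values: dict[str, np.ndarray]) -> list[EcosystemSample]:
    out = []
    for cname, vals in class_values.items():
        for i, v in enumerate(vals):
            out.append(EcosystemSample(i, 0, 0.0, 0.0, cname,
                                       {"VI": float(v)}))
    return out


class TestEcosystemAnova:
    def test_f_matches_hand_computation(self):
        """3 groups x 4 values toy table against textbook mean squares."""
        groups = {"forest": np.array([1.0, 2.0, 3.0, 4.0]),
                  "grassland": np.array([2.0, 3.0, 4.0, 5.0]),
                  "wetland": np.array([5.0, 6.0, 7.0, 8.0])}
        vals = np.concatenate(list(groups.values()))
        grand = vals.mean()
        ss_between = sum(4 * (g.mean() - grand) ** 2 for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        f_ref = (ss_between / 2) / (ss_within / 9)
        res = ecosystem_anova(_samples(groups), "VI")
        assert res.f_statistic == pytest.approx(f_ref)

    def test_balanced_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0.4, 0.1, 30)
        b = rng.normal(0.5, 0.1, 30)
        res = ecosystem_anova(_samples({"forest": a, "wetland": b}), "VI")
        t = stats.ttest_ind(a, b).statistic
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_extreme_separation_gets_distinct_letters(self, rng):
        a = rng.normal(0.0, 0.05, 40)
        b = rng.normal(10 * 0.05 * np.sqrt(2) + 1, 0.05, 40)
        res = ecosystem_anova(_samples({"forest": a, "wetland": b}), "VI")
        assert set(res.letters["forest"]) != set(res.letters["wetland"])

    def test_null_rarely_separates_letters(self, rng):
        """Tukey–Kramer controls the family-wise error near alpha."""
        identical = 0
        n_sim = 150
        for _ in range(n_sim):
            groups = {c: rng.normal(0.5, 0.1, 20)
                      for c in ("a", "b", "c", "d")}
            res = ecosystem_anova(_samples(groups), "VI")
            identical += len(set(res.letters.values())) == 1
        assert identical / n_sim >= 0.92  # ≈95% minus Monte-Carlo margin

    def test_small_class_dropped_with_warning(self, rng):
        groups = {"forest": rng.normal(0.4, 0.1, 20),
                  "wetland": rng.normal(0.5, 0.1, 20),
                  "cropland": np.array([0.3])}
        with pytest.warns(UserWarning, match="dropping"):
            res = ecosystem_anova(_samples(groups), "VI")
        assert "cropland" not in res.class_means


class TestCompactLetters:
    def test_chain_structure(self):
        # a > b > c with a~b and b~c distinct from a
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        distinct = {("x", "z")}
        letters = compact_letter_display(["x", "y", "z"], means, distinct)
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])

    def test_all_distinct(self):
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        distinct = {("x", "y"), ("x", "z"), ("y", "z")}
        letters = compact_letter_display(["x", "y", "z"], means, distinct)
        assert len({frozenset(v) for v in letters.values()}) == 3
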