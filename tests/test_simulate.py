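"""Generator contracts: geometry, field moments, masting, nests, NB counts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from snowsync.covariance import matern_correlation
from snowsync.simulate import (GenerativeConfig, MissingCovariateError,
                               StudyRegion, generate_region_and_triangles,
                               simulate_cone_series, simulate_counts,
                               simulate_dataset, simulate_matern_ar1_field,
                               simulate_nests)


class TestRegionAndTriangles:
    def test_counts_lengths_and_ids(self, small_region):
        cfg = GenerativeConfig(n_wildlife=100, n_field=50, n_years=3, seed=1)
        skel = generate_region_and_triangles(cfg, small_region)
        tri = skel.drop_duplicates("triangle_id")
        assert len(tri) == 150
        assert (tri.loc[tri.triangle_type == "wildlife", "length_km"] == 12.0).all()
        assert (tri.loc[tri.triangle_type == "field", "length_km"] == 6.0).all()
        assert tri.triangle_type.value_counts().to_dict() == {
            "wildlife": 100, "field": 50}

    def test_certain_census(self, small_region):
        cfg = GenerativeConfig(n_wildlife=30, n_field=10, n_years=4,
                               census_prob_per_year=1.0, seed=2)
        skel = generate_region_and_triangles(cfg, small_region)
        assert skel["censused"].all()

    def test_field_triangles_concentrated_south(self, small_region):
        cfg = GenerativeConfig(n_wildlife=50, n_field=400, n_years=1, seed=3)
        skel = generate_region_and_triangles(cfg, small_region)
        field = skel[skel.triangle_type == "field"].drop_duplicates("triangle_id")
        frac_south = (field["y_km"] < small_region.southern_cut_y_km).mean()
        assert frac_south >= 0.8

    def test_censused_per_year_is_binomial(self, small_region):
        """~1,900 transects at p=0.3 give ~570 censuses/year; exact binomial
        test on the total number of censuses at alpha=0.001."""
        cfg = GenerativeConfig(n_wildlife=1500, n_field=400, n_years=5,
                               census_prob_per_year=0.3, seed=4)
        skel = generate_region_and_triangles(cfg, small_region)
        per_year = skel.groupby("year")["censused"].sum()
        assert abs(per_year.mean() - 570) < 60
        test = binomtest(int(skel["censused"].sum()), len(skel), 0.3)
        assert test.pvalue > 0.001

    def test_invalid_config_rejected(self, small_region):
        with pytest.raises(ValueError):
            GenerativeConfig(n_wildlife=0, n_field=1).validate()
        with pytest.raises(ValueError):
            StudyRegion(width_km=-10, height_km=100)

    def test_fixed_coordinates_across_years(self, small_region):
        cfg = GenerativeConfig(n_wildlife=20, n_field=10, n_years=6, seed=5)
        skel = generate_region_and_triangles(cfg, small_region)
        assert (skel.groupby("triangle_id")[["x_km", "y_km"]].nunique() == 1).all().all()


class TestFieldSimulator:
    def test_marginal_variance_stationary(self):
        """Monte-Carlo marginal variance equals field_sd^2 in every year
        (stationary AR1 initialisation)."""
        coords = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 80.0]])
        rng = np.random.default_rng(0)
        reps = np.stack([simulate_matern_ar1_field(coords, 5, 100.0, 0.8, 0.7, rng)
                         for _ in range(2000)])
        var = reps.var(axis=0)  # (T, S)
        se = 0.8 ** 2 * np.sqrt(2 / 2000)
        assert np.all(np.abs(var - 0.64) < 4 * se)

    def test_spatial_correlation_at_range(self):
        """Correlation at d = range is the Matérn value ~0.14."""
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        rng = np.random.default_rng(1)
        reps = np.stack([simulate_matern_ar1_field(coords, 1, 100.0, 1.0, 0.5, rng)
                         for _ in range(2000)])[:, 0, :]
        r = np.corrcoef(reps[:, 0], reps[:, 1])[0, 1]
        assert r == pytest.approx(matern_correlation(100.0, 100.0), abs=3 / np.sqrt(2000))
        assert matern_correlation(100.0, 100.0) == pytest.approx(0.14, abs=0.005)

    def test_independence_at_large_distance(self):
        coords = np.array([[0.0, 0.0], [5000.0, 0.0]])
        rng = np.random.default_rng(2)
        reps = np.stack([simulate_matern_ar1_field(coords, 1, 50.0, 1.0, 0.0, rng)
                         for _ in range(2000)])[:, 0, :]
        r = np.corrcoef(reps[:, 0], reps[:, 1])[0, 1]
        assert abs(r) < 3 / np.sqrt(2000)

    def test_temporal_ar1_correlation(self):
        coords = np.array([[0.0, 0.0], [3000.0, 0.0]])
        rng = np.random.default_rng(3)
        reps = np.stack([simulate_matern_ar1_field(coords, 2, 50.0, 1.0, 0.6, rng)
                         for _ in range(2000)])
        r = np.corrcoef(reps[:, 0, 0], reps[:, 1, 0])[0, 1]
        assert r == pytest.approx(0.6, abs=3 / np.sqrt(2000))

    def test_duplicate_sites_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="singular|duplicate"):
            simulate_matern_ar1_field(coords, 2, 100.0, 1.0, 0.5, np.random.default_rng(0))


class TestConeSeries:
    def _sites(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"site_id": [f"C{i}" for i in range(n)],
                             "x_km": rng.uniform(0, 300, n),
                             "y_km": rng.uniform(0, 500, n)})

    def test_failure_year_rules(self):
        sites = self._sites()
        out = simulate_cone_series(sites, range(2000, 2006), {2002}, 7,
                                   southern_cut_y_km=250.0, missing_frac=0.4)
        south_fail = out[(out.year == 2002) & (out.y_km < 250.0)]
        vals = south_fail["cones_per_tree"]
        assert ((vals == 0) | vals.isna()).all()
        assert vals.isna().any()  # some recorded as missing for imputation
        north_fail = out[(out.year == 2002) & (out.y_km >= 250.0)]
        assert (north_fail["cones_per_tree"] > 0).all()

    def test_non_failure_years_non_negative(self):
        out = simulate_cone_series(self._sites(), range(2000, 2004), set(), 8)
        assert (out["cones_per_tree"] >= 0).all()

    def test_masting_year_effect_dominates_spatial_variation(self):
        """Between-year CV of the regional mean exceeds within-year spatial CV."""
        out = simulate_cone_series(self._sites(60, 1), range(2000, 2015), set(), 9)
        yearly = out.groupby("year")["cones_per_tree"].mean()
        between_cv = yearly.std() / yearly.mean()
        within_cv = (out.groupby("year")["cones_per_tree"]
                     .apply(lambda v: v.std() / v.mean()).mean())
        assert between_cv > within_cv


class TestNests:
    def test_poisson_intensity(self):
        region = StudyRegion(width_km=100.0, height_km=60.0, southern_cut_y_km=30.0)
        counts = [simulate_nests(region, [2000], 3.0, 0.9, np.random.default_rng(s))
                  ["nest_id"].nunique() for s in range(40)]
        # density x area = 3 * 6000 km^2 / 100 = 180 expected territories
        assert np.mean(counts) == pytest.approx(180, abs=3 * np.sqrt(180 / 40))

    def test_full_persistence(self):
        region = StudyRegion(width_km=100.0, height_km=60.0, southern_cut_y_km=30.0)
        nests = simulate_nests(region, range(2000, 2010), 3.0, 1.0,
                               np.random.default_rng(0))
        assert nests["occupied"].all()

    def test_default_density_in_reported_band(self):
        assert 2.0 <= GenerativeConfig().nest_density_per_100km2 <= 4.0


class TestCounts:
    def _skel(self, n, length=12.0):
        return pd.DataFrame({"triangle_id": [f"T{i}" for i in range(n)],
                             "year": 2000, "length_km": length})

    def test_offset_doubles_expected_count(self):
        cfg = GenerativeConfig(beta={"intercept": -1.0}, nb_overdispersion=np.inf)
        rng = np.random.default_rng(0)
        y12 = simulate_counts(self._skel(4000, 12.0), cfg, None, rng)
        y6 = simulate_counts(self._skel(4000, 6.0), cfg, None, rng)
        ratio = y12.mean() / y6.mean()
        assert ratio == pytest.approx(2.0, rel=0.08)

    def test_poisson_limit_mean(self):
        cfg = GenerativeConfig(beta={"intercept": -1.0}, nb_overdispersion=np.inf)
        y = simulate_counts(self._skel(20000), cfg, None, np.random.default_rng(1))
        assert y.mean() / 12.0 == pytest.approx(np.exp(-1.0), rel=0.03)

    def test_nb2_variance_identity(self):
        """var/mean at fixed mu is 1 + mu/alpha within Monte-Carlo error."""
        alpha, mu_per = 1.5, np.exp(-0.5)
        cfg = GenerativeConfig(beta={"intercept": -0.5}, nb_overdispersion=alpha)
        y = simulate_counts(self._skel(40000), cfg, None, np.random.default_rng(2))
        mu = 12.0 * mu_per
        expected = 1.0 + mu / alpha
        assert y.var() / y.mean() == pytest.approx(expected, rel=0.06)

    def test_missing_covariate_names_row(self):
        cfg = GenerativeConfig(beta={"intercept": -1.0, "cone_index": 0.4})
        skel = self._skel(3)
        skel["cone_index"] = [0.1, np.nan, 0.3]
        with pytest.raises(MissingCovariateError, match="T1"):
            simulate_counts(skel, cfg, None, np.random.default_rng(3))


class TestEndToEnd:
    def test_reproducible_byte_identical(self, small_config, small_region, small_dataset):
        again = simulate_dataset(small_config, small_region)
        for key in ("census", "nests", "cones"):
            pd.testing.assert_frame_equal(small_dataset[key], again[key])
            assert (small_dataset[key].to_csv(index=False)
                    == again[key].to_csv(index=False))

    def test_count_means_match_generative_mu(self):
        """Per-observation empirical count mean over replicates equals the
        generative NB mean within 3 standard errors."""
        rng = np.random.default_rng(12)
        n, alpha = 15, 1.5
        skel = pd.DataFrame({"triangle_id": [f"T{i}" for i in range(n)],
                             "year": 2000, "length_km": 12.0,
                             "cone_index": rng.normal(0, 0.5, n)})
        cfg = GenerativeConfig(beta={"intercept": -1.0, "cone_index": 0.4},
                               nb_overdispersion=alpha)
        w = rng.normal(0, 0.5, n)
        mu = 12.0 * np.exp(-1.0 + 0.4 * skel["cone_index"].to_numpy() + w)
        reps = 3000
        draws = np.stack([simulate_counts(skel, cfg, w, np.random.default_rng(s))
                          for s in range(reps)])
        se = np.sqrt((mu + mu ** 2 / alpha) / reps)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 3.5 * se)

    def test_schema_columns_present(self, small_dataset):
        census = small_dataset["census"]
        for col in ("triangle_id", "triangle_type", "x_km", "y_km", "length_km",
                    "year", "squirrel_tracks", "marten_tracks",
                    "temperature_prev_day", "precipitation_prev_day", "censused"):
            assert col in census.columns
        cens = census[census["censused"]]
        assert cens["squirrel_tracks"].notna().all()
        assert (cens["squirrel_tracks"].astype(int) >= 0).all()
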