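"""Balanced sampling, raster extraction, predictor filtering, PCA."""

import numpy as np
import pandas as pd
import pytest

from karstspat.drivers import (
    balance_sample,
    extract_env,
    filter_predictors,
    run_pca,
    separation_diagnostic,
)
from karstspat.rasters import Raster


def tagged_points(n_kl, n_nkl, rng=None, bbox=(0.0, 0.0, 10.0, 10.0)):
    rng = rng or np.random.default_rng(0)
    west, south, east, north = bbox
    n = n_kl + n_nkl
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(n)],
            "decimalLongitude": rng.uniform(west, east, n),
            "decimalLatitude": rng.uniform(south, north, n),
            "landscape": ["KL"] * n_kl + ["NKL"] * n_nkl,
        }
    )


class TestBalanceSample:
    def test_nkl_subsampled_to_kl_count(self):
        out = balance_sample(tagged_points(100, 500), seed=1)
        assert (out["landscape"] == "KL").sum() == 100
        assert (out["landscape"] == "NKL").sum() == 100

    def test_equal_counts_returns_input(self):
        df = tagged_points(50, 50)
        pd.testing.assert_frame_equal(balance_sample(df, 1), df)

    def test_fixed_seed_reproducible(self):
        df = tagged_points(30, 300)
        pd.testing.assert_frame_equal(
            balance_sample(df, 7), balance_sample(df, 7)
        )

    def test_smaller_nkl_class_left_alone(self):
        df = tagged_points(100, 40)
        out = balance_sample(df, 1)
        assert len(out) == 140

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_sample(tagged_points(0, 10), 1)


class TestExtractEnv:
    def _raster(self, data, west=0.0, south=0.0, cell=1.0):
        return Raster(np.asarray(data, dtype=float), west, south, cell)

    def test_constant_raster_gives_constant_column(self):
        r = self._raster(np.full((10, 10), 7.5))
        df = tagged_points(3, 3)
        env, dropped = extract_env(df, {"BIO1": r})
        assert (env["BIO1"] == 7.5).all() and dropped == 0

    def test_point_at_cell_center_reads_that_cell(self):
        data = np.arange(9).reshape(3, 3)
        r = self._raster(data, cell=1.0)
        df = pd.DataFrame(
            {
                "species": ["a"],
                "decimalLongitude": [1.5],
                "decimalLatitude": [1.5],
                "landscape": ["KL"],
            }
        )
        env, _ = extract_env(df, {"x": r})
        assert env.loc[0, "x"] == data[1, 1]

    def test_values_match_index_arithmetic_oracle(self, rng):
        data = rng.normal(size=(20, 30))
        r = self._raster(data, west=100.0, south=5.0, cell=0.1)
        lons = rng.uniform(100.0, 103.0, 200)
        lats = rng.uniform(5.0, 7.0, 200)
        df = pd.DataFrame(
            {
                "species": "s",
                "decimalLongitude": lons,
                "decimalLatitude": lats,
                "landscape": "NKL",
            }
        )
        env, _ = extract_env(df, {"x": r})
        for i, (lon, lat) in enumerate(zip(lons, lats)):
            col = int((lon - 100.0) / 0.1)
            row = int((7.0 - lat) / 0.1)
            assert env.loc[i, "x"] == data[row, col]

    def test_nodata_points_dropped_and_counted(self):
        data = np.full((4, 4), 1.0)
        data[0, 0] = -9999.0  # north-west cell
        r = self._raster(data, cell=1.0)
        df = pd.DataFrame(
            {
                "species": ["a", "b"],
                "decimalLongitude": [0.5, 2.5],
                "decimalLatitude": [3.5, 0.5],
                "landscape": ["KL", "NKL"],
            }
        )
        env, dropped = extract_env(df, {"x": r})
        assert dropped == 1 and len(env) == 1

    def test_point_outside_extent_rejected(self):
        r = self._raster(np.zeros((2, 2)), cell=1.0)
        df = pd.DataFrame(
            {
                "species": ["a"],
                "decimalLongitude": [5.0],
                "decimalLatitude": [0.5],
                "landscape": ["KL"],
            }
        )
        with pytest.raises(ValueError, match="outside raster extent"):
            extract_env(df, {"x": r})


def env_frame(columns, response):
    df = pd.DataFrame(columns)
    df["karst"] = response
    return df


class TestFilterPredictors:
    def test_response_copy_retained(self):
        y = [0, 0, 1, 1, 0, 1]
        env = env_frame({"good": [float(v) for v in y]}, y)
        out, log = filter_predictors(env)
        assert "good" in out.columns and log.n_dropped == 0

    def test_weak_predictor_dropped(self, rng):
        y = np.repeat([0, 1], 100)
        weak = rng.normal(size=200)  # r ~ 0 with the response
        strong = y + rng.normal(0, 0.5, 200)
        env = env_frame({"weak": weak, "strong": strong}, y)
        out, log = filter_predictors(env)
        assert "strong" in out.columns
        assert [c for c, _ in log.weak_response] == ["weak"]

    def test_zero_variance_predictor_dropped(self):
        y = [0, 1, 0, 1]
        env = env_frame({"flat": [1.0] * 4, "ok": [0.0, 1.0, 0.1, 0.9]}, y)
        out, log = filter_predictors(env)
        assert log.zero_variance == ["flat"]
        assert "ok" in out.columns

    def test_collinear_trio_keeps_best_response_correlate(self, rng):
        """Three mutually collinear predictors: the survivor equals the
        one chosen by stepping the stated greedy rule by hand."""
        y = np.repeat([0.0, 1.0], 150)
        base = y + rng.normal(0, 0.4, 300)
        a = base + rng.normal(0, 0.10, 300)
        b = base + rng.normal(0, 0.15, 300)
        c = base + rng.normal(0, 0.20, 300)
        env = env_frame({"a": a, "b": b, "c": c}, y.astype(int))
        out, log = filter_predictors(env)

        # independent re-derivation of the greedy pruning
        cols = {"a": a, "b": b, "c": c}
        resp = {k: np.corrcoef(v, y)[0, 1] for k, v in cols.items()}
        alive = list(cols)
        while len(alive) > 1:
            pairs = [
                (abs(np.corrcoef(cols[p], cols[q])[0, 1]), p, q)
                for i, p in enumerate(alive)
                for q in alive[i + 1 :]
            ]
            r, p, q = max(pairs)
            if r <= 0.70:
                break
            alive.remove(p if abs(resp[p]) < abs(resp[q]) else q)
        survivors = [col for col in out.columns if col != "karst"]
        assert survivors == alive

    def test_too_few_class_members_rejected(self):
        env = env_frame({"x": [0.0, 1.0, 2.0]}, [0, 1, 1])
        with pytest.raises(ValueError, match="each class"):
            filter_predictors(env)


class TestRunPca:
    def test_perfectly_correlated_pair_loads_on_single_component(self, rng):
        x = rng.normal(size=50)
        env = env_frame({"BIO1": x, "BIO4": 3 * x + 1}, rng.integers(0, 2, 50))
        res = run_pca(env)
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_isotropic_cloud_splits_variance_evenly(self, rng):
        env = env_frame(
            {"BIO1": rng.normal(size=4000), "BIO4": rng.normal(size=4000)},
            rng.integers(0, 2, 4000),
        )
        res = run_pca(env)
        assert res.explained_pct[0] == pytest.approx(50.0, abs=3.0)

    def test_known_covariance_matches_analytic_eigenvalues(self, rng):
        """Correlation matrix [[1, rho], [rho, 1]] has eigenvalues
        1 +- rho, so PC1 must explain (1 + rho)/2 of the variance."""
        rho = 0.6
        n = 60000
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        env = env_frame(
            {"BIO1": z[:, 0], "BIO4": z[:, 1]}, rng.integers(0, 2, n)
        )
        res = run_pca(env)
        sample_rho = abs(np.corrcoef(z[:, 0], z[:, 1])[0, 1])
        assert res.explained_pct[0] == pytest.approx(
            (1 + sample_rho) / 2 * 100, abs=1e-6
        )
        assert res.explained_pct[0] == pytest.approx((1 + rho) / 2 * 100, abs=1.0)

    def test_variance_explained_sums_to_hundred(self, rng):
        cols = {f"BIO{i}": rng.normal(size=40) for i in (1, 4, 7, 12)}
        res = run_pca(env_frame(cols, rng.integers(0, 2, 40)))
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(res.explained_pct) <= 1e-12)

    def test_matches_independent_eigendecomposition(self, rng):
        """Variance explained agrees with a direct eigendecomposition
        of the correlation matrix."""
        cols = {f"v{i}": rng.normal(size=80) * (i + 1) for i in range(5)}
        cols["v1"] = cols["v0"] * 0.5 + cols["v1"]
        env = env_frame(cols, rng.integers(0, 2, 80))
        res = run_pca(env)
        X = env.drop(columns="karst").to_numpy()
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        eig = np.linalg.eigvalsh(np.cov(Xz, rowvar=False))[::-1]
        np.testing.assert_allclose(
            res.explained_pct, eig / eig.sum() * 100, atol=1e-9
        )

    def test_loadings_orthonormal(self, rng):
        cols = {f"v{i}": rng.normal(size=50) for i in range(4)}
        res = run_pca(env_frame(cols, rng.integers(0, 2, 50)))
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-9)

    def test_invariant_to_column_order_and_rescaling(self, rng):
        cols = {"BIO1": rng.normal(size=60), "BIO4": rng.normal(size=60),
                "BIO7": rng.normal(size=60)}
        y = rng.integers(0, 2, 60)
        a = run_pca(env_frame(cols, y))
        shuffled = {
            "BIO7": cols["BIO7"] * 100 + 3,
            "BIO1": cols["BIO1"] * -2,
            "BIO4": cols["BIO4"],
        }
        b = run_pca(env_frame(shuffled, y))
        np.testing.assert_allclose(a.explained_pct, b.explained_pct, atol=1e-9)

    def test_mode_selects_variable_families(self, rng):
        cols = {
            "BIO1": rng.normal(size=30),
            "BIO4": rng.normal(size=30),
            "elevation": rng.normal(size=30),
            "clay": rng.normal(size=30),
        }
        env = env_frame(cols, rng.integers(0, 2, 30))
        assert list(run_pca(env, "bioclim_only").loadings.index) == ["BIO1", "BIO4"]
        assert list(run_pca(env, "soil_only").loadings.index) == ["elevation", "clay"]

    def test_single_variable_rejected(self, rng):
        env = env_frame({"BIO1": rng.normal(size=30)}, rng.integers(0, 2, 30))
        with pytest.raises(ValueError, match=">= 2 variables"):
            run_pca(env)


class TestSeparationDiagnostic:
    def _result_from_scores(self, kl, nkl):
        from karstspat.drivers import PcaResult

        scores = pd.DataFrame(
            np.vstack([kl, nkl]), columns=["PC1", "PC2"]
        )
        scores["landscape"] = ["KL"] * len(kl) + ["NKL"] * len(nkl)
        return PcaResult(
            loadings=pd.DataFrame(),
            explained_pct=np.array([60.0, 40.0]),
            scores=scores,
            mode="all",
        )

    def test_identical_clouds_are_nested(self, rng):
        cloud = rng.normal(size=(50, 2))
        s = separation_diagnostic(self._result_from_scores(cloud, cloud))
        assert s.centroid_distance == pytest.approx(0.0)
        assert s.nested

    def test_strongly_shifted_clouds_not_nested(self, rng):
        cloud = rng.normal(size=(50, 2))
        s = separation_diagnostic(
            self._result_from_scores(cloud, cloud + [10.0, 0.0])
        )
        assert not s.nested
        assert s.centroid_distance > 5

    def test_diagnostic_grows_with_planted_effect_size(self, rng):
        cloud = rng.normal(size=(100, 2))
        dists = [
            separation_diagnostic(
                self._result_from_scores(cloud, cloud + [shift, 0.0])
            ).centroid_distance
            for shift in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(dists, dists[1:]))
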