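import numpy as np
import pandas as pd
import pytest

from icfra.synthetic import PAPER_TONOTOPY_COEFFS, SceneConfig, generate_population
from icfra.tonotopy import (
    binned_summaries,
    cross_validate,
    depth_cf_correlation,
    fit,
    min_cf_position,
    project,
    soma_diameter,
    summarize_by_genotype,
)


def _population_xy_cf(n=300, jitter=0.0, seed=0, theta_deg=None):
    kw = {} if theta_deg is None else {"theta_deg": theta_deg}
    cfg = SceneConfig(n_neurons=n, cf_jitter_oct=jitter, seed=seed, **kw)
    pop = generate_population(cfg)
    return (
        np.array([p.x_um for p in pop]),
        np.array([p.y_um for p in pop]),
        np.array([p.true_cf_khz for p in pop]),
        cfg,
    )


class TestProjection:
    def test_axis_aligned(self):
        assert project(3.0, 7.0, 0.0) == pytest.approx(3.0)
        assert project(3.0, 7.0, np.pi / 2) == pytest.approx(7.0)

    def test_diagonal(self):
        assert project(100.0, 100.0, np.radians(45)) == pytest.approx(141.42, abs=0.01)


class TestJointFit:
    def test_noiseless_recovery_of_angle_and_coefficients(self):
        x, y, cf, cfg = _population_xy_cf(n=400, jitter=0.0, seed=2)
        f = fit(x, y, cf)
        assert abs(f.theta_deg - cfg.theta_deg) < 1.0
        np.testing.assert_allclose(f.coeffs, PAPER_TONOTOPY_COEFFS, rtol=0.01)
        assert f.variance_explained > 0.999

    def test_translation_changes_only_parameterization(self):
        x, y, cf, _ = _population_xy_cf(n=300, jitter=0.2, seed=3)
        f0 = fit(x, y, cf)
        f1 = fit(x + 500.0, y - 250.0, cf)
        assert f1.variance_explained == pytest.approx(
            f0.variance_explained, abs=1e-6
        )

    def test_variance_explained_monotone_in_order(self):
        x, y, cf, _ = _population_xy_cf(n=300, jitter=0.3, seed=4)
        ve = [fit(x, y, cf, order=k, compute_min=False).variance_explained
              for k in (1, 2, 3, 4, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(ve, ve[1:]))

    def test_theta_reported_in_half_circle(self):
        x, y, cf, _ = _population_xy_cf(n=100, jitter=0.1, seed=5)
        f = fit(x, y, cf)
        assert 0 <= f.theta_rad < np.pi

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match=">= 25"):
            fit(np.arange(10.0), np.arange(10.0), np.full(10, 8.0))


class TestMinimumPosition:
    def test_pure_quadratic_closed_form(self):
        # a2 r^2 + a1 r, minimum at -a1/(2 a2)
        r = min_cf_position((1.0, -0.004, 2e-6), (0.0, 2000.0))
        assert r == pytest.approx(-(-0.004) / (2 * 2e-6), rel=1e-6)

    def test_monotone_polynomial_raises_with_direction(self):
        with pytest.raises(ValueError, match="increasing"):
            min_cf_position((0.0, 1e-3, 1e-8), (0.0, 1000.0))

    def test_published_coefficients_minimum_near_625(self):
        r = min_cf_position(PAPER_TONOTOPY_COEFFS, (0.0, 1400.0))
        assert r == pytest.approx(625.0, abs=10.0)


class TestCrossValidation:
    def test_noiseless_test_matches_train(self):
        x, y, cf, _ = _population_xy_cf(n=400, jitter=0.0, seed=6)
        cv = cross_validate(x, y, cf, seed=1)
        assert cv["train_variance_explained"] > 0.999
        assert cv["test_variance_explained"] == pytest.approx(
            cv["train_variance_explained"], abs=0.005
        )

    def test_heavy_noise_shows_overfitting(self):
        x, y, cf, _ = _population_xy_cf(n=120, jitter=1.5, seed=7)
        cvs = [cross_validate(x, y, cf, seed=s) for s in range(8)]
        gaps = [c["train_variance_explained"] - c["test_variance_explained"]
                for c in cvs]
        assert np.mean(gaps) > 0

    def test_same_seed_same_split(self):
        x, y, cf, _ = _population_xy_cf(n=200, jitter=0.4, seed=8)
        assert cross_validate(x, y, cf, seed=5) == cross_validate(x, y, cf, seed=5)


class TestBinnedSummaries:
    def _table(self, x, y, cf=None, fra=None):
        d = {"x_um": x, "y_um": y}
        if cf is not None:
            d["cf_khz"] = cf
        if fra is not None:
            d["fra_type"] = fra
        return pd.DataFrame(d)

    def test_uniform_cf_gives_uniform_geomeans(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.uniform(0, 500, 60), rng.uniform(0, 500, 60),
                        cf=np.full(60, 7.3))
        out = binned_summaries(t, theta_rad=0.5)
        assert np.allclose(out["cf"]["cf_geomean_khz"], 7.3)

    def test_two_cells_geometric_mean(self):
        t = self._table([10.0, 20.0], [0.0, 0.0], cf=[4.0, 16.0])
        out = binned_summaries(t, theta_rad=0.0, cf_bin_um=75.0)
        assert len(out["cf"]) == 1
        assert out["cf"]["cf_geomean_khz"].iloc[0] == pytest.approx(8.0)

    def test_edge_cell_joins_upper_bin(self):
        t = self._table([75.0, 10.0], [0.0, 0.0], cf=[8.0, 8.0])
        out = binned_summaries(t, theta_rad=0.0, cf_bin_um=75.0)
        assert list(out["cf"]["r_lo_um"]) == [0.0, 75.0]
        assert list(out["cf"]["n"]) == [1, 1]

    def test_class_proportions_normalized_per_bin(self):
        t = self._table(
            [10, 20, 30, 40], [0, 0, 0, 0],
            fra=["onset", "onset", "inhibited", "offset"],
        )
        out = binned_summaries(t, theta_rad=0.0, class_axis_bin_um=50.0)
        row = out["class_axis"].iloc[0]
        assert row["onset"] == pytest.approx(0.5)
        assert row["inhibited"] == pytest.approx(0.25)
        assert row["n"] == 4


class TestDepthCorrelation:
    def test_perfect_negative_relation(self):
        depth = np.linspace(10, 100, 30)
        cf = 10.0 ** (3.0 - depth / 100.0)  # log10 CF linear in depth
        r, n = depth_cf_correlation(depth, cf)
        assert r == pytest.approx(-1.0)
        assert n == 30

    def test_strip_restriction_subsets(self):
        rng = np.random.default_rng(1)
        depth = rng.uniform(10, 150, 200)
        cf = rng.lognormal(2, 0.5, 200)
        r_um = rng.uniform(0, 1400, 200)
        _, n_all = depth_cf_correlation(depth, cf)
        _, n_strip = depth_cf_correlation(depth, cf, r_um, strip_um=(525, 725))
        assert n_strip == ((r_um >= 525) & (r_um <= 725)).sum() < n_all

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            depth_cf_correlation([1, 2], [3, 4])


class TestSomaSize:
    def test_circle_formula(self):
        assert soma_diameter(np.pi) == pytest.approx(2.0)
        assert soma_diameter(100.0) == pytest.approx(11.2838, abs=1e-3)

    def test_alternative_scaling(self):
        assert soma_diameter(100.0, formula="4_over_pi") == pytest.approx(
            (4 / np.pi) * 10.0
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            soma_diameter(0.0)

    def test_genotype_summary(self):
        t = pd.DataFrame(
            {
                "genotype": ["GP4.3"] * 3 + ["Gad2;Ai96"] * 2,
                "diameter_um": [12.0, 14.0, 13.0, 20.0, 22.0],
            }
        )
        s = summarize_by_genotype(t)
        assert s.loc["GP4.3", "mean"] == pytest.approx(13.0)
        assert s.loc["Gad2;Ai96", "mean"] == pytest.approx(21.0)
        assert s.loc["GP4.3", "n"] == 3
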