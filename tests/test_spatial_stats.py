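import numpy as np
import pandas as pd
import pytest

from sptstates import spatial_stats as sp
from sptstates import synthetic_data as sd
from sptstates import tracking_io as tio


def _loc(xy_um):
    xy = np.asarray(xy_um, float)
    return tio.LocalizationTable(
        pd.DataFrame(
            {"x_nm": xy[:, 0] * 1e3, "y_nm": xy[:, 1] * 1e3, "frame": range(len(xy))}
        )
    )


def _steps_at(mx, my, state=1):
    n = len(mx)
    return tio.StepTable(
        pd.DataFrame(
            {
                "track": 0,
                "start_frame": range(n),
                "lag": 0.05,
                "dx": 0.0,
                "dy": 0.0,
                "r": 0.0,
                "mx": mx,
                "my": my,
                "state": state,
            }
        ),
        lag=0.05,
    )


def test_render_all_points_one_pixel():
    dmap = sp.render_density(_loc([[0.01, 0.01]] * 7), pixel_nm=32.5, shape=(4, 4))
    assert dmap.counts.sum() == 7
    assert (dmap.counts > 0).sum() == 1


def test_render_uniform_counts_poisson_consistent():
    rng = np.random.default_rng(1)
    xy = rng.uniform(0, 3.25, size=(100000, 2))
    dmap = sp.render_density(_loc(xy), pixel_nm=32.5, shape=(100, 100))
    counts = dmap.counts.ravel()
    # index of dispersion ~ 1 for Poisson; se of ratio ~ sqrt(2/n)
    ratio = counts.var() / counts.mean()
    assert abs(ratio - 1.0) < 4 * np.sqrt(2 / counts.size)


def test_render_crop_is_centered_and_origin_shifts():
    rng = np.random.default_rng(2)
    xy = rng.uniform(0, 10, size=(1000, 2))
    full = sp.render_density(_loc(xy), pixel_nm=500.0, shape=(20, 20))
    crop = sp.render_density(_loc(xy), pixel_nm=500.0, shape=(20, 20), crop_px=10)
    assert crop.shape == (10, 10)
    assert np.allclose(crop.origin, (2.5, 2.5))
    assert np.array_equal(crop.counts, full.counts[5:15, 5:15])


def test_render_rejects_oversized_crop():
    with pytest.raises(ValueError, match="crop"):
        sp.render_density(_loc([[0.1, 0.1], [0.2, 0.2]]), pixel_nm=100.0,
                          shape=(5, 5), crop_px=10)


def test_classify_four_distinct_intensities():
    dmap = sp.DensityMap(counts=np.array([[1, 2], [3, 4]]), pixel_nm=32.5)
    sp.classify_density(dmap)
    assert np.array_equal(dmap.classes, np.array([[1, 2], [3, 4]]))
    assert not dmap.degenerate


def test_classify_ties_give_equal_class_sizes():
    counts = np.zeros((20, 20), dtype=int)
    counts[:2, :5] = 7  # a few non-zero pixels, many tied zeros
    dmap = sp.DensityMap(counts=counts, pixel_nm=32.5)
    sp.classify_density(dmap)
    occ = np.bincount(dmap.classes.ravel(), minlength=5)[1:]
    assert occ.max() - occ.min() <= 1


def test_classify_constant_map_flagged_degenerate():
    dmap = sp.DensityMap(counts=np.ones((8, 8), dtype=int), pixel_nm=32.5)
    sp.classify_density(dmap)
    assert dmap.degenerate
    occ = np.bincount(dmap.classes.ravel(), minlength=5)[1:]
    assert occ.max() - occ.min() <= 1


def test_enrichment_all_steps_in_top_class():
    counts = np.arange(16).reshape(4, 4)
    dmap = sp.classify_density(sp.DensityMap(counts=counts, pixel_nm=1000.0))
    # class 4 pixels are the last row; put all midpoints there
    steps = _steps_at(mx=[0.5, 1.5, 2.5], my=[3.5, 3.5, 3.5])
    enr = sp.step_enrichment(dmap, steps)
    assert np.allclose(enr.fractions(1), [0, 0, 0, 1])


def test_enrichment_uniform_midpoints_quarter_per_class():
    loc = sd.simulate_point_pattern(
        sd.PointPatternSpec(
            kind="thomas-cluster", window=(7.15, 7.15), seed=5,
            parent_intensity=4.0, cluster_sd=0.12, mean_offspring=60,
        )
    )
    dmap = sp.classify_density(sp.render_density(loc, pixel_nm=32.5, shape=(220, 220)))
    rng = np.random.default_rng(9)
    side = 220 * dmap.pixel_um
    mid = rng.uniform(0, side, size=(10000, 2))
    enr = sp.step_enrichment(dmap, _steps_at(mid[:, 0], mid[:, 1]))
    frac = enr.fractions(1)
    # binomial se = sqrt(.25*.75/1e4) ~ 0.0043
    assert np.all(np.abs(frac - 0.25) < 3 * 0.00433)
    assert np.isclose(frac.sum(), 1.0)


def test_enrichment_outside_crop_steps_dropped():
    dmap = sp.classify_density(
        sp.DensityMap(counts=np.arange(16).reshape(4, 4), pixel_nm=1000.0)
    )
    steps = _steps_at(mx=[0.5, 99.0], my=[0.5, 99.0])
    enr = sp.step_enrichment(dmap, steps)
    assert enr.n_dropped == 1
    assert enr.table["n"].sum() == 1


def test_average_enrichment_across_cells():
    dmap = sp.classify_density(
        sp.DensityMap(counts=np.arange(16).reshape(4, 4), pixel_nm=1000.0)
    )
    e1 = sp.step_enrichment(dmap, _steps_at([0.5], [3.5]))  # class 4
    e2 = sp.step_enrichment(dmap, _steps_at([0.5], [0.5]))  # class 1
    avg = sp.average_enrichment([e1, e2])
    f = avg.table.sort_values("class")["fraction"].to_numpy()
    assert np.allclose(f, [0.5, 0.0, 0.0, 0.5])


def test_ripley_two_distant_points_zero():
    kr = sp.ripley_k(np.array([[0.0, 0.0], [5.0, 0.0]]), area_S=100.0,
                     r_grid=np.array([1.0]))
    assert kr.K[0] == 0.0


def test_ripley_three_point_hand_example():
    """Collinear points at unit spacing, S = 10, r = 1.5:
    4 ordered pairs within r -> K = (10/2) * (4/3) = 20/3."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    kr = sp.ripley_k(pts, area_S=10.0, r_grid=np.array([1.5]))
    assert np.isclose(kr.K[0], 20.0 / 3.0)
    lmr = sp.l_function(kr)["L_minus_r"].to_numpy()
    assert np.isclose(lmr[0], np.sqrt(20.0 / (3.0 * np.pi)) - 1.5, atol=1e-12)


def test_ripley_equals_naive_double_loop():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 5, size=(100, 2))
    r_grid = np.linspace(0.1, 2.0, 10)
    kr = sp.ripley_k(pts, area_S=25.0, r_grid=r_grid)
    N = len(pts)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    for i, r in enumerate(r_grid):
        count = np.sum(d <= r) - N  # exclude self-pairs
        K_naive = (25.0 / (N - 1)) * (count / N)
        assert kr.K[i] == K_naive


def test_ripley_K_monotone_and_zero_at_origin():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 5, size=(500, 2))
    kr = sp.ripley_k(pts, area_S=25.0, r_grid=np.linspace(0.0, 1.0, 20))
    assert kr.K[0] == 0.0
    assert np.all(np.diff(kr.K) >= 0)


def test_ripley_rejects_degenerate_input():
    with pytest.raises(ValueError, match="at least 2"):
        sp.ripley_k(np.array([[0.0, 0.0]]), 10.0, np.array([1.0]))
    with pytest.raises(ValueError, match="area"):
        sp.ripley_k(np.zeros((3, 2)), 0.0, np.array([1.0]))


def test_l_minus_r_of_zero_K_is_minus_r():
    kr = sp.ripley_k(np.array([[0.0, 0.0], [5.0, 0.0]]), area_S=100.0,
                     r_grid=np.array([0.5, 1.0]))
    assert np.allclose(sp.l_function(kr)["L_minus_r"], [-0.5, -1.0])


def test_csr_mean_L_minus_r_within_envelope():
    """CSR replicate mean of L(r) - r stays inside the 95% envelope of 0
    at small r (uncorrected estimator, r <= 5% of window)."""
    r_grid = np.linspace(0.02, 0.5, 13)
    curves = []
    for s in range(40):
        loc = sd.simulate_point_pattern(
            sd.PointPatternSpec(kind="csr", window=(10.0, 10.0),
                                expected_count=3000, seed=600 + s)
        )
        kr = sp.ripley_k(loc.xy_um(), 100.0, r_grid)
        curves.append(kr.L_minus_r)
    curves = np.array(curves)
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(len(curves))
    # allow the small negative edge bias of the uncorrected estimator
    assert np.all(np.abs(mean) <= np.maximum(2 * se, 0.012))


def test_thomas_pattern_L_minus_r_positive_at_cluster_scale():
    cluster_sd = 0.1
    loc = sd.simulate_point_pattern(
        sd.PointPatternSpec(kind="thomas-cluster", window=(10.0, 10.0), seed=8,
                            parent_intensity=1.0, cluster_sd=cluster_sd,
                            mean_offspring=30)
    )
    kr = sp.ripley_k(loc.xy_um(), 100.0, np.array([cluster_sd, 2 * cluster_sd]))
    assert np.all(kr.L_minus_r > 0.05)
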