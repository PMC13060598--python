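import numpy as np
import pytest
from scipy import stats

from sptstates import msd_analysis as ma
from sptstates import spatial_stats as sp
from sptstates import synthetic_data as sd
from sptstates.state_hmm import StateModel


def _spec(model, **kw):
    defaults = dict(n_tracks=500, mean_track_length=20.0, loc_sd=0.0, seed=42)
    defaults.update(kw)
    return sd.SimulationSpec(model=model, **defaults)


def test_fixed_seed_gives_identical_output(interphase_model):
    a = sd.simulate_tracks(_spec(interphase_model, n_tracks=50))
    b = sd.simulate_tracks(_spec(interphase_model, n_tracks=50))
    assert a.data.equals(b.data)


def test_zero_diffusion_zero_noise_is_static():
    model = StateModel(D=[0.0], transmat=[[1.0]], frame_interval=0.05)
    ts = sd.simulate_tracks(_spec(model, n_tracks=20))
    steps = ma.compute_steps(ts, 1)
    assert np.all(steps.r == 0)


def test_single_state_step_variance_matches_2Ddt():
    # per-axis variance of one-frame steps is 2 D dt (sd = 0)
    D, dt = 0.1, 0.05
    model = StateModel(D=[D], transmat=[[1.0]], frame_interval=dt)
    ts = sd.simulate_tracks(_spec(model, n_tracks=2500, mean_track_length=42.0))
    steps = ma.compute_steps(ts, 1)
    assert len(steps) > 1e5 * 0.9
    expect = 2 * D * dt
    for axis in ("dx", "dy"):
        var = steps.data[axis].var()
        se = expect * np.sqrt(2 / len(steps))  # MC error of a variance estimate
        assert abs(var - expect) < 3 * se


def test_localization_noise_adds_to_step_variance():
    # per-axis step variance = 2 D dt + 2 sd^2 with localization error
    D, dt, lsd = 0.05, 0.05, 0.02
    model = StateModel(D=[D], transmat=[[1.0]], frame_interval=dt)
    ts = sd.simulate_tracks(_spec(model, n_tracks=2500, mean_track_length=42.0, loc_sd=lsd))
    steps = ma.compute_steps(ts, 1)
    expect = 2 * D * dt + 2 * lsd**2
    se = expect * np.sqrt(2 / len(steps))
    assert abs(steps.data["dx"].var() - expect) < 3 * se


def test_three_state_model_per_state_step_variances(interphase_tracks, interphase_model):
    """Per-state empirical MSD of one-frame steps matches 4 D dt."""
    steps = ma.compute_steps(interphase_tracks, 1)
    dt = interphase_model.frame_interval
    for s, D in enumerate(interphase_model.D, start=1):
        r2 = steps.data.loc[steps.data["state"] == s, "r"] ** 2
        expect = 4 * D * dt
        se = expect * np.sqrt(2 / len(r2))
        assert abs(r2.mean() - expect) < 4 * se


def test_state_occupancy_converges_to_stationary(interphase_model):
    ts = sd.simulate_tracks(_spec(interphase_model, n_tracks=5000, mean_track_length=22.0))
    labels = ts.data["state"].dropna().to_numpy(int)
    occ = np.bincount(labels - 1, minlength=3) / len(labels)
    assert np.abs(occ - interphase_model.occupancy).sum() < 0.02


def test_track_lengths_follow_geometric_law(interphase_model):
    mean_len = 20.0
    ts = sd.simulate_tracks(
        _spec(interphase_model, n_tracks=10000, mean_track_length=mean_len)
    )
    lengths = ts.track_lengths().to_numpy()
    assert lengths.min() >= 2
    # lengths - 1 ~ geometric (support 1, 2, ...) with mean mean_len - 1;
    # KS distance evaluated on the discrete support
    p = 1.0 / (mean_len - 1.0)
    ks_vals = np.arange(1, lengths.max())
    ecdf = np.searchsorted(np.sort(lengths - 1), ks_vals, side="right") / len(lengths)
    ks_dist = np.abs(ecdf - stats.geom(p).cdf(ks_vals)).max()
    assert ks_dist < 0.02


def test_invalid_specs_rejected(interphase_model):
    with pytest.raises(ValueError):
        sd.SimulationSpec(model=interphase_model, n_tracks=0)
    with pytest.raises(ValueError):
        sd.SimulationSpec(model=interphase_model, mean_track_length=1.0)
    with pytest.raises(ValueError):
        sd.SimulationSpec(model=interphase_model, loc_sd=-0.001)
    with pytest.raises(ValueError, match="sum to 1"):
        StateModel(D=[0.1, 0.2], transmat=[[0.9, 0.2], [0.1, 0.9]], frame_interval=0.05)
    with pytest.raises(ValueError, match="negative"):
        StateModel(D=[-0.1], transmat=[[1.0]], frame_interval=0.05)


def test_csr_pattern_count_and_uniformity():
    spec = sd.PointPatternSpec(kind="csr", window=(10.0, 10.0), expected_count=10000, seed=1)
    loc = sd.simulate_point_pattern(spec)
    n = len(loc)
    assert abs(n - 10000) < 4 * np.sqrt(10000)  # Poisson error
    # chi-square quadrat test on a 5x5 grid
    xy = loc.xy_um()
    counts, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=5, range=[[0, 10], [0, 10]])
    chi2 = ((counts - n / 25) ** 2 / (n / 25)).sum()
    assert chi2 < stats.chi2(24).ppf(0.999)


def test_csr_expected_count_zero_gives_empty_table():
    spec = sd.PointPatternSpec(kind="csr", window=(10.0, 10.0), expected_count=0, seed=1)
    assert len(sd.simulate_point_pattern(spec)) == 0


def test_thomas_cluster_has_short_range_pair_excess():
    """Clustered pattern shows pair-count excess at r <~ 2 cluster sd vs CSR."""
    window = (10.0, 10.0)
    sd_c = 0.05
    thomas = sd.simulate_point_pattern(
        sd.PointPatternSpec(
            kind="thomas-cluster", window=window, seed=3,
            parent_intensity=2.0, cluster_sd=sd_c, mean_offspring=25,
        )
    )
    csr = sd.simulate_point_pattern(
        sd.PointPatternSpec(kind="csr", window=window, expected_count=len(thomas), seed=4)
    )

    def pair_fraction(xy, r):  # brute-force pair counting
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        n = len(xy)
        return (np.sum(d <= r) - n) / (n * (n - 1))

    sub_t = thomas.xy_um()[:800]
    sub_c = csr.xy_um()[:800]
    assert pair_fraction(sub_t, 2 * sd_c) > 5 * pair_fraction(sub_c, 2 * sd_c)


def test_point_pattern_spec_validation():
    with pytest.raises(ValueError, match="positive area"):
        sd.PointPatternSpec(kind="csr", window=(0.0, 10.0), expected_count=10)
    with pytest.raises(ValueError, match="thomas-cluster requires"):
        sd.PointPatternSpec(kind="thomas-cluster", window=(10.0, 10.0))
    with pytest.raises(ValueError, match="only valid for thomas"):
        sd.PointPatternSpec(kind="csr", window=(10.0, 10.0), expected_count=5, cluster_sd=0.1)


def test_fixed_emitters_zero_sd_identical_positions():
    ts = sd.simulate_fixed_emitters(5, sd=0.0, frames=10, seed=0)
    for _, sub in ts.tracks():
        assert sub["x"].nunique() == 1
        assert sub["y"].nunique() == 1


def test_colocalized_tracks_uniform_and_coupled(interphase_model):
    # build a clustered density map
    loc = sd.simulate_point_pattern(
        sd.PointPatternSpec(
            kind="thomas-cluster", window=(7.15, 7.15), seed=5,
            parent_intensity=4.0, cluster_sd=0.12, mean_offspring=60,
        )
    )
    dmap = sp.classify_density(sp.render_density(loc, pixel_nm=32.5, shape=(220, 220)))
    spec = sd.SimulationSpec(
        model=interphase_model, n_tracks=3000, mean_track_length=8.0,
        loc_sd=0.0, window=(7.15, 7.15), seed=6,
    )
    # uniform placement: ~0.25 per class for every state
    ts0 = sd.simulate_colocalized_tracks(dmap, spec, coupling=[0.0, 0.0, 0.0])
    steps0 = ma.compute_steps(ts0, 1)
    enr0 = sp.step_enrichment(dmap, steps0)
    frac0 = enr0.fractions(2)
    assert np.all(np.abs(frac0 - 0.25) < 0.04)
    # liquid-like coupling > 0: top-density class enriched above 0.25
    ts1 = sd.simulate_colocalized_tracks(dmap, spec, coupling=[0.0, 1.5, 0.0])
    enr1 = sp.step_enrichment(dmap, ma.compute_steps(ts1, 1))
    assert enr1.fractions(2)[3] > 0.25 + 0.02
    assert enr1.fractions(2)[3] > frac0[3]


def test_coupling_weight_mismatch_rejected(interphase_model):
    loc = sd.simulate_point_pattern(
        sd.PointPatternSpec(kind="csr", window=(2.0, 2.0), expected_count=500, seed=1)
    )
    dmap = sp.classify_density(sp.render_density(loc, pixel_nm=100, shape=(20, 20)))
    spec = sd.SimulationSpec(model=interphase_model, n_tracks=5, seed=0)
    with pytest.raises(ValueError, match="one coupling weight per"):
        sd.simulate_colocalized_tracks(dmap, spec, coupling=[0.0, 1.0])
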