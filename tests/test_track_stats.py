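import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kar3team.synthetic_data import MotionPreset, PRESETS, Track, generate_tracks
from kar3team.track_stats import (
    MsdCurve,
    TrackTooShortError,
    assign_size,
    compute_msd,
    count_bleach_steps,
    diffusion_table,
    dwell_times,
    fit_brightness_mixture,
    fit_exponential,
    fit_gaussian,
    fit_msd_linear,
    fit_power_law,
    track_brightness,
    track_velocities,
    track_velocity,
)


def _line_track(v, n=20, dt=0.2, tid=0, noise=0.0, rng=None):
    t = np.arange(n) * dt
    x = v * t
    if noise and rng is not None:
        x = x + rng.normal(0, noise, n)
    return Track(tid, t, x, np.ones(n))


class TestVelocity:
    def test_exact_line(self):
        assert track_velocity(_line_track(77.0)) == pytest.approx(77.0)

    def test_static(self):
        assert track_velocity(_line_track(0.0)) == pytest.approx(0.0)

    def test_short_track_excluded(self):
        with pytest.raises(TrackTooShortError):
            track_velocity(_line_track(1.0, n=4))
        df = track_velocities([_line_track(1.0, n=4), _line_track(2.0, n=10, tid=1)])
        assert df.excluded.tolist() == [True, False]
        assert df.reason.tolist() == ["too_short", ""]

    def test_population_recovers_preset(self):
        # 0.5 s sampling keeps nearly every run above the 5-frame cut; coarser
        # sampling preferentially drops short-lived fast tracks and biases low
        tracks, _ = generate_tracks(PRESETS["wt_atp"], 699, 0.5, 1)
        df = track_velocities(tracks)
        g = fit_gaussian(df.loc[~df.excluded, "velocity_nm_s"])
        assert abs(g.mean - 77.0) < 2 * 23.0 / np.sqrt(g.n)


class TestDistributionFits:
    def test_exponential_uncensored_closed_form(self):
        assert fit_exponential([1.0, 2.0, 3.0]).mean == pytest.approx(2.0)

    def test_exponential_censored_closed_form(self):
        fit = fit_exponential([1.0, 2.0, 3.0], [False, False, True])
        assert fit.mean == pytest.approx(3.0)
        assert fit.n_censored == 1

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, 2.0], [True, True])

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=30),
        st.data(),
    )
    @settings(max_examples=30, deadline=None)
    def test_censored_mle_matches_likelihood_grid(self, values, data):
        censored = data.draw(
            st.lists(st.booleans(), min_size=len(values), max_size=len(values))
        )
        if all(censored):
            censored[0] = False
        mle = fit_exponential(values, censored).mean
        # brute-force likelihood over a mean grid around the closed form
        grid = np.linspace(mle / 3, mle * 3, 4001)
        v = np.asarray(values)
        c = np.asarray(censored)
        ll = -np.outer(1 / grid, v).sum(axis=1) - np.log(grid) * (~c).sum()
        assert abs(grid[np.argmax(ll)] - mle) / mle < 0.01

    def test_gaussian_fit_is_sample_moments(self, rng):
        x = rng.normal(10, 2, 500)
        g = fit_gaussian(x)
        assert g.mean == pytest.approx(x.mean())
        assert g.sd == pytest.approx(x.std(ddof=0))

    def test_runlength_recovery_with_censoring(self, rng):
        true = 5200.0
        draws = rng.exponential(true, 209)
        cap = true * np.log(10)
        censored = draws > cap
        vals = np.minimum(draws, cap)
        fit = fit_exponential(vals, censored)
        assert fit.mean == pytest.approx(true, rel=0.1)


class TestMsd:
    def test_pure_drift_quadratic(self):
        msd = compute_msd([_line_track(10.0, n=40)])
        np.testing.assert_allclose(msd.msd_nm2, (10.0 * msd.lag_s) ** 2, rtol=1e-9)

    def test_static_noise_plateau(self, rng):
        sigma = 20.0
        tracks = [
            Track(i, np.arange(200) * 0.1, rng.normal(0, sigma, 200), np.ones(200))
            for i in range(60)
        ]
        msd = compute_msd(tracks)
        assert np.mean(msd.msd_nm2) == pytest.approx(2 * sigma**2, rel=0.05)

    def test_brownian_recovers_d(self):
        d = 0.02
        p = MotionPreset("b", "diffusive", d_um2_s=d, residence_tau=3.0,
                         localization_sd=0.0)
        tracks, _ = generate_tracks(p, 1000, 0.0286, 3)
        d_est, _ = fit_msd_linear(compute_msd(tracks))
        assert d_est == pytest.approx(d, rel=0.05)

    def test_time_reversal_symmetric(self):
        tr = _line_track(5.0, n=30, noise=10.0, rng=np.random.default_rng(2))
        rev = Track(1, tr.time_s, tr.position_nm[::-1].copy(), tr.intensity)
        a = compute_msd([tr])
        b = compute_msd([rev])
        np.testing.assert_allclose(a.msd_nm2, b.msd_nm2, rtol=1e-12)

    def test_mixed_frame_intervals_rejected(self):
        a = _line_track(1.0, dt=0.1)
        b = _line_track(1.0, dt=0.2, tid=1)
        with pytest.raises(ValueError, match="mixed"):
            compute_msd([a, b])

    def test_lifetime_filter(self):
        short = _line_track(1.0, n=3, dt=0.1)  # 0.2 s
        ok = _line_track(1.0, n=20, dt=0.1, tid=1)  # 1.9 s
        msd = compute_msd([short, ok], lifetime_filter=(0.5, 5.0))
        assert msd.n_tracks.max() == 1
        with pytest.raises(ValueError, match="lifetime"):
            compute_msd([short], lifetime_filter=(0.5, 5.0))


class TestPowerLaw:
    def test_exact_power_law_recovered(self):
        lag = np.linspace(0.1, 3.0, 30)
        msd = MsdCurve(lag, 100.0 * lag**1.5, np.full(30, 1000))
        fit = fit_power_law(msd, offset=False)
        assert fit.a == pytest.approx(100.0, rel=1e-6)
        assert fit.n == pytest.approx(1.5, rel=1e-6)
        with_c = fit_power_law(msd)
        assert with_c.n == pytest.approx(1.5, rel=1e-3)

    def test_d_reported_only_near_linear(self):
        lag = np.linspace(0.1, 3.0, 20)
        lin = fit_power_law(MsdCurve(lag, 2e4 * lag, np.full(20, 100)))
        assert lin.d_um2_s == pytest.approx(0.01, rel=1e-3)
        quad = fit_power_law(MsdCurve(lag, 1e4 * lag**2, np.full(20, 100)),
                             offset=False)
        assert quad.d_um2_s is None

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(MsdCurve(np.array([0.1, 0.2, 0.3]),
                                   np.array([1.0, 2.0, 3.0]),
                                   np.array([5, 5, 5])))

    def test_directed_ensemble_exponent_near_two(self):
        tracks, _ = generate_tracks(PRESETS["wt_atp"], 150, 0.2, 8)
        fit = fit_power_law(compute_msd(tracks))
        assert 1.85 <= fit.n <= 2.1

    def test_diffusive_ensemble_exponent_near_one(self):
        tracks, _ = generate_tracks(PRESETS["mutant_atp"], 300, 0.0286, 9)
        fit = fit_power_law(compute_msd(tracks))
        assert 0.9 <= fit.n <= 1.1


class TestDiffusionTable:
    def test_ratios(self):
        table = diffusion_table(
            {"apo": {"wt": 0.00045, "mutant": 0.01},
             "adp": {"wt": 0.05, "mutant": 0.05},
             "amppnp": {"wt": None, "mutant": 0.0036}}
        )
        apo = table.set_index("state").loc["apo"]
        assert apo.mutant_to_wt_ratio == pytest.approx(22.2, rel=0.01)
        assert table.set_index("state").loc["adp"].mutant_to_wt_ratio == 1.0
        assert np.isnan(table.set_index("state").loc["amppnp"].mutant_to_wt_ratio)


class TestBleachSteps:
    def test_noiseless_single_step(self):
        trace = np.r_[np.full(30, 2.0), np.zeros(30)]
        n, times = count_bleach_steps(trace, frame_interval=1.0)
        assert n == 1
        assert times == [30.0]

    def test_noiseless_two_steps(self):
        trace = np.r_[np.full(20, 2.0), np.full(20, 1.0), np.zeros(20)]
        n, _ = count_bleach_steps(trace)
        assert n == 2

    def test_flat_trace_no_steps(self, rng):
        n, _ = count_bleach_steps(rng.normal(5.0, 0.1, 80))
        assert n == 0

    def test_upward_shift_not_counted_as_bleach(self):
        trace = np.r_[np.zeros(30), np.full(30, 2.0)]
        n, _ = count_bleach_steps(trace)
        assert n == 0

    def test_non_finite_rejected(self):
        trace = np.full(20, 1.0)
        trace[3] = np.nan
        with pytest.raises(ValueError):
            count_bleach_steps(trace)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            count_bleach_steps(np.ones(5))


class TestBrightnessMixture:
    def test_recovers_generator_truth(self, rng):
        sizes = rng.choice([1, 2, 3, 4], p=[0.55, 0.3, 0.1, 0.05], size=2000)
        vals = rng.normal(sizes * 1000.0, np.sqrt(sizes) * 150.0)
        fit = fit_brightness_mixture(vals)
        assert fit.mu1 == pytest.approx(1000.0, rel=0.05)
        np.testing.assert_allclose(fit.weights, [0.55, 0.3, 0.1, 0.05], atol=0.05)

    def test_single_component(self, rng):
        vals = rng.normal(1000.0, 100.0, 500)
        fit = fit_brightness_mixture(vals)
        assert fit.weights[0] > 0.95

    def test_scale_equivariance(self, rng):
        sizes = rng.choice([1, 2], p=[0.6, 0.4], size=800)
        vals = rng.normal(sizes * 500.0, np.sqrt(sizes) * 60.0)
        a = fit_brightness_mixture(vals)
        b = fit_brightness_mixture(vals * 3.0)
        assert b.mu1 == pytest.approx(3.0 * a.mu1, rel=1e-6)
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-8)

    def test_assignment(self, rng):
        sizes = rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1], size=1500)
        vals = rng.normal(sizes * 1000.0, np.sqrt(sizes) * 120.0)
        fit = fit_brightness_mixture(vals)
        assigned = np.array([assign_size(v, fit) for v in vals])
        assert (assigned == sizes).mean() > 0.9

    def test_track_brightness_first_frames(self):
        tr = Track(0, np.arange(5) * 0.1, np.zeros(5),
                   np.array([10.0, 12.0, 8.0, 100.0, 100.0]))
        assert track_brightness(tr) == pytest.approx(10.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_brightness_mixture([1.0, 2.0])


class TestDwellTimes:
    def test_exact(self):
        tracks = [_line_track(0.0, n=7, dt=0.1, tid=i) for i in range(3)]
        fit = dwell_times(tracks)
        assert fit.mean == pytest.approx(0.6)

    def test_adp_preset_recovery(self):
        tracks, _ = generate_tracks(PRESETS["adp"], 500, 0.0286, 10)
        fit = dwell_times(tracks)
        assert fit.mean == pytest.approx(0.6, rel=0.1)

    def test_all_censored_rejected(self):
        tracks = [
            Track(i, np.arange(5) * 2.0, np.zeros(5), np.ones(5), censored=True)
            for i in range(3)
        ]
        with pytest.raises(ValueError):
            dwell_times(tracks)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            dwell_times([])
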