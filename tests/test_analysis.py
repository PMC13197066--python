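import numpy as np
import pytest
from scipy import stats as sps

from photoswitch_sim.analysis import (
    direct_correlation,
    fit_pfa_model,
    histogram_suite,
    lifetime_from_chain,
    multiple_tau_correlation,
    pfa_ecdf,
    pfa_model_cdf,
    pooled_lifetime,
    second_order_coherence,
)
from photoswitch_sim.detection import FrameTrace, PhotonTrace, on_off_periods
from photoswitch_sim.model import build_single_model
from photoswitch_sim.ssa import simulate_chain, simulate_stats
from photoswitch_sim.synthetic import (
    poisson_photons,
    telegraph_frames,
    telegraph_photons,
    truncated_exponential_times,
)

from conftest import toy_rates


class TestPfaEcdf:
    def test_three_point_staircase(self):
        fit = pfa_ecdf([1.0, 2.0, 3.0], 0.0, 3.0)
        assert fit.values == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_poisson_times_are_uniform(self):
        trace = poisson_photons(100.0, 300.0, seed=1)
        fit = pfa_ecdf(trace.times, 0.0, 300.0)
        res = sps.kstest((fit.times - fit.t_start) / (fit.t_end - fit.t_start),
                         "uniform")
        assert res.pvalue > 0.01

    def test_truncation_renormalises(self):
        fit = pfa_ecdf([1.0, 2.0, 4.0, 5.0], truncate_start=3.0, T=6.0)
        assert len(fit.times) == 2
        assert fit.values[-1] == 1.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            pfa_ecdf([1.0, 2.0], truncate_start=5.0, T=10.0)


class TestPfaFit:
    def test_recovers_bleach_rate_within_ten_percent(self):
        k_b = 0.05
        times = truncated_exponential_times(k_b, 300.0, 10_000, seed=2)
        fit = fit_pfa_model(pfa_ecdf(times, 0.0, 300.0), n_components=1)
        assert fit.dominant_rate == pytest.approx(k_b, rel=0.10)

    def test_uniform_times_pin_rate_to_linear_limit(self):
        trace = poisson_photons(50.0, 300.0, seed=3)
        fit = fit_pfa_model(pfa_ecdf(trace.times, 0.0, 300.0), n_components=1)
        # k * T << 1 means the component is indistinguishable from uniform
        assert fit.dominant_rate * 300.0 < 0.5

    def test_steep_fingerprint_recovered(self):
        k_b = 0.5
        times = truncated_exponential_times(k_b, 300.0, 20_000, seed=4)
        fit = fit_pfa_model(pfa_ecdf(times, 0.0, 300.0), n_components=1)
        assert fit.dominant_rate == pytest.approx(k_b, rel=0.10)

    def test_two_component_mixture(self):
        rng = np.random.Generator(np.random.PCG64(5))
        fast = truncated_exponential_times(0.2, 300.0, 8000, seed=6)
        slow = rng.uniform(0.0, 300.0, 8000)
        fit = fit_pfa_model(pfa_ecdf(np.concatenate([fast, slow]), 0.0, 300.0),
                            n_components=2)
        assert fit.weights.sum() == pytest.approx(1.0)
        assert fit.rates[1] == pytest.approx(0.2, rel=0.25)
        assert fit.weights[1] == pytest.approx(0.5, abs=0.1)

    def test_model_cdf_uniform_limit_continuous(self):
        t = np.linspace(0.0, 300.0, 7)
        tiny = pfa_model_cdf(t, [1.0], [1e-12], 0.0, 300.0)
        assert tiny == pytest.approx(t / 300.0, abs=1e-6)


class TestCorrelation:
    def test_poisson_stream_uncorrelated(self):
        trace = poisson_photons(5e4, 50.0, seed=7)
        curve = multiple_tau_correlation(trace, bin_time=1e-3)
        assert np.max(np.abs(curve.G[:40])) < 0.02

    def test_telegraph_closed_form(self):
        k_on, k_off, rate_on = 50.0, 100.0, 2e4
        trace = telegraph_photons(k_on, k_off, rate_on, 400.0, seed=8)
        curve = multiple_tau_correlation(trace, bin_time=2e-4)
        rate_sum = k_on + k_off
        expected = (k_off / k_on) * np.exp(-rate_sum * curve.lags)
        band = (curve.lags > 1e-3) & (curve.lags < 3e-2)
        resid = curve.G[band] - expected[band]
        assert np.max(np.abs(resid)) < 0.25
        # amplitude at short lag close to k_off/k_on
        short = curve.lags < 2e-3
        assert np.mean(curve.G[short] / expected[short]) == pytest.approx(1.0, abs=0.15)

    def test_multiple_tau_matches_brute_force(self):
        trace = telegraph_photons(200.0, 300.0, 5e4, 30.0, seed=9)
        curve = multiple_tau_correlation(trace, bin_time=1e-3, m=8)
        oracle = direct_correlation(trace, curve.lags[:16], bin_time=1e-3)
        assert curve.G[:16] == pytest.approx(oracle.G, abs=1e-9)
        # coarsened levels agree with the direct estimator within binning error
        oracle_coarse = direct_correlation(trace, curve.lags[16:30], bin_time=1e-3)
        assert np.max(np.abs(curve.G[16:30] - oracle_coarse.G)) < 0.05

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            multiple_tau_correlation(
                FrameTrace(counts=np.zeros(100, int), frame_time=1e-3, threshold=1))

    def test_lags_strictly_increasing(self):
        trace = poisson_photons(1e4, 20.0, seed=10)
        curve = multiple_tau_correlation(trace, bin_time=1e-3)
        assert np.all(np.diff(curve.lags) > 0)


class TestCoherence:
    def test_single_emitter_antibunched(self):
        model = build_single_model(toy_rates(kEXC=1e7, kFLU=5e8), bleaching=False)
        st_ = simulate_stats(model, t_max=0.2, max_steps=4_000_000, seed=11,
                             photon_capacity=1_200_000)
        trace = PhotonTrace(times=st_.photon_times)
        res = second_order_coherence(trace, window=2e-10, max_delay=4e-8)
        assert res.g2_zero < 0.15

    def test_two_independent_emitters_halve_the_dip(self):
        model = build_single_model(toy_rates(kEXC=1e7, kFLU=5e8), bleaching=False)
        a = simulate_stats(model, t_max=0.12, max_steps=3_000_000, seed=12,
                           photon_capacity=800_000)
        b = simulate_stats(model, t_max=0.12, max_steps=3_000_000, seed=13,
                           photon_capacity=800_000)
        merged = np.sort(np.concatenate([a.photon_times, b.photon_times]))
        res = second_order_coherence(PhotonTrace(times=merged), window=2e-10,
                                     max_delay=4e-8)
        assert res.g2_zero == pytest.approx(0.5, abs=0.12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            second_order_coherence(PhotonTrace(times=np.array([0.0, 1.0])), window=0.0)


class TestLifetime:
    def test_mean_dwell_independent_of_exit_channel(self):
        # three competing S1 exits; FLU-conditioned dwell mean = 1/k_total
        rates = toy_rates(kEXC=1e5, kFLU=4e4, kIC=5e4, kISC_S1T1=1e4,
                          kISC_T1S0=1e6)
        model = build_single_model(rates, bleaching=False)
        chain = simulate_chain(model, t_max=10.0, max_steps=500_000, seed=14)
        est = lifetime_from_chain(chain)
        tau = 1.0 / 1e5
        assert est.tau_flu == pytest.approx(tau, rel=0.05)

    def test_matches_streaming_accumulators(self, cy5_model):
        chain = simulate_chain(cy5_model, t_max=0.02, max_steps=500_000, seed=15)
        st_ = simulate_stats(cy5_model, t_max=0.02, max_steps=500_000, seed=15)
        a = lifetime_from_chain(chain)
        b = lifetime_from_chain(st_)
        assert a.n_events == b.n_events
        assert a.tau_flu == pytest.approx(b.tau_flu, rel=1e-9)

    def test_no_fluorescence_rejected(self):
        model = build_single_model(toy_rates(kEXC=1e3, kIC=1e6), bleaching=False)
        chain = simulate_chain(model, t_max=0.01, max_steps=1000, seed=16)
        with pytest.raises(ValueError):
            lifetime_from_chain(chain)

    def test_pooling_weights_by_events(self):
        from photoswitch_sim.analysis import LifetimeEstimate

        pooled = pooled_lifetime([
            LifetimeEstimate(tau_flu=1.0, n_events=1000),
            LifetimeEstimate(tau_flu=2.0, n_events=3000),
        ])
        assert pooled.tau_flu == pytest.approx(1.75)
        assert pooled.n_events == 4000


class TestHistograms:
    def test_deterministic_counts_mass(self):
        frames = FrameTrace(counts=np.array([3, 3, 7]), frame_time=1e-3, threshold=5)
        out = histogram_suite(frames=frames)
        bins, probs = out["photons_per_frame"]
        assert probs[3] == pytest.approx(2 / 3)
        assert probs[7] == pytest.approx(1 / 3)

    def test_normalisation(self):
        frames = telegraph_frames(20.0, 50.0, 2e4, 50.0, 1e-3, seed=17, threshold=5)
        periods = on_off_periods(frames)
        out = histogram_suite(frames=frames, periods=periods)
        for bins, probs in out.values():
            assert probs.sum() == pytest.approx(1.0)

    def test_memoryless_frames_give_geometric_on_periods(self):
        # iid Bernoulli ON labels: mean ON-period length = 1/(1-p_on)
        rng = np.random.Generator(np.random.PCG64(18))
        p_on = 0.3
        counts = (rng.random(200_000) < p_on).astype(int)
        frames = FrameTrace(counts=counts, frame_time=1e-3, threshold=1)
        periods = on_off_periods(frames)
        mean_on = periods.on_periods.mean()
        expected = 1.0 / (1.0 - p_on)
        se = periods.on_periods.std(ddof=1) / np.sqrt(len(periods.on_periods))
        assert abs(mean_on - expected) < 3 * se

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            histogram_suite()
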