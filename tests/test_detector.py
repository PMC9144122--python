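import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from spadflim import (
    DetectorConfig,
    NoiseModel,
    apply_pileup,
    assign_pixels,
    detected_density_oracle,
    quantize_and_histogram,
    simulate_measurement,
)


class TestAssignPixels:
    def test_single_pixel_all_same(self, rng):
        labels = assign_pixels(np.ones(50), 1, rng)
        assert np.all(labels == 0)

    def test_uniform_frequencies(self, rng):
        labels = assign_pixels(np.zeros(100_000), 10, rng)
        freq = np.bincount(labels, minlength=10)
        assert np.all(np.abs(freq - 10_000) < 3 * np.sqrt(10_000))

    def test_empty_input(self, rng):
        assert assign_pixels(np.array([]), 5, rng).size == 0

    def test_invalid_pixel_count(self, rng):
        with pytest.raises(ValueError):
            assign_pixels(np.ones(3), 0, rng)


class TestApplyPileup:
    def test_single_pixel_keeps_fastest(self):
        w = np.array([0, 0])
        px = np.array([0, 0])
        t = np.array([1.0, 2.0])
        _, kept = apply_pileup(w, px, t, True, n_pixel=1)
        assert kept.tolist() == [1.0]

    def test_distinct_pixels_all_kept(self):
        """Five photons on five of nine pixels are all detected."""
        w = np.zeros(5, dtype=int)
        px = np.arange(5)
        t = np.array([3.0, 1.0, 4.0, 1.5, 2.0])
        _, kept = apply_pileup(w, px, t, True, n_pixel=9)
        assert sorted(kept.tolist()) == sorted(t.tolist())

    def test_disabled_is_passthrough(self, rng):
        w = rng.integers(0, 10, 100)
        px = rng.integers(0, 3, 100)
        t = rng.exponential(5, 100)
        wo, to = apply_pileup(w, px, t, False)
        assert np.array_equal(wo, w) and np.array_equal(to, t)

    def test_at_most_one_event_per_pixel_per_window(self, rng):
        n = 20_000
        w = rng.integers(0, 200, n)
        px = rng.integers(0, 4, n)
        t = rng.exponential(5, n)
        wo, to = apply_pileup(w, px, t, True, n_pixel=4)
        assert to.size <= 200 * 4
        # Each kept time is the minimum of its (window, pixel) group.
        key_all = w * 4 + px
        mins = {}
        for k, ti in zip(key_all, t):
            mins[k] = min(mins.get(k, np.inf), ti)
        assert to.size == len(mins)
        assert np.allclose(np.sort(to), np.sort(list(mins.values())))

    def test_dense_and_sparse_strategies_agree(self, rng):
        """The dense slot reduction matches the sort-based reduction."""
        n = 5000
        w = rng.integers(0, 300, n)
        px = rng.integers(0, 7, n)
        t = rng.exponential(5, n)
        key = w * 7 + px
        order = np.lexsort((t, key))
        ks = key[order]
        first = np.r_[True, ks[1:] != ks[:-1]]
        expect_w, expect_t = w[order][first], t[order][first]
        wo, to = apply_pileup(w, px, t, True, n_pixel=7)
        srt = np.lexsort((to, wo))
        srt_e = np.lexsort((expect_t, expect_w))
        assert np.array_equal(wo[srt], expect_w[srt_e])
        assert np.allclose(to[srt], expect_t[srt_e])


class TestQuantize:
    def test_boundary_conventions(self):
        cfg = DetectorConfig(tres_ns=0.5, tw_ns=10.0)
        h = quantize_and_histogram(np.array([0.0, 0.5, 9.99]), cfg)
        assert h.counts[0] == 1  # t=0 -> bin 0
        assert h.counts[1] == 1  # t=tres exactly -> bin 1
        assert h.total == 3 and h.n_dropped == 0

    def test_out_of_window_events_counted_separately(self):
        cfg = DetectorConfig(tres_ns=0.5, tw_ns=10.0)
        h = quantize_and_histogram(np.array([1.0, 10.0, 25.0]), cfg)
        assert h.total == 1 and h.n_dropped == 2

    @given(st.lists(st.floats(0, 100), max_size=200))
    def test_conservation(self, times):
        cfg = DetectorConfig(tres_ns=0.3125, tw_ns=35.0)
        h = quantize_and_histogram(np.array(times), cfg)
        assert h.total + h.n_dropped == len(times)


class TestSimulateMeasurement:
    def test_empty_without_photons_or_noise(self, default_params, rng):
        p = default_params
        h, res = simulate_measurement(
            p.pulse, p.fluor, NoiseModel(0.0), 0.0, p.detector, rng
        )
        assert h.total == 0 and res.n_arrived == 0

    def test_detected_never_exceeds_arrived(self, default_params, rng):
        p = default_params.with_detector(n_pixel=3, nw=3000)
        _, res = simulate_measurement(
            p.pulse, p.fluor, p.noise, 2.0, p.detector, rng
        )
        assert 0 < res.n_detected <= res.n_arrived

    def test_equality_when_pileup_disabled(self, default_params, rng):
        p = default_params.with_detector(nw=3000, pileup_enabled=False,
                                         wrap_slow_photons=True)
        h, res = simulate_measurement(
            p.pulse, p.fluor, p.noise, 2.0, p.detector, rng
        )
        assert res.n_detected == res.n_arrived
        assert h.total == res.n_detected  # wrap keeps every event in-window

    def test_deterministic_given_seed(self, default_params):
        p = default_params.with_detector(nw=2000)
        runs = [
            simulate_measurement(
                p.pulse, p.fluor, p.noise, 1.0, p.detector,
                np.random.default_rng(99),
            )[0]
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].counts, runs[1].counts)

    def test_monotone_in_pixel_count(self, default_params):
        """More pixels never detect fewer photons on average (paired seeds)."""
        detected = []
        for n_pixel in (1, 2, 5, 10):
            p = default_params.with_detector(n_pixel=n_pixel, nw=10_000)
            _, res = simulate_measurement(
                p.pulse, p.fluor, NoiseModel(0.0), 2.0, p.detector,
                np.random.default_rng(7),
            )
            detected.append(res.n_detected)
        assert detected == sorted(detected)

    def test_pileup_negligible_at_low_per_pixel_rate(self, default_params):
        """rate << n_pixel: histograms with and without pile-up agree."""
        hists = []
        for enabled in (True, False):
            p = default_params.with_detector(n_pixel=100, pileup_enabled=enabled)
            h, _ = simulate_measurement(
                p.pulse, p.fluor, NoiseModel(0.0), 0.033, p.detector,
                np.random.default_rng(5),
            )
            hists.append(h.counts)
        a, b = hists
        keep = (a + b) >= 10
        # two-sample chi-square homogeneity test on the binned counts
        _, p_val, _, _ = stats.chi2_contingency(np.array([a[keep], b[keep]]))
        assert p_val > 0.01


def _oracle_ks(mu, n_pixel, params, nw, rng):
    p = params.with_detector(n_pixel=n_pixel, nw=nw)
    _, res = simulate_measurement(
        p.pulse, p.fluor, NoiseModel(0.0), mu, p.detector, rng
    )
    t = np.linspace(0, p.detector.tw_ns, 20_001)
    dens = detected_density_oracle(t, mu, n_pixel, p.pulse, p.fluor)
    cdf = integrate.cumulative_trapezoid(dens, t, initial=0.0)
    cdf /= cdf[-1]
    times = res.time_ns[res.time_ns < p.detector.tw_ns]
    return stats.ks_1samp(times, lambda x: np.interp(x, t, cdf)).statistic


class TestDetectedDensityOracle:
    def test_no_pileup_limit(self, pulse, fluor):
        """mu/N -> 0: detected density approaches mu * f(t)."""
        from spadflim.emission import arrival_time_pdf

        t = np.linspace(0, 35, 1000)
        dens = detected_density_oracle(t, 0.001, 1000, pulse, fluor)
        assert np.allclose(dens, 0.001 * arrival_time_pdf(t, pulse, fluor),
                           rtol=1e-4)

    @pytest.mark.parametrize("mu,n_pixel", [(0.3, 1), (3.0, 1), (3.0, 10)])
    def test_integral_closed_form(self, mu, n_pixel, pulse, fluor):
        """Integral over [0, inf) equals N*(1 - exp(-mu/N))."""
        t = np.linspace(0, 300, 300_001)
        dens = detected_density_oracle(t, mu, n_pixel, pulse, fluor)
        total = np.trapezoid(dens, t)
        assert abs(total - n_pixel * (1 - np.exp(-mu / n_pixel))) < 1e-6

    def test_delta_pulse_closed_form(self, delta_pulse, fluor):
        """Delta excitation: mu*f*exp(-mu*F) in explicit exponential form."""
        t = np.linspace(0.1, 30, 500)
        dens = detected_density_oracle(t, 3.0, 1, delta_pulse, fluor)
        f = np.exp(-t / 5.0) / 5.0
        F = 1 - np.exp(-t / 5.0)
        assert np.allclose(dens, 3 * f * np.exp(-3 * F), rtol=1e-4)

    @pytest.mark.parametrize("mu,n_pixel", [(0.3, 1), (3.0, 1), (3.0, 10)])
    def test_simulation_matches_oracle(self, mu, n_pixel, default_params, rng):
        """Detected-time distribution matches the first-photon density."""
        assert _oracle_ks(mu, n_pixel, default_params, 100_000, rng) < 0.02


class TestDetectorConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_pixel": 0},
        {"tres_ns": 0.0},
        {"tw_ns": 0.1, "tres_ns": 0.5},
        {"nw": 0},
    ])
    def test_invariants(self, kwargs):
        with pytest.raises(ValueError):
            DetectorConfig(**kwargs)
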