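"""Spike/bulk separation, nanocluster detection, Fick sizing, flux math."""

import numpy as np
import pytest

from smds import synthetic
from smds.chip import FlowSettings
from smds.clusters import (
    FWHM_PER_SIGMA,
    analyze_cluster_scan,
    cluster_concentration,
    cluster_flux,
    concentration_from_volume_fraction,
    detect_cluster_events,
    fick_fit,
    fit_position_peaks,
    monomers_per_cluster,
    split_trace_by_threshold,
    volume_fraction,
)
from smds.exceptions import (
    ConfigurationRequiredError,
    DegenerateStatisticsError,
    InvalidParameterError,
    NoBroadeningError,
)
from smds.fitting import global_fit
from smds.profiles import DiffusionProfile


class TestSplitTrace:
    def test_flat_trace_has_no_spikes(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100.0, 2000).astype(float)  # 100 kHz at 1-ms bins
        st = split_trace_by_threshold(counts, 250.0)
        assert st.n_spikes == 0
        assert st.bulk_series.size == counts.size

    def test_constructed_spike_found(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100.0, 2000).astype(float)
        counts[800:805] += 400.0  # 5-ms 400-kHz spike on 100-kHz background
        st = split_trace_by_threshold(counts, 250.0)
        assert st.n_spikes == 1
        s, e = st.spike_segments[0]
        assert s <= 800 and e >= 805
        assert st.bulk_series.mean() == pytest.approx(100.0, rel=0.05)

    def test_window_validation(self):
        with pytest.raises(InvalidParameterError):
            split_trace_by_threshold(np.ones(5), 250.0, smooth_window=11)
        with pytest.raises(InvalidParameterError):
            split_trace_by_threshold(np.ones(100), 250.0, smooth_window=4)


class TestDetectEvents:
    def test_single_20_sigma_spike(self):
        rng = np.random.default_rng(2)
        x = rng.normal(100.0, 5.0, 5000)
        x[2500:2503] += 100.0  # 20 sd
        events = detect_cluster_events(x, k_sd=5.0)
        assert len(events) == 1

    def test_false_positive_rate_matches_normal_tail(self):
        # Phi-tail at 5 sd is 2.9e-7; expect ~0.03 false events in 1e5 bins
        rng = np.random.default_rng(3)
        x = rng.normal(50.0, 3.0, 100_000)
        assert len(detect_cluster_events(x, k_sd=5.0)) <= 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.normal(100.0, 5.0, 10_000)
        x[::500] += rng.uniform(10, 80, x[::500].size)
        counts = [len(detect_cluster_events(x, k)) for k in (3, 5, 8, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            detect_cluster_events(np.full(100, 7.0))


class TestPeakFits:
    def test_exact_gaussian_fwhm(self):
        x = np.linspace(0, 225, 113)
        sigma = 12.0
        y = 40.0 * np.exp(-0.5 * ((x - 110.0) / sigma) ** 2)
        fits, excl = fit_position_peaks(x, y, [(0.0, 225.0)])
        assert excl == []
        assert fits[0].fwhm_um == pytest.approx(FWHM_PER_SIGMA * sigma, rel=1e-4)
        assert fits[0].diffusion_distance_um == pytest.approx(
            0.5 * FWHM_PER_SIGMA * sigma, rel=1e-4)
        assert fits[0].mean_um == pytest.approx(110.0, abs=1e-3)

    def test_sampled_gaussian_within_ten_percent(self):
        sigma = 15.0
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = rng.normal(112.0, sigma, 500)
            edges = np.arange(0, 226, 4.0)
            counts, _ = np.histogram(samples, bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            fits, _ = fit_position_peaks(centers, counts, [(0.0, 225.0)])
            errs.append(abs(fits[0].fwhm_um / (FWHM_PER_SIGMA * sigma) - 1.0))
        assert np.median(errs) < 0.10

    def test_sparse_crossing_excluded(self):
        x = np.linspace(0, 225, 20)
        y = np.zeros(20)
        y[10] = 5.0
        fits, excl = fit_position_peaks(x, y, [(0.0, 225.0)])
        assert excl == [0] and fits == []


class TestFickFit:
    def test_forward_then_invert_120nm(self, cond):
        # distances generated from D = 2.045e-12 m^2/s at t = {10, 26, 55} s
        x = np.array([0.0, 6.40, 10.31, 15.00])
        t = np.array([0.0, 10.0, 26.0, 55.0])
        d, r = fick_fit(x, t, cond)
        assert d == pytest.approx(2.045e-12, rel=5e-3)
        assert r == pytest.approx(120.0, rel=5e-3)

    def test_no_broadening_error(self, cond):
        with pytest.raises(NoBroadeningError):
            fick_fit(np.array([8.0, 8.0, 8.0]), np.array([0.0, 10.0, 26.0]), cond)

    def test_quadratic_scaling(self, cond):
        x = np.array([0.0, 6.40, 10.31, 15.00])
        t = np.array([0.0, 10.0, 26.0, 55.0])
        d1, _ = fick_fit(x, t, cond)
        d2, _ = fick_fit(np.concatenate([[0.0], x[1:] * 3.0]), t, cond)
        assert d2 == pytest.approx(9.0 * d1, rel=1e-9)

    def test_quadrature_normalization(self, cond):
        # widths with a common instrumental floor x0: net distance in quadrature
        x0 = 9.0
        t = np.array([0.0, 10.0, 26.0, 55.0])
        net = np.array([6.40, 10.31, 15.00])
        x = np.concatenate([[x0], np.sqrt(net**2 + x0**2)])
        d, r = fick_fit(x, t, cond)
        assert r == pytest.approx(120.0, rel=5e-3)


class TestFluxMath:
    def test_flux_example(self):
        assert cluster_flux(100, 10.0, 1.0) == pytest.approx(10.0)

    def test_efficiency_inverse(self):
        assert cluster_flux(100, 10.0, 0.5) == pytest.approx(
            2.0 * cluster_flux(100, 10.0, 1.0))

    def test_efficiency_mandatory(self):
        with pytest.raises(ConfigurationRequiredError):
            cluster_flux(100, 10.0)

    def test_concentration_printed_value(self):
        c = cluster_concentration(72_606.0, FlowSettings(60.0))
        assert c == pytest.approx(7.24, rel=0.005)

    def test_concentration_trivial(self):
        assert cluster_concentration(0.0, FlowSettings(60.0)) == 0.0
        assert cluster_concentration(100.0, FlowSettings(120.0)) == pytest.approx(
            0.5 * cluster_concentration(100.0, FlowSettings(60.0)))

    def test_volume_fraction_printed_value(self):
        assert volume_fraction(7.24, 120.0) == pytest.approx(3.16e-5, rel=0.01)

    def test_volume_fraction_scaling_and_roundtrip(self):
        assert volume_fraction(0.0, 120.0) == 0.0
        assert volume_fraction(5.0, 240.0) == pytest.approx(
            8.0 * volume_fraction(5.0, 120.0), rel=1e-12)
        phi = volume_fraction(7.24, 120.0)
        assert concentration_from_volume_fraction(phi, 120.0) == pytest.approx(
            7.24, rel=1e-12)

    def test_monomers_per_cluster(self):
        lo, hi, ceiling = monomers_per_cluster(120.0, 4.29, (0.10, 0.35))
        assert ceiling == pytest.approx(2.19e4, rel=0.01)
        assert lo == pytest.approx(2.19e3, rel=0.01)
        assert hi == pytest.approx(7.66e3, rel=0.01)
        assert monomers_per_cluster(5.0, 5.0, (1.0, 1.0))[2] == pytest.approx(1.0)


def _binned_cluster_scan(seed, n_events=500):
    times = np.array([0.0, 10.0, 26.0, 55.0])
    pos, bounds, man = synthetic.generate_cluster_positions(
        2.045e-12, times, n_events, seed=seed)
    coords, counts = [], []
    for lo, hi in bounds:
        edges = np.arange(lo, hi + 1e-9, 2.0)
        c, _ = np.histogram(pos[(pos >= lo) & (pos <= hi)], bins=edges)
        coords.append(0.5 * (edges[:-1] + edges[1:]))
        counts.append(c)
    return np.concatenate(coords), np.concatenate(counts), bounds, times


def test_cluster_pipeline_recovers_120nm(cond):
    """Event histograms -> peak fits -> Fick fit across seeds."""
    recovered = []
    for seed in range(8):
        coords, counts, bounds, times = _binned_cluster_scan(seed)
        res = analyze_cluster_scan(coords, counts, bounds, times, cond)
        recovered.append(res.r_h_nm)
    assert np.mean(recovered) == pytest.approx(120.0, rel=0.15)


def test_cluster_report_includes_flux_chain(cond):
    coords, counts, bounds, times = _binned_cluster_scan(3)
    res = analyze_cluster_scan(coords, counts, bounds, times, cond,
                               flow=FlowSettings(60.0),
                               total_observation_s=500.0, detection_efficiency=0.5)
    assert res.flux_per_s == pytest.approx(res.n_events / 500.0 / 0.5)
    assert res.concentration_pm == pytest.approx(
        cluster_concentration(res.flux_per_s, FlowSettings(60.0)))
    assert res.volume_fraction == pytest.approx(
        volume_fraction(res.concentration_pm, res.r_h_nm), rel=1e-9)


def test_fibril_monomer_separation(geom, flow100, cond, basis_small):
    """Spike counting and bulk averaging size both mixture components."""
    pos, bounds = synthetic.step_positions(geom, 50)
    W = geom.observation_width_um
    p_mono = basis_small.interpolate(3.23)
    p_fib = basis_small.interpolate(56.43)
    bulk = np.zeros(pos.size)
    fib = np.zeros(pos.size)
    for k, (lo, hi) in enumerate(bounds):
        m = (pos >= lo) & (pos <= hi)
        y = (pos[m] - lo) / (hi - lo) * W
        bulk[m] = np.interp(y, basis_small.transverse_um, p_mono[k])
        fib[m] = np.interp(y, basis_small.transverse_um, p_fib[k])
    traces, _ = synthetic.generate_spike_traces(
        100.0 * bulk / bulk.max(), 8.0 * fib / fib.max(), dwell_s=2.0, seed=4)
    spikes = np.zeros(pos.size)
    means = np.zeros(pos.size)
    for j, tr in enumerate(traces):
        st = split_trace_by_threshold(tr, 250.0)
        spikes[j] = st.n_spikes
        means[j] = st.bulk_series.mean() if st.bulk_series.size else 0.0
    r_fib = global_fit(DiffusionProfile(pos, spikes, "step", bounds),
                       basis_small, compute_errors=False).r_h_nm
    r_mono = global_fit(DiffusionProfile(pos, means, "continuous", bounds),
                        basis_small, compute_errors=False).r_h_nm
    assert r_fib == pytest.approx(56.43, rel=0.15)
    assert r_mono == pytest.approx(3.23, rel=0.15)
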