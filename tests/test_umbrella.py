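"""Umbrella-sampling protocol and WHAM estimator tests."""

import numpy as np
import pytest

import hpbrush as hb
from hpbrush.umbrella import (
    UmbrellaWindow,
    WHAMConfig,
    bias_energy,
    integrated_autocorrelation_time,
    run_umbrella_protocol,
    sample_biased_windows,
    umbrella_schedule,
    wham_solve,
)


class TestBias:
    def test_zero_at_rest_length(self):
        assert bias_energy(1.0, k=0.3, l=1.0) == 0.0

    def test_zero_stiffness(self):
        z = np.linspace(0, 20, 7)
        np.testing.assert_array_equal(bias_energy(z, k=0.0), 0.0)

    def test_value(self):
        assert bias_energy(3.0, k=0.3, l=1.0) == pytest.approx(0.6)


class TestSchedule:
    def test_production_ladder(self):
        s = umbrella_schedule(dk=0.005, k_max=0.3, t_window=500.0, stride=10,
                              dt=0.005)
        assert s["n_windows"] == 61
        assert s["samples_per_window"] == 10_000
        np.testing.assert_allclose(s["k"][:3], [0.0, 0.005, 0.01])
        assert s["k"][-1] == pytest.approx(0.3)

    def test_degenerate_two_windows(self):
        s = umbrella_schedule(dk=0.3, k_max=0.3)
        assert s["n_windows"] == 2
        np.testing.assert_allclose(s["k"], [0.0, 0.3])

    def test_non_divisible_stride_warns(self):
        with pytest.warns(UserWarning, match="stride"):
            s = umbrella_schedule(t_window=1.0, stride=7, dt=0.005)
        assert s["samples_per_window"] == 200 // 7


def _double_well(z):
    z1, z2, h, fmax = 1.5, 3.9, 3.0, 4.0
    zm = 0.5 * (z1 + z2)
    raw = h * ((z - z1) * (z - z2)) ** 2 / ((zm - z1) * (zm - z2)) ** 2
    return np.minimum(raw, fmax)


class TestWham:
    def test_single_unbiased_window_is_log_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.uniform(0.5, 4.5, 20_000)
        cfg = WHAMConfig(lz=6.0, bin_width=0.5)
        prof = wham_solve([UmbrellaWindow(0.0, 1.0, samples)], cfg)
        hist, edges = np.histogram(samples, bins=cfg.edges())
        mask = hist > 0
        expected = -np.log(hist[mask] / hist[mask][-1])  # reference: last bin
        got = prof.pmf[mask] - prof.pmf[mask][-1]
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_normalization_and_reference(self):
        windows = sample_biased_windows(
            _double_well, ks=0.005 * np.arange(21), n_samples=2000,
            config=WHAMConfig(lz=6.0), support=(0.6, 5.4), seed=3,
        )
        prof = wham_solve(windows, WHAMConfig(lz=6.0))
        assert prof.converged
        assert prof.p.sum() * prof.bin_width == pytest.approx(1.0)
        i0 = np.nonzero(prof.p > 0)[0][-1]
        assert prof.pmf[i0] == pytest.approx(0.0)  # PMF(z0) = 0 at the bulk bin
        assert np.all(prof.p >= 0)

    def test_window_duplication_invariance(self):
        # same k, samples split across two windows == one concatenated window
        windows = sample_biased_windows(
            _double_well, ks=[0.0, 0.1, 0.2], n_samples=4000,
            config=WHAMConfig(lz=6.0), support=(0.6, 5.4), seed=5,
        )
        prof_a = wham_solve(windows, WHAMConfig(lz=6.0))
        w1 = windows[1]
        split = [
            windows[0],
            UmbrellaWindow(w1.kspring, w1.lspring, w1.samples[:2000]),
            UmbrellaWindow(w1.kspring, w1.lspring, w1.samples[2000:]),
            windows[2],
        ]
        prof_b = wham_solve(split, WHAMConfig(lz=6.0))
        mask = prof_a.p > 0
        np.testing.assert_allclose(prof_a.pmf[mask], prof_b.pmf[mask], atol=1e-6)

    def test_mean_extension_non_increasing_in_stiffness(self):
        # stiffer springs pull the COM toward the rest length near the wall
        windows = sample_biased_windows(
            _double_well, ks=0.05 * np.arange(7), n_samples=20_000,
            config=WHAMConfig(lz=6.0), support=(0.6, 5.4), seed=7,
        )
        means = [w.samples.mean() for w in windows]
        assert all(np.diff(means) < 1e-3)

    def test_overlap_gap_warns(self):
        a = UmbrellaWindow(0.0, 1.0, np.full(50, 1.05))
        b = UmbrellaWindow(0.1, 1.0, np.full(50, 5.05))
        with pytest.warns(UserWarning, match="overlap"):
            wham_solve([a, b], WHAMConfig(lz=6.0))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            wham_solve([])

    def test_autocorrelation_time_white_noise(self):
        rng = np.random.default_rng(11)
        tau = integrated_autocorrelation_time(rng.normal(size=20_000))
        assert tau == pytest.approx(0.0, abs=0.1)

    def test_g_estimation_correlated_series(self):
        rng = np.random.default_rng(12)
        # AR(1) with known tau = phi/(1-phi)
        phi = 0.9
        x = np.zeros(40_000)
        eps = rng.normal(size=40_000)
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + eps[i]
        tau = integrated_autocorrelation_time(x)
        assert tau == pytest.approx(phi / (1 - phi), rel=0.25)


class TestProtocol:
    def test_mini_protocol_runs_and_counts(self):
        # tiny single-protein box, 3 windows, short windows: mechanics only
        system = hb.make_fixture("single-protein", seed=2, np_beads=8,
                                 section=6.0, density=0.4)
        protein = 0
        cfg = hb.IntegratorConfig(steps=1, log_stride=10, traj_stride=1000)
        windows = run_umbrella_protocol(
            system, protein, dk=0.15, k_max=0.3, t_window=5.0, stride=10,
            seed=4, md_config=cfg,
        )
        assert len(windows) == 3
        np.testing.assert_allclose([w.kspring for w in windows], [0.0, 0.15, 0.3])
        # t_window/dt = 1000 steps, stride 10 -> 100 samples, minus 10% burn-in
        assert all(w.n == 90 for w in windows)
        for w in windows:
            assert np.all((w.samples > 0) & (w.samples < system.box.h))
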