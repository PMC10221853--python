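"""Observable tests: chain metrics, asphericity, adsorption, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hpbrush as hb
from hpbrush.analysis import (
    adsorbed_fraction,
    asphericity,
    chain_metrics,
    density_profile,
    dry_height,
    stationary_average,
)
from hpbrush.builder import classify_regime
from hpbrush.dynamics import Trajectory

import pandas as pd


def _traj(frames, times=None):
    frames = np.asarray(frames, float)
    n = frames.shape[1]
    return Trajectory(
        times=np.asarray(times if times is not None else np.arange(len(frames)), float),
        positions=frames,
        selection=np.arange(n),
        thermo=pd.DataFrame(),
    )


class TestChainMetrics:
    def test_single_bead(self):
        m = chain_metrics(np.array([[1.0, 2.0, 3.0]]))
        assert m.rg == 0.0 and m.r_end == 0.0 and m.height == 3.0

    def test_rod_along_z(self):
        n = 10
        coords = np.zeros((n, 3))
        coords[:, 2] = np.arange(n)
        m = chain_metrics(coords)
        assert m.r_end == pytest.approx(n - 1)
        assert m.height == pytest.approx(n - 1)

    def test_two_beads_rg(self):
        d = 1.7
        m = chain_metrics(np.array([[0, 0, 0], [d, 0, 0.0]]))
        assert m.rg2 == pytest.approx(d * d / 4)

    def test_empty_chain_errors(self):
        with pytest.raises(ValueError):
            chain_metrics(np.zeros((0, 3)))


class TestAsphericity:
    def test_rod_is_one(self):
        coords = np.outer(np.arange(12), [1.0, 2.0, -0.5])  # collinear
        assert asphericity(coords).alpha == pytest.approx(1.0, abs=1e-12)

    def test_spherical_symmetry_is_zero(self):
        # octahedron vertices: R1 = R2 = R3
        coords = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1.0]]
        )
        assert asphericity(coords).alpha == pytest.approx(0.0, abs=1e-12)

    def test_planar_symmetric_is_quarter(self):
        # ring in the xy-plane: R1 = R2, R3 = 0 -> alpha = 1/4
        t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        coords = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        assert asphericity(coords).alpha == pytest.approx(0.25, abs=1e-12)

    def test_eigenvalue_sum_is_rg2(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            coords = rng.normal(size=(30, 3)) * [2.0, 1.0, 0.5]
            rec = asphericity(coords)
            assert rec.rg2 == pytest.approx(chain_metrics(coords).rg2, abs=1e-10)

    def test_coincident_beads_error(self):
        with pytest.raises(ValueError):
            asphericity(np.ones((5, 3)))

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 1000))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(15, 3)) * [3.0, 1.0, 0.4]
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a0 = asphericity(coords)
        a1 = asphericity(coords @ q.T + rng.normal(size=3))
        assert a1.alpha == pytest.approx(a0.alpha, abs=1e-9)
        assert 0.0 <= a0.alpha <= 1.0

    def test_diagonal_reading_diverges_under_rotation(self):
        # the raw-diagonal variant is frame-dependent: diagnostic only
        coords = np.outer(np.arange(10), [1.0, 0, 0])
        rec_aligned = asphericity(coords)
        theta = np.pi / 4
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]]
        )
        rec_rot = asphericity(coords @ rot.T)
        assert rec_aligned.alpha_diagonal == pytest.approx(1.0)
        assert rec_rot.alpha_diagonal != pytest.approx(1.0, abs=0.01)
        assert rec_rot.alpha == pytest.approx(1.0, abs=1e-12)


class TestAdsorption:
    def test_counting(self):
        # 3 proteins of 2 beads; hmax fixed at 5, Rg_p = 1 -> threshold 4
        frame = np.array(
            [[0, 0, 3.0], [0, 0, 3.0],   # COM 3.0 adsorbed
             [0, 0, 3.9], [0, 0, 4.1],   # COM 4.0 not (< is strict)
             [0, 0, 8.0], [0, 0, 9.0]]   # COM 8.5 not
        )
        traj = _traj([frame])
        chains = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
        ads = adsorbed_fraction(traj, chains, rg_protein=1.0, hmax=5.0)
        assert ads.fraction[0] == pytest.approx(1 / 3)

    def test_all_above_and_all_below(self):
        chains = [np.array([0]), np.array([1])]
        lo = _traj([np.array([[0, 0, 0.5], [0, 0, 0.7]])])
        hi = _traj([np.array([[0, 0, 9.0], [0, 0, 9.5]])])
        assert adsorbed_fraction(lo, chains, 1.0, hmax=5.0).fraction[0] == 1.0
        assert adsorbed_fraction(hi, chains, 1.0, hmax=5.0).fraction[0] == 0.0

    def test_running_hmax_reference(self):
        # coating chain sinking between frames moves the threshold with it
        frames = [
            np.array([[0, 0, 6.0], [0, 0, 4.4]]),
            np.array([[0, 0, 3.0], [0, 0, 4.4]]),
        ]
        traj = _traj(frames)
        ads = adsorbed_fraction(
            traj, [np.array([1])], rg_protein=1.0, coating_chains=[np.array([0])]
        )
        assert ads.fraction[0] == 1.0  # threshold 5.0
        assert ads.fraction[1] == 0.0  # threshold 2.0
        np.testing.assert_allclose(ads.hmax, [6.0, 3.0])

    def test_invalid_rg(self):
        with pytest.raises(ValueError):
            adsorbed_fraction(_traj([np.zeros((1, 3))]), [np.array([0])], 0.0,
                              hmax=1.0)


class TestDensityProfile:
    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 10, size=(5, 200, 3))
        traj = _traj(frames)
        prof = density_profile(traj, np.ones(200, bool), area=64.0, h=10.0,
                               bin_width=0.5)
        assert prof.integral() == pytest.approx(200.0)

    def test_flat_for_uniform_beads(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 10, size=(400, 300, 3))
        traj = _traj(frames)
        prof = density_profile(traj, np.ones(300, bool), area=100.0, h=10.0,
                               bin_width=1.0)
        bulk = 300 / (100.0 * 10.0)
        np.testing.assert_allclose(prof.rho, bulk, rtol=0.05)

    def test_delta_selection(self):
        frames = np.zeros((3, 10, 3))
        frames[:, :, 2] = 4.32
        prof = density_profile(_traj(frames), np.ones(10, bool), area=1.0,
                               h=10.0, bin_width=0.2)
        assert (prof.rho > 0).sum() == 1

    def test_errors(self):
        traj = _traj(np.zeros((1, 4, 3)))
        with pytest.raises(ValueError):
            density_profile(traj, np.zeros(4, bool), 1.0, 10.0)
        with pytest.raises(ValueError):
            density_profile(traj, np.ones(4, bool), 1.0, 10.0, bin_width=0.0)


class TestStationaryAverage:
    def test_constant(self):
        mean, sem = stationary_average(np.full(100, 3.3))
        assert mean == pytest.approx(3.3, abs=1e-14)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_full_fraction_is_plain_mean(self):
        x = np.arange(10.0)
        mean, _ = stationary_average(x, fraction=1.0)
        assert mean == pytest.approx(x.mean())

    def test_linear_ramp_tail(self):
        x = np.linspace(0, 1, 10_000)
        mean, _ = stationary_average(x, fraction=0.3)
        assert mean == pytest.approx(0.85, abs=1e-3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            stationary_average(np.array([]))


class TestCoatingBookkeeping:
    @pytest.mark.parametrize("g,expected", [(81, 1.78), (196, 4.31), (306, 6.73)])
    def test_dry_height(self, g, expected):
        sigma = g / (54.29 * 64.44)
        assert dry_height(sigma, 50, 0.65) == pytest.approx(expected, abs=5e-3)

    def test_dry_height_degenerate(self):
        assert dry_height(0.023, 0, 0.65) == 0.0
        with pytest.raises(ValueError):
            dry_height(0.023, 50, 0.0)

    def test_regime_classification(self):
        # brush iff Rg^2 exceeds the area per chain Sigma = 1/sigma
        assert classify_regime(4.5 ** 2, 0.023) == "mushroom"   # Rg^2 << Sigma
        assert classify_regime(5.0 ** 2, 0.087) == "brush"      # Rg^2 > Sigma
        sigma = 0.056
        assert classify_regime(0.9 / sigma, sigma) == "intermediate"
        # the strict boundary puts anything above Sigma in the brush class
        assert classify_regime(1.1 / sigma, sigma) == "brush"
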