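"""Unit and property tests for the closed-form potentials."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from hpbrush.potentials import (
    BondSpec,
    BondOverstretchError,
    GeometryError,
    PairSpec,
    WallSpec,
    WALL_REPULSIVE_CUTOFF,
    WCA_CUTOFF,
    dimer_equilibrium_length,
    effective_wall_strength,
    fene_energy_force,
    pair_energy_force,
    wall_energy_force,
    wall_minimum,
)


class TestPairPotential:
    @pytest.mark.parametrize("spec", [PairSpec(), PairSpec(1.0, 1.5),
                                      PairSpec(120.0, 1.19)])
    def test_zero_at_and_beyond_cutoff(self, spec):
        for r in (spec.rc, spec.rc + 1e-12, 2 * spec.rc):
            e, f = pair_energy_force(r, spec)
            assert e == 0.0 and f == 0.0

    def test_wca_unit_energy_at_contact(self):
        # 4[(1-1) - (1/4 - 1/2)] = 1 at r=1 for the WCA choice
        e, _ = pair_energy_force(1.0, PairSpec())
        assert e == pytest.approx(1.0, abs=1e-12)

    def test_zero_force_at_wca_cutoff_minimum(self):
        _, f = pair_energy_force(WCA_CUTOFF - 1e-9, PairSpec())
        assert f == pytest.approx(0.0, abs=1e-6)

    def test_continuity_at_cutoff(self):
        spec = PairSpec(3.0, 1.5)
        e_in, _ = pair_energy_force(spec.rc - 1e-9, spec)
        assert e_in == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("r", [0.0, -1.0, 1e-9])
    def test_invalid_geometry(self, r):
        with pytest.raises(GeometryError):
            pair_energy_force(r, PairSpec())


class TestFene:
    def test_zero_at_origin(self):
        e, f = fene_energy_force(0.0, BondSpec())
        assert e == 0.0 and f == 0.0

    def test_monotone_divergence(self):
        spec = BondSpec()
        rs = np.linspace(0.1, spec.rfene - 1e-6, 200)
        es = [fene_energy_force(r, spec)[0] for r in rs]
        assert all(np.diff(es) > 0)
        # -0.5*k*R^2*ln(1-x^2) ~ 456 kBT at r = RFENE - 1e-6: diverging wall
        assert es[-1] > 400

    def test_overstretch_aborts(self):
        with pytest.raises(BondOverstretchError):
            fene_energy_force(1.5, BondSpec())

    def test_dimer_equilibrium_against_force_balance(self):
        # independent oracle: root of the total radial force
        def total_force(r):
            return (fene_energy_force(r, BondSpec())[1]
                    + pair_energy_force(r, PairSpec())[1])

        r_star = brentq(total_force, 0.8, 1.1, xtol=1e-12)
        assert dimer_equilibrium_length() == pytest.approx(r_star, abs=1e-6)
        assert r_star == pytest.approx(0.96, abs=0.005)


class TestWall:
    def test_zero_beyond_cutoff(self):
        spec = WallSpec(1.0, 1.0)
        for z in (1.0, 1.5, 10.0):
            assert wall_energy_force(z, spec) == (0.0, 0.0)

    def test_minimum_location_and_depth(self):
        # well minimum at (2/5)^(1/6) ~ 0.858 with W ~ -0.187 for eps=1, zc=1
        z_star, depth = wall_minimum(WallSpec(1.0, 1.0))
        assert z_star == pytest.approx(0.858, abs=1e-3)
        assert depth == pytest.approx(-0.187, abs=5e-4)
        _, f = wall_energy_force(z_star, WallSpec(1.0, 1.0))
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_repulsive_cutoff_is_the_minimum(self):
        assert WALL_REPULSIVE_CUTOFF == pytest.approx((2 / 5) ** (1 / 6))
        assert WallSpec().repulsive

    def test_invalid_geometry(self):
        with pytest.raises(GeometryError):
            wall_energy_force(-0.5, WallSpec())


class TestEffectiveWallStrength:
    def test_free_limit_is_cutoff(self):
        for zc in (0.5, 1.0, 2.5):
            assert effective_wall_strength(0.0, zc) == zc

    @pytest.mark.parametrize("eps,zc,expected", [(1.0, 1.0, 0.307),
                                                 (3.0, 2.5, 7.422)])
    def test_reference_values(self, eps, zc, expected):
        assert effective_wall_strength(eps, zc) == pytest.approx(expected, abs=5e-4)

    def test_strictly_increasing_in_epsilon_beyond_minimum(self):
        # deeper well -> larger Boltzmann weight once zc exceeds the minimum
        vals = [effective_wall_strength(e, 1.5) for e in (0.5, 1.0, 2.0, 3.0)]
        assert all(np.diff(vals) > 0)


@settings(deadline=None, max_examples=60)
@given(
    r=st.floats(0.3, 2.4),
    eps=st.floats(0.1, 10.0),
    rc=st.floats(1.0, 2.0),
)
def test_pair_force_matches_numerical_derivative(r, eps, rc):
    spec = PairSpec(eps, rc)
    h = 1e-6
    if abs(r - rc) < 2 * h:  # force is discontinuous at the truncation
        return
    e_p, _ = pair_energy_force(r + h, spec)
    e_m, _ = pair_energy_force(r - h, spec)
    _, f = pair_energy_force(r, spec)
    assert f == pytest.approx(-(e_p - e_m) / (2 * h), abs=1e-4, rel=1e-5)


@settings(deadline=None, max_examples=60)
@given(z=st.floats(0.5, 2.6), eps=st.floats(0.1, 5.0), zc=st.floats(0.858, 2.5))
def test_wall_force_matches_numerical_derivative(z, eps, zc):
    spec = WallSpec(eps, zc)
    h = 1e-6
    if abs(z - zc) < 2 * h:
        return
    e_p, _ = wall_energy_force(z + h, spec)
    e_m, _ = wall_energy_force(z - h, spec)
    _, f = wall_energy_force(z, spec)
    assert f == pytest.approx(-(e_p - e_m) / (2 * h), abs=1e-4, rel=1e-5)


@settings(deadline=None, max_examples=40)
@given(r=st.floats(0.05, 1.45))
def test_fene_force_matches_numerical_derivative(r):
    spec = BondSpec()
    h = 1e-7
    e_p, _ = fene_energy_force(r + h, spec)
    e_m, _ = fene_energy_force(r - h, spec)
    _, f = fene_energy_force(r, spec)
    assert f == pytest.approx(-(e_p - e_m) / (2 * h), abs=1e-3, rel=1e-4)
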