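"""Shared fixtures.

The MD fixtures are session-scoped where the tests only read them; tests
that mutate state build their own copies.
"""

from __future__ import annotations

import numpy as np
import pytest

import hpbrush as hb


@pytest.fixture(scope="session")
def mini_mushroom() -> hb.ParticleSystem:
    """Tiny coating + 2 proteins + water at n=0.65 (read-only)."""
    return hb.make_fixture("mini-mushroom", seed=3)


@pytest.fixture()
def mini_mushroom_copy(mini_mushroom) -> hb.ParticleSystem:
    return mini_mushroom.copy()


@pytest.fixture(scope="session")
def dimer() -> hb.ParticleSystem:
    return hb.make_fixture("dimer", seed=1)


def brute_force_reference(system, bias_indices=None, bias_k=0.0, bias_l=1.0):
    """Independent O(n^2) numpy force/energy oracle for the compiled kernels.

    Evaluates the same physical model (truncated-shifted LJ pairs with 1-2
    exclusions, FENE+WCA bonds, 9-3/LJ walls, COM z-spring) directly from
    the spec objects, with no shared code path with the cell-list kernels.
    """
    from hpbrush.potentials import (
        PairSpec,
        fene_energy_force,
        pair_energy_force,
        wall_energy_force,
    )

    box = system.box
    n = system.n_beads
    pos = system.positions
    forces = np.zeros((n, 3))
    pe = 0.0
    bonded = {(min(i, j), max(i, j)) for i, j in system.bonds}
    table = system.interactions
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d[0] -= box.lx * np.rint(d[0] / box.lx)
            d[1] -= box.ly * np.rint(d[1] / box.ly)
            if box.periodic_z:
                d[2] -= box.h * np.rint(d[2] / box.h)
            r = np.linalg.norm(d)
            if (i, j) in bonded:
                e_b, f_b = fene_energy_force(r, table.bond)
                e_w, f_w = pair_energy_force(r, PairSpec())
                pe += e_b + e_w
                forces[i] += (f_b + f_w) * d / r
                forces[j] -= (f_b + f_w) * d / r
            else:
                spec = table.pair_spec(int(system.types[i]), int(system.types[j]))
                if r < spec.rc:
                    e, f = pair_energy_force(r, spec)
                    pe += e
                    forces[i] += f * d / r
                    forces[j] -= f * d / r
    if not box.periodic_z:
        for i in range(n):
            t = int(system.types[i])
            lo = table.lower_wall.get(t)
            if lo is not None:
                e, f = wall_energy_force(pos[i, 2], lo)
                pe += e
                forces[i, 2] += f
            hi = table.upper_wall.get(t)
            if hi is not None:
                e, f = wall_energy_force(box.h - pos[i, 2], hi)
                pe += e
                forces[i, 2] -= f
    if bias_indices is not None and len(bias_indices):
        zcom = pos[bias_indices, 2].mean()
        pe += 0.5 * bias_k * (zcom - bias_l) ** 2
        forces[bias_indices, 2] += -bias_k * (zcom - bias_l) / len(bias_indices)
    return forces, pe
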