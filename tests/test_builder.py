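"""Construction tests: coatings, sequences, doping, water fill, placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hpbrush as hb
from hpbrush.builder import (
    ConstructionError,
    anchor_lattice,
    build_coating,
    fill_water,
    generate_hp_sequence,
    grafting_density,
    place_proteins,
)
from hpbrush.presets import compact_conformation
from hpbrush.system import (
    BoxGeometry,
    ParticleSystem,
    TYPE_A,
    TYPE_A_LIGAND,
    TYPE_H,
    TYPE_R_TETHERED,
    TYPE_W,
)


@pytest.fixture(scope="module")
def small_box():
    return BoxGeometry(lx=12.0, ly=12.0, h=12.0)


class TestCoating:
    @pytest.mark.parametrize("g,sigma", [(81, 0.023), (196, 0.056), (306, 0.087)])
    def test_production_grafting_densities(self, g, sigma):
        system = build_coating(BoxGeometry(), g=g, n=50)
        assert grafting_density(system) == pytest.approx(sigma, abs=5e-4)
        assert system.n_beads == g * 50

    def test_anchors_immobile_at_surface(self, small_box):
        system = build_coating(small_box, g=9, n=10)
        anchors = system.types == TYPE_R_TETHERED
        assert anchors.sum() == 9
        assert np.all(system.positions[anchors, 2] == 0.0)
        assert not system.mobile[anchors].any()
        assert system.mobile[~anchors].all()

    def test_rod_taller_than_box_errors_without_folding(self, small_box):
        with pytest.raises(ConstructionError):
            build_coating(small_box, g=4, n=50, fold=False)

    def test_folded_chain_fits_and_keeps_bonds_valid(self, small_box):
        system = build_coating(small_box, g=4, n=50, fold=True)
        assert system.positions[:, 2].max() < small_box.h - 1.0
        d = np.linalg.norm(
            system.positions[system.bonds[:, 0]]
            - system.positions[system.bonds[:, 1]],
            axis=1,
        )
        assert d.max() < 1.5 and d.min() >= 0.95

    def test_anchor_lattice_uniform_and_exact_count(self, small_box):
        pts = anchor_lattice(small_box, 9)
        assert pts.shape == (9, 2)
        assert np.all((pts >= 0) & (pts < 12.0))
        # near-square grid: pairwise minimum spacing close to sqrt(A/G)
        d = np.linalg.norm(pts[None] - pts[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(np.sqrt(144 / 9), rel=0.3)


class TestHpSequence:
    @pytest.mark.parametrize("np_beads,hp,n_h", [(40, 0.25, 10), (60, 0.35, 21),
                                                 (40, 0.35, 14), (60, 0.25, 15)])
    def test_composition(self, np_beads, hp, n_h):
        seq = generate_hp_sequence(np_beads, hp, seed=1)
        assert (seq == TYPE_H).sum() == n_h
        assert len(seq) == np_beads

    def test_seed_determinism(self):
        a = generate_hp_sequence(40, 0.25, seed=7)
        b = generate_hp_sequence(40, 0.25, seed=7)
        c = generate_hp_sequence(40, 0.25, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert (a == TYPE_H).sum() == (c == TYPE_H).sum()

    def test_degenerate_composition_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            generate_hp_sequence(40, 0.005, seed=0)

    @settings(deadline=None, max_examples=30)
    @given(np_beads=st.integers(4, 200), hp=st.floats(0.05, 0.95), seed=st.integers(0, 10))
    def test_composition_property(self, np_beads, hp, seed):
        n_h = round(hp * np_beads)
        if n_h in (0, np_beads):
            return
        seq = generate_hp_sequence(np_beads, hp, seed)
        assert (seq == TYPE_H).sum() == n_h


class TestDoping:
    def _coating(self, seed=0):
        return build_coating(BoxGeometry(12, 12, 12), g=9, n=10)

    def test_none_is_identity(self):
        s = self._coating()
        before = s.types.copy()
        hb.apply_doping(s, "none")
        assert np.array_equal(s.types, before)

    def test_middle_retypes_one_bead_per_chain_same_index(self):
        s = self._coating()
        pos_before = s.positions.copy()
        hb.apply_doping(s, "middle")
        a = np.nonzero(s.types == TYPE_A)[0]
        assert len(a) == 9
        # 1-based index ceil(N/2) = 5 for N=10 -> offset 4 from the anchor
        assert np.all(a % 10 == 4)
        assert np.array_equal(s.positions, pos_before)

    def test_terminal_retypes_free_end(self):
        s = self._coating()
        hb.apply_doping(s, "terminal")
        a = np.nonzero(s.types == TYPE_A)[0]
        assert len(a) == 9
        assert np.all(a % 10 == 9)

    def test_random_never_hits_anchor_and_is_seeded(self):
        s1, s2 = self._coating(), self._coating()
        hb.apply_doping(s1, "random", seed=5)
        hb.apply_doping(s2, "random", seed=5)
        a1 = np.nonzero(s1.types == TYPE_A)[0]
        assert len(a1) == 9
        assert np.all(a1 % 10 != 0)  # tethered bead excluded
        assert np.array_equal(a1, np.nonzero(s2.types == TYPE_A)[0])

    def test_ligand_count_and_conservation(self):
        s = self._coating()
        fill_water(s, density=0.3, rng=2)
        n_before = s.n_beads
        hb.apply_doping(s, "ligand", sigma_lig=0.023, z_lig=3.0, seed=1)
        lig = np.nonzero(s.types == TYPE_A_LIGAND)[0]
        assert len(lig) == round(0.023 * 144)  # round(sigma_lig * A)
        assert s.n_beads == n_before  # ligands replace water beads
        assert np.all(s.positions[lig, 2] == 3.0)
        assert not s.mobile[lig].any()

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            hb.apply_doping(self._coating(), "sideways")


class TestWaterFill:
    def test_zero_density_is_noop(self, small_box):
        s = ParticleSystem.empty(small_box)
        fill_water(s, density=0.0)
        assert s.n_beads == 0

    def test_exact_count_and_min_distance(self, small_box):
        s = ParticleSystem.empty(small_box)
        fill_water(s, density=0.65, rng=3)
        assert s.n_beads == round(0.65 * small_box.volume)
        assert s.min_pair_distance() >= 1.0
        assert np.all(s.types == TYPE_W)

    def test_density_too_high_errors(self, small_box):
        s = ParticleSystem.empty(small_box)
        with pytest.raises(ConstructionError):
            fill_water(s, density=1.5)

    def test_rejection_method_low_density(self, small_box):
        s = ParticleSystem.empty(small_box)
        fill_water(s, density=0.1, rng=4, method="random")
        assert s.n_beads == round(0.1 * small_box.volume)
        assert s.min_pair_distance() >= 1.0


class TestProteinPlacement:
    def test_no_overlap_and_grid_layout(self, small_box):
        system = build_coating(small_box, g=9, n=10, max_height=4.0)
        rng = np.random.default_rng(0)
        library = [
            {"positions": compact_conformation(12),
             "sequence": generate_hp_sequence(12, 0.25, rng), "rg": 1.0}
            for _ in range(2)
        ]
        place_proteins(system, library, hmax=4.0, clearance=1.0, seed=0)
        proteins = system.chains(types=(TYPE_H,))
        assert len(proteins) == 2
        assert system.min_pair_distance(exclude_bonded=True) >= 1.0
        for idx in proteins:
            assert system.positions[idx, 2].min() >= 5.0 - 1e-9

    def test_fixture_determinism(self):
        a = hb.make_fixture("mini-mushroom", seed=11)
        b = hb.make_fixture("mini-mushroom", seed=11)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)
        assert np.array_equal(a.types, b.types)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="dimer"):
            hb.make_fixture("nope")


class TestProteinLibrary:
    def test_library_size_sequences_and_centring(self):
        # miniature chains and a very short run: exercises the harvest
        # mechanics, not production physics (hence the non-collapse warning)
        with pytest.warns(UserWarning, match="not collapsed"):
            lib = hb.sample_protein_library(
                np_beads=8, hp=0.25, gp=2, seed=3, t_run=20.0,
                t_collect_from=10.0, density=0.4,
            )
        assert len(lib) == 2
        for entry in lib:
            assert entry["positions"].shape == (8, 3)
            assert (entry["sequence"] == TYPE_H).sum() == 2  # round(0.25 * 8)
            np.testing.assert_allclose(entry["positions"].mean(axis=0), 0.0,
                                       atol=1e-9)
        # independent copies: different sequences given different sub-seeds
        assert not np.array_equal(lib[0]["sequence"], lib[1]["sequence"])
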