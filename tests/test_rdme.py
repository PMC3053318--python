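"""Geometry builders, obstacle packing, lattice RDME, crowding effects."""

import numpy as np
import pytest
from scipy import ndimage

from lacswitch.rdme import (LatticeError, build_fast_growth_geometry,
                            build_slow_growth_geometry, discretize,
                            fast_growth_obstacles,
                            mrna_localization_experiment, msd_analysis,
                            nucleoid_random_walk, place_obstacles,
                            rebind_experiment, slow_growth_obstacles)
from lacswitch.rdme.geometry import CellGeometry
from lacswitch.rdme.lattice import (SITE_CYTOPLASM, SITE_EXTRACELLULAR,
                                    SITE_MEMBRANE, SITE_NUCLEOID,
                                    SITE_OPERATOR, Lattice, LatticeReaction,
                                    rdme_run)


@pytest.fixture(scope="module")
def fast_geom():
    return build_fast_growth_geometry()


@pytest.fixture(scope="module")
def slow_geom():
    return build_slow_growth_geometry(seed=2)


class TestFastGrowthGeometry:
    def test_enclosed_volume(self, fast_geom):
        # pi r^2 L_cyl + 4/3 pi r^3 for 2 um x 0.8 um spherocylinder
        assert fast_geom.volume() / 1e9 == pytest.approx(0.871, abs=0.005)

    def test_operator_at_center(self, fast_geom):
        np.testing.assert_array_equal(fast_geom.operator_position,
                                      np.zeros(3))

    def test_membrane_closed_on_lattice(self, fast_geom):
        lat = discretize(fast_geom, spacing=32.0, dt=1e-3)
        outside = lat.site_type == SITE_EXTRACELLULAR
        # flood fill from a corner: the outside component must not touch
        # any cytoplasm voxel through the membrane shell
        lab, _ = ndimage.label(outside)
        corner = lab[0, 0, 0]
        grown = ndimage.binary_dilation(lab == corner)
        assert not np.any(grown & (lat.site_type == SITE_CYTOPLASM))


class TestSlowGrowthGeometry:
    def test_ribosome_census(self, slow_geom):
        assert slow_geom.ribosome_positions.shape == (3021, 3)

    def test_mirrored_pole(self, slow_geom):
        rib = slow_geom.ribosome_positions
        n_pole = 3021 // 3
        pole = rib[:n_pole]
        mirrored = rib[-n_pole:]
        np.testing.assert_allclose(mirrored[:, 0], -pole[:, 0])
        np.testing.assert_allclose(mirrored[:, 1:], pole[:, 1:])

    def test_nucleoid_excludes_ribosomes(self, slow_geom):
        assert not np.any(slow_geom.in_nucleoid(slow_geom.ribosome_positions))

    def test_operator_near_membrane_and_pole(self, slow_geom):
        op = slow_geom.operator_position
        assert op[0] < -0.2 * slow_geom.length / 2  # toward a pole
        assert slow_geom.contains(op[None, :])[0]


class TestNucleoidWalk:
    def test_full_chromosome(self, slow_geom):
        chain = nucleoid_random_walk(slow_geom, n_segments=31000, seed=3)
        assert chain.shape == (31000, 3)
        # total contour length: segments x 50 nm
        assert 31000 * 50.0 == pytest.approx(1.55e6)
        assert slow_geom.in_nucleoid(chain).all()

    def test_angle_constraint(self, slow_geom):
        chain = nucleoid_random_walk(slow_geom, n_segments=2000, seed=4,
                                     angle_max=90.0)
        # midpoint differences are 0.5*(d_i + d_{i+1}); the 90-degree cap
        # on successive directions bounds each difference from below,
        # except across the rare unwind-restart joints where the new path
        # direction is unconstrained
        steps = np.diff(chain, axis=0)
        norms = np.linalg.norm(steps, axis=1)
        bound = 50.0 * np.sqrt(2) / 2 - 1e-9
        assert np.mean(norms >= bound) > 0.97

    def test_impossible_region_raises(self, slow_geom):
        import dataclasses
        tiny = dataclasses.replace(
            slow_geom, nucleoid={"x_min": -60, "x_max": 60, "radius": 55})
        with pytest.raises(RuntimeError):
            nucleoid_random_walk(tiny, n_segments=31000, seed=0,
                                 max_retries=200)


class TestObstacles:
    def test_census_counts(self):
        fast = fast_growth_obstacles()
        slow = slow_growth_obstacles()
        assert fast.classes[0].count == 35005     # ribosomes, fast growth
        assert slow.classes[0].count == 3021      # ribosomes, slow growth
        assert fast.total_fraction() == pytest.approx(0.50, abs=0.005)

    def test_packing_reaches_target(self):
        box = 120.0
        spec = fast_growth_obstacles().scaled_to_volume(box ** 3,
                                                        packing=0.5)
        dummy = CellGeometry(shape="box", length=box, diameter=box,
                             operator_position=np.full(3, box / 2))
        centers, radii, _ = place_obstacles(
            dummy, spec, seed=1,
            region=(np.zeros(3), np.full(3, box)))
        achieved = (4 / 3 * np.pi * radii ** 3).sum() / box ** 3
        assert achieved == pytest.approx(0.5, abs=0.01)
        # non-overlap spot check on the largest class
        big = radii == radii.max()
        c = centers[big]
        d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * radii.max() - 1e-9

    def test_zero_target_empty(self, fast_geom):
        spec = fast_growth_obstacles().scaled_to_volume(100.0 ** 3,
                                                        packing=0.0)
        assert sum(c.count for c in spec.classes) == 0


class TestDiscretize:
    def test_operator_site_unique(self, fast_geom):
        lat = discretize(fast_geom, spacing=32.0, dt=1e-3)
        assert (lat.site_type == SITE_OPERATOR).sum() == 1
        assert lat.site_type[lat.operator_site] == SITE_OPERATOR

    def test_slow_growth_has_nucleoid_sites(self, slow_geom):
        lat = discretize(slow_geom, spacing=32.0, dt=1e-3)
        assert (lat.site_type == SITE_NUCLEOID).sum() > 100

    def test_courant_bound_enforced(self):
        site = np.full((6, 6, 6), SITE_CYTOPLASM, dtype=np.uint8)
        # 16 nm, 50 us caps representable diffusion at ~0.85 um^2/s
        lat = Lattice(spacing=16.0, dt=50e-6, site_type=site,
                      species=["A"],
                      diffusion={("A", SITE_CYTOPLASM): 1.28})
        lat.zero_counts()
        with pytest.raises(LatticeError):
            rdme_run(lat, t_end=1e-3, seed=0)
        lat.diffusion[("A", SITE_CYTOPLASM)] = lat.max_diffusion()
        rdme_run(lat, t_end=1e-3, seed=0)  # at the cap: accepted

    def test_unsupported_spacing_rejected(self, fast_geom):
        with pytest.raises(ValueError):
            discretize(fast_geom, spacing=10.0, dt=1e-3)


class TestRdmeRun:
    @staticmethod
    def _uniform(n=10, species=("A",), diffusion=None, reactions=()):
        site = np.full((n, n, n), SITE_CYTOPLASM, dtype=np.uint8)
        lat = Lattice(spacing=32.0, dt=1e-4, site_type=site,
                      species=list(species),
                      diffusion=diffusion or
                      {(s, SITE_CYTOPLASM): 1.0 for s in species},
                      reactions=list(reactions), capacity=8)
        lat.zero_counts()
        return lat

    def test_diffusion_conserves_particles(self, rng):
        lat = self._uniform()
        for _ in range(500):
            lat.place("A", tuple(rng.integers(0, 10, 3)))
        _, totals = rdme_run(lat, t_end=0.05, seed=2)
        assert set(totals["A"].tolist()) == {500}

    def test_first_order_decay_matches_law(self, rng):
        lat = self._uniform(reactions=[
            LatticeReaction("decay", ("A",), (), 0.5, 1)])
        for _ in range(600):
            lat.place("A", tuple(rng.integers(0, 10, 3)))
        times, totals = rdme_run(lat, t_end=2.0, seed=1,
                                 sample_interval=0.5)
        expected = 600 * np.exp(-0.5 * times)
        sd = np.sqrt(expected * (1 - np.exp(-0.5 * times)))
        assert np.all(np.abs(totals["A"] - expected) <= 3.5 * sd + 1)

    def test_bimolecular_matches_well_mixed_kinetics(self, rng):
        lat = self._uniform(species=("A", "B", "C"), reactions=[
            LatticeReaction("ab", ("A", "B"), ("C",), 1e7, 2)])
        lat.dt = 5e-5
        for _ in range(300):
            lat.place("A", tuple(rng.integers(0, 10, 3)))
            lat.place("B", tuple(rng.integers(0, 10, 3)))
        times, totals = rdme_run(lat, t_end=0.5, seed=3,
                                 sample_interval=0.1)
        v_liters = (10 * 32.0) ** 3 * 1e-24
        k_pair = 1e7 / (6.02214076e23 * v_liters)
        ode = 300 - 300 / (1 + k_pair * 300 * times)
        assert np.all(np.abs(totals["C"] - ode) < 15)

    def test_mrna_never_enters_nucleoid(self, slow_geom):
        lat = discretize(slow_geom, spacing=32.0, dt=1e-3,
                         species=["mY"],
                         diffusion={("mY", SITE_CYTOPLASM): 0.1,
                                    ("mY", SITE_MEMBRANE): 0.1,
                                    ("mY", SITE_OPERATOR): 0.1})
        lat.place("mY", lat.operator_site, 40)
        rdme_run(lat, t_end=0.2, seed=5)
        nucleoid = lat.site_type == SITE_NUCLEOID
        assert lat.counts["mY"][nucleoid].sum() == 0
        assert lat.total("mY") == 40


class TestRebinding:
    def test_binding_disabled_never_rebinds(self):
        res = rebind_experiment(0.0, n_traj=100, k_rb=0.0, msd_tracks=0,
                                seed=1)
        assert res.rebind_probability == 0.0
        assert res.n_rebinds + res.n_escapes == 100

    def test_uncrowded_alpha_is_one(self):
        res = rebind_experiment(0.0, n_traj=10, msd_tracks=150,
                                msd_steps=8000, seed=2)
        t = res.msd["t"]
        reliable = t <= 0.25 * t[-1]
        assert np.all(np.abs(res.msd["alpha"][reliable] - 1) < 0.08)

    def test_invalid_packing_rejected(self):
        with pytest.raises(ValueError):
            rebind_experiment(0.7, n_traj=10)


class TestLocalization:
    def test_zero_diffusion_hits_nearest_membrane_site(self, fast_geom):
        xs = mrna_localization_experiment(fast_geom, n_mrna=20, D_mrna=0.0,
                                          seed=1)
        assert np.unique(xs).size == 1

    def test_slow_growth_localizes_transcripts(self, fast_geom, slow_geom):
        xs_fast = mrna_localization_experiment(fast_geom, n_mrna=120, seed=5)
        xs_slow = mrna_localization_experiment(slow_geom, n_mrna=120, seed=5)
        assert np.std(xs_slow) < 0.6 * np.std(xs_fast)


class TestMsdAnalysis:
    def test_requires_enough_tracks(self):
        with pytest.raises(ValueError):
            msd_analysis(np.zeros((5, 10, 3)), dt=1e-3)
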