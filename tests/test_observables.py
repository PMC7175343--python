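"""Observables: free-energy profiles, g(r), orientations, shape factors."""

import numpy as np
import pytest

import cgadsorb as cg
from cgadsorb.interactions import SurfaceField
from cgadsorb.mc import SampleSet
from cgadsorb.observables import block_stderr, min_surface_separation
from cgadsorb.synthetic import make_ideal_chain


def _samples_from_z(z_values, n_beads=1):
    pos = np.zeros((len(z_values), n_beads, 3))
    pos[:, :, 2] = np.asarray(z_values)[:, None]
    return SampleSet(pos, np.zeros(len(z_values)))


class TestFreeEnergyProfile:
    def test_uniform_density_gives_flat_zero_profile(self, rng):
        z = rng.uniform(0, 100, size=200_000)
        prof = cg.free_energy_profile(
            _samples_from_z(z), np.ones(1), bin_width=5.0, z_max=100.0
        )
        vals = prof.values[~np.isnan(prof.values)]
        assert np.allclose(vals, 0.0, atol=0.1)

    def test_single_bead_boltzmann_round_trip(self, conditions, rng):
        """F(z) from exact Boltzmann samples matches the wall energy."""
        field = SurfaceField.from_conditions(-0.01, conditions)
        zq = np.linspace(2.5, 120.0, 2400)
        w = np.array([cg.gc_energy(1.0, z, field) for z in zq])
        p = np.exp(-w)
        p /= p.sum()
        z = rng.choice(zq, size=400_000, p=p)
        prof = cg.free_energy_profile(
            _samples_from_z(z), np.ones(1), bin_width=4.0, z_max=120.0
        )
        # compare with the analytic energy at the bin centers (zero at bulk)
        centers = prof.bin_centers
        ref = np.array([cg.gc_energy(1.0, c, field) for c in centers])
        sel = ~np.isnan(prof.values) & (centers > 4.0)
        assert np.allclose(prof.values[sel], ref[sel], atol=0.1)

    def test_exp_minus_f_renormalizes_to_density(self, rng):
        z = rng.uniform(0, 50, 5000) ** 1.3
        samples = _samples_from_z(z)
        prof = cg.free_energy_profile(samples, np.ones(1), bin_width=2.0)
        counts, _ = np.histogram(z, bins=prof.bin_edges)
        p = counts / counts.sum()
        mask = counts > 0
        q = np.exp(-prof.values[mask])
        q = q / q.sum() * p[mask].sum()
        assert np.allclose(q, p[mask], atol=1e-12)


class TestRadialG:
    def test_ideal_gas_is_unity(self, rng):
        npart = cg.Nanoparticle(np.zeros(3), 100.0, -503)
        # uniform points in a shell around the particle
        n = 400_000
        r = (rng.uniform(100.0**3, 300.0**3, n)) ** (1 / 3)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = (r[:, None] * u)[:, None, :]
        samples = SampleSet(pos, np.zeros(n))
        prof = cg.radial_g(samples, np.ones(1), npart, bin_width=10.0,
                           r_max=200.0)
        assert np.allclose(prof.values, 1.0, atol=0.05)
        assert np.all(prof.values >= 0)

    def test_contact_peak_for_attractive_particle(self, rng):
        npart = cg.Nanoparticle(np.zeros(3), 100.0, -503)
        n = 50_000
        # density enhanced within 20 Å of the surface
        r_near = 100.0 + rng.uniform(0, 20, n)
        r_far = (rng.uniform(100.0**3, 300.0**3, n)) ** (1 / 3)
        r = np.concatenate([r_near, r_far])
        u = rng.normal(size=(len(r), 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        samples = SampleSet((r[:, None] * u)[:, None, :], np.zeros(len(r)))
        prof = cg.radial_g(samples, np.ones(1), npart, bin_width=10.0,
                           r_max=200.0)
        assert prof.values[0] > 1.5
        assert prof.values[-1] < prof.values[0]


class TestOrientation:
    def test_collinear_rod_axis_exact(self):
        direction = np.array([1.0, 2.0, 2.0]) / 3.0
        pos = np.outer(np.arange(20), direction * 5.0)
        axis = cg.axis_vector(pos)
        assert abs(axis @ direction) == pytest.approx(1.0, abs=1e-12)

    def test_axis_invariant_under_reordering(self, rng):
        pos = np.outer(np.arange(30), np.array([3.0, 0.5, 1.0]))
        pos += rng.normal(scale=0.5, size=pos.shape)
        perm = rng.permutation(len(pos))
        assert np.allclose(cg.axis_vector(pos), cg.axis_vector(pos[perm]),
                           atol=1e-12)

    def test_axis_rotates_covariantly(self, rng):
        from cgadsorb.mc import _rotate_about

        pos = np.outer(np.arange(25), np.array([4.0, 1.0, 0.0]))
        pos += rng.normal(scale=0.3, size=pos.shape)
        axis0 = cg.axis_vector(pos)
        u = np.array([0.1, 0.7, -0.7])
        u /= np.linalg.norm(u)
        rotated = _rotate_about(pos, pos.mean(axis=0), u, 0.9)
        axis1 = cg.axis_vector(rotated)
        expected = _rotate_about(axis0[None, :], np.zeros(3), u, 0.9)[0]
        assert min(np.linalg.norm(axis1 - expected),
                   np.linalg.norm(axis1 + expected)) < 1e-9

    def test_degenerate_body_raises(self):
        # perfect tetrahedron: all gyration eigenvalues equal
        pos = np.array([
            [1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
        ])
        with pytest.raises(ValueError, match="degenerate"):
            cg.axis_vector(pos)

    @pytest.mark.parametrize("direction,expected", [
        (np.array([0.0, 0.0, 1.0]), 1.0),                  # standing up
        (np.array([1.0, 0.0, 0.0]), 0.0),                  # lying flat
        (np.array([np.sqrt(3) / 2, 0.0, 0.5]), 0.5),       # 60° from normal
    ])
    def test_cos_to_surface_normal(self, direction, expected):
        pos = np.outer(np.arange(15), direction * 4.0)
        assert cg.cos_to_surface_normal(pos) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_cos_to_np_radial_and_tangential(self):
        npart = cg.Nanoparticle(np.zeros(3), 100.0, -500)
        radial = np.outer(np.arange(10), [0.0, 0.0, 4.0]) + [0, 0, 110.0]
        assert cg.cos_to_np(radial, npart) == pytest.approx(1.0)
        tangential = np.outer(np.arange(10) - 4.5, [4.0, 0.0, 0.0])
        tangential[:, 2] += 110.0
        assert cg.cos_to_np(tangential, npart) == pytest.approx(0.0, abs=1e-9)

    def test_cos_to_np_flat_limit_matches_surface_normal(self):
        # huge particle directly below the molecule ~ flat wall
        R = 1.0e7
        npart = cg.Nanoparticle(np.array([0.0, 0.0, -R]), R, -1)
        tilted = np.outer(np.arange(12), [3.0, 0.0, 1.0]) + [0, 0, 30.0]
        assert cg.cos_to_np(tilted, npart) == pytest.approx(
            cg.cos_to_surface_normal(tilted), abs=1e-4
        )


class TestAdsorbedFraction:
    def _flat_layout(self):
        return cg.SurfaceLayout(kind="flat", rho=-0.005)

    def test_all_touching_gives_100_percent(self, mimic_rod):
        cell = cg.SimulationCell(1000, 1000, 600)
        pos = mimic_rod.positions.copy()
        pos[:, 2] -= pos[:, 2].min() - 2.6  # feet at the wall
        samples = SampleSet(np.repeat(pos[None], 50, axis=0), np.zeros(50))
        frac, flags = cg.adsorbed_fraction(
            samples, mimic_rod, self._flat_layout(), cell, cutoff=38.0
        )
        assert frac == 1.0
        assert flags.all()

    def test_monotone_in_cutoff(self, mimic_rod, rng):
        cell = cg.SimulationCell(1000, 1000, 600)
        frames = []
        for _ in range(100):
            pos = mimic_rod.positions.copy()
            pos[:, 2] += rng.uniform(30.0, 500.0)
            frames.append(pos)
        samples = SampleSet(np.array(frames), np.zeros(100))
        cuts = [5.0, 20.0, 50.0, 150.0, 500.0]
        fracs = [
            cg.adsorbed_fraction(samples, mimic_rod, self._flat_layout(),
                                 cell, c)[0]
            for c in cuts
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_min_separation_counts_nanoparticles(self, conditions):
        cell = cg.SimulationCell(1200, 1039.23, 1000)
        layout = cg.hex_lattice(200.0, 600.0, cell, -0.005)
        pos = np.array([[0.0, 0.0, 410.0]])  # 7.5 Å above an NP pole
        gap = min_surface_separation(pos, np.array([2.5]), layout, cell)
        assert gap == pytest.approx(7.5)


class TestShapeDescriptors:
    def test_two_equal_beads(self):
        pos = np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])
        assert cg.rg(pos, np.ones(2)) == pytest.approx(3.0)

    def test_mass_weighting(self):
        pos = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        # heavy bead pulls the center of mass toward itself
        masses = np.array([3.0, 1.0])
        assert cg.rg(pos, masses) == pytest.approx(
            np.sqrt((3 * 2.5**2 + 1 * 7.5**2) / 4.0)
        )

    def test_three_collinear_beads_shape_factor_six(self):
        pos = np.outer([0, 1, 2], [5.0, 0.0, 0.0])
        assert cg.shape_factor(pos) == pytest.approx(6.0)

    @pytest.mark.parametrize("n", [10, 100, 10_000])
    def test_straight_rod_closed_form(self, n):
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * 4.1
        assert cg.shape_factor(pos) == pytest.approx(
            12.0 * (n - 1) / (n + 1), rel=1e-12
        )

    def test_fjc_ensemble_shape_factor_near_six(self):
        rng = np.random.default_rng(77)
        n = 400
        ratios_num, ratios_den = [], []
        for _ in range(3000):
            pos = make_ideal_chain(n, 4.1, rng=rng)
            ratios_num.append(cg.end_to_end(pos) ** 2)
            ratios_den.append(cg.rg(pos, np.ones(n)) ** 2)
        ratio = np.mean(ratios_num) / np.mean(ratios_den)
        assert ratio == pytest.approx(6.0 * n / (n + 1), rel=0.05)


class TestBlockAveraging:
    def test_stderr_scales_with_independent_samples(self, rng):
        x = rng.normal(size=10_000)
        se = block_stderr(x, n_blocks=10)
        assert se == pytest.approx(1.0 / np.sqrt(10_000), rel=0.5)
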