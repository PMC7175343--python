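"""Monte Carlo engine: moves, acceptance rule, Boltzmann sampling."""

import math

import numpy as np
import pytest
from scipy import stats

import cgadsorb as cg
from cgadsorb import mc
from cgadsorb.interactions import SurfaceField
from cgadsorb.synthetic import make_ideal_chain, make_two_state_toy
from cgadsorb.system import AdsorptionSystem


class TestMetropolisRule:
    def test_downhill_always_accepted(self):
        assert cg.metropolis_accept(-3.0, 0.999999)

    def test_infinite_barrier_always_rejected(self):
        assert not cg.metropolis_accept(math.inf, 0.0)

    def test_ln2_threshold(self):
        assert cg.metropolis_accept(math.log(2), 0.499)
        assert not cg.metropolis_accept(math.log(2), 0.501)


class TestMoves:
    def test_zero_step_moves_are_identity(self, rng):
        pos = rng.uniform(0, 50, size=(20, 3))
        for func in (mc.rigid_translate, mc.bead_translate):
            new, _ = func(pos, 0.0, np.random.default_rng(5))
            assert np.allclose(new, pos)
        new, _ = mc.rigid_rotate(pos, 0.0, np.random.default_rng(5))
        assert np.allclose(new, pos, atol=1e-12)

    def test_translation_mean_displacement_vanishes(self):
        rng = np.random.default_rng(7)
        pos = np.zeros((1, 3))
        shifts = np.array([
            mc.rigid_translate(pos, 3.0, rng)[0][0] for _ in range(4000)
        ])
        assert np.allclose(shifts.mean(axis=0), 0.0, atol=0.15)

    def test_bead_translate_moves_exactly_one_bead(self, rng):
        pos = rng.uniform(0, 50, size=(10, 3))
        new, moved = mc.bead_translate(pos, 2.0, np.random.default_rng(3))
        changed = np.where(np.any(new != pos, axis=1))[0]
        assert len(changed) == 1
        assert changed[0] == moved[0]

    def test_crankshaft_preserves_segment_and_bonds(self):
        rng = np.random.default_rng(11)
        pos = make_ideal_chain(20, 4.1, seed=2)
        bond_ref = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        for _ in range(100):
            new, moved = mc.crankshaft(pos, 1.0, rng)
            bond_new = np.linalg.norm(np.diff(new, axis=0), axis=1)
            assert np.allclose(bond_new, bond_ref, atol=1e-9)
            pos = new

    def test_pivot_preserves_bond_lengths(self):
        rng = np.random.default_rng(13)
        pos = make_ideal_chain(20, 4.1, seed=3)
        bond_ref = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        for _ in range(100):
            new, moved = mc.pivot(pos, 1.0, rng)
            bond_new = np.linalg.norm(np.diff(new, axis=0), axis=1)
            assert np.allclose(bond_new, bond_ref, atol=1e-9)
            pos = new

    def test_crankshaft_endpoints_fixed(self):
        rng = np.random.default_rng(17)
        pos = make_ideal_chain(15, 4.1, seed=4)
        new, moved = mc.crankshaft(pos, 1.2, rng)
        untouched = sorted(set(range(15)) - set(moved.tolist()))
        assert np.allclose(new[untouched], pos[untouched])

    def test_rotation_reversibility(self):
        from cgadsorb.mc import _rotate_about

        pos = make_ideal_chain(12, 4.1, seed=5)
        axis = np.array([0.3, -0.5, 0.8])
        axis /= np.linalg.norm(axis)
        fwd = _rotate_about(pos, pos[0], axis, 0.7)
        back = _rotate_about(fwd, pos[0], axis, -0.7)
        assert np.allclose(back, pos, atol=1e-9)

    def test_move_model_mismatch_rejected(self, conditions, mimic_rod):
        system = AdsorptionSystem(
            mimic_rod.copy(), conditions, cg.SimulationCell(1000, 1000, 1000),
            cg.SurfaceLayout(kind="flat", rho=0.0),
        )
        system.model.positions[:, 2] += 400.0
        with pytest.raises(ValueError, match="chain move"):
            mc.run(system, [mc.MoveSpec("pivot", 1.0)],
                   mc.RunSchedule(1, 1, 1, 0))


def _one_bead_system(conditions, rho, lz=150.0, charge=1.0):
    model = cg.BeadModel(
        positions=[[50.0, 50.0, lz / 2]], radii=[2.5], charges=[charge],
        masses=[110.0], labels=["BEAD"], rigid=True,
    )
    cell = cg.SimulationCell(100.0, 100.0, lz)
    layout = cg.SurfaceLayout(kind="flat", rho=rho)
    return AdsorptionSystem(model, conditions, cell, layout)


class TestEngine:
    def test_same_seed_bit_identical(self, conditions):
        def one_run():
            system = _one_bead_system(conditions, -0.005)
            return mc.run(
                system, [mc.MoveSpec("rigid_translate", 8.0)],
                mc.RunSchedule(100, 500, 5, seed=42),
            )

        a, b = one_run(), one_run()
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.energies, b.energies)

    def test_overlapping_start_rejected(self, conditions):
        system = _one_bead_system(conditions, -0.005)
        system.model.positions[0, 2] = 1.0
        with pytest.raises(ValueError, match="re-initialize"):
            mc.run(system, [mc.MoveSpec("rigid_translate", 5.0)],
                   mc.RunSchedule(1, 1, 1, 0))

    def test_two_state_occupancies(self):
        toy = make_two_state_toy(gap=1.0)
        states = toy.sample(120_000, seed=9)
        p0, p1 = toy.analytic_occupancies()
        observed = 1.0 - states[2000:].mean()
        se = 3.0 / math.sqrt(len(states) - 2000)  # generous 3-sigma band
        assert observed == pytest.approx(p0, abs=5 * se)

    def test_two_state_zero_gap_is_fifty_fifty(self):
        toy = make_two_state_toy(gap=0.0)
        states = toy.sample(50_000, seed=10)
        assert states.mean() == pytest.approx(0.5, abs=0.02)

    def test_two_state_infinite_gap_stays_ground(self):
        toy = make_two_state_toy(gap=math.inf)
        assert make_two_state_toy(math.inf).sample(2000, seed=3).sum() == 0
        assert toy.analytic_occupancies() == (1.0, 0.0)

    def test_boltzmann_z_density_above_charged_wall(self, conditions):
        """Sampled P(z) of one +1 bead matches the quadrature oracle (chi^2)."""
        system = _one_bead_system(conditions, -0.005)
        samples = mc.run(
            system, [mc.MoveSpec("rigid_translate", 12.0)],
            mc.RunSchedule(2000, 60_000, 30, seed=21),
        )
        z = samples.positions[:, 0, 2]
        edges = np.linspace(2.5, 150.0 - 2.5, 13)
        counts, _ = np.histogram(z, bins=edges)
        field = SurfaceField.from_conditions(-0.005, conditions)
        zq = np.linspace(2.5, 147.5, 4001)
        boltz = np.exp(-np.array([cg.gc_energy(1.0, s, field) for s in zq]))
        expected = np.array([
            np.trapezoid(boltz[(zq >= a) & (zq <= b)],
                         zq[(zq >= a) & (zq <= b)])
            for a, b in zip(edges[:-1], edges[1:])
        ])
        expected *= counts.sum() / expected.sum()
        chi2 = stats.chisquare(counts, expected)
        assert chi2.pvalue > 0.01

    def test_uniform_z_above_uncharged_wall(self, conditions):
        """Neutral-wall sampling is uniform over the accessible z (KS test)."""
        system = _one_bead_system(conditions, 0.0, charge=0.0)
        samples = mc.run(
            system, [mc.MoveSpec("rigid_translate", 15.0)],
            mc.RunSchedule(1000, 40_000, 40, seed=22),
        )
        z = samples.positions[:, 0, 2]
        ks = stats.kstest(z, stats.uniform(loc=2.5, scale=145.0).cdf)
        assert ks.pvalue > 0.01

    def test_no_hard_core_violations_in_sampleset(self, conditions):
        model = cg.build_flexible_chain("DKEARDKEAR")
        model.positions[:, 2] += 10.0
        model.positions[:, :2] += 50.0
        cell = cg.SimulationCell(150.0, 150.0, 200.0)
        system = AdsorptionSystem(
            model, conditions, cell, cg.SurfaceLayout(kind="flat", rho=-0.01)
        )
        samples = mc.run(system, schedule=mc.RunSchedule(500, 3000, 10, 23))
        radii = model.radii
        for pos in samples.positions:
            d = pos[:, None, :] - pos[None, :, :]
            rij = np.sqrt((d ** 2).sum(axis=-1))
            sigma = radii[:, None] + radii[None, :]
            np.fill_diagonal(rij, np.inf)
            assert np.all(rij >= sigma - 1e-9)
            assert np.all(pos[:, 2] >= radii - 1e-9)

    def test_ideal_chain_limits(self, conditions):
        """Phantom chain: <Ree^2>/<Rg^2> near the Gaussian value, <Rb> ~ Req."""
        n_res = 28  # 30 beads with termini
        model = cg.build_flexible_chain("A" * n_res)
        model.charges[:] = 0.0
        model.positions[:, :2] += 500.0
        cell = cg.SimulationCell(10_000.0, 10_000.0, 10_000.0)
        model.positions[:, 2] += 5000.0
        system = AdsorptionSystem(
            model, conditions, cell, cg.SurfaceLayout(kind="flat", rho=0.0),
            use_lj=False, use_intra_dh=False, intra_hard_core=False,
        )
        samples = mc.run(system, schedule=mc.RunSchedule(1000, 12_000, 6, 31))
        ree2 = np.array([
            cg.end_to_end(p) ** 2 for p in samples.positions
        ])
        rg2 = np.array([
            cg.rg(p, np.ones(len(p))) ** 2 for p in samples.positions
        ])
        n = model.n_beads
        expected = 6.0 * n / (n + 1)
        assert ree2.mean() / rg2.mean() == pytest.approx(expected, rel=0.05)
        bonds = np.array([
            np.linalg.norm(np.diff(p, axis=0), axis=1).mean()
            for p in samples.positions
        ])
        # quadrature oracle: <Rb> under P(Rb) ∝ Rb^2 exp(-kh (Rb-Req)^2)
        r = np.linspace(0.0, 12.0, 20_001)
        w = r**2 * np.exp(-0.76 * (r - 4.1) ** 2)
        expected_rb = np.trapezoid(r * w, r) / np.trapezoid(w, r)
        assert bonds.mean() == pytest.approx(expected_rb, rel=0.02)
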