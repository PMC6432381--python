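"""Force-field unit tests: potentials, analytic forces, neighbor lists."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from nanodozer import (BondOverstretchError, ForceFieldParams, NeighborList,
                       build_neighbor_list, bend_energy, fene_energy,
                       total_forces, wca_energy)
from nanodozer.forcefield import wca_force_mag
from nanodozer.geometry import ChainState, ChannelGasket

PARAMS = ForceFieldParams()


def random_chain(n, seed, spread=0.5, scale=0.3, offset=(0.0, 8.0, 8.0)):
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(0, spread, (n, 3)), axis=0) * scale
    return pos + np.asarray(offset)


class TestPairPotentials:
    def test_wca_values(self):
        # cutoff continuity: 4e(1/4 - 1/2) + e = 0
        assert wca_energy(2 ** (1 / 6), PARAMS) == pytest.approx(0.0, abs=1e-12)
        # contact at sigma_b: 4e(1 - 1) + e = e
        assert wca_energy(1.0, PARAMS) == pytest.approx(1.0)
        # direct scalar evaluation of the formula at r = 0.9 sigma
        expected = 4.0 * (0.9 ** -12 - 0.9 ** -6) + 1.0
        assert wca_energy(0.9, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_wca_zero_beyond_cutoff_and_continuous(self):
        rc = PARAMS.wca_cutoff
        assert wca_energy(rc + 1e-12, PARAMS) == 0.0
        assert wca_energy(2.0, PARAMS) == 0.0
        assert abs(wca_energy(rc - 1e-7, PARAMS)) < 1e-5
        assert wca_force_mag(rc + 1e-12, PARAMS) == 0.0

    def test_wca_domain_error(self):
        with pytest.raises(ValueError):
            wca_energy(0.0, PARAMS)
        with pytest.raises(ValueError):
            wca_energy(-1.0, PARAMS)

    def test_fene_values(self):
        assert fene_energy(0.0, PARAMS) == pytest.approx(0.0)
        expected = -0.5 * 30 * 1.5**2 * np.log(1 - 0.97**2 / 1.5**2)
        assert fene_energy(0.97, PARAMS) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-33.75 * np.log(1 - 0.9409 / 2.25))

    def test_fene_monotone_and_divergent(self):
        r = np.linspace(0.0, 1.49, 200)
        e = fene_energy(r, PARAMS)
        assert np.all(np.diff(e) > 0)
        big = fene_energy(1.4999, PARAMS)
        assert np.isfinite(big) and big > 100

    def test_fene_overstretch_raises(self):
        with pytest.raises(BondOverstretchError):
            fene_energy(1.5, PARAMS)
        with pytest.raises(BondOverstretchError):
            fene_energy(2.0, PARAMS)

    def test_bend_values(self):
        assert bend_energy(0.0, PARAMS) == pytest.approx(0.0)
        assert bend_energy(np.pi / 2, PARAMS) == pytest.approx(3.2)
        assert bend_energy(np.pi, PARAMS) == pytest.approx(6.4)
        # clamp against rounding: slightly out-of-range cos must not NaN
        assert np.isfinite(bend_energy(np.pi + 1e-9, PARAMS))

    def test_combined_bond_minimum_near_097(self):
        """FENE + WCA bond potential has its minimum in (0.95, 0.99)."""
        res = minimize_scalar(
            lambda r: fene_energy(r, PARAMS) + wca_energy(r, PARAMS),
            bounds=(0.8, 1.2), method="bounded")
        assert 0.95 < res.x < 0.99


class TestTotalForces:
    def test_finite_difference_gradient(self):
        """Analytic forces match central differences to 1e-6 relative."""
        pos = random_chain(10, seed=0)
        st = ChainState(pos, np.zeros_like(pos))
        forces, energy = total_forces(st, None, PARAMS)
        eps = 1e-6
        fd = np.zeros_like(pos)
        for i in range(10):
            for k in range(3):
                for sgn in (1, -1):
                    p = pos.copy()
                    p[i, k] += sgn * eps
                    _, e = total_forces(ChainState(p, np.zeros_like(p)),
                                        None, PARAMS)
                    fd[i, k] += sgn * -e / (2 * eps)
        scale = np.max(np.abs(forces))
        assert np.max(np.abs(forces - fd)) / scale < 1e-6

    def test_finite_difference_with_walls(self):
        chan = ChannelGasket(width_D=10.0, gasket_enabled=False)
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 0.4, (8, 3)), axis=0) * 0.5
        pos[:, 1:] = 0.8 + np.abs(pos[:, 1:]) % 8.0  # near the lower walls
        st = ChainState(pos, np.zeros_like(pos))
        forces, _ = total_forces(st, chan, PARAMS)
        eps = 1e-6
        fd = np.zeros_like(pos)
        for i in range(8):
            for k in range(3):
                for sgn in (1, -1):
                    p = pos.copy()
                    p[i, k] += sgn * eps
                    _, e = total_forces(ChainState(p, np.zeros_like(p)),
                                        chan, PARAMS)
                    fd[i, k] += sgn * -e / (2 * eps)
        scale = np.max(np.abs(forces))
        assert np.max(np.abs(forces - fd)) / scale < 1e-6

    def test_internal_forces_sum_to_zero(self):
        pos = random_chain(12, seed=5)
        forces, _ = total_forces(ChainState(pos, np.zeros_like(pos)),
                                 None, PARAMS)
        # zero up to floating-point cancellation at the force scale
        assert np.max(np.abs(forces.sum(axis=0))) < 1e-12 * \
            np.max(np.abs(forces))

    def test_collinear_chain_zero_bending_force(self):
        pos = np.array([[0.0, 8, 8], [2.0, 8, 8], [4.0, 8, 8]])
        fb, eb = __import__(
            "nanodozer.forcefield", fromlist=["_bend_forces"]
        )._bend_forces(pos, PARAMS)
        assert eb == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fb, 0.0, atol=1e-9)

    def test_bending_energy_rotation_invariant(self):
        pos = random_chain(10, seed=7)
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([0.3, -1.1, 0.5]).as_matrix()
        _, e1 = total_forces(ChainState(pos, np.zeros_like(pos)), None, PARAMS)
        p2 = pos @ rot.T
        _, e2 = total_forces(ChainState(p2, np.zeros_like(p2)), None, PARAMS)
        assert e1 == pytest.approx(e2, rel=1e-10)

    def test_overstretch_aborts(self):
        pos = np.array([[0.0, 8, 8], [1.51, 8, 8]])
        with pytest.raises(BondOverstretchError):
            total_forces(ChainState(pos, np.zeros_like(pos)), None, PARAMS)


class TestNeighborList:
    def test_line_of_three(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        pairs = {tuple(p) for p in build_neighbor_list(pos, 1.2, 0.0)}
        assert pairs == {(0, 1), (1, 2)}

    def test_empty_chain(self):
        assert len(build_neighbor_list(np.empty((0, 3)), 1.2, 0.3)) == 0

    def test_matches_all_pairs_energy(self):
        """WCA energy from the list equals the brute-force all-pairs sum."""
        pos = random_chain(50, seed=2)
        pairs = build_neighbor_list(pos, PARAMS.wca_cutoff, 0.3)
        r = np.linalg.norm(pos[pairs[:, 1]] - pos[pairs[:, 0]], axis=1)
        e_list = np.sum(wca_energy(r, PARAMS))
        e_brute = 0.0
        for i in range(50):
            for j in range(i + 1, 50):
                rij = np.linalg.norm(pos[j] - pos[i])
                if rij <= PARAMS.wca_cutoff:
                    e_brute += wca_energy(rij, PARAMS)
        assert e_list == pytest.approx(e_brute, rel=1e-12)

    def test_rebuild_on_displacement(self):
        pos = random_chain(20, seed=9)
        nl = NeighborList(PARAMS.wca_cutoff, skin=0.4)
        first = nl.update(pos).copy()
        # below skin/2: no rebuild, same list object contents
        assert np.array_equal(nl.update(pos + 0.05), first)
        moved = pos.copy()
        moved[0] += 0.5  # beyond skin/2 forces a rebuild
        nl.update(moved)
        assert nl._ref is not None and np.allclose(nl._ref, moved)


class TestKernelConsistency:
    """The compiled force kernel agrees with the reference implementation."""

    @pytest.mark.parametrize("seed,scale", [(0, 0.3), (4, 1.0)])
    def test_kernel_matches_reference(self, seed, scale):
        from nanodozer import _kernels

        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.normal(0, 0.5, (16, 3)), axis=0) * scale
        if scale >= 1.0:  # rescale bonds below R0
            b = np.diff(pos, axis=0)
            b = 0.9 * b / np.linalg.norm(b, axis=1)[:, None]
            pos = np.vstack([[0, 0, 0], np.cumsum(b, axis=0)])
        pos = pos + np.array([0.0, 8.0, 8.0])
        ref, _ = total_forces(ChainState(pos, np.zeros_like(pos)),
                              None, PARAMS)
        F = np.empty_like(pos)
        head = np.empty(20000, dtype=np.int64)
        stamp = np.full(20000, -1, dtype=np.int64)
        nxt = np.empty(len(pos), dtype=np.int64)
        code = _kernels._forces(
            np.ascontiguousarray(pos), F, PARAMS.epsilon, PARAMS.sigma_b,
            PARAMS.k_fene, PARAMS.r0_fene, PARAMS.kappa, 0.0, False, False,
            0.0, 0.0, head, nxt, stamp, 0, _kernels.CUTOFF_FACTOR)
        assert code == 0
        scale_f = max(np.max(np.abs(ref)), 1.0)
        assert np.max(np.abs(F - ref)) / scale_f < 1e-6
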