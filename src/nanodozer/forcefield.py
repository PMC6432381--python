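"""Coarse-grained bead-spring force field.

The chain Hamiltonian is the semiflexible Kremer--Grest model:

* excluded volume between *every* pair of beads (bonded pairs included) via
  the purely repulsive, cut-and-shifted Lennard-Jones (WCA) potential,
* finitely extensible nonlinear elastic (FENE) springs between consecutive
  beads,
* a discrete bending potential ``kappa * (1 - cos(theta))`` on consecutive
  bond pairs, which gives a persistence length ``Lp = kappa / kB T``.

All quantities are in reduced units: lengths in bead diameters ``sigma_b``,
energies in the LJ strength ``epsilon``, with ``kB = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ForceFieldParams",
    "BondOverstretchError",
    "wca_energy",
    "wca_force_mag",
    "fene_energy",
    "bend_energy",
    "total_forces",
    "build_neighbor_list",
    "NeighborList",
]


class BondOverstretchError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension R0."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field and thermostat constants of the bead-spring model.

    Defaults are the validated parameter set for a stable, non-crossing
    chain: ``gamma=0.7, k=30, R0=1.5, T=1.2`` with ``epsilon = sigma_b =
    m = 1`` and bending stiffness ``kappa = 3.2``.
    """

    epsilon: float = 1.0
    sigma_b: float = 1.0
    k_fene: float = 30.0
    r0_fene: float = 1.5
    kappa: float = 3.2
    mass: float = 1.0
    gamma: float = 0.7
    temperature: float = 1.2
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma_b <= 0:
            raise ValueError("epsilon and sigma_b must be positive")
        if self.r0_fene <= self.sigma_b:
            raise ValueError("r0_fene must exceed sigma_b")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.gamma <= 0 or self.temperature <= 0 or self.dt <= 0:
            raise ValueError("gamma, temperature and dt must be positive")
        if self.mass <= 0 or self.k_fene <= 0:
            raise ValueError("mass and k_fene must be positive")

    @property
    def wca_cutoff(self) -> float:
        """Cutoff ``2^(1/6) sigma_b`` beyond which the pair potential is 0."""
        return 2.0 ** (1.0 / 6.0) * self.sigma_b

    def with_(self, **kwargs) -> "ForceFieldParams":
        return replace(self, **kwargs)


def wca_energy(r, params: ForceFieldParams):
    """Purely repulsive cut-and-shifted LJ (WCA) pair energy at distance ``r``.

    ``4 eps [(sigma/r)^12 - (sigma/r)^6] + eps`` for ``r <= 2^(1/6) sigma``,
    exactly zero beyond; continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (params.sigma_b / r) ** 6
    e = 4.0 * params.epsilon * (sr6 * sr6 - sr6) + params.epsilon
    out = np.where(r <= params.wca_cutoff, e, 0.0)
    return out if out.ndim else float(out)


def wca_force_mag(r, params: ForceFieldParams):
    """Magnitude of the repulsive WCA central force, ``-dU/dr`` (>= 0)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (params.sigma_b / r) ** 6
    f = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    out = np.where(r <= params.wca_cutoff, f, 0.0)
    return out if out.ndim else float(out)


def fene_energy(r, params: ForceFieldParams):
    """FENE bond energy ``-k R0^2/2 * ln(1 - r^2/R0^2)``.

    Raises :class:`BondOverstretchError` at ``r >= R0``; a simulation must
    abort rather than silently continue past the divergence.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be nonnegative")
    if np.any(r >= params.r0_fene):
        raise BondOverstretchError(
            f"bond length >= R0={params.r0_fene}: max r={np.max(r):.6g}"
        )
    x = (r / params.r0_fene) ** 2
    out = -0.5 * params.k_fene * params.r0_fene**2 * np.log1p(-x)
    return out if out.ndim else float(out)


def bend_energy(theta, params: ForceFieldParams):
    """Bending energy ``kappa (1 - cos theta)`` for the angle between
    successive bond vectors (theta = 0 for a straight chain)."""
    c = np.clip(np.cos(np.asarray(theta, dtype=float)), -1.0, 1.0)
    out = params.kappa * (1.0 - c)
    return out if out.ndim else float(out)


def build_neighbor_list(positions: np.ndarray, cutoff: float, skin: float = 0.3):
    """All bead pairs (i < j) within ``cutoff + skin``.

    Energies and forces computed from the list equal the all-pairs result
    exactly, since pairs beyond the bare cutoff contribute zero.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] == 0:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff + skin, output_type="ndarray")
    return pairs.astype(np.intp)


class NeighborList:
    """Verlet list with a skin; rebuilt when any bead moved more than skin/2."""

    def __init__(self, cutoff: float, skin: float = 0.3):
        if skin < 0:
            raise ValueError("skin must be nonnegative")
        self.cutoff = float(cutoff)
        self.skin = float(skin)
        self._ref = None
        self.pairs = np.empty((0, 2), dtype=np.intp)

    def update(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        if (
            self._ref is None
            or self._ref.shape != positions.shape
            or (self.skin > 0
                and np.max(np.linalg.norm(positions - self._ref, axis=1))
                > 0.5 * self.skin)
            or self.skin == 0
        ):
            self.pairs = build_neighbor_list(positions, self.cutoff, self.skin)
            self._ref = positions.copy()
        return self.pairs


def _bend_forces(positions: np.ndarray, params: ForceFieldParams):
    """Analytic bending forces and energy over all consecutive bond triples."""
    n = positions.shape[0]
    forces = np.zeros_like(positions)
    if n < 3 or params.kappa == 0.0:
        return forces, 0.0
    b = np.diff(positions, axis=0)                      # (n-1, 3) bond vectors
    lb = np.linalg.norm(b, axis=1)
    e = b / lb[:, None]
    c = np.clip(np.sum(e[:-1] * e[1:], axis=1), -1.0, 1.0)
    energy = params.kappa * np.sum(1.0 - c)
    # dU/d(b1) = -kappa (e2 - c e1)/|b1|, dU/d(b2) = -kappa (e1 - c e2)/|b2|
    g1 = -params.kappa * (e[1:] - c[:, None] * e[:-1]) / lb[:-1, None]
    g2 = -params.kappa * (e[:-1] - c[:, None] * e[1:]) / lb[1:, None]
    # b1 = r_i - r_{i-1}, b2 = r_{i+1} - r_i for the triple (i-1, i, i+1)
    np.add.at(forces, np.arange(0, n - 2), g1)
    np.add.at(forces, np.arange(1, n - 1), -g1 + g2)
    np.add.at(forces, np.arange(2, n), -g2)
    return forces, float(energy)


def total_forces(state, geometry, params: ForceFieldParams):
    """Analytic forces and total potential energy of a chain conformation.

    Reference (pure numpy) implementation of the negative gradient of
    ``U_WCA + U_FENE + U_bend + U_wall + U_gasket``; the production BD loop
    uses a numba kernel validated against this function.

    Parameters
    ----------
    state : ChainState or (N, 3) array of positions
    geometry : ChannelGasket or None (free chain)
    params : ForceFieldParams

    Returns
    -------
    forces : (N, 3) array
    energy : float
    """
    positions = np.asarray(getattr(state, "positions", state), dtype=float)
    t = float(getattr(state, "time", 0.0))
    n = positions.shape[0]
    forces = np.zeros_like(positions)
    energy = 0.0

    # WCA between all pairs within cutoff (bonded pairs included)
    pairs = build_neighbor_list(positions, params.wca_cutoff, 0.0)
    if len(pairs):
        d = positions[pairs[:, 1]] - positions[pairs[:, 0]]
        r = np.linalg.norm(d, axis=1)
        energy += float(np.sum(wca_energy(r, params)))
        fmag = wca_force_mag(r, params)
        fvec = (fmag / r)[:, None] * d
        np.add.at(forces, pairs[:, 1], fvec)
        np.add.at(forces, pairs[:, 0], -fvec)

    # FENE bonds on consecutive pairs
    if n >= 2:
        b = np.diff(positions, axis=0)
        rb = np.linalg.norm(b, axis=1)
        energy += float(np.sum(fene_energy(rb, params)))  # raises on overstretch
        fmag = -params.k_fene / (1.0 - (rb / params.r0_fene) ** 2)
        fvec = fmag[:, None] * b                          # force on bead i+1
        forces[1:] += fvec
        forces[:-1] -= fvec

    fb, eb = _bend_forces(positions, params)
    forces += fb
    energy += eb

    if geometry is not None:
        from .geometry import wall_interaction

        for i in range(n):
            e_w, f_w = wall_interaction(positions[i], geometry, params, t=t)
            energy += e_w
            forces[i] += f_w

    return forces, energy
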