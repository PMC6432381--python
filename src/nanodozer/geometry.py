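"""Channel, wall and sliding-gasket geometry; chain initialization.

Coordinate convention: the channel axis is ``x`` (translationally invariant,
effectively infinite toward ``-x``); the square cross-section spans
``y, z in [0, D]``.  The gasket (piston) is a plane normal to ``x`` that
approaches the chain from ``+x`` moving toward ``-x`` and later retracts.

Walls can be represented two ways:

* ``analytic`` (default): each wall and the gasket is a smooth plane with a
  WCA interaction as a function of perpendicular distance.  This is the
  production mode - it is cheap and realizes exactly the purely repulsive
  confinement the physics depends on.
* ``beads``: immobile WCA particles on a square lattice on each wall plane,
  and a rigid square lattice of beads for the gasket (which makes the piston
  impermeable).  Retained for fidelity cross-checks.

Time bookkeeping: the BD timestep is ``dt = 0.01`` reduced time units, one
"snapshot" is 1000 steps (10 time units) and one MD time unit is 100 steps.
Gasket speeds quoted in bond lengths per snapshot are converted to
sigma per reduced-time via ``v * bl / 10`` with ``bl = 0.97 sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forcefield import ForceFieldParams, wca_energy, wca_force_mag

__all__ = [
    "BOND_LENGTH",
    "STEPS_PER_SNAPSHOT",
    "ChannelGasket",
    "ChainState",
    "bl_per_snapshot_to_sigma_per_time",
    "gasket_position",
    "init_chain",
    "wall_interaction",
]

#: Mean equilibrium bond length in sigma_b units (the "bl" length unit).
BOND_LENGTH = 0.97

#: Integration steps per snapshot; with dt=0.01 one snapshot = 10 time units.
STEPS_PER_SNAPSHOT = 1000


def bl_per_snapshot_to_sigma_per_time(v_bl_per_snapshot: float,
                                      dt: float = 0.01) -> float:
    """Convert a speed in bond lengths/snapshot to sigma per reduced time."""
    return v_bl_per_snapshot * BOND_LENGTH / (STEPS_PER_SNAPSHOT * dt)


@dataclass(frozen=True)
class ChannelGasket:
    """Channel of width ``D`` with a moving gasket plane.

    ``gasket_speed_schedule`` is a tuple of ``(duration, speed)`` segments in
    reduced units (sigma / time); the final segment's speed extends
    indefinitely.  Negative speed compresses (moves toward ``-x``).
    """

    width_D: float = 16.0
    wall_mode: str = "analytic"
    wall_lattice_spacing: float = 1.0
    gasket_x0: float = 0.0
    gasket_speed_schedule: tuple = ((np.inf, 0.0),)
    gasket_lattice_spacing: float = 1.0
    gasket_enabled: bool = True

    def __post_init__(self) -> None:
        if self.width_D <= 2.0:
            raise ValueError("channel width must exceed 2 sigma_b")
        if self.wall_mode not in ("analytic", "beads"):
            raise ValueError("wall_mode must be 'analytic' or 'beads'")
        if self.gasket_lattice_spacing > 1.0 + 1e-12:
            raise ValueError(
                "gasket lattice spacing must be <= sigma_b (impermeability)")
        for seg in self.gasket_speed_schedule:
            if len(seg) != 2 or seg[0] < 0:
                raise ValueError("schedule segments are (duration>=0, speed)")

    def with_(self, **kwargs) -> "ChannelGasket":
        return replace(self, **kwargs)


@dataclass
class ChainState:
    """Positions/velocities of the N beads and the current time."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have equal shape")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ChainState":
        return ChainState(self.positions.copy(), self.velocities.copy(),
                          self.time)


def gasket_position(t: float, channel: ChannelGasket) -> float:
    """Gasket plane x-position at time ``t``.

    Computed exactly from the schedule breakpoints (piecewise-linear in t),
    never by accumulating steps.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    x = channel.gasket_x0
    remaining = float(t)
    speed = 0.0
    for duration, speed in channel.gasket_speed_schedule:
        seg = min(remaining, duration)
        x += speed * seg
        remaining -= seg
        if remaining <= 0.0:
            return x
    return x + speed * remaining  # last segment extends indefinitely


def _wlc_positions(n_beads: int, kappa_red: float, bl: float, rng,
                   clash: float = 0.85, max_resample: int = 40):
    """Self-avoiding discrete worm-like chain grown bond by bond.

    Each bond direction is drawn from the equilibrium bending weight
    ``p(cos t) ~ exp(kappa_red * cos t)`` (uniform azimuth) around the
    previous bond; a draw that brings the new bead within ``clash`` of any
    earlier bead is resampled.  Returns None if growth dead-ends.
    """
    pos = np.empty((n_beads, 3))
    pos[0] = 0.0
    t = np.array([1.0, 0.0, 0.0])
    pos[1] = pos[0] + bl * t
    for i in range(2, n_beads):
        for _ in range(max_resample):
            u = rng.random()
            if kappa_red > 1e-12:
                cos_t = np.log(np.exp(-kappa_red) + u *
                               (np.exp(kappa_red) - np.exp(-kappa_red))) \
                    / kappa_red
            else:
                cos_t = 2.0 * u - 1.0
            phi = rng.random() * 2.0 * np.pi
            a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 \
                else np.array([0.0, 1.0, 0.0])
            n1 = np.cross(t, a)
            n1 /= np.linalg.norm(n1)
            n2 = np.cross(t, n1)
            s = np.sqrt(max(1.0 - cos_t * cos_t, 0.0))
            e_new = cos_t * t + s * (np.cos(phi) * n1 + np.sin(phi) * n2)
            cand = pos[i - 1] + bl * e_new
            d2 = np.sum((pos[:i - 1] - cand) ** 2, axis=1)
            if d2.min() > clash * clash:
                pos[i] = cand
                t = e_new
                break
        else:
            return None
    return pos


def init_chain(n_beads: int, channel: ChannelGasket | None,
               params: ForceFieldParams, seed: int,
               initial_extension: float | None = None,
               conformation: str = "straight") -> ChainState:
    """Seeded initial conformation, inside the channel if one is given.

    ``straight`` (default): chain along the channel axis at the
    cross-section center with bond length ``0.97 sigma_b`` and small
    transverse perturbations; when ``initial_extension`` (sigma units,
    < contour) is given, the chain is wound on a helix of that x-extent so
    long chains can start near their confined equilibrium density.
    ``wlc``: equilibrium worm-like-chain bond angles (free chains only;
    resampled until self-overlap-free).  Velocities are Maxwell-Boltzmann
    at T.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    bl = BOND_LENGTH * params.sigma_b

    if conformation == "wlc":
        kappa_red = params.kappa / params.temperature
        for _ in range(200):
            pos = _wlc_positions(n_beads, kappa_red, bl * params.sigma_b, rng)
            if pos is not None:
                break
        else:
            raise ValueError("could not draw an overlap-free conformation")
        if channel is not None:
            c = 0.5 * channel.width_D
            pos[:, 1] += c - pos[:, 1].mean()
            pos[:, 2] += c - pos[:, 2].mean()
            half = c - params.wca_cutoff
            if np.any(np.abs(pos[:, 1:] - c) > half):
                raise ValueError("wlc conformation does not fit the channel")
        vel = rng.standard_normal((n_beads, 3)) * np.sqrt(
            params.temperature / params.mass)
        return ChainState(pos, vel, 0.0)
    if conformation != "straight":
        raise ValueError("conformation must be 'straight' or 'wlc'")

    if channel is None:
        raise ValueError("straight initialization requires a channel")
    cy = cz = 0.5 * channel.width_D
    contour = (n_beads - 1) * bl

    if initial_extension is None or initial_extension >= contour:
        dx = bl
        radius, phi = 0.0, 0.0
    else:
        dx = initial_extension / (n_beads - 1)
        chord = np.sqrt(bl**2 - dx**2)
        radius = max(1.5, 0.5 * channel.width_D - 1.8)
        if radius > 0.5 * channel.width_D - 1.2:
            radius = 0.5 * channel.width_D - 1.2
        if radius <= 0 or 2.0 * radius < chord:
            raise ValueError(
                "chain cannot fit: channel too narrow for the helical "
                "initialization at this extension")
        phi = 2.0 * np.arcsin(chord / (2.0 * radius))
    i = np.arange(n_beads)
    pos = np.empty((n_beads, 3))
    pos[:, 0] = i * dx
    pos[:, 1] = cy + radius * np.cos(phi * i)
    pos[:, 2] = cz + radius * np.sin(phi * i)
    if radius == 0.0:
        pos[:, 1] += 0.01 * rng.standard_normal(n_beads)
        pos[:, 2] += 0.01 * rng.standard_normal(n_beads)

    half = 0.5 * channel.width_D
    margin = params.wca_cutoff
    if np.any(np.abs(pos[:, 1] - cy) > half - margin + 1e-9) or np.any(
            np.abs(pos[:, 2] - cz) > half - margin + 1e-9):
        raise ValueError("chain does not fit inside the channel cross-section")

    vel = rng.standard_normal((n_beads, 3)) * np.sqrt(
        params.temperature / params.mass)
    return ChainState(pos, vel, 0.0)


def _plane_wca(d: float, params: ForceFieldParams):
    """WCA energy and force magnitude for perpendicular plane distance d."""
    if d <= 0:
        raise ValueError("bead exactly on or beyond a wall plane")
    if d > params.wca_cutoff:
        return 0.0, 0.0
    return float(wca_energy(d, params)), float(wca_force_mag(d, params))


def _lattice_sites_near(u: float, v: float, spacing: float, cutoff: float):
    """Square-lattice nodes (in-plane coords) within cutoff of point (u, v)."""
    iu0, iu1 = int(np.floor((u - cutoff) / spacing)), int(
        np.ceil((u + cutoff) / spacing))
    iv0, iv1 = int(np.floor((v - cutoff) / spacing)), int(
        np.ceil((v + cutoff) / spacing))
    uu, vv = np.meshgrid(
        np.arange(iu0, iu1 + 1) * spacing,
        np.arange(iv0, iv1 + 1) * spacing, indexing="ij")
    return uu.ravel(), vv.ravel()


def wall_interaction(position, channel: ChannelGasket,
                     params: ForceFieldParams, t: float = 0.0,
                     include_gasket: bool = True):
    """Wall + gasket WCA energy and force on a bead at ``position``.

    ``analytic`` mode: perpendicular-distance WCA to each of the four wall
    planes and to the gasket plane.  ``beads`` mode: sum of bead-bead WCA
    over all wall/gasket lattice particles within the cutoff.
    """
    p = np.asarray(position, dtype=float)
    D = channel.width_D
    energy = 0.0
    force = np.zeros(3)
    cutoff = params.wca_cutoff

    if channel.wall_mode == "analytic":
        for axis in (1, 2):
            for plane, normal in ((0.0, 1.0), (D, -1.0)):
                d = (p[axis] - plane) * normal
                e, f = _plane_wca(d, params)
                energy += e
                force[axis] += normal * f
        if include_gasket and channel.gasket_enabled:
            xg = gasket_position(t, channel)
            d = xg - p[0]
            if d <= 0:
                raise ValueError("bead at or beyond the gasket plane")
            e, f = _plane_wca(d, params)
            energy += e
            force[0] -= f
    else:
        planes = [(1, 0.0), (1, D), (2, 0.0), (2, D)]
        for axis, plane in planes:
            d_perp = abs(p[axis] - plane)
            if d_perp > cutoff:
                continue
            other = 2 if axis == 1 else 1
            uu, vv = _lattice_sites_near(p[0], p[other],
                                         channel.wall_lattice_spacing, cutoff)
            site = np.zeros((len(uu), 3))
            site[:, 0] = uu
            site[:, other] = vv
            site[:, axis] = plane
            dvec = p[None, :] - site
            r = np.linalg.norm(dvec, axis=1)
            if np.any(r < 1e-10):
                raise ValueError("bead overlaps a wall bead center")
            keep = r < cutoff
            r, dvec = r[keep], dvec[keep]
            energy += float(np.sum(wca_energy(r, params)))
            force += np.sum(
                (wca_force_mag(r, params) / r)[:, None] * dvec, axis=0)
        if include_gasket and channel.gasket_enabled:
            xg = gasket_position(t, channel)
            if abs(p[0] - xg) <= cutoff:
                uu, vv = _lattice_sites_near(
                    p[1], p[2], channel.gasket_lattice_spacing, cutoff)
                site = np.column_stack([np.full(len(uu), xg), uu, vv])
                dvec = p[None, :] - site
                r = np.linalg.norm(dvec, axis=1)
                if np.any(r < 1e-10):
                    raise ValueError("bead overlaps a gasket bead center")
                keep = r < cutoff
                r, dvec = r[keep], dvec[keep]
                energy += float(np.sum(wca_energy(r, params)))
                force += np.sum(
                    (wca_force_mag(r, params) / r)[:, None] * dvec, axis=0)
    return energy, force
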