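"""Underdamped Langevin propagation of the bead-spring chain.

The equation of motion per bead is ``m r'' = F - gamma v + R`` with Gaussian
noise R obeying the fluctuation--dissipation relation: per component,
``<R(t) R(t')> = 2 gamma kB T delta(t - t')``.

Two schemes are provided:

``gunsteren_berendsen``
    A stochastic-Verlet variant of the van Gunsteren--Berendsen family:
    the friction/noise (Ornstein--Uhlenbeck) part is integrated exactly
    over each half step around a velocity-Verlet core (the symmetric
    O-B-A-B-O splitting).  Free-particle velocity statistics are exact at
    any dt; configurational errors are O(dt^2).

``baoab``
    Symmetric B-A-O-A-B splitting with an exact OU mid-step; offered as
    an independent cross-check with the same statistical contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forcefield import BondOverstretchError, ForceFieldParams
from .geometry import ChainState, ChannelGasket, gasket_position

__all__ = ["LangevinConfig", "step", "advance", "SCHEMES"]

SCHEMES = {"gunsteren_berendsen": _kernels.SCHEME_GVB,
           "baoab": _kernels.SCHEME_BAOAB}


class PropagationError(RuntimeError):
    """Numerical failure during propagation (non-finite force/position)."""


@dataclass(frozen=True)
class LangevinConfig:
    """Thermostat configuration for the stochastic integrator."""

    dt: float = 0.01
    gamma: float = 0.7
    temperature: float = 1.2
    mass: float = 1.0
    seed: int = 0
    scheme: str = "gunsteren_berendsen"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.dt <= 0 or self.gamma <= 0 or self.mass <= 0:
            raise ValueError("dt, gamma, mass must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")
        if self.gamma * self.dt / self.mass > 0.1:
            warnings.warn("gamma*dt/m > 0.1: the step may be too coarse",
                          stacklevel=2)


def _ou_coefficients(cfg: LangevinConfig):
    beta = cfg.gamma / cfg.mass
    kTm = cfg.temperature / cfg.mass
    c_full = np.exp(-beta * cfg.dt)
    sd_full = np.sqrt(kTm * (1.0 - c_full * c_full))
    c_half = np.exp(-0.5 * beta * cfg.dt)
    sd_half = np.sqrt(kTm * (1.0 - c_half * c_half))
    return c_full, sd_full, c_half, sd_half


def _eval_forces(forces_fn, state) -> np.ndarray:
    forces = np.asarray(forces_fn(state), dtype=float)
    if not np.all(np.isfinite(forces)):
        raise PropagationError("non-finite force encountered")
    return forces


def step(state: ChainState, forces_fn, config: LangevinConfig,
         step_index: int = 0) -> ChainState:
    """Advance one Langevin step with an arbitrary force callback.

    Deterministic given ``(state, config.seed, step_index)``.  This is the
    generic (pure numpy) propagator; long runs use :func:`advance`, which
    dispatches to the compiled kernels.
    """
    forces = _eval_forces(forces_fn, state)
    rng = np.random.default_rng((config.seed, step_index))
    pos, vel = state.positions, state.velocities
    c_full, sd_full, c_half, sd_half = _ou_coefficients(config)
    half = 0.5 * config.dt
    if config.scheme == "gunsteren_berendsen":
        # O(dt/2) B(dt/2) A(dt) B(dt/2) O(dt/2)
        v = c_half * vel + sd_half * rng.standard_normal(pos.shape)
        v = v + forces * half / config.mass
        new_pos = pos + v * config.dt
        f2 = _eval_forces(forces_fn, ChainState(new_pos, v, state.time))
        v = v + f2 * half / config.mass
        new_vel = c_half * v + sd_half * rng.standard_normal(pos.shape)
    else:  # baoab: B(dt/2) A(dt/2) O(dt) A(dt/2) B(dt/2)
        v = vel + forces * half / config.mass
        x = pos + v * half
        v = c_full * v + sd_full * rng.standard_normal(pos.shape)
        new_pos = x + v * half
        f2 = _eval_forces(forces_fn, ChainState(new_pos, v, state.time))
        new_vel = v + f2 * half / config.mass
    return ChainState(new_pos, new_vel, state.time + config.dt)


def _cell_capacity(positions: np.ndarray, channel, n_steps: int, dt: float,
                   margin: float = 30.0) -> int:
    cell = _kernels.CUTOFF_FACTOR
    span_x = float(np.ptp(positions[:, 0])) + margin + 0.2 * n_steps * dt
    if channel is not None:
        span_t = channel.width_D + 4.0
    else:
        span_t = float(max(np.ptp(positions[:, 1]),
                           np.ptp(positions[:, 2]))) + margin
    nx = int(span_x / cell) + 4
    nt = int(span_t / cell) + 4
    return nx * nt * nt


def advance(state: ChainState, params: ForceFieldParams,
            channel: ChannelGasket | None, n_steps: int, seed: int,
            scheme: str = "gunsteren_berendsen", gasket_on: bool = False,
            fext: float = 0.0) -> ChainState:
    """Advance ``n_steps`` using the compiled kernel (in a copied state).

    The gasket plane moves at the (piecewise-constant) scheduled speed; the
    caller must not let a schedule breakpoint fall inside the segment.
    Walls are applied whenever ``channel`` is given.
    """
    pos = state.positions.copy()
    vel = state.velocities.copy()
    n = pos.shape[0]
    if channel is not None:
        D = channel.width_D
        walls_on = True
        gx0 = gasket_position(state.time, channel)
        eps_t = 1e-9
        gv = ((gasket_position(state.time + n_steps * params.dt, channel)
               - gx0) / (n_steps * params.dt)) if n_steps else 0.0
        del eps_t
        gasket = gasket_on and channel.gasket_enabled
    else:
        D, walls_on, gx0, gv, gasket = 0.0, False, 0.0, 0.0, False

    nxt = np.empty(n, dtype=np.int64)
    rng = np.random.default_rng(int(seed) % (2**31))
    steps_left = n_steps
    noise = rng.standard_normal((n_steps, n, 3, 2))
    while steps_left > 0:
        ncap = _cell_capacity(pos, channel, steps_left, params.dt)
        head = np.empty(ncap, dtype=np.int64)
        stamp = np.full(ncap, -1, dtype=np.int64)
        code, done = _kernels.run_chain(
            pos, vel, steps_left, params.epsilon, params.sigma_b,
            params.k_fene, params.r0_fene, params.kappa, params.mass,
            params.gamma, params.temperature, params.dt, D, walls_on,
            gasket, gx0, gv, fext, SCHEMES[scheme], noise, head, nxt, stamp)
        if code == 1:
            raise BondOverstretchError(
                f"bond overstretch after {n_steps - steps_left + done} steps")
        if code == 2:
            raise PropagationError("bead reached a wall or gasket plane")
        if code == 4:
            raise PropagationError("non-finite coordinate encountered")
        gx0 += gv * done * params.dt
        steps_left -= done
        noise = noise[done:]
        if code == 0:
            break
        # code == 3: capacity exceeded; loop reallocates a larger grid
    return ChainState(pos, vel, state.time + n_steps * params.dt)
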