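"""Nonlinear moving-boundary diffusion model of the squeezed chain.

The axial concentration profile c(x, t) obeys a nonlinear diffusion
equation with a concentration-dependent cooperative diffusivity,

    dc/dt = d/dx [ Dc(c) dc/dx - c V ],      Dc(c) = Do (c / c0),

supplemented by two edge equations that halt the relaxation when the edge
concentration reaches the equilibrium plateau c0: a force balance in which
the osmotic pressure

    Pi(c) = Pi0 [ -(c0/c) + (c/c0)^2 ]          (zero at c = c0)

drives each edge outward against an edge friction xi, and a flux balance
that ties edge motion to the boundary flux (mass conservation through the
moving edges).  In reduced variables (u = c/c0, X = x/r0, s = t/tau with
tau = r0^2/Do, Vo = r0/tau) the only free constants are V/Vo and the
dimensionless edge friction alpha = xi Do / (Pi0 D^2 r0); the steady
compression profile is a linear ramp of reduced slope exactly V/Vo.

Conventions: compression is solved in the co-moving frame of the gasket
(right edge pinned to the gasket, zero flux through it; material streams
toward the gasket at V), so the steady state is a fixed point.  During
retraction the gasket outruns the chain and is dropped: V = 0 and both
edges are free.

Numerics: the moving domain [x1, x2] is mapped to the unit interval; a
conservative finite-volume discretization (central fluxes, explicit Euler,
diffusive-CFL-limited adaptive step) advances the cell masses, with the
boundary faces carrying exactly zero relative flux so total mass is
conserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "NPDEParams",
    "NPDEState",
    "osmotic_pressure",
    "free_energy",
    "cooperative_diffusivity",
    "step_npde",
    "solve_compression",
    "solve_retraction",
    "steady_state_ramp",
    "to_profile",
]

MODE_COMPRESSION = 0
MODE_RETRACTION = 1
_MODES = {"compression": MODE_COMPRESSION, "retraction": MODE_RETRACTION}


class NPDESolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class NPDEParams:
    """Constants of the moving-boundary diffusion model.

    Units follow the BD analysis layer: lengths in bond lengths (bl),
    time in snapshots, so Do is bl^2/snapshot and V is bl/snapshot.
    ``A`` and ``rb_param`` parameterize the diagnostic free energy only;
    the dynamics uses the osmotic pressure directly.
    """

    Do: float = 0.74
    c0: float = 1.0
    r0: float = 235.0
    V: float = 0.05
    alpha: float = 0.07
    Pi0: float = 1.0
    D_channel: float = 16.0
    A: float = 1.0
    rb_param: float = 0.0

    def __post_init__(self) -> None:
        if self.Do <= 0 or self.c0 <= 0 or self.r0 <= 0:
            raise ValueError("Do, c0, r0 must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def tau(self) -> float:
        """Diffusive time scale tau = r0^2 / Do (snapshots)."""
        return self.r0**2 / self.Do

    @property
    def Vo(self) -> float:
        """Velocity scale Vo = r0 / tau = Do / r0."""
        return self.Do / self.r0

    @property
    def vbar(self) -> float:
        """Reduced compression speed V / Vo."""
        return self.V / self.Vo

    def with_(self, **kwargs) -> "NPDEParams":
        return replace(self, **kwargs)


@dataclass
class NPDEState:
    """Reduced concentration field on the moving domain [x1, x2] (x in r0)."""

    x1: float
    x2: float
    u: np.ndarray            # c/c0 at the M mapped cell centers
    s: float = 0.0           # reduced time t/tau

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if not self.x1 < self.x2:
            raise ValueError("need x1 < x2")
        if np.any(self.u < 0):
            raise ValueError("concentration must be nonnegative")

    @property
    def extent(self) -> float:
        return self.x2 - self.x1

    @property
    def grid(self) -> np.ndarray:
        """Physical (reduced-x) cell-center positions."""
        m = len(self.u)
        y = (np.arange(m) + 0.5) / m
        return self.x1 + y * self.extent

    @property
    def mass(self) -> float:
        return float(np.sum(self.u) * self.extent / len(self.u))

    def copy(self) -> "NPDEState":
        return NPDEState(self.x1, self.x2, self.u.copy(), self.s)


def osmotic_pressure(c, params: NPDEParams):
    """Osmotic pressure Pi0 [-(c0/c) + (c/c0)^2]; zero at c = c0."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    out = params.Pi0 * (-(params.c0 / c) + (c / params.c0) ** 2)
    return out if out.ndim else float(out)


def free_energy(r, params: NPDEParams):
    """Extended-de Gennes confinement free energy per chain (units kBT).

    ``f = A [ (rb - r)/r0 + (r0/r)^2 ]``; diagnostic only - the solver
    uses the osmotic pressure directly.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("extension must be positive")
    out = params.A * ((params.rb_param - r) / params.r0 + (params.r0 / r) ** 2)
    return out if out.ndim else float(out)


def cooperative_diffusivity(c, params: NPDEParams):
    """Dc = Do (c / c0): linear in concentration, zero at c = 0."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    out = params.Do * c / params.c0
    return out if out.ndim else float(out)


@njit(cache=True)
def _npde_run(u, L, X1, alpha, vbar, mode, s_end, cfl, fixed_ds,
              save_s, out_u, out_L, out_X1, out_s):
    """Advance the reduced moving-boundary system to s_end.

    Returns (code, n_saved, s, L, X1); codes: 0 ok, 2 nonpositive edge
    extrapolation, 3 negative interior concentration, 5 step-count guard.
    """
    m = u.shape[0]
    dy = 1.0 / m
    jhat = np.empty(m + 1)
    s = 0.0
    isave = 0
    nsave = save_s.shape[0]
    max_steps = 200_000_000
    for _ in range(max_steps):
        if s >= s_end - 1e-14:
            return 0, isave, s, L, X1
        # edge values by linear extrapolation of the two nearest cells
        u1e = 1.5 * u[0] - 0.5 * u[1]
        u2e = 1.5 * u[m - 1] - 0.5 * u[m - 2]
        if u1e <= 0.0 or u2e <= 0.0:
            return 2, isave, s, L, X1
        p1 = -1.0 / u1e + u1e * u1e
        p2 = -1.0 / u2e + u2e * u2e
        if mode == 0:  # compression, gasket frame
            w1 = vbar - p1 / alpha
            w2 = 0.0
        else:          # retraction, both edges free, no advection
            w1 = -p1 / alpha
            w2 = p2 / alpha

        # time step: diffusive CFL plus advective/edge limits
        umax = u[0]
        for j in range(m):
            if u[j] > umax:
                umax = u[j]
        h = L * dy
        ds = cfl * h * h / (2.0 * umax + 1e-30)
        amax = abs(vbar) + abs(w1) + abs(w2)
        if amax > 0.0:
            ds_a = cfl * h / amax
            if ds_a < ds:
                ds = ds_a
        if fixed_ds > 0.0:
            ds = fixed_ds
        if s + ds > s_end:
            ds = s_end - s
        if isave < nsave and s + ds > save_s[isave] - 1e-14:
            ds = save_s[isave] - s
            if ds <= 0.0:
                ds = 1e-14

        # relative fluxes at faces (zero at both boundaries by construction)
        jhat[0] = 0.0
        jhat[m] = 0.0
        for j in range(1, m):
            uf = 0.5 * (u[j - 1] + u[j])
            grad = (u[j] - u[j - 1]) / (L * dy)
            yf = j * dy
            xdot = (1.0 - yf) * w1 + yf * w2
            jhat[j] = -uf * grad + uf * (vbar - xdot)
        # flux limiting at the edge cells: outflow cannot exceed content
        if jhat[1] > 0.0:
            lim = u[0] * L * dy / ds * 0.9
            if jhat[1] > lim:
                jhat[1] = lim
        if jhat[m - 1] < 0.0:
            lim = -u[m - 1] * L * dy / ds * 0.9
            if jhat[m - 1] < lim:
                jhat[m - 1] = lim

        Lnew = L + ds * (w2 - w1)
        if Lnew <= 0.0:
            return 3, isave, s, L, X1
        for j in range(m):
            lu = L * u[j] + ds * (jhat[j] - jhat[j + 1]) / dy
            u[j] = lu / Lnew
            if u[j] < 0.0:
                if u[j] > -1e-12:
                    u[j] = 0.0
                else:
                    return 3, isave, s, L, X1
        L = Lnew
        X1 += ds * w1
        s += ds

        if isave < nsave and s >= save_s[isave] - 1e-13:
            for j in range(m):
                out_u[isave, j] = u[j]
            out_L[isave] = L
            out_X1[isave] = X1
            out_s[isave] = s
            isave += 1
    return 5, isave, s, L, X1


def _run(state: NPDEState, params: NPDEParams, mode: int, s_end: float,
         save_s: np.ndarray, cfl: float = 0.4,
         fixed_ds: float = 0.0) -> list[NPDEState]:
    u = state.u.copy()
    m = len(u)
    save_s = np.asarray(save_s, dtype=float)
    out_u = np.empty((len(save_s), m))
    out_L = np.empty(len(save_s))
    out_X1 = np.empty(len(save_s))
    out_s = np.empty(len(save_s))
    vbar = params.vbar if mode == MODE_COMPRESSION else 0.0
    code, nsaved, s, L, X1 = _npde_run(
        u, state.extent, state.x1, params.alpha, vbar, mode, s_end, cfl,
        fixed_ds, save_s, out_u, out_L, out_X1, out_s)
    if code == 2:
        raise NPDESolverError("edge concentration extrapolated nonpositive")
    if code == 3:
        raise NPDESolverError("negative concentration (positivity violated)")
    if code == 5:
        raise NPDESolverError("step-count guard exceeded")
    states = [NPDEState(out_X1[i], out_X1[i] + out_L[i], out_u[i],
                        state.s + out_s[i]) for i in range(nsaved)]
    if not states or abs(states[-1].s - (state.s + s_end)) > 1e-9:
        states.append(NPDEState(X1, X1 + L, u, state.s + s))
    return states


def step_npde(state: NPDEState, params: NPDEParams, mode: str,
              ds: float) -> NPDEState:
    """Advance one explicit step of size ``ds`` (reduced time)."""
    if ds <= 0:
        raise ValueError("ds must be positive")
    h = state.extent / len(state.u)
    if ds > h * h / (2.0 * max(float(state.u.max()), 1e-30)):
        raise NPDESolverError("ds violates the diffusive CFL limit")
    return _run(state, params, _MODES[mode], ds, np.empty(0),
                fixed_ds=ds)[-1]


def solve_compression(params: NPDEParams, duration: float,
                      n_save: int = 20, m_cells: int = 200,
                      cfl: float = 0.4) -> list[NPDEState]:
    """Compress from the uniform equilibrium profile u = 1 on [-1, 0].

    Solved in the gasket frame (gasket pinned at x2 = 0); approaches the
    steady linear ramp of reduced slope V/Vo.  ``duration`` in units of tau.
    """
    if params.V <= 0:
        raise ValueError("compression requires V > 0")
    init = NPDEState(-1.0, 0.0, np.ones(m_cells), 0.0)
    save = np.linspace(duration / n_save, duration, n_save)
    return [init] + _run(init, params, MODE_COMPRESSION, duration, save,
                         cfl=cfl)


def solve_retraction(params: NPDEParams, initial: NPDEState | None,
                     duration: float, n_save: int = 20,
                     cfl: float = 0.4) -> list[NPDEState]:
    """Relax a compressed profile with both edges free and V = 0.

    Defaults to the analytic steady-state ramp as the initial condition.
    The profile decays through an approximately parabolic shape toward the
    flat plateau u = 1 with extent -> mass (r0 for unit reduced mass).
    """
    if initial is None:
        initial = steady_state_ramp(params)
    save = np.linspace(duration / n_save, duration, n_save)
    return [initial.copy()] + _run(initial, params, MODE_RETRACTION,
                                   duration, save, cfl=cfl)


def steady_state_ramp(params: NPDEParams, total_mass: float = 1.0,
                      m_cells: int = 200) -> NPDEState:
    """Analytic steady compression profile: a linear ramp of slope V/Vo.

    The far-edge value u1 solves the stationary edge force balance
    ``u1^3 - alpha (V/Vo) u1 - 1 = 0`` and the width follows from mass
    conservation.  Domain is [-w, 0] with the gasket at 0.
    """
    vbar = params.vbar
    if vbar <= 0:
        raise ValueError("steady ramp requires V > 0")
    roots = np.roots([1.0, 0.0, -params.alpha * vbar, -1.0])
    real = roots[np.abs(roots.imag) < 1e-10].real
    u1 = float(real[real > 0].min())
    if u1 <= 0:
        raise ValueError("no positive edge concentration")
    w = (-u1 + np.sqrt(u1 * u1 + 2.0 * vbar * total_mass)) / vbar
    y = (np.arange(m_cells) + 0.5) / m_cells
    u = u1 + vbar * w * y
    if np.any(u < 0):
        raise ValueError("parameters imply negative concentrations")
    return NPDEState(-w, 0.0, u, 0.0)


def to_profile(state: NPDEState, params: NPDEParams, bin_width_bl: float = 2.0):
    """Resample an NPDE state onto a uniform bond-length grid.

    Returns a :class:`nanodozer.observables.ConcentrationProfile` in the
    same units/schema as BD profiles so the fitting layer consumes both
    uniformly.
    """
    from .observables import ConcentrationProfile

    x_bl = state.grid * params.r0
    lo = np.floor(x_bl[0] / bin_width_bl) * bin_width_bl - bin_width_bl
    hi = np.ceil(x_bl[-1] / bin_width_bl) * bin_width_bl + bin_width_bl
    n = int(round((hi - lo) / bin_width_bl))
    edges = lo + bin_width_bl * np.arange(n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    vals = np.interp(centers, x_bl, state.u * params.c0, left=0.0, right=0.0)
    return ConcentrationProfile(edges, vals, time=state.s * params.tau,
                                c0=params.c0, r0=params.r0)
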