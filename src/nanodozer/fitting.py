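"""Model-to-data layer: thermal-broadening convolution and least-squares fits.

Thermal fluctuations of the chain extension broaden the sharp edges of the
NPDE profiles; this is modeled by convolving the NPDE output with a
unit-integral Gaussian whose width sigma may differ between the edge near
the gasket and the far edge (sigma varies linearly in x between the two
edge values).  The fits implemented here mirror the analysis pipeline:

* ``extract_Do``       - cooperative diffusivity from the steady ramp slope,
* ``fit_sigma_initial``- sigma from a broadened box/ramp fit to the t=0 profile,
* ``fit_alpha``        - 1-D bounded least-squares fit of the edge friction,
* ``fit_parabola``     - broadened-parabola fit of retraction profiles
                         (fluctuation-robust concentration maximum),
* ``fit_speed_exponent`` - power law of steady extension vs sliding speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .npde import NPDEParams, NPDEState

__all__ = [
    "ConvolutionSpec",
    "FitResult",
    "gaussian_convolve",
    "extract_Do",
    "fit_sigma_initial",
    "fit_alpha",
    "fit_parabola",
    "fit_speed_exponent",
    "FitError",
]


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConvolutionSpec:
    """Edge-broadening widths, in units of r0.

    ``sigma_left`` applies at the edge opposite the gasket, ``sigma_right``
    at the gasket-adjacent edge; retraction analyses use a single sigma for
    both edges.
    """

    sigma_left: float
    sigma_right: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_left < 0:
            raise ValueError("sigma must be nonnegative")
        if self.sigma_right is None:
            object.__setattr__(self, "sigma_right", self.sigma_left)
        elif self.sigma_right < 0:
            raise ValueError("sigma must be nonnegative")


@dataclass
class FitResult:
    """Parameter estimates plus the optimizer's objective and diagnostics."""

    params: dict
    objective: float
    n_eval: int = 0
    message: str = ""


def gaussian_convolve(x: np.ndarray, c: np.ndarray,
                      spec: ConvolutionSpec) -> np.ndarray:
    """Convolve a profile on a uniform grid with an edge-dependent Gaussian.

    Each source cell spreads its mass with a unit-sum discrete Gaussian of
    width sigma(x) interpolated linearly between the two edge values across
    the profile's support, so total mass is preserved exactly and each edge
    is broadened by its own sigma.  The grid spacing and sigmas must be in
    the same units.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if len(x) != len(c):
        raise ValueError("x and c must have equal length")
    dx = np.diff(x)
    if np.any(dx <= 0) or np.ptp(dx) > 1e-9 * dx[0]:
        raise ValueError("grid must be uniform and increasing")
    h = float(dx[0])
    support = np.where(c > 0)[0]
    if len(support) == 0:
        return c.copy()
    xl, xr = x[support[0]], x[support[-1]]
    frac = np.clip((x - xl) / max(xr - xl, h), 0.0, 1.0)
    sigma = spec.sigma_left + (spec.sigma_right - spec.sigma_left) * frac
    out = np.zeros_like(c)
    for j in support:
        s = sigma[j]
        if s < 0.25 * h:
            out[j] += c[j]
            continue
        kern = np.exp(-0.5 * ((x - x[j]) / s) ** 2)
        out += c[j] * kern / kern.sum()
    return out


def extract_Do(x_reduced: np.ndarray, u: np.ndarray, V: float, r0: float,
               lower: float = 1.2, upper_frac: float = 0.8) -> float:
    """Cooperative diffusivity from the steady-state ramp slope.

    Fits a line to the central ramp (reduced concentration between
    ``lower`` and ``upper_frac * max``), excluding the edge-broadened
    zones; the reduced slope m gives ``Do = V * r0 / m``.
    """
    x = np.asarray(x_reduced, dtype=float)
    u = np.asarray(u, dtype=float)
    # the ramp is the rising flank toward the gasket; points past the peak
    # belong to the broadened gasket edge and must not enter the fit
    peak = int(np.argmax(u))
    sel = (u > lower) & (u < upper_frac * u.max())
    sel[peak:] = False
    if sel.sum() < 3:
        sel = u > 0.5 * u.max()
        sel[peak:] = False
    if sel.sum() < 2:
        raise FitError("no resolvable ramp region")
    m = np.polyfit(x[sel], u[sel], 1)[0]
    if not m > 1e-12:
        raise FitError("ramp slope indistinguishable from zero")
    return float(V * r0 / m)


def _box_model(x, xl, xr, height, sl, sr):
    base = np.where((x >= xl) & (x <= xr), height, 0.0)
    return gaussian_convolve(x, base, ConvolutionSpec(sl, sr))


def _ramp_model(x, xl, xr, u1, slope, s):
    base = np.where((x >= xl) & (x <= xr), u1 + slope * (x - xl), 0.0)
    base = np.maximum(base, 0.0)
    return gaussian_convolve(x, base, ConvolutionSpec(s, s))


def fit_sigma_initial(x_reduced: np.ndarray, u: np.ndarray,
                      model: str = "uniform_plateau") -> "tuple[ConvolutionSpec, FitResult]":
    """Edge-broadening sigma from a least-squares fit to the t=0 profile.

    ``uniform_plateau``: broadened box with distinct per-edge sigmas
    (compression initial condition; left = far edge, right = gasket edge).
    ``ramp``: broadened linear ramp with a single sigma (retraction
    initial condition).  Returns sigma in units of r0 (the grid's units).
    """
    x = np.asarray(x_reduced, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.max() <= 0 or (u > 0.5 * u.max()).sum() < 4:
        raise FitError("degenerate profile")
    above = x[u > 0.5 * u.max()]
    xl0, xr0 = float(above.min()), float(above.max())
    h = float(x[1] - x[0])

    if model == "uniform_plateau":
        height0 = float(np.median(u[u > 0.5 * u.max()]))

        def resid(p):
            xl, xr, height, sl, sr = p
            return _box_model(x, xl, xr, height, abs(sl), abs(sr)) - u

        p0 = [xl0, xr0, height0, 2 * h, 2 * h]
        res = optimize.least_squares(resid, p0, method="lm", max_nfev=4000)
        spec = ConvolutionSpec(abs(res.x[3]), abs(res.x[4]))
        params = {"x_left": res.x[0], "x_right": res.x[1],
                  "height": res.x[2], "sigma_left": spec.sigma_left,
                  "sigma_right": spec.sigma_right}
    elif model == "ramp":
        slope0 = max((u.max() - u[u > 0].min()) / max(xr0 - xl0, h), 0.1)

        def resid(p):
            xl, xr, u1, slope, s = p
            return _ramp_model(x, xl, xr, u1, slope, abs(s)) - u

        p0 = [xl0, xr0, max(float(u[u > 0].min()), 0.5), slope0, 2 * h]
        res = optimize.least_squares(resid, p0, method="lm", max_nfev=4000)
        spec = ConvolutionSpec(abs(res.x[4]))
        params = {"x_left": res.x[0], "x_right": res.x[1], "u_edge": res.x[2],
                  "slope": res.x[3], "sigma": spec.sigma_left}
    else:
        raise ValueError("model must be 'uniform_plateau' or 'ramp'")
    if not res.success:
        raise FitError(f"sigma fit failed: {res.message}")
    return spec, FitResult(params, float(np.sum(res.fun**2)),
                           res.nfev, res.message)


def _resolve_states(p: NPDEParams, mode: str, times: np.ndarray,
                    m_cells: int) -> list[NPDEState]:
    from .npde import _run, MODE_COMPRESSION, MODE_RETRACTION, steady_state_ramp
    times = np.asarray(times, dtype=float)
    s_end = float(times.max())
    if mode == "compression":
        init = NPDEState(-1.0, 0.0, np.ones(m_cells), 0.0)
        states = _run(init, p, MODE_COMPRESSION, s_end, times)
    else:
        init = steady_state_ramp(p, m_cells=m_cells)
        states = _run(init, p, MODE_RETRACTION, s_end, times)
    picked = []
    for t in times:
        if t <= 0:
            picked.append(init)
            continue
        picked.append(min(states, key=lambda st: abs(st.s - t)))
    return picked


def fit_alpha(bd_profiles, params: NPDEParams, mode: str,
              spec: ConvolutionSpec, m_cells: int = 200,
              bounds=(1e-3, 10.0)) -> FitResult:
    """Least-squares fit of the dimensionless edge friction alpha.

    ``bd_profiles`` is a sequence of ``(t_reduced, x_reduced, u)`` tuples
    (profiles already in reduced variables, in the model frame: gasket
    edge at x = 0 for compression, COM-aligned for retraction).  The NPDE
    model is solved at candidate alpha, sampled at the supplied times,
    Gaussian-convolved with ``spec`` and compared on each profile's grid;
    a deterministic bounded Brent search minimizes the summed squared
    difference.
    """
    bd = [(float(t), np.asarray(x, float), np.asarray(u, float))
          for t, x, u in bd_profiles]
    if not bd:
        raise FitError("no profiles supplied")
    times = np.array([t for t, _, _ in bd])
    if mode == "retraction":
        spec = ConvolutionSpec(spec.sigma_left)  # same sigma at both edges
    n_eval = 0

    def objective(log_alpha: float) -> float:
        nonlocal n_eval
        n_eval += 1
        alpha = float(np.exp(log_alpha))
        states = _resolve_states(params.with_(alpha=alpha), mode, times,
                                 m_cells)
        sse = 0.0
        for (t, x, u), st in zip(bd, states):
            grid = st.grid
            model = np.interp(x, grid, st.u, left=0.0, right=0.0)
            if spec.sigma_left > 0 or spec.sigma_right > 0:
                model = gaussian_convolve(x, model, spec)
            if mode == "retraction":
                # compare shapes about their centroids (COM-aligned data)
                mcom = np.sum(model * x) / max(np.sum(model), 1e-30)
                dcom = np.sum(u * x) / max(np.sum(u), 1e-30)
                model = np.interp(x, x - mcom + dcom, model,
                                  left=0.0, right=0.0)
            sse += float(np.sum((model - u) ** 2))
        return sse

    res = optimize.minimize_scalar(
        objective, bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded", options={"xatol": 1e-4})
    if not res.success:
        raise FitError(f"alpha fit did not converge: {res.message}")
    return FitResult({"alpha": float(np.exp(res.x))}, float(res.fun),
                     n_eval, "converged")


def fit_parabola(x: np.ndarray, c: np.ndarray,
                 fit_sigma: bool = True) -> FitResult:
    """Fit ``max(0, cm [1 - ((x-xc)/w)^2])`` convolved with a Gaussian.

    Returns the parabola amplitude ``cm`` (a fluctuation-robust estimate
    of the profile maximum), center ``xc``, half-width ``w`` and the
    broadening ``sigma``.  Raises on profiles without a resolvable peak.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    pos = c[c > 0]
    if len(pos) < 5 or c.max() - np.median(pos) < 0.05 * c.max():
        raise FitError("no resolvable peak (flat or degenerate profile)")
    h = float(x[1] - x[0])
    xc0 = float(np.sum(x * c) / np.sum(c))
    w0 = max(2.0 * np.sqrt(max(np.sum(c * (x - xc0) ** 2) / np.sum(c), h**2)),
             3 * h)

    def model(p):
        cm, xc, w, s = p
        base = np.maximum(cm * (1.0 - ((x - xc) / w) ** 2), 0.0)
        if fit_sigma and abs(s) > 0.25 * h:
            base = gaussian_convolve(x, base, ConvolutionSpec(abs(s)))
        return base

    best = None
    for w_start in (w0, 0.6 * w0, 1.6 * w0):
        p0 = [float(c.max()), xc0, w_start, h]
        res = optimize.least_squares(lambda p: model(p) - c, p0,
                                     method="lm", max_nfev=4000)
        if best is None or res.cost < best.cost:
            best = res
    cm, xc, w, s = best.x
    if cm <= 0 or abs(w) < h:
        raise FitError("parabola fit collapsed")
    return FitResult({"cmax": float(cm), "center": float(xc),
                      "width": float(abs(w)), "sigma": float(abs(s))},
                     float(np.sum(best.fun**2)), best.nfev, best.message)


def fit_speed_exponent(extensions: dict, n_high: int | None = None) -> float:
    """Power-law exponent of steady-state extension vs sliding speed.

    ``extensions`` maps speed -> extension (>= 3 speeds spanning >= 4x).
    ``n_high`` restricts the fit to the largest n speeds (the asymptotic
    regime).  Returns d ln(extension) / d ln(speed).
    """
    speeds = np.array(sorted(extensions))
    if len(speeds) < 3 and n_high is None:
        raise ValueError("need at least 3 speeds")
    if speeds.max() / speeds.min() < 4 and n_high is None:
        raise ValueError("speeds must span at least a factor of 4")
    ext = np.array([extensions[s] for s in speeds])
    if np.any(ext <= 0) or np.any(speeds <= 0):
        raise ValueError("speeds and extensions must be positive")
    if n_high is not None:
        speeds, ext = speeds[-n_high:], ext[-n_high:]
    return float(np.polyfit(np.log(speeds), np.log(ext), 1)[0])
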