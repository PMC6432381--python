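"""Three-stage experiment driver: equilibrate, compress, retract.

The squeezing protocol mirrors the nanodozer experiment: an equilibrated
channel-confined chain is approached by the gasket at ``v_push`` (bond
lengths per snapshot), compressed until the chain translates bodily with
the gasket (steady state: the slopes of XCOM, xmin and xmax all equal the
gasket speed and the extension is stationary), then released by retracting
the gasket at ``v_retract_factor * v_push`` while the profile relaxes back
to the flat equilibrium plateau.

Compression profiles are recorded on a fixed grid in the gasket frame
(origin at the gasket plane), which makes time- and ensemble-averaging of
the steady ramp well defined; retraction profiles are recorded in the lab
frame and COM-aligned downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forcefield import ForceFieldParams
from .geometry import (BOND_LENGTH, STEPS_PER_SNAPSHOT, ChainState,
                       ChannelGasket, bl_per_snapshot_to_sigma_per_time,
                       gasket_position, init_chain)
from .integrator import advance
from .observables import (ConcentrationProfile, chain_metrics,
                          concentration_profile, ensemble_average_profiles)

__all__ = [
    "RunPlan",
    "EquilibriumSummary",
    "StageResult",
    "equilibrate",
    "compress",
    "retract",
    "run_ensemble",
    "EnsembleResult",
]

log = logging.getLogger("nanodozer")


@dataclass(frozen=True)
class RunPlan:
    """Full parameterization of one squeezing experiment."""

    n_beads: int = 1024
    channel: ChannelGasket = field(default_factory=ChannelGasket)
    params: ForceFieldParams = field(default_factory=ForceFieldParams)
    v_push: float = 0.05            # bond lengths per snapshot
    v_retract_factor: float = 4.0
    snapshot_interval: int = STEPS_PER_SNAPSHOT
    ensemble_size: int = 10
    base_seed: int = 0
    scheme: str = "gunsteren_berendsen"
    bin_width: float = 2.0          # bond lengths
    initial_extension_fraction: float = 0.3
    stationarity_window: int = 100  # snapshots
    drift_tolerance: float = 0.01
    min_equil_snapshots: int = 200  # burn-in before testing stationarity
    max_equil_snapshots: int = 4000
    equil_sample_snapshots: int = 100
    steady_window: int = 100
    steady_speed_tolerance: float = 0.15
    steady_extra_snapshots: int = 200
    max_compress_snapshots: int = 20000
    retract_snapshots: int = 2000

    def with_(self, **kwargs) -> "RunPlan":
        return replace(self, **kwargs)

    @property
    def v_push_sigma(self) -> float:
        """Gasket compression speed in sigma per reduced time."""
        return bl_per_snapshot_to_sigma_per_time(self.v_push, self.params.dt)

    @property
    def snapshot_time(self) -> float:
        return self.snapshot_interval * self.params.dt


@dataclass
class EquilibriumSummary:
    r0: float                       # equilibrium extension, bond lengths
    r0_sem: float
    c0: float                       # plateau concentration (contour/length)
    profile: ConcentrationProfile   # COM-aligned average equilibrium profile
    extension_series: np.ndarray    # per-snapshot extension, bond lengths


@dataclass
class StageResult:
    """Per-snapshot record of one protocol stage."""

    metrics: pd.DataFrame           # time, XCOM, xmin, xmax, extension (+gasket)
    profiles: list                  # ConcentrationProfile per recorded snapshot
    final_state: ChainState
    steady_start: int | None = None  # snapshot index where steady state begins

    def steady_profile(self, last_k: int = 150) -> ConcentrationProfile:
        """Time-averaged profile over the trailing steady-state window.

        Only the last ``last_k`` recorded snapshots are averaged, so a
        slightly early steady-state detection cannot mix transient
        profiles into the ramp.
        """
        if self.steady_start is None:
            raise ValueError("stage has no detected steady state")
        sel = self.profiles[max(self.steady_start,
                                len(self.profiles) - last_k):]
        return ensemble_average_profiles(sel, align="none")


def _segment_seeds(seed: int, stage: int):
    rng = np.random.default_rng((int(seed), int(stage)))
    while True:
        yield int(rng.integers(2**31))


def _block_se(a: np.ndarray) -> float:
    """Standard error of the mean from 4 block means (tolerates the strong
    autocorrelation of extension series better than i.i.d. formulas)."""
    blocks = a[: 4 * (len(a) // 4)].reshape(4, -1).mean(axis=1)
    return float(blocks.std(ddof=1)) / 2.0


def _is_stationary(series: np.ndarray, window: int, tol: float) -> bool:
    """Two-window drift test: stationary when the means of the last two
    disjoint windows agree within their own (block-estimated) noise plus
    the relative tolerance.

    The extension of a confined chain wanders with O(window) correlation
    times, so a fitted-slope significance test against white-noise
    residuals would flag equilibrium fluctuations as drift; comparing
    disjoint window means against block noise catches the systematic
    relaxation transient and accepts stationary wandering.
    """
    if len(series) < 2 * window:
        return False
    cur = series[-window:]
    prev = series[-2 * window:-window]
    gap = abs(cur.mean() - prev.mean())
    noise = 2.0 * np.hypot(_block_se(cur), _block_se(prev))
    return gap < noise + tol * abs(cur.mean())


def equilibrate(plan: RunPlan, seed: int | None = None,
                return_series: bool = True):
    """Gasket-free confined dynamics until the extension is stationary.

    Returns ``(state, EquilibriumSummary)``; the summary's r0 and c0 are
    the normalization scales of the reduced description.  Raises if the
    extension has not stabilized after ``max_equil_snapshots``.
    """
    seed = plan.base_seed if seed is None else seed
    seeds = _segment_seeds(seed, 0)
    channel = plan.channel.with_(gasket_enabled=False)
    contour = (plan.n_beads - 1) * BOND_LENGTH * plan.params.sigma_b
    init_ext = plan.initial_extension_fraction * contour \
        if plan.n_beads > 128 else None
    state = init_chain(plan.n_beads, channel, plan.params, seed,
                       initial_extension=init_ext)
    ext = []
    stationary_at = None
    for snap in range(plan.max_equil_snapshots):
        state = advance(state, plan.params, channel, plan.snapshot_interval,
                        next(seeds), plan.scheme)
        ext.append(chain_metrics(state)[3] / BOND_LENGTH)
        if ((snap + 1) >= plan.min_equil_snapshots
                and (snap + 1) % plan.stationarity_window == 0
                and _is_stationary(np.asarray(ext),
                                   plan.stationarity_window,
                                   plan.drift_tolerance)):
            stationary_at = snap + 1
            break
    if stationary_at is None:
        raise RuntimeError(
            f"extension not stationary after {plan.max_equil_snapshots} "
            "snapshots")
    log.info("equilibrate: stationary after %d snapshots", stationary_at)

    # sampling phase for r0, c0 and the equilibrium profile; the leading
    # quarter is discarded against residual slow relaxation that the
    # stationarity test cannot resolve below its noise floor
    ext_samples, profiles = [], []
    for _ in range(plan.equil_sample_snapshots):
        state = advance(state, plan.params, channel, plan.snapshot_interval,
                        next(seeds), plan.scheme)
        ext_samples.append(chain_metrics(state)[3] / BOND_LENGTH)
        profiles.append(concentration_profile(state, plan.bin_width))
    discard = len(ext_samples) // 4
    ext_samples = ext_samples[discard:]
    profiles = profiles[discard:]
    r0 = float(np.mean(ext_samples))
    r0_sem = float(np.std(ext_samples, ddof=1) / np.sqrt(len(ext_samples)))
    avg = ensemble_average_profiles(profiles, align="com")
    # plateau concentration from the central 60% of the averaged profile
    centers = avg.centers
    com = float(np.sum(centers * avg.values) / np.sum(avg.values))
    half = 0.3 * r0
    sel = np.abs(centers - com) < half
    c0 = float(avg.values[sel].mean())
    avg.c0, avg.r0 = c0, r0
    summary = EquilibriumSummary(r0, r0_sem, c0, avg,
                                 np.asarray(ext + ext_samples)
                                 if return_series else np.asarray(ext_samples))
    return state, summary


def _gasket_frame_profile(state: ChainState, xg: float, plan: RunPlan,
                          span_bl: float) -> ConcentrationProfile:
    shifted = state.positions.copy()
    shifted[:, 0] -= xg
    n_bins = int(np.ceil((span_bl + 4) / plan.bin_width))
    prof = concentration_profile(
        ChainState(shifted, state.velocities, state.time),
        plan.bin_width, bin_origin=-n_bins * plan.bin_width + 2.0,
        n_bins=n_bins)
    return prof


def compress(state: ChainState, plan: RunPlan, seed: int | None = None,
             equilibrium: EquilibriumSummary | None = None) -> StageResult:
    """Drive the gasket at -v_push until the chain reaches steady state.

    The gasket starts just beyond the chain's +x edge.  Steady state is
    declared when, over a trailing window, the fitted drifts of XCOM, xmin
    and xmax all match the gasket speed within tolerance and the extension
    is stationary; the run then continues for ``steady_extra_snapshots``
    to time-average the ramp.
    """
    seed = plan.base_seed if seed is None else seed
    seeds = _segment_seeds(seed, 1)
    _, _, xmax, ext0 = chain_metrics(state)
    xg0 = xmax + 2.0 * plan.params.sigma_b
    v_sigma = -plan.v_push_sigma
    channel = plan.channel.with_(
        gasket_x0=xg0 - v_sigma * state.time,  # so gasket_position(t0) = xg0
        gasket_speed_schedule=((np.inf, v_sigma),), gasket_enabled=True)
    # generous grid: the chain can also diffuse away from a slow gasket
    span_bl = (ext0 / BOND_LENGTH) * 1.5 + 60

    rows, profiles = [], []
    steady_at = None
    extra = 0
    v_snap = v_sigma * plan.snapshot_time  # gasket sigma-per-snapshot drift
    for snap in range(plan.max_compress_snapshots):
        state = advance(state, plan.params, channel, plan.snapshot_interval,
                        next(seeds), plan.scheme, gasket_on=True)
        xg = gasket_position(state.time, channel)
        xcom, xmin, xmax, ext = chain_metrics(state)
        rows.append((state.time, xcom, xmin, xmax, ext, xg))
        profiles.append(_gasket_frame_profile(state, xg, plan, span_bl))
        if steady_at is None and len(rows) >= 2 * plan.steady_window:
            w = plan.steady_window
            arr = np.asarray(rows[-w:])
            t = np.arange(w)
            ok = xg - xmax < 3.0 * plan.params.sigma_b  # chain in contact
            for col in (1, 2, 3):
                slope, icept = np.polyfit(t, arr[:, col], 1)
                resid = arr[:, col] - (slope * t + icept)
                se = np.sqrt(np.sum(resid**2) / (w - 2)
                             / np.sum((t - t.mean())**2))
                # drift equals the gasket speed within tolerance, allowing
                # for the statistical resolution of the windowed fit
                if abs(slope - v_snap) > plan.steady_speed_tolerance * \
                        abs(v_snap) + 2.0 * se:
                    ok = False
                    break
            # the extension drift test (two disjoint windows) catches the
            # systematic transient decay that the slope test misses
            ext_series = np.asarray([r[4] for r in rows])
            if ok and _is_stationary(ext_series, w, 0.02):
                steady_at = snap
                log.info("compress: steady state at snapshot %d", snap)
        elif steady_at is not None:
            extra += 1
            if extra >= plan.steady_extra_snapshots:
                break
    metrics = pd.DataFrame(rows, columns=["time", "XCOM", "xmin", "xmax",
                                          "extension", "gasket_x"])
    return StageResult(metrics, profiles, state, steady_at)


def retract(state: ChainState, plan: RunPlan, seed: int | None = None,
            r0: float | None = None,
            n_snapshots: int | None = None) -> StageResult:
    """Reverse the gasket at +v_retract_factor*v_push and record relaxation.

    The gasket is dropped from force evaluation once it outruns the chain
    by more than the interaction cutoff.  Runs for ``n_snapshots``
    (default ``plan.retract_snapshots``) or until the extension has
    recovered to r0 (if given) and is stationary.
    """
    seed = plan.base_seed if seed is None else seed
    seeds = _segment_seeds(seed, 2)
    n_snapshots = n_snapshots or plan.retract_snapshots
    _, xmin0, xmax0, ext0 = chain_metrics(state)
    xg0 = xmax0 + 1.0 * plan.params.sigma_b
    v_sigma = plan.v_retract_factor * plan.v_push_sigma
    channel = plan.channel.with_(
        gasket_x0=xg0 - v_sigma * state.time,
        gasket_speed_schedule=((np.inf, v_sigma),), gasket_enabled=True)
    # wide grid: the released chain also diffuses bodily along the channel
    span = max(ext0, (r0 or 0) * BOND_LENGTH) + 40
    origin_bl = (xmin0 / BOND_LENGTH) - 1.4 * span / BOND_LENGTH
    n_bins = int(np.ceil(3.8 * span / BOND_LENGTH / plan.bin_width))

    rows, profiles = [], []
    gasket_on = True
    for snap in range(n_snapshots):
        state = advance(state, plan.params, channel, plan.snapshot_interval,
                        next(seeds), plan.scheme, gasket_on=gasket_on)
        xg = gasket_position(state.time, channel)
        xcom, xmin, xmax, ext = chain_metrics(state)
        if gasket_on and xg - xmax > plan.params.wca_cutoff + 2.0:
            gasket_on = False
            if snap < 20 and (xmax - xmax0) / max(snap + 1, 1) >= \
                    v_sigma * plan.snapshot_time:
                warnings.warn("retraction speed does not exceed the free "
                              "chain-expansion speed", stacklevel=2)
        rows.append((state.time, xcom, xmin, xmax, ext, xg))
        profiles.append(concentration_profile(
            state, plan.bin_width, bin_origin=origin_bl, n_bins=n_bins))
        if r0 is not None and len(rows) > 50:
            ext_bl = np.asarray([r[4] for r in rows]) / BOND_LENGTH
            if ext_bl[-1] >= 0.98 * r0 and _is_stationary(
                    ext_bl, min(50, len(ext_bl)), 0.02):
                break
    metrics = pd.DataFrame(rows, columns=["time", "XCOM", "xmin", "xmax",
                                          "extension", "gasket_x"])
    return StageResult(metrics, profiles, state, None)


@dataclass
class EnsembleResult:
    replicas: list                  # per-replica dicts of stage results
    failures: list

    def averaged_profiles(self, stage: str, index: int,
                          align: str = "none") -> ConcentrationProfile:
        """Ensemble-average the profiles at one snapshot index."""
        profs = [rep[stage].profiles[index] for rep in self.replicas]
        return ensemble_average_profiles(profs, align=align)


def run_ensemble(plan: RunPlan, stages=("equilibrate", "compress"),
                 seeds=None) -> EnsembleResult:
    """Run independent replicas (seeds base_seed + i) through the protocol.

    Replica failures are caught and reported; partial results preserved.
    """
    if plan.ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if seeds is None:
        seeds = [plan.base_seed + i for i in range(plan.ensemble_size)]
    replicas, failures = [], []
    for s in seeds:
        try:
            rep = {}
            state, summary = equilibrate(plan, seed=s)
            rep["equilibrium"] = summary
            if "compress" in stages:
                rep["compress"] = compress(state, plan, seed=s,
                                           equilibrium=summary)
                state = rep["compress"].final_state
            if "retract" in stages:
                rep["retract"] = retract(state, plan, seed=s,
                                         r0=summary.r0)
            replicas.append(rep)
        except Exception as exc:  # preserve partial ensemble
            log.error("replica seed=%s failed: %s", s, exc)
            failures.append((s, exc))
    if not replicas:
        raise RuntimeError(f"all replicas failed: {failures}")
    return EnsembleResult(replicas, failures)
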