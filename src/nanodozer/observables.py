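"""Measurements on BD trajectories.

The central observable is the coarse-grained axial concentration profile
c(x): each bond's length is apportioned to uniform x-bins (default width 2
bond lengths) by the fraction of the bond's x-projection overlapping each
bin, so a single frame's profile integrates exactly to the chain contour
length.  Profiles are reported in bond-length units: positions x/bl, values
in contour (bl) per unit channel length (bl), so the reduced profile c/c0
is dimensionless with an equilibrium plateau at 1.

Also here: chain extension metrics, bond-length statistics, the
persistence-length estimator (exponential fit to bond-vector correlations)
and the averaging conventions (center-of-mass alignment, three-point
running average) used for reported profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import BOND_LENGTH

__all__ = [
    "ConcentrationProfile",
    "concentration_profile",
    "chain_metrics",
    "bond_length_stats",
    "persistence_length",
    "ensemble_average_profiles",
    "running_average",
]


@dataclass
class ConcentrationProfile:
    """Binned axial density c(x) with optional (c0, r0) normalization."""

    bin_edges: np.ndarray          # uniform, length nbins+1, bond-length units
    values: np.ndarray             # contour per unit length, >= 0
    time: float = 0.0              # snapshot index
    c0: float | None = None
    r0: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bin_edges) != len(self.values) + 1:
            raise ValueError("need len(bin_edges) == len(values) + 1")
        w = np.diff(self.bin_edges)
        if np.any(w <= 0) or np.ptp(w) > 1e-9 * w[0]:
            raise ValueError("bins must be uniform and increasing")
        if np.any(self.values < -1e-12):
            raise ValueError("concentration must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mass(self) -> float:
        """Integral of c over x (= chain contour for a single frame)."""
        return float(np.sum(self.values) * self.bin_width)

    def reduced(self):
        """(x/r0, c/c0) arrays; requires normalization constants."""
        if self.c0 is None or self.r0 is None:
            raise ValueError("profile has no (c0, r0) normalization")
        return self.centers / self.r0, self.values / self.c0


def concentration_profile(state, bin_width: float = 2.0,
                          bin_origin: float | None = None,
                          n_bins: int | None = None,
                          c0: float | None = None,
                          r0: float | None = None) -> ConcentrationProfile:
    """Bin a conformation into the axial concentration profile.

    Positions are converted to bond-length units (x/bl); ``bin_width`` is in
    bond lengths (default 2).  Bond mass is split among bins by exact
    x-projection overlap, so ``profile.mass`` equals the contour length to
    machine precision.  A fixed grid may be imposed via ``bin_origin`` /
    ``n_bins`` (then mass falling outside raises).
    """
    positions = np.asarray(getattr(state, "positions", state), dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least one bond")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x_bl = positions / BOND_LENGTH
    if bin_origin is None:
        lo = np.floor(x_bl[:, 0].min() / bin_width) * bin_width - bin_width
        hi = np.ceil(x_bl[:, 0].max() / bin_width) * bin_width + bin_width
        bin_origin = lo
        n_bins = int(round((hi - lo) / bin_width))
    elif n_bins is None:
        raise ValueError("n_bins required when bin_origin is given")
    out = np.zeros(n_bins)
    lost = _kernels.bin_bonds(np.ascontiguousarray(x_bl), float(bin_origin),
                              float(bin_width), int(n_bins), out)
    if lost > 1e-9:
        raise ValueError("chain extends beyond the requested bin range")
    edges = bin_origin + bin_width * np.arange(n_bins + 1)
    t = float(getattr(state, "time", 0.0))
    return ConcentrationProfile(edges, out / bin_width, time=t, c0=c0, r0=r0)


def chain_metrics(state):
    """(XCOM, xmin, xmax, extension) of the bead x-coordinates (sigma)."""
    positions = np.asarray(getattr(state, "positions", state), dtype=float)
    if positions.shape[0] == 0:
        raise ValueError("empty chain")
    x = positions[:, 0]
    return float(x.mean()), float(x.min()), float(x.max()), \
        float(x.max() - x.min())


def bond_length_stats(trajectory):
    """Time-and-bond mean bond length with the standard error of the mean.

    ``trajectory`` is an iterable of states or position arrays.  The SEM
    treats frames as the independent unit (bonds within a frame and nearby
    frames are correlated, so this is an effective-error estimate).
    """
    frame_means = []
    for fr in trajectory:
        p = np.asarray(getattr(fr, "positions", fr), dtype=float)
        frame_means.append(np.linalg.norm(np.diff(p, axis=0), axis=1).mean())
    frame_means = np.asarray(frame_means)
    mean = float(frame_means.mean())
    sem = float(frame_means.std(ddof=1) / np.sqrt(len(frame_means))) \
        if len(frame_means) > 1 else 0.0
    return mean, sem


def persistence_length(trajectory, max_sep: int | None = None,
                       floor: float = 0.25) -> float:
    """Persistence length from the bond-vector correlation decay.

    Fits ``ln <cos theta(s)> = -s * bl_mean / Lp`` (zero intercept, since
    the model fixes corr(0) = 1) over the contiguous separations where the
    correlation exceeds ``floor``; returns Lp in sigma units.  The floor
    is deliberately high: excluded volume adds a slowly decaying
    large-separation tail on top of the local exponential, and the
    persistence length is defined by the initial decay only.  A frozen
    straight chain (no decay) raises.
    """
    frames = [np.asarray(getattr(fr, "positions", fr), dtype=float)
              for fr in trajectory]
    n = frames[0].shape[0]
    if max_sep is None:
        max_sep = min(n - 2, 60)
    bl_sum, bl_n = 0.0, 0
    corr = np.zeros(max_sep + 1)
    cnt = np.zeros(max_sep + 1)
    for p in frames:
        b = np.diff(p, axis=0)
        lb = np.linalg.norm(b, axis=1)
        e = b / lb[:, None]
        bl_sum += lb.sum()
        bl_n += len(lb)
        for s in range(max_sep + 1):
            dots = np.sum(e[:len(e) - s] * e[s:], axis=1)
            corr[s] += dots.sum()
            cnt[s] += len(dots)
    corr /= cnt
    bl_mean = bl_sum / bl_n
    # contiguous decaying head only: noise beyond the first floor crossing
    # would otherwise flatten the log-linear fit
    sel = []
    for s in range(1, max_sep + 1):
        if corr[s] <= floor:
            break
        sel.append(s)
    sel = np.asarray(sel, dtype=int)
    if len(sel) < 1:
        raise ValueError("no resolvable correlation decay")
    y = np.log(corr[sel])
    slope = float(np.sum(sel * y) / np.sum(sel * sel))  # zero-intercept fit
    if slope >= -1e-12:
        raise ValueError("bond correlations do not decay (rigid-rod limit)")
    return float(-bl_mean / slope)


def _shift_profile(values: np.ndarray, edges: np.ndarray,
                   shift: float) -> np.ndarray:
    """Shift a binned profile by a continuous offset, conserving mass.

    Rebins via linear interpolation of the cumulative mass; mass shifted
    past the grid ends is lost, so callers pad the grid beforehand.
    """
    w = edges[1] - edges[0]
    cum = np.concatenate([[0.0], np.cumsum(values) * w])
    shifted = np.interp(edges - shift, edges, cum,
                        left=0.0, right=cum[-1])
    return np.diff(shifted) / w


def ensemble_average_profiles(profiles, align: str = "none",
                              origin: float | None = None
                              ) -> ConcentrationProfile:
    """Average profiles on a common grid, optionally COM-aligned.

    ``align='com'`` shifts each profile continuously so its first moment
    sits at a common origin (the mean COM by default) before the pointwise
    average - this removes center-of-mass diffusion broadening from
    retraction ensembles.  ``align='none'`` averages in fixed coordinates.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to average")
    w = profiles[0].bin_width
    for p in profiles:
        if abs(p.bin_width - w) > 1e-9:
            raise ValueError("profiles must share a bin width")
    lo = min(p.bin_edges[0] for p in profiles)
    hi = max(p.bin_edges[-1] for p in profiles)
    pad = 0.25 * (hi - lo) + 2 * w
    lo, hi = lo - pad, hi + pad
    n = int(np.ceil((hi - lo) / w))
    edges = lo + w * np.arange(n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def on_grid(p: ConcentrationProfile) -> np.ndarray:
        v = np.zeros(n)
        i0 = int(round((p.bin_edges[0] - lo) / w))
        v[i0:i0 + len(p.values)] = p.values
        return v

    stacked = np.stack([on_grid(p) for p in profiles])
    if align == "com":
        masses = stacked.sum(axis=1) * w
        coms = (stacked * centers).sum(axis=1) * w / masses
        if origin is None:
            origin = float(coms.mean())
        stacked = np.stack([
            _shift_profile(v, edges, origin - c)
            for v, c in zip(stacked, coms)])
    elif align != "none":
        raise ValueError("align must be 'none' or 'com'")
    mean = stacked.mean(axis=0)
    return ConcentrationProfile(edges, np.maximum(mean, 0.0),
                                time=profiles[-1].time,
                                c0=profiles[0].c0, r0=profiles[0].r0)


def running_average(values, window: int = 3) -> np.ndarray:
    """Centered moving mean with truncated windows at the ends."""
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and positive")
    v = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        out[i] = v[max(0, i - half):i + half + 1].mean()
    return out
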