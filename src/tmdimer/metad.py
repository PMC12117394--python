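"""Well-tempered metadynamics on toy Langevin systems and its analysis.

Implements the full well-tempered workflow on one-dimensional collective
variables (CVs): biased sampling of an overdamped Langevin particle in an
analytic potential, hill bookkeeping, bias summation, free-energy-surface
(FES) reconstruction, Boltzmann reweighting, dimerization free energy and
convergence diagnostics (hill-height decay, time evolution of the
bound/unbound free-energy difference, block-analysis error curves).

Conventions
-----------
* Energies in kJ/mol, temperature in K, k_B = 0.0083145 kJ/(mol K).
* Hill heights follow the well-tempered rule
  W = W0 * exp(-V(s, t) / ((f - 1) k_B T)), with V the bias already
  accumulated at the deposition point and f > 1 the bias factor.
* The FES estimator is F(s) = -f/(f-1) * V(s) + C with C fixed so that
  min F = 0 over the grid.
* Bias summation is exact Gaussian summation over all hills (no kernel
  truncation).
* The sampler is Euler-Maruyama overdamped Langevin; between grid nodes
  the bias is linearly interpolated, so its force is piecewise constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

#: Boltzmann constant in kJ/(mol K)
KB = 0.0083145


# ---------------------------------------------------------------------------
# containers


@dataclass
class HillsLog:
    """Record of deposited Gaussian hills.

    Arrays are aligned per deposit: ``time`` (simulation time units),
    ``center`` (CV units), ``sigma`` (CV units), ``height`` (kJ/mol, the
    already-tempered deposited height).
    """

    time: np.ndarray
    center: np.ndarray
    sigma: np.ndarray
    height: np.ndarray
    bias_factor: float
    temperature: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        n = len(self.time)
        if not (len(self.center) == len(self.sigma) == len(self.height) == n):
            raise ValueError("hill arrays must have equal length")
        if n and ((self.height <= 0).any() or (self.sigma <= 0).any()):
            raise ValueError("hill heights and widths must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")

    @property
    def n_hills(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(time=self.time, center=self.center, sigma=self.sigma,
                 height=self.height, biasf=np.full(self.n_hills, self.bias_factor))
        )


@dataclass
class FreeEnergySurface:
    """1D free energy on a grid, minimum pinned to zero."""

    grid: np.ndarray
    values: np.ndarray  # kJ/mol
    temperature: float
    zero_convention: str = "minimum set to 0"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must align")

    def value_at(self, s: float) -> float:
        return float(np.interp(s, self.grid, self.values))


@dataclass(frozen=True)
class ToySystem:
    """Overdamped Langevin particle in a polynomial potential.

    ``coeffs`` are polynomial coefficients c0..c4 of
    U(x) = sum_k c_k x^k (kJ/mol, CV units).  ``friction`` gamma enters the
    overdamped equation dx = -U'(x)/gamma dt + sqrt(2 kT/gamma) dW.
    """

    coeffs: tuple[float, ...]
    temperature: float = 310.0
    friction: float = 1.0
    timestep: float = 0.002

    def __post_init__(self):
        c = tuple(float(v) for v in self.coeffs)
        object.__setattr__(self, "coeffs", c)
        lead = next((v for v in reversed(c) if v != 0.0), 0.0)
        degree = max((k for k, v in enumerate(c) if v != 0.0), default=0)
        if degree > 0 and (degree % 2 == 1 or lead < 0):
            raise ValueError("potential must be bounded below")
        if self.temperature < 0 or self.friction <= 0 or self.timestep <= 0:
            raise ValueError("temperature >= 0, friction > 0, timestep > 0 required")

    @classmethod
    def double_well(cls, a: float, b: float = 0.0, **kw) -> "ToySystem":
        """U(x) = a (x^2 - 1)^2 + b x — two basins near x = +/-1, tilt b."""
        return cls(coeffs=(a, b, -2 * a, 0.0, a), **kw)

    @classmethod
    def harmonic(cls, k: float, x0: float = 0.0, **kw) -> "ToySystem":
        """U(x) = k/2 (x - x0)^2."""
        return cls(coeffs=(0.5 * k * x0**2, -k * x0, 0.5 * k, 0.0, 0.0), **kw)

    def potential(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coeffs)


@dataclass
class WTMetadRun:
    """Output of one well-tempered metadynamics run."""

    times: np.ndarray  # frame times
    cv: np.ndarray  # CV samples at those times
    hills: HillsLog
    system: ToySystem
    grid: np.ndarray
    bias_final: np.ndarray  # V(s, t_end) on grid, from the on-the-fly grid


# ---------------------------------------------------------------------------
# well-tempered rule


def wt_hill_height(V_at_s: float, W0: float = 0.05, bias_factor: float = 10.0,
                   T: float = 310.0) -> float:
    """Deposited hill height W = W0 exp(-V / ((f - 1) k_B T)).

    ``V_at_s`` is the bias already accumulated at the deposition point.  In
    the f -> inf limit W -> W0 (standard metadynamics).
    """
    if bias_factor <= 1:
        raise ValueError("bias factor must exceed 1")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return W0 * math.exp(-V_at_s / ((bias_factor - 1.0) * KB * T))


# ---------------------------------------------------------------------------
# sampler


@njit(cache=True)
def _wtmetad_kernel(c0, c1, c2, c3, c4, x0, n_steps, dt, gamma, kT,
                    W0, wt_denom, sigma, pace, stride, grid, vbias, seed):
    """Euler-Maruyama + on-grid bias. Returns (cv, hill_t, hill_s, hill_w, status)."""
    np.random.seed(seed)
    n_grid = grid.shape[0]
    lo = grid[0]
    dx = grid[1] - grid[0]
    inv_dx = 1.0 / dx
    n_frames = n_steps // stride + 1
    n_hills = n_steps // pace
    cv = np.empty(n_frames)
    hill_t = np.empty(n_hills)
    hill_s = np.empty(n_hills)
    hill_w = np.empty(n_hills)
    x = x0
    cv[0] = x
    noise_amp = math.sqrt(2.0 * kT * dt / gamma)
    i_frame = 1
    i_hill = 0
    for step in range(1, n_steps + 1):
        # physical force -U'(x)
        f_pot = -(c1 + x * (2.0 * c2 + x * (3.0 * c3 + x * 4.0 * c4)))
        # bias force from linear interpolation of vbias
        u = (x - lo) * inv_dx
        i0 = int(u)
        if i0 < 0 or i0 >= n_grid - 1:
            return cv, hill_t, hill_s, hill_w, 1  # left the grid: unstable
        f_bias = -(vbias[i0 + 1] - vbias[i0]) * inv_dx
        x = x + (f_pot + f_bias) * dt / gamma + noise_amp * np.random.normal()
        if not math.isfinite(x):
            return cv, hill_t, hill_s, hill_w, 2
        if step % pace == 0:
            u = (x - lo) * inv_dx
            i0 = int(u)
            if i0 < 0 or i0 >= n_grid - 1:
                return cv, hill_t, hill_s, hill_w, 1
            frac = u - i0
            v_here = vbias[i0] * (1.0 - frac) + vbias[i0 + 1] * frac
            w = W0 * math.exp(-v_here / wt_denom)
            for g in range(n_grid):
                z = (grid[g] - x) / sigma
                vbias[g] += w * math.exp(-0.5 * z * z)
            hill_t[i_hill] = step * dt
            hill_s[i_hill] = x
            hill_w[i_hill] = w
            i_hill += 1
        if step % stride == 0:
            cv[i_frame] = x
            i_frame += 1
    return cv, hill_t, hill_s, hill_w, 0


def run_wtmetad(
    system: ToySystem,
    n_steps: int,
    seed: int,
    W0: float = 0.05,
    bias_factor: float = 10.0,
    sigma: float = 0.05,
    pace: int = 5000,
    stride: int = 500,
    x0: float | None = None,
    grid: tuple[float, float, int] = (-3.0, 3.0, 1201),
) -> WTMetadRun:
    """Run well-tempered metadynamics on a toy system.

    One hill of width ``sigma`` is deposited every ``pace`` steps with the
    tempered height evaluated at the deposition point; the CV is recorded
    every ``stride`` steps.  Identical seeds give identical output.  Raises
    ``RuntimeError`` if the particle leaves the bias grid or the
    integration blows up.
    """
    if W0 < 0 or sigma <= 0 or pace < 1 or stride < 1 or n_steps < 1:
        raise ValueError("W0 >= 0, sigma > 0; pace, stride, n_steps >= 1 required")
    if bias_factor <= 1:
        raise ValueError("bias factor must exceed 1")
    c = list(system.coeffs) + [0.0] * (5 - len(system.coeffs))
    glo, ghi, gn = grid
    gridv = np.linspace(glo, ghi, int(gn))
    vbias = np.zeros_like(gridv)
    if x0 is None:
        x0 = float(gridv[np.argmin(system.potential(gridv))])
    kT = KB * system.temperature
    wt_denom = (bias_factor - 1.0) * kT if system.temperature > 0 else np.inf
    # W0 = 0 means plain (unbiased) Langevin: suppress deposits entirely
    pace_eff = int(pace) if W0 > 0 else int(n_steps) + 1
    cv, hill_t, hill_s, hill_w, status = _wtmetad_kernel(
        c[0], c[1], c[2], c[3], c[4], float(x0), int(n_steps),
        system.timestep, system.friction, kT, W0, wt_denom, sigma,
        pace_eff, int(stride), gridv, vbias, int(seed) % (2**31),
    )
    if status == 1:
        raise RuntimeError("unstable integration: particle left the bias grid")
    if status == 2:
        raise RuntimeError("unstable integration: coordinate became non-finite")
    times = np.arange(len(cv)) * (stride * system.timestep)
    hills = HillsLog(hill_t, hill_s, np.full(len(hill_t), sigma), hill_w,
                     bias_factor, system.temperature)
    return WTMetadRun(times=times, cv=cv, hills=hills, system=system,
                      grid=gridv, bias_final=vbias)


# ---------------------------------------------------------------------------
# bias summation and FES


def sum_hills(log: HillsLog, grid: np.ndarray, up_to_time: float | None = None) -> np.ndarray:
    """Bias V(s, t) = sum over hills with time <= t of W exp(-(s-s_k)^2/2 sigma_k^2).

    Exact Gaussian summation over all selected hills (no truncation).
    An empty selection yields the zero field.
    """
    grid = np.asarray(grid, dtype=float)
    if up_to_time is None:
        idx = np.arange(log.n_hills)
    else:
        idx = np.flatnonzero(log.time <= up_to_time)
    v = np.zeros_like(grid)
    # chunk over hills to bound memory at ~8 MB
    chunk = max(1, int(1_000_000 // max(len(grid), 1)))
    for k0 in range(0, len(idx), chunk):
        ks = idx[k0 : k0 + chunk]
        z = (grid[None, :] - log.center[ks, None]) / log.sigma[ks, None]
        v += (log.height[ks, None] * np.exp(-0.5 * z * z)).sum(axis=0)
    return v


def fes_from_bias(grid: np.ndarray, bias: np.ndarray, bias_factor: float,
                  temperature: float = 310.0) -> FreeEnergySurface:
    """F(s) = -(f/(f-1)) V(s) + C, with C so that min F = 0."""
    if bias_factor <= 1:
        raise ValueError("bias factor must exceed 1")
    values = -(bias_factor / (bias_factor - 1.0)) * np.asarray(bias, dtype=float)
    values = values - values.min()
    return FreeEnergySurface(grid=np.asarray(grid, float), values=values,
                             temperature=temperature)


# ---------------------------------------------------------------------------
# reweighting


def frame_weights(
    times: np.ndarray,
    cv: np.ndarray,
    log: HillsLog,
    temperature: float | None = None,
    mode: str = "time-dependent",
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame Boltzmann reweighting factors removing the metadynamics bias.

    ``mode="time-dependent"`` uses w_t proportional to
    exp((V(s_t, t) - c(t)) / k_B T) with the offset
    c(t) = kT ln [ integral exp(b f V/(f-1)) ds / integral exp(b V/(f-1)) ds ]
    evaluated from the bias accumulated up to each frame's time.
    ``mode="final"`` evaluates the final bias at every frame (the constant
    offset then cancels).  Weights are returned normalised to sum to 1.
    """
    times = np.asarray(times, float)
    cv = np.asarray(cv, float)
    if times.shape != cv.shape:
        raise ValueError("times and cv must align")
    T = log.temperature if temperature is None else temperature
    kT = KB * T
    f = log.bias_factor
    if grid is None:
        span = max(cv.max() - cv.min(), 1e-9)
        grid = np.linspace(cv.min() - 0.1 * span, cv.max() + 0.1 * span, 801)
    if mode == "final":
        vfin = sum_hills(log, grid)
        v_at = np.interp(cv, grid, vfin)
        logw = v_at / kT
    elif mode == "time-dependent":
        # V(s, t) and c(t) are piecewise constant between hill deposits,
        # so walk the hills once and handle each epoch's frames in bulk
        epoch = np.searchsorted(log.time, times, side="right")
        logw = np.zeros_like(cv)
        vgrid = np.zeros_like(grid)
        for k in range(log.n_hills + 1):
            if k > 0:
                z = (grid - log.center[k - 1]) / log.sigma[k - 1]
                vgrid = vgrid + log.height[k - 1] * np.exp(-0.5 * z * z)
            sel = np.flatnonzero(epoch == k)
            if len(sel) == 0:
                continue
            num = np.log(np.trapezoid(np.exp((f / (f - 1.0)) * vgrid / kT), grid))
            den = np.log(np.trapezoid(np.exp(vgrid / ((f - 1.0) * kT)), grid))
            c_t = kT * (num - den)
            logw[sel] = (np.interp(cv[sel], grid, vgrid) - c_t) / kT
    else:
        raise ValueError("mode must be 'time-dependent' or 'final'")
    logw = logw - logw.max()
    w = np.exp(logw)
    return w / w.sum()


def reweight_boltzmann(
    cv: np.ndarray,
    observable: np.ndarray,
    log: HillsLog,
    times: np.ndarray,
    temperature: float | None = None,
    bins: int | np.ndarray = 101,
    mode: str = "time-dependent",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bias-removed (Boltzmann) histogram of an auxiliary observable.

    Returns ``(bin_centers, density, weights)`` with the weighted histogram
    normalised as a probability density.  ``observable`` must align with
    the CV series frame by frame.
    """
    observable = np.asarray(observable, float)
    cv = np.asarray(cv, float)
    if observable.shape != cv.shape:
        raise ValueError("observable and cv series must have equal length")
    w = frame_weights(times, cv, log, temperature=temperature, mode=mode)
    hist, edges = np.histogram(observable, bins=bins, weights=w, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, hist, w


def fes_from_weights(
    observable: np.ndarray,
    weights: np.ndarray,
    bins: int | np.ndarray = 101,
    temperature: float = 310.0,
) -> FreeEnergySurface:
    """-kT ln of the weighted histogram, minimum pinned to zero."""
    hist, edges = np.histogram(observable, bins=bins, weights=weights, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(divide="ignore"):
        vals = -KB * temperature * np.log(hist)
    vals = vals - vals[np.isfinite(vals)].min()
    return FreeEnergySurface(grid=centers, values=vals, temperature=temperature)


# ---------------------------------------------------------------------------
# dimerization free energy


def _window_mask(grid: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise ValueError("window upper bound must exceed lower bound")
    if lo < grid.min() - 1e-12 or hi > grid.max() + 1e-12:
        raise ValueError("window lies outside the sampled grid")
    mask = (grid >= lo) & (grid <= hi)
    if not mask.any():
        raise ValueError("window contains no grid points")
    return mask


def delta_g_bind(
    fes: FreeEnergySurface,
    bound_window: tuple[float, float],
    unbound_window: tuple[float, float],
) -> float:
    """Dimerization free energy: F at the bound minimum minus the mean F
    over the unbound window (kJ/mol; negative = association favourable).

    The windows are explicit, must be disjoint and must lie on the grid.
    """
    if not (bound_window[1] <= unbound_window[0] or unbound_window[1] <= bound_window[0]):
        raise ValueError("bound and unbound windows must be disjoint")
    mb = _window_mask(fes.grid, bound_window)
    mu = _window_mask(fes.grid, unbound_window)
    fb = fes.values[mb]
    fu = fes.values[mu]
    if not (np.isfinite(fb).all() and np.isfinite(fu).all()):
        raise ValueError("window overlaps unsampled (non-finite) FES region")
    return float(fb.min() - fu.mean())


def basin_free_energy_difference(
    fes: FreeEnergySurface,
    window_a: tuple[float, float],
    window_b: tuple[float, float],
) -> float:
    """Basin-integrated free energy difference G_a - G_b where
    G = -kT ln integral over the window of exp(-F/kT)."""
    kT = KB * fes.temperature
    out = []
    for win in (window_a, window_b):
        m = _window_mask(fes.grid, win)
        out.append(-kT * np.log(np.trapezoid(np.exp(-fes.values[m] / kT), fes.grid[m])))
    return float(out[0] - out[1])


def boltzmann_reference_dg(
    system: ToySystem,
    window_a: tuple[float, float],
    window_b: tuple[float, float],
    n_points: int = 20001,
) -> float:
    """Quadrature reference: basin free-energy difference G_a - G_b of the
    analytic potential via numerical integration of the Boltzmann weight."""
    kT = KB * system.temperature
    # shared energy zero so the basin difference is exact
    x_all = np.linspace(min(window_a[0], window_b[0]), max(window_a[1], window_b[1]), n_points)
    u0 = system.potential(x_all).min()
    g = []
    for lo, hi in (window_a, window_b):
        x = np.linspace(lo, hi, n_points)
        u = system.potential(x) - u0
        g.append(-kT * np.log(np.trapezoid(np.exp(-u / kT), x)))
    return float(g[0] - g[1])


def suggest_windows(
    fes: FreeEnergySurface, well_depth: float = 2.0, plateau_slope: float = 0.5
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Heuristic bound/unbound windows from a 1D FES over a distance CV.

    Bound: the contiguous region around the global minimum where
    F < well_depth * kT.  Unbound: the trailing region (largest CV values)
    where |dF/ds| stays below ``plateau_slope`` kT per CV unit.
    """
    kT = KB * fes.temperature
    g, v = fes.grid, fes.values
    imin = int(np.argmin(v))
    thresh = well_depth * kT
    lo = imin
    while lo > 0 and v[lo - 1] < thresh:
        lo -= 1
    hi = imin
    while hi < len(g) - 1 and v[hi + 1] < thresh:
        hi += 1
    slope = np.abs(np.gradient(v, g)) / kT
    j = len(g) - 1
    while j > 0 and slope[j] < plateau_slope:
        j -= 1
    if j >= len(g) - 2:
        raise ValueError("no flat unbound plateau detected")
    return (float(g[lo]), float(g[hi])), (float(g[min(j + 1, len(g) - 1)]), float(g[-1]))


# ---------------------------------------------------------------------------
# block analysis and convergence


def weighted_block_error(
    observable: np.ndarray,
    weights: np.ndarray | None,
    n_blocks: int,
) -> tuple[float, float]:
    """Weighted block-average mean and standard error for one block count.

    The series is cut into ``n_blocks`` contiguous blocks; the mean is the
    weight-averaged block mean and the error follows the weighted
    block-analysis estimator (reducing to std(block means)/sqrt(n) for
    uniform weights).  With a single block the error is undefined (NaN).
    """
    obs = np.asarray(observable, float)
    n = len(obs)
    if n_blocks < 1 or n_blocks > n:
        raise ValueError("need 1 <= n_blocks <= number of samples")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    bw = np.array([w[a:b].sum() for a, b in zip(edges[:-1], edges[1:])])
    bm = np.array([
        np.average(obs[a:b], weights=w[a:b]) for a, b in zip(edges[:-1], edges[1:])
    ])
    wtot = bw.sum()
    mean = float(np.average(bm, weights=bw))
    if n_blocks == 1:
        return mean, float("nan")
    neff = wtot**2 / (bw**2).sum()
    var = np.average((bm - mean) ** 2, weights=bw) * neff / (neff - 1.0)
    return mean, float(math.sqrt(var / neff))


def block_error_curve(
    observable: np.ndarray,
    weights: np.ndarray | None = None,
    block_counts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Error-vs-block-count table, by default every 10 blocks from 1 to 1000.

    Columns: ``n_blocks, block_size, mean, error``.  Block counts larger
    than the sample size are a hard error.
    """
    obs = np.asarray(observable, float)
    if block_counts is None:
        block_counts = np.concatenate([[1], np.arange(10, 1001, 10)])
    rows = []
    for nb in block_counts:
        mean, err = weighted_block_error(obs, weights, int(nb))
        rows.append((int(nb), len(obs) // int(nb), mean, err))
    return pd.DataFrame(rows, columns=["n_blocks", "block_size", "mean", "error"])


def delta_g_time_series(
    log: HillsLog,
    grid: np.ndarray,
    bound_window: tuple[float, float],
    unbound_window: tuple[float, float],
    n_checkpoints: int = 20,
) -> pd.DataFrame:
    """Time evolution of the bound/unbound free-energy difference.

    The bias is summed up to each checkpoint time, converted to a FES and
    reduced to delta G; returns columns ``time, delta_g``.
    """
    if log.n_hills == 0:
        raise ValueError("empty hills log")
    ts = np.linspace(log.time[0], log.time[-1], n_checkpoints)
    rows = []
    for t in ts:
        v = sum_hills(log, grid, up_to_time=t)
        fes = fes_from_bias(grid, v, log.bias_factor, log.temperature)
        rows.append((t, delta_g_bind(fes, bound_window, unbound_window)))
    return pd.DataFrame(rows, columns=["time", "delta_g"])


@dataclass
class ConvergenceReport:
    """Bundle of the four standard convergence diagnostics."""

    cv_trace: pd.DataFrame  # time, cv
    hill_heights: pd.DataFrame  # time, height
    delta_g_series: pd.DataFrame  # time, delta_g
    block_table: pd.DataFrame  # n_blocks, block_size, mean, error
    delta_g_final: float = field(default=float("nan"))


def convergence_report(
    run: WTMetadRun,
    bound_window: tuple[float, float],
    unbound_window: tuple[float, float],
    block_counts: np.ndarray | None = None,
    n_checkpoints: int = 20,
    reweight_mode: str = "final",
) -> ConvergenceReport:
    """Convergence diagnostics of a well-tempered run.

    (1) CV diffusion trace, (2) hill-height decay, (3) delta G(t) from
    time-sliced bias, (4) block-analysis error of the reweighted
    bound-state indicator, by default every 10 blocks from 1 to 1000.
    """
    log = run.hills
    cv_trace = pd.DataFrame(dict(time=run.times, cv=run.cv))
    hill_heights = pd.DataFrame(dict(time=log.time, height=log.height))
    dg = delta_g_time_series(log, run.grid, bound_window, unbound_window, n_checkpoints)
    w = frame_weights(run.times, run.cv, log, mode=reweight_mode)
    indicator = (
        (run.cv >= bound_window[0]) & (run.cv <= bound_window[1])
    ).astype(float)
    if block_counts is None:
        block_counts = np.concatenate([[1], np.arange(10, 1001, 10)])
    block_counts = np.asarray(block_counts, dtype=int)
    if block_counts.max() > len(run.cv):
        raise ValueError("more blocks requested than CV samples available")
    blocks = block_error_curve(indicator, w, block_counts)
    fes = fes_from_bias(run.grid, sum_hills(log, run.grid), log.bias_factor,
                        log.temperature)
    dg_final = delta_g_bind(fes, bound_window, unbound_window)
    return ConvergenceReport(cv_trace, hill_heights, dg, blocks, dg_final)
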