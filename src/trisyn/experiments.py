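"""Analysis layer: input-output curves, logistic transfer fit, steady states,
bifurcation and hysteresis scans.

The open-loop transfer of the synapse-neuron chain, f_out = Q(f_in), is
sampled by Monte-Carlo simulation and summarized by a logistic fit

    Q(f) = floor + L / (1 + exp(-(f - x0) / s)).

Closed-loop steady states are the fixed points of the one-dimensional rate
map f = f0 + k_N * Q(f); a fixed point f* is stable iff k_N * Q'(f*) < 1
(the standard cobweb slope condition). Bistability of the full stochastic
loop is probed empirically by dual-initialization scans, and hysteresis by
warm-started up/down parameter sweeps.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import SimulationConfig
from .engine import run_open_loop
from .errors import ComparisonError, FitError, InvalidParameterError
from .network import StimulusWindow, run_closed_loop

__all__ = [
    "IOCurve",
    "QParams",
    "SteadyState",
    "SteadyStateSet",
    "BifurcationDiagram",
    "HysteresisResult",
    "scan_io_curve",
    "fit_logistic",
    "compare_conditions",
    "steady_states",
    "bifurcation_scan",
    "hysteresis_scan",
    "presyn_suppression_curve",
]


# ---------------------------------------------------------------------------
# Open-loop IO curve
# ---------------------------------------------------------------------------

@dataclass
class IOCurve:
    """Sampled (f_in, f_out) relation with per-seed replicates.

    ``f_out`` has shape (n_grid, n_seeds); replicate j of every grid point
    shares the same event-stream substream across conditions, so curves
    measured at the same global seed are pairwise comparable.
    """

    f_in: np.ndarray  # kHz, shape (n_grid,)
    f_out: np.ndarray  # kHz, shape (n_grid, n_seeds)
    seeds: np.ndarray  # global seeds per replicate
    gamma1: float
    gamma2: float

    @property
    def mean(self) -> np.ndarray:
        return self.f_out.mean(axis=1)

    @property
    def se(self) -> np.ndarray:
        n = self.f_out.shape[1]
        return self.f_out.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(self.f_in))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "f_in_khz": self.f_in, "f_out_mean_khz": self.mean,
            "f_out_se_khz": self.se, "n_seeds": self.f_out.shape[1],
            "gamma1": self.gamma1, "gamma2": self.gamma2,
        })


def scan_io_curve(f_in_grid, reps: int, cfg: SimulationConfig,
                  seed: int | None = None,
                  duration: float | None = None) -> IOCurve:
    """Measure the open-loop IO curve over a grid of input rates.

    Each grid point is simulated ``reps`` times with replicate-specific
    seeds derived from the base seed; the recorded f_out is the mean
    post-transient rate of each run.
    """
    f_in_grid = np.asarray(f_in_grid, dtype=float)
    if f_in_grid.size == 0 or reps < 1:
        raise InvalidParameterError("need a nonempty grid and reps >= 1")
    seed = cfg.seed if seed is None else seed
    out = np.empty((f_in_grid.size, reps))
    seeds = np.array([seed + 1000 * r for r in range(reps)])
    for i, f_in in enumerate(f_in_grid):
        for r, s in enumerate(seeds):
            res = run_open_loop(cfg, f_in, seed=int(s) + i, duration=duration)
            out[i, r] = res.f_out
    return IOCurve(f_in=f_in_grid, f_out=out, seeds=seeds,
                   gamma1=cfg.astrocyte.gamma1 if cfg.astrocyte.enabled else 0.0,
                   gamma2=cfg.astrocyte.gamma2 if cfg.astrocyte.enabled else 0.0)


# ---------------------------------------------------------------------------
# Logistic transfer fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QParams:
    """Logistic transfer Q(f) = floor + L/(1+exp(-(f-x0)/s))."""

    L: float  # ceiling, kHz
    x0: float  # midpoint, kHz
    s: float  # slope scale, kHz
    floor: float = 0.0  # offset, kHz
    residual_rms: float = np.nan

    def __call__(self, f: np.ndarray | float) -> np.ndarray | float:
        f = np.asarray(f, dtype=float)
        out = self.floor + self.L / (1.0 + np.exp(-(f - self.x0) / self.s))
        return out if out.ndim else float(out)

    def derivative(self, f: np.ndarray | float) -> np.ndarray | float:
        f = np.asarray(f, dtype=float)
        e = np.exp(-(f - self.x0) / self.s)
        out = self.L * e / (self.s * (1.0 + e) ** 2)
        return out if out.ndim else float(out)


def _logistic(f, L, x0, s, floor):
    return floor + L / (1.0 + np.exp(-(f - x0) / s))


def fit_logistic(curve: IOCurve | tuple[np.ndarray, np.ndarray]) -> QParams:
    """Least-squares logistic fit of an IO curve.

    Requires >= 5 distinct input rates with points on both sides of the
    half-maximum. Degenerate (flat) data raise :class:`FitError`.
    """
    if isinstance(curve, IOCurve):
        x, y = curve.f_in, curve.mean
    else:
        x, y = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if np.unique(x).size < 5:
        raise FitError("need >= 5 distinct f_in points for a logistic fit")
    span = float(y.max() - y.min())
    if span <= 0 or not np.isfinite(span):
        raise FitError(f"degenerate IO data: f_out span={span}")
    half = y.min() + 0.5 * span
    below, above = np.sum(y < half), np.sum(y > half)
    if below == 0 or above == 0:
        raise FitError("data do not span the half-maximum; widen the f_in grid")
    x0_guess = float(np.interp(half, y, x)) if np.all(np.diff(y) >= 0) else float(
        x[np.argmin(np.abs(y - half))])
    p0 = (span, x0_guess, max((x.max() - x.min()) / 10.0, 1e-4), float(y.min()))
    try:
        popt, _ = optimize.curve_fit(
            _logistic, x, y, p0=p0, maxfev=20_000,
            bounds=([1e-9, x.min() - (x.max() - x.min()), 1e-6, -0.5 * span],
                    [10.0 * span + 1e-6, x.max() + (x.max() - x.min()), x.max() - x.min() + 1e-3,
                     y.max()]),
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    resid = y - _logistic(x, *popt)
    return QParams(L=float(popt[0]), x0=float(popt[1]), s=float(popt[2]),
                   floor=float(popt[3]),
                   residual_rms=float(np.sqrt(np.mean(resid**2))))


# ---------------------------------------------------------------------------
# Condition comparison (astrocytic modulation signature)
# ---------------------------------------------------------------------------

def compare_conditions(control: IOCurve, modulated: IOCurve,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Pointwise paired comparison of two IO curves on shared seeds.

    Returns a frame with the mean difference delta = modulated - control, its
    SE, the paired-t p-value and a label in {depressed, potentiated,
    unchanged} at significance ``alpha``.
    """
    if control.f_in.shape != modulated.f_in.shape or not np.allclose(
            control.f_in, modulated.f_in):
        raise ComparisonError("f_in grids differ between conditions")
    if not np.array_equal(control.seeds, modulated.seeds):
        raise ComparisonError("seed sets differ between conditions; pairing is invalid")
    diff = modulated.f_out - control.f_out
    n = diff.shape[1]
    mean = diff.mean(axis=1)
    se = diff.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(mean), np.nan)
    pvals = np.empty(len(mean))
    for i in range(len(mean)):
        d = diff[i]
        if np.allclose(d, d[0]):
            # Identical replicates (e.g. both conditions truly inert).
            pvals[i] = 0.0 if d[0] != 0 else 1.0
        else:
            pvals[i] = stats.ttest_rel(modulated.f_out[i], control.f_out[i]).pvalue
    label = np.where(pvals >= alpha, "unchanged",
                     np.where(mean < 0, "depressed", "potentiated"))
    return pd.DataFrame({
        "f_in_khz": control.f_in, "delta_f_out_khz": mean, "se_khz": se,
        "p_value": pvals, "label": label,
    })


# ---------------------------------------------------------------------------
# Steady states of the rate map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyState:
    f: float  # kHz
    stable: bool
    slope: float  # k_N * Q'(f*)


@dataclass(frozen=True)
class SteadyStateSet:
    """Fixed points of f = f0 + k_N*Q(f) with stability and regime label."""

    points: tuple[SteadyState, ...]
    k_n: float
    f0: float
    q_mid: float  # transfer-curve midpoint x0, used to label low vs high

    @property
    def stable_points(self) -> tuple[SteadyState, ...]:
        return tuple(p for p in self.points if p.stable)

    @property
    def regime(self) -> str:
        ns = len(self.stable_points)
        if ns >= 2:
            return "bistable"
        f = self.stable_points[0].f if ns else self.points[0].f
        return "low" if f < self.q_mid else "high"


def steady_states(q: QParams, k_n: float, f0: float,
                  f_upper: float | None = None, n_grid: int = 4000) -> SteadyStateSet:
    """All fixed points of the rate map on [0, f_upper], with stability.

    Roots of g(f) = f0 + k_N*Q(f) - f are bracketed on a dense grid and
    polished by bisection to |g| < 1e-9; f* is stable iff k_N*Q'(f*) < 1.
    For a bounded Q at least one root exists.
    """
    if k_n < 0:
        raise InvalidParameterError("k_n must be >= 0")
    if f_upper is None:
        f_upper = f0 + k_n * (q.floor + q.L) + 0.05

    def g(f: float) -> float:
        return f0 + k_n * q(f) - f

    grid = np.linspace(0.0, f_upper, n_grid)
    vals = g(grid)
    roots: list[float] = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(float(optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    # Deduplicate near-identical roots.
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 1e-7 * max(f_upper, 1.0):
            uniq.append(r)
    assert uniq, "bounded transfer curve must yield at least one fixed point"
    pts = tuple(
        SteadyState(f=r, stable=bool(k_n * q.derivative(r) < 1.0),
                    slope=float(k_n * q.derivative(r)))
        for r in uniq
    )
    return SteadyStateSet(points=pts, k_n=k_n, f0=f0, q_mid=q.x0)


# ---------------------------------------------------------------------------
# Bifurcation / hysteresis scans
# ---------------------------------------------------------------------------

_SCANNABLE = {"k_n", "delta_f0", "gamma1", "gamma2"}


def _apply_param(cfg: SimulationConfig, param: str, value: float) -> SimulationConfig:
    if param == "k_n":
        return cfg.with_overrides({"network": {"k_n": float(value)}})
    if param == "delta_f0":
        return cfg.with_overrides({"network": {"f0": float(cfg.network.f0 + value)}})
    if param in ("gamma1", "gamma2"):
        return cfg.with_overrides({"astrocyte": {param: float(value)}})
    raise InvalidParameterError(f"unknown scan parameter {param!r}; valid: {_SCANNABLE}")


@dataclass
class BifurcationDiagram:
    """Converged closed-loop rates vs a scanned parameter, per initialization."""

    param: str
    grid: np.ndarray
    low_rates: np.ndarray  # shape (n_grid, n_seeds), from the low f_init
    high_rates: np.ndarray  # shape (n_grid, n_seeds), from the high f_init
    bistable: np.ndarray  # bool per grid point
    interval: tuple[float, float] | None  # first/last bistable grid value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.param: self.grid,
            "rate_low_init_khz": self.low_rates.mean(axis=1),
            "rate_high_init_khz": self.high_rates.mean(axis=1),
            "bistable": self.bistable,
        })

    @property
    def interval_width(self) -> float:
        return 0.0 if self.interval is None else self.interval[1] - self.interval[0]


def bifurcation_scan(param: str, grid, cfg: SimulationConfig, seeds,
                     f_init_low: float = 0.0, f_init_high: float | None = None,
                     duration: float | None = None,
                     bistable_frac: float = 0.2) -> BifurcationDiagram:
    """Dual-initialization scan of the closed loop over one parameter.

    For every grid value the loop is run from a low and a high initial
    feedback rate for each seed; a point is flagged bistable when the two
    converged rates differ by more than ``bistable_frac`` of the observed
    dynamic range of the whole scan.
    """
    grid = np.asarray(grid, dtype=float)
    seeds = np.asarray(seeds, dtype=int)
    if seeds.size < 2:
        raise InvalidParameterError("need >= 2 seeds per grid point")
    if f_init_high is None:
        f_init_high = cfg.network.f_max / 2.0
    low = np.empty((grid.size, seeds.size))
    high = np.empty((grid.size, seeds.size))
    for i, val in enumerate(grid):
        cfg_i = _apply_param(cfg, param, val)
        for j, s in enumerate(seeds):
            low[i, j] = run_closed_loop(cfg_i, f_init=f_init_low, seed=int(s),
                                        duration=duration).converged_rate
            high[i, j] = run_closed_loop(cfg_i, f_init=f_init_high, seed=int(s) + 7919,
                                         duration=duration).converged_rate
    all_rates = np.concatenate([low.ravel(), high.ravel()])
    dyn_range = float(all_rates.max() - all_rates.min())
    gap = np.abs(high.mean(axis=1) - low.mean(axis=1))
    bistable = gap > bistable_frac * max(dyn_range, 1e-12)
    idx = np.flatnonzero(bistable)
    interval = (float(grid[idx[0]]), float(grid[idx[-1]])) if idx.size else None
    return BifurcationDiagram(param=param, grid=grid, low_rates=low,
                              high_rates=high, bistable=bistable, interval=interval)


@dataclass
class HysteresisResult:
    """Warm-started up/down sweep of a parameter through a bistable window."""

    param: str
    grid: np.ndarray
    up_rates: np.ndarray  # rates along the increasing sweep
    down_rates: np.ndarray  # rates along the decreasing sweep (same grid order)
    up_threshold: float | None  # grid value of the low->high jump (up sweep)
    down_threshold: float | None  # grid value of the high->low jump (down sweep)

    @property
    def hysteretic(self) -> bool:
        if self.up_threshold is None or self.down_threshold is None:
            return False
        return self.up_threshold != self.down_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.param: self.grid, "rate_up_khz": self.up_rates,
                             "rate_down_khz": self.down_rates})


def _largest_jump(grid: np.ndarray, rates: np.ndarray) -> tuple[float | None, float]:
    jumps = np.abs(np.diff(rates))
    if jumps.size == 0 or jumps.max() <= 0:
        return None, 0.0
    k = int(np.argmax(jumps))
    return float(grid[k + 1]), float(jumps[k])


def hysteresis_scan(param: str, grid, cfg: SimulationConfig, seed: int,
                    duration: float | None = None, jump_frac: float = 0.4,
                    f_init_high: float = 0.5) -> HysteresisResult:
    """Sweep a parameter up then down, warm-starting from the last attractor.

    The initial feedback rate of each run is the converged input rate of the
    previous grid point, so the loop tracks its current attractor branch and
    jumps only at a fold (saddle-node) of the underlying rate map. A
    threshold is reported only if the largest jump exceeds ``jump_frac`` of
    the sweep's dynamic range.
    """
    grid = np.asarray(grid, dtype=float)
    rates = {"up": np.empty(grid.size), "down": np.empty(grid.size)}
    for direction, order in (("up", range(grid.size)),
                             ("down", range(grid.size - 1, -1, -1))):
        f_init = cfg.network.f_init if direction == "up" else f_init_high
        for count, i in enumerate(order):
            cfg_i = _apply_param(cfg, param, grid[i])
            res = run_closed_loop(cfg_i, f_init=f_init, seed=seed + 31 * count,
                                  duration=duration)
            rates[direction][i] = res.converged_rate
            # Warm start: next point begins at this attractor's input rate.
            f_init = float(res.f[-1]) if res.f.size else f_init
    dyn = float(max(rates["up"].max(), rates["down"].max())
                - min(rates["up"].min(), rates["down"].min()))
    up_thr, up_jump = _largest_jump(grid, rates["up"])
    down_thr, down_jump = _largest_jump(grid[::-1], rates["down"][::-1])
    if dyn <= 0 or up_jump < jump_frac * dyn:
        up_thr = None
    if dyn <= 0 or down_jump < jump_frac * dyn:
        down_thr = None
    return HysteresisResult(param=param, grid=grid, up_rates=rates["up"],
                            down_rates=rates["down"], up_threshold=up_thr,
                            down_threshold=down_thr)


def presyn_suppression_curve(gamma1_grid, cfg: SimulationConfig, seeds,
                             duration: float | None = None) -> pd.DataFrame:
    """Closed-loop converged rate vs presynaptic depression gain.

    ``gamma1_grid`` lies in [-1, 0]; the critical gain is the grid value with
    the largest rate drop between adjacent points (transition to the
    spontaneous, f0-driven firing level).
    """
    grid = np.asarray(gamma1_grid, dtype=float)
    if np.any(grid < -1) or np.any(grid > 0):
        raise InvalidParameterError("gamma1 grid must lie in [-1, 0]")
    seeds = np.asarray(seeds, dtype=int)
    rates = np.empty((grid.size, seeds.size))
    for i, g1 in enumerate(grid):
        cfg_i = _apply_param(cfg, "gamma1", g1)
        for j, s in enumerate(seeds):
            rates[i, j] = run_closed_loop(cfg_i, seed=int(s),
                                          duration=duration).converged_rate
    mean = rates.mean(axis=1)
    # Order by increasing depression strength (-gamma1).
    order = np.argsort(-grid)
    drops = -np.diff(mean[order])
    critical = float(grid[order][int(np.argmax(drops)) + 1]) if drops.size else np.nan
    df = pd.DataFrame({"gamma1": grid, "rate_khz": mean,
                       "rate_se_khz": rates.std(axis=1, ddof=1) / np.sqrt(seeds.size)})
    df.attrs["critical_gamma1"] = critical
    return df
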