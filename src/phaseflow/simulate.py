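"""Stochastic logistic growth (sLGE) ensemble simulation.

Euler–Maruyama integration of

    dx = [r x (1 - x/K) - H x] dt + sigma x dW        (noise on abundance)

or of the deterministic logistic update with a white-noise-perturbed
carrying capacity k_j = K + sigma K sqrt(dt) Z_j (noise on K).  H is a
"harvest" (dilution/defecation) rate; its stable equilibrium is
K (1 - H/r) for H < r and 0 otherwise.

The initial condition x(t0) = x0 is imposed at the start of the time grid,
so phase boundaries (measured in time-since-start coordinates, see
:mod:`phaseflow.logistic`) align with the grid after subtracting t0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .logistic import GrowthParams, GrowthPhase, PhaseBoundaries

__all__ = [
    "SLGEConfig",
    "TrajectoryEnsemble",
    "simulate_slge",
    "simulate_slge_stochastic_k",
    "equilibrium_with_harvest",
    "phase_window_correlation",
]

_FLOOR = 1e-12  # absorbing floor for abundances


@dataclass
class SLGEConfig:
    """Configuration of one sLGE ensemble.

    sigma is the noise magnitude, noise_target selects where the noise
    enters ("abundance" or "carrying_capacity"), harvest is the proportional
    removal rate H (0 disables), n_steps is the number of integration steps
    per unit time (dt = 1/n_steps), and n_iter the ensemble size.  A fixed
    seed makes the ensemble bit-reproducible; each iteration consumes an
    independent substream so changing n_iter does not reshuffle paths.
    """

    params: GrowthParams
    sigma: float = 0.1
    noise_target: str = "abundance"
    harvest: float = 0.0
    t0: float = 1.0
    t_final: float = 100.0
    n_steps: int = 100
    n_iter: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.harvest < 0:
            raise ValueError(f"harvest rate must be >= 0, got {self.harvest}")
        if not self.t0 < self.t_final:
            raise ValueError(f"need t0 < t_final, got [{self.t0}, {self.t_final}]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.noise_target not in ("abundance", "carrying_capacity"):
            raise ValueError(f"unknown noise_target {self.noise_target!r}")
        if self.params.r * self.dt > 0.5:
            raise ValueError(
                f"r*dt = {self.params.r * self.dt:.3g} > 0.5: the deterministic Euler step "
                "would overshoot; increase n_steps"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.n_steps


@dataclass
class TrajectoryEnsemble:
    """Simulated abundance paths on a shared time grid.

    ``abundances`` has shape (n_iter, n_times); ``deltas`` are the forward
    differences x(t_{j+1}) - x(t_j) (the simulation-side growth-rate proxy),
    with one fewer column.
    """

    times: np.ndarray
    abundances: np.ndarray
    config: SLGEConfig = field(repr=False, default=None)

    @property
    def deltas(self) -> np.ndarray:
        return np.diff(self.abundances, axis=1)

    @property
    def n_iter(self) -> int:
        return self.abundances.shape[0]

    def index_of(self, t: float) -> int:
        """Grid index closest to time ``t``."""
        return int(np.argmin(np.abs(self.times - t)))

    def thin(self, stride: int) -> "TrajectoryEnsemble":
        """Subsample the grid every ``stride`` points (e.g. to daily spacing)."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return TrajectoryEnsemble(
            times=self.times[::stride], abundances=self.abundances[:, ::stride], config=self.config
        )


def _grid(config: SLGEConfig) -> np.ndarray:
    n = int(round((config.t_final - config.t0) * config.n_steps))
    return config.t0 + np.arange(n + 1) * config.dt


def _noise_matrix(config: SLGEConfig, n_steps_total: int) -> np.ndarray:
    ss = np.random.SeedSequence(config.seed)
    rows = [np.random.default_rng(child).standard_normal(n_steps_total) for child in ss.spawn(config.n_iter)]
    return np.stack(rows)


def simulate_slge(config: SLGEConfig) -> TrajectoryEnsemble:
    """Euler–Maruyama ensemble with multiplicative noise on abundance (Itô).

    Update: x_{j+1} = x_j + [r x_j (1 - x_j/K) - H x_j] dt + sigma x_j sqrt(dt) Z_j,
    clamped at a floor of 1e-12 (absorbing at effective zero).
    """
    if config.noise_target != "abundance":
        raise ValueError("simulate_slge requires noise_target='abundance'")
    times = _grid(config)
    n_steps_total = len(times) - 1
    r, K, x0 = config.params.r, config.params.K, config.params.x0
    H, dt, sig = config.harvest, config.dt, config.sigma
    Z = _noise_matrix(config, n_steps_total)
    sqdt = math.sqrt(dt)
    x = np.full(config.n_iter, float(x0))
    out = np.empty((config.n_iter, n_steps_total + 1))
    out[:, 0] = x
    for j in range(n_steps_total):
        drift = r * x * (1.0 - x / K) - H * x
        x = x + drift * dt + sig * x * sqdt * Z[:, j]
        np.maximum(x, _FLOOR, out=x)
        out[:, j + 1] = x
    return TrajectoryEnsemble(times=times, abundances=out, config=config)


def simulate_slge_stochastic_k(config: SLGEConfig) -> TrajectoryEnsemble:
    """Deterministic logistic update with a white-noise-perturbed carrying capacity.

    At each step the effective capacity is k_j = K + sigma K sqrt(dt) Z_j
    (independent across steps, floored at 1e-6 K); the abundance update is
    the deterministic logistic (plus harvest) step with k_j, so sigma = 0
    reduces exactly to the deterministic Euler path.
    """
    if config.noise_target != "carrying_capacity":
        raise ValueError("simulate_slge_stochastic_k requires noise_target='carrying_capacity'")
    times = _grid(config)
    n_steps_total = len(times) - 1
    r, K, x0 = config.params.r, config.params.K, config.params.x0
    H, dt, sig = config.harvest, config.dt, config.sigma
    Z = _noise_matrix(config, n_steps_total)
    sqdt = math.sqrt(dt)
    x = np.full(config.n_iter, float(x0))
    out = np.empty((config.n_iter, n_steps_total + 1))
    out[:, 0] = x
    for j in range(n_steps_total):
        k = np.maximum(K + sig * K * sqdt * Z[:, j], 1e-6 * K)
        x = x + (r * x * (1.0 - x / k) - H * x) * dt
        np.maximum(x, _FLOOR, out=x)
        out[:, j + 1] = x
    return TrajectoryEnsemble(times=times, abundances=out, config=config)


def equilibrium_with_harvest(params: GrowthParams, H: float) -> float:
    """Stable steady state of logistic growth with proportional harvest.

    K (1 - H/r) when H < r; once the harvest rate meets the maximal growth
    rate the only non-negative stable point is extinction (0).
    """
    if H < 0:
        raise ValueError(f"harvest rate must be >= 0, got {H}")
    if H >= params.r:
        return 0.0
    return params.K * (1.0 - H / params.r)


def phase_window_correlation(
    ens: TrajectoryEnsemble,
    boundaries: PhaseBoundaries,
    phase: GrowthPhase,
    pooled: bool = False,
):
    """Pearson correlation between abundance and forward delta inside a phase window.

    Grid times are aligned to the boundaries' time origin by subtracting the
    first grid time.  For each iteration independently, the correlation is
    computed over grid points t_j inside the window (pairing x(t_j) with
    x(t_{j+1}) - x(t_j)); windows with fewer than 3 usable points yield NaN
    for that iteration rather than an exception.  With ``pooled=True`` the
    points of all iterations are pooled into a single correlation.
    """
    rel = ens.times - ens.times[0]
    lo, hi = boundaries.window(GrowthPhase(phase))
    mask = (rel >= lo) & (rel < hi)
    mask[-1] = False  # last grid point has no forward delta
    idx = np.nonzero(mask)[0]
    x = ens.abundances[:, idx]
    d = ens.abundances[:, idx + 1] - x
    if pooled:
        if idx.size * ens.n_iter < 3 or np.std(x) == 0:
            return float("nan")
        return float(sps.pearsonr(x.ravel(), d.ravel())[0])
    out = np.full(ens.n_iter, np.nan)
    if idx.size >= 3:
        for i in range(ens.n_iter):
            if np.std(x[i]) > 0 and np.std(d[i]) > 0:
                out[i] = sps.pearsonr(x[i], d[i])[0]
    return out
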