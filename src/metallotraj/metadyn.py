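"""Desk-scale well-tempered multiple-walkers metadynamics.

The engine reproduces the bookkeeping of enhanced-sampling runs -- bias
deposition, tempering, walker sharing, free-energy reconstruction -- on
toy potentials, with overdamped Langevin dynamics standing in for the
molecular integrator.  Energies are expressed in units of kB*T at the
schedule temperature, lengths in the collective variable's own unit.

Well-tempered deposition adds, every ``deposit_interval`` steps and for
every walker, a Gaussian of width sigma whose height is damped by
exp(-V(s)/kB*deltaT); the accumulated bias V(s) therefore converges, and
the free energy follows as F(s) = -(T+deltaT)/deltaT * V(s) (the
"well-tempered-rescaled" convention) or as the plain opposite of the
converged bias ("negative-bias").

"Altruistic" sharing: every walker deposits into a private copy of the
bias and the copies are merged into the shared sum at each
``exchange_interval``; the strict ``"shared"`` mode makes every deposit
visible to all walkers immediately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


@dataclass
class ToySystem:
    """A toy potential with a collective variable.

    ``potential`` maps configurations (n_walkers, dimension) to energies
    (n_walkers,) in kBT units; ``force`` returns -grad U with the same
    batching, or is None for a central-difference fallback.  ``cv`` maps
    configurations to the scalar collective variable; identity in the
    common 1D case.
    """

    dimension: int
    potential: Callable[[np.ndarray], np.ndarray]
    force: Callable[[np.ndarray], np.ndarray] | None = None
    cv: Callable[[np.ndarray], np.ndarray] | None = None
    cv_grad: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.cv is None:
            if self.dimension != 1:
                raise ValueError("cv required when dimension > 1")
            self.cv = lambda q: q[:, 0]
            self.cv_grad = lambda q: np.ones_like(q)

    def eval_force(self, q: np.ndarray, h: float = 1e-5) -> np.ndarray:
        if self.force is not None:
            return self.force(q)
        out = np.empty_like(q)
        for d in range(self.dimension):
            dq = np.zeros_like(q)
            dq[:, d] = h
            out[:, d] = -(self.potential(q + dq) - self.potential(q - dq)) / (2 * h)
        return out

    def eval_cv_grad(self, q: np.ndarray, h: float = 1e-5) -> np.ndarray:
        if self.cv_grad is not None:
            return self.cv_grad(q)
        out = np.empty_like(q)
        for d in range(self.dimension):
            dq = np.zeros_like(q)
            dq[:, d] = h
            out[:, d] = (self.cv(q + dq) - self.cv(q - dq)) / (2 * h)
        return out


@dataclass
class MetadSchedule:
    """Deposition / exchange schedule and integrator settings.

    ``temperature`` and ``delta_T`` are in kelvin; their ratio fixes the
    tempering (bias factor (T+deltaT)/deltaT).  ``steps_per_ps`` maps the
    physical deposition and exchange intervals of a production run onto
    integrator steps when one wants to mimic a physical clock.
    """

    w0: float = 0.5                 # initial Gaussian height, kBT
    sigma: float = 0.1              # Gaussian width, CV units
    deposit_interval: int = 100     # steps between deposits
    exchange_interval: int = 1000   # steps between bias synchronizations
    temperature: float = 300.0      # K
    delta_T: float = 2700.0         # K
    n_walkers: int = 8
    n_steps: int = 100_000          # per walker
    seed: int = 0
    dt: float = 0.002               # overdamped-Langevin step
    grid_min: float = -2.0
    grid_max: float = 2.0
    grid_spacing: float | None = None   # default sigma / 4
    wall_k: float = 200.0           # harmonic wall stiffness beyond the grid
    mode: str = "altruistic"        # or "shared"
    sample_interval: int | None = None  # default deposit_interval
    steps_per_ps: float | None = None

    def __post_init__(self):
        positive = {"w0": self.w0 + 1e-300, "sigma": self.sigma,
                    "deposit_interval": self.deposit_interval,
                    "exchange_interval": self.exchange_interval,
                    "temperature": self.temperature,
                    "n_walkers": self.n_walkers, "n_steps": self.n_steps,
                    "dt": self.dt}
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.w0 < 0:
            raise ValueError("w0 must be >= 0")
        if self.delta_T <= 0:
            raise ValueError("delta_T must be positive")
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be below grid_max")
        if self.mode not in ("altruistic", "shared"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def bias_factor(self) -> float:
        return bias_factor(self.temperature, self.delta_T)

    @property
    def spacing(self) -> float:
        return self.grid_spacing if self.grid_spacing else self.sigma / 4.0


def bias_factor(temperature: float, delta_T: float) -> float:
    """Well-tempered biasing factor (T + deltaT) / deltaT."""
    if temperature <= 0 or delta_T <= 0:
        raise ValueError("temperature and delta_T must be positive "
                         "(delta_T -> infinity recovers unbiased sampling)")
    return (temperature + delta_T) / delta_T


def wt_height(v_at_center: float, w0: float, temperature: float,
              delta_T: float) -> float:
    """Tempered deposition height w0 * exp(-V / kB*deltaT).

    ``v_at_center`` is the accumulated bias in kBT units at the walker's
    current CV value; the height decreases strictly with it.
    """
    v = np.asarray(v_at_center, dtype=float)
    if np.any(v < 0):
        raise ValueError("accumulated bias must be non-negative")
    return w0 * np.exp(-v * temperature / delta_T)


@dataclass
class BiasState:
    """Accumulated bias on a CV grid plus the exact kernel log."""

    grid: np.ndarray                # CV values
    values: np.ndarray              # V(s), kBT units, non-negative
    kernel_log: pd.DataFrame        # center, height, width, walker, step
    temperature: float
    delta_T: float
    wall_events: int = 0

    def interpolate(self, s) -> np.ndarray:
        return np.interp(s, self.grid, self.values)


@dataclass
class FreeEnergyProfile:
    grid: np.ndarray
    values: np.ndarray              # anchored so min F = 0
    convention: str                 # negative-bias | well-tempered-rescaled

    def at(self, s: float) -> float:
        if s < self.grid[0] or s > self.grid[-1]:
            raise ValueError(f"s = {s} outside the profile grid")
        return float(np.interp(s, self.grid, self.values))


def _gaussian_on_grid(grid: np.ndarray, center: float, height: float,
                      sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def run_metadynamics(system: ToySystem, schedule: MetadSchedule,
                     init_positions: np.ndarray | None = None,
                     ) -> tuple[BiasState, pd.DataFrame]:
    """Evolve the walkers and build the shared well-tempered bias.

    Returns the converged :class:`BiasState` and a tidy per-walker CV
    series (columns walker, step, s).  Runs with identical schedules and
    seeds are bitwise reproducible.
    """
    rng = np.random.default_rng(schedule.seed)
    nw, dim = schedule.n_walkers, system.dimension
    grid = np.arange(schedule.grid_min,
                     schedule.grid_max + schedule.spacing / 2, schedule.spacing)
    ng = len(grid)

    if init_positions is None:
        span = schedule.grid_max - schedule.grid_min
        s0 = schedule.grid_min + span * (np.arange(nw) + 0.5) / nw
        q = np.zeros((nw, dim))
        q[:, 0] = s0
    else:
        q = np.array(init_positions, dtype=float).reshape(nw, dim)

    v_shared = np.zeros(ng)
    v_local = np.tile(v_shared, (nw, 1))          # per-walker view of the bias
    snapshot = v_shared.copy()
    dv_local = np.zeros((nw, ng))                 # dV/ds per walker
    kernel_rows: list[tuple] = []
    wall_events = 0
    sample_every = schedule.sample_interval or schedule.deposit_interval
    samples_walker: list[np.ndarray] = []
    samples_step: list[int] = []
    samples_s: list[np.ndarray] = []
    sqrt2dt = np.sqrt(2.0 * schedule.dt)
    walker_ids = np.arange(nw)
    temp_ratio = schedule.temperature / schedule.delta_T

    def bias_force_on(s: np.ndarray) -> np.ndarray:
        pos = np.clip((s - grid[0]) / schedule.spacing, 0, ng - 1)
        j = np.minimum(pos.astype(int), ng - 2)
        frac = pos - j
        dv = dv_local[walker_ids, j] * (1 - frac) + dv_local[walker_ids, j + 1] * frac
        return -dv

    def recompute_gradients() -> None:
        dv_local[:] = np.gradient(v_local, schedule.spacing, axis=1)

    for step in range(1, schedule.n_steps + 1):
        f_sys = system.eval_force(q)
        s = system.cv(q)
        fb = bias_force_on(s)[:, None] * system.eval_cv_grad(q)
        # restraining walls keep walkers on the grid
        f_wall = np.zeros_like(q)
        below = q[:, 0] < schedule.grid_min
        above = q[:, 0] > schedule.grid_max
        if below.any() or above.any():
            wall_events += int(below.sum() + above.sum())
            f_wall[below, 0] = -schedule.wall_k * (q[below, 0] - schedule.grid_min)
            f_wall[above, 0] = -schedule.wall_k * (q[above, 0] - schedule.grid_max)
        noise = rng.standard_normal((nw, dim))
        q = q + (f_sys + fb + f_wall) * schedule.dt + sqrt2dt * noise

        if step % schedule.deposit_interval == 0:
            if not np.all(np.isfinite(q)):
                bad = int(np.nonzero(~np.isfinite(q).all(axis=1))[0][0])
                raise FloatingPointError(
                    f"non-finite configuration for walker {bad} at step {step}")
            s = system.cv(q)
            if schedule.w0 > 0:
                centers = np.clip(s, grid[0], grid[-1])
                v_here = v_local[walker_ids,
                                 np.argmin(np.abs(grid[None, :] - centers[:, None]),
                                           axis=1)]
                heights = schedule.w0 * np.exp(-v_here * temp_ratio)
                if schedule.mode == "shared":
                    for wlk in range(nw):
                        v_here_w = float(np.interp(centers[wlk], grid, v_shared))
                        h = schedule.w0 * np.exp(-v_here_w * temp_ratio)
                        v_shared += _gaussian_on_grid(grid, centers[wlk], h,
                                                      schedule.sigma)
                        kernel_rows.append((centers[wlk], h, schedule.sigma,
                                            wlk, step))
                    v_local[:] = v_shared
                else:
                    for wlk in range(nw):
                        v_local[wlk] += _gaussian_on_grid(
                            grid, centers[wlk], heights[wlk], schedule.sigma)
                        kernel_rows.append((centers[wlk], float(heights[wlk]),
                                            schedule.sigma, wlk, step))
                recompute_gradients()
        if step % sample_every == 0:
            samples_walker.append(walker_ids.copy())
            samples_step.append(step)
            samples_s.append(system.cv(q).copy())
        if schedule.mode == "altruistic" and \
                step % schedule.exchange_interval == 0 and schedule.w0 > 0:
            v_shared = snapshot + (v_local - snapshot[None, :]).sum(axis=0)
            v_local[:] = v_shared
            snapshot = v_shared.copy()
            recompute_gradients()

    if schedule.mode == "altruistic" and schedule.w0 > 0:
        v_shared = snapshot + (v_local - snapshot[None, :]).sum(axis=0)

    log = pd.DataFrame(kernel_rows,
                       columns=["center", "height", "width", "walker", "step"])
    samples = pd.DataFrame({
        "walker": np.concatenate(samples_walker) if samples_walker else [],
        "step": np.repeat(samples_step, nw) if samples_step else [],
        "s": np.concatenate(samples_s) if samples_s else [],
    })
    bias = BiasState(grid=grid, values=v_shared, kernel_log=log,
                     temperature=schedule.temperature,
                     delta_T=schedule.delta_T, wall_events=wall_events)
    return bias, samples


def free_energy_from_bias(bias: BiasState,
                          convention: str = "well-tempered-rescaled",
                          temperature: float | None = None,
                          delta_T: float | None = None) -> FreeEnergyProfile:
    """Free-energy profile from an accumulated bias, anchored to min 0.

    ``negative-bias``: F = -V, the plain opposite of the converged bias.
    ``well-tempered-rescaled``: F = -(T+deltaT)/deltaT * V, the standard
    well-tempered estimator (equal to -gamma/(gamma-1) * V for the
    bias-factor convention gamma = (T+deltaT)/T).
    """
    temperature = bias.temperature if temperature is None else temperature
    delta_T = bias.delta_T if delta_T is None else delta_T
    if convention == "negative-bias":
        f = -bias.values
    elif convention == "well-tempered-rescaled":
        f = -bias_factor(temperature, delta_T) * bias.values
    else:
        raise ValueError(f"unknown free-energy convention {convention!r}")
    f = f - f.min()
    return FreeEnergyProfile(bias.grid.copy(), f, convention)


def barrier_work(profile: FreeEnergyProfile, s_from: float, s_to: float) -> float:
    """Free-energy difference F(s_to) - F(s_from) along the profile."""
    return profile.at(s_to) - profile.at(s_from)


def basin_free_energy_difference(profile: FreeEnergyProfile,
                                 split: float) -> float:
    """Delta F (kBT) between the basins right and left of ``split``.

    Computed from basin partition functions: -ln(Z_right / Z_left) with
    Z = integral of exp(-F) over the basin, trapezoidal on the grid.
    """
    s, f = profile.grid, profile.values
    left = s <= split
    right = ~left
    if not left.any() or not right.any():
        raise ValueError("split point must lie inside the grid")
    z_left = np.trapezoid(np.exp(-f[left]), s[left])
    z_right = np.trapezoid(np.exp(-f[right]), s[right])
    return float(-np.log(z_right / z_left))
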