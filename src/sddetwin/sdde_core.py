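"""Generic numerical machinery for stochastic delay differential equations.

A stochastic delay differential equation (SDDE) couples the instantaneous
state X(t) to past states X(t - tau) in both the drift and the diffusion:

    dX(t) = f(t, X(t), X(t - tau_1), ..., X(t - tau_m)) dt
          + g(t, X(t - tau_1), ..., X(t - tau_m)) o dW(t)

where dW is a vector of independent Wiener increments (one channel per
state component) and ``o`` denotes the component-wise product. The module
provides:

* :class:`TimeGrid` — a fixed uniform grid; delays are represented as
  integer step counts on this grid (discrete indexing, no interpolation).
* :class:`HistoryBuffer` — stored past states plus a constant pre-history
  vector that answers every lookup before the grid start.
* :func:`integrate_sdde` — an Euler–Maruyama scheme adapted for delays:
  at each step the delayed states are read from the buffer, the drift and
  diffusion are evaluated, a Gaussian increment of variance dt is applied
  per component, and the new state is clipped at zero (states here are
  concentrations/counts, which cannot go negative).

Randomness is fully deterministic given an integer seed: each state
component draws from its own stream spawned as
``SeedSequence(seed, spawn_key=(component,))``, so a single trajectory is
reproducible in isolation and streams never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TimeGrid",
    "HistoryBuffer",
    "SDDESystem",
    "Trajectory",
    "SDDEError",
    "GridError",
    "InvalidLagError",
    "LookupAheadError",
    "NumericalDivergenceError",
    "delay_to_steps",
    "lookup_delayed",
    "integrate_sdde",
    "component_noise",
]


class SDDEError(Exception):
    """Base class for errors raised by the SDDE machinery."""


class GridError(SDDEError, ValueError):
    """Invalid time grid (non-positive dt, inconsistent step count...)."""


class InvalidLagError(SDDEError, ValueError):
    """A delay was negative or not representable on the grid."""


class LookupAheadError(SDDEError, ValueError):
    """A delayed lookup asked for a state beyond the filled history."""


class NumericalDivergenceError(SDDEError, ArithmeticError):
    """Drift or diffusion returned a non-finite value during integration."""


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid [t0, t_end] with step dt (abstract time units)."""

    t0: float = 0.0
    t_end: float = 100.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise GridError(f"dt must be positive, got {self.dt}")
        if self.t_end <= self.t0:
            raise GridError(f"t_end ({self.t_end}) must exceed t0 ({self.t0})")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t0) / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)

    def index_of(self, t: float) -> int:
        """Grid index of time t (must lie on the grid up to rounding)."""
        i = int(round((t - self.t0) / self.dt))
        if abs(self.t0 + i * self.dt - t) > 1e-9 * max(1.0, abs(t)):
            raise GridError(f"t={t} is not a point of the grid (dt={self.dt})")
        return i


def delay_to_steps(tau: float, dt: float) -> int:
    """Convert a lag to an integer step count: round(tau/dt), half away from zero."""
    if tau < 0:
        raise InvalidLagError(f"negative lag: {tau}")
    return int(math.floor(tau / dt + 0.5))


@dataclass
class HistoryBuffer:
    """Past states on a grid plus a constant pre-history for t < t0.

    ``states`` holds one state vector per grid point filled so far;
    ``pre_history`` is the constant initial history function answering any
    lookup that reaches before the grid start.
    """

    grid: TimeGrid
    pre_history: np.ndarray
    states: np.ndarray = field(default=None)  # (n_steps+1, dim), filled up to fill_index
    fill_index: int = -1

    def __post_init__(self) -> None:
        self.pre_history = np.asarray(self.pre_history, dtype=float)
        if self.states is None:
            self.states = np.empty((self.grid.n_steps + 1, self.pre_history.size))

    def append(self, state: np.ndarray) -> None:
        self.fill_index += 1
        self.states[self.fill_index] = state

    def lookup_index(self, i: int) -> np.ndarray:
        """State at grid index i; indices before the grid return pre_history."""
        if i < 0:
            return self.pre_history
        if i > self.fill_index:
            raise LookupAheadError(
                f"lookup at index {i} but history filled only to {self.fill_index}"
            )
        return self.states[i]


def lookup_delayed(buffer: HistoryBuffer, t: float, tau: float) -> np.ndarray:
    """Delayed state X(t - tau) by discrete indexing on the buffer's grid.

    The lag is converted to a step count with round-half-away-from-zero;
    an index before the grid start returns the pre-history vector exactly.
    """
    if tau < 0:
        raise InvalidLagError(f"negative lag: {tau}")
    i = buffer.grid.index_of(t)
    if i > buffer.fill_index:
        raise LookupAheadError(
            f"t={t} (index {i}) is beyond the filled history ({buffer.fill_index})"
        )
    return buffer.lookup_index(i - delay_to_steps(tau, buffer.grid.dt))


DriftFn = Callable[[float, np.ndarray, Sequence[np.ndarray]], np.ndarray]
DiffusionFn = Callable[[float, Sequence[np.ndarray]], np.ndarray]


@dataclass(frozen=True)
class SDDESystem:
    """An SDDE specified by its drift, diffusion and the lags they read.

    ``drift(t, x, delayed)`` and ``diffusion(t, delayed)`` receive the list
    of delayed state vectors in the order of ``delays``; the diffusion sees
    only delayed states (delayed multiplicative noise).
    """

    state_dim: int
    delays: tuple
    drift: DriftFn
    diffusion: DiffusionFn

    def __post_init__(self) -> None:
        object.__setattr__(self, "delays", tuple(float(d) for d in self.delays))
        for d in self.delays:
            if d < 0:
                raise InvalidLagError(f"negative lag in system: {d}")


@dataclass(frozen=True)
class Trajectory:
    """One subject's simulated paths on a grid, with the seed that made them."""

    grid: TimeGrid
    times: np.ndarray
    states: np.ndarray  # (n_steps+1, state_dim)
    seed: int
    subject_id: int = 0

    def component(self, k: int) -> np.ndarray:
        return self.states[:, k]


def component_noise(seed: int, n_steps: int, state_dim: int, dt: float) -> np.ndarray:
    """Wiener increments, shape (n_steps, state_dim), variance dt per entry.

    Component k draws from the stream SeedSequence(seed, spawn_key=(k,)),
    so any component's noise is reproducible independently of the others.
    """
    sqrt_dt = math.sqrt(dt)
    out = np.empty((n_steps, state_dim))
    for k in range(state_dim):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        out[:, k] = rng.standard_normal(n_steps) * sqrt_dt
    return out


def integrate_sdde(
    system: SDDESystem,
    pre_history: np.ndarray,
    grid: TimeGrid,
    seed: int,
    subject_id: int = 0,
    noise: np.ndarray | None = None,
) -> Trajectory:
    """Euler–Maruyama integration of an SDDE with constant pre-history.

    The state at t0 is the pre-history vector; each step applies

        X(t+dt) = max(0, X(t) + f dt + g o dW)

    with dW ~ N(0, dt) independently per component (``noise`` may supply the
    increments explicitly, e.g. for cross-checking another integrator).
    Raises :class:`NumericalDivergenceError` naming the step if drift or
    diffusion go non-finite.
    """
    pre_history = np.asarray(pre_history, dtype=float)
    if not np.all(np.isfinite(pre_history)):
        raise NumericalDivergenceError("pre_history contains non-finite values")
    for d in system.delays:
        if d != 0.0 and d < grid.dt:
            raise InvalidLagError(f"lag {d} is smaller than dt={grid.dt}")

    n = grid.n_steps
    dim = system.state_dim
    lag_steps = [delay_to_steps(d, grid.dt) for d in system.delays]
    if noise is None:
        noise = component_noise(seed, n, dim, grid.dt)

    buf = HistoryBuffer(grid=grid, pre_history=pre_history)
    buf.append(pre_history.copy())
    times = grid.times
    for i in range(n):
        t = times[i]
        x = buf.states[i]
        delayed = [buf.lookup_index(i - L) for L in lag_steps]
        f = np.asarray(system.drift(t, x, delayed), dtype=float)
        g = np.asarray(system.diffusion(t, delayed), dtype=float)
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(g))):
            raise NumericalDivergenceError(
                f"non-finite drift/diffusion at step {i} (t={t:.6g})"
            )
        x_new = x + f * grid.dt + g * noise[i]
        np.maximum(x_new, 0.0, out=x_new)
        buf.append(x_new)

    return Trajectory(
        grid=grid, times=times, states=buf.states, seed=int(seed), subject_id=subject_id
    )
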