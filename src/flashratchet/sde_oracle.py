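"""Euler–Maruyama Monte-Carlo simulation of the (flashing) ratchet SDE.

The continuous processes obey dX = dB + mu(X) dt (ratchet) and
dY = dB + eta(t) mu(Y) dt (flashing, with eta switching the drift off for
tau1 then on for tau2).  This module simulates them with an explicit
Euler–Maruyama scheme — drift and switching state evaluated at the left
endpoint of each step — as an independent stochastic cross-check of the
exact lattice propagation and of the closed-form equilibrium density.

All randomness flows through a single named generator seeded explicitly;
there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .ratchet_model import FlashingSchedule, RatchetParams, drift_value

__all__ = ["SimConfig", "simulate_flashing", "simulate_ratchet_wrapped"]


@dataclass(frozen=True)
class SimConfig:
    """Euler–Maruyama discretization: step dt, path count, seed, horizon."""

    dt: float
    n_paths: int
    seed: int
    t_end: float

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.n_paths < 1:
            raise ValueError("n_paths must be a positive integer")

    @property
    def n_steps(self) -> int:
        k = round(self.t_end / self.dt)
        if abs(k * self.dt - self.t_end) > 1e-9 * max(1.0, self.t_end):
            raise ValueError("t_end must be an integer multiple of dt")
        return int(k)


def _phase_step_counts(s: FlashingSchedule, dt: float) -> tuple[int, int]:
    """Steps per off/on phase; dt must divide tau1 and tau2 (within 1e-12)."""
    counts = []
    for tau in (s.tau1, s.tau2):
        k = round(float(tau) / dt)
        if abs(k * dt - float(tau)) > 1e-12:
            raise ValueError(f"dt={dt} must divide the flash duration {tau}")
        counts.append(int(k))
    return counts[0], counts[1]


def simulate_flashing(
    p: RatchetParams,
    s: FlashingSchedule,
    cfg: SimConfig,
    start: float = 0.0,
) -> np.ndarray:
    """Endpoints of n_paths Euler–Maruyama paths of the flashing ratchet.

    Whether the potential is on at a step is decided by integer step
    counting within the flash period (dt divides both durations exactly by
    precondition), never by floating-point time comparison, so no step is
    misclassified at a phase boundary.
    """
    k1, k2 = _phase_step_counts(s, cfg.dt)
    period_steps = k1 + k2
    rng = np.random.default_rng(cfg.seed)
    x = np.full(cfg.n_paths, float(start))
    sqdt = np.sqrt(cfg.dt)
    for k in range(cfg.n_steps):
        if (k % period_steps) >= k1:  # potential on
            x += drift_value(x, p) * cfg.dt
        x += sqdt * rng.standard_normal(cfg.n_paths)
    return x


def simulate_ratchet_wrapped(
    p: RatchetParams,
    cfg: SimConfig,
    bins: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint histogram of the always-on ratchet, wrapped onto [0, L).

    Paths start uniform on the circle and run to t_end (which should be
    large relative to L**2 so the law has relaxed); returns (bin_edges,
    bin_masses) with masses summing to one, comparable bin-by-bin with the
    integrated equilibrium density C*exp(-2*gamma*V).
    """
    rng = np.random.default_rng(cfg.seed)
    x = rng.uniform(0.0, p.L, size=cfg.n_paths)
    sqdt = np.sqrt(cfg.dt)
    for _ in range(cfg.n_steps):
        x += drift_value(x, p) * cfg.dt + sqdt * rng.standard_normal(cfg.n_paths)
    xw = np.mod(x, p.L)
    edges = np.linspace(0.0, p.L, bins + 1)
    counts, _ = np.histogram(xw, bins=edges)
    return edges, counts / counts.sum()
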