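"""Generalized capital-dependent Parrondo games.

Game A is a fair coin toss.  Game B is a nearest-neighbour random walk on the
integers whose up-probability depends on the current capital modulo an
integer period ``L_int``: it is ``p0`` on residues below ``l`` and ``p1``
otherwise, with ``alpha = l / L_int`` the shape of the underlying ratchet
potential.  Requiring the walk to admit a periodic reversible invariant
measure (detailed balance) forces

    (1 - p0)**l * (1 - p1)**(L - l) == p0**l * p1**(L - l),

which is solved by the one-parameter family

    p0 = rho**((1-alpha)/alpha) / (1 + rho**((1-alpha)/alpha)),
    p1 = 1 / (1 + rho),            0 < rho < 1.

Game B is asymptotically fair, yet random mixtures c*A + (1-c)*B and periodic
patterns A^r B^s (except r = s = 1) are winning when alpha < 1/2 — Parrondo's
paradox — and losing when alpha > 1/2 (the anti-Parrondo effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gcd

import numpy as np

__all__ = [
    "GameBSpec",
    "PeriodicWalkChain",
    "probs_from_rho",
    "game_b_invariant_profile",
    "cycle_stationary",
    "mean_profit",
    "mixture_mean_profit",
    "pattern_mean_profit",
]


def probs_from_rho(rho: float, l: int, L_int: int) -> tuple[float, float]:
    """Up-probabilities (p0, p1) of the fair game B at parameter rho.

    ``rho = 1`` is admitted as the degenerate symmetric boundary
    (p0 = p1 = 1/2).
    """
    if not (0 < l < L_int) or gcd(l, L_int) != 1:
        raise ValueError(f"need coprime 0 < l < L_int, got l={l}, L_int={L_int}")
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    e = (L_int - l) / l  # (1 - alpha) / alpha
    re = rho**e
    p0 = re / (1.0 + re)
    p1 = 1.0 / (1.0 + rho)
    return p0, p1


@dataclass(frozen=True)
class PeriodicWalkChain:
    """A nearest-neighbour walk on Z with residue-periodic up-probabilities.

    ``up_probs[j]`` is the probability of stepping +1 from any site congruent
    to ``j`` modulo ``len(up_probs)``.
    """

    up_probs: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.up_probs, dtype=float)
        if u.ndim != 1 or u.size < 2:
            raise ValueError("up_probs must be a vector of length >= 2")
        if np.any(u <= 0.0) or np.any(u >= 1.0):
            raise ValueError("up-probabilities must lie strictly in (0, 1)")
        object.__setattr__(self, "up_probs", u)

    @property
    def L_int(self) -> int:
        return self.up_probs.size


@dataclass(frozen=True)
class GameBSpec:
    """The fair game B at shape l/L_int and parameter rho in (0, 1]."""

    l: int
    L_int: int
    rho: float
    p0: float = field(init=False)
    p1: float = field(init=False)

    def __post_init__(self) -> None:
        p0, p1 = probs_from_rho(self.rho, self.l, self.L_int)
        if self.rho == 1.0:
            warnings.warn("rho=1 is the degenerate symmetric game", stacklevel=2)
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)

    @property
    def alpha(self) -> float:
        return self.l / self.L_int

    @property
    def chain(self) -> PeriodicWalkChain:
        u = np.where(np.arange(self.L_int) < self.l, self.p0, self.p1)
        return PeriodicWalkChain(u)


def game_b_invariant_profile(spec: GameBSpec) -> np.ndarray:
    """Reversible invariant profile of game B on residues {0, ..., L_int-1}.

    Closed form from the detailed-balance recursions: with
    e = (1-alpha)/alpha,

        pi(j) ∝ rho**(j*e)                                   for j < l,
        pi(j) ∝ rho**(l*e - (j-l+1)) * (1+rho)/(1+rho**e)    for j >= l,

    normalized to sum to one.
    """
    if spec.rho >= 1.0:
        raise ValueError("invariant profile requires rho < 1")
    L, l, rho = spec.L_int, spec.l, spec.rho
    e = (L - l) / l
    j = np.arange(L)
    pi = np.where(
        j < l,
        rho ** (j * e),
        rho ** (l * e - (j - l + 1)) * (1.0 + rho) / (1.0 + rho**e),
    )
    return pi / pi.sum()


def _cycle_matrix(up_probs: np.ndarray) -> np.ndarray:
    L = up_probs.size
    P = np.zeros((L, L))
    idx = np.arange(L)
    np.add.at(P, (idx, (idx + 1) % L), up_probs)
    np.add.at(P, (idx, (idx - 1) % L), 1.0 - up_probs)
    return P


def cycle_stationary(chain: PeriodicWalkChain | np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary law of the walk wrapped onto the cycle of its period.

    Solved directly from the linear system (P^T - I) pi = 0 with the
    normalization row appended (the period is tiny here, so a direct solve
    is exact to machine precision); the residual ||pi P - pi||_inf is checked
    against ``tol``.
    """
    u = chain.up_probs if isinstance(chain, PeriodicWalkChain) else np.asarray(chain, float)
    P = _cycle_matrix(u)
    L = u.size
    A = np.vstack([P.T - np.eye(L), np.ones(L)])
    b = np.zeros(L + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.max(np.abs(pi @ P - pi)))
    if not np.isfinite(residual) or residual > tol:
        raise np.linalg.LinAlgError(
            f"stationary solve failed: residual {residual:.3e} > tol {tol:.1e}"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def mean_profit(chain: PeriodicWalkChain | np.ndarray) -> float:
    """Long-run expected profit per play: sum_j pi(j) * (2*up(j) - 1)."""
    u = chain.up_probs if isinstance(chain, PeriodicWalkChain) else np.asarray(chain, float)
    pi = cycle_stationary(u)
    return float(pi @ (2.0 * u - 1.0))


def mixture_mean_profit(c: float, spec: GameBSpec) -> float:
    """Mean profit per play of the random mixture c*A + (1-c)*B.

    Each play is game A (fair coin) with probability c, game B otherwise;
    the resulting chain has up-probabilities c/2 + (1-c)*p_j.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError("mixing probability c must lie in [0, 1]")
    u = c * 0.5 + (1.0 - c) * spec.chain.up_probs
    return mean_profit(PeriodicWalkChain(u))


def pattern_mean_profit(r: int, s: int, spec: GameBSpec) -> float:
    """Mean profit per play of the deterministic periodic pattern A^r B^s.

    The pattern is analysed through the augmented Markov chain on
    (capital residue, phase) with phase k in {0, ..., r+s-1}: phases below r
    play A, the rest play B, and the phase advances cyclically each play.
    The profit is the stationary time-average of 2*u_k(j) - 1 over that
    chain (the phase marginal is uniform).
    """
    if r < 1 or s < 1:
        raise ValueError("pattern exponents r, s must be >= 1")
    L, T = spec.L_int, r + s
    ub = spec.chain.up_probs
    # u[k, j]: up-probability at phase k, residue j
    u = np.empty((T, L))
    u[:r, :] = 0.5
    u[r:, :] = ub[None, :]
    N = L * T
    P = np.zeros((N, N))
    for k in range(T):
        k2 = (k + 1) % T
        for j in range(L):
            i = k * L + j
            P[i, k2 * L + (j + 1) % L] += u[k, j]
            P[i, k2 * L + (j - 1) % L] += 1.0 - u[k, j]
    A = np.vstack([P.T - np.eye(N), np.ones(N)])
    b = np.zeros(N + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.max(np.abs(pi @ P - pi)))
    if residual > 1e-11:
        raise np.linalg.LinAlgError(f"pattern stationary solve residual {residual:.3e}")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return float(pi @ (2.0 * u.reshape(-1) - 1.0))
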