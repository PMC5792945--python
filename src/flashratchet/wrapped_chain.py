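"""Wrapped flashing walk on the circle and its stationary behaviour.

Because the step kernels are periodic with period n*L_int sites, the walk
reduced modulo n*L_int remains Markov.  Observing the wrapped walk once per
full flash period gives a finite Markov chain on nL sites whose transition
matrix is built here by propagating all start sites simultaneously through
the n**2*tau1 symmetric and n**2*tau2 ratchet steps of one period.  If nL
and the total step count are both even the chain is parity-trapped, so one
extra symmetric step is appended to make it irreducible; its unique
stationary law pi_bar approximates the stationary distribution of the
wrapped flashing Brownian ratchet sampled at period boundaries.

The headline statistic is the stationary mean displacement mu_bar: the
expected unwrapped displacement of the walk over one flash period when the
starting site is drawn from pi_bar.  Per-start expected displacements are
accumulated during the same propagation (only ratchet steps contribute in
expectation; symmetric steps are a martingale), always over the unmodified
period — the irreducibility step never enters the displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ratchet_model import FlashingSchedule, RatchetParams
from .walk_pmf import LatticePMF, rho_from_lambda
from .parrondo_games import probs_from_rho

__all__ = [
    "PeriodMatrix",
    "StationaryLaw",
    "wrap",
    "period_matrix",
    "stationary",
    "remap_to_unimodal",
    "stationary_mean_displacement",
]


@dataclass(frozen=True)
class PeriodMatrix:
    """One-flash-period transition matrix of the wrapped walk.

    ``matrix[i, j]`` is the probability of being at circle site j one flash
    period after starting at circle site i (plus one extra symmetric step
    when ``extra_step`` is set, the parity fix that makes the chain
    irreducible).  ``displacement[i]`` is the exact expected unwrapped
    displacement, in lattice units, of one full period (without the extra
    step) started at site i.
    """

    size: int
    matrix: np.ndarray
    extra_step: bool
    displacement: np.ndarray
    n: int
    steps: int  # number of steps the matrix propagates (incl. extra step)


@dataclass(frozen=True)
class StationaryLaw:
    """Stationary vector of a PeriodMatrix with its fixed-point residual."""

    pi_bar: np.ndarray
    residual: float


def wrap(pmf: LatticePMF, nL_int: int) -> np.ndarray:
    """Reduce a lattice pmf modulo nL_int onto the circle of nL_int sites."""
    if nL_int < 1:
        raise ValueError("circle size must be positive")
    return np.bincount(
        np.mod(pmf.sites, nL_int), weights=pmf.probs, minlength=nL_int
    )


def _sym_step_all(M: np.ndarray) -> np.ndarray:
    """One symmetric circular step applied to every row-distribution."""
    return 0.5 * (np.roll(M, 1, axis=1) + np.roll(M, -1, axis=1))


def period_matrix(n: int, p: RatchetParams, s: FlashingSchedule) -> PeriodMatrix:
    """Build the one-flash-period transition matrix on the nL-site circle.

    All nL start rows are propagated together: each step is a circular
    shift-add of the row matrix (deterministic summation order).  During the
    ratchet phase the per-row expected displacement increment
    E[2*u(site) - 1] is accumulated, yielding the exact K-step displacement
    vector alongside the matrix.
    """
    if not math.isclose(p.L, float(p.L_int), rel_tol=0, abs_tol=1e-12):
        raise ValueError(
            "lattice wrapping requires the real period L to equal L_int "
            f"(got L={p.L}, L_int={p.L_int})"
        )
    k1, k2 = s.step_counts(n)
    rho = rho_from_lambda(n, p.lam)
    p0, p1 = probs_from_rho(rho, p.l, p.L_int)
    N = n * p.L_int
    u = np.where(np.arange(N) < n * p.l, p0, p1)
    drift = 2.0 * u - 1.0
    um = u[None, :]
    dm = (1.0 - u)[None, :]

    M = np.eye(N)
    for _ in range(k1):
        M = _sym_step_all(M)
    d = np.zeros(N)
    for _ in range(k2):
        d += M @ drift
        M = np.roll(M * um, 1, axis=1) + np.roll(M * dm, -1, axis=1)
    extra = (N % 2 == 0) and ((k1 + k2) % 2 == 0)
    if extra:
        M = _sym_step_all(M)
    row_err = float(np.max(np.abs(M.sum(axis=1) - 1.0)))
    if row_err > 1e-12:
        raise ArithmeticError(f"row-stochasticity lost: max error {row_err:.3e}")
    return PeriodMatrix(
        size=N,
        matrix=M,
        extra_step=extra,
        displacement=d,
        n=n,
        steps=k1 + k2 + int(extra),
    )


def stationary(P: PeriodMatrix | np.ndarray, tol: float = 1e-12) -> StationaryLaw:
    """Stationary distribution pi_bar of the period chain.

    Direct null-space solve of (P^T - I) with the normalization row
    appended; tiny negative entries (down to -1e-14, solver noise) are
    clipped before renormalizing.  Raises if the fixed-point residual
    ||pi P - pi||_inf exceeds ``tol``.
    """
    M = P.matrix if isinstance(P, PeriodMatrix) else np.asarray(P, dtype=float)
    N = M.shape[0]
    A = np.vstack([M.T - np.eye(N), np.ones(N)])
    b = np.zeros(N + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if pi.min() < -1e-14:
        raise np.linalg.LinAlgError(
            f"stationary vector has negative mass {pi.min():.3e}"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = float(np.max(np.abs(pi @ M - pi)))
    if not np.isfinite(residual) or residual > tol:
        raise np.linalg.LinAlgError(
            f"stationary residual {residual:.3e} exceeds tolerance {tol:.1e}"
        )
    return StationaryLaw(pi_bar=pi, residual=residual)


def remap_to_unimodal(
    law: StationaryLaw, p: RatchetParams, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Shift circle positions x >= alpha*L by -L, mapping the support from
    [0, L) to [-(1-alpha)*L, alpha*L) so the stationary density is unimodal
    (peaked at the potential minimum 0) instead of U-shaped.

    Returns (positions, probabilities) sorted by position; mass unchanged.
    """
    N = law.pi_bar.size
    x = np.arange(N) / n
    aL = p.alpha * p.L
    x_new = np.where(x < aL, x, x - p.L)
    order = np.argsort(x_new)
    return x_new[order], law.pi_bar[order]


def stationary_mean_displacement(law: StationaryLaw, pm: PeriodMatrix) -> float:
    """mu_bar: expected one-period displacement (in scaled units) under the
    stationary start law — sum_i pi_bar(i) * displacement(i) / n."""
    if law.pi_bar.size != pm.size:
        raise ValueError("stationary law and period matrix sizes differ")
    return float(law.pi_bar @ pm.displacement) / pm.n
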