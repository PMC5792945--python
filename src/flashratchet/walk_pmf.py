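"""Exact distribution propagation for the approximating lattice walks.

The flashing Brownian ratchet is approximated by a nearest-neighbour random
walk on the integer lattice {i/n : i in Z}: during an off phase the walk is
simple symmetric; during an on phase its up-probability at site j is p0 when
mod(j, n*L_int) < n*l and p1 otherwise, with (p0, p1) from the fair-game
parametrization at rho = 1 - lambda/n.  Time is sped up so the walk makes
n**2 steps per unit of model time.

The probability mass function is propagated exactly (one shift-add update
per step, deterministic summation order), never sampled and never pruned:
the walk's distribution after k steps is held as a dense vector over its
full contiguous support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ratchet_model import FlashingSchedule, RatchetParams
from .parrondo_games import probs_from_rho

__all__ = [
    "LatticePMF",
    "SymmetricKernel",
    "RatchetKernel",
    "rho_from_lambda",
    "step",
    "evolve",
    "flash_evolve",
]

_MASS_TOL = 1e-12


@dataclass(frozen=True)
class LatticePMF:
    """Exact pmf of a lattice walk over a contiguous block of integer sites.

    ``probs[i]`` is the probability of site ``offset + i``; the scaled
    position of a site is ``site / n``.  Because each step moves exactly one
    site, mass started from a single site alternates parity: sites of the
    wrong parity carry exact zeros inside the stored block.
    """

    offset: int
    probs: np.ndarray
    n: int = 1
    steps_taken: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probs must be a nonempty vector")
        if np.any(p < 0.0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        if self.n < 1:
            raise ValueError("refinement n must be a positive integer")
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_point(cls, site: int, n: int = 1) -> "LatticePMF":
        return cls(offset=site, probs=np.array([1.0]), n=n, steps_taken=0)

    @property
    def sites(self) -> np.ndarray:
        return self.offset + np.arange(self.probs.size)

    @property
    def positions(self) -> np.ndarray:
        return self.sites / self.n

    @property
    def total_mass(self) -> float:
        return float(self.probs.sum())

    def mean_position(self) -> float:
        return float(self.positions @ self.probs)


class SymmetricKernel:
    """One step of the simple symmetric walk: up-probability 1/2 everywhere."""

    def up_probs(self, sites: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(sites).shape, 0.5)


@dataclass(frozen=True)
class RatchetKernel:
    """One step of the ratchet walk at refinement n.

    Up-probability p0 on sites with mod(site, n*L_int) < n*l, p1 elsewhere
    (floor-division residues, so negative sites wrap into [0, n*L_int)).
    """

    n: int
    l: int
    L_int: int
    rho: float
    p0: float = field(init=False)
    p1: float = field(init=False)

    def __post_init__(self) -> None:
        p0, p1 = probs_from_rho(self.rho, self.l, self.L_int)
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)

    def up_probs(self, sites: np.ndarray) -> np.ndarray:
        r = np.mod(np.asarray(sites), self.n * self.L_int)
        return np.where(r < self.n * self.l, self.p0, self.p1)


def rho_from_lambda(n: int, lam: float) -> float:
    """Walk parameter rho = 1 - lambda/n; requires n > lambda >= 0."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if n <= lam:
        raise ValueError(f"refinement n={n} must exceed lambda={lam}")
    return 1.0 - lam / n


def step(pmf: LatticePMF, kernel) -> LatticePMF:
    """One exact step: mass at j becomes up-flow from j-1 plus down-flow
    from j+1.  The support widens by one site on each end."""
    u = kernel.up_probs(pmf.sites)
    old = pmf.probs
    new = np.zeros(old.size + 2)
    new[:-2] += old * (1.0 - u)
    new[2:] += old * u
    return LatticePMF(pmf.offset - 1, new, pmf.n, pmf.steps_taken + 1)


def evolve(pmf: LatticePMF, kernel, steps: int) -> LatticePMF:
    """Apply ``steps`` exact steps of ``kernel``.

    Equivalent to iterating :func:`step` but runs on two preallocated
    full-width buffers with the kernel's up-probabilities computed once for
    the final support, so that long propagations (tens of thousands of
    steps) stay cheap.  Summation order is fixed, making the result
    bit-reproducible.
    """
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    if steps == 0:
        return pmf
    m0 = pmf.probs.size
    width = m0 + 2 * steps
    lo_site = pmf.offset - steps  # site of buffer index 0
    u_full = np.asarray(kernel.up_probs(lo_site + np.arange(width)), dtype=float)
    a = np.zeros(width)
    a[steps : steps + m0] = pmf.probs
    b = np.zeros(width)
    left, size = steps, m0
    for _ in range(steps):
        seg = a[left : left + size]
        useg = u_full[left : left + size]
        b[left - 1 : left + size - 1] = seg * (1.0 - useg)
        b[left + size - 1 : left + size + 1] = 0.0
        b[left + 1 : left + size + 1] += seg * useg
        a, b = b, a
        left -= 1
        size += 2
    return LatticePMF(lo_site, a, pmf.n, pmf.steps_taken + steps)


def flash_evolve(
    start_site: int,
    n: int,
    p: RatchetParams,
    s: FlashingSchedule,
    periods: int = 1,
) -> LatticePMF:
    """Propagate the flashing walk from a point through full flash periods.

    Each period is n**2*tau1 symmetric steps (potential off) followed by
    n**2*tau2 ratchet steps (potential on) with rho = 1 - lambda/n.  The
    refinement n must be a multiple of the schedule's m (so the step counts
    are integers) and must exceed lambda.
    """
    if periods < 0:
        raise ValueError("periods must be nonnegative")
    k1, k2 = s.step_counts(n)  # validates n multiple of m
    rho = rho_from_lambda(n, p.lam)  # validates n > lambda
    sym = SymmetricKernel()
    ratchet = RatchetKernel(n=n, l=p.l, L_int=p.L_int, rho=rho)
    pmf = LatticePMF.from_point(start_site, n)
    for _ in range(periods):
        pmf = evolve(pmf, sym, k1)
        pmf = evolve(pmf, ratchet, k2)
    return pmf
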