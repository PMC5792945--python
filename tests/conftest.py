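"""Shared fixtures: the reference flashing-ratchet configuration and small
evolved pmfs reused across test modules."""

from fractions import Fraction
from itertools import product

import pytest

import flashratchet as fr


@pytest.fixture(scope="session")
def params5() -> fr.RatchetParams:
    """alpha=1/4, L=4, lambda=5 (gamma=15/8) — the strong-drift reference."""
    return fr.RatchetParams(l=1, L_int=4, lam=5.0)


@pytest.fixture(scope="session")
def schedule() -> fr.FlashingSchedule:
    """tau1 = tau2 = 2.4 (m = 5)."""
    return fr.FlashingSchedule(Fraction(12, 5), Fraction(12, 5))


@pytest.fixture(scope="session")
def pmf_n10(params5, schedule) -> fr.LatticePMF:
    """One flash period at coarse refinement n=10 (240+240 steps)."""
    return fr.flash_evolve(0, 10, params5, schedule, periods=1)


def enumerate_paths(start: int, up_prob, steps: int) -> dict[int, float]:
    """Brute-force weighted path enumeration over all 2**steps sign paths.

    ``up_prob(site)`` gives the probability of a +1 move from an integer
    site.  Independent of the propagation code: it multiplies path weights
    move by move.
    """
    dist: dict[int, float] = {}
    for signs in product((+1, -1), repeat=steps):
        site = start
        w = 1.0
        for sgn in signs:
            u = up_prob(site)
            w *= u if sgn > 0 else 1.0 - u
            site += sgn
        dist[site] = dist.get(site, 0.0) + w
    return dist
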