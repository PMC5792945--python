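"""Continuous-model definitions for the (flashing) Brownian ratchet.

A Brownian ratchet is a one-dimensional diffusion with unit diffusion
coefficient whose drift is proportional to minus the gradient of a periodic
asymmetric sawtooth potential ``V``; it drifts towards the potential minima.
The flashing Brownian ratchet alternates between free Brownian motion
(potential off, duration ``tau1``) and the ratchet (potential on, duration
``tau2``), which produces directed transport.

This module holds the parameter containers (:class:`RatchetParams`,
:class:`FlashingSchedule`) and the closed-form quantities of the continuous
model: the sawtooth potential, its drift field, and the reversible equilibrium
density ``C * exp(-2*gamma*V(x))`` of the wrapped ratchet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np

__all__ = [
    "RatchetParams",
    "FlashingSchedule",
    "potential_value",
    "drift_value",
    "equilibrium_density",
    "equilibrium_mean_drift",
]


@dataclass(frozen=True)
class RatchetParams:
    """Parameters of the sawtooth-potential Brownian ratchet.

    The potential shape is ``alpha = l / L_int`` with ``l`` and ``L_int``
    coprime, rising on the first fraction ``alpha`` of each period and
    falling on the rest.  ``L`` is the (real) spatial period; for the lattice
    approximations it must coincide with ``L_int`` so that the potential
    period spans an integer number of lattice cells.

    The drift strength may be given either as ``gamma`` (the continuous-model
    drift scale, drift is ``-gamma * V'``) or as ``lam`` (the rate parameter
    of the approximating walks); the two are linked by
    ``gamma = lam * (1 - alpha) / 2`` and whichever is missing is derived.
    """

    l: int
    L_int: int
    L: float | None = None
    gamma: float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.l < self.L_int):
            raise ValueError(f"need 0 < l < L_int, got l={self.l}, L_int={self.L_int}")
        if gcd(self.l, self.L_int) != 1:
            raise ValueError(f"l={self.l} and L_int={self.L_int} must be coprime")
        if self.L is None:
            object.__setattr__(self, "L", float(self.L_int))
        if self.L <= 0:
            raise ValueError("period L must be positive")
        a = self.alpha
        if self.gamma is None and self.lam is None:
            raise ValueError("one of gamma or lam must be given")
        if self.gamma is None:
            object.__setattr__(self, "gamma", self.lam * (1.0 - a) / 2.0)
        elif self.lam is None:
            object.__setattr__(self, "lam", 2.0 * self.gamma / (1.0 - a))
        else:
            if not math.isclose(self.gamma, self.lam * (1.0 - a) / 2.0, rel_tol=1e-12):
                raise ValueError(
                    "inconsistent gamma/lam: require gamma = lam*(1-alpha)/2"
                )
        if self.gamma < 0:
            raise ValueError("drift strength must be nonnegative")

    @property
    def alpha(self) -> float:
        return self.l / self.L_int

    @property
    def alpha_fraction(self) -> Fraction:
        return Fraction(self.l, self.L_int)

    @classmethod
    def from_alpha(cls, alpha: str | Fraction, **kw) -> "RatchetParams":
        """Build from a shape given as a fraction, e.g. ``"1/4"``."""
        frac = Fraction(alpha)
        if not (0 < frac < 1):
            raise ValueError(f"alpha must lie in (0,1), got {frac}")
        return cls(l=frac.numerator, L_int=frac.denominator, **kw)


def _as_fraction(x) -> Fraction:
    """Exact rational from int/str/Fraction; floats are snapped to the
    nearest rational with denominator <= 10**6 (binary floats like 2.4 are
    not exactly rational in the intended sense)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    return Fraction(x).limit_denominator(10**6)


def _minimal_square_clearer(den: int) -> int:
    """Smallest m >= 1 such that den divides m**2 (den from a reduced
    fraction's denominator; trial-division factorization, denominators are
    small here)."""
    m = 1
    d = den
    p = 2
    while p * p <= d:
        if d % p == 0:
            e = 0
            while d % p == 0:
                d //= p
                e += 1
            m *= p ** ((e + 1) // 2)
        p += 1
    if d > 1:
        m *= d  # leftover prime, exponent 1 -> need p**1
    return m


@dataclass(frozen=True)
class FlashingSchedule:
    """Durations of the off (``tau1``) and on (``tau2``) phases.

    Both must be positive rationals.  ``m`` is the smallest positive integer
    such that ``m**2 * tau1`` and ``m**2 * tau2`` are integers; the lattice
    refinement ``n`` of any walk approximation must be a multiple of ``m``
    so that the phase step counts ``n**2 * tau`` are exact integers.
    """

    tau1: Fraction
    tau2: Fraction
    m: int = field(init=False)

    def __post_init__(self) -> None:
        t1 = _as_fraction(self.tau1)
        t2 = _as_fraction(self.tau2)
        if t1 <= 0 or t2 <= 0:
            raise ValueError("flash durations must be positive")
        object.__setattr__(self, "tau1", t1)
        object.__setattr__(self, "tau2", t2)
        den = (t1.denominator * t2.denominator) // gcd(t1.denominator, t2.denominator)
        object.__setattr__(self, "m", _minimal_square_clearer(den))

    def step_counts(self, n: int) -> tuple[int, int]:
        """Exact step counts ``(n**2 * tau1, n**2 * tau2)`` for refinement n.

        Raises if ``n`` is not a positive multiple of ``m`` (the counts would
        not be integers; they are never rounded).
        """
        if n <= 0 or n % self.m != 0:
            raise ValueError(
                f"lattice refinement n={n} must be a positive multiple of m={self.m}"
            )
        k1 = self.tau1 * n * n
        k2 = self.tau2 * n * n
        assert k1.denominator == 1 and k2.denominator == 1
        return int(k1), int(k2)

    @property
    def period(self) -> Fraction:
        return self.tau1 + self.tau2


def potential_value(x, p: RatchetParams):
    """Sawtooth potential V(x), periodic with period L.

    Rises linearly with slope 1/alpha from 0 at x=0 to the maximum L at
    x = alpha*L, then falls with slope -1/(1-alpha) back to 0 at x=L.
    """
    x = np.asarray(x, dtype=float)
    a = p.alpha
    xm = np.mod(x, p.L)
    aL = a * p.L
    v = np.where(xm <= aL, xm / a, (p.L - xm) / (1.0 - a))
    return v if v.ndim else float(v)


def drift_value(x, p: RatchetParams):
    """Ratchet drift mu(x) = -gamma * V'(x), right-continuous at the kinks.

    Equals -gamma/alpha on [kL, (k+alpha)L) and +gamma/(1-alpha) on
    [(k+alpha)L, (k+1)L) for every integer k.
    """
    x = np.asarray(x, dtype=float)
    a = p.alpha
    xm = np.mod(x, p.L)
    mu = np.where(xm < a * p.L, -p.gamma / a, p.gamma / (1.0 - a))
    return mu if mu.ndim else float(mu)


def _normalizer(p: RatchetParams) -> float:
    """Closed-form Z = int_0^L exp(-2*gamma*V) dx = (1 - e^{-2 gamma L})/(2 gamma).

    Both linear pieces of V integrate to exponentials; the slopes cancel so
    that each piece contributes in proportion to its width.
    """
    g = p.gamma
    if g == 0.0:
        return p.L
    return -math.expm1(-2.0 * g * p.L) / (2.0 * g)


def equilibrium_density(x, p: RatchetParams):
    """Reversible equilibrium density C*exp(-2*gamma*V(x)) of the wrapped
    ratchet on [0, L), with the closed-form normalizer (no quadrature).

    For gamma = 0 (flat potential) this is the uniform density 1/L.
    """
    z = _normalizer(p)
    v = potential_value(x, p)
    return np.exp(-2.0 * p.gamma * np.asarray(v, dtype=float)) / z


def equilibrium_mean_drift(p: RatchetParams) -> float:
    """Mean drift of the wrapped ratchet under its equilibrium measure.

    Computed as the ratio of closed-form piecewise integrals
    ``int_0^L mu e^{-2 gamma V} dx / int_0^L e^{-2 gamma V} dx``.  The two
    pieces telescope (V(L) = V(0) = 0) so the result is zero for every
    parameter choice, up to floating-point cancellation.
    """
    g = p.gamma
    if g == 0.0:
        return 0.0
    a = p.alpha
    w = -math.expm1(-2.0 * g * p.L)  # 1 - e^{-2 gamma L}
    # int over the rising piece: (-g/a) * (a/(2g)) * w ; falling piece mirrors it
    left = (-g / a) * (a / (2.0 * g)) * w
    right = (g / (1.0 - a)) * ((1.0 - a) / (2.0 * g)) * w
    return (left + right) / _normalizer(p)
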