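# Methods

## Model

The sawtooth potential with shape `α ∈ (0,1)` and period `L > 0` is

    V(x) = x/α            for 0 ≤ x ≤ αL,
           (L − x)/(1−α)  for αL ≤ x ≤ L,

extended periodically; its maximum is `V(αL) = L`, its minima sit at the
multiples of `L`. The Brownian ratchet is the diffusion with unit diffusion
coefficient and drift `μ(x) = −γV′(x)`, i.e. `−γ/α` on the rising flank and
`+γ/(1−α)` on the falling flank; `μ` is taken right-continuous at the
kinks, so `μ(kL) = −γ/α`. The flashing ratchet alternates free Brownian
motion for `τ₁` with the ratchet for `τ₂`.

Drift strength may be supplied as `γ` or as the walk-rate parameter `λ`
with `γ = λ(1−α)/2`; both are stored and kept consistent. `γ = 0` is
admitted as the degenerate flat-potential case (used by the Monte-Carlo
moment checks).

## Lattice approximation

With `α = l/L_int` in lowest terms, the approximating walk at refinement
`n` lives on `{i/n}`, makes `n²` steps per unit time, and during an on
phase steps up with probability `p₀` on sites whose residue mod `n·L_int`
is below `n·l` and `p₁` otherwise, where

    p₀ = ρ^(1−α)/α / (1 + ρ^(1−α)/α),   p₁ = 1/(1+ρ),   ρ = 1 − λ/n  (n > λ).

Residues of negative sites use floor-division mod (wrap into `[0, nL)`).
The off phase is the simple symmetric walk. `n` must be a multiple of the
smallest integer `m` for which `m²τ₁` and `m²τ₂` are integers (durations
are exact rationals; floats are snapped to a nearby rational with
denominator ≤ 10⁶); non-multiples are refused rather than rounding the step
counts. For `τ₁ = τ₂ = 2.4`, `m = 5`.

The pmf is propagated exactly: one step is two shifted vector adds on a
dense array over the contiguous support, which grows by one site per step
and is never pruned. Summation order is fixed, so results are
bit-reproducible; total mass stays within 1e−12 of 1 across 48 000 steps.
Since each step moves exactly one site, the support parity alternates and
off-parity entries are exact zeros.

## Density and peak statistics

After an even number of steps from a point start, occupied sites are 2/n
apart, so the histogram node at an occupied site has height `prob·n/2`;
linear interpolation between nodes defines the density. Peaks are
delimited by the potential maxima `x ≡ αL (mod L)`; the default window is
one period either side of the start, giving the three-peak decomposition
(outer regions unbounded, absorbing all distant mass).

Two conventions required a decision and were fixed by requiring that every
printed digit of the published parameter-study rows be reproduced (the
weak-drift row λ=1 discriminates; the strong-drift rows are insensitive):

- **Boundary mass.** A lattice site falling exactly on a region boundary
  is assigned wholly to the region on its right (regions are `[lo, hi)`).
  The alternative half-split (consistent with integrating the interpolated
  density) is available as `peak_areas(..., boundary_mass="split")` but
  does not reproduce the λ=1 areas.
- **Peak heights.** Heights are the interpolated density evaluated *at the
  peak centres* (the potential minima), not the per-region maxima. For
  strong drift the two coincide; for λ=1 the third region's maximum
  (0.122244 at x=3.98) differs from the value at the centre (0.121751 at
  x=4), and the published tables print the latter.

The Gaussian reference areas use the normal law with mean at the start and
**variance** `τ₁` (standard deviation `√τ₁`): the published reference
values are reproduced by `Φ(boundary/√2.4)`, so the off-phase duration is
treated as the variance of the spread, and this convention is applied
as-is rather than renormalized elsewhere.

## Equilibrium of the ratchet

The wrapped ratchet is reversible with density `C·exp(−2γV)` on `[0, L)`.
Both flanks integrate in closed form and the slopes cancel, giving
`C = 2γ/(1 − e^(−2γL))`; the equilibrium mean drift is the ratio of two
closed-form piecewise integrals whose pieces telescope (V(L)=V(0)=0), so it
vanishes identically — the implementation computes both pieces and checks
cancellation to < 1e−12 rather than returning a hard-coded zero.
Uniqueness of the invariant measure is not asserted anywhere; tests check
fixed-point residuals only.

## Wrapped period chain and μ̄

The walk wrapped on the circle of `N = n·L_int` sites, observed once per
flash period (`K = n²(τ₁+τ₂)` steps), is a finite Markov chain. Its
transition matrix is built by propagating all `N` start rows
simultaneously with circular shift-add updates. When `N` and `K` are both
even the chain is trapped on one parity class; one extra **symmetric**
step is appended (the natural continuation — the next period starts with
the potential off), making it irreducible with a unique stationary law
`π̄`, solved directly from `(Pᵀ − I)` with the normalization row appended
(residual ≤ ~1e−15 at N=400; tolerance 1e−12).

The stationary mean displacement is `μ̄ = Σᵢ π̄(i)·d(i)/n`, where `d(i)` is
the exact expected unwrapped displacement of one **K-step** period started
at site `i` — the irreducibility step is excluded from `d` (it exists only
to make `π̄` well defined). `d` is accumulated during the same propagation:
symmetric steps are a martingale and contribute nothing; each ratchet step
adds `E[2u(site) − 1]` under the current row law. This convention
reproduces the published μ̄ = 0.684827 for the reference configuration.

## Parrondo games

Game B's `(p₀, p₁)` come from the detailed-balance solvability condition
`(1−p₀)^l (1−p₁)^(L−l) = p₀^l p₁^(L−l)`; its reversible invariant profile
has the closed form given in `game_b_invariant_profile` and is
cross-checked against an independent linear stationary solve. Stationary
laws of general cycle walks (mixtures, patterns) are obtained by a direct
least-squares solve of `(Pᵀ − I)π = 0, Σπ = 1` — the periods involved are
tiny, so a direct solve is preferable to power iteration. The pattern
`AʳBˢ` is analysed on the augmented (residue, phase) chain, phases below
`r` playing A; the reported profit is the stationary time-average. The
package computes pattern profits rather than assuming their sign.

## Monte-Carlo oracle

The SDEs are simulated with explicit Euler–Maruyama: drift and flashing
state evaluated at the left endpoint of each step, discontinuities not
smoothed. `dt` must divide `τ₁` and `τ₂`; whether the potential is on is
decided by integer step counting within the period, never by float time
comparison. The default `dt = 1e−3` keeps the discretization bias of the
mean displacement well below the Monte-Carlo standard error at the path
counts used (2·10⁴). A single `numpy` generator seeded per call makes
every simulation reproducible; there is no global RNG state.

The Monte-Carlo route approximates the *continuous* process, so it is
compared with fine-lattice values within 4 standard errors — a stochastic
consistency check, not a digit-level reproduction.

## Problem sizes

The test suite and acceptance script use the study's own configurations:
`α = 1/4, L = 4, τ₁ = τ₂ = 2.4`, refinements `n = 10` (480 steps) and
`n = 100` (48 000 steps; ~5 s per propagation), the 400-state period chain
(48 001 steps; ~50 s), and Monte-Carlo samples of 8 000–20 000 paths.
Cross-checks by exhaustive path enumeration run at ≤ 12 steps (4 096
paths) and on a 6-site wrapped chain (9 steps).

## Limitations

- The lattice results are exact for the *walk*, not the diffusion; the
  refinement study (Table-2 grid) shows the O(1/n) drift of the statistics
  towards the continuum values.
- Stationarity of `π̄` is computed for the period-*sampled* chain; the
  within-period evolution is available by propagating from `π̄` but no
  continuous-time stationary density is claimed.
- Tilted potentials, schedule optimization of `μ̄/(τ₁+τ₂)`, and
  non-sawtooth potential variants are out of scope.
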