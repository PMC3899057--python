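# Methods

## Model and assumptions

The simulator is a forward-time, discrete-generation, biparental
genealogy model (the forward analogue of classical common-ancestor
models of sexual reproduction). Generation t has n(t) individuals; each
child of generation t+1 independently receives a parent pair from
generation t, so individuals can parent many children or none, there is
no couple persistence, no sexes, and no overlapping generations. The
two parents of one child are drawn independently, so self-pairing is
possible with probability O(1/n) per child; at the population sizes used
here this has no measurable effect on any reported statistic and keeps
the sampler simple and exactly exchangeable.

Identity (type-1 vs type-2) is culturally transmitted: same-type pairs
breed true, mixed pairs produce either type with probability ½. The
pair-type distribution at type-1 fraction x is the convex interpolation

    p11 = αx + (1−α)x²
    p12 = (1−α)·2x(1−x)
    p22 = α(1−x) + (1−α)(1−x)²

This is the unique linear-in-α family that matches the panmictic
binomial limit at α = 0 and the fully assortative limit (x, 0, 1−x) at
α = 1 while preserving the expected type fraction, p11 + p12/2 = x, for
every α. Conservation plus the ½-rule for mixed offspring make x(t) a
martingale, which the test suite checks directly.

The simulation uses the *realized* x(t) of the current generation when
computing pair-type probabilities, not the initial x₀. If a type
subpopulation is empty its pair types receive probability zero
(automatically, since x ∈ {0, 1} then) and the multinomial is
renormalized over feasible pair types as a floating-point guard.

### Preference parameter and odds mapping

α is dimensionless in [0, 1]; default scenarios use α = 0 (panmixia),
0.9 (strong preference) and 0.999 (extreme preference). A stated
in-group:out-group odds ratio is converted by `alpha_from_odds`:

- `suppression` (default): α = 1 − 1/odds — the cross-type pairing
  weight (1−α) is suppressed odds-fold relative to random mixing; 1000:1
  gives α = 0.999.
- `conditional`: solves 2·p11/p12 = odds at a reference fraction
  (default 0.2), i.e. odds is the relative likelihood that a given
  type-1 individual's partner is type-1 rather than type-2; 1000:1
  gives α ≈ 0.99875.

The two differ by <0.2% in α at 1000:1 but by about a generation in
first-passage times (the contraction constant c is five times closer to
1 under the suppression mapping at x₀ = 0.2). Both are exposed; the
suppression mapping is the default because it reads the odds as a direct
suppression of the cross-type multinomial weight.

## Genealogical identity and the recursion

g(individual) = 1 iff at least one generation-0 ancestor is type-1;
type-1 founders initialize g = 1, type-2 founders g = 0, so
F(0) = x₀. Since a type-1 child always has a type-1 parent, only three
states are reachable: (1, g=1), (2, g=0), (2, g=1). Incrementally, a
child's g is the OR of its parents' flags.

Let q(t) be the fraction of *type-2* individuals with no type-1
ancestor. A g=0 child must be a type-2 child of a (2,2) pair whose
parents are both g=0. Holding x at x₀ (the martingale property makes
this exact in expectation for one step, and an independence
approximation beyond), the fraction of type-2 children that are g=0 is

    q(t+1) = [p22 · q(t)²] / (1 − x₀) = c·q(t)²,  c = α + (1−α)(1−x₀)

with q(0) = 1 and closed form q(t) = c^(2^t − 1). The fraction of all
individuals with at least one type-1 ancestor is F(t) = 1 − (1−x₀)q(t).
State probabilities are p(1,1) = x₀, p(2,0) = (1−x₀)q(t),
p(2,1) = (1−x₀)(1−q(t)).

Numerics: the recursion is iterated in the log domain
(log q(t+1) = log c + 2·log q(t)) so t = 30+ does not underflow
intermediate products; q below 1e-300 is reported as exactly 0. The
closed form and the iterated map agree to 1e-12 relative error (tested
over an (x₀, α) grid, t ≤ 30). x₀ = 1 leaves no type-2 subpopulation
and c undefined; it raises a domain error.

## Engine data structures

- Per-generation arrays: type (uint8) and g (bool); observables
  (x, F_sim, q_sim) are exact integer-count ratios, so
  F_sim = 1 − (1−x)q_sim holds to machine precision by construction.
- Pedigree: per-child parent indices into the previous generation,
  recorded on request.
- Founder-ancestor sets: packed uint64 bitset matrix per generation
  (n(t) × ⌈n0/64⌉ words); a child's row is the bitwise OR of its
  parents' rows, and popcounts give set sizes and intersections. Exact
  tracking is allowed only for n0 ≤ 20,000 (memory is n(t)·n0 bits per
  generation); larger runs use g-flags only. The set-intersection
  definition of g (ancestor set meets the type-1 founder set) is tested
  for exact equivalence with the incremental OR propagation, and both
  against a brute-force recursive pedigree walk.
- Growth schedule: constant, or geometric interpolation between n0 and
  n_final rounded to the nearest integer with exact endpoints.
- Randomness: one `numpy` Generator seeded from the scenario seed;
  replicate r of a scenario uses seed + r. Identical seed and config
  give byte-identical outputs.
- Founder composition is deterministic: round(x₀·n0) type-1 founders.

## Scenarios and defaults

The `sephardic1492` preset encodes the motivating application: x₀ = 0.2
(the minority community's share of the founder population), 1000:1
in-group odds, 20 generations (≈500 years), population growing
geometrically from 10,000 to 100,000. The growth endpoints are
desk-scale stand-ins — the qualitative behaviour is insensitive to
them because the first-passage condition depends on population size
only through a log — and both are config-overridable. Under these
defaults the median first generation (seeds 1–10) at which every
individual has a type-1 ancestor is 16 with the default suppression
mapping; the conditional mapping reaches it about a generation sooner.

## What the synthetic populations do and do not show

All inputs are generated by the simulator itself; there is no external
data. The generator emulates: discrete non-overlapping generations,
exchangeable biparental reproduction, type-assortative pair formation,
deterministic population growth. It does not emulate: sex structure,
couple persistence (full-sibling clustering beyond chance), spatial or
community structure, migration, identity loss or conversion, or
overlapping generations. Passing tests therefore demonstrate the
internal consistency of the model and the accuracy of its closed-form
theory under these idealizations — not that real populations mixed at
the predicted rate. In particular, population structure would slow the
early spread of genealogical identity, while the superexponential
mechanism itself is robust to most such extensions.

## Stochastic spread around the deterministic theory

The recursion is an infinite-population, independence-approximation
limit. Finite-n runs scatter around it with a characteristic
amplification: the number of earliest cross-type matings is
n·p12/2 ≈ n(1−α)x₀(1−x₀), and the relative Poisson noise of that small
seed count is roughly doubled every generation by the quadratic
contraction until q crosses ½. At n = 10⁵ this leaves |F_sim − F_theory|
a few ×10⁻³ for α ≤ 0.9 at x₀ ≥ 0.2, but O(0.015) at (α=0.9, x₀=0.05)
(~475 seed matings) and O(0.1) at α = 0.999 (~16 seed matings),
shrinking only as 1/√n. The engine itself is unbiased: the mean of
q_sim(1) and q_sim(2) over replicates matches c and c³ to within Monte
Carlo error. Single-run agreement checks at extreme α should therefore
be read as measurements of this intrinsic spread, not as convergence
failures, and the test suite estimates typical agreement by the median
over seeded replicates.

## Problem sizes used in the checks

The packaged checks run at n = 10⁵ (theory agreement, conservation),
n = 10⁴ × 200 replicates (martingale), n = 2000 with full ancestry
tracking (ancestor-composition convergence), and 100 instances with
n ≤ 64, T ≤ 6 (exact oracle equivalence) — sizes chosen so the full
suite completes in a few minutes on one CPU while keeping Monte Carlo
error well below each asserted tolerance.
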