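# Methods

## Model structure

The community is a zero-sum lottery: `M` patches on a gridded torus, one
adult per patch, patch spacing `1/√g` metres so that one adult per patch
realises the adult density `g`. Species are identical except for intrinsic
fitness `Y` (a composite of fecundity and baseline offspring survival, only
relative values matter), drawn i.i.d. lognormal with `ln Y ~ N(0, σ_Y²)`.
Each time-step every adult dies independently with probability `δ`; a dying
adult is replaced by one offspring drawn with probability proportional to
per-species offspring abundance on that patch. A fraction `D` of every
tree's seeds is dispersed uniformly over all `M` patches (natal patch
included); `1 − D` stays on the natal patch. Surviving adults' patches are
untouched — there is no seed bank and no immigration, so spatial richness
traces are non-increasing.

Janzen–Connell mortality multiplies offspring abundance by a survival
kernel `J ∈ (0, 1]` that depends on the local conspecific-adult
configuration. The four kernels (NF/AF/ND/AD) combine two axes: additive
versus non-additive accumulation over conspecific adults, and a fixed
effect radius `r` versus exponential decay with length `v`. In all four, a
conspecific adult occupying the focal patch contributes predation weight 1
(distance zero); context sums therefore exclude the focal occupant, which
is tracked separately. This makes the kernels coincide in the right limits:
AD with a single source tree equals ND, and all kernels reduce to 1 at
`a = 0`.

In the spatial simulator the distance-decay forms use minimum-image
Euclidean distances between patch centres; the fixed-distance forms use
square `k × k` Moore neighbourhoods (focal patch included), as is natural
on a lattice. The mapping between the two conventions lives in the
normalisation module: a `k × k` block of patches covers `k²/g` m², so its
area-equivalent radius is `r = k/√(πg)` — which makes the mean-field
effect area `E_F = πgr²` equal `k²`, the exact adult count of a full Moore
block. The printed endpoint correspondences (3×3 ↔ r ≈ 4.0 and
11×11 ↔ r ≈ 14 at `g = 0.2`) are reproduced by this mapping after rounding.

## Mean-field approximation

Taking expectations of the per-patch abundances over a random (Poisson)
adult configuration gives, per form, a mean away-survival `E[J_away](p)`:

* NF: `e^(−pE_F) + e^(−a)(1 − e^(−pE_F))` — survive fully unless the
  Poisson count (mean `pE_F`) in the effect circle is positive;
* AF: `exp(−(1 − e^(−a)) p E_F)` — the Poisson moment generating function;
* AD: `exp(−a p E_D H(a))` with `H(a) = ₃F₃(1,1,1;2,2,2;−a)` — the Laplace
  functional of the exponentially weighted conspecific density;
* ND: a second-order (delta-method) expansion of `E[exp(−a e^(−X/v))]`
  around the mean nearest-conspecific distance `1/(2√(gp))`, using the
  nearest-neighbour variance `(1 − π/4)/(πgp)`:
  `e^(−w)[1 + w(w−1)(1−π/4)/(pE_D)]` with `w = a e^(−√(π/(2pE_D)))`.

The ND expression is an approximation; an exact quadrature mode
(`nd_mode="quadrature"`, integrating against the nearest-neighbour density
`P(X > x) = e^(−πgpx²)`) is selectable everywhere and is the arbiter in
tests. Over `a ∈ [0.5, 4.5]` and `p ∈ [1/300, 0.3]` the closed form tracks
the quadrature to within ~6% (worst at very small `p` with very large `a`),
and to well under 1% at moderate proportions.

Mean natal-patch survival is `e^(−a)` times, for the additive forms, the
same surrounding-conspecific factor as the away term (the focal adult
guarantees weight 1; neighbours add independently). The community dynamics
(the replicator-like ODE above) conserve `Σp` exactly at the level of the
right-hand side — the lottery probabilities on each patch type sum to one —
and reduce at `a = 0, D = 1` to `dp_i/dt = δ p_i (Y_i/Σp_nY_n − 1)`, the
fitness-weighted lottery that excludes all but the fittest species.

`H(a)` is evaluated through `a H(a) = Σ_{k≥1} (−1)^(k−1) a^k/(k! k²)` with a
term recurrence in double precision for `a ≤ 15` (relative error `< 1e−10`
against 50-digit arithmetic) and arbitrary-precision evaluation beyond.

## Parameters and defaults

| parameter | meaning | default | rationale |
|-----------|---------|---------|-----------|
| `g` | adult density (adults·m⁻²) | 0.172 | 86,069 adults / 50 ha at the Barro Colorado Island plot |
| `N0` | initial species count | 300 | ≈ woody-plant richness at BCI |
| `σ_Y` | lognormal scale of `ln Y` | sweeps 0.1–1.0 | empirical interspecific fitness variation ≈ 1.0; 0.55 as mid-range headline |
| `1 − e^(−a)` | death probability on a conspecific patch | 0.4 / 0.7 / 0.99 | moderate to very strong predation |
| `v` | predation decay length (m) | sweeps 2.5–15 | seedling-survival distance decay estimates ≈ 5–10 m |
| `D` | dispersed seed fraction | 1 / 0.5 / 0.1 | none / moderate / strong dispersal limitation |
| `δ` | adult death probability per step | 0.1 (spatial), 1 (ODE) | δ only rescales time; richness outcomes are insensitive |
| extinction | `ln p < −11` (inclusive boundary is extant) | `ln(1/86,006) ≈ −11`: under one individual at BCI; grid runs use `ln(1/M)` |

Natural logarithms throughout. The extinction boundary is inclusive
(extant iff `ln p ≥` threshold): the threshold is defined by *falling
below* one individual.

## Normalisations

Cross-form comparisons equalise predation pressure twice. First, the
per-tree total pressure `2πg∫x G(x)dx` is equalised between the step kernel
(`πgr²`) and the exponential kernel (`2πgv²`), giving `r = v√2` and
`E_F = E_D`. Second, additive accumulation raises the *mean* pressure on a
random patch by `aE/N` relative to non-additive predation, so the
non-additive baseline is inflated to `a_n = a_A(1 + E/N_A)`, where `N_A` is
the equilibrium richness of the additive reference run (AD by default; AF
gives near-identical `a_n`). Reference runs are cached per parameter cell
so sweeps do not recompute them.

## Invasion criteria

For `N` residents under global dispersal (`D = 1`) the minimum invader
fitness decomposes exactly as

```
Ȳ · E[J_away](1/N)  +  N·Cov(p, Y) · d/dp[p · E[J_away](p)] at p = 1/N
```

(mean-JCE-fitness term + covariance-JCE term). The derivative coefficient
has closed forms for NF, AF and AD; for ND it is evaluated by central
differences on the same derivative — the quantity the three analytic
coefficients instantiate, which the tests confirm to `1e−6` relative error.
`Cov(p, Y)` is the population covariance (divisor `N`); this is the only
convention under which the `a = 0` limit reproduces the lottery threshold
`Σp_iY_i`. An exact numerical threshold (bisection on the invader's
mean-field growth rate at proportion `1e−8`, residents renormalised) serves
as the oracle; it is insensitive to the invader proportion over
`1e−10`–`1e−6` and agrees with the approximate criteria to a few percent at
symmetric resident communities.

## Spatial simulator: numerics

Offspring abundances are evaluated lazily, only on dying patches (results
identical to full evaluation — replacement on a patch depends only on that
patch's pool). Because the focal occupant always contributes weight 1, all
four kernels unify to one per-species expression that includes the focal
adult in the context; the decay forms aggregate a precomputed
lattice-offset kernel table over all adults per species (sum for AD;
maximum for ND, since `e^(−d_min/v) = max_m e^(−d_m/v)`) in a compiled
loop. AD kernel tails with `e^(−d/v) < 1e−8` may be truncated (error in
`J` below `a·1e−8` per neighbour); tests use the exact mode. The optimised
field computation is verified exactly against an `O(M²)` brute-force
double loop.

One seeded generator drives each run (initialisation, deaths, lottery
draws); the seed is recorded in the output. The stop rule is richness
unchanged over a trailing 500-step window, capped at 10,000 steps; runs
report whether they converged.

## ODE integration

LSODA (stiff-capable, adaptive) with `rtol 1e−8`, `atol 1e−12`, integrating
to `t = 10,000` generations from uniform initial proportions (the source
analysis starts 300-species communities; initial proportions are otherwise
unspecified, and uniform is the symmetric choice). Integration proceeds in
segments; after each segment, species with `ln p < −30` — far below the
`−11` reporting threshold — are pruned from the active system and recorded,
keeping the system well-conditioned. Reported richness uses the inclusive
`−11` (or `ln(1/M)`) threshold at the final time.

## Validation design and what it shows

The paired spatial/ODE validation mirrors the full-scale design
(`σ_Y ∈ {0.1, 0.45, 0.8}`, `a ∈ {0.5, 1.0, 2.75, 4.5}`, `v ∈ {5, 7.5, 10}`
or Moore 3×3–11×11, `g = 0.2`, 275×275 patches). At full scale every
species starts with ~252 adults and demographic drift is mild over the
transient. That ratio, not the grid side alone, controls agreement: on a
60×60 torus with 300 species (12 adults each) drift removes 50–160 species
that the deterministic ODE keeps, which is a finite-size artefact rather
than a mean-field failure. The reduced-scale runs used by the test suite
and the acceptance script therefore preserve the adults-per-species ratio
(60×60 with `N0 = 14`, ≈ 257 adults per species) and match the ODE
extinction threshold to the grid (`ln(1/M)`). At that scale the per-form
mean absolute richness difference stays within a couple of species over 12
combinations per form (0–2.4 across probed seeds). Squared correlations
are high but degrade below full-scale values for forms whose richness
outcomes cluster near the ceiling (richness can only take 14 values, so
±1-species lottery noise is a large fraction of the variance); pooled over
all 48 pairs they land around 0.8–0.92 depending on seed. The
full-scale 275×275 / 300-species reproduction is available through
`jcelottery validate --long` (overnight on one CPU).

What the synthetic communities do *not* emulate: immigration, ecological
drift in the ODE, species-specific `a`, `v` or `δ`, trait correlations,
sub-linear additivity, and seed banks. Passing tests show the spatial
process and its mean field agree and that the comparative statics across
functional forms are robust in the stated parameter ranges — not that any
single form describes a real forest.

## Known limitations

* The ND closed form is approximate (documented above); use
  `nd_mode="quadrature"` where exactness matters.
* The mean field is a Poisson-continuum idealisation of Bernoulli occupancy
  on a lattice; at community-scale proportions the exact lattice
  expectation of the AD away-survival differs from the closed form by
  under 1% (focal-patch exclusion dominates), which is invisible at the
  richness level but detectable by sufficiently large Monte-Carlo.
* Lottery replacement assumes at least one offspring on every dying patch;
  in the measure-zero case of an empty pool the previous occupant is
  retained.
* `equilibrium_invasion_analysis` treats species above the extinction
  threshold as the resident community and renormalises their proportions;
  residents just below threshold are ignored.
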