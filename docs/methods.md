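# Methods

## Model and assumptions

`slowerx` computes fixation probabilities and mutation-relative
substitution rates of new mutations at three locus classes — autosomal,
hemizygous X-linked, and diploid X-linked (functional, non-recombining Y
homolog) — under sex-specific selection. The assumptions shared by all
components:

- one biallelic locus; no recombination between the X and Y homologs at a
  diploid X locus, and the Y-linked allele is fixed ancestral;
- even sex ratio (no sex-ratio parameter is exposed);
- the same dominance coefficient `h` in females and males;
- selection weak enough per sex that genotype fitness can be averaged
  across sexes and second-order terms in `s` dropped (the forward
  simulator quantifies, rather than assumes, where this breaks down);
- new mutations only; no standing variation, linkage, or epistasis.

Each class reduces to drift coefficients `(s̄, σ, Ne, p0)` (table in the
README). The autosomal pair follows from expanding the marginal-fitness
difference `w₂ − w₁ = s(h + x(1−2h))` per sex with equal transmission
weights; the X classes use 2/3–1/3 female/male weights. The hemizygous
class equals the diploid class under the exposure substitution
`s_m → s_m/h`, but is stored in closed form so `h = 0` is legal.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `s_f`, `s_m` | homozygote fitness effect per sex (dimensionless) | — | must exceed −1 |
| `h` | dominance, 0 recessive … 1 dominant | — | in [0, 1] |
| `N` | census diploid individuals | 10⁶ in scans | makes `p0 ≲ 10⁻⁶`, so exact and first-order rates agree to ~10⁻⁶ |
| `Ne_A` | autosomal effective size | `N` | idealized WF reproduction |
| `Ne_X` | X effective size | `0.75·Ne_A` | 1.5N X copies vs 2N autosomal; override (`Ne_X = Ne_A`) isolates sheltering + transmission from copy number |
| `mu` | per-locus mutation rate | 10⁻⁸ | only a scale factor: all reported rates are relative to `mu` |
| `p0` | initial frequency | `1/(2N)` autosomal, `2/(3N)` X | one copy among the class's chromosomes; overridable for testing |

Scans use `h ∈ {0, 0.05, …, 1}` and population-scaled strengths
`Ne_A·s ∈ {−3, −2, −1, −0.5, 0.5, 1, 3, 5}` by default, covering the
modeled range −3…5.

## Numerical choices

- **Closed form.** The exponent of `G` is quadratic, so
  `∫ exp(αy − βy²) dy` is evaluated via `erfcx` (β > 0) or
  `exp(x²)·dawsn(x)` (β < 0), entirely in log space, with exponent
  differences computed in factored form to avoid cancellation. When the
  exponent varies by less than 0.5 over the integration interval the
  error-function differences themselves cancel, and the evaluation
  switches to an exact term-by-term integrated Taylor series of
  `exp(αy − βy²)` (converges in ≲ 20 terms at full precision).
- **Kimura switch.** For `|4Ne σ| < 10⁻⁸` the general closed form is
  numerically meaningless and the additive limit
  `U(p) = expm1(−4Ne s̄ p)/expm1(−4Ne s̄)` is used (log-space for large
  negative `s̄`; `U(p) = p` at `s̄ = 0`). Continuity across the switch is
  unit-tested.
- **Quadrature path.** `scipy.integrate.quad` on the integrand rescaled
  by its maximum over the interval, `epsabs = 10⁻¹²`, `epsrel = 10⁻¹⁰`;
  an error estimate exceeding ten times the tolerance raises. This path
  is algorithmically independent of the closed form and the two are
  required to agree to 10⁻⁸ in the tests (observed ≲ 10⁻¹⁴).
- **Rate conventions.** The default rate is the exact `U(p0)/p0`. The
  `first_order=True` form `1/∫₀¹G` is its `p0 → 0` limit; the two differ
  at `O(p0)`. Statements that are exact identities only in the limit —
  the Kimura formula, and the equality of all three classes for
  female-limited mutations at `Ne_X = 0.75·Ne_A` — are asserted at
  10⁻¹⁰ on the first-order form, since at any finite `N` the class- and
  parameter-dependent `p0` perturbs the exact ratio at the 10⁻⁶ level.
- **Branching validity flag.** `valid` requires
  `1/Ne < p_fix/2 < 0.1`; reported as a flag, never an exception, so
  grid scans may cross the boundary.

## Forward simulator

The verification engine is an individual-based two-sex Wright–Fisher
model with fecundity selection: each offspring draws its mother and
father independently, with probability proportional to fitness within
sex. Because parents are drawn independently with replacement, the
per-sex genotype counts are a sufficient statistic, and one generation is
an exact (multinomial, binomial) draw from the selection-weighted
transmission probabilities — the simulation is genotype-exact while
remaining vectorizable. Design choices:

- **Initial placement.** The single mutant copy lands uniformly on the
  chromosome copies of the class (for X classes: probability 2/3 in a
  female), matching `p0` exactly.
- **Seeding.** Replicates run in blocks of 8192; block *i* uses the
  *i*-th spawned child of the root `SeedSequence`. Results are
  reproducible from the root seed and independent of block execution
  order.
- **Absorption.** Trajectories run to fixation or loss, capped at
  `100·N` generations; capped runs are excluded from the `u_hat`
  denominator and a warning is recorded if they exceed 0.1% of
  replicates.
- **Uncertainty.** Wilson 95% binomial intervals (statsmodels).
- **Verification grid.** `h ∈ {0, ½, 1} × Ne_A·s ∈ {1, 3} × 3 classes`
  at `N = 500` (250 per sex) with 5×10⁴ replicates per point — 18
  points, about half a minute on one core. Each point is scored by
  `z = (u_hat − u_diff)/SE(u_diff)`. Since each z is approximately
  standard normal when the diffusion is correct, a grid of n points is
  expected to produce ~0.05·n exceedances of |z| = 2 by chance; the
  pass criterion therefore allows up to `ceil(0.05·n)` exceedances
  (one on the standard grid). A negative control (diffusion fed a
  tenfold-too-small `Ne`) must raise the fail flag.

### What the simulator does and does not emulate

It reproduces exactly the idealized conditions of the analytic model:
discrete generations, even sex ratio, fecundity selection, independent
parent sampling (so `Ne_A = N`, `Ne_X = 0.75N`, verified via the drift
variance of each chromosome class). It does **not** model variance in
male reproductive success, overlapping generations, linked selection,
recurrent mutation, or multi-locus interference — so agreement between
simulator and diffusion validates the mathematics under the model's own
assumptions, not the model's adequacy for any particular natural
population.

## Design decisions taken where the design was open

- The equal-`Ne` scenario reports the dominance value at which
  `R(diploid X)` crosses 1 (linear interpolation on the grid) rather
  than asserting a fixed cutoff; the crossover location depends on the
  selection strength.
- Branching-limit convergence is certified at the strong-selection
  boundary (`Ne·s·h ≥ 50`) for the equal-effects regime; sex-limited
  regimes converge in their smaller class-specific effective selection
  intensity and are checked deep in the asymptotic regime instead.
- CLI exit codes follow the argparse convention: 0 success, 2 usage
  error, 1 runtime error.
- Neutral-rate normalization is an identity on the mutation-relative
  scale (neutral rate ≡ 1); the `normalized_rate` column is kept for
  symmetry with dN/dS-style summaries.

## Known limitations

- Selection coefficients of order 0.1 and larger leave the weak-selection
  regime of the diffusion; the simulator remains valid there but the
  analytic rates degrade gracefully rather than provably.
- Sex-specific dominance, sex-biased mutation rates, and unequal sex
  ratios are not modeled.
- The branching approximation is for beneficial mutations only; the
  `valid` flag must be consulted before quoting `p_fix` near the
  boundaries of its regime.
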