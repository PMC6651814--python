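# Methods

## Model

The simulator treats a polygenic late-onset disease as a proportional-
hazards frailty process at one-year resolution.  An individual `u` has a
lifelong multiplicative risk score `G_u = exp(Σ_k b_k g_k)` built from
Hardy–Weinberg genotype dosages over a grid of allele classes, and a yearly
diagnosis probability `p_u(t) = clamp(A(t)·G_u, 0, 1)` conditional on being
alive and disease-free.  The aging coefficient `A(t)` is the inverse image
of a clinical yearly incidence curve `I(t)` under this model: at each age
the population-mean probability over the still-unaffected pool must equal
`I(t)`.  All environmental and aging effects are absorbed into `A(t)`; the
PRS is constant for life; mortality is independent of the PRS.

Key assumptions, and what they imply:

- **Multiplicative architecture, no LD/dominance/epistasis.**  Dosages are
  independent across SNPs, so `ln G` is a sum of independent bounded terms;
  with hundreds of causal SNPs it is close to normal.
- **PRS-independent mortality.**  Incidence inversion runs on the
  disease-free pool only; mortality enters once, downstream, through the
  survivor fraction `S(t)`.  This is why `A(t)` discovery contains no life
  table.
- **Yearly discretization.**  Probabilities are per-year conditional
  probabilities on half-open `[t, t+1)` intervals, not instantaneous rates.
  The hazard-to-probability map is the direct clamp `min(A·G, 1)` by
  default; `1 − exp(−A·G)` is available as `transform="exponential"` for
  sensitivity checks and changes results only where `A·G` is large.

## Aging-coefficient discovery

For each age with `I(t) > 0` the equation
`Σ_u w_u·clamp(A·G_u,0,1) / Σ_u w_u = I(t)` is solved for `A`.  The left
side is non-decreasing in `A` and piecewise linear under the clamp
transform; below clamp saturation it is exactly `A·mean(G)`, and the solver
takes the closed-form root `A = I/mean(G)` there (this is the bisection
fixed point, obtained without grinding against the floating-point noise
floor at incidence values of 1e-6 and below).  Where the clamp is active
the solver bisects on a geometrically grown bracket to an absolute
incidence mismatch of `min(1e-12, I·1e-12)`.  The unaffected masses are
then depleted by `w ← w·(1 − p)`.  Round-trip validation — applying the
discovered `A(t)` back to the discovery population — reproduces `I(t)` to
better than 1e-10 relative per age, and is asserted in the test suite.

Degenerate cases: `I(t) ≥ 1` raises (with bounded score support the
solution is unbounded or non-unique); an exhausted unaffected pool
(cumulative risk reached 1) truncates `A` at that age with a warning;
`I(t) = 0` gives `A(t) = 0` and no depletion.

## Population representation

Default is **expectation mode**: `ln G` is approximated as normal with the
analytic Hardy–Weinberg moments and represented by 10,001 equal-mass
midpoint quantiles, renormalized to mean exactly 1.  This removes all
sampling noise and makes every pipeline deterministic.  **Stochastic
mode** samples explicit individuals (per-class dosages are Binomial sums,
which is exact for iid SNPs within a class) and is used for validation and
for allele-level therapy; default 100,000 individuals, reproducible under
a fixed seed.

The normal approximation is accurate for the common-allele scenario at
realistic SNP counts (hundreds to thousands).  For the rare-allele
scenario at the small SNP counts that match a common-allele architecture's
variance (~58 SNPs), the true `ln G` distribution is visibly right-skewed;
sampled rare-allele populations agree with common-allele ones on baseline
and life-extension projections but can differ by ~5% on therapy
projections, and by up to ~8% on fixed-hazard-ratio projections.  The
equivalence of the two architecture scenarios at matched ln-score variance
therefore holds at the population-projection level (and exactly so in
expectation mode), which is also the level at which the scenarios are
compared in the test suite.

## Projection bookkeeping

`D(t) = m(t)·S(t)` where `m(t)` is the first-diagnosis mass among the
birth cohort (conditional incidence × disease-free fraction), and
`C(t) = Σ D` accumulates to the lifetime risk, guaranteed ≤ 1.  For a
fixed hazard ratio `h`, lifetime risk is
`Σ_t p(t)·Π_{s<t}(1−p(s))·S(t)` with `p(t) = clamp(A(t)·h, 0, 1)` — the
individual's own disease-free survival composed multiplicatively with the
all-cause survivor curve (independence of mortality and PRS).

A consequence worth stating explicitly: with the disease-free depletion
factor included, lifetime risk is proportional to the hazard ratio only
asymptotically as risk → 0.  The relative deviation from exact
proportionality is roughly half the cumulative hazard: ~1.5% at a 2.7%
lifetime risk, ~4% at 6–7%, and large for high-risk steep-incidence
diseases — which is precisely the regime split the scenario analyses
exhibit (near-proportional response for low-risk cancer-like diseases,
strongly sublinear response for the dementia-like fixture, where the clamp
also saturates at old ages).

Onset delay is measured where cumulative incidence crosses a fraction
(default 30%) of its own lifetime value, linearly interpolated between
integer ages and reported in whole years.  "Years to regain baseline"
scans integer life-expectancy extensions (default 0–40) for the smallest
shift at which the treated lifetime risk reaches the untreated baseline.

## Demography

Life tables carry one-year death probabilities `q(t)` with
`S(t+1) = S(t)(1−q(t))`, ages 0–119.  The synthetic default is
Gompertz–Makeham `q(t) = a + b·e^{ct}` with `a = 5e-4`, `b = 3.5e-5`,
`c = 0.09`, chosen once to give a life expectancy `Σ_t S(t) ≈ 80` years —
a modern high-income population.  Life-expectancy extension translates the
`q` curve along the age axis (`q'(t) = q(t−δ)`, holding ages below δ at
`q(0)`); for adult-mortality-dominated tables this adds ≈ δ years of
expectancy and is monotone (survival never decreases).  The rule is one
admissible reading of "shifting the mortality curve"; alternatives (e.g.
scaling `b`) would differ in detail but not in the qualitative scenario
ordering.

Incidence curves are logistic `a/(1+e^{−k(t−t50)})` for most diseases and
exponential-then-linear for the breast-cancer-like pattern, where the
linear piece continues the exponential's value and *yearly first
difference* at the switch age, making value and first-difference
continuity exact at integer ages.  All forms are zero below the onset age
and clamp to [0, 1]; parameters that would exceed 1 are rejected.

## Synthetic fixtures

Three incidence regimes, calibrated once against the magnitudes typical of
their disease classes and frozen:

| fixture | form | plateau | onset | t50 | k | baseline lifetime risk |
|---|---|---|---|---|---|---|
| `cancer_like` | logistic | 0.005 | 40 | 70 | 0.25 | ~6.3% |
| `t2d_like` | logistic | 0.025 | 25 | 60 | 0.15 | ~40% |
| `ad_like` | logistic | 0.30 | 60 | 88 | 0.30 | ~35% |

The acceptance script uses a lower-plateau logistic (0.002, same shape,
lifetime risk ~2.7%) because the proportionality law it checks is an
asymptotic statement (see above) and its printed exemplars are the
lowest-risk diseases.  What fixtures do **not** emulate: real incidence
curves fitted to clinical registries, sex-specific life tables matched to
disease-specific cohorts, declining very-old-age cancer incidence, or
cause-of-death competition beyond an all-cause life table.  Passing tests
on fixtures therefore validates the machinery and its qualitative regime
behavior, not clinical numbers for any specific disease.  The eight
shipped disease presets carry published heritabilities and architecture
SNP counts, but their incidence curves are synthetic stand-ins anchored
only to each disease's maximum-yearly-incidence magnitude.

## Therapy

Default therapy is a uniform OR multiplier `m ≤ 1` applied to every score,
leaving the normalization reference untouched so post-therapy risk stays
expressed relative to the pre-therapy population mean.  The equivalent
average edit count is `round(ln(1/m)/mean_k ln OR_k)` over the grid
classes (15 edits for m = 0.25 on the common-allele grid).  Allele-editing
mode reverts actual sampled alleles largest-OR-first until each individual
reaches the target multiplier; because it spends the largest effects
first it needs fewer edits per person (ln 4 / ln 1.15 ≈ 10 for m = 0.25)
and slightly overshoots per individual, but its population projections
converge to the uniform-multiplier results.  Post-therapy populations are
aged under the unchanged baseline `A(t)`: therapy alters genotypes, not
the aging/environment process.

## Numerical choices and limitations

- Bisection tolerance `min(1e-12, I·1e-12)` absolute on the incidence
  mismatch; bracket grown geometrically; ≤ 200 iterations.
- Quantile binning uses midpoint probabilities `(i+0.5)/N`; weighted mean
  renormalized to 1 exactly (within 1e-9 asserted).
- Ties and edges: `delta = 0` shift returns the same table; `hr = 0` gives
  zero risk; onset-delay interpolation falls back to the interval start on
  flat cumulative segments.
- One-year resolution means onset delays are only resolved to whole years;
  sub-year dynamics and continuous-time hazard integration are out of
  scope.
- No pleiotropy, comorbidity coupling, partial therapy coverage, linkage
  disequilibrium, or disease-specific mortality feedback.
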