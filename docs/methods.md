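# Methods

## Model

`divtree` analyzes rooted phylogenetic trees of cells in which every branch
carries a non-negative integer: the number of somatic mutations assigned to
it (infinite-sites reconstruction). The generative model is a constant-rate
birth–death process. Time is measured in units of the division rate (birth
rate ≡ 1) and runs backwards from the moment of observation; cell death
*plus differentiation out of the observed compartment* occurs at relative
rate `q < 1`, so the net growth rate is `1 − q`. At the moment of
observation every extant cell is sampled independently with probability
`rho`.

Mutations arise at cell divisions, not in calendar time: each division adds
a Poisson(`mu`) number of new mutations to each daughter genome. A branch of
the reconstructed tree hides an unknown number `i` of divisions whose other
daughter lineage left no sampled descendant. For a branch occupying the
backwards-time window `[tau_e, tau_s]`, `i` is Poisson with mean

    Lambda = 2 q (tau_s − tau_e) + 2 log[ f(tau_e) / f(tau_s) ],
    f(t)   = (1 − rho − q) e^{−(1−q) t} + rho,

and the joint weight that the branch lineage traverses the window while all
side clades go unsampled is

    p1(i | tau_s, tau_e) = e^{−(1+q)(tau_s − tau_e)} Lambda^i / i! .

These are embedding intensities rather than plain path probabilities: at a
hidden division either daughter may continue the branch, which contributes
the factor 2 inside `Lambda` (the Monte-Carlo oracle in
`divtree.simulate.mc_estimate_p1` makes this explicit by weighting
single-path hits with `2^i`). Summing the per-division Poisson counts over
`i + 1` divisions (the `+1` is the division founding the branch) makes the
branch mutation count compound Poisson — overdispersed relative to the
equal-mean Poisson of a molecular clock, which is the observable signature
of division-coupled mutagenesis.

The probability that a clade founded `tau` ago has no (or exactly one)
sampled extant descendant uses the standard sampled birth–death results
(`p0_sampled`, `p1_sampled`); the pendant-branch message carries one extra
factor `rho` for the sampling of the observed leaf.

## Likelihood algorithm

Branch durations and hidden division counts are latent. The likelihood of
`(q, mu)` given a tree integrates them out with a post-order message-passing
(pruning) scheme on a uniform time grid:

* pendant branch, `m` mutations: `P(nu|tau_s) = rho · Σ_i P(m|i) p1(i|tau_s, 0)`;
* internal branch: `P(nu|tau_s) = Σ_i ∫_0^{tau_s} dtau_e P(m|i) p1(i|tau_s,tau_e) · 2 P(nu'|tau_e) P(nu''|tau_e)`;
* root: `L = ∫_0^T dtau_s 2 P(nu'|tau_s) P(nu''|tau_s)`, a uniform origin-time
  prior truncated at the grid upper bound `T = 2 log(n_tips/rho)/(1−q)`
  (twice the expected tree age; the improper-prior limit is insensitive to
  `T` because the integrand decays at rate `1−q`).

Numerical choices:

* All time integrals use the trapezoidal rule on the shared grid
  (default 1000 subintervals); messages are tabulated at grid nodes only, no
  interpolation. Discretization error in the log-likelihood is O(h²) and
  ~3·10⁻⁶ per branch at the default resolution; it is smooth in `(q, mu)`
  and therefore cancels in likelihood comparisons, which is why a
  200-subinterval grid is sufficient (and is used) for fitting.
* Sums over `i` are truncated at `i_max` (default 50; 200 when `rho < 1`,
  where branches hide more divisions) and evaluated by Horner's rule in the
  grid-wide array `Lambda`. When `i_max` lies beyond the numerically
  negligible tail the sum is cut early; this changes nothing at double
  precision.
* Within one evaluation the internal-branch kernel depends on the branch
  only through `m`, so kernels are cached per distinct mutation count; each
  internal branch then costs one matrix–vector product. Cost is linear in
  the number of branches and quadratic in the number of grid subintervals.
* Messages are stored in log space with per-branch max-shifts; kernels are
  probabilities (≤ 1) and are kept in linear space. Entries that underflow
  double precision are flushed to zero — they are negligible relative to the
  near-diagonal kernel mass that every row retains.
* The grid upper bound depends on `q`, so grids (and kernels) are rebuilt at
  every parameter point during optimization; all model comparisons use the
  same grid policy.

### Molecular-clock comparison model

The comparison model keeps the identical population process but lets
mutations accrue as a Poisson process in calendar time at rate `mu_t`. Its
per-branch factor is `Poisson(m; mu_t (tau_s − tau_e)) · Σ_i p1(i|tau_s,
tau_e)`, i.e. the same survive-unsampled weight with the division-coupled
mutation kernel replaced by a clock. This factor is the natural analogue
chosen here; the two models have the same number of free parameters, so
their maximized log-likelihoods are directly comparable.

## Fitting and the heterogeneity test

`fit_mle` maximizes the (joint) log-likelihood over `(q, mu)` at fixed
`rho`: a coarse scan (linear in `q` over `[0, 0.98]`, geometric in `mu`
bracketing the per-branch mean mutation count) followed by bounded
Nelder–Mead with an explicit inward initial simplex (robust when the coarse
maximum sits on a boundary; `q = 0` is a legitimate optimum, e.g. for clock
fits). All evaluations are recorded in the fit trace.

For a tree containing several deep clades, `select_postnatal_clades` keeps
maximal disjoint clades strictly more than 100 mutations from the root with
at least 23 leaves (defaults chosen for adult hematopoietic trees, where
neonatal root-to-tip distances stay below ~85 mutations). Each clade is
analyzed independently — its own origin-time integral — and clades share the
time grid derived from the full tree's tip count.

`heterogeneity_test` compares the homogeneous model (one `(q, mu)` for all
clades) with a model granting one focal clade its own `(q_dist, mu_dist)`.
Because the joint likelihood factorizes over clades, the heterogeneous
optimum splits into two independent 2-parameter fits, both warm-started at
the homogeneous optimum so that `lambda_LR = 2 (logL_het − logL_hom) ≥ 0` up
to optimizer tolerance. `lambda_LR` is referred to chi-squared with 2
degrees of freedom; testing each of `k` clades in turn uses the Bonferroni
threshold `alpha / k` (default `alpha = 0.05`).

## Simulator

`simulate_tree` realizes exactly the process the likelihood describes:
Gillespie simulation from one founder, stopped the *first* time the
population reaches `N` (size-conditioned ensembles would also count later
passages; for supercritical growth at these sizes the difference is minor —
populations that die out first are simply redrawn, with the restart count
logged). Extant cells are Bernoulli(`rho`)-sampled, the spanning tree of the
samples is extracted with degree-2 nodes suppressed, and every branch
records its true duration and hidden-division count before mutations are
drawn as Poisson(`(i+1) mu`) per branch. Default study conditions follow the
recovery protocol: `N = 300`, `q = 3/4`, `mu = 1`, `rho = 1`, 50 replicate
populations.

What the generator does *not* emulate: sequencing noise and allelic dropout
(every true mutation is observed and correctly placed), time-accumulated
(lesion-type) mutations, age-structured cell cycles, and time-varying rates.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness of the model on
noisy real data.

## Problem sizes used in the shipped experiments

The replicate-recovery study uses 50 populations of 300 cells fitted on a
200-subinterval grid; the Monte-Carlo oracle comparisons use 10⁶ replicates
per parameter point; the null calibration of the heterogeneity test uses
200 homogeneous 8-clade datasets of 15-leaf clades on an 80-subinterval
grid. These sizes give standard errors comfortably inside the asserted
tolerances while keeping the full suite runnable on a laptop.

## Known limitations

* Multifurcations in input trees are resolved caterpillar-style in input
  order with zero-mutation branches (simultaneous divisions have probability
  zero in continuous time); the resolution is logged but alternative
  resolutions are not explored.
* `rho` is treated as known. Misspecifying it by an order of magnitude
  mostly rescales `mu` downward (more implied hidden divisions) and can
  shift `q`; on simulated data this shift is larger than on the published
  HSC trees, so `rho` should be fixed from external census estimates where
  possible.
* The likelihood conditions on neither survival nor final population size,
  matching the simulation protocol; estimates from very small trees
  (≲ 20 leaves) show visible downward bias in `q`.
* Asymptotic chi-squared calibration of the LRT holds well at the tested
  sizes, but boundary optima (`q = 0`) can make `lambda_LR` conservative.
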