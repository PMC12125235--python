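# Methods

## Model and sampling design

Lifetimes follow the generalized exponential distribution (GED)
`G(w) = (1 - e^{-λw})^θ` with shape `θ > 0` and known rate `λ > 0`. The
design measures lower k-records: for a stream of iid draws, the running k-th
smallest value each time it strictly decreases. The scheme draws `m1`
streams and keeps the l-th record of stream `l`, plus `m2` streams keeping
the first record; sorting the `n = m1 + m2` values gives the ordered sample,
and double type-II censoring observes ranks `r..s` only.

### The gamma reduction

Everything rests on one exact identity: if `W` is the i-th lower k-record of
a continuous base CDF `G`, then `U = -k log G(W) ~ Gamma(i, 1)`. For the GED
`U = kθ·t(W)` with `t(w) = -log(1 - e^{-λw})`. Consequences used throughout:

* record pdf/CDF/SF are gamma density/tails of `U`. Note the orientation:
  because records *decrease*, the **finite** Poisson sum
  `G^k Σ_{v<i} (-k log G)^v / v!` is the record's **CDF** `P(W ≤ w)` (upper
  gamma tail) and the complementary **infinite** series is its SF. The
  functions `krecord_cdf` / `krecord_sf` are named by what they compute, and
  the infinite series is never summed — it is evaluated as `1 − finite sum`.
* descending ranks in `w` are ascending ranks in `u`, so the ordered sample
  is the vector of order statistics of independent `Gamma(i_j, 1)` variables
  (independent but non-identically distributed, INID).

## Likelihood

The censored joint density of INID order statistics is a matrix permanent:
in the ascending convention, `r−1` rows of `P(W ≤ z_r)` (one per left-
censored unit), density rows at `z_r..z_s`, and `n−s` rows of `P(W > z_s)`,
each column carrying one record index; the permanent is divided by
`(r−1)!(n−s)!`. Which gamma tail enters which censor block is fixed by a
normalization test: with one censor block and a window of length ≥ 2 the
correct assignment integrates to 1 while the swapped one integrates to the
number of admissible orderings (= 2 in the three-unit case). The swapped
variant remains available (`swap_censor=True`) because the source tables'
conventions are ambiguous; both are reported by the reproduction driver.

The permanent is computed by Ryser's inclusion–exclusion with Gray-code
updates (exact, `O(2^n n)`, batched over parameter grids, per-row scaling in
log space). `n ≤ 14` is enforced; the study designs use `n ≤ 7`.

The **series form** expands the censor entries in powers of θ, giving
`Σ coef · θ^η · e^{-θW}` with θ-free `coef`, `η`, `W`; per multiset
permutation the per-slot series are combined by polynomial convolution over
the total degree. The one infinite direction (the `P(W > z_s)` entries) is
truncated at `lmax = 60` terms per slot (`TruncationPolicy`), far beyond the
Poisson tail at the magnitudes arising here; the permanent/series agreement
test (rel. 1e−6, in practice ~1e−14) bounds the truncation error. A
typographical sign in the source's expansion coefficients is resolved as
`(−1)^{i−1} k^i`, the factorization under which the per-permutation
reconstruction test passes exactly.

**Random sample size**: `N ~ Uniform(ρ, ξ)` independent of lifetimes, left-
truncated at `s` with constant conditional pmf
`((ξ−ρ+1) P(N ≥ s))^{-1}`. The mixture likelihood sums the per-n censored
likelihoods over `n ∈ {max(s,ρ),…,ξ}`; the per-n design truncates the scheme
to its first `n` sequences (`m1' = min(m1, n)`, `m2' = n − m1'`) — an
explicit modeling choice, as the construction for `n < m1 + m2` is otherwise
underdetermined.

**MLE**: Newton–Raphson on the numeric score, stopping at
`|θ_{j+1} − θ_j| < 1e−6` with a 100-iteration cap, initialized by moment
matching of the window gamma means (`θ0 = Σ i_κ / (k Σ t_κ)`); if the
curvature is not concave or Newton leaves `(0, ∞)`, a bracketed bounded
search takes over. The estimate is scale-equivariant (data × c with λ/c
leaves θ̂ unchanged), which the suite checks.

## Bayesian estimation

Prior `θ ~ Exp(b)`. Because every series summand is
`coef·θ^η e^{-θW}`, the posterior functionals are finite gamma-integral
sums — the normalizer `Σ coef·Γ(η+1)/(b+W)^{η+1}`, the mean with `η+2`, and
`E[e^{-cθ}|z]` with `b+c+W` — evaluated in log space. The *canonical* route,
however, is Gauss–Legendre quadrature (400 nodes on an adaptively located
support) against the exact permanent-form posterior; the gamma-integral
series is the cross-check (agreement ~1e−14, tested at 1e−5). Estimators:

* SE → posterior mean; LINEX → `−(1/c) log E[e^{-cθ}|z]` (continuous in c,
  decreasing in c);
* balanced versions: BSE `Δ·θ̂_MLE + (1−Δ)·E[θ|z]`; BLINEX mixes on the
  `e^{-cθ}` scale. Δ endpoints reproduce the components bit-for-bit.

**Empirical Bayes.** The prior rate is estimated by maximizing the exact
marginal likelihood `m(b) = ∫ L(θ|z) b e^{-bθ} dθ` (likelihood cached on a
quadrature grid; bounded search on `log b` over `(1e−6, 1e3)`). An
alternative recipe — integrating θ out of a *single base observation* first
(`G_b(w) = b/(b + t(w))`, `g_b = b·λe^{-λw}/((1-e^{-λw})(b+t)^2)`) and
rebuilding the record likelihood on that marginal base — is retained as
`method="base_marginal"` but is **not** the default: it treats the sequences
as if each drew its own θ, whereas one θ is shared by all `n` sequences, and
in simulation it under-recovers the true rate by a factor ~2.5, versus a
median within ~40% for the marginal-likelihood route (which is the expected
small-sample behavior of a single rate learned from seven values).

## Pivotal prediction

In the descending view the future `z_{τ:n}` (τ > s) is predicted from
`z_{s:n}` via `Ψ = (t(z_τ) − t(z_s)) / t(z_s)`. Under the gamma reduction
`Ψ = (u_{(τ)} − u_{(s)}) / u_{(s)}` for ascending order statistics of INID
gammas: free of θ, λ and k — an exact pivot (numerically verified to 1e−8
across θ, λ). Its survival function is computed three ways:

1. **quadrature** (canonical): 2-D tensor Gauss–Legendre over the exact
   permanent-form joint density of `(u_{(s)}, u_{(τ)})`;
2. **closed form**: expanding the censor blocks of the pair density in
   gamma-tail polynomials and integrating analytically; with integer record
   indices the hypergeometric representation of the integral collapses to an
   elementary finite sum, which is what is implemented;
3. **Monte Carlo**: simulate the scheme, compute the pivot, count
   exceedances (with binomial SE).

All three agree (closed vs quadrature ~1e−13; MC within 3 SE at 1e5 reps).
Solving `P(Ψ > ψ) = π` (Brent, tol 1e−8) yields the `(1−π)` interval
`[−(1/λ) log(1 − (1−e^{-λ z_s})^{ψ+1}), z_s]`. The quantile depends only on
`(s, τ, n)` and the record-index multiset — not on the data, k, θ or λ — so
it is computed once per design. Random N mixes the per-n survival functions
with the τ-truncated size pmf.

## Simulation harnesses

The estimation study generates censored samples at a fixed true θ, applies
MLE / Bayes / empirical-Bayes estimators and reports AV (mean estimate),
ABE (mean |θ̂−θ|) and RAB (= ABE/θ); these metric definitions are the ones
consistent with the internal ratios of the published tables, which also pin
the true shape used there at θ = 2/3 — adopted as the default study
condition, with λ = 1.5 (the data-analysis value) and prior rate b = 1.5
(prior mean equal to the true θ). The prediction study hides ranks beyond
`s`, builds the interval from the precomputed pivot quantile and reports
coverage (PC) and average width (AIW). The fixed-vs-random width comparison
keeps everything inside one master scheme (m1 = 5, m2 = 2), setting the
fixed size to the mean (n = 5) of the τ-truncated size distribution of
`N ~ Uniform(2, 7)`.

### Samplers

`generate_melrrss` walks actual streams (judgment ranking): per sequence it
draws blocks of `a` observations (doubling the block while waiting, since
record waiting times are heavy-tailed — the time past record value R is
geometric with success `G(R)`, and `E[T_2] = ∞`). `sample_melrrss_marginal`
draws each slot exactly from its `Gamma(i,1)` marginal via inverse CDF.
The suite validates the stream sampler against the gamma law (χ² at α=0.01)
and the two samplers against each other (two-sample KS); the Monte Carlo
harnesses default to the marginal sampler for speed. What the generator does
*not* emulate about real data: ranking errors (judgment ranking is assumed
perfect), ties (measure zero under the continuous model), model misfit
(lifetimes are exactly GED), and any dependence between streams. Passing
tests therefore certify the mathematics of the inference machinery, not the
robustness of the design to those violations.

## Reproduction of the published worked examples, and discrepancies

The embedded fixtures reproduce the published record extractions verbatim,
and `omelrrss reproduce` compares every worked-example cell. Two families of
discrepancies are documented rather than chased:

* **Point estimates.** The published case-I estimates (e.g. MLE 0.9045 for
  the nerve-impulse fixture at k=1) are not reproducible from the model's
  likelihood under *any* censor orientation, data ordering, or rate value —
  an inversion scan over λ ∈ (0.05, 8) cannot even reach some printed values
  (k=3 target 0.3283 vs an attainable minimum ≈ 0.48). The package reports
  its exact values under both orientations (0.7353 / 0.8124 for that cell)
  next to the printed ones.
* **Prediction intervals.** The published interval quantiles differ across k
  and across data sets for the same `(s, τ, n)` design, which an exact pivot
  cannot do; correspondingly the published simulated coverages miss their
  nominal levels by wide margins (e.g. 0.76 at nominal 0.95), whereas this
  implementation's coverage is exact to Monte Carlo error. With the exact
  quantile (ψ = 3.0916 at π = 0.05 for s=3, τ=4, n=7) the nerve-impulse
  interval width 0.0799 is reproduced to the printed precision; the
  renal-transplant widths are narrower than the published ones.

## Numerical choices and limitations

* Permanents: exact Ryser, `n ≤ 14`; densities with θ < 1 diverge at w = 0,
  so all quadratures use open endpoints.
* Posterior quadrature: 400 Gauss–Legendre nodes after locating the mode on
  a 160-point log grid and extending the support until the log-density falls
  45 nats below the peak.
* Pivot quadrature: 140-node tensor Gauss–Legendre with the gamma support
  cut at `isf(1e−13)` of the largest shape.
* Series truncation: `lmax = 60` per infinite slot; adequate for the
  magnitudes in the study designs (`k·t ≲ 10`); extreme inputs (very small
  `λ z_s`) would need a larger cap.
* λ is treated as known everywhere; joint (θ, λ) estimation, other priors,
  credible intervals and imperfect-ranking models are out of scope.
* Real-data caveat: three of the eight published true values fall outside
  the *exact* 95% intervals (all involving one unusually small renal value),
  consistent with model misfit of the fixed-λ GED on that data set rather
  than with a defect of the pivot, whose simulated coverage is exact.
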