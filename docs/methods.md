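# Methods

## The model

Crossovers transmitted to offspring are treated as a thinned renewal
process along the genetic map. Chiasmata on the four-strand bundle form a
stationary **gamma renewal process**: inter-chiasma distances are
Gamma-distributed with shape `nu > 0` and rate `2*nu*lam` per Morgan, so
their mean is `1/(2*lam)` Morgans. `nu` is the unitless interference
strength: `nu = 1` is the memoryless (Poisson, no-interference) case, and
larger `nu` makes chiasma spacing more regular. Under no chromatid
interference a given chiasma involves the transmitted chromatid with
probability 1/2, independently across chiasmata, so the observed crossover
process is the chiasma process thinned by a fair coin. Its inter-arrival
density is the geometric mixture

    f*(y) = sum_{k>=1} 2^{-k} Gamma(y; k*nu, 2*nu*lam),

with CDF `F*` defined term-by-term, and the chromosome start (which does
not coincide with a chiasma) sees the stationary first-arrival density
`g*(y) = lam * (1 - F*(y))`. The observed process has intensity exactly
`lam` crossovers per Morgan, so with `lam = 1` it reproduces the genetic
map by construction.

The **gamma-sprinkling (Housworth–Stahl) model** superposes on this an
independent homogeneous Poisson pathway of rate `p` per Morgan — the
non-interfering ("class II") crossovers — and sets the interfering
pathway's rate to `lam = 1 - p`, keeping the total at 1 per Morgan. The
likelihood of the ordered crossover positions `y_1 < ... < y_n` on a
chromosome of genetic length `L` Morgans is the exact sum over all `2^n`
assignments of observed crossovers to the two pathways:

    L(y | nu, p) = e^{-pL} * sum_{S subset of y} p^{n-|S|} * L_gamma(S | nu, 1-p)

where the gamma-pathway term for a subset `S = {s_1 < ... < s_m}` is
`g*(s_1) * prod f*(s_{j+1}-s_j) * (1-F*(L-s_m))`, and the empty subset
contributes `P(no observed gamma-pathway crossover on [0,L])`. At `p = 0`
this reduces exactly to the pure gamma model (`nu` then plays the role of
the single-parameter estimate usually denoted `nu0`).

Assumptions worth keeping in view: no chromatid interference; a stationary
start at the left telomere with right-censoring at `L` (no conditioning on
an obligate crossover — an alternative convention some implementations
use); both `nu` and `p` constant along a chromosome; and the two pathways
statistically independent. These are statistical abstractions, not
mechanistic claims.

## Hierarchical group-effect model

`nu` and `p` vary over groups of meioses (i = 1..m) and groups of
chromosomes (j = 1..n) through additive link-scale effects:

    log(nu_ij)  = beta0 + beta_i + beta_j
    logit(p_ij) = alpha0 + alpha_i + alpha_j

Priors are independent normals: group effects `N(0, sigma^2)` with
`sigma_nu = sigma_p = 1` by default (weak shrinkage: one prior SD spans
roughly a 2.7-fold change in `nu` or in the odds of `p`, comfortably
covering the plausible ranges `nu ~ 1-40`, `p ~ 0.001-0.15`), intercepts
`N(0, 10^2)` (effectively flat over those ranges while keeping the
posterior proper). The hyper-parameters are fixed, not sampled. The
additive parameterization is deliberately redundant — moving mass between
the intercept and the effects leaves every `nu_ij` unchanged — and the
shrinkage prior is what makes the posterior proper along that direction.
A grouping dimension with a single level (the chromosome dimension under
the by-sex scheme) has its effect fixed at 0 rather than sampled, since it
is wholly confounded with the intercept.

Grouping schemes: `by_sex` (m=2, n=1); `by_sex_and_size` with chromosome
bins long (1–5), medium (6–12), short (13–19), each roughly one third of
the cumulative genetic map; `by_sex_and_chromosome`; or a custom mapping.

## Inference

**MCMC.** A component-wise Gaussian random-walk Metropolis sampler run as
Metropolis-coupled chains (default 3) at tempered posteriors with a
geometric ladder (1, 0.7, 0.49); adjacent-pair swap proposals every
iteration; inference uses only the cold chain. Proposal scales adapt
during burn-in only, by Robbins–Monro steps on the log scale
(`c/t^0.6`), targeting a rejection rate of 0.4 per coordinate; scales are
frozen after burn-in so the retained draws satisfy detailed balance. The
default run length is 25,000 iterations with 5,000 discarded as burn-in.
Initialization: all link-scale parameters 0 except `beta0 = log(10)`
(interference near typical mouse values); the posterior here is close to
unimodal, so results are insensitive to the ladder. All randomness flows
from a single integer seed; identical options and seed reproduce the
draws bit-for-bit.

Summaries are computed on the natural scale (`nu_ij`, `p_ij`, or their
ratios between cells), per draw: posterior mean, central 50% and 95%
quantile intervals, the shortest 95% HPD interval (empirical
shortest-interval method via ArviZ), and effective sample size.

**Maximum likelihood.** The same additive link-scale model without the
prior. Because the parameterization is redundant, the optimizer works in
a reference-coding gauge (first effect of each multi-level block pinned at
0), which spans the same set of cell parameters and makes the free
parameter count equal the identifiable count — the count used for AIC and
likelihood-ratio degrees of freedom. Optimization is derivative-free
Nelder-Mead from 5 seeded starts (for the sprinkling model one start is
placed near the gamma solution with small `p`, which also enforces the
nested-model inequality in practice). The gamma vs. sprinkling comparison
under `by_sex` has df = 2.

**Per-chromosome interference.** Under `by_sex_and_chromosome` the
chromosome-specific `nu` posterior means come from the reduced (pure
gamma) model — the sprinkling model is weakly identified at
per-chromosome sample sizes — and are rank-correlated with sex-specific
genetic length (Spearman, average ranks for ties, t-approximation
p-value) over all sex × chromosome points. Constant inputs are reported
as rho = 0, p = 1 with a degeneracy flag.

## Numerics

* All public data interfaces use centimorgans; likelihood internals use
  Morgans, where the process rates are unit-free.
* The thinning series is summed with all density terms in log space. The
  survival series `sum_k 2^{-k} Q(k*nu, b*y)` is closed with its exact
  geometric tail `2^{-K}` once `Q` has saturated at 1, giving truncation
  error below `2^{-K} * 1e-14`; the term cap (500) raises an error rather
  than truncate silently.
* The zero-crossover probability uses the term-by-term closed form
  `int_0^L P(a, b t) dt = L P(a, bL) - (a/b) P(a+1, bL)`, exact up to
  series truncation; adaptive quadrature of `g*` serves as an independent
  oracle in the tests, not as the production path.
* Dataset-level evaluation has two engines. The *exact* engine evaluates
  every record through scipy's incomplete-gamma functions. The *fast*
  engine (numba) tabulates `log f*` and `log(1-F*)` on a 1,024-point grid
  per parameter proposal and evaluates records by cubic Hermite
  interpolation with exact derivatives; distances below 0.02 Morgans,
  where `log f*` has a `(nu-1) log y` singularity, and all points in
  small group cells are evaluated by the exact series instead. The two
  engines agree to ~1e-6 per record in the tests. The fast path carries
  its own regularized incomplete-gamma implementation (power series plus
  Lentz continued fraction), validated against scipy to 1e-12 over the
  parameter ranges in use.
* The subset sum is guarded at n = 20 crossovers per chromatid (2^n
  terms); real and simulated records stay below ~6.
* Crossovers closer than 1e-4 cM on one chromatid are rejected as data
  errors: below any real map resolution, and zero distances have no
  density under the renewal model. Junctions reported as intervals in
  segment tables are placed at the interval midpoint, the unbiased
  single-point summary.

## The synthetic-data generator

`simulate_chromosome` draws the chiasma train from the gamma renewal
process started 20 mean inter-arrivals before the chromosome start —
far beyond the process's relaxation time, so the state at position 0 is
stationary to below simulation noise — thins it with a fair coin, and
superposes the Poisson pathway. `simulate_dataset` emulates the study
design the package targets: 474 fully observed meioses per sex (948
total) across the 19 mouse autosomes, with default parameters at the
published genome-wide sex-specific estimates (`nu_F = 11.2,
p_F = 0.0094; nu_M = 18.6, p_M = 0.027`).

The bundled genetic map fixture has sex totals of exactly 1,355 cM
(female) and 1,221 cM (male), allocated across chromosomes 1–19 by a
linear decline (weights 33..15, ratio ~2.2 between chromosomes 1 and 19)
— a realistic monotone profile, not the measured per-chromosome map. It
ships as a TSV precisely so users can substitute the real map.

What the generator does *not* emulate: chromosome-specific interference
(defaults use one `nu` per sex, so per-chromosome analyses on synthetic
data should find no length correlation); the X chromosome; genotyping
error and junction-localization uncertainty (positions are exact);
crossover suppression near centromeres; and any obligate-crossover
mechanism. Consequently, passing tests demonstrate self-consistency of
likelihood, sampler and simulator under the stated model — not that the
model captures every feature of real data. Two visible symptoms of that
gap, expected and harmless: the synthetic female mean inter-crossover
distance is ~43 cM where real mouse data show ~44.8 cM, and a pure-gamma
fit to sprinkling-generated data gives much lower `nu` (and a much larger
gamma-vs-sprinkling likelihood ratio) than the same fit on real data.

## Problem sizes in the tests and the acceptance script

Monte-Carlo checks use 1e5–1e6 replicate chromatids (count classes,
zero-class probability, rate conservation) and 1e5 inter-crossover
distances for the distributional KS check; the KS check uses a 100-Morgan
chromosome because complete renewal intervals inside a finite window are
a length-biased-down sample with mean bias of order `E[y^2]/L`. The
parameter-recovery check runs 6 replicate full-size datasets with
6,000-iteration single chains (1,000 burn-in). The acceptance script
refits the full synthetic dataset with 3 coupled chains of 6,000
iterations (1,500 burn-in); posterior means stabilize well within these
lengths (ESS of several hundred per scalar), and longer default runs are
available through `McmcOptions`.

## Known limitations

* The stationary-start / right-censoring convention at chromosome ends is
  one of several in the literature; implementations that condition on an
  obligate crossover will give slightly different `nu` on short
  chromosomes.
* `p` is identified mainly by the short-distance tail of inter-crossover
  distances; with few multi-crossover chromatids (short maps, small
  samples) its posterior is prior-sensitive.
* Hyper-parameters (`sigma_nu`, `sigma_p`) are fixed, not given
  hyperpriors; with very many groups a hierarchical scale estimate would
  be preferable.
* The exact subset-sum likelihood is exponential in the per-chromatid
  crossover count; fine for mammalian pedigree data (n <= ~5), unsuitable
  for organisms with long genetic maps per chromosome unless records are
  segmented.
* No interaction effects between meiosis groups and chromosome groups on
  the link scales, and no individual-meiosis random effects.
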