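# Methods

`zicoex` tests whether the co-expression of a gene pair differs between two
conditions in multi-patient single-cell RNA-seq, while accounting for the
count nature of the data, excess zeros, sequencing-depth variation, and the
correlation between cells drawn from the same patient.

## Model

For a cell $i$ with counts $(y_{i1}, y_{i2})$ of the two genes, the
pre-dropout joint distribution is a Gaussian copula with NBII negative
binomial marginals.  The NBII distribution has mean $\mu$ and variance
$\mu + \mu^2\sigma$; as $\sigma \to 0$ it becomes Poisson($\mu$).  We
implement it as a standard negative binomial with size $r = 1/\sigma$ and
success probability $r/(r+\mu)$, the unique mapping with that mean and
variance; $\sigma < 10^{-8}$ switches to the Poisson limit because $1/\sigma$
overflows the NB parameterization.

The copula cdf is
$G(y_1,y_2) = \Phi_2\!\big(\Phi^{-1}F_{NB}(y_1),\,\Phi^{-1}F_{NB}(y_2);\rho\big)$
and the discrete joint pmf is the rectangle difference
$g(y_1,y_2) = G(y_1,y_2)-G(y_1{-}1,y_2)-G(y_1,y_2{-}1)+G(y_1{-}1,y_2{-}1)$.
Dropout enters as independent per-gene Bernoulli masking with
probabilities $(p_1, p_2)$, giving the four-branch mixture
$f = (1-p_1)(1-p_2)\,g + [y_2{=}0]\,(1-p_1)p_2 f_{NB}(y_1)
 + [y_1{=}0]\,p_1(1-p_2) f_{NB}(y_2) + [y_1{=}y_2{=}0]\,p_1 p_2$,
whose marginals are zero-inflated negative binomials.

Each of the seven natural parameters
$\theta \in \{\mu_1,\mu_2,\sigma_1,\sigma_2,\rho,p_1,p_2\}$ has a linear
predictor with its own fixed effects and optional patient-level random
intercepts,

$\log\mu_{ij} = x_i^\top\beta_j + z_i^\top u_{\mu_j} + \log S_i$,
$\log\sigma_{ij} = x_i^\top\alpha_j (+\,\ldots)$,
$\operatorname{atanh}\rho_i = x_i^\top\tau + z_i^\top u_\rho$,
$\operatorname{logit} p_{ij} = x_i^\top\kappa_j + z_i^\top u_{p_j}$,

where $S_i$ is the cell's total sequencing depth (the offset enters only
the mean predictors) and each row of a random-effect design $Z_\theta$ is a
standard basis vector indicating the cell's patient (or patient-by-condition
cell).  With a 0/1 condition indicator, $\tau_1$ — the condition coefficient
of the $\rho$ predictor — is the differential co-expression parameter, and
the population-level correlations are $\rho_g = \tanh(\tau_0 + \tau_1 g)$.

Random effects are treated as penalized coefficients: the objective is the
penalized log-likelihood
$\ell(\delta,u) = \sum_i \log f(y_{i1},y_{i2};\delta,u)
  - \tfrac12\sum_\theta u_\theta^\top \mathrm{diag}(\lambda_\theta)\, u_\theta$,
with one smoothing parameter per variance component (all intercepts of a
component share a $\lambda$).  The implied random-effect variance reported
for a component is $1/\lambda$, the scale of the equivalent normal prior.

## Numerics

- **Bivariate normal cdf.**  Owen's T representation via
  `scipy.special.owens_t`, vectorized over cells and accurate to ~1e-14
  absolute (validated in tests against `scipy.stats.multivariate_normal`).
  Results are clamped to the Fréchet bounds.
- **Clipping.**  Marginal cdf values are clipped to $[10^{-15}, 1-10^{-15}]$
  before the normal quantile; logit predictors are clipped to $[-15,15]$,
  the atanh predictor to $[-7,7]$, log-dispersion to $[-12,12]$ (guards the
  $p\to0/1$, $|\rho|\to1$ boundaries when a margin has no excess zeros), and
  the total log-mean to $[-30,30]$ as an overflow guard.
- **Rectangle clamp.**  Negative rectangle probabilities of magnitude below
  1e-12 are floating-point cancellation and are clamped to zero; anything
  larger raises an internal-consistency error.
- **Log floor.**  Cell log-probabilities floor at $\log(10^{-300})$ so an
  isolated impossible-looking cell cannot produce $-\infty$.
- **Derivatives.**  Per-cell first derivatives of $\log f$ with respect to
  the seven predictors are closed-form through the copula rectangle, the
  dropout mixture, and the links ($\partial\Phi_2/\partial x$ and
  $\partial\Phi_2/\partial\rho$ are analytic; $\partial F_{NB}/\partial\mu$
  is the incomplete-beta partial).  Only
  $\partial F_{NB}/\partial(\log\sigma)$ uses a tight central difference
  (step $10^{-5}$), since the incomplete beta has no closed-form partial in
  its first parameter.  Per-cell second derivatives are central differences
  of that score (step $10^{-4}$).  The correctness contract — enforced in
  the test-suite on random coefficient states — is agreement with central
  finite differences of the penalized log-likelihood itself (gradient
  relative error $<10^{-5}$; Hessian diagonal $<10^{-3}$ at FD step
  $10^{-3}(1+|x|)$, the step at which the difference quotient's own
  round-off, $4\varepsilon|\ell|/h^2$, stays below the tolerance).

## Fitting

**Inner loop (fixed $\lambda$).**  Trust-region ascent with an exact
subproblem solver (eigendecomposition; Moré–Sorensen style boundary root,
hard case included).  Steps are accepted only if they strictly increase the
objective; the radius shrinks ×0.25 when the actual/predicted improvement
ratio falls below 0.25 and doubles when the ratio exceeds 0.75 on a
boundary step (standard Conn–Gould–Toint constants).  Iteration ends when
an accepted step improves the objective — or the quadratic model predicts
an improvement — of less than machine epsilon relative to the objective's
magnitude, with an iteration cap (default 200) that flags rather than
raises.  By default a cheap phase using the score outer-product (BHHH) as
curvature takes the bulk of the steps, and an observed-Hessian phase
finishes the convergence; `hessian="exact"` uses the observed Hessian
throughout.

**Starting values.**  Cells with a zero count get weight 0.5 (others 1).
Dropout predictors start from a weighted ridge-IRLS logistic regression of
the zero indicator on $[X_p\,|\,Z_p]$; margins with no zeros start at the
clipped predictor $-15$.  Mean rates start from weighted per-pattern
moments $\hat\mu = \sum w y / \sum w S$, dispersions from weighted
method-of-moments residuals, and the copula predictor from the weighted
Pearson correlation of marginal normal scores (mid-cdf transform).  All
other random effects start at zero.  A gene that is zero in every cell is a
degenerate margin and is rejected.

**Outer loop ($\lambda$ selection).**  Two strategies:

- `lambda_method="em"` (default): iterate the variance-component fixed
  point $\lambda_j \leftarrow r_j / (\lVert\hat u_j\rVert^2 +
  \operatorname{tr} V_{jj})$, where $V = (-H_{pen})^{-1}$ and $r_j$ is the
  component size — the EM update of the equivalent normal-prior variance —
  warm-starting each refit, until the largest $\log_{10}\lambda$ change
  falls below 0.05 (cap 15 iterations).  This typically costs 3–8 inner
  fits.
- `lambda_method="aic_grid"`: per-component coordinate search over a
  $\lambda$ grid (default $10^{-4..6}$, 11 points, optional golden-section
  refinement), minimizing $\mathrm{AIC}_{edf} = -2\hat\ell + 2\,edf$ with
  $edf = \operatorname{tr}(H_{pen}^{-1} H_{unpen})$, the standard
  penalized-likelihood effective degrees of freedom.

Both are documented substitutes for the nested outer update of the
literature this model family builds on, whose exact criterion is not fully
specified; they select essentially the same $\lambda$ on our simulations
(the EM default recovers the generating $\lambda$ of the droplet preset to
within a factor ~1.5 at m=10 patients).  The default is the EM update
because the grid search costs ~5× more inner refits with no measurable
difference in the $\tau_1$ estimate.

**Inference.**  Wald tests use the observed Hessian of the penalized
log-likelihood at the optimum: $SE$ from the corresponding diagonal of
$(-H_{pen})^{-1}$, $p = 2\Phi(-|z|)$, and 95% intervals
$\hat\beta \pm z_{0.975}\,SE$ on the link scale (natural-scale intervals
map the endpoints through the inverse link).  We use the exact quantile
$z_{0.975}=1.959964$ so that the test/interval duality
($p<0.05 \iff$ CI excludes 0) holds identically.  If the Hessian is not
negative definite at termination, a diagonal ridge is added for inversion
and the fit is flagged; non-converged fits propagate missing p-values and
are excluded from the Benjamini–Hochberg denominator.  Because the
covariance treats the selected $\lambda$ as fixed and the random effects as
penalized coefficients, intervals for $u$ are conservative, while
population-level contrasts can be slightly anticonservative at small
patient counts (see Limitations).

## Simulator

`simulate(preset, seed)` follows the model's own mechanism: draw patient
random intercepts $u_\theta \sim N(0, \sigma_\theta^2)$; form per-cell
parameters through the links; draw a standard bivariate Gaussian pair with
correlation $\rho_i$; set $v_{ij} = F_{NB}^{-1}(\Phi(z_{ij}); \mu_{ij},
\sigma_{ij})$; mask with independent Bernoulli($p_{ij}$) dropout.
Per-patient RNG substreams are spawned deterministically from the seed, so
growing the patient count leaves earlier patients' data unchanged, and a
fixed seed reproduces the dataset bit-for-bit.

Two presets encode the study conditions used throughout the tests:

- **droplet** (10x-style): coefficients
  $[\beta_{01},\beta_{11},\beta_{02},\beta_{12}] = [-7.26, 0.45, -7.10,
  0.20]$, $[\alpha_{01},\alpha_{11},\alpha_{02},\alpha_{12}] = [-0.46,
  -0.19, -0.44, -0.04]$, $[\tau_0, \tau_1] = [0.06, -0.20]$, dropout
  probabilities $[p_{01}, p_{11}, p_{02}, p_{12}] = [0.01, 0.05, 0.01,
  0.01]$, offset $\log(3\times10^4)$; half of each patient's cells in each
  condition (a within-patient pre/post design).
- **plate** (Smart-seq2-style): $[-7.43, -1.26, -8.26, -0.65]$,
  $[0.51, 0.65, 0.85, 0.26]$, $[0.35, -0.34]$, $[0.08, 0.14, 0.11, 0.21]$,
  offset $\log(5\times10^5)$; cells split 50/50 at random (a cell-type
  contrast within patients).

The dropout entries are on the probability scale: $p_{0j}$ is gene $j$'s
dropout probability in the reference condition and $p_{1j}$ its increment
in the other condition (so condition-1 dropout is $p_{0j}+p_{1j}$); the
robustness scenarios set all four to exactly zero, which the logit scale
could not express.  Patient random-intercept SDs are 0.2 for the means and
$\rho$ and 0.1 for the dropout logits — values chosen once to induce
visible within-patient correlation; they are a package convention, not a
quantity the calibration fixes.  The presets emulate a two-gene pair with
realistic droplet/plate sparsity and depth; they do not emulate
genome-scale count matrices, ambient contamination, batch structure, or
cell-type mixtures, so passing tests demonstrate correctness of the
mechanism and estimator, not robustness to those real-data features.

## Screening pipeline

Counts are read from a 10x-style MTX triplet or dense TSV/CSV; metadata
from a TSV with `cell_id, patient, group[, depth]`.  Depth defaults to the
cell's total count over all genes before any gene filtering (a metadata
depth column takes precedence).  Gene filters: user-supplied exclusion
lists (mitochondrial/housekeeping/non-coding); zero fraction > 0.70;
nearest-rank (type-1) 97.5% quantile < 4 (the type-1 rule keeps integer
counts reproducible across platforms).  Plate-mode screens additionally
drop genes whose normalized expression has SD < 0.4 in either group or
between-group |SD difference| < 0.1; when no externally normalized matrix
is supplied, a log1p of median-depth-scaled counts is used as the
(pluggable) fallback normalization.  All $\binom{n}{2}$ pairs are fitted
independently; per-pair failures are recorded with a convergence flag and
missing p rather than aborting; per-pair JSON caching makes screens
resumable and reruns bit-identical.  The top table ranks converged pairs by
$|\Delta\rho| = |\tanh(\hat\tau_0+\hat\tau_1) - \tanh(\hat\tau_0)|$
(population level, random effects excluded).

## Problem sizes used by the test-suite

The statistical acceptance tests run the simulation studies at these
sizes, chosen as the package's standard verification workload:
parameter recovery at 25 replicates of m=10 patients × 250 cells; null
calibration at B=200 replicates of m=10 × 100 cells; CI coverage at B=100
replicates of m=5 × 200 cells (with and without zero-inflation);
Monte-Carlo density oracles at $10^6$ draws; simulator law checks at
$10^5$ cells.  `scripts/acceptance.py` re-runs the same studies at smaller
replicate counts and records the resulting quantities.

## Limitations

- Only the Gaussian copula is implemented.  The density layer funnels all
  dependence through one bivariate-normal cdf routine so Archimedean
  copulas (Clayton/Joe/Gumbel/Frank) are a backend swap away, but none is
  provided.
- One grouping factor per parameter; no crossed random effects; no smooth
  (spline) terms in predictors.
- Wald covariance conditions on the selected $\lambda$, so
  smoothing-parameter uncertainty is not propagated into the standard
  errors; the null-calibration test in the suite measures the practical
  consequence at the droplet preset.
- The $p_j$ predictors never receive the depth offset (the links place it
  only in the means); dropout is depth-independent by construction.
- BH correction treats pairs as exchangeable tests; no dependence
  adjustment across overlapping pairs.
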