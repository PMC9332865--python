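# Methods

## The model

For child $k$ let $Y_{k1} \in \{0,1\}$ indicate anaemia (haemoglobin
$< 9.9$ g/dL) and $Y_{k2} \in \{0,1\}$ malnutrition (weight-for-age z-score
$< -3.0$); values exactly at a threshold are classified healthy. Each margin
has an event probability

$$p_{km} = g_m^{-1}\big(\mathbf{x}_{km}^\top \boldsymbol\beta_m + f_m(\text{age}_k)
 + u_{\,r(k),m}^{\text{str}} + u_{\,r(k),m}^{\text{unstr}}\big), \qquad m = 1, 2,$$

with link $g_m \in \{\text{logit}, \text{probit}, \text{cloglog}\}$,
treatment-coded categorical fixed effects, a penalized smooth in age, and two
region-level effects indexed by the child's region $r(k)$. The two margins
are joined by a one-parameter Archimedean copula $C(\cdot,\cdot;\theta)$,
giving the joint cell probabilities by inclusion–exclusion:

$$p_{11} = C(p_1, p_2;\theta), \quad p_{10} = p_1 - p_{11}, \quad
  p_{01} = p_2 - p_{11}, \quad p_{00} = 1 - p_1 - p_2 + p_{11}.$$

The log-likelihood sums the log cell probability matching each observed pair.
Supported families: Clayton ($\theta > 0$, lower tail dependence), Gumbel
($\theta \ge 1$, upper tail dependence), Frank ($\theta \ne 0$, no tail
dependence), and the independence copula as a parameter-free reference.
Clayton is restricted to positive dependence: the printed $[-1,\infty]$
domain is degenerate at $0$, and negative-dependence Clayton has no
counterpart in the Gumbel comparison set, which would make family selection
ill-posed. Independence is its own family rather than a boundary case.

### Penalties

* **Age smooth**: cubic B-spline basis, $k = 10$ basis functions on equally
  spaced clamped knots over $[0, 59]$ months, second-order difference penalty
  (rank 8). A centering constraint (null space of the training-sample basis
  column means) makes the smooth orthogonal to the intercept; its penalty
  null space after centering is one-dimensional (a linear trend).
* **Structured spatial effect**: one coefficient per region, intrinsic
  autoregressive penalty $K = D - A$ (graph Laplacian of the region
  adjacency), sum-to-zero constraint absorbed per connected component.
* **Unstructured spatial effect**: one coefficient per region, identity
  (ridge) penalty, capturing exchangeable regional heterogeneity.

Penalized blocks $b$ contribute $-\tfrac12 \lambda_b
\boldsymbol\beta_b^\top S_b \boldsymbol\beta_b$ to the objective.

## Estimation

The dependence parameter is optimized on an unconstrained scale
(Gumbel $\theta = 1 + e^{\eta}$, Clayton $\theta = e^{\eta}$, Frank
$\theta = \eta$). Starting values come from separate unpenalized
Fisher-scoring fits of the two margins and from inverting the empirical
tau-b of the observed 2×2 outcome table to $\theta$ (falling back to
near-independence when the observed tau is unattainable by the family).

The inner optimizer maximizes the penalized log-likelihood with ascent
directions from the outer product of per-record analytic scores (the BHHH
information) plus the exact penalty Hessian, under a backtracking line
search. Once progress slows or the gradient is small it switches to Newton
steps on a central-finite-difference Hessian of the analytic gradient;
converged fits reach a gradient 2-norm below $10^{-6}$ (typical final
gradients are $10^{-8}$–$10^{-12}$). The fitter is deterministic.

Smoothing parameters minimize $\mathrm{AIC}(\lambda) = -2\ell +
2\,\mathrm{edf}(\lambda)$ with $\mathrm{edf} =
\operatorname{tr}(H_u H_p^{-1})$, where $H_u$ is the unpenalized and
$H_p = H_u + \sum_b \lambda_b S_b$ the penalized information. The search is
coordinate-wise over each block's $\log\lambda$ on the grid
$10^{-4}\ldots10^{4}$ (5 points) followed by golden-section refinement
(4 steps), with warm starts. During the search $H_u$ is approximated by the
score outer product (cheap and adequate for ranking $\lambda$ values); the
final fit recomputes the exact finite-difference Hessian, from which the
reported EDF, the coefficient covariance $H_p^{-1}$, and all standard errors
derive. With nothing penalized the EDF equals the raw parameter count — 31
for the seven-factor fixed-effects model (15 coefficients per margin plus
$\theta$).

Numerical safeguards: marginal probabilities are clipped to
$[10^{-10}, 1-10^{-10}]$ and cell probabilities floored at $10^{-12}$ inside
the log; $p_{11}$ is clipped into the Fréchet–Hoeffding band so all four
cells are nonnegative and sum to one by construction; Frank quantities use
`expm1`/`log1p` and switch to a series in $\theta$ below $|\theta| =
10^{-5}$; the unconstrained dependence parameter is kept in $[-15, 15]$. A
fit where more than 10% of fitted probabilities sit at the clip bounds
triggers a separation warning.

## Selection and inference

Copula families (Clayton, Gumbel, Frank) and the four link pairs
(logit, logit), (logit, cloglog), (logit, probit), (cloglog, probit) are
compared by AIC on the seven-factor fixed-effects model by default; exact
ties resolve to the earlier candidate in order. Fixed effects get Wald
$z$ tests from the covariance diagonal. Penalized blocks get
$\chi^2 = \boldsymbol\beta_b^\top \mathrm{Cov}_b^- \boldsymbol\beta_b$
(generalized inverse) on the block EDF rounded to the nearest 0.5, referred
to the chi-square via the gamma CDF — the exact reference distribution under
penalization is an open question generally; this recipe is simple,
documented, and its empirical size on synthetic nulls is close to nominal
(measured ≈7.5% at $\alpha = 5\%$ in the packaged simulations). The
model-implied Kendall's tau uses the closed forms (Gumbel $1 - 1/\theta$,
Clayton $\theta/(\theta+2)$, Frank via the Debye function) with a
delta-method CI through the unconstrained-parameter transform.

## Synthetic data

The generator draws covariates with frequencies approximating the pooled
three-country sample (≈60% rural, 50% female, education 12/55/33%,
wealth 45/25/30%, …), uniform integer ages 0–59 months, and uniform region
assignment on a rook-adjacency lattice (default 4×4). Default fixed-effect
coefficients are moderate (|β| ≤ 0.6) with prevalences near the observed
ones; the default dependence is Gumbel θ = 2 (tau 0.5) with links
(logit, probit). The default age curve is a single-arch sine,
$0.5\sin(\pi\,\text{age}/59)$, rising to a peak near 30 months — the shape
reported for anaemia risk — and is centered over the age range so the
intercept stays comparable. Structured effects are drawn from the
properized-Laplacian Gaussian (ridge $10^{-6}$), deterministically rescaled
so the average marginal variance equals the configured value (default 0.15)
and centered per component; unstructured effects are i.i.d. (default
variance 0.05) and also centered. Binary pairs are drawn as one multinomial
cell per child from the four true cell probabilities.

What the generator does **not** emulate: DHS two-stage cluster sampling and
survey weights, non-response, country pooling heterogeneity, measurement
error in haemoglobin/WAZ, and real administrative geographies (a lattice
stands in for the region maps). Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to survey-design features.

## Simulation sizes and what the packaged checks show

The recovery check fits 20 replicates at $n = 5000$ on a 4×4 grid from the
default generator and verifies that 95% Wald intervals cover the generating
fixed-effect coefficients in at least 90% of coefficient–replicate pairs
(intercepts excluded: centered smooth/region effects identify them only up
to $O_p(n^{-1/2})$ centering shifts), that the mean $\hat\theta$ is within
10% of 2, and that AIC selection picks Gumbel in a clear majority. The
block-test study runs the flat-age null at $n = 3000$ (40 replicates) and
the sine alternative at the same size (20 replicates); the simulation size
was chosen so the default alternative is detectable with high power, the
usual design criterion for a power study. The acceptance script repeats
these analyses at slightly reduced sizes (10 replicates at $n = 4000$;
20/12 replicates for size/power).

## Known limitations

* Structured and unstructured effects are both region-level; only the
  penalties separate them, so AIC often attributes shared regional variance
  to the unstructured block (the familiar identifiability feature of
  such convolution models). Interpret the two blocks jointly.
* Smoothing-parameter selection is AIC-based; no REML/marginal-likelihood
  option, no sandwich covariance, no survey weights, no multiple imputation
  (complete-case only).
* Link-pair discrimination by AIC is intrinsically weak at moderate sample
  sizes; selection tables should be read as rankings, not evidence of a
  "true" link.
* The copula is restricted to the bivariate Archimedean families above;
  d > 2 outcomes and tail-dependence estimation are out of scope.
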