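# Methods

## Model

A treatment cycle `i` transfers `n_i` embryos. The outcome `k_i` (number of
implantations) is modelled as the product of two latent Bernoulli layers:
uterine receptivity `R_i ~ Bernoulli(u_i)` at the cycle level and embryo
viability `V_ij ~ Bernoulli(e_ij)` per embryo, mutually independent given
covariates, with `k_i = R_i · Σ_j V_ij`. Both probabilities carry logistic
regression sub-models; a cycle-level covariate may appear in either or both
sub-models, an embryo-level covariate only in the embryo sub-model. The
observed-data likelihood marginalises the latent layers:

    P_ik = (1 − u_i)·δ(k) + u_i · S_k(e_i1 … e_in),

where `S_k` is the subset-sum (Poisson-binomial) probability of exactly `k`
viable embryos. `S_k` is evaluated exactly — explicit subset enumeration for
`n_i ≤ 10`, a dynamic-programming convolution beyond (identical values; the
cap only bounds the enumeration cost). Inside the vectorised likelihood the
convolution is always used, over a padded per-cycle layout in which padding
slots carry `e = 0` and are transparent to the recursion.

Key model assumptions: independence of embryos within a cycle given
covariates, independence of the uterine and embryo layers, and independence
across cycles (no repeat-cycle random effects; see Limitations).

## Identifiability

With single embryo transfers only, the likelihood depends on `u` and `e` only
through the product `u·e`: the sub-models are separately identified only via
cycles with two or more embryos, through the twin rate. The fitter therefore
treats a near-singular observed information (condition number above 1e8) as a
statistical warning, not an error, and still returns the ridge solution.

## Fitting

The coefficient space is unconstrained under the logit parametrisation, so
the log-likelihood is maximised directly: BFGS with the analytic gradient
(derived from leave-one-out Poisson-binomial tables), followed by damped
Newton steps using a central finite-difference Hessian of the analytic
gradient until the gradient norm falls below 1e-8 (maximum 500 iterations
overall). The polish Hessian is computed once and reused while steps make
progress. Starting values are moment-matched intercepts — the receptivity
rate taken as twice the overall success rate (roughly half of receptive uteri
yield a pregnancy in the calibrated regime), the embryo intercept from the
per-embryo implantation rate among successful cycles, both clipped to
[0.02, 0.98] before the logit — with all slopes at zero. Fitting is
deterministic given data and specification. Standard errors from the inverse
observed information are exposed as a diagnostic only; all hypothesis tests
are likelihood-ratio tests, which behave better than Wald tests at these
sample sizes.

Degenerate inputs: a cycle whose outcome has probability zero under the
parameters (e.g. an observed implantation while the viability path underflows
to zero) is reported by id via `ZeroProbabilityError` in the public
log-likelihood; inside the optimiser the per-cycle likelihood is floored at
the smallest positive normal so the search can move away rather than abort.

## Inference strategies

For a patient-level variable whose sub-model is unknown, with nominal level α
(default 0.05):

- Found-in-Either: two 1-df LR tests (variable in U; in E); reject if either
  p < α. Anti-conservative (~7–9% size at α = 5%).
- Found-in-Both: both p < α. Conservative (~2.5%).
- Bonferroni: either p < α/2. Slightly conservative, near-nominal.
- Global: one 2-df LR test of the variable in both sub-models, p < α.

Comparisons are strict; ties have probability zero for continuous statistics.
When the sub-model is known a priori, the single 1-df test at α is the more
powerful choice, but mis-specifying the sub-model costs more power than
correct pre-specification gains, which motivates Bonferroni as the default.

## Model selection and evidence grading

Choosing between the E- and U-placements is a non-nested comparison of
equal-parameter models, where AIC and BIC differences coincide. The BIC uses
the number of *cycles* as sample size, since the outcome is observed at the
cycle level. The BIC difference is interpreted as an approximate Bayes factor
via Raftery's bands — [0,2) Weak, [2,6) Positive, [6,10) Strong, ≥10 Very
strong, with expected correct-assignment proportions 50–75 / 75–95 / 95–99 /
>99%. Printed band endpoints overlap in the usual presentation; here the
half-open convention [lo, hi) is imposed, assigning boundary values to the
higher band. Exact IC ties are recorded as "tie" and excluded from
correct/incorrect tallies.

## Synthetic-data generator

The generator emulates a large multi-centre IVF registry at the level of its
fitted linear predictors; its defaults are the study conditions used
throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `prop_double` | 0.70 | fraction of cycles with two embryos (rest single) |
| `alpha_u`, `alpha_e` | 0.1, −3.66 | sub-model intercepts |
| `U` | N(−0.5, 0.5²), coefficient 1 | fixed uterus-side prognostic score |
| `Ep` | N(−0.1, 0.3²), coefficient 1 | fixed patient-level embryo-side score |
| `Ee` | N(3, 0.6²), coefficient 1 | fixed embryo-level score, drawn per embryo |
| `P` | N(0, 1) | putative patient variable under study |
| `beta_up`, `beta_ep2` | 0 | effects of `P` in U and in E (the study dials) |

The number of double transfers is fixed at `round(prop_double·n)` — a design
quantity — and which cycles are double is randomised. With both `P` effects
zero these defaults give a 19.7% pregnancy rate and a 3.2% twin rate (4.6%
among double transfers); exact design values obtained by Gauss–Hermite
quadrature are 19.79 / 3.28 / 4.68%, rising to 24.78% pregnancies and 6.80%
twins with both effects at 1.

`Ee` is drawn independently per embryo, matching its role as the embryo-level
predictor; a `ee_per_cycle` switch draws it once per cycle instead (shared by
both embryos) for sensitivity analyses — the choice between the two is a
genuinely open design point, and per-embryo was adopted as the default.

What the generator does **not** emulate: repeat cycles per couple (no
within-couple correlation), donor structures, categorical prognostic factors,
informative transfer-number assignment, or model misspecification (data are
generated from the EU model itself). Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness to
their failure on real registry data.

## Study engine and reproducibility

Every replicate is seeded from `(base_seed, scenario_index, replication
index)` through `SeedSequence`, so studies are reproducible replicate-by-
replicate and independent of batching. All strategies are evaluated on the
same replicate fits (paired design, reducing the variance of between-strategy
contrasts). A replicate whose required fits do not all converge is retried
once from the base-model solution and otherwise dropped with the count
reported (`n_dropped`), so rejection proportions are never silently biased.
All proportions carry the binomial Monte-Carlo standard error; the design
precision helper `mc_precision(p, reps) = 1.96·√(p(1−p)/reps)` gives ±0.6%
on a 5% test size and ±1.3% on a 50% rate at 6000 replications.

Problem sizes: the packaged studies default to 2000 replications (the
headline type-I-error comparisons), 1000 for the classification rates and 500
per scenario for the pooled BIC-difference calibration, with the comparison
tolerances tied to `mc_precision` at the replication count actually used.
Population outcome rates are estimated from 2,000,000 simulated cycles.

The naive power comparator simulates a fully observed single-level logistic
model with the marginal event rate matched to the pregnancy rate (intercept
solved by Gauss–Hermite quadrature + Brent root-finding) and tests the
coefficient with a 1-df LR test; it quantifies how severely a power
calculation that ignores partial observability overstates the achievable
power.

## Known limitations

- No random effects for repeat cycles or shared-donor structures; cycles are
  assumed independent.
- Covariates are used as supplied (no internal standardisation or categorical
  encoding).
- The four-model selection treats one candidate variable at a time; joint
  selection over many variables is out of scope.
- Wald-type inference is deliberately not provided.
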