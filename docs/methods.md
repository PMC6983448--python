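# Methods

## The design being modelled

`cfscreen` implements a matched phenome-wide screen of morbidity associated
with carrying a single defective *CFTR* allele. The design it reproduces is a
retrospective matched-cohort study on administrative claims: an exposure
cohort (genetically identified CF carriers, or CF cases for the comparison
arm) is matched 1:5 to unexposed enrollees on sex, age band and total months
of enrollment; for each of a catalog of CF-related conditions, an
ever-diagnosed indicator is compared between index subjects and their matched
controls with conditional logistic regression; and the resulting per-condition
odds-ratio profile of carriers is compared with that of CF cases.

Real claims databases of this kind are proprietary, so the package ships a
synthetic-data generator that reproduces the statistical structure the
analysis depends on, and every downstream stage is exercised and calibrated
against it.

## Synthetic cohort model

For subject *s* and condition *c* the diagnosis indicator is a single
Bernoulli draw with

```
logit P(X_sc = 1) = logit(p0_c) + beta_c·[carrier_s] + gamma_c·[cf_s]
                    + u_{s,sys(c)} + delta·log(months_s / median months)
```

* `p0_c` — baseline probability of diagnosis over an average enrollment
  window, drawn log-uniform on (0.0005, 0.15) by default: the catalog is
  dominated by rare conditions with a few common ones, as in claims data.
* `gamma_c` — CF log-odds effect, uniform on (0.5, 3.0) by default
  (odds ratios roughly 1.6 to 20); nonnegative because the catalog is defined
  as CF-*related* (risk-increasing) conditions.
* `beta_c = lambda·gamma_c + eps_c`, `eps_c ~ N(0, 0.15)` — the carrier
  effect profile is an attenuated, noisy copy of the CF profile with
  attenuation `lambda = 0.22`. This is the generative counterpart of the
  "muted phenotype": carriers show the same ordering of condition risks as CF
  cases at roughly a fifth of the log-odds scale.
* `u_{s,sys} ~ N(0, sigma)` — one Gaussian frailty per subject and organ
  system (default sigma 0.5, 8 systems, conditions assigned round-robin).
  This induces within-system positive association between condition
  indicators and the multimorbidity inflation the burden analysis measures.
  It is the simplest mechanism with those two consequences; it is a modelling
  stand-in, not a claim about the dependence structure of real claims.
* `delta·log(months/median)` (default delta 0.5) — longer enrollment means
  more opportunities for a diagnosis to be recorded. A single log-linear
  exposure term creates exactly the confounding that matching on enrollment
  months is designed to remove, with one parameter, in place of a per-visit
  hazard model. Occurrence is ever-diagnosed 0/1; no visit-level stream is
  simulated because the analysis only consumes the indicator.

Demographics default to the claims setting being emulated: carriers are
predominantly adult women screened during reproductive care (81.4% female,
half in the 27–35 band), CF cases skew young and are balanced by sex, and
enrollment windows are discretized lognormal clipped to 1–204 months
(median 42 carriers / 33 CF). Conditions can be sex-restricted
(male-infertility or pregnancy-related analogues) or adult-onset
(`min_age_years`), and the applicability mask forces their indicators to 0
elsewhere.

Indicators are realised as `U < p` with uniforms drawn independently of the
effect sizes, so paired runs that share a seed share random numbers; this
makes monotonicity experiments (e.g. larger effects → more significant
conditions) well-posed.

Two deliberate impurities mirror the real design's hazards: a configurable
number of latent CF cases can be hidden in the labelled carrier group
(misclassification), and a suspicion flag can be set preferentially for
carriers with disease in a chosen organ system (ascertainment bias); both are
off or neutral by default.

### Familial validation families

`generate_families` emits mother–child pairs: unscreened true-carrier mothers
whose CF child's birth month lies inside the mother's enrollment window. Each
mother carries two indicator sets — full-window and pre-birth — generated
from the *same* latent uniforms with the exposure term evaluated at the two
window lengths, so the pre-birth set is a monotone restriction of the
full-window set. The validation screen rewrites mothers to their pre-birth
window (months and indicators) before matching, so index subjects and
controls have equal observation time; male-only conditions are dropped.

## Matching

Matching keys are sex, age band (0–9, 10–17, 18–26, 27–35, 36–45, ≥46 years
at first enrollment) and months of enrollment, exact by default with a
configurable ± tolerance. Age is matched on the band rather than exact years
because cohorts are reported in these bands and exact-age matching would
starve the control pool. Controls from any family containing a labelled
carrier or CF subject are ineligible, and controls are never reused across
sets (global sampling without replacement), which preserves independence
across sets in the conditional likelihood. Ties are broken uniformly at
random under a recorded seed; index subjects are processed in seeded random
order so scarce key cells are not allocated systematically. Sets with fewer
than M eligible controls are emitted short and flagged rather than dropped.

## Conditional likelihood

For one binary, set-constant exposure (index vs control) the per-set
conditional likelihood given the set's event total `k` is

```
l_j(beta) = beta·y1 - log( C(m, k-1)·e^beta + C(m, k) ),   C(m,-1) = 0
```

where `m` is the number of controls and `y1` the index outcome. Sets with
`k = 0` or `k = m+1` carry no information. The whole screen therefore reduces
to counts of sets by `(m, k, y1)`; fitting cost is independent of cohort
size. This construction is implemented from scratch (it is the package's
core), with statsmodels' `ConditionalLogit` used only as an independent
cross-check in the test suite.

Numerical choices:

* The log-likelihood is strictly concave with a monotone decreasing score;
  the maximizer is found by Newton steps safeguarded by a maintained bracket,
  falling back to bisection on [−30, 30] whenever a step leaves the bracket.
  Convergence at |score| < 1e-10 or a bracket width below 1e-13, at most 50
  iterations.
* `se = 1/sqrt(observed information at the MLE)`; 95% Wald interval
  `exp(beta ± 1.959964·se)`; the primary p-value is one-sided for OR > 1
  (`1 − Phi(beta/se)`), matching the screen's directional hypothesis; a
  two-sided value is also reported.
* Degenerate tabulations map to status codes, never exceptions:
  `no_information` (no informative sets); `separation_up` / `separation_down`
  (every informative set has the index event present / absent, MLE at ±∞).
  Under separation no point estimate or CI is fabricated — no continuity
  correction is applied — and the one-sided p is the exact permutation tail:
  for upward separation, `prod_j (k_j/(m_j+1))`, the null probability that
  every index subject carries an event given the per-set totals.
* For m = 1 tabulations the MLE reduces to the discordant-pair closed form
  `log(n10/n01)` exactly (verified in tests).

## Screens, comparison and burden

A screen fits every catalog condition applicable to the cohort
(sex-restricted conditions are dropped when the cohort lacks the relevant
sex; the maternal validation screen additionally drops male-only ids and any
configured exclusion list). Conditions with fewer than 5 combined
index+control events (configurable, logged) are marked `insufficient_data`
rather than fitted; zero-event conditions report `no_information`.
Prevalences are reported per 100 and per 1,000 enrollees.

The effect-profile comparison takes the conditions with status `ok` in both
screens and reports the Pearson correlation of the carrier and CF natural log
ORs and the unweighted OLS slope of carrier on CF log OR with its t-test
p-value. Separated or uninformative conditions are excluded with logged
reasons, since their log OR is undefined. The regression is unweighted
because the target of inference is a plain trend across conditions; a
precision-weighted variant (weights `1/(se_carrier² + se_cf²)`) is available
behind a flag.

The burden analysis counts, per subject, distinct conditions and distinct
affected organ systems, buckets them ({0, 1–2, 3–4, 5–6, 7–8, 9–10, >10} and
{0, 1, 2, 3, 4, >4}), and fits the bucket-membership indicator on the same
matched sets with the same conditional-logit machinery. Bucket percentages
are recomputed from counts at 2 decimal places.

## Sensitivity analyses

**Expected misclassification.** A screening panel that detects a given
mutated allele with probability `d` labels a true carrier "carrier" with
probability `d`, and a true CF case "carrier" with probability `2d(1−d)`
(exactly one of two alleles detected). With `rho` CF cases per carrier among
the screened, the expected number of hidden CF cases among `n` observed
carriers is `n·rho·2d(1−d)/(d + rho·2d(1−d))`. The panel parameters are
exposed, not asserted: `d` and `rho` vary by panel and population, so the
function is reported at reference values rather than fit to any published
bound.

**Contamination sweep.** For each contamination count `m`, a pseudo-carrier
cohort of fixed size draws `m` subjects from the latent-CF pool and the rest
from the noncarrier pool (without replacement — with-replacement draws would
duplicate subjects across matched sets and break the disjointness the
likelihood assumes), is matched 1:5 and screened. Common random numbers
across the grid (one shuffled pool ordering per replicate) make the mean OR
monotone in `m` cleanly comparable. Reported per condition: mean OR at each
`m` and the smallest grid `m` reaching a target OR; an optional joint flag
counts replicates where every condition reaches its target simultaneously.
Replication counts are desk-scale by design and recorded in the output.

**Empirical false discovery.** Analytic multiplicity corrections are
unattractive here because the conditions are strongly interdependent (shared
organ-system frailty; in real data, shared physiology and coding practice).
The simulation instead reassigns, within every matched set, the index label
uniformly at random among the set's members, holding all condition indicators
fixed — marginal prevalences and the entire condition–condition association
matrix are preserved bit for bit — then reruns the screen and counts
conditions significant at one-sided alpha. Under this null the index outcome
is hypergeometric given the set totals, which is exactly the beta = 0
conditional model, so the mean count estimates the expected number of false
discoveries with the dependence structure intact.

A calibration caveat, measured and deliberate: the per-condition one-sided
Wald rejection rate under this exact null is not ≤ 0.05 identically but
5.2–5.4% for rare conditions (event counts in the tens to hundreds), because
the Wald statistic is a normal approximation applied to a skewed score
distribution; it converges to 5.0% for common conditions. The acceptance
suite therefore checks the bound `alpha·K` within 3 Monte-Carlo standard
errors of the permutation mean rather than as a strict inequality. This is a
property of the Wald test itself, shared with any screen that uses it, and is
why the per-set permutation p-value (used under separation) is exact while
the headline p is approximate.

**Ascertainment exclusion.** Carriers whose screening was triggered by
clinical suspicion (the `suspicion_flag`) are removed and the match+screen
pipeline is rerun. With the generator's planted bias (flag probability
elevated for carriers with respiratory disease) the filtered respiratory ORs
fall below the unfiltered ones in expectation, which the tests verify.

## Problem sizes and what the tests do (and do not) show

Calibration studies that only need the sampling distribution of per-set
sufficient statistics (CI coverage, type-I error across null screens,
attenuation recovery) use `simulate_matched_tabulation`, which samples the
counts over the 2×(M+1) cells of (index outcome, control event count) as a
single multinomial draw — the exact distribution of the tabulation under
homogeneous within-set probabilities. This lets those studies run at their
full sizes (500 replicates; 50,000 sets per arm; 59 conditions) in seconds.
The full generator → matching → screen path is exercised separately: the
acceptance run uses 19,802 carriers, 23,557 CF subjects and a 600,000-subject
control pool (the reference cohort sizes), and the pipeline tests use cohorts
of a few hundred to a few thousand. The contamination sweep runs at a
2,000-subject pseudo-cohort over a 3-point grid with 3 replicates in the
acceptance run; its monotonicity is established separately at 10 replicates.

Passing tests show that the estimator, the matching bookkeeping and the
sensitivity machinery behave correctly under the generator's assumptions:
logistic effects, Gaussian organ-system frailty, log-exposure enrollment
confounding, exact within-set exchangeability. They do not show robustness to
features of real claims data the generator omits: coding error correlated
with exposure, time-varying diagnosis intensity, informative disenrollment,
family-level clustering beyond the exclusion rule, or effect heterogeneity
across CFTR genotypes.

## Known limitations

* The one-sided Wald p is mildly anticonservative for rare conditions (see
  above); exact conditional p-values are only used under separation.
* Exact matching on enrollment months can leave short sets when the control
  pool is thin in a key cell; short sets are flagged and retained, so
  realised control counts can fall slightly below 5 per index.
* The attenuation slope from a single catalog draw scatters around the
  generating 0.22 (the catalog's 59 effect pairs are themselves one sample);
  recovery to within Monte-Carlo error is a statement about the mean over
  replicate catalogs.
* Burden ORs inherit whatever marginal dependence the frailty induces; they
  are not adjusted for total enrollment beyond the matching.
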