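# Methods

## Trajectory model

We model repeated post-bronchodilator FEV1 and FVC Z-scores jointly with a
finite mixture of bivariate-target linear regressions — a Bayesian take on
group-based trajectory modeling. Subject `i` has one latent trajectory
indicator for all of their visits; given the trajectory, the two targets are
conditionally independent, each with its own coefficient vector and residual
precision. The predictor set is fixed to `[1, t, pack-years, smoker × t]`,
where `t` = age − 20 (men) / age − 18 (women), pack-years is the cumulative
exposure recorded at the visit (visit-updated, configurable to baseline-only),
and the interaction lets current smokers decline at a different rate.

### Priors and inference

All factors are conjugate:

| parameter | prior | default | rationale |
|---|---|---|---|
| mixture weights | symmetric Dirichlet `α₀` | 0.1 (per component, `K_max` = 20 available, 8 used in the scripts) | sparse (< 1) so superfluous components empty out; the 2% rule then prunes |
| residual precision `λ_kd` | Gamma(`a₀`, `b₀`) | (2, 1) | mean 2 ⇒ residual SD ≈ 0.7 Z, weakly informative |
| coefficients `β_kd | λ_kd` | N(`m₀`, diag(`v₀`)/`λ_kd`) | `m₀` = 0; `v₀` = (25, 0.25, 0.25, 0.25) | zero-centered intercept prior mitigates missing early-adulthood data; slope-scale priors are loose relative to plausible decline rates |

The coefficient prior is scaled by the residual precision (classical
normal–gamma). This keeps every update closed-form and makes the single-
component posterior *exactly* the textbook conjugate regression posterior,
which the test suite exploits as an oracle. Inference is coordinate-ascent
variational Bayes (responsibilities → Dirichlet → per-component
normal–gamma), iterated to a relative ELBO change < 1e-6 or 500 sweeps. The
ELBO is monotone nondecreasing by construction and checked to 1e-8 slack.
CAVI is deterministic given its initialization, which is what makes the
restart-and-rank protocol reproducible: every restart seed is derived from
one base seed via `numpy.random.SeedSequence`.

### Model selection

Restarts are ranked by WAIC2, computed by Monte Carlo over the variational
posterior (default S = 200 seeded draws) with the **subject** as the
pointwise unit — subjects, not visits, are exchangeable here; the
observation-level alternative would change the effective-parameter penalty.
Components holding < 2% of the sample are pruned and weights renormalized.
The best `top_m` (default 5) candidates are then screened clinically:
active trajectories are ordered by predicted FEV1 Z at t = 40 years
(median pack-years, non-smoker), the trajectory nearest Z = 0 is taken as
reference, and every adjacent pair along increasing severity must be
discriminated at p < 0.05 by the reduced Cox model or the reduced ZINB model
(the less severe member as reference). The first candidate in WAIC2 order
passing all adjacent contrasts wins; if none passes the best-WAIC2 model is
returned with an explicit audit flag. On the bundled 2000-subject example no
candidate discriminates *all* adjacencies — with six trajectories and ~70
deaths in the low-risk groups, adjacent hazard contrasts of 1.2–1.5× are
underpowered at this scale; the flag is the designed behavior, not an error.

### Assignment

Posterior trajectory probabilities multiply the mixture weight by the
predictive density of all of a subject's usable visits — one visit is
enough, which is how the baseline-only replication arm works. The default
predictive plugs in posterior means (deterministic, fast); a Student-t full
posterior predictive is available (`method="predictive"`). Subjects are
"assigned" when their maximum posterior reaches `min_posterior`
(default 0.5; the criterion behind the published 85% assigned fraction is
unstated, so the threshold is configurable).

## Dysanapsis

`a/l = geomean(13 airway lumen diameters in mm) / (lung volume in mm³)^(1/3)`.
Lung volume is input in liters and converted; this scaling puts the ratio on
the scale implied by the published reference-trajectory SD of 0.0039. All 13
labeled anatomic locations are required — no imputation of missing sites
(the source text says 13 locations while enumerating 14 anatomic names; we
fixed the labeled set at 13, omitting the RML medial segmental bronchus,
whose lobar parent is in the set). Tertile 1 = lowest a/l = most dysanapsis.

Group comparisons use two-sided Mann–Whitney tests: the exact null
distribution when n + m ≤ 12 without ties (verified against full
enumeration), otherwise the tie-corrected normal approximation with
continuity correction. Bonferroni families are the explicitly requested pair
lists — reference-vs-at-risk and adjacent-at-risk are adjusted separately,
matching how the two families are reported. Cross-sectional OLS age trends
of a/l, Pi10 and Perc15 within trajectories serve as confound diagnostics: a
static anatomic feature should show no age slope.

## Outcome models

**Mortality** — extended Cox with age as the time scale: subjects enter the
risk set at their study-entry age (left truncation) and exit at death or
censoring. Efron tie handling; reduced covariates (current smoking,
pack-years, sex, race) or full (+ BMI, MMRC, 6MWD); Wald CIs. The
proportional-hazards check is a Grambsch–Therneau scaled-Schoenfeld
chi-square test with rank time transform, implemented in-package because the
residuals must respect left truncation (risk sets on the age scale); ties
share Breslow-style risk sets, which is immaterial for continuous ages.

**Exacerbations** — zero-inflated negative binomial (NB2) on each subject's
total follow-up count with a log person-years offset and intercept-only
inflation. The motivating analysis used a mixed ZINB; with a single
aggregate count per subject a random intercept is unidentifiable, so the
package deliberately fits fixed effects only — rate-ratio contrasts between
trajectories are preserved, subject-level overdispersion is absorbed by the
NB dispersion. On non-convergence the model falls back to a plain negative
binomial and flags it.

**Dysanapsis association** — forward-stepwise multinomial logistic
regression of trajectory assignment on the scaled a/l ratio and parental
history flags: likelihood-ratio entry at p < 0.05, no removal step
(entry/removal thresholds are unstated in the source; pure-forward 0.05 is
the documented default). a/l is divided by the reference trajectory's sample
SD; RRRs for a/l are reported per one SD *decrease* (sign flipped), so
values > 1 mean more dysanapsis makes the at-risk trajectory more likely.
Predictors causing separation are excluded with an audit entry.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
latent labels drawn from the trajectory weights; visit grid 0/5/10 years
with per-visit dropout and censoring; Z-scores from the per-trajectory
linear predictors plus Gaussian noise; deterministic pack-year accrual
(0.75/year while smoking, quit probability 0.15/visit); a/l drawn normal
per trajectory with per-site diameters rescaled so the geometric mean
reproduces the drawn ratio exactly; death from an exponential baseline
hazard (0.008/year) scaled by the trajectory hazard ratio, censored
uniformly 8–12 years after entry; exacerbation counts from a gamma–Poisson
(NB2, dispersion 0.5) with person-years exposure and a per-trajectory
structural-zero probability; parental flags independent Bernoulli given the
trajectory.

The default ground truth uses the published seven-trajectory membership
fractions, FEV1/FVC intercepts and spreads, mortality hazard ratios,
exacerbation rate ratios, and per-trajectory Pi10/Perc15 means. Slopes,
smoke-exposure coefficients, per-trajectory a/l means, the reference
exacerbation rate (0.25/person-year), and structural-zero probabilities are
**not** published; the defaults are plausible values chosen once
(a/l decrements of 0.2–3 reference-SDs across severity, decline rates of
0.002–0.025 Z/year) and are not calibrated against any output.

What a green test does and does not establish: the generator satisfies the
model's assumptions by construction (linear trajectories, proportional
hazards, NB2 counts, normal a/l). Recovery tests therefore establish
correctness of the estimation machinery, not robustness to real-data
violations — informative dropout, measurement drift, reference-equation
misspecification and within-subject correlation of counts are all absent.

## Numerical and design notes

- Weight fractions printed for the source cohort sum to 0.999; the default
  ground truth normalizes them (perturbation ≤ 4e-5).
- Empty mixture components revert toward their proper priors; no update is
  singular, so "component death" is handled by the 2% pruning rule rather
  than special-casing.
- WAIC2 ties between restarts break on the lower seed.
- Degenerate inputs: all-identical values make tertiles undefined (error);
  groups with < 3 points or no age variance are skipped in age trends with a
  log entry; eventless trajectories are flagged non-estimable in the Cox
  table rather than dropped.
- Pipeline runs split one base seed into per-stage seeds (cohort, baseline
  cohort, ensemble, WAIC) and record them in `audit.json`; repeated runs are
  byte-identical on all text artifacts.

## Known limitations

- Trajectories under ~3% of the sample need cohorts well beyond desk scale
  to resolve; at n = 2000 the two smallest published trajectories merge.
- The GLI reference-equation machinery is out of scope; Z-scores are inputs
  (a pluggable `zscore` helper covers externally supplied reference values).
- No MCMC, no covariate-dependent mixture weights, no cross-target residual
  correlation (the conditional-independence assumption is an explicit
  extension point).
- CT image processing (airway segmentation, Pi10/Perc15 extraction) is out
  of scope; CT measures enter as tabular values.
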