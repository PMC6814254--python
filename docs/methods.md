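# Methods

`coprescribenet` implements a network-epidemiological analysis of opioid
doctor shopping on longitudinal prescription claims. This note records the
models, the generative design of the synthetic data, and the numerical and
design choices a maintainer would want to know.

## The co-prescription network

For each focal quarter *T*, non-MAT opioid fills from quarters
{*T*−2, *T*−1, *T*} define a bipartite patient–prescriber graph: an edge
(*p*, *d*) is present iff prescriber *d* wrote at least one opioid fill for
patient *p* in the window (multiplicity is discarded). Medication-assisted
treatment agents (buprenorphine in the shipped dictionary) are excluded
before any graph is built, because MAT prescribers are sparsely located and
would induce clustering unrelated to drug seeking. The one-mode projection
onto patients carries integer weights

  w_ij = |N(i) ∩ N(j)|,

the number of unique shared prescribers. Two patients served by the same
three prescribers are tied with weight 3. All panel patients are retained
as nodes — the network is sparse and most patients are isolates — so that
prominence scores and percentiles are defined for the entire panel.
Projection is done by per-prescriber combination counting (cost
Σ_d C(deg d, 2), not |patients|²), and satisfies the conservation law
Σ_{i<j} w_ij = Σ_d C(deg d, 2), which the tests check exactly.

Quarters 0 and 1 have incomplete trailing windows. The default policy pools
whatever quarters exist (`truncate`); a `drop` policy that refuses such
quarters is available. In the shipped configuration the analysis panel is
the last 4 of 7 observed quarters, so every panel quarter has a full
3-quarter window; the truncation policy only matters for nonstandard
configurations.

## Prominence metrics

**Weighted PageRank.** PR(i) = (1−d)/N + d Σ_{j∈M(i)} w_ij PR(j)/s_j with
damping d = 0.85, each undirected edge treated as two directed edges, and
s_j = Σ_k w_jk. Isolates have s = 0; taken literally the recursion would
leave them at (1−d)/N and the scores would not sum to one. Since PageRank
is a stationary probability distribution over all nodes, the default policy
redistributes dangling mass uniformly (`dangling="uniform"`); the literal
recursion is available as `dangling="literal"`. Power iteration starts from
the uniform vector and stops when the L1 change drops below 1e−10 (max
1000 iterations; non-convergence raises with the final residual). Scores
are invariant to global rescaling of the weights and equivariant under node
relabeling.

**Percentiles.** Raw PageRank is heavily right-skewed, so it is reported as
an average-rank percentile, pct = 100 (rank − 0.5)/N, computed within
quarter. Ties share their mean rank (midrank), which makes the panel mean
exactly 50; a `min` tie rule is available. A z-score transform (population
SD) and degree metrics are carried as alternates; `degree_log` is
ln(degree + 1) because isolates with degree 0 are in the panel.

**Co-HITS.** Bipartite prominence uses the generalized Co-HITS coupled
fixed point with all edge weights 1:

  x_p = (1−λ_p)/N_p + λ_p Σ_{d∈N(p)} y_d / deg(d)
  y_d = (1−λ_d)/N_d + λ_d Σ_{p∈N(d)} x_p / deg(p)

Both damping parameters default to 0.85, mirroring the one-mode damping;
they are exposed in `CentralityParams`. Patient scores are
percentile-transformed per quarter, consistent with the one-mode pipeline.

## Outcomes and panel

Four dependent variables per patient-quarter: the opioid fill count
`n_rx`; `mme_gt90`, whether the maximum daily morphine-milligram-equivalent
dose exceeds 90 mg (the CDC high-risk threshold; strictly greater, so 90.0
exactly does not flag); `overdose_any`, accidental poisoning by opioids or
unspecified drugs (the inclusive measure — unspecified-drug coding is known
to absorb opioid overdoses; the opioid-only variant is kept alongside); and
`oud`, opioid abuse/dependence codes in the quarter.

Maximum daily MME is computed on a 90-day grid: each fill contributes
daily_dose × conversion factor on every day from its fill day through its
days' supply (clipped to the quarter); concurrent fills are summed per day
and the quarter maximum is taken. This matches CDC-calculator semantics and
is testable against a brute-force per-day loop. The shipped conversion
factors (hydrocodone 1.0, oxycodone 1.5, morphine 1.0, fentanyl patch 2.4,
codeine 0.15) are configurable.

ICD-10 code groups are reconstructions from the clinical categories, not a
published list: T40.0x–T40.4x and T40.6x (opioid poisoning) and T50.9x
(unspecified-drug poisoning), both restricted to the accidental-intent
sixth character '1'; F11.1x/F11.2x for OUD; C00–C96 for cancer. Matching is
prefix-based on normalized (dot-free, upper-case) codes.

The panel includes every patient with at least one non-MAT opioid fill
anywhere in the study window; an included patient contributes one row for
*every* panel quarter, with zeros where inactive. Cancer is a
study-period-level flag, constant within patient. The high-risk subsample
drops, at the patient level, everyone whose per-quarter unique-prescriber
count never reaches 2; qualifying patients keep all their quarters (the
alternative — dropping quarters — would break the balanced-panel structure
that the person-mean decomposition assumes).

## Panel models

A prominence metric x_it is decomposed into a between-person term
BP_i = mean_t(x_it)/10 and a within-person term WP_it = (x_it − mean_t)/10,
per 10 percentile points (z-score and log-degree metrics enter per unit).
The decomposition is exact: 10(BP + WP) reconstructs x and the per-patient
WP mean is zero. BP compares patients with each other; WP compares a
patient with their own average and is analogous to a fixed-effects
estimate, absorbing all time-invariant patient heterogeneity. The person
mean is taken over the patient's observed panel quarters.

Outcomes are modeled with random-intercept GLMMs: negative binomial
(log link, NB2 variance μ + αμ²) for the count, logit for the binaries,
with fixed effects for gender, age (per decade), insurance (reference
"Other"), state (reference West Virginia), cancer, the quarterly
unique-prescriber count, BP and WP. The prescriber-count control is what
separates network *position* from sheer prescriber *volume*. Covariates
that are constant in a given sample (e.g. a state with no events) are
dropped automatically and recorded on the result.

Estimation is maximum likelihood with the single random intercept
integrated out by Gauss–Hermite quadrature (21 nodes by default — ample
for σ_u up to ~3 with 4-quarter panels; the likelihood agrees with
independent adaptive quadrature to ~1e−6 at 60 nodes). The analytic
gradient (posterior-weighted conditional scores) drives BFGS; standard
errors come from the finite-difference Hessian at the optimum. Fixing
σ_u = 0 reduces the fit to an ordinary GLM, and the tests require
agreement with statsmodels' GLM/NegativeBinomial to 1e−3 there.
Coefficients are reported exponentiated (IRR for counts, OR for binaries)
with Wald CIs; BIC uses the observation count.

ICC on the latent scale is σ_u²/(σ_u² + π²/3) for logit models. No exact
latent decomposition exists for NB models; the lognormal-Poisson
approximation σ_u²/(σ_u² + ln(1 + 1/μ̄ + α)) is used and should be read as
qualitative.

Predicted margins hold other covariates at sample means (binaries at
observed proportions), average over the random intercept by quadrature
(population-averaged predictions), span ±1 SD of the term by default, and
carry delta-method CIs over the full parameter vector.

## The synthetic generator

No real claims ship with the package; the generator emulates the
statistical structure the analysis assumes so that every stage is testable
end to end:

- **Population.** Demographics follow fixed marginals typical of a
  commercially insured Appalachian-region opioid cohort (59% female, age
  56 ± 17, a seven-state mix dominated by Georgia/North Carolina, 13.8%
  cancer). Exactly round(frac·n) patients are latent shoppers (default
  10%) and round(frac·m) prescribers are flagged at-risk (default 13%,
  reflecting the concentration of shopping around a minority of
  clinicians).
- **Claims.** Patients visit prescribers at Poisson rates (0.5/quarter for
  non-shoppers, 3.0 for shoppers). Prescribers carry lognormal popularity
  weights; shoppers additionally up-weight at-risk prescribers 25-fold.
  This preferential attachment concentrates shared-prescriber ties and
  produces the right-skewed, hub-heavy degree distribution the analysis
  expects. A 2% patient-quarter MAT rate exercises the exclusion filter.
- **Outcomes (two-stage).** Because the analysis regresses outcomes on
  *realized* network position, outcomes are planted only after a first
  network pass on the generated claims: for each outcome,
  η = a + β_BP (BP−5) + β_WP WP + u_i with u_i ~ N(0, σ_u), Bernoulli
  through the logit link or NB2 through the log link. BP is centered at
  its expectation (5, i.e. the 50th percentile /10). The intercept a is
  calibrated in-sample so the marginal rate matches the configured target
  (defaults: mean 1.26 fills, 8.1% MME>90, 1.16% OUD, 0.16% overdose —
  rates typical of such panels). Default planted effects are realistic
  magnitudes (per-10-percentile IRR/OR 1.1–2.0); default σ_u values (1–2)
  imply ICCs in the 0.25–0.55 range.
- **Materialization.** OUD and overdose become ICD-10 codes in the
  diagnosis table (overdose: 80% opioid, 20% unspecified), so the derived
  flags reproduce the planted draws exactly. The MME flag boosts one
  existing fill to 150 mg morphine-equivalent (leaving fill counts and the
  network untouched). The count is realized by duplicating or trimming
  fills while preserving one fill per existing (patient, prescriber) pair —
  so the realized count is floor-censored at the prescriber count, and
  count-model estimates on the realized claims are distorted relative to
  the planted NB coefficients. Clean count-family recovery is therefore
  tested on `simulate_panel`, a direct panel simulator with no exposure
  censoring. Count and MME planting apply only to patient-quarters with at
  least one fill.

All randomness flows from one root seed through `numpy.SeedSequence`
stream-splitting (population / claims / outcomes), and identical configs
reproduce byte-identical tables.

What the generator does **not** emulate: calendar time (quarters are
integer indices), cash or Medicaid transactions, realistic NDC-level drug
coding, geographic micro-structure within states, or any information-
diffusion dynamics among shoppers. Passing recovery tests therefore show
that the estimators recover effects *under the assumed data-generating
model*, not that the substantive findings hold in real claims.

## Problem sizes and verification

The recovery suite uses 2,000 patients × 4 panel quarters with σ_u = 1 and
a planted within-person odds multiplier of 1.5, 20 seeded replicates; the
95% CI covers the planted value in ≥ 18/20 replicates, and planted-null
runs keep every exponentiated estimate within 3 SE of 1. Oracle checks use
50 random graphs for projection and PageRank (dense linear-solve oracle,
1e−8 per node), independent fixed-point iteration for Co-HITS, and
brute-force day grids for MME. `scripts/acceptance.py` reruns the whole
pipeline at the default configuration and reports the computed quantities.

## Known limitations

- Wald CIs from the observed-information Hessian can undercover for very
  rare outcomes (a handful of events per state cell); the overdose outcome
  at desk-scale n is on that edge.
- The NB ICC is an approximation, and the count outcome on realized claims
  is floor-censored (above).
- Adaptive (per-group-mode) quadrature is not implemented; for σ_u ≫ 3 or
  long panels the fixed Gauss–Hermite grid would need more nodes.
- Co-HITS damping has no published reference value for this application;
  0.85 mirrors the one-mode damping and is configurable.
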