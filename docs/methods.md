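# Methods

`threatdyn` models how perceived threats shape nationalism, religiosity,
political conservativism and anti-immigrant sentiment, at two levels: a
respondent-level survey model (a latent two-cluster structural equation
model with its surrounding psychometric battery) and a society-level
deterministic system-dynamics model exercised through uniform parameter
sweeps.  This note documents the models, their assumptions, the defaults,
the numerics, and what the synthetic data can and cannot show.

## 1. The survey model

### Latent structure

Five threat-perception subscales — social, predation, contagion, financial
and natural — load on two correlated latent clusters:

    threat_sp  =~ 1.00*threat_social + 0.81*threat_predation
    threat_cfn =~ 1.00*threat_financial + 0.86*threat_contagion + 0.56*threat_natural

with latent variances 0.30 and 0.19 and covariance 0.13.  The clusters push
nationalism in opposite directions (slopes +2.75 and −3.62); nationalism,
both clusters, religious identification and supernatural belief feed the two
0–10 political sliders; and the sliders feed the binary "immigrants as
undesirable neighbours" item (slopes 0.06 and 0.02).  Religious
identification and supernatural belief are exogenous observed variables
(variances 2.76 and 3.87, covariance 1.23) whose moments are held at their
sample values.  The full default parameter table is
`threatdyn.sem.reference_estimates()`.

### SEM estimation

`SemModel` implements maximum likelihood on the sample covariance matrix in
the RAM parametrisation: Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, minimising
F_ML = log|Σ| + tr(S_xx Σ⁻¹) − log|S_xx| − p with L-BFGS-B, an analytic
gradient (dF = tr[(Σ⁻¹ − Σ⁻¹S_xxΣ⁻¹)dΣ], propagated through A and S), and up
to three deterministically jittered restarts.  Variances are bounded below
at 1e-6; an estimate pinned at that bound raises a Heywood-case warning but
estimates are still returned.  Standard errors come from the numerical
Hessian of the discrepancy, Var(θ) = 2H⁻¹/(n−1).  Fit indices: χ² = (n−1)·F
at the optimum; the baseline for CFI/TLI is the independence model
(diagonal Σ); RMSEA = sqrt(max(χ²−df, 0)/(df(n−1))); the AIC reported is the
χ²-based criterion χ² + 2k, which orders nested and non-nested models fitted
to the same data identically to the likelihood AIC.  Degrees of freedom
exclude the saturated exogenous moments (66 moments − 29 free − 3 saturated
= 34 for the default model).  Listwise deletion throughout.

The politics-slider slopes deserve a caveat: nationalism is almost
deterministic in the two clusters (residual variance 0.08 against a
systematic variance of ≈2.2), so the slider equations are near-collinear and
their slopes are weakly identified — their sampling standard errors are of
the same order as the estimates.  Parameter-recovery experiments therefore
use the *median* across replicates, which is stable even for these slopes.

### The synthetic survey generator

`generate_survey` emulates a cleaned respondent-level survey file:

- **Structural core.** Continuous scores are drawn exactly from the
  reference estimates via the reduced form v = (I−A)⁻¹e, then shifted to
  survey-scale means and clipped to their response ranges.  Clipping is rare
  for most scores; it trims a few percent of the supernatural-belief and
  identification tails, which slightly attenuates those variances (the exact
  moment-recovery guarantees hold for the unclipped
  `simulate_from_estimates`).
- **Demographics.** Gender (1038/970/10) and the fourteen religious
  identities are allocated by deterministic largest-remainder quota and
  shuffled, so the default n = 2018 table reproduces the target counts
  exactly and any other n reproduces the proportions.  Ages are drawn from a
  normal truncated at 18 whose *truncated* mean equals 39.06 (sd 13.00); the
  location is solved numerically, since naive truncation would inflate the
  mean by about 1.3 years.
- **Group structure.** Two religiosity indices in [0,1] — "practice"
  (attendance-like) and "spirit" (belief-like) — are assigned per religious
  identity, ordered so that atheists sit lowest and the
  spiritual-but-not-religious are high on belief but low on attendance.
  They generate 30% of the religious-identification variance and 38% of the
  supernatural-belief variance as between-group variance (the remainder is
  individual noise with the reference covariance), a small (5%) group
  component in nationalism, attendance ordinals, and gender shifts of ±0.07
  (and +0.3 for the small "other" group) on the threat scores.  These
  produce strongly significant religious-identity ANOVAs on the two
  supernatural-belief extension items and a significant gender ANOVA on
  overall threat, mirroring the qualitative structure of the emulated data;
  the exact F values of the real file depend on group means the generator
  does not know.
- **Likert items.** Each scale's items are generated from the standardised
  score with compound-symmetric latent correlation, then discretised at
  equal-probability normal thresholds.  Discretisation attenuates
  correlations, so the latent correlation is inflated by numerically
  inverting the bivariate-normal cell-probability attenuation map; the
  *discretised* block then hits the target Cronbach alpha (nationalism
  extension .90 — which places the 7-item core at ≈.88 automatically —
  identification .92/.94, fusion .95/.96, supernatural belief .98, threat
  dimensions .80 per three-item block; the threat-block target is a
  conventional choice, not a reported value).  Item counts: nationalism 7+1,
  identification 4, fusion 7, supernatural belief 10+2, threat 3 per
  dimension, Big-Five 10 (two markers per trait, pairwise latent r = 0.55).
- **Binary outcome.** The anti-immigrant item is a Bernoulli draw on a
  linear predictor clipped to [0.01, 0.99] — the weakest distributional
  assumption, since the family behind the published binary model is
  ambiguous (its printed log-likelihood is inconsistent with a Bernoulli
  likelihood).  The default standardised effects put nationalism first
  (0.16) and religious-identity fusion second (0.11), ahead of the political
  sliders — the ordering the feature-importance analysis is designed to
  detect.

What passing tests show: that the analysis stack recovers known structure
from data with realistic measurement properties.  What they do not show:
agreement with the deposited file's idiosyncrasies (its exact group means,
missingness patterns, or response styles), which the generator does not
model.

### The battery

Scale scoring is the reverse-keyed item mean with casewise missingness.
Cronbach's alpha uses unbiased variances with the Feldt F-interval
(cross-checked against `pingouin`).  The Big-Five check is principal-axis
EFA with varimax rotation: communalities start at squared multiple
correlations and iterate with damping 0.5, a 0.98 communality cap, and the
conventional 1e-3 stopping rule (tighter tolerances stall on two-indicator
factors); RMSR is the root-mean-square off-diagonal residual correlation
and the χ² is the Bartlett-corrected ML discrepancy of the factor model.
Regressions and ANOVA wrap statsmodels: OLS with listwise deletion and
QR-based collinearity diagnosis; binomial-logistic GLM by default with a
linear-probability option and an L2-penalised fallback under complete
separation; classical one-way ANOVA (F defined as 0 when the between-group
sum of squares vanishes) with Tukey HSD post-hocs.  No multiple-testing
adjustment is applied beyond Tukey, matching the analysis style being
reproduced.  Feature importance fits a random forest (300 trees, minimum
leaf 5) on a 70/30 stratified split and computes ROC-AUC permutation
importance (10 shuffles) on the held-out split.

## 2. The system-dynamics model

### Threat channels

Each of the five channels carries a concern stock C_i.  Discrete hazard
events arrive evenly spaced over the horizon (event j of m at t = jT/m) and
update concern by the Rescorla–Wagner rule with habituation:

    lambda*_i = hazard_intensity_i * (1 + threatPctOfMedia * (w_tv*tvMediaUse + w_sm*socialMediaUse))
    alpha_k   = alpha0 * exp(-habituationRate * k)
    C_i      <- C_i + alpha_k * (lambda*_i - C_i)

Between events concern decays exactly, C_i(t+dt) = C_i e^(-energyDecay*dt),
and each channel accrues its engagement integral analytically
(C·(1−e^(−δdt))/δ per segment), so the zero-stimulus integral
C₀(1−e^(−δT))/δ is exact to machine precision.  Events are delivered at
their exact scheduled times by splitting decay segments, which makes
outputs independent of how the grid aligns with the schedule.

### Coupled stocks

Engagements mirror the survey clusters: E_sp = mean(C_social, C_predation),
E_cfn = mean(C_contagion, C_financial, C_natural).  Six stocks follow
first-order relaxation dx/dt = input − ρx (ρ = 0.25; sentiment reacts
faster, ρ = 1.0), advanced with an exact exponential step plus a Heun
predictor–corrector on the inputs using step-average engagements, making
the scheme second order in dt (halving dt moves every output by < 1%).

- **Nationalism** N: +0.5·E_sp − 0.5·E_cfn + 0.15·attendance.
- **Anthropomorphic promiscuity** AP (agent-detection religiosity):
  +0.4·(E_sp − E_cfn) − 0.8·openness.
- **Sociographic prudery** SGP (norm-guarding religiosity):
  +0.8·attendance + 0.4·E_sp.
- **Social / economic conservativism**: +E_sp-cluster, −E_cfn-cluster,
  −0.25·N (resp. −0.15), +0.12·AP (resp. +0.06).
- **Anti-immigrant sentiment** AIS:
  (0.5 + 1.6·conscientiousness)·(0.35·SC + 1.6·N)
  + (1.3 − openness)·(−0.8·gate_N·F_shock − 2.0·gate_rel·media)
  + 0.4·attendance + 0.8·openness − 0.1·conscientiousness
  − 0.3·agreeableness.

`F_shock` is a financial-pressure stock that gains α₀ per financial event —
habituation-free and unamplified, because economic shocks bite regardless of
attentional habituation or media framing — and decays at ρ = 0.5.  The two
gates are steep logistic switches: gate_N = 1 − σ((N − 0.3)/0.05) closes the
financial pathway once nationalism is established, and
gate_rel = 1 − σ((attendance − 0.5)/0.01) closes the media pathway for
religiously observant societies.  `media` is
threatPctOfMedia·(0.3·tvMediaUse + 0.7·socialMediaUse), weighting social
media more heavily on the sentiment side.

The two susceptibility multipliers are the model's deliberate
heterogeneity: conscientious (order-valuing) societies convert threat-driven
politics into exclusionary sentiment more readily, and open societies blunt
the gated negative pathways.  Besides their substantive readings (both
directions are consistent with the personality coefficients the sweep
analysis reproduces), they give the sweep regressions a realistic residual:
without them a deterministic model fit linearly has near-zero residual
variance and *every* parameter is "significant" at n = 5000, which would
make moderation-by-significance analyses meaningless.

Extraversion and neuroticism are accepted as parameters but never coupled,
keeping the survey and simulator parameter spaces aligned.

### Calibration of the coupling constants

The exact equations of the original simulator are not published; the update
rules above are re-derivations constrained by the stated ingredients
(Rescorla–Wagner habituation, stock-and-flow form, two cluster aggregates
mirroring the survey model) and the published sign patterns.  Magnitudes
are free configuration.  The defaults were calibrated once against the
qualitative validation suite on broad uniform sweeps across many design
seeds: (a) regressing sentiment on the five engagement integrals gives
+social, +predation, −contagion, −financial, −natural, all p < .01; (b) the
financial event-count term is significant in the bottom-nationalism
quartile and non-significant in the top quartile; (c) media terms
(threat-percent and social-media use) are significant, negative, only in
the low-attendance half; (d) mean nationalism rises monotonically in
attendance.  Two calibration notes: the conservativism→sentiment gain
(0.35) centres the high-nationalism count-term null, whose two leakage
paths (a direct engagement path and an opposite-signed collider induced by
conditioning on final nationalism) cancel there; and the amplifier media
weights (0.25 each) keep a second-order media leak through the nationalism
gate inside the high-religiosity null.  The "non-significant" halves of the
moderation checks are honest nulls: their systematic component is ≈0, so
under re-randomisation of the design each carries the usual ~5% per-term
false-positive rate.

### Sweep design

Defaults (`default_sweep_design`): 20,000 sets, design seed 0 (the pinned
experimental design), independent uniform draws per parameter in sorted
name order from one seeded stream.  Bounds: use-frequencies, personality
traits and initial concerns in [0,1]; hazard intensities in [0,5]; event
counts integer 0–20; attendance ordinal 0–9; habituation rate [0,1];
energy decay [0, 0.3] — decay timescales of at least a few time units keep
concern persistent between events; with much faster decay the engagement
integrals become event-count-dominated and the count moderation cannot
arise.  Horizon 20 time units, dt 0.1, base learning rate 0.5, natural
channel starts at zero concern.  Each set runs once (the model is
deterministic to the bit); execution is chunked, checkpointable by run id,
and order-independent.

Subset analyses follow the published layout: "high/low nationalism" are the
top/bottom output quartiles (5,000 of 20,000), religiosity splits at the
attendance midpoint, the subset regressions use the full parameter list
plus output nationalism as terms (the conservativism and religiosity
stocks, printed without coefficients in the original tables, are excluded),
and significance is judged at α = .05.  Output magnitudes are in arbitrary
stock units; only signs and significance are meaningful, by design.

## 3. Problem sizes and tolerances

The shipped experiments use the sizes the analyses are designed around:
survey n = 2018 (the emulated file), SEM recovery 200 replicates at
n = 5000 (median absolute bias < 5% per free loading/slope), reliability
targets within ±0.03 at n ≥ 2000, OLS coverage 500 replicates at n = 2000
(each 95% CI covering ≥ 93%), the full 20,000-run sweep, dt-halving
tolerance 1% relative to each output's typical magnitude (near-zero
crossings are scaled by the field mean to avoid 0/0 inflation), and
analytic-decay agreement to 1e-10.

## 4. Known limitations

- The simulator is a single-society aggregate; no agent heterogeneity.
- Coupling-constant magnitudes are not fitted to the survey data; only the
  sign structure carries over, so sweep coefficients have no interpretable
  units.
- The generator does not model missing data, response styles, or free-text
  fields (news sources and referendum votes are passthrough columns).
- The politics-slider SEM slopes are weakly identified by construction of
  the generating model (see above); point estimates from a single survey-
  sized fit are imprecise even when the model is exactly right.
- Statistics that depend on unpublished properties of the deposited survey
  file (its exact group means and hence exact F statistics) are reproduced
  qualitatively, not numerically, by the emulation.
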