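# Methods

## Model

The friendship network of one school year group is a directed binary
adjacency `y` over `n` students.  Students are additionally affiliated to
online groups through a fixed binary incidence `z` (undirected
student–group ties).  The model is the exponential family

    P(Y = y | z, x) = exp(θ · s(y, z, x)) / κ(θ)

with friendship arcs as the only random variables: affiliations and
covariates `x` enter as exogenous predictors.  The sample space is doubly
constrained.  Arcs whose sender did not complete the survey are structural
zeros — the free tie variables are exactly the ordered pairs with a
respondent sender, `Σ_respondents (n−1)` of them — and, because the survey
capped nominations at six, the space is further restricted to networks
where no respondent's out-degree exceeds six.  Estimates are therefore
conditional on both the observed response pattern and the instrument's cap.

### Statistics

With r = 1 − 1/λ, TP(i,j) the number of directed two-paths i→k→j,
dX(i) = Σ_g z_ig and s(i,j) = Σ_g z_ig z_jg:

| term | statistic |
|---|---|
| ArcA | Σ y_ij |
| ReciprocityA | Σ_{i<j} y_ij y_ji |
| AinSA / AoutSA | λ² Σ_i [r^{d(i)} + d(i)/λ − 1], d = in/out-degree |
| ATA-T | λ Σ_{y_ij=1} [1 − r^{TP(i,j)}] |
| A2PA-T | λ Σ_{i≠j} [1 − r^{TP(i,j)}] |
| Sender/Receiver(x) | Σ_{y_ij=1} x_i  /  Σ_{y_ij=1} x_j |
| Interaction(b) | Σ_{y_ij=1} b_i b_j (binary b) |
| Difference(x) | Σ_{y_ij=1} \|x_i − x_j\| (continuous x) |
| PSTalkingSender/Receiver | Σ_{y_ij=1} ps·talk on the sender / receiver |
| In2StarAX / Out2StarAX | Σ_i d_in(i)·dX(i)  /  Σ_i d_out(i)·dX(i) |
| TXAXarc | Σ_{y_ij=1} s(i,j) |
| L3XAX | Σ_{y_ij=1} [dX(i)·dX(j) − s(i,j)] |

Conventions that were genuinely open and are fixed here:

* **λ parameterisation.**  The alternating in/out-star closed form equals
  the alternating series Σ_k (−1)^k S_k / λ^{k−2} over star counts S_k
  (verified numerically in the tests for λ ∈ {1.5, 2, 3}); λ defaults to 2,
  the customary choice in this model family, and is configurable per term.
* **Closure/two-path split.**  A2PA-T sums the damped two-path count over
  *all* ordered pairs (arc present or not); ATA-T multiplies it by arc
  presence.  A variant can be swapped in behind the same term name.
* **L3XAX** counts ordered endpoint group pairs (g, h) with g ≠ h, i.e.
  dX(i)·dX(j) − s(i,j) per arc.  Whether the original estimation software
  excludes g = h is not documented; the form used here is stated explicitly
  so results are self-consistent.
* **PS × talking terms** apply the sender/receiver template to the
  constructed covariate ps·talk; the source tables name these rows without
  printing formulas.
* **Missing attributes** (non-respondents, item non-response) are resolved
  at design-build time: continuous scores get respondent-mean imputation,
  binary flags get 0.  Both are logged and configurable; means can
  optionally be centred.  Continuous scores are used on their raw scale.

## Sampling

A Metropolis chain proposes a uniform single toggle over the free dyads and
accepts with probability min(1, exp(θ·Δz)).  Proposals that would push a
respondent past the out-degree cap are rejected in place — Metropolis on
the constrained space, which preserves detailed balance for the
cap-conditioned distribution.  Change statistics Δz are computed
incrementally in O(n) per step from maintained degree vectors and a
two-path matrix; the identical compiled routine backs the public
change-statistic API, and retained samples are always *recounted in full*
from the adjacency, with the incremental state checked against exact
recounts at regular intervals.  Default chain lengths scale with the state
space: burn-in 50×|free dyads|, thinning 10×|free dyads| for stand-alone
simulation.  Correctness is validated two ways: long-run state frequencies
on an enumerable 64-state space (4 students, 2 respondents) match the
exhaustively enumerated distribution within total variation 0.004 at 2×10⁶
steps, and unconstrained density-only runs match Bernoulli closed forms.
The 64-state space is the largest on which a total-variation comparison at
this chain length is informative: on the 4096-state full four-node space
even an independent sampler of 2×10⁶ draws has expected TV ≈ 0.02.

## Estimation

Three-phase stochastic approximation with the moment equation
E_θ[s] = s_obs:

1. **Phase 1** (default 100 samples) at θ₀ — logit of observed density on
   ArcA, zeros elsewhere — estimates per-term variances D for scaling.
2. **Phase 2**: 5 subphases of Robbins–Monro iterations
   θ ← θ − a·D⁻¹(z_sim − z_obs); the gain a starts at 0.1 and halves per
   subphase while the subphase length doubles from 40; per-component steps
   are clipped at 0.5; θ̂ is the final-subphase iterate average.
3. **Phase 3** (default 1500 samples, thinning = |free dyads|) at θ̂ gives
   convergence t-ratios, the statistic covariance Σ̂, and SEs
   √diag(Σ̂⁻¹).  If any |t| ≥ 0.1 the estimate is polished by damped
   Newton steps θ ← θ − Σ̂⁻¹(mean z_sim − z_obs) with phase 3 re-run, up
   to 6 rounds.  The Newton polish is this package's own refinement: it
   solves the same moment equation using the phase-3 information matrix,
   and in validation brings the estimator within 0.01–0.03 of the exact
   logistic MLE on dyad-independent designs (SEs within a few percent).

Guards, not silent failures: empty/complete observed networks and observed
zeros of non-negative statistics (e.g. no reciprocated dyads with
ReciprocityA in the model) raise boundary errors; chains stuck on
empty/complete graphs or statistic variances collapsing to zero raise
degeneracy errors; change-statistic columns that are linearly dependent on
a (up to) 1000-dyad probe raise a collinearity error before any simulation.

Phase-3 sample sizes were chosen against the Monte-Carlo noise floor of the
t-ratio (≈ √(2τ/N) with autocorrelation time τ): 1500 samples at thinning
|free| keeps the floor safely below the 0.1 threshold, so convergence
declarations are not noise.

### Significance

A parameter is flagged when |θ̂| ≥ 2·SE, the conventional
twice-standard-error rule, two-sided.  The comparison is inclusive at the
boundary: published tables round to three decimals, and a true ratio
slightly above 2 can print as exactly 2.0 — with the inclusive rule the
package reproduces the five-school published marking row for row (130
rows), while for full-precision fitted values the boundary case has
probability zero and the rule coincides with the strict inequality.

## Goodness of fit

Simulation at θ̂ compares observed and simulated distributions through
t = (observed − sim mean)/sim sd, for the fitted statistics (|t| < 0.1
expected, since they were matched in estimation) and an auxiliary panel not
in the model: in/out-degree standard deviation and skew, global
transitivity (fraction of directed two-paths closed by an arc), isolate
count and mutual-dyad count (|t| < 2).  The original study reports GOF only
as adequate without listing its panel; this panel is a stated stand-in and
is configurable.  Run on the estimator's own phase-3 sample, the fitted-term
t-ratios equal the convergence t-ratios exactly (shared sample, opposite
centring sign).

## Synthetic data

The generator emulates what the analysis needs from the undeposited survey:

* year-group size 130 (60–200 supported), response rate 0.79, male share
  0.45, nomination cap 6, mean out-degree target 4;
* friendship growth by sequential weighted nominations with reciprocity
  (+1.5 log-odds), saturating transitivity (+0.6 per common friend, max 3),
  gender match (+1.2) and attribute-distance decay (−0.3 per mean absolute
  score difference) — values chosen once to yield densities, reciprocity
  and clustering in the range typical of classroom friendship networks;
* peer supporters from the top 25% of a noisy in-degree nomination score
  with 52% uptake (≈13% of the year group); in-degree proxies the separate
  nomination instrument, which is summarised, not tabulated, in the source;
* each peer supporter opens one group; students linked to the supporter by
  an arc in either direction join with probability 8×baseline (baseline
  0.05), producing the offline–online alignment the cross-level terms
  measure;
* non-response removes outgoing arcs but keeps incoming ones and blanks the
  three questionnaire scores, mirroring the retention of nominated
  non-participants.

Attribute means/SDs (knowledge 6.0±1.5, norms 7.0±1.2, talking 4.0±1.8,
common correlation 0.3) are plausible questionnaire scales; the study's
school-level descriptive tables are unpublished, so these are placeholders
and clearly labelled as such.  What passing tests show, therefore, is that
the *method* recovers known generating parameters and published decision
rules on data with this structure — not that any particular school's
estimates are reproduced; the original estimate tables cannot be
regenerated without the original data.

## Validation problem sizes

The shipped validation suite uses 6-student networks for exhaustive
change-statistic recounts (500 networks, every free dyad, all 16 term
families), the 64-state space for exact-distribution comparison, a
40-student school for the logistic-oracle comparison, and ten 60-student
replicates for parameter recovery (θ* = {ArcA −3, ReciprocityA 2, ATA-T 1},
each component within 3 SE, all |t| < 0.1) — sizes at which independent
oracles are exact or closed-form while the constrained-space machinery
(structural zeros, cap conditioning) is fully exercised.

## Known limitations

* Single cross-sectional networks only: no longitudinal (actor-oriented)
  dynamics, no model-based treatment of missing ties beyond structural
  zeros, no control-school comparison layer.
* Per-school fits are deliberately not pooled: estimates are not comparable
  across networks of different sizes.
* The sampler uses single-dyad toggles; tie-swap proposals (useful under
  tight degree constraints) are a documented extension point.
* Estimation settings of the original software are unpublished; all
  defaults here are this package's own and are recorded in fit diagnostics.
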