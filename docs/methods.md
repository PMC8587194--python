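# Methods

This note documents the modelling choices behind `carechoice`: the utility
model and estimator, what the synthetic-market generator does and does not
emulate, the numerical conventions, and known limitations.

## Choice model

Each patient chooses once, at admission, among the surgeon–hospital pairs
geographically available in that quarter.  Utility is additively separable
in surgeon-level quality information and hospital characteristics:

```
U_ijkt = Q_ijkt' β_i + X_ijk' γ + FE_k + ε_ijkt,     ε i.i.d. EV1
```

* `Q_ijkt` — four mutually exclusive-by-block indicators evaluated at
  admission time: high online rating (running average ≥ 4.0 stars, boundary
  inclusive), no online rating yet, high report-card score
  (lower-than-expected mortality on the card in effect), no report-card
  score.  The omitted categories are "low rating" and "rated but not high",
  so each block's two dummies are interpreted against those references.
* `X_ijk` — patient–hospital distance in miles (untransformed) plus bed
  size, teaching status and cardiac-ICU indicators.
* `FE_k` — surgeon fixed effects: nonrandom alternative-specific constants
  with the first surgeon (sorted by id) pinned to zero.  They absorb
  time-invariant surgeon quality, so the information coefficients are
  identified from *within-surgeon changes* in rating states over time.
* Random coefficients: the four information indicators and distance carry
  `β_i ~ N(μ, diag(σ²))`; hospital attributes, fixed effects and any
  interaction terms are nonrandom.  Whether hospital attributes should also
  be random is a genuinely open design point; they are fixed by default and
  switchable via `ModelSpec`.

Conditional on `β_i`, choice probabilities are multinomial logit.  The
unconditional log-likelihood integrates over the mixing density and is
simulated as

```
LL(θ) = Σ_i log( (1/R) Σ_r P_i(chosen | β = μ + σ ⊙ z_ir) )
```

with `z_ir` standard-normal draws.  Because the likelihood depends on σ
only through σ·z, the sign of σ is unidentified; σ is unconstrained during
optimization and reported as |σ|.

## Information linkage

* **Timing.** All dates are calendar quarters.  The running average rating
  uses reviews posted *strictly before* the admission quarter — the
  information a patient could have seen before surgery; a flag
  (`include_same_quarter`) switches to the inclusive convention, and the two
  differ only on same-quarter reviews.
* **Report cards** are in effect from their publication quarter (inclusive)
  until the next publication (exclusive); before the first card every
  surgeon is unscored.  Surgeons absent from the card in effect get the
  "no score" state.
* A surgeon's states are identical across their practice hospitals.

## Estimation

* **Draws.** Halton sequences by default, distinct primes (2, 3, 5, 7, 11)
  per random attribute, 100-element burn-in, consecutive non-overlapping
  segments per patient; `pseudo` draws from a seeded PCG64 generator are
  available.  Halton draw sets are deterministic, so estimates do not
  depend on the seed option.  The default for publication-scale fits is
  1000 draws per patient; the test suite uses 48–64 draws on its smaller
  synthetic markets and 256 in the parameter-recovery experiment, where 64
  draws leave a measurable (~3%) attenuation of the precisely estimated
  distance mean while 256 draws remove it.
* **Optimizer.** BFGS on the negative simulated log-likelihood with an
  analytic score (verified against central finite differences at 1e-5
  relative error in the tests).  Parameters are preconditioned by the RMS
  of their design columns so curvature is O(1) in every direction.  The
  warm start is the exact conditional logit (Newton with step-halving);
  σ parameters start at 0.1.  The gradient tolerance is expressed per
  patient (`gtol = tol · n_patients`).
* **Standard errors** come from the inverse of a finite-difference Hessian
  of the analytic gradient (central scheme by default, forward available),
  i.e. the observed-information estimator; a BHHH (outer product of
  per-patient scores) estimator is available for large Monte-Carlo
  experiments and agrees with observed information within a few percent on
  the mean parameters in the shipped recovery design.  A sandwich variant
  is not implemented.
* **Degenerate inputs.** Covariates constant within every choice set,
  collinear blocks, and perfectly separating covariates are rejected with
  the offending columns named.  A likelihood evaluating to an essentially
  perfect fit (|LL| < 1e-4) is treated as separation.  Simulated
  probabilities are floored at 1e-300 with a logged count; floored patients
  contribute zero gradient.
* **Oracles.** `gh_loglik` implements tensor-product Gauss–Hermite
  quadrature of the same integral for at most two random attributes,
  written independently of the simulation path (explicit per-patient loop,
  scipy softmax).  With all σ = 0 both reduce exactly to the conditional
  logit, which is itself cross-checked against statsmodels'
  `ConditionalLogit` in the tests.

## Choice sets and sample restrictions

* **Fixed radius** (default 50 miles): alternatives are all pairs whose
  hospital lies within the radius; patients whose realized choice is
  farther are excluded and audited.
* **Variable radius**: each hospital's market radius is the 90th percentile
  (linear interpolation between order statistics — the percentile
  definition is configurable and documented because it is not standardized)
  of its own patients' distances; a pair is available if the hospital's
  market covers the patient.  Patients whose realized choice falls outside
  the constructed set are excluded and counted; variable-radius sets
  neither contain nor are contained in the fixed-radius sets in general.
* **Attrition filter**: a surgeon is treated as exited at quarter *t* if
  their last realized surgery predates *t*; exited surgeons are removed as
  *alternatives*, and patients whose chosen row is removed are dropped
  entirely (a patient cannot be kept without their realized choice) with a
  logged count.  Emergency and referral filters drop patients.
* Duplicate pairs from a surgeon practicing at two hospitals are distinct
  alternatives sharing quality states but differing in distance and
  hospital attributes.

## Synthetic markets

The generator emulates the data landscape of a ten-year regional CABG
market: 40 quarters, patients and hospitals placed uniformly in a square
(default side 200 miles) with coordinates snapped to a 5-mile grid to mimic
zip-code granularity; surgeons affiliated with one or two hospitals; a
per-surgeon-quarter Poisson review stream with i.i.d. stars skewed high
(default distribution 0.10/0.05/0.05/0.20/0.60 over 1–5 stars, emulating
the documented underrepresentation of low ratings); seven report-card
issues at fixed quarters assigning categories from a noisy latent mortality
score (bottom decile of mortality → "lower than expected", top decile →
"greater than expected", thresholds configurable), with surgeons below a
30-case volume threshold in the card's 8-quarter collection window left
unrated.  Attrition assigns a random exit quarter in the second half of the
window to a configurable share of surgeons, after which they leave all
rosters.  Choices are drawn from the exact utility model above with EV1
shocks via the inverse-CDF transform, so every downstream stage can be
tested against known parameters.

Default sizes follow the study population this design emulates: 12,521
discharges by 184 surgeons, review arrival rate 0.149 per surgeon-quarter
(1096 reviews / 184 surgeons / 40 quarters), emergency share 31.52%.
Values the source setting does not pin down were chosen once as plausible:
60 hospitals, referral share 0.30, attrition share 0.15, second-affiliation
probability 0.35, log-normal latent volumes (median 6 cases/quarter) giving
roughly an 80% rated share.

What the generator does *not* emulate: real geography or zip centroids,
review-posting selection bias (stars are i.i.d., uncorrelated with latent
quality), insurance networks, or the empirical concentration of reviews in
later years.  Passing tests therefore demonstrate correctness of the
machinery under the stated model, not robustness to the selection processes
present in real review data.

A note on identification at small scale: hospital attributes are identified
alongside surgeon fixed effects only through surgeons whose practice
hospitals differ in the attribute.  In very small synthetic markets a
binary attribute (e.g. cardiac ICU at its realistic 90% prevalence) can be
exactly collinear with the fixed-effect block, which the estimator rejects
by name; small fixtures therefore use attribute shares nearer 0.5, more
dual affiliations, or drop the attribute from the specification.

## Post-estimation conventions

* Heterogeneity shares are `Φ(μ/σ)`; σ = 0 returns the degenerate 0/1 share
  with a flag.
* AME: per bootstrap replicate one alternative is drawn uniformly from each
  patient's set; the indicator is toggled 1 vs 0 with its exclusive "none"
  companion forced to 0 in both arms (the counterfactual compares a high
  rating to a *low* rating, matching the estimand "changed from low to
  high").  Predicted probabilities integrate over the fitted mixing
  distribution with a fresh 1000-draw Halton set by default
  (point evaluation at μ is available via `integrate=False`).  AMEs are
  reported in percentage points; the relative effect is AME divided by the
  baseline choice probability (mean of 1/|choice set|), computed exactly
  from the stored fields.
* Year trend: integer years since the first study year
  (`floor((quarter − origin)/4)`), origin exposed as a parameter.  Yearly
  marginal utilities are `μ_main + θ_ix · t` with delta-method SEs.
* Willingness to travel implements `−μ_attr/μ_dist` exactly as stated in
  this literature.  Applied to the published main-specification
  coefficients (0.317 and −0.278) this gives 1.14 miles, which does not
  match the separately printed figure of 0.59 miles; the package implements
  the stated formula and records the discrepancy rather than reconciling
  it.

## Problem sizes used in the shipped experiments

The test suite runs the full machinery at sizes chosen to make Monte-Carlo
experiments practical on a single core: a shared 800-patient market for
unit and property tests, 50–200-patient fixtures for the likelihood
oracles, and the parameter-recovery experiment at 5000 patients × ~15
alternatives × 20 replicates with 256 Halton draws and BHHH standard
errors.  Publication-scale runs (12,521 patients, 1000 draws) use the same
code paths through the CLI.

## Known limitations

* Random coefficients are independent normals: no correlation across
  attributes and no non-normal mixing.
* One choice per patient; no panel structure.
* The review process is exogenous — no feedback from realized choices to
  review volume and no selection on outcomes.
* Observed-information standard errors only; bootstrap SEs for the fit
  itself are not implemented (the AME bootstrap resamples surgeons, not
  refits).
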