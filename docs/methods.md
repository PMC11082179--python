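# Methods

This note documents the statistical procedures the package implements,
the choices made where the methodology was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model and exclusions

A coded dataset is one row per signal with half-open timing
`[onset, offset)` in seconds from event start; half-open intervals make
back-to-back signals non-overlapping, which matters for bigram
extraction. `unknown` is an explicit level for attention, awareness and
olfactory variables and is only dropped where a specific analysis
requires a known value. Distances are metres; field coders estimate them
in body lengths, and `body_lengths_to_metres` converts with a
configurable factor defaulting to the 3 m mean adult body length of the
study animals.

Case exclusions follow the acuity argument: under equal-visual-angle
scaling of the documented near-field limit (a 2.75 cm object resolvable
at the 2 m reach of the trunk tip), a 2.5 m elephant is detectable to
≈180 m and a 1 m body part to ≈70 m, so body acts coded with the
recipient beyond 100 m are conservatively excluded. Reported distances
are floored to the nearest 10 m, which reproduces both printed values
simultaneously. The cutoff is applied to body acts only by default:
vocalisations carry over such distances regardless of vision
(`distance_applies_to="all"` extends it). Records with unknown distance
are retained — distance cannot disqualify what it could not measure.

Inter-observer reliability is unweighted Cohen's κ per coded variable
(categories are nominal). The degenerate case in which both coders use a
single identical label returns 1.0: no chance-corrected information, but
not disagreement.

## Repertoire and sociality

The repertoire filter reads "observed at least twice in at least two
individuals" as *total frequency ≥ 2 AND ≥ 2 distinct signallers*; the
stricter reading (≥2 uses by each of ≥2 signallers) is available via
`per_signaller_rule` because the verbal rule is ambiguous. Saturation is
assessed by a type-accumulation curve averaged over 100 random case
orders (seeded), with a min/max envelope.

The nearest-neighbour index is the proportion of a focal's scans in
which a partner was nearest. Strong associates are partners strictly
above mean + 0.25·SD of the focal's own indices, with the sample (n−1)
SD — conventional for small groups — and a `pool="global"` option since
the original pooling is not fully specified. Dyad strength is the
arithmetic mean of the two directed indices; its z-transformation is
performed within each modelling sample, not globally.

## Audience-directedness

A body-act type is an audience-directed gesture when all applicable
criteria pass: (1) social use (the type occurs in the coded data, whose
coding scheme already requires a recipient present); (2) the signaller
visually checks the recipient above chance — waived for tactile types;
(3) the recipient is visually attending above chance — waived for
audible and tactile types, and applied to candidate-olfactory tail types
because their a-priori channel is silent-visual. "Above chance" is an
exact one-tailed binomial test with `chance_p = 0.5` at α = 0.05, both
configurable: the attention state is binary and no chance level is
otherwise defined. Trials count only productions with a codeable gaze
state. Types with fewer than 5 usable trials return `insufficient_data`
rather than a verdict — exact tests at trivial n cannot discriminate,
and the recovery study below quantifies how power grows with sampling.

The percentage-deviation statistic is `(β/α − 1) × 100` with α a
modality's share of all body acts (known recipient attention) and β its
share within one attention state. Two identities are enforced in tests:
shares sum to one within every margin, and the attention-state-weighted
mean of β returns α, which forces the deviations under the two states to
have opposite signs (or both be zero). The tail assessment builds the
binary tail-vs-silent-visual response for the GLMM, the analogous
deviation against the pooled tail+reference distribution, and per-type
distance profiles binned at [0,1), [1,3), [3,10), [10,100] m with a
within-1 m share (candidate olfactory use is expected at very close
range).

## Collocation analysis (MDCA)

Bigram tokens are overlapping (vocalisation, body act) pairs within an
event, slots filled in onset order with ties going to the vocalisation.
The order-aware mode keeps, per vocalisation, only the first overlapping
body act per articulator: a body act cannot start while the previous act
of the same articulator still runs, so later same-articulator overlaps
carry no order information. The order-free mode keeps every overlapping
pair. Both modes retain onset order in the slots, so the two orders of a
pair are distinct rows of the result — the mode governs only the
first-overlap filter.

For bigram (A, B): trials are all tokens with A in the first slot, the
expected probability is B's share of the second slot over the whole
corpus, and the exact binomial tail is taken in the direction of the
deviation (ties use the upper tail). The score `pbin = −log10 p` is
signed positive for attraction, negative for repulsion, with bands at
|pbin| > 1.30103, 2, 3 (p < .05, .01, .001). No multiple-testing
correction is applied by default, matching how raw pbin bands are
conventionally reported; a Holm option exists. Because the marginals are
estimated from the same corpus, the procedure is conservative for small
tables and approaches the nominal 5% null rate only for large corpora
with several types per slot — the calibration tests exercise both
regimes.

## Mixed models

Modality choice is a multinomial logit of body-act modality
(silent-visual, audible; tactile as reference) on recipient attention,
with per-category random intercepts within signaller — equivalently, a
random "modality" slope within signaller. The sample is restricted to
signallers contributing every modality (the standard restriction for
this design) and to known recipient attention. Binomial logit GLMMs
handle the tail assessment and the two combination questions (response:
vocal-first order, or Rumble+Ear-Flapping vs other combinations) with
the maximal random-effect structure: signaller intercept plus slopes for
the z-transformed dyad strength and the sex × sex-dyad interaction, and
an event intercept. Dummy predictors are coded and centred before
entering interactions or random slopes.

Estimation maximises the Laplace-approximate marginal likelihood in the
lme4 relative-covariance parameterisation `b = Λu`, `u ~ N(0, I)`, which
keeps the zero-variance boundary an interior smooth point. The fixed
effects and random-effect modes are profiled out by an exact damped
Newton on the jointly concave penalized problem (converged to gradient
< 1e−10 so the outer objective is smooth to machine precision), and the
outer optimiser (BFGS with an explicit 1e−6 finite-difference step,
Nelder–Mead polish on failure) searches only the covariance parameters
(log-free Cholesky entries). For a single scalar random effect, adaptive
Gauss–Hermite quadrature (21 nodes) is available and doubles as an
independent accuracy check on the Laplace route; the two agree to ~1e−2
on the fixtures tested. Identical design rows are collapsed to
frequency-weighted cells, which leaves every likelihood quantity exactly
unchanged while making fits on categorical designs essentially
instantaneous. Wald standard errors come from the central-difference
Hessian of the full marginal likelihood at the optimum, so they account
for covariance-parameter uncertainty. Grouping factors with fewer than
three levels are dropped to a fixed-effects fit (statsmodels GLM /
MNLogit) with a note — two levels cannot identify a variance.

Diagnostics follow standard practice: LRT of full vs nested reduced
models (χ² = 2Δℓ, df = parameter-count difference); VIF per fixed-effect
column (1/(1−R²) from regressing it on the others); parametric-bootstrap
percentile CIs (simulate responses from the fitted model with fresh
random effects, refit, seeded; an error if >20% of refits fail);
leave-one-level-out stability extrema; and Nakagawa-style latent-scale
marginal R² = var(Xβ̂) / (var(Xβ̂) + mean(zᵀΣ̂z) + π²/3).

## Synthetic-data generator

The generator emulates the structure a coder would produce: six sexed
individuals, 89 events between dyads, Poisson signal counts (mean 14 per
event, 21% vocalisations), log-normal signal durations (median 2 s — no
durations are reported anywhere, only overlap structure matters),
attention-dependent modality choice on the log-odds scale with Gaussian
per-signaller effects (SD 0.5), and planted bigram attraction: each
placed vocalisation spawns an overlapping body act of an attracted type
with probability `base_pair_rate × multiplier` (default 10× for
Rumble+Ear-Flapping), the vocalisation starting first with probability
`p_vocal_first`. Default modality log-odds (intercepts 1.9/1.7,
attention effects 1.5/1.2 for silent-visual/audible vs tactile) place
the expected modality-by-attention margins at the field-reported scale.
Recipient attention runs at 0.84 for targeted body acts and at the 0.5
chance level for candidate-olfactory tail types, making tail types
attention-independent by construction. Signaller checking is 0.9.

What the generator does *not* emulate: real temporal clustering of
signalling bouts, signal sequences within an articulator, distance
dynamics during an approach, dyad-specific behavioural styles beyond the
random effects, and any dependence of combination use on sex or bond
strength (those generating effects are zero unless configured).
Passing tests therefore show the machinery is correct and calibrated on
data of this structure, not that real greeting data satisfy the models'
assumptions.

Two deterministic fixtures exist for desk-checkable numbers: a 670-case
body-act table whose modality × attention margins equal the
field-reported counts (344/54, 209/44, 11/8), and a 337-token ordered
bigram table with the reported 33 + 36 Rumble/Ear-Flapping counts.
Non-anchored cells of the bigram fixture are filled at plausible
frequencies and are not estimates of any real quantity.

## Calibration studies: problem sizes

The test suite's calibration studies use sizes chosen to put each
estimator in its regime while keeping the default run conveniently
short: parameter recovery pools 95% Wald-interval coverage over the
fixed effects of three routes (mixed multinomial, binomial Laplace with
correlated slope, binomial AGQ) at n = 5000 per dataset, 30 grouping
levels, 200 seeds per route — 30 levels because Wald intervals are
asymptotic in the number of levels, while ~170 observations per level
keeps the Laplace approximation accurate. LRT null calibration uses 200
simulations at n = 600 with 12 levels. MDCA null calibration uses 1000
corpora of 1000 tokens over a 5 × 6 type table, where the null flag rate
sits near the nominal 5%; small-corpus conservatism is asserted
separately. Classifier recovery uses 100 generator seeds at 120 events,
scoring types with at least 20 usable records — below that, exact-test
power is the binding constraint, not classifier logic.

## Known limitations

- The Laplace approximation shows the usual mild attenuation for binary
  data with small clusters; the AGQ route is exact in its 1-D setting
  and is the cross-check.
- Wald intervals under-cover when a grouping factor has very few levels
  (the study's own six signallers): for real analyses at that scale the
  parametric bootstrap CIs are the appropriate interval, as reported.
- The mixed multinomial supports one grouping factor (the design used
  here); crossed factors would need the binomial engine's joint-b
  machinery generalised.
- pbin values depend on the marginal conventions of the collocation
  script family; different slot/marginal conventions give different
  numerical attractions for the same data, so only the statistic's
  mathematical contract is asserted, not published table values.
- EAF import expects one alignable tier per column (the layout this
  package writes); arbitrary ELAN tier hierarchies need a tier map and
  may not be representable.
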