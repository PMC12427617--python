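# Methods

`lingdist` measures *linguistic distancing* — the degree to which language
frames an experience as removed from the self and the present moment — in
message-based therapy corpora, and relates it to internalizing symptoms
(PHQ-8 depression + GAD-7 anxiety, summed to a 0–45 scale) over the course
of treatment.  This note documents the models, the synthetic data the test
suite runs on, and the numerical and design choices a maintainer should
know about.

## Distancing measures

**Word-count composite (`wc_self`).**  Two sub-measures are computed from
closed-class counts and averaged:

* temporal distance = (past + future) / (past + future + present), over
  tensed verbs;
* social distance = (second + first-plural + third-singular + third-plural)
  / (all five personal-pronoun categories).

The composite lives on [0, 1]; a ×10 display helper reproduces the 0–10
scale used when quoting message scores.  Messages without a tensed verb or
without a personal pronoun have an undefined composite and are excluded
from *all* analyses, so every method is compared on the same message set.
Impersonal pronouns (*it, its, itself, this, that, these, those, one*) are
tallied but excluded from the social-distance denominator by default (a
config switch includes them); the bundled floor/ceiling worked examples are
consistent with exclusion.

Tense tagging is rule-based: an irregular-past lookup plus the `-ed`
suffix; `will`/`shall`/`'ll`/`going to` for future; base and `-s` forms of
a curated verb lexicon, present forms of *be/have/do*, and the contracted
auxiliaries `'s`/`'re`/`'m`/`'ve` for present.  Infinitival `to VERB`,
bare participles and `-ing` forms carry no tense; a participle after a
*be*/*have* auxiliary is part of a compound verb phrase whose tense the
auxiliary already carries ("are puzzled" counts one present).  The clitic
`'s` is an auxiliary only after a closed list of subject hosts ("it's")
and possessive otherwise ("the job's").  The lexicon deliberately omits
verbs whose `-ed` form is predominantly adjectival (*detached*, *puzzled*)
and noun-heavy homographs (*experience*, *matter*, *shoot*): for a
context-free counter a false verb costs more than a missed one.  This is
the known, documented weakness of any dictionary approach — it is exactly
the brittleness the prompted-model measure is meant to overcome.

**Prompted-model expected score (`llm_self`, `llm_other`).**  An
instruction prompt defines the construct (self-distance for any author;
other-distance = how much a therapist's message *encourages* the client to
take a distanced perspective) and ends with a five-level scale labelled
A–E.  A scoring backend returns next-token logits for the five labels; the
score is the expected label rank under a softmax restricted to those five
logits,

    score = Σ_{i=1..5} i · softmax(logit_i)  ∈ [1, 5],

computed in double precision with max-subtraction.  This replaces sampling
with a deterministic readout.  Messages are truncated to 1,000 tokens
before prompting (whitespace tokens for the bundled backend).  Backends
are pluggable and must be deterministic and local (no network calls); real
model adapters must verify each label maps to a single vocabulary token.
The shipped instruction texts are this package's own re-creations of the
construct definitions in the distancing literature.  The bundled
`MockBackend` reads a synthetic message's hidden generating latent `d` and
emits `logit_i = −sharpness·(i − (1+4d))²`, i.e. a peak at the latent's
position under the affine [0,1]→[1,5] map — enabling full-pipeline tests
with known ground truth and no model weights.

## Longitudinal structure

Assessment window *k* for a client is the half-open interval from
assessment *k−1* (exclusive) to assessment *k* (inclusive); window 1 opens
at the dyad's first-message date, and messages after the last assessment
are unmapped.  Scores are averaged per window over defined messages only,
without weighting by message length; a window with no defined score is
dropped.  Days in treatment count from the first message with the primary
therapist — defined here as the therapist with the most messages to that
client (earliest first message breaks ties), since multi-therapist clients
need some convention.  The `time` column expresses days in units of the
~3-week assessment interval by default (`time_unit_days=21`); analyses that
must match a generator's latent time scale pass the generator's unit.

For modelling, window scores are split into a between-person part (person
mean, centered on the unweighted grand mean of person means) and a
within-person part (observation − person mean).  The parts reconstruct the
observation exactly and the within parts sum to zero per person; both are
verified to 1e-12 in the tests.

## Mixed models and effect sizes

Two REML-fitted families, both with a random intercept per client and
random slopes for repeated-measure predictors:

* distance ~ time, random `(1 + time | client)`;
* internalizing ~ within + between, random `(1 + within | client)`.

The engine (`lingdist.lmm`) profiles the fixed effects out of the
restricted likelihood and optimizes the handful of variance parameters
(log-Cholesky for the random-effects covariance, log residual SD) with
L-BFGS-B; per-group matrices are padded and all algebra batched over
groups, keeping a refit at bootstrap scale to a few milliseconds.  Tests on
a coefficient use Satterthwaite's approximation: df = 2(l'Cl)²/Var(l'Cl),
with the variance from the delta method and Cov(θ̂) = 2·H⁻¹ of the
finite-difference REML-deviance Hessian.  The engine is cross-checked in
the test suite against statsmodels MixedLM (likelihood, estimates) and
lme4/lmerTest via Rscript (Satterthwaite df and p to ~1e-4 relative).

Coefficients are reported pseudo-standardized: predictor scaled by its SD
at its own level (pooled within-person SD for repeated measures, SD of
person means for person-level predictors), outcome by its SD at the
matching level.  Effect size per predictor is the semipartial
R²β = F/(F + df₂) with F the Wald statistic (numerator df 1) and df₂ the
Satterthwaite denominator df.

**Paired cluster bootstrap.**  To compare two scoring methods, N clusters
(clients, or therapists carrying their clients) are resampled with
replacement B times (default B = 2,000); duplicated clusters are relabeled
as distinct — required for a valid random-effects refit; both methods'
models are refitted on the identical resample, after re-deriving the
within/between decomposition on the resample, and the difference in the
focal predictor's R²β recorded.  The central 95% of the B differences is
the confidence interval; a difference is significant when it excludes
zero.  In resamples only, a failed random-slope fit falls back to an
intercept-only random structure (counted and logged); headline fits never
fall back.  More than 10% failed resamples flags the comparison
unreliable.

## Bayesian mediation

Mediator and outcome models are hierarchical linear regressions with a
random intercept per client, Gaussian(0, 10) priors on coefficients and
near-improper inverse-gamma(1e-3, 1e-3) priors on the two variances.  With
this structure every full conditional is conjugate, so the posterior is
sampled by a blocked Gibbs sampler with exact draws — two chains of 12,500
iterations, first 2,500 discarded, by default; a fast mode (2 × 2,000,
500 burn-in) serves the simulation studies.  The mediator enters the
outcome model as its within-person component, so per retained draw
indirect = a·b (within-person pathway) and proportion mediated =
100·indirect/(indirect + c′); draws with |indirect + c′| < 1e-8 are
excluded from the ratio and counted.  Significance: the central 95%
credible range of the indirect effect excludes zero.  Convergence is gated
on split-chain R-hat < 1.01 (arviz) for a, b and c′; failures flag the
result.  A prior-predictive identity (no data → coefficient draws match
the Gaussian(0,10) prior) is tested directly.

Three standard configurations: time → client self-distance → symptoms;
time → therapist other-distance → symptoms; therapist other-distance →
client self-distance → symptoms controlling for time.

## Synthetic corpus generator

The generator is first-class, tested code: it is the only way to obtain a
corpus with known effect structure, since real transcript corpora of this
kind are proprietary.  Per client *i* and window *k* (time τ as a fraction
of the planned course):

    d_i  ~ N(mu_d, sigma_between²)
    d_ik = d_i + gamma_time·τ_ik + N(0, sigma_within²)
    Y_ik = beta0 + beta_within·(d_ik − d_i) + beta_between·(d_i − mu_d)
           + c_prime·τ_ik + u_i + N(0, sigma_symptom²)

Y is rounded and clipped to 0–45 by default (clip rates are reported; a
continuous mode exists for estimator studies where discretization is not
the question).  Therapist streams follow an analogous independent latent
with the same time trend.  Assessments are spaced 21 days (the first and
last unjittered so every generated client passes the ≥3-assessments/
≥6-weeks inclusion rule; interior dates jitter ±3 days).  Message text is
template prose ("SUBJ VERB OBJ") in which P(non-first-singular subject) =
P(past-tense verb) = d_ik clipped to [0,1]; 7.1% of messages are verb-free
and 9.4% pronoun-free fragments, reproducing the undefined-score rates the
word-count measure shows on real therapy text.  Message counts per window
are fixed by default (Poisson optional) purely for test stability.
Defaults (300 clients, ~2.7 clients/therapist, 4 assessments, 30 client /
18 therapist messages per window) mirror the scale ratios of real
text-therapy corpora at a size a laptop handles.

**What the generator does not emulate:** clinical prose (templates carry
grammatical signal only — the mock model can therefore track the latent
far better than any real model tracks a real construct), topic or affect
content, message-length variation, client dropout, and informative
missingness.  Passing recovery tests show the *estimators* are correct
under the assumed generative model; they say nothing about construct
validity of any scorer on real language.

## Simulation scales and frozen study conditions

All scales below were fixed before the corresponding checks were run, from
pilot power calculations; they are the package's own choice of test size.

* **End-to-end recovery** (word-count path): 100 replicates of 500 clients
  × 4 windows × 8 messages.  Because the pipeline observes window means of
  two-Bernoulli message scores, fitted coefficients are attenuated; the
  comparison target is the analytic large-sample value
  (`expected_standardized_effects`), which accounts for binomial
  measurement noise (including the truncated-binomial defined-message
  count), the omitted latent time trend, and rounding variance 1/12.
  Tolerance: 4 Monte-Carlo SEs + 0.01 for the residual approximations
  (clipping, finite samples).
* **Bootstrap calibration**: two equally informative methods (independent
  noise at SD 0.03 around the same latent), 80 outer replicates of B = 100
  at 25 clients; significance expected at ~5%.  Power: informative vs
  row-permuted noise method, 20 replicates of B = 100 at 50 clients with
  sigma_within = 0.15, sigma_symptom = 1.5 — conditions under which a
  pilot gave 10/10 correct significant decisions.
* **Mediation recovery**: a = 0.5 (per treatment course), b = −0.4,
  c′ = −0.1 at 300 clients × 4 windows, continuous outcomes, mediator =
  latent window value; the analytic proportion mediated is
  100·ab/(ab+c′) = 66.7%.  The continuous/latent route isolates the
  estimator: window means of discrete scores attenuate b and rounding
  noise would dwarf latent-scale effects of this magnitude, so 66.7% is
  the correct target only on the latent scale.  The null (b = 0) uses 20
  replicates.
* **Type-I calibration** of the within-effect test: 120 replicates at 120
  clients with no time trend (an omitted time trend induces a real
  nonzero within coefficient — a confound, not a false positive).

## Numerical choices and limitations

* Optimizer bounds on log-SDs are centered on the response/design scale
  (±12), and singular fits are flagged when a component collapses 7 log
  units below that scale — mirroring lme4's boundary warnings.
* Satterthwaite derivatives use central finite differences (step 1e-4
  relative); with ≤4 variance parameters this is accurate and cheap.  A
  degenerate Hessian falls back to residual df with the result still
  reported.
* The proportion-mediated posterior is summarized by median and central
  95% range; it is a ratio and can be heavy-tailed when |ab + c′| is
  small.
* Rule-based tagging has no syntactic context: verbs unknown to the
  lexicon are missed, noun/verb homographs in the lexicon are over-counted,
  and modal constructions (`could go`, `'d like`) carry no tense by
  design.  The curated lexicon trades recall for precision.
* Mixed-model fits assume one grouping factor; therapist-level analyses
  keep client clustering and move the *bootstrap* unit to therapists
  rather than crossing random effects.
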