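# Methods

`ehrlit` implements the psychometric pipeline used to build short
comprehension instruments from crowdsourced responses to an item bank:
quality-control filtering, 3PL item-response-theory calibration, local
independence diagnostics, an item-screening cascade, information-based
short-form selection, and EAP scoring of respondents.

## Model

Responses are dichotomous (correct / incorrect / not administered). The
probability that respondent *j* with latent ability θ_j answers item *i*
correctly follows the three-parameter logistic (3PL) item characteristic
curve

    p_ij = c_i + (1 − c_i) / (1 + exp(−a_i (θ_j − b_i)))

with discrimination a_i, difficulty b_i (in population-SD units of
ability) and guessing parameter c_i ∈ [0, 1). The slope is in the
logistic metric: no D = 1.7 appears inside the ICC (the convention of the
common IRT fitting packages). D = 1.7 enters only the factor-analytic
conversion between a slope and a communality,

    λ = (a/D) / √(1 + (a/D)²),    h² = λ²,

which is the unique convention under which the screening floor a = 0.71
corresponds to h² = 0.15 (15% of a hypothetical continuous item's
variance explained by the ability factor).

Model assumptions: a single latent ability dimension; monotone ICCs;
local independence (responses conditionally independent given θ);
independent respondents drawn from a N(0, 1) ability population. The
normal population anchors the location and scale of the ability metric,
so an ability of 0 means "the average respondent of the calibration
population". Missing responses arise from planned block administration
and are missing-by-design: they contribute nothing to any likelihood.

## Estimation

Items are calibrated by marginal maximum likelihood: the ability random
effect is integrated out over a quadrature grid of 61 equally spaced
nodes on [−6, 6] carrying renormalized N(0, 1) density weights
(transparent, and accurate to ~1e−6 for these integrands; the node count
and range are configurable). An EM iteration computes each respondent's
posterior over the grid (E-step) and then maximizes each item's expected
complete-data log-likelihood by bounded L-BFGS-B with analytic gradients
(M-step). Convergence is declared when the largest absolute parameter
change falls below 1e−4, with a cap of 500 cycles; the marginal
log-likelihood history is retained and is non-decreasing (an EM
guarantee, verified in the tests). Starting values: a = 1,
b = −logit(observed proportion correct), c = 0.1.

Bounds: a ∈ [−8, 20] (negative slopes must be estimable so that
reverse-keyed items can be screened out; the upper bound accommodates the
occasional extreme slope seen in easy crowdsourced banks), b ∈ [−6, 6],
c ∈ [0, 0.5]. The c ceiling tames the well-known 3PL instability. No
prior is placed on c by default, matching the defaults of the standard
fitting packages; a stabilizing Beta prior is available behind a config
flag and off by default.

Standard errors come from the observed information: the Hessian of the
marginal log-likelihood at the solution, obtained by central-differencing
the analytic marginal gradient (by Fisher's identity that gradient equals
the expected complete-data gradient under the E-step posterior, so each
evaluation costs one E-step). A guessing estimate resting on its box
boundary has no interior curvature; it is excluded from the Hessian and
reported with an NaN standard error, and the Wald verdict is resolved by
the boundary itself (an estimate at 0 is "not significantly different
from 0"; one at the ceiling is "significant").

Wald tests use α = 0.05 throughout: two-sided for c = 0, one-sided for
a > 0 (the direction the screening rule asks about).

### Known 3PL limitations

Two behaviours of the unpenalized 3PL estimator matter for interpreting
simulation results, and both are properties of the estimator rather than
of this implementation (each was verified against a direct optimizer of
the same marginal likelihood):

* **Guessing runaway on easy banks.** When most items are easy, few
  respondents probe the lower asymptote, c is weakly identified, and the
  global MML optimum can place ĉ at its ceiling while dragging b̂ upward.
  Calibration studies that generate c = 0 data therefore fit with c fixed
  at 0; free-c fits on easy banks should be read with the c–b trade-off
  in mind (or stabilized with the optional prior).
* **Local-dependence absorption.** If a pair of items is strongly
  dependent (the limit being a duplicated item), the unidimensional model
  can absorb the doublet by driving both slopes toward the bound — the
  pair becomes near-Guttman and, with strong dependence, the latent trait
  reorients toward it. Marginal residuals computed from such a
  contaminated fit then look clean. Diagnostics are sharpest when
  residuals are computed against a calibrated bank, and an implausibly
  extreme slope estimate should itself be read as a dependence signal.

## Diagnostics

Local independence is checked through marginal residuals of item pairs
and triplets on the all-correct margin: observed joint proportion versus
the model-implied Σ_k w_k Π p_i(θ_k), standardized by the binomial SE.
|z| > 3 flags a set (the threshold is configurable; the convention
"large" is not standardized). A z is only computed when at least 30
respondents saw the set jointly. Residuals within one administration are
positively correlated through the shared respondents; the calibration
tests therefore aggregate one residual per independent replicate.
Flagged sets are resolved by a greedy minimal cover: repeatedly remove
the item in the most flagged sets, ties broken by lower slope, until no
flagged set survives. Full 2^k contingency-pattern residuals are a noted
extension, not implemented.

## Screening cascade

1. Fit the 3PL to all items.
2. Remove local-dependence violators (greedy cover above).
3. Remove items with a negative estimated slope.
4. Fix c = 0 on items whose guessing parameter is not significantly
   different from 0; refit the survivors under these constraints.
5. On the refit, remove items whose slope is negative (labelled
   negative_slope), below 0.71 (slope_below_threshold), or not
   significantly greater than 0 (slope_not_significant) — checked in that
   order of precedence.
6. Refit the retained set; this final fit is the calibrated instrument.

Fewer than two surviving items at any point aborts with "bank exhausted".

## Information and the short form

Item information follows Birnbaum's 3PL formula
I_i(θ) = a² ((p − c)/(1 − c))² (1 − p)/p, which reduces to a² p (1 − p)
for c = 0 with maximum a²/4 at θ = b. Test information is the pointwise
sum, and SE(θ) = 1/√I(θ): information 4 is the conventional adequacy
floor (SE below 0.5). Curves are evaluated on 401 points over [−4, 4];
threshold crossings are linearly interpolated between grid nodes. Average
information over a range is an unweighted mean on a uniform grid (a
normal-density-weighted variant is available behind a flag).

The short form takes the k (default 14) retained items with the highest
average information over [−4, 4], ties broken by larger slope and then
item id. Average information is the primary key because it subsumes the
slope for well-behaved items; no topic-coverage constraint is imposed.

## Scoring

Respondents are scored by the posterior mean of θ (EAP) under the
N(0, 1) prior on the same quadrature grid, with the posterior SD as
uncertainty. EAP is finite for all-correct and all-incorrect patterns,
where the ML estimate diverges, and is shrunk toward the population mean.
A respondent with no administered items receives the prior moments.
Stratum summaries report mean percent-correct and mean EAP per level of
each demographic variable; percents are kept unrounded internally and
rounded only for display.

## Quality control

Two person-level screens, applied before any fitting: a repeated question
(two different answers exclude the respondent; with dichotomous
recording, identical option choice and identical correctness coincide)
and two catch questions (one or both wrong excludes). Exclusion is
person-wise and idempotent; the report counts removals by reason, with
the repeat rule reported when both apply. Platform-level screens
(approval rate, location) are upstream inclusion criteria and only
carried as metadata.

## Synthetic data generator

The generator emulates the statistical structure of a crowdsourced
administration of an EHR-comprehension bank — the real responses of such
studies are typically not deposited:

* **Item bank** — a ~ LogNormal(log 1.2, 0.4) (discriminating, with an
  occasional extreme slope), b ~ N(−1, 1) (a mostly-easy bank: ~84% of
  difficulties below 0), c ~ U(0, 0.25) or fixed 0. Topics cycle through
  six disease labels.
* **Respondents** — θ ~ N(shift, 1) per demographic stratum; strata are
  pure mean-shifts (e.g. an education gradient of −0.9 SD), sized by
  largest-remainder rounding of the design proportions.
* **Administration** — defaults to the balanced block design of an
  18-item task: 3 groups of 6 items, each respondent answering a random
  2 of 3 (12 items each); complete administration is the no-block case.
* **Quality control** — per respondent, one administered item repeated
  (second answer inconsistent with probability 0.05) and two catch
  answers (each wrong with probability 0.03, independent of ability).
  The implied expected exclusion rate is 1 − 0.95·0.97² ≈ 10.6%, in line
  with the ~10% exclusion rates reported for comparable crowdsourced
  tasks.

Every generator draws from a single design seed through separate child
streams, so studies are bit-reproducible. The generator does not emulate
question text or semantics, response times, learning or fatigue effects,
ability-correlated carelessness (a config-gated extension point), or
differential item functioning — so passing simulation tests shows the
pipeline recovers the structure it assumes, not that real crowdsourced
data satisfies those assumptions.

## Problem sizes in the test suite

The simulation studies in the tests use 12–20 items with 400–2000
respondents and 5–10 replicate seeds: large enough that calibration
standard errors are a few hundredths to ~0.1 (so planted effects of 0.3–1
SD separate cleanly from noise), small enough that the full suite runs in
a few minutes on one CPU. The 3-item oracle-equivalence check uses an
independent cyclic grid maximizer of the same marginal likelihood; the
2-item variant is excluded because it is not identified (four parameters
against three free pattern probabilities).

## Numerical conventions

Probabilities are clipped to [1e−10, 1 − 1e−10] inside likelihoods; the
posterior over grid nodes is computed with the log-sum-exp trick. JSON
artifacts serialize floats at 12 significant digits; pipeline artifacts
carry the configuration hash and seed, and repeated runs under one seed
are byte-identical. Short-form and tie-break orderings are total
(information, then slope, then item id), so selections are deterministic.
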