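# Methods

This note documents the models, conventions and defaults behind the
package, and what the synthetic-data generator does and does not
emulate.

## Respirometry

**Chamber physics.** A bimodal respirometer of total volume 2.5 L holds
an air phase (~0.2 L, calibrated per chamber) above the water phase.
The effective water volume subtracts both the air phase and the fish
body, with fish density assumed 1.0 g/mL; whether body volume should be
subtracted is genuinely ambiguous in practice, so the choice is flagged
in the output metadata (`fish_volume_subtracted: true`).

**Cycle reduction.** Cycles are 900 s (600 s closed + 300 s flush),
anchored at the first sample; the number of analysable cycles is
`floor(span / period)`. The first 60 s of each closed phase are skipped
by default (`settle_skip`) to discard the mixing transient after
flushing; the value is configurable because the artefact depends on
chamber stirring. Slopes are plain OLS on the remaining closed-phase
samples, reported per hour with r²; no r² rejection filter is applied
by default — an optional threshold excludes cycles from the summary and
logs the count, never silently.

**Unit conversions.** Air-phase declines (kPa/hr) convert to uptake
through the ideal gas law, `ṀO₂,air = (−slope·V_air)/(R·T)/m`, with
R = 8.31446×10⁻³ L·kPa·mmol⁻¹·K⁻¹. Water-phase declines (%sat/hr) scale
by the O₂ content of air-saturated fresh water from the Benson–Krause
(1984) fit at trial temperature and barometric pressure (0.251 mmol/L
at 26.5 °C, 101.325 kPa), vapour-pressure corrected. A closed-phase O₂
*increase* beyond 0.05 units/hr flags the cycle; smaller positive slopes
are truncated to zero uptake as noise.

**SMR and %ṀO₂,air.** SMR is the q = 0.12 quantile of the per-cycle RMR
series with *linear interpolation between order statistics* (the
convention of common statistical software; the quantile method itself
does not fix one). The interpolation rule is recorded in profile
metadata. %ṀO₂,air is 100·ΣṀO₂,air/Σ(ṀO₂,air+ṀO₂,water) over the
analysed cycles — a ratio of sums, not a mean of ratios, so cycles with
more uptake weigh more.

**Air-volume calibration.** An N₂ bolus V_b into a well-mixed,
isobarically vented air space of volume V dilutes PO₂ by
F₁ = F₀·V/(V+V_b); inversion gives V = V_b·p₁/(p₀−p₁). The plug-flow
alternative was rejected as physically implausible for a stirred
headspace. Multi-bolus protocols are supported elementwise (average the
per-bolus estimates).

## Event-stream statistics

**CD.** Counts in 30-s bins anchored at trial start (trials are 900 s,
so 30 bins exactly; a non-multiple duration drops the trailing partial
bin with a warning). CD = sample variance (n−1 denominator) / mean; the
source literature is ambiguous about the variance convention, so it is
recorded in the result object. An empty stream has *no* CD — it is
signalled, never reported as 0. For a homogeneous Poisson stream the
expectation is 1 (verified by simulation in the test suite).

**Proximity attribution.** A breath at time t qualifies for a category
iff at least one reference event lies in the half-open window
(t−5 s, t): a simultaneous event (lag 0) does not count, and a breath
qualifies once per category no matter how many reference events precede
it (fractions are per-breath, not per-pair). Avoids count as
interactions involving only the avoider, because targets of avoids are
not coded in the ethogram. "Being attacked" requires coded attack
targets; when a dataset lacks them the category is reported unavailable
(NaN), not zero.

**Dominance.** The dominant individual is the fish with the most attacks
summed over its group's trials; ties break on attacks + pushes, then
lexicographic id, with the tie-break path logged.

## Mixed models

Fitted with statsmodels `MixedLM`. Fish-nested-in-group uses a group
random intercept plus a variance component over fish dummies within
group; this is exactly the nested two-level Gaussian model. Count-like
responses (breaths, attacks) use log1p where a log is wanted (zeros
occur); activity (distance moved) likewise. The analysis table keeps
the recovery observation out of the LMEs by default (five levels), while
proximity and synchrony tables include it as a sixth level.

* **Random-structure choice**: random-intercept vs. added per-fish slope
  over (standardised) numeric oxygen, REML LRT with the halved χ²₁
  p-value because the tested variance sits on its boundary; equal
  likelihoods retain the simpler model. The slope covariate is
  standardised internally — on the raw 20–100 scale the optimiser is
  unreliable.
* **Backward elimination** under ML: the candidate is the droppable term
  (not contained in any surviving interaction) with the smallest |t|
  (multi-coefficient terms use their largest |t|, so a term with any
  strong coefficient is not an early candidate); it is dropped unless
  the removal LRT is significant at α = 0.05 (equivalently, unless
  removal significantly inflates AIC). The full trail (term, t, ΔAIC,
  LRT p, decision) is emitted and replays deterministically. Final
  models are refit under REML for reporting.
* **R²**: marginal = V_fixed/(V_fixed+V_id+V_group+V_res) with V_fixed
  the variance (n−1 denominator) of the fixed-effect predictions;
  conditional adds the random-intercept variances to the numerator.
* **Repeatability**: R = V_id/(V_id+V_group+V_res) from the REML fit
  with adjustment covariates (oxygen level) as fixed effects. CI by
  parametric bootstrap: `n_boot` (default 1000) simulations from the
  fitted model, refit on cached design arrays, percentile 95% interval,
  seed mandatory and recorded. The p-value is a boundary-corrected LRT
  of the id variance; because statsmodels has no comparable REML
  likelihood for the no-random-effect reduction, both LRT models are
  refit under ML. A dataset with mostly single observations per id is
  reported unidentifiable, never given a number. Reported degrees of
  freedom for fixed-effect t-statistics are the simple n − p residual
  df; denominator-df approximations differ across software in decimals,
  not conclusions, and the convention is stated in the output.

## The generator

The simulator reproduces the study structure: 11 groups × 4 fish, five
oxygen levels plus recovery, 15-min trials, 68 respirometry cycles.

*Respirometry*: per cycle, RMR = SMR·(1+s) with the surcharge s drawn
from a mixture — with probability 0.25 the fish rests (s ~ U(0, 0.03)),
otherwise s ~ 0.03 + Exp(0.35) — giving the right-skewed RMR
distribution the quantile method assumes, with a genuine resting floor
so the q = 0.12 quantile identifies SMR. The partition into air/water
jitters around the fish's true %ṀO₂,air (SD 2 points). Declines are
forward-simulated through the same gas/solubility physics the analysis
inverts, plus Gaussian sensor noise (0.015 kPa air, 0.10 %sat water at
5-s sampling) and a 20-s-decay settle artefact — values chosen as
realistic optode behaviour; recovery tests hold at several multiples of
these.

*Behaviour*: attacks are per-fish Poisson (1.5 per subordinate per
trial, ×5 for the designated dominant, × a lognormal group aggression
multiplier with σ = 0.6 echoing the large among-group variance in
aggression, × a hypoxia factor up to 1.4 at 20% sat). Baseline breaths
are Poisson (3 per fish per trial at normoxia, same hypoxia scaling,
with a per-fish lognormal multiplier of CV 0.5 so individuals have a
repeatable breathing tendency; the same fish-specific baseline, divided
by the facilitation factor, drives that fish's isolation trials).
After each attack, actor and target each breathe with probability 0.35
at an exponential lag (scale 2 s) truncated at 5 s; after each primary
breath every other fish breathes with probability 0.03 at a U(0, 5]
lag. The trigger probabilities and baseline rate were calibrated once
so the default summary statistics land in realistic observed ranges for
social air-breathers (~20–30 breaths per group-trial, breath CD median
~1.2, ~19% of breaths within 5 s of another fish's breath, ~16% after
own attacks, ~33% after any involving interaction); the follow
probability must be small because coincidental 5-s overlap already
contributes substantially at these breath densities. One deliberate
mismatch remains: because one probability governs actor- and target-
triggered breaths, breaths after being attacked are as common as after
attacking, whereas real subordinates likely surface more after being
attacked.
Truncating lags at the 5-s proximity window makes the trigger
probabilities directly identified by the proximity statistics — real
physiological lags surely exceed 5 s sometimes, so on real data the
proximity fraction *underestimates* triggering. Follower breaths do not
recruit further followers: unrestricted cascading is supercritical once
p_follow ≥ 1/3 with three listeners, so the generator is single-
generation by construction. Activity is a + b·(own attacks) + Gaussian
noise (50, 30, SD 15 length units); isolated fish breathe at the group
baseline divided by a social-facilitation factor (6).

These defaults put per-trial group breath totals, CD values and
proximity fractions in realistic ranges for a social air-breather, but
the generator is deliberately idealised: no diurnal rhythm, no
habituation across the oxygen ladder, no dominance turnover, marked
Poisson processes rather than full Hawkes dynamics, and Gaussian trait
noise. Passing recovery tests therefore demonstrates the *estimators*
are correct and calibrated under the design's structure — not that real
catfish obey these distributions.

*Trait tables*: `simulate_trait_table` builds repeated-measures data
with exact variance components (defaults v_id = 0.3, v_group = 0.1,
v_resid = 0.6) for repeatability recovery and coverage studies;
`simulate_analysis_table` builds the fish × oxygen table with real
activity and attack effects (2.095, 1.687 on the log scales) and null
SMR/mass/%ṀO₂,air effects for elimination-pattern recovery. Activity
noise there is multiplicative (lognormal), keeping activity and attacks
correlated but separately identifiable — with additive noise the two
log covariates are nearly collinear and the design's effect pattern is
unrecoverable by any method.

## Problem sizes

The test suite and acceptance script size their simulations so the whole
run stays desk-scale: 50 fish for trace recovery, 10,000 streams for the
CD null, 1,000 random trials for oracle equality, 31 datasets for
repeatability point recovery, 40 studies × 100 bootstrap resamples for
CI coverage, 100 datasets for elimination pattern recovery, and
bootstrap n = 200 inside the full replica. These are the package's own
reproducibility choices; all scale up via configuration.

## Known limitations

* Background (microbial) respiration is not corrected (none was in the
  design being replicated) and instrument control is out of scope.
* The Dryad ingestion path is a column-mapping layer; the exact deposit
  schema is unverified, which is precisely why mapping is configurable
  and missing columns raise named errors.
* Repeatability CIs are parametric-bootstrap percentiles; analytic or
  case-bootstrap intervals would differ in decimals.
* The LRT for fixed-effect elimination uses the χ² reference; with
  44 individuals and ~220 rows this is mildly anticonservative compared
  with Kenward–Roger-style corrections.
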