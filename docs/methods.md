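# Methods

## Model structure

The engine is a deterministic compartment (cohort Markov) model: expected
person counts on a dense grid of sex × 10-year age band (35–44 … 85–94) ×
risk-factor stratum × health state, advanced in annual cycles.  Individual
microsimulation was deliberately avoided: the quantities of interest are
expected counts and their input-uncertainty distribution, both of which the
expected-value recursion delivers exactly and cheaply.

The default stratum ontology is the cartesian product of smoking (2),
systolic blood pressure band (3), HDL band (2), LDL band (2), BMI band (3),
diabetes (2) and physical-inactivity status (2) — 288 strata.  Diastolic
blood pressure is not a default axis (systolic only); the ontology is
configurable, and any factor set containing binary `diabetes` and
`pi_status` works.  Health states are CVD-free, post-CHD, post-stroke and
post-both.

Within a cycle the order of operations is: rebalance of the inactivity
split to the scenario trajectory → annual transition step → aging.  Events
are computed on start-of-year populations and attributed to the age band
occupied at event time.  Aging moves 1/10 of each band up per year; outflow
from the 85–94 band leaves the model.  The cohort is closed (no new
entrants at 35) for the 7-year counterfactuals; an entrant stream is a
deliberate non-feature until credible projection inputs exist, and the
2016–2030 runs therefore describe the aging 2016 cohort.  No half-cycle
correction is applied — targets and tallies are annual counts, not
person-time integrals.

### Transition step

Among the CVD-free: incident T2D moves a person to the diabetes-flipped
twin stratum (risk feedback from the next cycle, per annual-cycle Markov
convention); incident CHD resolves through the bridge into cardiac arrest /
MI / angina with type-specific 30-day case fatality, survivors entering
post-CHD; incident stroke analogously.  In the history states, recurrent
coronary events are counted as MIs, a first stroke in post-CHD (or first
coronary event in post-stroke) moves survivors to post-both, and chronic
CVD death is attributed to the CHD stream in post-CHD, the stroke stream in
post-stroke, and split 50/50 in post-both (configurable share).  All CHD
survivors share one post-CHD state; angina is not tracked as a separate
persistent state, though the history-parameter hooks would admit one.

Outcome tallies: first events from the CVD-free state plus first events of
the other disease in history states count as incidence; "total MI" is the
MI share of bridge events plus all recurrent coronary events; mortality
streams combine bridge case fatalities with attributed chronic CVD deaths.
Competing risks within a cycle are handled in the expected-value sense
(independent annual probabilities applied to the start-of-year count); the
engine validates that total annual exit probability never exceeds 1.
Person conservation (in = out + deaths) is asserted to 1e-9 relative every
cycle.

## Rates, risks and the inactivity effect

Annual probabilities are used directly as rates (no exponential
conversion): every rate involved is well below 0.2/year, where the
distinction is smaller than any input uncertainty.  Conversion helpers
exist for callers who want them.

Physical inactivity acts only on incident T2D, CHD and stroke — the three
outcomes with published relative risks — never on non-CVD death.  Because
no published splitting of calibrated overall rates across activity strata
exists, the package uses the attributable-fraction decomposition
λ_inactive = λ/(p + (1−p)·RR), λ_active = RR·λ_inactive, anchored at the
**baseline** prevalence p.  Anchoring matters: the decomposition preserves
the population-average rate at p, so the calibrated totals are honoured in
the base year, while a scenario that moves the population mix away from p
shifts average rates — that shift *is* the modelled effect.  (Decomposing
at each year's realised prevalence would, by construction, erase the effect
entirely.)  Relative risks supplied without sex stratification apply to
both sexes and all age bands.

Multi-level activity contrasts are collapsed by inverse-variance pooling of
log relative risks.  A logistic annual-risk function over categorical
levels stands in for cohort-estimated parametric risk equations; its
coefficients are configuration inputs, since no coefficients are published.

The prevalence rebalance operates within every (other-factor combination,
health state) pair, setting the inactive share to the target in each, which
preserves every non-PI marginal exactly; it applies to the bands a scenario
steers (35–64) and leaves older bands at their evolved composition.

## Calibration

Streams: total acute CHD events, total acute stroke events, CHD deaths,
stroke deaths, per sex × age band (48 factors).  Event factors scale
first-event incidence and history event rates; death factors scale 30-day
case fatalities (clipped at 1) and chronic CVD-death rates.  The update is
multiplicative proportional fitting, factor ← factor × (target/simulated)^d
with damping d = 1 by default, re-simulating the base year after each
update so the population at risk is refreshed.  The stopping rule is the
published one: every stream within 1% (relative) of its target.  Event
counts are exactly linear in their own factor and death counts linear given
the event factors, so convergence takes 2–3 iterations; damping < 1 is
exposed for configurations that interact more strongly.  Exhausting
`max_iter` raises an error carrying the worst residual; a positive target
on a stream with zero simulated events raises a structural-infeasibility
error.

## Scenarios and reporting

The 2006-vs-2012 counterfactual runs two flat trajectories for 7 years from
the 2010 base year.  The WHO scenario starts in 2016 from the 2012
prevalence (the surveys showed no evidence of change between 2012 and
2016), declining linearly in prevalence to 90% of the start value at 2025
and 85% at 2030 — the 2030 target read as a **total** 15% reduction
including the 2025 decrease, the more natural reading of the global
targets; the incremental reading is available by passing a different end
reduction.  Headline outputs sum both sexes over the 35–64 bands.  Counts
are rounded half-up to the nearest 100 in human-readable summaries only;
percents are computed from unrounded counts, half-up to one decimal for
count deltas and to the nearest integer for prevalence changes.  Raw counts
are always what gets serialized.

The accelerometer sensitivity analysis is a pure substitution: an adjusted
prevalence table replaces the self-report one and the comparisons re-run
unchanged.  The published Mexican adjustment equation is an external input;
the analysis driver uses a clearly labelled synthetic stand-in (self-report
× 1.5) to exercise the path.

## Uncertainty

Each Monte Carlo draw perturbs every log relative risk and, per scenario
and band, the logit prevalence (as a constant logit shift of the whole
trajectory, preserving its shape) by standard-normal multiples of their
standard errors, then re-runs the paired comparison.  SEs derive from 95%
CIs as (g(hi) − g(lo))/(2·1.96) on the log/logit scale, which also
guarantees positive RRs and prevalences in (0, 1) at any draw.  Draws use
counter-based substreams (`default_rng([seed, draw])`) so results are
reproducible and order-independent.  The reported SE is the SD of draws
divided by √n, mirroring the "mean ± SE" presentation convention for
simulation means; the raw draw SD is available via `se_kind="sd"`.  Which
inputs the original analysis perturbed is not documented beyond "1000
standard-normal draws per outcome"; perturbing the two input families with
published CIs is this package's interpretation, and no numeric equivalence
with previously printed SEs is claimed.

## Synthetic inputs

`generate_inputs` emulates what national sources would supply:

* population ≈ 6.9, 4.9, 3.3, 2.0, 0.9, 0.2 million per sex across the six
  bands (2010-plausible magnitudes), log-normally jittered (σ = 0.05) and
  multiplied by `scale` — `scale` touches population only, so a down-scaled
  bundle runs identical epidemiology;
* risk-factor stratum distributions from independent per-factor marginals
  (Dirichlet-jittered around plausible national levels) combined
  multiplicatively — the minimal assumption given that no joint
  distribution is published — with the inactivity marginal pinned to the
  packaged survey fixture (2006 by default; 65+ bands reuse the 55–64
  value, the oldest published band);
* base rates anchored at the youngest band (e.g. CHD 2.2/1000·yr men,
  1.3/1000·yr women) growing per decade of age (factors 1.25–2.0 by
  outcome), bridge splits ≈ 7/45/48% arrest/MI/angina with case fatalities
  rising with age, history rates of the same order as first-event rates,
  and a prior-CVD fraction doubling per decade from 0.4%.

Everything is deterministic given the seed.  What the generator does *not*
emulate: survey weighting and clustering, secular risk-factor trends,
migration, correlation between risk factors, or the true Mexican registry
counts — so passing tests demonstrate the machinery's correctness and
contracts, not agreement with Mexican surveillance data.  Accordingly the
published absolute projections are not reproduction targets; the packaged
projection fixture is used to verify reporting arithmetic, not to re-derive
its counts.

## Numerical choices and limitations

Tolerances: stratum-distribution and bridge-split sums to 1e-9;
conservation to 1e-9 relative; mixture identity exact to 1e-12; calibration
stopping at 1e-2 (configurable).  Tiny negative counts from floating-point
cancellation (below the conservation tolerance) are clipped to zero after
the conservation check.  Analyses use the full synthetic population
(~35 million aged 35–94, seed 12345); tests and the acceptance run use the
same generator at `scale = 0.01`, which leaves every rate, share and
relative result unchanged.

Known limitations: no same-year competing-risk adjustment beyond the
expected-value approximation; one pooled post-CHD state; closed cohort;
independence across risk factors in the synthetic generator; the
history-state event typing (recurrent coronary events = MI) is a modelling
convention, not an observed split.
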