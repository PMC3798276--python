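# Methods

This note documents the model, the numerical choices and the design
decisions behind `cyclesim`, and what the synthetic-data tests do and do
not establish.

## Population model

The population is a collection of cohorts indexed by cycle `i` (0..f),
phase (G1, S, G2M) and age compartment `k` within the phase.  Compartment
`k` represents ages `[(k−1)Δ, kΔ)`; the default step is Δ = 0.5 h.  One
simulation step advances every cohort by Δ using balance equations: the
number of cells in a compartment at `t+Δ` equals those that stayed, plus
those that advanced from `k−1`, minus exits, deaths and diversions.

### Phase-duration laws and exit probabilities

Phase durations are continuous random variables specified by mean and CV.
Two families are supported — lognormal (default) and gamma — both standard
right-skewed models of intermitotic-time variability and fully determined
by (mean, CV).  The main scientific object is the discretized mass
`F_ph(k)`, the probability that a duration takes `k` grid steps, from which
the age-dependent exit probability is

    β_ph(k) = F_ph(k) / (1 − Σ_{j<k} F_ph(j)),  β_ph(n_max) = 1.

**Discretization is mean-preserving**: `F_ph(k)` collects durations in
`[(k−1/2)Δ, (k+1/2)Δ)` (durations round to the nearest whole number of
steps, minimum one step).  Binning by `ceil(T/Δ)` instead would bias every
phase mean by +Δ/2 (≈2.5% of a 10 h phase at Δ = 0.5), which propagates to
the cycle time and growth rate; rounding keeps the discretized mean within
well under 1% of the nominal value on all grids used here.  The law is
truncated at the first compartment where cumulative mass reaches 0.9999,
with the residual tail folded into the last compartment and the mass
renormalized.  CV = 0 is an exact delta at `round(mean/Δ)` steps.

### Sub-step ordering

One canonical order is used everywhere (engine and microsimulation):

1. per-age exits and aging, modulated by a type-I delay where bound;
2. interception of a fraction `p_bl` of the exiting flux into the blocked
   pool; death (`dr_bl`) and recycling (`rec`) act **simultaneously on the
   start-of-step blocked pool** — newly intercepted cells are at risk from
   the next step.  Simultaneous resolution makes the eventual fates
   order-independent and available in closed form
   (death `dr/(dr+rec)`, recycling `rec/(dr+rec)`);
3. cycling-cell death (`dr`) on all non-exited cycling cells — cells that
   complete the phase in a step are not also at risk of dying in it —
   and quiescent/G0/polyploid pool deaths;
4. division of G2M completers (`m_div` newborns per completer; the deficit
   `2 − m_div` per division is booked as death in mitosis so that the
   bookkeeping identity below holds for `m_div < 2`), routing of newborns
   to cycle `i` or `i+1` by `p_out[i]`, pairwise re-fusion of a fraction
   `p_pol` of arrivals into the destination cycle's polyploid pool
   (2 newborns → 1 polyploid cell);
5. entries: every flux entering a phase first passes that phase's
   quiescence module; G1 entry optionally transits G0 (`θ` bypass, `γ`
   exit, `dr_g0` death), and G0 leavers pass the G1 quiescence draw on
   exit.

All rates are per-step probabilities; configuration validation rejects
any competing combination exceeding 1 per step (e.g. `dr_bl + rec > 1`).

Every state carries cumulative per-cycle death and entry counters and a
net-birth counter, so that

    alive(t) + cumulative deaths(t) = N(0) + net births(t)

holds to floating-point accuracy at every step (net births = divisions −
sibling-fusion losses − discarded overflow when `p_out[f] = 1`).

### Cycle wiring

`p_out[i]` is the fraction of newborns of cycle `i` entering cycle `i+1`;
the rest re-enter cycle `i`.  `p_out = (0,)` gives the single-cycle model;
all ones gives the multi-generation model where cycle ≡ generation;
`p_out[f] = 0` pools generations ≥ f in the final cycle (the "g3+" class
of time-lapse summaries; default f = 5).  Intermediate values can express
differentiation chains, though no feedback between stages is modelled.

### Starting state

`desynchronize` iterates the unperturbed single-cycle model from a rough
seed (phase shares proportional to mean durations, uniform over ages)
until the phase percentages change by < `tol` (default 0.1 percentage
points) per step **and** the per-step growth factor is stationary to
1e−9 relative.  The second condition is deliberate: percentage
stationarity alone leaves a slow transient in the growth factor
(≈2×10⁻³ spread over 72 h from the 0.1% criterion), while the returned
state should sit on the asynchronous exponential-growth attractor (the
renewal theorem's stable age distribution).  The converged distribution is
rescaled to `n0` (default 1000) cells in cycle 0 at t = 0.  The seed shape
is irrelevant at convergence; it is fixed for reproducibility.

BrdU pulse-chase: the t = 0 state is split into a BrdU+ state holding the
cycling S-phase cells and a BrdU− state holding everything else (quiescent
cells do not synthesize DNA and stay unlabelled); the two evolve
independently, with perturbation modules optionally scoped per label.
Continuous labelling transfers the cycling cells entering S from the
unlabelled to the labelled run each step until washout.

### Confluence

Optionally, G1 quiescence increases with total cell number via a Hill
term `pq_max·N^s/(N50^s + N^s)` added to the baseline `pQ_G1` (clipped to
1).  Off by default: the treated-run fits cover a 72 h window in which the
cultures stay subconfluent.  The density feedback is not implemented in
the microsimulation (it raises if configured).

## Observables

%G1/%S/%G2M count cycling + quiescent + blocked cells of each phase over
all cycles and both labels: blocked and quiescent cells retain the DNA
content of their phase, so a DNA histogram counts them there.  Polyploid
cells are excluded from the denominator by default (their DNA content lies
beyond the G2M position); a switch includes them.  %BrdU+ is the labelled
share of the whole population; %Und+ the share of labelled cells still in
generation 0 (cycling, blocked or quiescent — they have not divided).
Generation counts are normalized to N(0) = 1000.  F(Tc) is the double
convolution of the three duration masses (untreated or delay-only
configurations; under blocks the intermitotic time is no longer the sum of
three phase durations and no simple closed form exists).  With type-I
delays the mean cycle time is `Σ T_ph/(1 − del_ph)`.

## Microsimulation

`cyclesim.microsim` runs the identical per-step process as vectorized
Bernoulli draws over individual cells, including division (2 children with
probability `m_div/2`, else death in mitosis), per-pair destination and
re-fusion draws, and optional field-loss (FL) hazards.  Its expectation
equals the deterministic trajectory by construction — the engine
cross-validation tests exploit this.  As the time-lapse generator it
rounds event times to a 20-minute capture grid and emits one record per
tracked cell (M/D/S/R/FL outcomes); re-fused pairs yield two R records and
one unrecorded polyploid entity.

What the generator does *not* emulate: correlated sibling fates beyond
shared lineage history, cell–cell signalling, spatial effects, tracking
errors, and FC gating/deconvolution noise (FC noise is plain Gaussian on
the derived percentages).  A green recovery test therefore establishes
identifiability under the model's own assumptions, not robustness to
misspecification.

## Time-lapse statistics

Intermitotic times are `outcome − birth` of M-outcome cells.  Generation
counts are corrected for cells lost to follow-up by Kaplan–Meier-style
risk-set renormalization: each loss at time `s` multiplies all later
counts by `n_at_risk(s)/(n_at_risk(s) − 1)`.  The exact correction used
for the published curves is not stated; this censoring convention is the
standard estimator for that situation.  Counts are normalized to
N(0) = 1000.  Raw intermitotic samples from a finite observation window
are right-censored (slow cells never divide in-window); tests that check
the generator against the nominal mean therefore restrict to cells born
early enough to complete a cycle.

## Fitting

The objective is a weighted SSE over all series, with inverse-variance
weights throughout: FC residuals by the replicate SD (floored at 1
percentage point); TL generation counts, on the percent-of-N(0) scale, by
the sampling SD implied by the number of tracked roots
(`var(N) ≈ N·N0/n_roots`, a Poisson-type estimate — an earlier fixed-scale
weighting overweighted the TL curves about fourfold and measurably biased
the estimator); per-generation death fractions by their binomial SD.  Mean
absolute errors are reported per platform.  The loss, weights and
optimizer of the original analysis are unpublished; these defaults are
this package's own choices.

Optimization defaults to bounded nonlinear least squares on the residual
vector (trust-region-reflective, finite-difference gradients, seeded
multi-starts).  The simulation output is empirically smooth in the
parameters, and least squares converges in ~15–40 residual evaluations
where Nelder–Mead and Powell needed thousands without converging; both
derivative-free methods remain selectable (`method=`).  Multi-dose fits
replace per-dose parameters with Hill (`max·D^h/(ED50^h+D^h)`) or gamma
(`a·D^b·e^{−cD}`) dose–response laws and fit the coefficients jointly;
evaluated values are clipped to the target parameter's range.  The gamma
form is a standard non-monotone dose-response shape with interior maximum
at `D = b/c`; its exact intended form was not printed and this is a
documented assumption.

Bootstrap uncertainty is parametric: replicate datasets are drawn from the
best-fit model with the measurement-noise model — FC percentages with the
dataset's stated replicate SDs, and the TL side regenerated by re-running
the stochastic lineage microsimulation from the best-fit configuration.
The regeneration matters: TL curves are counts of the same cells observed
repeatedly, so independent per-point noise understates the estimator
spread several-fold (measured ~4x too-narrow CIs).  Each replicate is
refitted warm-started at the optimum; percentile 95% CIs, the estimate SD
and the failed-replicate count are reported.  With 95% intervals on
several coefficients, the event "every CI brackets its true value" has
less than 95% nominal probability, and at 50 replicates the percentile
endpoints themselves are order-statistic-noisy; coverage checks should be
read per-coefficient and preferably against the bootstrap SD.

Type-IV time courses keep IT50 and the steepness m fixed (defaults 24 h
and 4; the published values are not printed) — they are configuration
constants, not fitted.

## Synthetic stand-in X-ray model

`cyclesim.synthetic_xray_model` is a synthetic parameterization assembled
once from published qualitative dose-dependencies (block probabilities per
generation, blocked-cell fates, S delays by label, polyploidization
rates), because the original best-fit values are not tabulated in the
available text.  It is used for demonstrations and an acceptance check of
72 h population compositions; it is not a fitted model, and the
composition check documents how far the narrative-derived stand-in lands
from the published best-fit compositions.

## Known limitations

- No sibling-fate correlations, signalling or spatial structure.
- Polyploid cells do not divide; death modes are not distinguished.
- Dead cells vanish from all counts immediately (no debris compartment).
- F(Tc) is not defined under block-type perturbations.
- The confluence feedback is minimal (Hill on total N driving pQ_G1 only)
  and absent from the microsimulation.
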