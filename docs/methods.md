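# Methods

## Data model and arrest classification

A lineage is the ordered series of cell-cycle durations (minutes, 10-min
acquisition grid) of one tracked cell position, from telomerase
inactivation (negative lineages) or the start of imaging (positive
lineages) to death or the end of observation. A cycle is *long* (an
arrest) when its duration strictly exceeds the threshold *D*; a cycle
equal to *D* counts as normal, which at 10-min resolution is the natural
reading of "longer than *D*". *D* is the mean plus three sample (n−1)
standard deviations of the telomerase-positive durations after censoring
the first and last cycle of each positive lineage (imaging is not
synchronised with divisions); with the default generator this lands near
180 min.

Maximal runs of consecutive long cycles are classified as *terminal*
(the last run of a died lineage, extending to its final cycle — the
senescence run) or *non-terminal* (at least one normal cycle follows).
Censored lineages have no terminal run and are excluded from senescence
analyses, since their fate is unknown. For analyses of non-terminal
arrests, lineages whose only long cycles are terminal are excluded;
lineages with no long cycles at all are retained as right-censored
observations — they contribute to the at-risk denominator of the hazard
but never to the numerator. This choice (the natural one for discrete-time
hazard estimation) matters only for the empirical hazard, not for the
first-arrest sample itself.

## First-arrest hazard model

The generation *X* of the first non-terminal arrest is modelled as a
sequence of Bernoulli trials with per-generation hazard p(j):
P(X = k) = p(k)·∏_{j<k}(1 − p(j)). Two families are fitted:

* constant p(j) = p — then X is geometric and the MLE is 1/mean
  (support {1, 2, ...});
* logistic p(j) = 1/(1 + exp(−(j − midpoint)/scale)) — strictly
  increasing, ≈ exponential growth while small, and bounded in (0, 1).

The empirical hazard at generation j is the fraction of at-risk lineages
(no earlier non-terminal arrest, still observed, not yet in their terminal
run) whose first arrest occurs at j; generations with at most 5 lineages
at risk are dropped. The default logistic estimator is weighted least
squares on these hazard points with the at-risk counts as weights,
mirroring how the hazard curve is constructed; a maximum-likelihood
estimator under the chain pmf is available as an option. Both use
multi-start local optimisation (midpoint grid over the observed range,
scales 0.5–16, objective tolerance ~1e−12 in the residual solver) because
the weighted-LS surface has shallow ridges when the observed hazard only
covers the lower tail of the logistic.

Goodness of fit uses a Pearson chi-square over the integer support with
mass beyond the largest observed generation pooled into the last bin, bins
merged from the right tail inward until every expected count is at least 5
(configurable), and degrees of freedom reduced by the number of parameters
estimated from the same data (1 constant, 2 logistic). Fewer than two bins
after merging, or non-positive degrees of freedom, raise an error rather
than returning a meaningless p-value.

## Telomere-shortening simulator

Each cell carries 32 telomeres. Per division each telomere independently
loses twice the shortening rate with probability 1/2, else nothing
(the asymmetric end-replication problem); an exact-half mode (a random
16-of-32 subset shortens) is available behind a flag — the two differ only
in variance. Defaults: shortening rate 3 bp/division; initial lengths
drawn i.i.d. from a truncated normal surrogate (location 300 bp, spread
75 bp, clipped at 0), standing in for the steady-state length distribution
under telomerase. Both values are configuration-exposed and recorded in
provenance; fitted threshold parameters are therefore meaningful only
relative to a stated telomere-model configuration. A "stationary" sampler
is also provided: a telomerase-positive burn-in chain in which short
telomeres are preferentially elongated (logistic elongation probability,
midpoint 220 bp, width 30 bp, +40 bp per elongation, 500 burn-in
divisions), whose steady state has a comparable location and spread.

Signalling rules, evaluated once per completed division after shortening:

* deterministic — trigger iff L₁ + α·L₂ ≤ L_min (inclusive: trigger when
  the combination has *reached* the threshold);
* probabilistic — trigger with probability p(L₁) = b·e^{−a·L₁}, forced to
  1 when L₁ = 0 (an eroded telomere always signals).

## Threshold fitting

Given the ordered experimental first-arrest generations Ḡ(1..n), the fit
minimises e(θ) = Σ_{j=1}^{N} Σ_{i=1}^{n} (G(i,j;θ) − Ḡ(i))², where G(·,j)
is the ordered j-th simulated replicate of n lineages. Telomere length
paths do not depend on the signalling parameters, so one frozen block of
N×n trajectories of (L₁, L₂) with per-division uniforms is simulated once
and reused for every candidate (common random numbers): the objective
becomes a deterministic surface and candidate evaluation is a vectorised
scan. Optimisation is by differential evolution (population 12, up to 40
iterations, Sobol initialisation, no polish — the surface is piecewise
constant in places) with three restarts from different optimizer seeds;
bounds default to α ∈ [0, 2], L_min ∈ [0, 200] bp, a ∈ (0, 0.2] per bp,
b ∈ (0, 1). Out-of-bounds candidates are clipped. Paths are truncated once
every second-shortest telomere has reached 0, at which point every rule
with L_min ≥ 0 has triggered; untriggered paths (impossible under the
defaults) would be censored at the horizon.

Because a and b partially trade off along a ridge of nearly identical
arrest-time distributions, recovery of the probabilistic fit is scored on
the induced ordered first-arrest distribution (mean absolute rank-wise
difference, i.e. an empirical Wasserstein-1 distance, required below 2
generations) rather than on the raw parameters; the deterministic fit is
scored on L_min at known α = 0, within about two shortening steps.
Censored experimental lineages (no observed non-terminal arrest) do not
enter Ḡ: the objective compares observed arrest generations only.

## Arrest-run statistics

Gaps count individual long cycles: two consecutive long cycles are two
arrests at gap 1 (juxtaposed). Run-length inventories take every
non-terminal run across lineages (runs of lineages that later die count;
only their terminal run is excluded) and the terminal run per died
lineage. The per-generation run-ending probability q (repair for
non-terminal runs, death for terminal) is the geometric MLE of the run
lengths, tested by the chi-square machinery above with one fitted
parameter. Duration comparisons split each run into its final long cycle
("last") versus all earlier ones ("preceding"); medians are computed on
the raw 10-min grid and compared by a two-sided Mann-Whitney U test —
exact enumeration for tie-free combined samples of at most 25, otherwise
the tie-corrected normal approximation without continuity correction (so
identical samples give p = 1 exactly).

## Synthetic-data generator

The generator composes the mechanisms above into full datasets; its
defaults are the study conditions and are not tuned per analysis:
187 negative and 31 positive lineages; normal cycles N(90, 30) min
(so mean + 3 SD = 180); non-terminal arrest cycles 180 + lognormal
(median 250 total); terminal preceding/final cycles 180 + lognormal with
medians 290/730; repair probability 0.65 per generation; probabilistic
first-arrest threshold (a = 0.023, b = 0.276); deterministic senescence
threshold at L_min = 19 bp (the senescence-onset value reported for this
telomere model in prior work, smaller than the first-arrest threshold);
terminal run-ending probability 0.58; 10% of died lineages re-truncated
as censored; all durations rounded to the 10-min grid.

Two generator-specific mechanisms deserve note. First, on repair the
signalling (shortest) telomere is re-elongated by 100 bp — the data the
analyses see carry no information about post-repair telomere state, so
this is the simplest rule that lets lineages resume normal divisions and
arrest again later; a refractory-period alternative (no re-trigger for 5
generations) is available behind a flag, and is also the configuration
under which "repair probability 1 ⇒ all runs have length 1" holds exactly,
since under the elongation rule two juxtaposed episodes merge into one
observed run. Second, when the shortest telomere falls below 30 bp but has
not yet reached the senescence threshold, the cell enters a committed
pre-senescent slowdown: cycles lengthen to ~215 min and transient episodes
no longer trigger. At D = 180 these slowdown cycles attach to the terminal
run, making its length a hitting-time count rather than a geometric draw —
which is what produces the qualitative contrast between the two run-length
laws; at higher D they drop below threshold and the terminal count reverts
towards geometric. Real lineages need not share this particular mechanism;
what the generator guarantees is the statistical signature the analyses
test, not the biology underneath.

What passing tests on generator output do show: the pipeline correctly
distinguishes generation-dependent from constant hazards at n ≈ 115–150,
recovers the repair probability within ±0.1 at that scale, recovers
threshold parameters up to their intrinsic confounding, and reproduces the
two-regime contrast. What they do not show: anything about features of
real data the generator omits — measurement noise beyond grid rounding,
within-lineage dependence between successive episodes beyond telomere
length (e.g. an arrest raising the probability of the next one),
cross-lineage heterogeneity in shortening rate, or post-senescence
survivors, which are out of scope throughout.

## Problem sizes and numerical choices

The test suite and analysis scripts use simulation sizes chosen to keep
statistical power adequate at interactive runtimes: N = 100 simulation
replicates for threshold fits (N = 1000 remains the default of
`FitObjectiveConfig` for final analyses), 200 replicates for
parameter-recovery studies, 1000 replicates for type-I-error calibration,
and 5 dataset replicates for majority-vote regime checks. Simulation
horizons are capped at 1000 generations with censored draws flagged.
Random number use is explicit everywhere (numpy Generators); fits with
common random numbers are bit-reproducible given a seed.

## Known limitations

* The logistic-hazard weighted-LS fit extrapolates beyond the observed
  hazard range when computing the pmf for goodness of fit; with few
  late-generation at-risk lineages the midpoint/scale pair is only weakly
  identified (the fitted curve, not the parameters, is the stable object).
* The chi-square binning convention (right-tail merging, df reduced by
  fitted parameters, minimum expected count 5) is one of several
  reasonable conventions; p-value sweeps over D can shift slightly under
  others.
* Fitted L_min and (a, b) values are relative to the configured shortening
  rate and initial-length distribution.
* The population-level first-arrest hazard of telomere-driven lineages is
  flattened by frailty (short-telomere lineages arrest first and leave the
  risk set), so the logistic family is an approximation that can be
  rejected at large n even when the mechanism is telomere-driven.
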