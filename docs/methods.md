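# Methods

## The model

In a visual-search display a target bar that is unique in color (C),
orientation (O), motion direction (M), or redundantly in two of these
features (CO, MO, CM) pops out because some population of early visual
neurons responds to it more strongly than to the uniform background. Under
the highest-response-wins reading of bottom-up saliency, the neuron type
with the strongest evoked response dictates how fast attention (and hence
the manual response) arrives. Each candidate neuron type is treated as a
*racer* whose would-be reaction time (RT) is a random draw from its own
distribution; the observed RT for a double-feature target is the minimum
over the racers that respond to it — the two single-feature types and, if
it exists, a conjunctively tuned type. Racers draw independently.

All computation happens on a discrete per-subject time grid. A racer is a
probability vector `p` over `N` bins; its survivor function is
`S(i) = Σ_{j≥i} p_j`. The winner (minimum) of racers `k = 1..K` lands in
bin `i` with probability

    q_i = Π_k S_k(i) − Π_k S_k(i+1),        S_k(N+1) ≡ 0.

The *contribution* of racer `k` is its probability of winning the race,
`c_k = P(T_k ≤ T_j ∀j)`. Because bins are finite, two or three racers can
tie for the winning bin; every joint winner receives full credit by
default, so `c_first + c_second + c_conj ≥ 1`, with the excess equal to the
tie mass (counted once per extra winner). A `tie_credit="fractional"`
option splits ties evenly instead (contributions then sum to exactly 1);
it is not the default because the full-credit convention is the one the
summed-excess diagnostics assume.

## Data cleaning

Per subject and condition, incorrect-response trials are dropped; among the
correct trials the mean `m` and sample (n−1) SD `s` are computed **once**,
and trials with `rt < 0.2 s` or `rt > m + 3s` are removed. The rule is
deliberately single-pass — iterative trimming would change the retained
set — and one-sided at the top, since only implausibly long RTs are
trimmed. Boundary-equal values are retained (strict inequalities).
Thresholds never mix conditions.

## Binning

RTs of all six conditions of a subject are pooled and split into `N` bins:
`t_0 = min(RT) − 0.0001 s`, `t_{N−1} = max(RT) + 0.0001 s`, `t_N = ∞`, with
interior boundaries midway between consecutive order statistics so the
first `N−1` bins hold equal pooled counts to within one sample. Bins are
half-open `(t_{i−1}, t_i]`. The terminal *reservoir* bin contains no
observed RT; it exists so a conjunctive racer can park probability mass on
RTs long enough to never win — mass the behavioral data cannot constrain.
Default `N = 10`, the center of the 7–13 range over which results are
robust (the fitted races then tie in roughly the 10–20% range).

## Fitting

The six racer distributions are estimated jointly by minimizing the
multinomial negative log likelihood: single-feature counts against their
racer's distribution directly, double-feature counts against the
three-racer winner distribution. The single racers are shared across
races (P_C appears in the CO and CM races), so the fit is genuinely joint.
One attribution assumption is built in: conjunctive racers never dictate
single-feature RTs, so the recovered conjunctive contribution is the
*additional* contribution beyond any share silently absorbed into the
single racers; reports should be read accordingly.

Optimization is SLSQP with analytic gradients, explicit simplex equality
constraints and [0,1] bounds — not a softmax reparameterization, so
boundary solutions (conjunctive mass exactly in the reservoir) are
reachable. Model probabilities are floored at `ε = 1e−12` inside logs.
Defaults: 5 restarts (the first from smoothed empirical singles + uniform
conjunctives, the rest Dirichlet-jittered), `ftol = 1e−9`, 2000 iterations.
SLSQP often exits with a "positive directional derivative" status at the
optimum, so convergence is declared when either scipy reports success or
independent restarts agree in NLL to 1e−6 relative. A fit never reports a
worse NLL than its starting point (it falls back to the start otherwise).

## Consistency diagnostics

After fitting, the model-implied winner distribution of each double
condition is compared with the observed histogram via
`k = KL(empirical‖model) / H(empirical)` (natural log; the ratio is
base-invariant), with `0·log 0 = 0` and the model floored at ε; the same
index applies to single conditions against their fitted racer. `k = 0` iff
the distributions coincide; values above a warn-only threshold of 0.1 are
flagged. On well-specified synthetic data at 320 trials/condition the
median post-fit `k` is well below 0.05.

## Bootstrap

Uncertainty comes from a percentile bootstrap (default 500 replicates,
2.5/97.5 percentiles). Each condition's empirical CDF is interpolated
piecewise-linearly through the sorted sample — knot `k` at height
`(k − 0.5)/n`, anchored at 0 and 1 at 0.0001 s outside the sample range —
and new samples of the original size are drawn by inverse-CDF sampling.
The full pipeline (grid, fit, contributions) reruns per replicate,
warm-started from the point fit with a single restart for tractability.
Because every replicate rebuilds its own grid, per-bin coverage of the
true probabilities runs somewhat below nominal (≈0.8 at the 95% level in
our checks) — the intervals describe the pipeline's total variability, not
fixed-grid multinomial noise alone.

## Chance level and significance

A fitted conjunctive contribution is positive even when none exists,
because the fit absorbs sampling noise. The chance level is estimated by
simulation under the two-racer null: the double condition's counts are
replaced by simulated winner counts of the two fitted single racers (same
trial count), the model is refitted, and the conjunctive contribution
recomputed; over 1000 evaluations the observed value is *significant* if
it strictly exceeds the 95th percentile. The default refit scope
(`race_only`) refits the three racers of the affected race against that
race's three conditions, warm-started from the original fit; each
evaluation also tries a start with the conjunctive racer reset to the
reservoir (the null-consistent configuration), keeping whichever ends at
the lower NLL — a warm start alone can stay stuck at a strong observed
conjunctive mass. A `full` scope refits all six distributions.

**Known limitation (measured, and retained deliberately).** The recovered
null contribution has two noise sources: multinomial noise in the double
sample, and estimation error in the single racers. The conventional null
simulation draws the winner counts *from the fitted singles themselves*,
so its chance distribution reproduces only the first source. On 100
simulated null subjects the convention gives a mean chance level of
≈0.05–0.08 (matching the historical "typically around 0.05") but fires
the 95% criterion for roughly half of the null subjects. The
`null_resample="parametric"` option also redraws the single conditions'
counts from their fitted distributions each evaluation (a parametric
two-racer bootstrap); it restores the nominal ≈5–10% false-positive rate,
at the cost of a mean chance level of ≈0.11 that no longer matches the
historical figure. The double-only convention remains the default for
comparability; significance flags from it should be read as
anticonservative, and the parametric option is recommended when a
calibrated test is the goal.

## Synthetic data generator

The generator emulates the study conditions the analysis was designed for:
8 subjects × 6 conditions × 320 trials. Single racers are truncated
normals with location 600 ms and scale 118 ms (floor 0.2 s, redraw below);
the scale is a calibration, not a reported value — the mean of the minimum
of three i.i.d. normals is `μ − 0.8463σ`, so matched CO and MO conjunctive
racers give double-target means near 500 ms, reproducing the reported
600/500 ms pattern. No CM racer exists by default (V1 lacks color-motion
conjunctive cells), making CM a pure two-racer race. Button-press errors
(3%) and long outlier RTs (2%, +1.5–3 s so they clear the 3-SD cut even
after inflating it) give the cleaning rules realistic work and keep
exclusions under the reported 9.2% ceiling. An ex-Gaussian family is
available for skewed RTs, and an `empirical_table` family for resampling
fixed values. A `latent_response` family generates RTs as a monotone
decreasing map `f(r) = offset + scale/r` of a normal latent response `r` —
off by default, since the analysis is invariant to the map (only the
ordering of racer draws matters); it exists to make that invariance
testable. A continuous-limit oracle (`true_contributions`) estimates
each racer's win probability by Monte Carlo with ties of measure zero; the
grid-level oracle (`discretized_truth`) bins the racers' exact
distributions on a given grid and applies the exact race algebra —
including the finite-bin tie excess — which is the right reference for
what a perfect fit could recover at that resolution.

What the generator does **not** emulate: correlated racers, sequential
effects across trials, subject heterogeneity (subjects are i.i.d.
replicates), lapses that produce fast guesses, or any stimulus-level
structure. Passing tests therefore certify the inference machinery under
the model's own assumptions, not the assumptions themselves.

## Problem sizes used in the shipped checks

The automated checks scale some Monte-Carlo sizes to keep a full run quick
while leaving conclusions unchanged: recovery uses 20 seeds at 320
trials/condition (5 at 5000), the null-calibration check uses 100
simulated subjects with 80 chance evaluations each, the bootstrap coverage
check uses 150 replicates, and the chance-level reproduction in
`scripts/acceptance.py` uses the full 1000 evaluations.
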