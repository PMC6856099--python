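# Methods

This note documents the models, statistics, and numerical choices behind
`infoseek`, and what the synthetic-data generators do and do not emulate.

## Data model

A *session* holds every trial recorded from one neuron in one task.  Each
trial is aligned so that CS (conditioned-stimulus) onset is time 0; event and
spike times are in seconds, gaze (x, y, blink) and lick strain are sampled at
1 kHz, and all analysis windows are half-open `[t_start, t_end)` so that no
sample or spike is ever counted twice at a window boundary.  Sessions
round-trip losslessly through plain-text bundles (a JSON metadata record plus
tidy TSV tables) written with 17-significant-digit floats, so writing is
byte-stable and bundles are language-agnostic.

Two task families are covered.  In the **standard uncertainty task**, five
CSs predict reward with 0/25/50/75/100% probability and are displayed for
2.5 s, with the outcome at CS offset.  In the **information task**, Info or
Noinfo CSs at 0/50/100% reward probability (1 s) are followed by a cue (2 s)
and the outcome at 3 s; informative cues reveal the outcome, noninformative
cues do not.  Conditions are combinations of CS and cue (seven in the
information task).

## Uncertainty signals and anticipation indexes

The central statistic is the ROC area `U` for discriminating firing on
uncertain-reward trials (0 < p < 1) from certain trials, computed as the
Mann-Whitney U statistic divided by `n1*n2` with ties counting one half.
Neurons are included as uncertainty-coding if (standard tasks) rates in
[0.1, 2.5) s differ from both the 0% and 100% conditions with the same sign
(rank-sum tests, p < 0.05), or (information tasks) the Noinfo pre-outcome
0.5 s window discriminates certain from uncertain reward.  The sign of
uncertainty coding `S` is +1/-1 by whether the uncertain-vs-certain ROC
exceeds 0.5, and signals from both signs pool through
`U_N = 0.5 + (U - 0.5) S`.

Single-trial activity is normalized by smoothing with a causal exponential
kernel (mean 30 ms, unit integral, so output stays in spikes/s), z-scoring
against the moments of the concatenated per-condition average time courses,
and multiplying by `S`.  Windowed statistics always use raw window spike
counts; smoothed traces are used only where a per-millisecond quantity is
needed (latency detection, display).

The **Informative Cue Anticipation Index** is the Info-minus-Noinfo
normalized uncertainty signal in the 0.5 s pre-cue window; the **Uncertain
Outcome Anticipation Index** is the growth of the Noinfo signal from the
post-cue window ([0.15, 0.65) s after cue onset) to the 0.5 s pre-outcome
window.  Significance is by permutation: the cue index shuffles Info/Noinfo
labels *within each reward-probability level* (the exchangeable null that
preserves the trial counts entering each ROC); the outcome index swaps each
Noinfo trial's pair of window values independently.  P-values are
`(1 + #extreme) / (n_perms + 1)`, two-tailed, so they are exact under
exchangeability at any permutation count; the default is 20,000 but tests of
calibration use 200-1,000 since only the distribution's shape matters.
Behavioral versions of both indexes replace the firing rate with the binary
gaze-on-stimulus flag at the last millisecond of each window, with S = +1.

## Latency of uncertainty coding

Normalized activity is further smoothed with a causal 101 ms boxcar (partial
means at the trace start, so no startup bias), and every millisecond from
50 ms post-CS is tested for uncertain-vs-0% and uncertain-vs-100%
discrimination at p < 0.005 with a common sign.  Per-millisecond p-values use
the normal approximation to Mann-Whitney with tie and continuity correction
(an exact test at every millisecond would be prohibitively slow and changes
nothing at the trial counts involved).  The latency is the first millisecond
where the criteria hold for >= 24 consecutive ms; information-task sessions
take the shorter of the Info and Noinfo latencies, and variants without a 0%
condition drop that criterion.  Because every kernel is causal, a detected
latency can trail but never precede the true change point; with the 30 ms
exponential plus 101 ms boxcar the expected detection delay at high SNR is
roughly 20-40 ms.  Area latencies trim the shortest `ceil(1% of n)`
single-neuron latencies before taking the minimum and are compared by
permuting neuron-to-area assignments.

## Gaze events

Gaze is "on the stimulus" within a 3-degree circular window whose center is
recalibrated per session and CS location as the argmax of a 2-D histogram of
eye positions (0.25-degree bins, Gaussian blur SD 0.5 degrees -- finer than
the window radius and robust to fixational jitter) built from reward-CS
trials between 0.2 s post CS onset and 0.1 s post CS offset.  Blink samples
carry the last gaze state, so blinks never fabricate transitions; separately,
shifts with a blink in the preceding 100 ms are discarded.

A gaze shift off the stimulus at millisecond t requires >= 150 ms of stable
on-state before t, >= 100 ms of stable off-state from t, and gaze at least
5 degrees from the window center 100 ms later; onto-shifts mirror these
criteria and are reported at t - 40 ms, approximating saccade start rather
than window entry.  Controls for a shift are same-condition time points from
other trials with the same prior 150 ms gaze state that stayed in-state for
>= 100 ms; they are selected greedily to balance the gaze-to-stimulus
distance 50 ms before the event (first the smallest |difference|, then
repeatedly the smallest-magnitude candidate whose sign opposes the running
mean).  The balancing keeps the across-event mean difference near zero; the
per-event mean is not strictly bounded by the first pick, which is why the
package asserts the population property rather than a per-event one.  The
-40 ms onto-shift correction is also applied to the control time grid, so
events and controls sample identical trial times.  Distance at -50 ms is
linearly interpolated across blink gaps up to 20 ms; longer gaps drop the
candidate or event.  Shift-aligned activity is always the event's normalized
activity minus the mean over its own controls, averaged per neuron and then
across neurons, with statistics in the [-0.4, -0.1), [-0.1, +0.1), and
[+0.1, +0.4) s windows and trials grouped by the *current knowledge state*
(certain-no-reward / uncertain / certain-reward; an informative cue updates
the state at cue onset).

Licks are detected by low-pass filtering the absolute strain signal
(causal eighth-order Butterworth, 10 Hz cutoff, steady-state initial
conditions so there is no onset transient) and thresholding at the mean plus
two SDs of the pooled filtered baseline samples (first 0.4 s of each correct
trial).  Pooling the per-millisecond baseline samples, rather than per-trial
baseline means, makes the threshold a genuine two-sigma point of the
filtered noise distribution (about 2% of noise samples flagged); on real,
slowly drifting strain signals the two choices converge because inter-trial
drift dominates the baseline variance.

## The gaze-modulation model

Firing is modeled as

    Rate(tr, t) = beta(c, t) * (1 + GazeMod(tr, t) * w_gain)
                  + GazeMod(tr, t) * w_offset + eps

where `beta(c, t)` is the gaze-off response profile (one parameter per
condition and 50 ms bin spanning 0.2 s post-CS to 0.1 s post-outcome),
`GazeMod` is the binary gaze trace convolved with a Gaussian kernel
(mean mu in [-1, 1] s, SD sigma in [0, 1] s, truncated at +/-4 sigma and
renormalized) and averaged within each bin, and eps is homoscedastic
Gaussian noise.  Positive mu means neural modulation *leads* the gaze change
("neurons first"); around an isolated onto-shift the modulation time course
is the cumulative Gaussian `Phi((t + mu) / sigma)`, and the modulation
latency is its 10%-of-maximum point, `Phi^-1(0.1) * sigma - mu` in closed
form.

Because the likelihood is Gaussian, `beta` and the noise variance maximize
in closed form given `(mu, sigma, w_gain, w_offset)` (per-condition-bin
weighted least squares and the residual variance).  Profiling them out
reduces the fit to a bounded 4-parameter nonlinear least-squares problem
solved with the Trust Region Reflective algorithm from the initial point
`(mu, sigma, w_gain, w_offset) = (0, 0.1, 0, 0)`, capped at 100 function
evaluations; finite-difference gradients are used, which the evaluation
budget easily absorbs in four dimensions.  Inside the fitter the gaze trace
is down-sampled to 10 ms resolution before convolution -- the model only ever
consumes 50 ms bin means of GazeMod, which change negligibly below the
kernel's scale -- making a fit roughly 20x faster at identical recovered
parameters.  A fit is never reported worse than the initial parameters (the
profiled likelihood at the start point is a floor).

Significance is a one-tailed permutation test: gaze traces are shuffled
among trials that share a condition and the model refitted (warm-started at
the true-fit parameters, which cannot bias the test direction since
shuffling cannot improve the expected fit); a neuron is significantly
gaze-modulated when its true log likelihood exceeds at least a 191/200
fraction of the permuted fits (p <= 0.05).  Multi-task neurons sum log
likelihoods over tasks and average the gain, time course, and latency.

The model is fitted on firing rates (spikes/s), not normalized activity, so
`w_offset` has rate units and `w_gain` is dimensionless; the reported
`gain_log2` (log2 of 1 + w_gain) is 0 for no change and +1/-1 for a
doubled/halved response.

## Inactivation statistics

The Infobias Index `(Noinfo RT - Info RT) / (Noinfo RT + Info RT)` is
computed per session and per 2x2 epoch-by-laterality cell from mean reaction
times of trials whose offline and online RT records agree within 0.2 s.
Inactivation effects are the post-minus-pre change, tested by reassigning
each session's trials between epochs (preserving counts) -- the finest
reading of shuffling pre- with post-injection data -- with a two-tailed
`(1 + #extreme)/(n + 1)` p-value.  The default is 100,000 permutations
rather than the hundreds of millions a compute cluster could afford; the
p-value resolution (1e-5) is far below any threshold applied to it.  An
optional animal weighting averages per-animal mean changes with weights
equal to the number of inactivation sessions each animal contributed.

Normalized-RT analyses z-score RTs within each session and CS laterality
(pooled across epochs and CS types), then test pre-vs-post per CS type
(rank-sum) and the CS-type-by-epoch interaction with a fixed-effects two-way
ANOVA using type-II sums of squares (cells are mildly unbalanced and no
interaction-driven imbalance is expected).  Between-area contrasts compare
each area's overall RT change, the *hypothesized* component (icbDS slowing
Info RTs combined with Pal speeding Noinfo RTs), and the *orthogonal*
component, with the same within-session epoch-shuffle permutation null;
all three are tested two-tailed.

## The circuit model

The five-unit rate model is a feed-forward affine map: ACC = 2 + 20*I,
icbDS = ACC, Pal = 50 - 2*icbDS, Visual = 100*S, Gaze = Visual - Pal + eps,
with eps ~ N(0, 30) on the Gaze unit only and I/S the binary Info-CS and
contralateral-stimulus indicators.  Ipsilateral trials use S = 0, so Gaze is
driven only by Pal (the model describes one hemisphere).  Inactivation
multiplies the target area's rate by 0.7 (a 30% reduction) before it
propagates.  With zero noise the Gaze rates are 94 (Info, contra), 54
(Noinfo, contra), 80.8 (Info with icbDS scaled), and 62.8 (Noinfo with Pal
scaled) -- the signatures of the double dissociation.  Gaze rates become RTs
by rank-matching against a reference RT pool (Kth highest rate gets the Kth
fastest RT, stable ties): the output is always a permutation of the pool, so
inactivation reshapes which conditions are fast, never the marginal RT
distribution.  Because the real control-session RT pool is not distributed
with the package, virtual experiments default to a log-normal pool (median
0.25 s, log-SD 0.3), matching the scale and skew of primate saccadic RTs in
this task class; the pool is pluggable.

## Synthetic data: what it does and does not emulate

Generators expand one global seed into per-trial substreams via
`SeedSequence` spawn keys, so adding trials never reshuffles existing ones.
Spikes are inhomogeneous-Poisson draws (per-millisecond thinning) from the
gaze-modulation rate equation, clipped at 0 spikes/s; recovery tests stay
out of the clipped regime.  Default tuning gives an inverted-U over reward
probability (peaks 2/10/16/10/2 spikes/s ramping from a 2 spikes/s baseline
to the outcome) for the standard task; information-task "hypothesis 1"
neurons ramp to the informative cue on Info trials and to the outcome on
Noinfo trials (base 2, peak 20 spikes/s), while "hypothesis 2" profiles are
identical across Info/Noinfo during the CS and "hypothesis 0" is flat (the
exchangeable null used for calibration).

Gaze is a two-state Markov chain in position space: "on" samples jitter
(SD 0.5 degrees, clipped inside the 3-degree window) around the CS center,
"off" samples jitter around a point 10 degrees away; baseline hazards
(0.002/ms onto, 0.0015/ms off) give bout lengths of a few hundred
milliseconds and roughly balanced occupancy.  The uncertainty-attracted
variant ramps the onto-hazard exponentially (x8) over the epoch ending at
the next informative event and ramps the off-hazard (x6) for stimuli known
to predict no reward, reproducing the observed structure: gaze-on
probability near 0.9 just before information arrives on uncertain trials,
value-ordered occupancy elsewhere, and avoidance of no-reward cues.  Blinks
are Poisson events (0.2/s, mean 80 ms).

Not emulated: saccade kinematics (position jumps instantaneously between
states), microsaccades, pupil dynamics, inter-animal RT differences (the RT
pool shape is a single log-normal), drift or nonstationarity in firing,
and spike-sorting artifacts.  Passing tests therefore demonstrate that the
*analysis chain* is correct and calibrated under the assumed statistical
structure, not that real recordings satisfy that structure.

## Problem sizes and tolerances

Tests and the acceptance script run the pipeline at desk scale: tens of
neurons, tens of trials per condition, hundreds to thousands of
permutations.  These sizes were chosen so every statistical property under
test (calibration, power, recovery bands) is already stable at that scale;
all analysis defaults remain at their full values.  Numerical tie-breaking
is stable and documented where order matters (rank-matching RTs, control
selection); degenerate inputs (constant neurons, zero-variance RT cells,
missing conditions, empty ROC samples) raise validation errors rather than
producing silent NaNs, except where the quantity is naturally undefined and
reported as missing (empty Infobias cells, undetected latencies).
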