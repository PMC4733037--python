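# Methods

This note documents the models and procedures `unblk` implements, the
defaults it ships with and why, and what its synthetic sessions do and do
not establish about real recordings.

## Task and session model

A session is a sequence of non-overlapping trials on a common clock.
Each trial runs house light → odor-port entry → odor onset → (on compound
trials) novel-odor onset 200 ms later → odor offset at 1 s → reward-well
entry → reward → well exit. Timestamps are seconds, stored at 0.1 ms
resolution; intervals are half-open `[start, end)` everywhere, so a spike
exactly on a boundary belongs to the later bin. Restarted/aborted trials
are retained in files with `completed=false` and excluded from all
firing-rate analyses; the per-odor trial counts refer to completed trials.
Two task variants share all analysis code: the blocking variant (novel
odors follow a 200 ms presentation of the pre-trained odor) and a control
variant (each cue presented alone after 200 ms of clean air); epochs are
data (`EpochDefinition`), not code, so the variant only changes
definitions.

## Epoch statistics

* ITI baseline: the 2 s preceding house-light onset.
* Novel-odor epoch: 300–1300 ms after initial odor onset (default).
  A second convention — the 1 s following novel-odor onset, i.e.
  200–1200 ms after initial onset — appears in the literature for the same
  analysis; both are provided (`NOVEL_ODOR_EPOCH`, `NOVEL_ODOR_EPOCH_ALT`)
  and the choice is a config parameter. Which convention produced any
  particular published screen is not decidable; the two differ by a 100 ms
  shift of a 1 s window.
* Normalized firing = epoch rate − same-trial ITI rate (Hz, may be
  negative).
* Odor-period analyses drop the first 7 trials of a session
  (`min_trial = 8`), except trial-resolved heat maps and trial-resolved
  decoding, which exist precisely to look at early trials.
* Moving averages (4-bin on 50 ms rate bins, 3-bin on 100 ms decoding
  bins, 3-window on trial curves) are trailing, and shorten the series by
  k−1 rather than padding edges with invented values.

## Unit screens and taxonomy

Units with mean ITI rate ≥ 10 Hz are ineligible (putative non-single-unit
or fast-spiking activity; the taxonomy is defined for low-rate cells).
For each of the four odors, trialwise epoch rates are compared with the
same trials' ITI rates by a Welch two-sample t-test, one-tailed for an
*increase*, at α = 0.01 per test with no multiple-comparison correction.
The screen is directional because it is defined as a screen for excitatory
phasic responses; a two-sided variant (requiring p < α and an upward mean
difference) and a trial-paired variant are config switches. Welch rather
than pooled variance because the 2 s ITI and 1 s epoch windows have
unequal count variance by construction.

Value coding = (≥1 odor excitatory) AND (upshift > blocked, p < α) AND
(downshift < blocked, p < α), pairwise one-tailed Welch tests on epoch
rates between trial types. Categories are then assigned in a fixed
decision order: nonresponsive → sensory-excluded (all four odors
significant, not value-coding) → value → initial-only → single-novel-cue
tuned → predictive (upshift + downshift, not blocked) → salience (all
three novel cues, not initial) → other-mixed. Tuned/predictive/salience
categories require the initial odor to be non-significant; units driven by
the initial odor plus a subset of novel cues land in `other_mixed`.
The sizes of the three tuned subpopulations are compared with a
uniform-expectation chi-squared (df = 2); on counts (19, 16, 16) this
gives χ² = 0.353, p = 0.84.

## Heat maps and significance maps

For a given trial type, firing is measured in 150 ms windows stepped by
50 ms away from novel-odor onset, per trial (first N trials, default 10).
Each map cell is the across-unit mean of window rate minus same-trial ITI
rate; a mode normalizing to the initially trained cue (subtracting the
unit's same-window mean over initial-odor trials) is provided.
Significance per cell is a one-tailed one-sample t-test across units
against zero; α is a parameter (0.01 and 0.001 are both conventional).
Zero-variance cells are degenerate for a t-test and are reported
significant iff their mean is positive, with a warning. With ~150 ms
windows and few-Hz baselines the per-cell power at 2 Hz modulation is
modest by construction; maps are read for their pattern, not cell-wise.

## Pseudo-ensemble decoding

Units recorded in different sessions are combined by aligning trials of
the same type by within-type index (preserving learning stage; random
pairing is available as an ablation) and truncating all (unit, type)
pairs to a common trial count. Features are per-unit firing rates in
100 ms bins spanning −0.2 to +1.2 s around novel-odor onset.

The classifier is a linear discriminant with Ledoit–Wolf shrinkage toward
a scaled identity (suited to more features than samples); multinomial
logistic regression is a config switch. Cross-validation is
leave-one-trial-index-out: each fold holds out one pseudo-trial of every
class. This keeps training folds class-balanced, which matters: plain
leave-one-out is biased *below* chance under the null (the held-out class
is always under-represented in training), and would violate the exact
binomial chance band the package promises. If a training fold has zero
within-class variance (noiseless synthetic classes), prediction falls back
to the nearest class mean, which is the LDA limit.

Chance is 1/4 (four trial types decoded). Significance is the exact
binomial upper tail. For time-resolved decoding, every 100 ms bin of a
held-out pseudo-trial inside the stated accuracy window (400 ms after
novel-odor onset for unselected ensembles, 500 ms for tuned cells) is
scored as its own prediction, so n_eff = n_trials × n_window_bins; this
bin-as-trial augmentation offsets low trial counts and is capped at that
product. Disjoint Poisson bins make these predictions approximately
independent, so the binomial reference is calibrated (verified against
the null ensemble). Trial-resolved decoding (sliding windows of 10
trials, step 1) scores one prediction per pseudo-trial from the
window-mean rates and uses n_eff = 4 × window only — augmenting there
would let within-trial correlations inflate the test. The learning trend
is summarized as the Spearman rank correlation of window position with
the 3-window-smoothed accuracy curve.

## Behavior

Latency = well entry − odor offset; time in well = well exit − well entry
(cumulative until exit). The probe-test ANOVA is two-way (odor × trial
1–10, with interaction) on the unrewarded extinction trials, pooling
trials across rats and rounds as replicates — that is the convention the
printed degrees of freedom of this design imply; a per-rat-round
aggregation mode is available because trial-level pooling inflates the
error df. When a design has no within-cell replicates the interaction is
dropped rather than fit with zero residual df. Planned comparisons
(upshift vs blocked in the first four-trial block; downshift vs blocked
over all trials) are paired t-tests on per-rat-round means. Training
latencies are analyzed with trial (1–30) × day factors. Constant data
yield F = 0, not NaN.

## Synthetic generator

The generator's defaults *are* the study conditions and are not
re-tuned per analysis:

| parameter | default | rationale |
|---|---|---|
| trials per novel odor per day | 30 | middle of the 20–40 design range |
| reminder trials per day | 30 | comparable sampling of the trained cue |
| probe: reminders / extinction trials | 10 / 10 per cue | probe design |
| ITI | uniform 4–8 s | unstated in the task description; only the 2 s pre-light window is analyzed |
| baseline rates | lognormal, median 3 Hz, σ = 0.3 | low-rate population, "mostly < 10 Hz"; narrow enough that a 2 Hz response is detectable at α = 0.01, as the reported populations imply |
| cue modulation | 2 Hz at asymptote | the reported tuned-cell effect size (~2 spikes/s over baseline) |
| value-cell profile | +0/+2/+4 Hz on downshift/blocked/upshift | monotone value code with the tuned-cell step size |
| response window | cue onset + 100 ms, 1.2 s duration | short sensory latency; response outlasts the 1 s cue slightly, so the analysis epoch sees the full modulation |
| learning curve | logistic in cumulative novel-cue trials, midpoint 82, slope 0.10/trial | see below |
| aborted-trial rate | 2% | exercises the incomplete-trial path |
| probe time-in-well means | 2.6 / 1.6 / 0.9 s (upshift/blocked/downshift), decaying 12%/trial toward 0.4 s, noise SD 0.45 s | reproduces the expected first-block ordering and an extinction trial effect |
| latency | lognormal (median 0.35 s, σ = 0.25) + novelty term 0.9 s (day 1) / 0.35 s (day 2) decaying over ~3 trials | novel odors slow responding, most on the very first trials of day 1 |

Spikes are sampled by thinning a piecewise-constant rate (baseline plus
per-trial cue modulation); the contract is the rate function, not the
algorithm. Sensory and initial-odor profiles respond from trial 1;
associative profiles scale with the learning factor. Day 2 continues day
1's cumulative trial count; each round of a study gets fresh units (the
electrode is advanced between days and rounds, so units are treated as
new) with unique ids.

The learning midpoint/slope were fixed once to satisfy four qualitative
constraints simultaneously: the first trial of day 1 is ≤ 10% of
asymptote; day 2 is near asymptote from the 8th trial (so day-2 analyses
see ~2 Hz modulation); day-1 trial-window decoding stays below the
binomial significance threshold; and day-1 accuracy nevertheless drifts
upward, so its rank correlation with window position is positive. These
four constraints pin the curve to a narrow region — steeper or later
curves leave day 1 with no measurable trend, earlier ones make day-1
windows significant.

What the generator does **not** emulate: correlated variability between
units, refractoriness (beyond the 0.1 ms resolution floor), latency-to-
peak heterogeneity (available as an optional per-unit onset jitter,
default off), reward-period firing, drift or unit loss within a session,
and any coupling between spiking and behavior (latency is independent of
firing by construction, which is what makes the latency-correlation null
calibration meaningful). Passing tests on these sessions show the
*analysis* is correct and calibrated under the stated statistical
structure; they do not show that real lOFC data satisfy that structure.

## Numerical and reproducibility choices

* Timestamps quantized to 0.1 ms; files store full float repr, so
  read(write(s)) == s exactly.
* All randomness flows from `numpy` Generators seeded via
  `SeedSequence([seed, round, day])`; a pipeline master seed therefore
  reproduces every stage bit-exactly, and partial re-runs are
  reproducible.
* Default problem sizes (20 recovery seeds, 10 learning-dynamics seeds,
  2000 calibration units, 100 label shuffles, 8 behavioral rounds) keep
  the full verification run at a few minutes on one CPU while leaving
  Monte-Carlo error well inside the asserted margins.

## Known limitations

* The bin-as-trial augmentation rule for the binomial test is one of
  several defensible readings of the original analysis; it is explicit
  and configurable here, and published accuracy curves should be treated
  as qualitative, not numeric, references.
* Category recovery rates depend on the generator's noise parameters;
  the reported ≥ 70–90% diagonals are properties of these study
  conditions, not of the screen in general — at broader baseline
  distributions the multi-cue categories (salience, sensory) lose power
  fastest, since they require three or four simultaneous detections.
* The value category is small by construction (5 units per study, the
  reported proportion); its recovery rate (~0.6, a conjunction of three
  directional tests) is reported but not part of the recovery surface.
* Real-data quantities (unit counts, behavioral F values, the published
  day-1 trend coefficient) require the original recordings and are out of
  scope; the pipeline reproduces their *patterns* on synthetic data.
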