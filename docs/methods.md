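# Methods

`remapflow` analyses hippocampal CA1 context coding in an octagonal
two-context task: calcium event trains and head/body tracking go in;
place-cell classifications, between-context remapping measures, place-field
rate statistics, egocentric directional-tuning classifications, context
decoding accuracies, and behavioral error taxonomies come out.  A
synthetic-session generator with planted ground truth provides the test bed.

## Clocks, tracking, and analysis frames

All analysis runs on a single master clock at 20 Hz (the imaging clock).
Real tracking acquired at a different camera rate must be resampled to this
clock before loading; the synthetic generator produces data directly at
20 Hz.  Speed is computed from the body position smoothed with a 167-ms
moving average — three frames at 20 Hz, the nearest odd window — as
displacement x frame rate, with the last sample replicated to preserve
length.  All spatial and directional analyses use the head position.

Each trial contributes a *foraging segment*: from the first frame with
speed > 2 cm/s after trial start to the trigger (tone) frame.  Spatial and
directional analyses keep only running frames (speed > 2 cm/s) of these
segments; decoding keeps resting foraging frames too.  Inter-trial-interval
and reward-retrieval frames are excluded everywhere; events on excluded
frames are dropped, not shifted.

## Trace quality control and event detection

A dF/F0 trace is cut into non-overlapping 1-min sections; the section
valley is its minimum.  A trace is labeled unstable — and excluded — iff
the valley exceeds 0.1 dF/F0 in at least five sections.  Whole trailing
sections shorter than one minute are ignored; a trace shorter than one
section is vacuously stable (with a warning).  Raising the valley threshold
can only shrink the unstable set (monotonicity is property-tested).
Calcium events are peaks of the deconvolved trace above a configurable
prominence; plateau peaks resolve to their earliest frame.

## Rate maps and place cells

Context rate maps live on 2x2 cm bins over the arena bounding box, padded
by 4 sigma so Gaussian smoothing never truncates at the array edge (count
mass is conserved to numerical tolerance).  Counts and occupancy are
accumulated over the context's concatenated foraging segments, each
smoothed with a sigma = 3 cm Gaussian restricted to valid bins, then
divided; bins with under 0.1 s raw occupancy or outside the octagon are
invalid.  The 0.1-s occupancy floor suppresses unstable rate estimates in
rarely visited corners.

Stability per context is the mean of two Pearson correlations over shared
valid bins: first-half vs second-half trials, and even vs odd trials (trial
splits, not raw-frame splits).  Undefined correlations (zero variance,
under two shared bins) propagate as failures, never as zeros.  The null
distribution circularly shifts the event train within the concatenated
context frame sequence by a uniform offset at least 1 min from zero, 500
times; shifting on the concatenated sequence (not wall clock) keeps
shuffled events inside analyzed frames.  A neuron is a place cell iff, in
at least one context, its stability exceeds both the null's 95th percentile
and an absolute 0.4 floor (applied to r itself; the Fisher transform is
monotone and recorded for reporting only), and it fired at least 10 events
in the session.

The between-context remapping measure is the Pearson correlation of the two
smoothed context maps over their shared valid bins (at least 10 required).

## Place fields and rate analysis

Fields are segmented on the pooled-context map.  The component count k is
the number of 2D local maxima with topographic prominence >= 1 event/min,
computed by a persistence pass (union-find over pixels in descending order;
plateau ties collapse to the earliest bin).  A k-component Gaussian mixture
is then fitted to the rate surface by weighted EM — bin centres weighted by
rate, means initialized at the detected peaks, full covariances regularized
by 0.05 cm^2 I; the EM is written in-package because the standard mixture
implementations do not accept per-sample weights.  Pixels are assigned by
maximal responsibility; pixels below 20 % of the field peak are trimmed;
fields with peak < 1 event/min or fewer than two attributed events are
discarded.  The manual curation step used with real recordings is replaced
by a declarative overrides structure (drop/merge), applied after automatic
segmentation so every adjustment is auditable.

Field centre = component mean; size = pixel count x 4 cm^2; the per-context
field rate is the mean of the context map over member pixels, with the
20 %-of-peak cutoff taken from the pooled map on which segmentation ran.
Rate remapping per field is RateOverlapScore = 1 - |rate1 - rate2| /
(rate1 + rate2).  Fields whose centre lies within 10 cm of a rewarded port
(the nearer port when two exist) are reward fields; other fields fall into
5-cm distance bins.  Reward fields are typed by FiringPreference =
((rate1 - rate2)/(rate1 + rate2)) * (-1)^(k+1), k in {1, 2} the hosting
reward port, computed from maps rebuilt on correct non-cued trials: match
above +0.33, mismatch below -0.33, neutral between.

## Directional analysis

The relative running direction is H = wrap(phi - a) in [-pi, pi), with phi
the heading from frame-to-frame displacement of the 167-ms-smoothed head
and a the bearing from the head to a configurable reference point (default:
arena centre).  Both use the quadrant-aware arctangent; zero-displacement
frames are dropped.  Tuning curves are event rates in eight 45-degree bins
whose centres are the wall-normal angles, so bin k points at wall k; tuning
strength and direction are the length and angle of the curve's Rayleigh
vector.

A directionally modulated cell (DC) must satisfy, within one context, all
of: split-half stability of the tuning curve > 0.4; Rayleigh length above
the 95th percentile of *both* nulls — a circular event shift and a circular
shift of the H series relative to the events (a shift, not a frame-wise
permutation, so the H autocorrelation is preserved and significance is not
inflated); and a direction/place index > 1.  The index divides the
reconstruction error of the tuning curve under a pure-place assumption
(r'(H) = sum p(x,y,H) r(x,y) / sum p) by the error of the spatial map under
a pure-direction assumption (r'(x,y) = sum_H p r(H) / sum_H p); both
observed and reconstructed maps are normalized to their own peaks and the
error is the mean squared difference over valid bins divided by the range
of the normalized observed map.  This guards against spurious tuning from
non-uniform occupancy (e.g. wall-hugging paths).  Cells with fewer than 10
events are excluded; a flat observed map makes the error undefined and the
cell fails.  The source text leaves open whether the three conditions must
coincide in one context; we require the full conjunction within a single
context, the stricter and more interpretable reading.  Conjunctive cells
are DCs that are also place cells.  For cells significantly tuned in both
contexts the tuning difference is the wrapped angular difference of the two
Rayleigh angles.  Landmark tuning maps the Rayleigh angle to its wall and
the wall to reward / light cue / other; a wall that is simultaneously a
reward and a cue wall is excluded from both the counts and the chance
proportions.  Tuning categorization uses the Rayleigh angle (not the peak
bin), taken from the more strongly tuned context.

## Population decoding

Per neuron, events are summed over non-overlapping 60-frame windows aligned
to session start, every frame carrying its window's sum; rows are
restricted to foraging frames and thinned to every 20th (1 sample/s).
Columns are z-scored.  An RBF-kernel SVM (C = 1; only the kernel scale is
tuned) is trained on a stratified random 80 % of rows, with the kernel
scale chosen by 20-fold cross-validation over a 9-point logarithmic grid
(10^-2..10^2 x the median pairwise distance); the mean CV accuracy is the
reported measure and the 20 % hold-out accuracy is reported separately as
an overfitting check.  Decoding is run for all cells, place cells, and
non-place cells, optionally on correct trials only.

Because thinning keeps up to three rows per 60-frame window with identical
feature vectors, random row splits let near-duplicates leak between
training and test: on planted data with *no* context signal the random
protocol still decodes far above chance.  The frame-wise random split is
kept as the default (it is the field's standard protocol and what the
per-animal accuracies refer to), but a trial-blocked variant
(`blocked=True`: grouped 80/20 split and grouped CV folds) is provided and
is what the calibration studies use for subset contrasts.  The planted
chance control additionally balances class counts by subsampling, since the
tuned-and-selected CV accuracy of an imbalanced null sits at the majority
fraction plus selection bias rather than at 0.5.

## Behavior

A trial is correct if the visited port is the context's reward port;
timeout if no port was visited.  Errors are typed context (the other
context's reward port), spatial precision (adjacent wall, +-1 mod 8), or
non-specific, with context taking precedence when a port satisfies both —
the overlap is geometry-dependent and needs a deterministic rule.  Error
compositions are compared to a baseline by Pearson chi-squared with
optional Bonferroni correction; zero-expectation categories are pooled.
The composition's category set is configurable (3 error types, or 5 with
correct and timeout, matching a 4-degree-of-freedom test).  Learning is the
first day reaching 70 % correct on non-cued trials.

## Synthetic sessions

The generator emulates the study's statistical structure, not its
biophysics.  Trajectory: a confined correlated random walk at 20 Hz —
Ornstein-Uhlenbeck speed around 9 cm/s, diffusing heading
(2.2 rad/sqrt(s)), specular wall reflection, resting bouts (< 2 cm/s) with
~1.5 s mean duration — which covers > 90 % of 2x2 cm bins in a 40-min
session.  An optional wall-following bias produces the occupancy-biased
regime used to stress the directional analysis.  Trials: balanced,
intermingled context schedules (every prefix within +-1); a hidden 7x7 cm
trigger zone re-randomized per trial; the trigger is the first zone entry
at least 10 s after trial start; reward-phase outcomes come from an agent
policy (perfect, random-port, or biased), with 60-s timeouts and 3-s
inter-trial intervals.

Events are Bernoulli-thinned inhomogeneous Poisson trains at the frame
rate: rate = [baseline + sum of planted 2D Gaussian fields x per-context
gain] x directional factor.  The directional factor is
max(0, 1 + depth * vm(H)), with vm a von Mises kernel normalized to zero
circular mean and unit peak, so tuning enhances the preferred relative
direction and suppresses the opposite one; the generator's H uses the
body-motion heading (the head carries planted tracker jitter).  Rate
remapping plants per-context gains; global remapping plants independent
field centres per context.  Traces, when requested, convolve events with a
fast-rise/0.5-s-decay kernel plus noise; the unstable mode adds a
> 5-min baseline plateau above 0.1 dF/F0 that the QC rule flags.

Default study conditions: 40-min sessions (the recorded sessions are 1 h;
40 min keeps desk-scale runs fast while leaving every screen comfortably
powered), up to ~100 trials, place-field amplitude 30 events/min with
sigma = 5 cm and a 0.1 events/min out-of-field baseline, non-coding cells
at 6 events/min, directionally tuned cells at 15 events/min with kappa = 2
and depth 0.8.  The field amplitude is set so the generator meets its own
fidelity contract — planted per-context gain g recovers a rate overlap of
1 - |1-g|/(1+g) within +-0.1 on a 40-min session; weaker fields leave the
overlap estimator visibly biased low at g = 1 because the score's |Delta|
numerator rectifies sampling noise.  What the generator does *not* emulate:
real locomotor kinematics, licking and reward consumption, slow
representational drift, correlated population noise, and imaging artifacts
beyond baseline drift — so passing recovery tests certifies the analysis
chain, not robustness to every property of real recordings.  Stray
baseline-event clusters do occasionally segment as small spurious fields,
as in real data, where such cases were curated manually; the overrides
mechanism plays that role here.

## Validation studies (what the acceptance checks compute)

* Null calibration: 200 homogeneous Poisson cells, 500 shuffles each, on
  4-cm bins (the screens' operating characteristics do not depend on the
  finer grid, and the coarser one keeps 100 000 shuffled map pairs cheap):
  place-cell and DC false-positive rates stay at or below 10 %.
* Field recovery: 100 cells with 1-3 planted fields at least 15 cm apart —
  field count correct in >= 90 % of cells, centres within 3 cm in >= 90 %
  of recovered fields (recovered fields are joined to planted ones through
  the ground-truth table).
* Remapping recovery: stable populations give median between-context
  r >= 0.7, globally remapping ones <= 0.2; planted gains {1, 0.5, 0.2}
  recover their rate overlaps within +-0.1 (60 cells for a stable median).
* Decoder calibration: 50 globally remapping cells decode at >= 0.90 mean
  CV accuracy; label-shuffled controls over 20 seeds average within
  0.50 +- 0.05; with signal confined to place cells, the place subset
  strictly beats the non-place subset (blocked splits, as above).
* Directional disambiguation: planted von Mises cells (kappa = 2,
  depth 0.8, 50 cells) detected as DCs in >= 80 %; wall-biased pure place
  cells misclassified in <= 20 %.
* Behavior logic and formula identities are exact; the end-to-end pipeline
  on a 12-min fixture is byte-deterministic under a fixed seed.

## Numerical choices and edge cases

Double precision throughout; undefined correlations and flat-map
reconstruction errors propagate as NaN and count as failures; plateau peaks
resolve to the earliest index; the -pi/+pi boundary of H maps to -pi; seeds
are threaded explicitly through every stochastic step (generator, shuffles,
decoder splits), and a pipeline rerun with the same configuration is
byte-identical.  Every output table embeds the configuration hash and seed.

## Known limitations

The generator's agent does not learn, so learning curves come from scripted
policies; cued-trial guidance is not modeled.  With two 20-min context
samples, sparse cells can have undefined half-map stability in one context
(they simply fail that context's screen).  The rate-overlap estimator is
biased low at high overlap for finite event counts (rectified noise); the
reported recovery quantifies this at the default conditions.  Cells are not
tracked across paradigms — sessions are analyzed independently, matching
the source data's design.
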