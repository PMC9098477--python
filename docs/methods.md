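# Methods

This note documents the statistical model behind each stage, the parameter
defaults and why they are what they are, the numerical choices that are not
visible from the API, and what the synthetic-data generator does and does not
emulate.

## Data model

A session is a neurons × frames matrix of deconvolved activity: nonnegative
per-frame amplitudes in arbitrary units, approximately proportional to
instantaneous firing rate. The default design is 20 min at 10 Hz (12,000
frames) split in half by the injection frame; epochs are half-open frame
ranges, pre = [0, injection) and post = [injection, end). The ~30-min wait
between injection and the post recording in a typical protocol is outside
the recorded window and is not modelled. A *calcium event* is a frame with
amplitude strictly greater than zero.

## Response classification

The activity score (A_after − A_before)/(A_after + A_before) is the
normalised pre/post contrast of a neuron's total activity. Properties used
by the tests: it is antisymmetric under epoch swap, invariant under
rescaling the train, and equals ±1 when all activity falls in one epoch.

**Baseline filter.** Neurons with A_before outside [1000, 4000] a.u.
(bounds inclusive) are excluded before classification: at very low baselines
the score is forced toward +1 and at very high baselines toward negative
values regardless of treatment, so a drug effect cannot be read off the
score there. The window is a property of the deconvolved-unit scale; both
limits are configuration fields.

**Shuffle null.** The null hypothesis is exchangeability of frames across
the session. Each iteration permutes the frame order uniformly at random and
recomputes the score; the default is 100,000 iterations with 0.1% tails.
Implementation: only the k nonzero frames matter, and under a uniform
permutation the indicator "nonzero frame lands in the pre epoch" follows the
sequential hypergeometric scheme P(take | history) = remaining-pre-slots /
remaining-frames. Sampling these indicators directly costs O(k · iterations)
instead of O(frames · iterations) and reproduces the permutation null
*exactly*; the test suite checks this against exhaustive enumeration of all
4! permutations of a toy train and against a literal permutation oracle
(Kolmogorov–Smirnov). A circular-shift scheme (preserving within-train
structure) is available via `shuffle_scheme="circular"`.

**Decision rule.** The upper cutoff is the k-th largest null score with
k = round(tail · iterations) (the 100th largest at the defaults), and a
neuron is excited only if its score is *strictly* greater; symmetrically for
inhibited. Strict exceedance makes the type-I rate k/(B+1) per tail for any
iteration count B, which is why reduced-B runs remain calibrated (they only
lose tail resolution). Each neuron gets its own null because the null width
depends on that neuron's amplitude multiset.

**Event metrics.** Frequency per epoch is the event count in the 10-min
window; the frequency score applies the same normalised contrast to counts.
Event sizes are normalised by the neuron's mean pre-epoch event amplitude,
so pre-epoch normalised sizes average exactly 1; neurons with no pre-epoch
events have undefined sizes and are flagged out of the size analysis.
Group comparisons pool post-epoch normalised sizes across neurons at the
event level by default (`event_size_level="neuron_mean"` aggregates per
neuron first).

## Synchrony

The CCG statistic is the maximum over lags −1, 0, +1 frames of the lag
product sum of two trains, divided by √(s₁s₂) where s are total activities.
Edges are truncated (no wraparound). Because the normalisation uses totals
rather than L2 norms, the statistic is not bounded by 1 and scales as √c
when one train is scaled by c — both asserted as properties in the tests.

The null permutes the frame order of *both* trains independently (10,000
iterations, top-1% cutoff, strict exceedance). Implementation: each train's
events are placed on a uniformly random ordered tuple of distinct frame
positions (sampling without replacement, O(events) per iteration), and lag
coincidences are located by integer-code binary search; this is again the
exact permutation null, validated against a dense-permutation oracle.

Eligibility mirrors the response stage: pairs are formed within the excited
and within the stable group only, among neurons with A_after ≥ 3000 a.u.
(complement of the strict "< 3000" exclusion); inhibited neurons are not
analysed, since the treatment suppresses their post-epoch activity below
that floor anyway. Group proportions of synchronous pairs are compared with
a two-sided Fisher 2×2 exact test. Epoch choice defaults to the post
epoch (the eligibility floor is a post-epoch quantity); `ccg_epoch="pre"`
is exposed.

## Cell tracking

Candidate matches pair every cell of session A with its nearest cell of
session B; candidates are accepted in ascending distance order when the
distance is strictly below 6.5 µm, with each B cell usable once (exact ties
broken by the lower A index — the deterministic resolution of a rule that
is otherwise ambiguous under collisions). Coordinates are assumed
pre-registered; no image registration is performed. Cross-session label
association collapses labels to responsive (excited/inhibited) vs stable
and uses Fisher's exact test.

## Decoding

Sessions are binned into 30-s windows by summation (sum preserves the
total-activity semantics of deconvolved trains; mean is exposed and is
equivalent after standardisation), giving 40 bins labelled by their midpoint
relative to the injection. The decoder is scikit-learn's `LinearSVC` with an
L1 penalty, C = 1.0, on a stratified 70/30 split, with features standardised
using training-fold statistics — L1-SVM solutions are scale-sensitive and
deconvolved units are arbitrary, so unstandardised fits would be dominated
by high-amplitude neurons. Accuracy is the test-set proportion correct.

Neuron counts are matched within a mouse: the larger session is decoded from
random subsets of the smaller session's size, with subset choice and split
randomness redrawn together over 100 repeats and averaged; the smaller
session is scored with the same number of repeated splits. The decoding
universe is the baseline-filtered neuron set by default (required for the
class-ablation decoders to be well defined; `decoding_universe="all"` is
exposed). Ablation drops one response class from both sessions before count
matching. Per-mouse accuracies are compared across treatments with
two-sided paired t-tests.

## Statistical-test conventions

Mann–Whitney U uses exact enumeration when the combined sample is ≤ 20 with
no ties and the tie-corrected normal approximation otherwise (the two
branches agree within 0.02 at the crossover, asserted in tests). Fisher
tests are two-sided by the minimum-likelihood rule; for the exploratory 2×3
class-proportion table a Freeman–Halton enumeration is implemented (scipy
provides no r×c exact test). Degenerate inputs are flagged rather than
returning silent NaNs, with one deliberate asymmetry: a paired test of a
vector against itself reports (t = 0, p = 1) with a note, while a
zero-variance one-sample test is reported as undefined.

## Synthetic-data generator

Per neuron, events are a homogeneous Poisson process discretised to frames
(counts per frame Poisson; colliding events add their amplitudes, so a
frame's value is Gamma(count·shape, scale)), with i.i.d. gamma amplitude
marks — exponential by default (`amplitude_shape=1`), the simplest positive
mark model consistent with activity-proportional deconvolved units. The
treatment multiplies post-epoch rates of planted excited (×2.0) and
inhibited (×0.4) subpopulations; stable neurons keep their rate. Effects and
synchrony groups are planted only in non-saline sessions; saline sessions
are stationary with an all-stable truth.

**Calibration of defaults.** No amplitude or rate statistics are available
for the real recordings the analysis was designed around, so the defaults
are calibration choices, not biological estimates: base rates uniform in
[0.2, 0.6] events/s with mean amplitude 10 a.u. put E[A_before] = 6000·rate
in [1200, 3600], so ≥ 80% (in practice ≈ 98%) of stable neurons fall inside
the [1000, 4000] baseline window and the filter behaves as in the intended
regime. These values were fixed once, before the downstream tests, and are
asserted as a generator invariant.

**Planted synchrony.** Each group shares a parent Poisson train
(0.5 events/s by default) spanning the post epoch; members copy each parent
event — amplitude included — with probability 0.8 at a lag uniform on
{−1, 0, +1}. The post-epoch default mimics treatment-induced synchrony and,
importantly, leaves pre-epoch baselines untouched (a full-session parent
would push group members past the upper baseline limit); `sync_epoch="full"`
is exposed. The parent rate was set by the prescribed detectability
calibration: at copy probability 0.8 over default backgrounds, planted pairs
exceed the top-1% CCG threshold in 100/100 seeded runs. Note that planting
synchrony on otherwise-stable neurons adds post-epoch activity and can make
them score as excited; groups are therefore drawn from the excited
subpopulation when one exists.

**Paired sessions** share a configurable fraction of cells (default 0.8)
with identical base rates and centroids jittered by Gaussian noise
(sd 1.5 µm in a 300 µm field); response classes are assigned independently
per session, so cross-session label association is null by construction.

**What passing tests do and do not show.** The generator reproduces the
event-train statistics the analysis consumes, so passing tests demonstrate
that the pipeline recovers effects of the planted form at the planted
magnitudes and controls its error rates under exchangeable nulls. Real
recordings additionally contain slow drift, correlated population activity,
deconvolution artifacts and non-stationary baselines, none of which are
modelled; behaviour under those features is untested here.

## Problem sizes and runtime

The published iteration counts (100,000 score-null and 10,000 CCG-null
iterations, 100 decoding repeats) are the configuration defaults. The test
suite and the `AnalysisConfig.fast()` preset run reduced counts
(500–10,000 score-null iterations, 100–1,000 CCG-null iterations, 4–20
repeats) chosen as desk-scale problem sizes; by the strict-exceedance
argument above this changes tail resolution, not calibration. Calibration
tests use 5,000 stationary neurons at 10,000 shuffle iterations for the
response type-I rate and 2,000 disjoint independent pairs for the CCG
false-positive rate, with binomial 99.9% acceptance bands computed in the
tests themselves.

## Known limitations

* The pipeline consumes already-deconvolved trains; motion correction,
  source extraction, dF/F and deconvolution are upstream concerns.
* No multiple-testing correction is applied anywhere (by design of the
  comparison structure it reproduces).
* The CCG is restricted to ±1 frame of lag; slower co-modulation is
  invisible to it.
* Greedy one-to-one matching is order-independent but not globally optimal;
  at the default 6.5 µm threshold and realistic jitter the difference is
  negligible (recovery ≥ 95% with ≤ 2% false matches in tests).
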