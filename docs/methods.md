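# Methods

## Bout model and conventions

All analyses consume bout tables: per-trial lists of
`(fly, action, start_frame, end_frame)` with 0-based frames and
half-open intervals `[start, end)`. Half-open intervals make adjacency
and clipping arithmetic unambiguous: two bouts touching at a frame do
not overlap, and clipping at a copulation onset is a single `min`.
Seconds-valued thresholds convert to frames by round-half-up, so the
standard 0.5 s minimum on classifier-derived wing-extension (UWE) bouts
is exactly 15 frames at the 30 Hz video rate, with an inclusive ("at
least") comparison. Video assays run at 30 Hz; the y-maze camera at
45 Hz.

Copulation is trial metadata, not a bout: when `copulation_onset` is
set, analysis is truncated there (straddling bouts shortened, later
bouts dropped) and the copulation latency becomes the normalizer for
every fraction, rate and latency. Truncation is idempotent. The
"copulation attempt" action remains an ordinary bout.

No bout post-processing beyond the minimum-duration filter (e.g.
gap-bridging of classifier output) is applied.

## Ethograms

Node weights are per-action bout counts pooled over both flies of a
pair, normalized to the total scored bouts, so node frequencies sum
to 1. Transitions are *within-fly*: for each bout of action A by fly f,
the destination is the action of f's earliest subsequent bout starting
within the window (1 s default) of A's end; self-transitions are
allowed and edge weight is transitions(A→B)/count(A). Under this
first-transition rule, per-origin outgoing weights sum to ≤ 1. Whether
one should count only the earliest successor or every action inside the
window is genuinely open; both are implemented (`multi_edge=True` for
the latter) and first-only is the default as the more conservative
reading. Bouts of *other* actions that overlap the origin bout are not
successors; the successor must start at or after the origin's end.

## Sliding-window expressivity

The per-frame trace is the fraction of a centered window (10 s for
screen-scale comparisons, 5 s for threat induction) annotated as the
action, with the indicator pooled over flies unless restricted. At
trial edges the window is truncated and renormalized to the frames
actually available, which avoids the artificial ramp-down of
zero-padded convolution; a `clamp` variant slides the full-length
window inside the trial instead. With truncation, a window at least
twice the trial length degenerates to the whole-trial fraction at every
frame (the clamped variant already does so at one trial length) — the
two conventions differ only near edges. Group traces report the
frame-wise mean with an SEM envelope (ddof = 1).

## Social indices

Every index is a difference normalized by a sum. Preference:
`(t1 − t2)/(t1 + t2)` over time courting each of two simultaneous
targets. Dominance ("one-sidedness") within a pair:
`|tA − tB|/(tA + tB)`, in [0, 1]; this formula is an explicit package
choice for consistency with the preference index (the field uses the
evident [0, 1] bias scale without printing a formula) and is
scale-invariant. Ties and all-zero denominators leave the index
undefined; undefined values are flagged and excluded from group
statistics, never coerced.

Female receptivity combines wing spreading (acceptance) and
courtship-normalized ovipositor extrusion
`OE(norm) = (t_OE − t_UWE)/(t_OE + t_UWE)` (rejection): per female,
WS present iff `t_WS > 0` and OE present iff `OE(norm) > −0.25`, both
strict; the contribution `WS − OE ∈ {1, 0, −1}` is averaged over
females.

Priming concordance asks whether the male that dominated male-directed
courtship in a pair phase also dominates female-directed courtship
after a female is added. Pairs with under 20 s of total male–male
courtship are filtered (inclusive at 20 s). The trio value is signed
toward the pair-dominant fly; concordance requires it strictly
positive (a tie counts against concordance — conservative, and a
zero-measure event for continuous times). A configurable high-bias
threshold (default 0.8) reports the strongly one-sided subset
separately.

## Photostimulation analyses

The canonical activation protocol is six 30 s ON blocks after a 2 min
baseline with 1 min inter-block intervals; frequencies rise
monotonically over 1–40 Hz. The exact six-step ladder is configurable
with default {1, 2, 5, 10, 20, 40} Hz spanning that range. Pulse width
and intensity are serialized labels only; analyses treat ON blocks as
intervals. Segment masks partition every frame exactly once into
baseline / ON blocks / IBIs / post-final; "PS−" is the baseline and
"PS+" pools ON blocks for courtship but IBIs-plus-post for aggression,
matching the observation that evoked attack occurs mostly after light
offset while courtship is light-locked.

Onset-locked suppression curves average the binary action indicator
across qualifying (fly, block) events, where qualifying means an action
bout overlaps onset ± 0.5 s (the symmetric, most literal reading of
"courting within 0.5 s of onset"). The default window is −1 s to +5 s
around onset — a 6 s window surrounding the block — with both bounds
configurable since the exact registration is a free choice. The sham
persistence baseline is the fraction of spontaneous bouts strictly
longer than 2 s, pooled over sham trials. Penetrance is the fraction of
flies with ≥ 1 action frame per time bin (1 s default); expressivity is
the group mean ± SEM of per-fly 5 s sliding fractions.

## Song analysis

Coarse annotations are refined to the maximum *absolute* amplitude in a
20 ms centered window (song pulses are biphasic; a signed mode exists).
Tie-breaking: if the annotation sample itself attains the window
maximum it is kept (so a flat window returns the annotation point);
otherwise the earliest maximizing sample wins. Train segmentation
chains consecutive same-type events whose gap is strictly below the
type threshold (pulse 0.2 s, clack 0.4 s) — single linkage, so a chain
may span more than one threshold end to end; types never mix; unsorted
input is sorted internally. Event detection itself is out of scope
(annotations are produced manually upstream), as is pulse/clack
classification.

## Place preference

Backgrounds are per-pixel medians over an evenly spaced frame subset
(default 25), valid wherever a fly occupies a pixel in fewer than half
the subset frames. Positions are centroids of connected components of
`|frame − background| > threshold` above a minimum area (5 px); the
threshold is absolute with an Otsu fallback when omitted. Occupancy
counts each detected centroid per frame against the left/right arm
masks — the central bowl is excluded and flies are not identity-tracked
(cumulative positions). The normalized index is
`(t_left − t_right)/(t_left + t_right)`, with a fraction-of-total
variant behind a flag; the difference-over-sum form matches the
package-wide index convention.

## Statistics

Nonparametric throughout: Mann-Whitney U for unpaired two-sample
comparisons, Wilcoxon signed-rank for paired and one-sample (vs a null
median) cases, two-sample Kolmogorov-Smirnov for time-evolving or
cumulative distributions, Kruskal-Wallis followed by Dunn's z-tests
(tie-corrected pooled-rank variance) with Benjamini-Hochberg adjustment.
Compact letters are the maximal cliques of the non-significance graph,
so two groups share a letter iff their adjusted p ≥ α (0.05 default).
Benjamini-Hochberg uses the statsmodels step-up implementation; an
independent brute-force step-up oracle verifies exact agreement in the
tests. Binomial comparisons are exact: one-sample via the binomial
tail, two-sample via the exact conditional (hypergeometric/Fisher)
test, chosen for determinism over unconditional alternatives. Cohen's d
pools variances with n−1 weights and reports a large-sample normal CI.
Outlier fences are Tukey's Q1 − 1.5·IQR / Q3 + 1.5·IQR with
linear-interpolation quartiles; values are flagged only and always
retained in downstream tests. Censored latencies enter rank tests at
their censoring value (the fixed-assay-length convention) and carry an
explicit flag. Tests default to two-sided.

## Simulator

The bout generator is an alternating-renewal (semi-Markov) process per
fly rather than per-frame Bernoulli draws: idle time to the next
initiation is exponential in the summed action rates, the action is
chosen proportionally to rate, and the bout lasts a gamma dwell (shape
2 by default — unimodal with a heavy-enough tail for behavioral bouts).
This matches the bout-level structure of the data and yields closed
forms: expected bouts per trial `T·λ/(1 + λ·μ)`, trio preference
`(λFμF − λMμM)/(λFμF + λMμM)`, and two-rate occupancy ratios under PS
gain. Time-varying PS modulation is generated by thinning against the
worst-case rate, and the acceptance draw is consumed only when the
acceptance probability is below one, so a null modulation reproduces
the unmodulated stream draw for draw. Continuous times are rounded
half-up to frames at the end; zero-length bouts are discarded.

Dominance is a single scalar δ ∈ [0, 1] scaling both courtship and
aggression initiation as (1 + δ) vs (1 − δ), so the same fly courts and
attacks more by construction. An optional row-stochastic kernel chains
a bout into a successor with probability `chain_prob` after a uniform
0.1–0.5 s gap (inside the 1 s ethogram window); a row-stochastic kernel
alone would chain forever, hence the explicit chaining probability.
Copulation fires with constant hazard during copulation-attempt bouts
and ends generation. Per-fly streams are split from the trial seed with
`SeedSequence` spawn keys, so adding a fly never perturbs another's
draws, and identical (spec, seed) pairs are bit-identical.

Reference profiles (`santomea_like_profile`,
`melanogaster_like_profile`) encode the qualitative species contrast —
high male-male courtship vs high aggression — at rates giving realistic
bout counts (tens per 20 min trial). No generative model was ever fit
to real recordings; all simulator distributions are package choices
with known ground truth, which is their purpose. Consequently, passing
tests demonstrate correctness of the *analyses* under renewal-like
bout statistics, calibrated test sizes, and exact oracle agreement —
not that real fly behavior follows these distributions; real data add
non-stationarity, interaction feedback between flies, and classifier
noise that the simulator deliberately omits.

The song synthesizer places Gabor-like wavelets (cosine carrier under a
Gaussian envelope, amplitudes uniform in 0.5–1) at sample-aligned times
with within-train gaps drawn strictly inside the segmentation
thresholds (pulse 80–150 ms, clack 150–350 ms) and between-train gaps
of 0.8–1.5 s, so ground-truth trains are identifiable. Y-maze walks are
Gaussian steps (2 px/frame) plus a drift of β px/frame toward the odor
arm, rejected when leaving the walkable mask; the default arena is
left/right symmetric so β = 0 implies a zero expected occupancy index.
Rendering draws dark disks (radius 3 px) on a bright field, optionally
with Gaussian pixel noise.

## Problem sizes in the verification suite

The test suite and acceptance script use desk-scale replicates chosen
to keep Monte-Carlo error well inside the asserted tolerances: 200
trio trials of 20 min for preference recovery (tolerance ±0.05 against
the analytic 0.5), ≥ 5,000 pooled bouts for the exact ethogram oracle,
1,000 random event sets and p-vectors for the segmentation and BH
oracles, 10,000 exponential bout durations for the persistence
fraction (±0.02 of 1/e), 500 replicate null comparisons (12 vs 12
trials of 2 min) for Mann-Whitney type-I calibration, and 50 ten-minute
null walks for occupancy symmetry.

## Known limitations

* No pose tracking, classifier training, or video decoding; bout CSVs
  are the entry point, and TIFF/real-video ingestion for the y-maze is
  limited to in-memory arrays.
* Indices are descriptive; no state inference about why dominance or
  priming arises.
* The dominance-bias formula and occupancy normalization are package
  conventions (flagged above) where the field prints no formula.
* Two-sample binomial comparisons condition on margins; very small
  unbalanced designs may prefer unconditional tests.
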