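# Methods

## The reconciliation problem

Two sources describe one brushing session.  Video observation (VO) is
timed-event coding: a trained observer assigns, exhaustively over the
session, events of the form (start, end, area).  Motion tracking (MT)
samples the brush position at 100 Hz and labels every sample with an area;
the occlusal-vs-smooth decision comes from the brush-head angle.  The two
records live on different time bases and error models, so all comparisons
run on a common grid: time is seconds from session start, intervals are
half-open `[k·0.5, (k+1)·0.5)`, and each interval takes the majority vote
of the samples it contains.

Conventions, chosen where the procedure itself leaves room:

* **VO rasterisation.** Events are expanded to a 50 fps frame grid; a frame
  is labelled by the event covering its *midpoint*, which prevents
  double-labelling at event boundaries.  Frames covered by no event get an
  explicit `uncoded` sentinel; uncoded time is excluded from every
  agreement denominator and duration sum, never silently dropped.
* **Majority ties** go to the label occurring first in time within the
  interval (not first in any code ordering).
* **Trailing partial intervals** (< 0.5 s) are kept and voted from their
  available samples; dropping them would break duration conservation.
* **Angle classification** happens per sample, before voting.  The angle is
  the inclination of the brush-head axis relative to the occlusal plane;
  `angle ≤ threshold` (20° on molars, 13° on front teeth) means
  occlusal/incisal contact, larger angles mean the smooth surface given by
  the side flag.  The inequality direction is a package convention; the
  synthetic generator uses the same one, keeping the system
  self-consistent.  A ±3° sensitivity probe (`threshold_sensitivity`)
  reports the changed-label fraction.
* **Pairing** uses the intersection of the two coded spans; surplus
  trailing intervals of the longer stream are dropped with a warning.
* **Sextant numbering.** Upper arch 01–03 (right posterior → anterior →
  left posterior), lower arch 04–06 (left posterior → anterior → right
  posterior), so the vertically opposing pairs are (01,06), (02,05),
  (03,04) — exactly the pairs the combined closed-jaw codes 16/25/34 span.
  Nothing downstream depends on absolute orientation, only on this
  opposition/neighbourhood structure.

## Agreement measures

The matching proportion is the percentage of commonly coded intervals with
identical area labels.  The confusion matrix cross-tabulates VO against MT
labels (21 labels: 18 areas + 3 combined codes) pooled over sessions.
Mismatch cells are classed **adjacent** — same surface in neighbouring
sextants (consecutive within an arch or vertically opposing), or the
occlusal-vs-smooth decision within one sextant, or a combined code against
either member's vestibular area — and **non-adjacent** otherwise (notably
vestibular↔oral and opposite mouth sides).  The class definition is
interpretive: it formalises the examples that accompany the heat-map
convention (neighbouring-sextant and occlusal/smooth confusions shaded
grey, opposite-side and vestibular/oral shaded red) and marks vertically
opposing sextants adjacent because closed-jaw brushing physically spans
them.  Cohen's κ is unweighted, computed on the 0.5 s grid, on the full
code or its sextant/surface projections; two identical constant sequences
(chance agreement 1) are defined as κ = 1 with a warning.

## Systematics metrics

Computed per session and source from the aggregated intervals, over the 12
smooth-surface areas only (occlusal/incisal intervals are removed first):

    C   = max(0, (1 − b/x) · i/n)
    I   = 1 − n/(2(n−1)) · Σ_i |d_i/x − 1/n|
    TSI = C + I

with b the number of changes between areas, x the smooth-surface brushing
duration in seconds, i the number of reached areas, n = 12, and d_i the
per-area durations after the even split of combined codes.  Decisions the
formulas leave open:

* x is smooth-surface time, not whole-session time (consistent with
  ignoring occlusal brushing); the per-area duration vector conserves x
  exactly.
* b counts transitions after removing occlusal intervals and collapsing
  equal-label runs, so an occlusal interruption returning to the same
  smooth area is not a change.  A combined code is its own label here: the
  brush genuinely moved.
* i counts areas with strictly positive duration (no minimum dwell).
* The reported per-session `events` count is taken over all areas on the
  aggregated grid; the TSI-internal b (12-area restriction) is emitted
  separately.

## Inference

Nonparametric throughout, summaries as median (min; max), α = 0.05.
Mann–Whitney U for independent groups (exact null when the smaller group
has ≤ 8 observations and no ties, else tie-corrected normal
approximation); Wilcoxon signed-rank for paired data (zeros dropped —
classical convention — exact for n ≤ 25 without tied magnitudes); Spearman
ρ with average ranks; Bonferroni–Holm across the 18 per-area VO-vs-MT
duration tests.  The tracker-effect check uses the two-sided 90 % t
interval of mean paired differences against a ±8 s margin (TOST duality at
5 %).  The exact/approximate switchovers were chosen for desk-scale
tractability.  Degenerate comparisons (all-zero paired differences,
constant equal groups, missing sessions) are reported as skipped rows and
never counted significant.

## The synthetic-data generator

The generator is first-class code: it defines the conditions every test
and the acceptance computation run under.

**Ground truth.** A semi-Markov walk over the 18 areas: dwell times are
truncated normal (lower bound 0.3 s), the next area is drawn from visit
weights with the current area excluded.  The habitual profile switches
~14/min with a manual and ~17.5/min with a powered brush (dwell mean
60/rate, sd half the mean), weights vestibular 1.0 / occlusal 0.5 / oral
1.0 with an oral-neglect factor of 0.7 multiplying oral weights, a 0.15
probability that a vestibular stretch uses the closed-jaw combined code,
and 120 s total duration — the frequent-switching, buccal-dominated,
oral-neglecting pattern observer studies describe.  The instructed profile
follows the systematic sequence deterministically (all oral areas lower
right → anterior → lower left then upper, all vestibular areas upper right
around to lower right, occlusal areas last) with near-equal dwell
(sd 0.8 s) and no combined codes.  Segment boundaries are quantised to the
20 ms grid — the common period of 100 Hz tracking and 50 fps video — which
makes the zero-noise case exact: with all noise off, both sources
aggregate to identical interval labels and the matching proportion is
100 % by construction, not approximately.

**MT noise.**  No measured magnitudes exist for the tracker's error
channels, so these are free parameters, set once to reproduce the
qualitative structure of tracker-vs-observer data and not otherwise
calibrated:

| parameter | default | role |
|---|---|---|
| `neighbour_confusion_prob` | 0.08 | per-sample probability, within ±0.3 s of a boundary, of sitting in the adjacent sextant; realised as one contiguous cluster per crossing |
| `occlusal_smooth_jitter_sd_deg` | 4.0° | sd of block-wise (1–2 s) angle offset around the 20°/13° thresholds (generated angles sit 6° from the threshold) |
| `micro_transition_rate` | 10/min | spurious short (0.1–0.3 s) excursions into an adjacent sextant; Poisson per true boundary crossing, calibrated so behaviour switching at the nominal 15/min realises this rate |
| `vo_min_event_s` | 0.5 s | human-coder smoothing: ground-truth stretches shorter than this merge into their longer neighbour before VO events are emitted |

The temporal structure matters as much as the magnitudes: errors must
persist on the half-second scale to survive majority voting, so confusion
comes in contiguous clusters and angle error in 1–2 s blocks, and the
spurious-event load rides on boundary crossings (the tracker errs where
the brush crosses borders), which keeps the MT/VO event ratio roughly
stable across behaviour profiles.  Under the defaults a simulated study
shows median matching ≈ 90 %, ≈ 90 % of mismatches in adjacent cells, MT
event counts roughly 1.5–2× VO, and a clear post-instruction rise in TSI
with a fall in events for both sources — the qualitative fingerprint the
analysis is meant to detect.  What the generator does **not** model:
kinematics or brush geometry, toothpaste/plaque, coder drift or fatigue,
inter-coder disagreement, session-to-session learning.  Passing tests
therefore show the *pipeline* is correct under a plausible error
structure, not that any particular tracker meets these error magnitudes.

**Seeds.** One master seed; each subject×session draws its generator from
`SeedSequence(master, spawn_key=(subject_index, session_index))`, so any
subset of a study is reproducible in isolation.  In a simulated study the
instructed subjects are allocated to arms floor-proportionally (at the
default 51/52/46 design: 22 manual, 24 powered).

## Problem sizes

The acceptance computation simulates the full default design (103
subjects, 46 instructed, 120 s sessions; ≈ 25,000 pooled coded interval
pairs) and completes in well under a minute.  The test suite's Monte-Carlo
components use deliberately smaller problems — formula oracles on 1,000
random draws, aggregation oracles on 1,000 random streams, a 200-replicate
null simulation at 12 subjects × 40 s with noiseless observation and no
instruction arm, and 100 direction-of-effect study replicates at 16
subjects × 120 s — sizes chosen as the smallest that make the checked
properties statistically unambiguous.

## Known limitations

* The adjacency classification and the angle-inequality direction are
  package conventions (documented above); other formalisations are
  defensible.
* κ is computed on the interval grid; coding tools compute it on their own
  native units, so absolute values are not directly comparable across
  implementations.
* The equivalence check assumes approximately normal paired differences
  (t interval); with n = 6 per arm this is an approximation.
* No weighted κ or chance-corrected alternatives; no inference on κ.
* Brushing-technique recognition (circling/scrub/jiggling) is out of
  scope.
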