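# Methods

## The fusion model

The package fuses two complementary predictors of the same image:

* a **semantic probability map** `P_SEM` of shape H×W×N — per-pixel,
  per-class probabilities from any semantic segmenter (N ≥ 2; class 0 is
  non-occlusion). Rows must sum to 1 within 1e-6; the container validates
  and never renormalizes.
* a **segment stack** `P_SAM` — an ordered list of O binary masks, each a
  class-agnostic object/part proposal with the generator's own
  `predicted_confidence` and `stability` scores. Masks may overlap.

The core assumption is that proposals are semantically pure: any two pixels
in the same proposal share one hidden occlusion class. Under that
assumption, per-proposal classification is sufficient, and each proposal's
class is chosen by **soft voting**: per-class probabilities are summed over
the proposal's pixels and the argmax wins. Soft voting (summing
probabilities) rather than hard voting (counting per-pixel argmax labels)
bounds each pixel's influence at 1, which matters when the semantic model is
overconfident from small-data training. For a proposal whose per-pixel
noise is i.i.d. and whose majority class is correct, the vote is correct
with probability approaching 1 in the proposal area — this is the mechanism
by which fusion removes isolated label noise while inheriting the
proposal's sharp boundary.

### Policies where the accumulation is underdetermined

The plain "paint each segment with its class" loop leaves two cases open;
both are explicit configuration:

* **Uncovered pixels** (`uncovered_policy`): proposals rarely tile the
  frame after filtering. `background` (default) leaves uncovered pixels at
  class 0 — faithful to an all-zeros accumulator and the conservative
  choice, at the cost of missing anything the mask generator missed;
  `semantic_argmax` falls back to the semantic map's own per-pixel argmax,
  which is the configuration used in the improvement experiment because it
  makes the comparison fusion-vs-semantic rather than
  fusion-vs-everything.
* **Overlaps** (`overlap_policy`): `smaller_wins` (default) applies
  proposals in decreasing area order so small, fine-detail proposals
  overwrite large ones — the standard choice when thin structures matter;
  `larger_wins` is the reverse. The sort is stable, so equal-area
  overlapping proposals resolve to the later-listed one.

Argmax ties break to the lowest class id, so an exact tie defaults to
non-occlusion (conservative).

### Filtering and prompting

Proposals are filtered on `predicted_confidence ≥ 0.90`,
`stability ≥ 0.85` and `area ≥ 5` px (all inclusive — the conventional
reading of a stated threshold) before voting. The companion
`grid_prompt_points` helper produces the dense prompting geometry such a
generator is driven with: an n×n cell-center grid (default 40×40 = 1600
points), placed at `(i + 0.5)/n` of each extent so no prompt degenerates
onto an image border.

### Soft scores for threshold-sweep evaluation

ROC-AUC needs a per-pixel score, which a hard fused mask does not provide.
`fused_soft_scores` assigns each covered pixel its segment's vote vector
divided by the segment area (rows sum to 1 again; uncovered pixels carry
the semantic probabilities or the background one-hot per the uncovered
policy). Its per-pixel argmax coincides with the hard fused mask
everywhere, so the hard and soft outputs are mutually consistent. How a
fused pipeline's AUC "should" be defined is genuinely open; this is the
package's documented choice.

## Rasterization and preprocessing

Polygon annotations (Label-Studio percent coordinates or a generic absolute
JSON dialect) are rasterized with exact, unambiguous semantics: pixel
(r, c) has center (c + 0.5, r + 0.5); a pixel takes a polygon's class iff
its center is inside under the even-odd rule; the last-listed polygon wins
overlaps; uncovered pixels are class 0. Percent→pixel conversion stays
continuous — only rasterization discretizes, so nothing is rounded twice.
Vertices may extend up to one full image extent beyond the frame (annotation
tools produce these routinely); anything farther is rejected as corrupt.
The occlusion category set is a user-supplied name→id table, not something
the package hard-codes.

ROI preprocessing crops a half-open window and pads symmetrically to a
target size (extra pixel to the bottom/right): class 0 for label masks, the
class-0 one-hot for probability maps, black for images.

The label-class space is N-way throughout; the binary occlusion task is
simply N = 2.

## Metrics

Evaluation is pixel-wise and one-vs-rest per class, restricted to an ROI
when given (a true positive is an ROI pixel correctly predicted as the
evaluated class). From TP/FP/TN/FN: accuracy, precision, recall, F1
(harmonic mean), IoU = TP/(TP+FP+FN); AUC by threshold sweep (delegated to
scikit-learn's `roc_auc_score`, equivalent to Mann-Whitney with ties at
half). Ratios that are 0/0 are reported as NaN with a warning — silently
reporting 0 would be indistinguishable from genuinely poor performance.
Multi-image pooling sums confusion counts before taking ratios (default) or
averages per-image metrics; reports label which protocol produced them. No
object-level overlap criterion is implemented: all counting is per pixel.

## Augmentations

A fixed-order pipeline (flips → photometric → copy-paste) driven by one
seeded generator, so a spec replays bit-identically. Photometric jitter is
`clip(contrast·(x − mean) + mean + brightness)` with hue/saturation jitter
in HSV space applied first (and skipped exactly when the sampled jitter is
the identity, keeping the identity spec bit-exact). Copy-paste samples
whole 4-connected occlusion components — not annotation polygons, so it
works on rasterized and synthetic masks alike — translates each by a
uniform in-bounds offset and composites source pixels and labels over the
destination. A source with no occlusion component makes the paste a logged
no-op rather than an error, since that is a data property, not a caller
mistake.

Magnitude defaults (hflip 0.5, vflip 0.25, brightness ±32/255, contrast
0.8–1.2, hue ±0.05, saturation 0.8–1.2, copy-paste 0.5 with ≤ 3 instances)
are conventional mid-strength values; the transform *families* are the
fixed part of the design, the magnitudes are configuration.

## Synthetic data: what it emulates and what it does not

`make_scene` draws 3–6 objects per 128×128 frame (defaults): ellipse blobs,
rotated bars and random-walk cables of thickness 1–3 px — a caricature of
bulky occlusions (blankets, pillows), rigid ones (rails, tubes) and thin
ones (cables), each with a distinct mean color plus Gaussian pixel noise.

`degrade_to_probmap` emulates a small-data semantic segmenter's two failure
modes: per-object boundary displacement (random dilation/erosion up to 2 px
by default — over-smoothing) and i.i.d. label flips (15 % by default),
then softens the winner to probability `1/(1 + (N−1)·e^(−1/T))` with
temperature T = 0.5 (winner ≈ 0.88 for N = 2 — confident but not one-hot).
The flip rate and jitter were chosen as a regime where the semantic route
is clearly degraded but per-segment majorities remain overwhelmingly
correct; i.i.d. flips are deliberately the *weakest* noise model under
which per-segment majority voting provably helps.

`shatter_to_segments` partitions every connected ground-truth region
(background included — a real mask generator partitions the whole frame)
into `1 + Poisson(3)` nearest-seed pieces, so proposals represent parts of
objects but never cross object boundaries: the purity assumption holds by
construction. Proposal scores are drawn from [0.92, 1] / [0.88, 1], above
the default filter thresholds. Two stress knobs break the idealization on
purpose: `weak_score_rate` gives proposals sub-threshold scores (exercises
filtering) and `impurity_rate` leaks single pixels across region boundaries
(exercises graceful degradation when purity fails). `segment_drop_rate`
omits small occlusion objects entirely, emulating a mask generator missing
thin structures between prompt points — with the `background` uncovered
policy this reproduces the method's known failure mode (a dropped cable
vanishes from the fused mask even when the semantic map saw it).

What the generator does **not** emulate: real image appearance (the fusion
never reads the rendered image), spatially correlated semantic errors
beyond boundary morphology, proposals that merge *different* objects, and
camera/sensor noise. Passing tests therefore demonstrate the algorithmic
properties of the fusion — not clinical-grade performance on real imagery,
which depends on the quality of the two upstream models.

## Numerical choices

* Probability-sum tolerance 1e-6 per pixel; vote sums in float64, so
  segment sums are exact to ~1e-12 relative and argmax decisions are
  stable.
* All argmax tie-breaks go to the lowest class id, everywhere, so the
  vectorized path, the soft-score path and any re-implementation agree
  exactly.
* Temperature softening is computed as `1/(1 + (N−1)·e^(−1/T))`, which is
  overflow-safe and reaches exactly 1.0 below T ≈ 1/700.
* Nearest-seed shattering breaks distance ties to the lowest seed index;
  region iteration order is the label order of the region map — both fixed,
  making the generator a pure function of its spec.
* Seeded streams: the probability-map and partition generators derive
  independent child seeds from the same spec seed, so the two corruptions
  are mutually independent but jointly reproducible.

## Experiment sizes

The bundled improvement experiment uses 20 seeds at 128×128 (the regime
above), which is ample for its one-sided sign test at α = 0.05 while
keeping the full suite and the acceptance script to seconds on a single
CPU; the scene and corruption parameters are the package defaults stated
above, fixed once in the specs' dataclasses.

## Known limitations

* The fused output can only be as complete as the proposal stack: with the
  `background` policy, anything the mask generator misses is lost.
* Class-impure proposals (two objects merged into one proposal) are voted
  as a unit; the fusion has no mechanism to split them.
* AUC for the fused route depends on the `fused_soft_scores` construction
  described above; other constructions would give different AUC values for
  the same hard masks.
* The synthetic benchmark shows large fusion gains because its corruption
  is exactly the regime soft voting corrects; gains on real data are
  expected to be far smaller and depend on the upstream models.
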