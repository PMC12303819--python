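# Methods

`ubermask` fuses instance segmentation masks of cell nuclei produced by
several segmenters into one consensus mask, and ships the machinery needed
to exercise and validate that fusion end to end without any external data:
preprocessing operators, a classical watershed segmenter, an instance-level
evaluator, a synthetic scene generator and diagnostic catalogs. This note
records the model, the parameter choices, the numerical decisions, and what
the synthetic benchmark does and does not demonstrate.

## Consensus model

The inputs are two or more co-registered integer label masks of the same
image (0 = background, each positive label one nucleus). The image is
partitioned into square neighborhoods of side `s` (default 40 px). Within
each neighborhood every method is scored by a user-chosen **metric of
merit**:

- `jaccard_total` — the sum over all other methods of the binary Jaccard
  agreement Σmin/Σmax between the binarized masks clipped to the
  neighborhood. Two empty regions agree perfectly (score 1). This metric
  seeks consensus: it rewards the method closest to everyone else.
- `nucleus_count` — the number of nuclei whose centroids fall in the
  neighborhood. Appropriate when under-segmentation is the dominant
  failure, as it typically is for densely packed nuclei.
- `inv_log_area_sd` — `1 / ln(σ(A)/n)` where `σ(A)` is the standard
  deviation of nucleus areas in the neighborhood and `n` their count.
  Rewards many, consistently sized nuclei; appropriate when the tissue has
  one dominant cell population.

The winner's nuclei (those with centroids inside the half-open
neighborhood) are harvested with full pixel sets and provenance. Because
pixel sets may spill outside the neighborhood, harvested nuclei from
different methods can overlap; overlaps are detected in two stages —
candidate pairs whose centers are closer than the equivalent radius
`sqrt(area/π)` of the larger nucleus, confirmed when the true pixel overlap
strictly exceeds 5% of the 32nd percentile of harvested nucleus areas —
grouped by connected components, and each group re-voted on a neighborhood
enclosing it, restricted to the methods that contributed a member. Only
the winner's members survive. Survivors are rasterized with fresh
contiguous labels; a provenance table maps each label to its source method
and original label. Every output instance is therefore an exact copy of
one input instance (up to the rare contested pixel, see below) — the
consensus never invents shapes.

A per-pixel topological voting scheme over window-wise Jaccard totals
(score all methods, eliminate the lowest, re-score, assign the pixel to
the winner) is included as a reference implementation for small-image
cross-checks; it is quadratic in image size and not part of the pipeline.

### Numerical decisions

- **Neighborhood semantics.** A per-pixel ±s window would harvest each
  nucleus up to (2s+1)² times; the image is instead partitioned into
  non-overlapping s×s tiles so each centroid is voted on exactly once.
  A trailing partial tile thinner than s/2 is merged into its neighbor;
  wider remainders stand alone. Sizes below 20 px are rejected: with
  ~10 px nuclei a neighborhood must be able to contain at least two.
- **Ties** in any vote go to the method listed earlier in the
  configuration. This single rule makes the whole pipeline deterministic
  for a fixed input, configuration and method order.
- **`inv_log_area_sd` guards.** Fewer than two nuclei, zero area spread,
  or `σ(A)/n = 1` (zero logarithm) give −∞: the method cannot win on this
  metric in that neighborhood. Ratios below 1 give a negative score and
  are allowed; the signed value (not its magnitude) is used, so ordering
  is preserved continuously through the singularity's sides.
- **Overlap threshold population.** The 32nd-percentile reference area is
  the empirical percentile over all harvested candidates of the image,
  computed once per image after voting and before resolution.
- **Residual conflicts.** Overlaps at or below the confirmation threshold
  can leave a few contested pixels at rasterization; each goes to the
  instance with the nearer centroid, ties to the lower (earlier) new
  label. Instance pixel sets can therefore be shaved by a few pixels but
  never extended.
- **Re-vote neighborhood.** An overlap group's joint bounding box, padded
  symmetrically to at least s×s and clipped to the image.

## Preprocessing

All segmenters see the same conditioned input: intensities are rescaled to
[0, 1] between the 1st and 95th percentiles (`(d − d_min)/(d_max − d_min)`,
clipped), then locally histogram-equalized (window defaults to 1/8 of the
shorter side). The watershed path additionally repairs hot pixels and
subtracts background:

- **Hot pixels.** A pixel is hot when it strictly exceeds 10× the median
  of its 3×3 neighborhood (center excluded); it is reassigned to that
  median. A median over the 8 surrounding pixels is used as the robust
  local baseline ("k nearest neighbors" is ill-defined on a square grid).
  A zero median flags any positive pixel. The operation is a single pass;
  on realistic images (smooth background, isolated spikes) it is
  idempotent, which the test suite checks.
- **Background.** A smooth field at 75 px scale: bright outliers (above
  median + 2σ) are replaced by the median, the result smoothed with a
  Gaussian of σ = radius/2, and the field subtracted with clipping at 0.
  Only the contract — a slowly varying baseline at the configured scale is
  removed while compact features keep their amplitude — is observable, and
  that is what the tests pin down.
- **Synthetic cytoplasm.** For segmenters needing a cytoplasm channel:
  the nuclear channel is smoothed, Canny edges (standing in for cell
  outlines) are added back, and the sum is re-smoothed to remove the
  intensity dip between nucleus and outline, then rescaled to [0, 1].

## Watershed segmenter

Binarization is Otsu's threshold on the Gaussian-smoothed image
(`outline_sigma`, default 1 px). Markers are maxima of the Euclidean
distance-to-background transform after `spot_sigma` (2 px) smoothing, with
non-maximum suppression at `min_peak_distance` (5 px — half the ~10 px
nucleus diameter). Instances grow by watershed on the negated distance
transform restricted to the foreground, so instances partition the
binarized foreground exactly; instances below `min_area` (4 px²) are
dropped. The same machinery runs on an external [0, 1] probability map in
place of raw intensity.

## Evaluation

Scoring against ground truth builds a sparse IOU matrix: pairs whose
centroids are more than 80 px apart are assumed disjoint and skipped (kept
even for hypothetically larger nuclei, as a documented shortcut; an
independent dense oracle in the test suite confirms the shortcut never
drops a real intersection at benchmark scales). Predictions are processed
in descending best-IOU order (ties by ascending label):

- best IOU ≤ 0.1 (configurable) → false positive;
- best IOU shared, after round-half-even to two decimals, by several
  ground-truth nuclei → **merge error** (an under-segmented blob), counted
  as FP;
- claimed nucleus already matched → **split error** (an over-segmented
  fragment), counted as FP;
- otherwise → true positive, and the nucleus is marked matched.

Ground-truth nuclei left unmatched are false negatives. This makes
under-segmentation visible to recall: a nucleus swallowed by a merged
prediction still overlaps it well, but only one of the swallowed nuclei
can be matched, so the others count as missed. A consequence worth
noting: `2·TP + FP + FN = N_pred + N_gt` is constant in the threshold, so
F1 and Jaccard are provably non-increasing as the IOU threshold rises.

Scores are `recall = TP/(TP+FN)`, `precision = TP/(TP+FP)`,
`F1 = 2PR/(P+R)`, `Jaccard = TP/(TP+FP+FN)`; the identity
`J = F1/(2−F1)` holds for every match result. `expand_labels` grows
nuclear instances into approximate cells by up to d px without merging
(equidistant pixels are resolved by the distance transform's
deterministic nearest-feature choice). Method comparison reports medians
with mean-absolute-deviation error bars and Wilcoxon signed-rank p-values
on the concatenated Jaccard and F1 scores (identical pairs are defined to
give p = 1).

## Synthetic benchmark

The generator renders non-overlapping ellipses (semi-axes 3–5 × 3–8 px,
i.e. ~6–16 px diameters, the imaging-mass-cytometry scale at 1 µm/px) with
a squared-cosine radial intensity profile, peak 50–100 counts over a flat
background of 4 counts, Poisson photon noise, and hot pixels at rate 10⁻⁴
and 20× amplitude (to exercise the repair operator). Placement is bounded
rejection sampling with a 12 px minimum center separation. Everything is a
pure function of the configuration including its seed.

Degradations emulate segmenter failures: *merge* fuses each selected
nucleus with its nearest neighbor and paints a bridging blob
(under-segmentation changes the footprint, not just labels — that is what
lets footprint-based metrics detect it); *split* bisects across the major
axis; *jitter* dilates or erodes boundaries by up to 2 px; *dropout*
deletes; *shift* translates. A region predicate restricts failures to,
e.g., one half of the image.

Three standard fixtures (256², 100 nuclei by default) drive the
acceptance suite: **unanimity** (three identical methods — fusion must be
the identity), **complementary halves** (one method perfect on the left
and merge-degraded at rate 0.5 on the right, one the mirror image, plus a
globally jittered third method whose role is to break the two-method
symmetry of the total-Jaccard vote — with two methods that metric is
symmetric and ties everywhere), and a **noisy trio** (jitter 0.4 / dropout
0.15 / split 0.3) for overlap resolution and neighborhood robustness.

What passing these benchmarks shows: the voting, harvesting and overlap
resolution machinery selects the locally best method and assembles a
consistent mask that outperforms its inputs when their strengths are
spatially complementary. What it does not show: performance on real
tissue, where failures are correlated with morphology rather than
assigned by region, boundaries are genuinely ambiguous, and staining
varies across the slide. The synthetic scenes have no texture, no
spectral noise model, and their degradations are stylized.

Problem sizes used by the default test run and the acceptance script —
256×256 scenes with 100 nuclei (10 replicate seeds for the stochastic
properties), 128×128 scenes with 20–25 nuclei for oracle comparisons —
were chosen so each property is exercised on hundreds of instances while
the whole suite stays fast to iterate on.

## Diagnostics

Without ground truth, masks are compared through population statistics:
nucleus area histograms; a k-nearest-neighbor density
`ρ = N/(πR̄²)` per nucleus with `R̄` the mean centroid distance to the
N = 50 nearest neighbors (note `R̄` is a mean, not an enclosing radius, so
on uniform fields the estimator reads ~9/4 above the true point density —
it is a relative crowding measure, not a calibrated density); and
per-channel intensity catalogs flagging "bright" nuclei above the 68th
percentile of per-nucleus mean intensities (percentile over nuclei, since
nuclei are the population being flagged; a raw-pixel variant is available
via `percentile_over_pixels=True`).

## Known limitations

- Neighborhood tiling is axis-aligned and abutting; a method winning a
  tile by one nucleus takes the whole tile, so very heterogeneous tiles
  can be decided by small margins. The overlap-resolution stage corrects
  the resulting boundary disagreements but cannot mix methods within one
  nucleus (by design).
- The total-Jaccard metric is blind to label topology (it binarizes), so
  it cannot distinguish a split from a perfect mask with the same
  footprint, and it degenerates to a tie for exactly two methods.
- The 80 px IOU cutoff is unsafe for instances larger than ~160 px;
  retained deliberately for fidelity to the evaluation protocol.
- Hot-pixel repair is one pass and not idempotent in the adversarial case
  of adjacent spikes of graded heights.
- I/O supports single 2D planes (TIFF pages, flat Zarr arrays); no OME
  metadata, pyramids, or 3D.
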