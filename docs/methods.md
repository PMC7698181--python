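# Methods

## Model and assumptions

The package detects diabetic-retinopathy lesions by *decomposing* a color
fundus photograph rather than by segmenting it directly.  The central
assumption is that, after appearance normalization, every retinal structure
deviates from the local background with a characteristic **color of
deviation**: the per-channel magnitude of the difference between the image
and a smooth background estimate.  Red lesions and vessels (hemoglobin)
produce green-dominant dark deviations; choroidal/tigroid texture produces
wrap-around reddish-magenta deviations; exudates produce yellow-green
bright deviations; nerve-fiber reflections produce cyan-blue bright
deviations concentrated along the major vessels.  Fixed inclusive HSV boxes
then separate the residual images into layers, and the non-black pixels of
the two candidate layers become lesion candidates.  A feature-based
classifier removes the false candidates the color rules cannot.

This works when (i) preprocessing actually makes deviation colors
consistent across and within images, (ii) vessels are removed before the
dark layers are read (their color is indistinguishable from red lesions),
and (iii) confounder layers are given precedence over candidate layers
where the printed HSV ranges overlap.

## Stage parameters

All sizes scale with the FOV diameter `D`; defaults in parentheses.

* Preprocessing: rim-replacement annulus width (`0.015 D`); illumination
  equalization window (`0.25 D`); 3×3 median denoise; CLAHE on the value
  channel, tile `0.125 D`, clip limit **0.005**.  The clip limit matters
  more than any other preprocessing constant: local histogram equalization
  mixes a background-hued component into every structure's residual, and
  the admixture grows with equalization strength.  At clip 0.01 the
  observed residual hues of dark structures compress to within ~0.03 of the
  red end of the candidate range no matter what the true structure colors
  are; at 0.005 they sit mid-range.  Both the layer separation and its
  robustness to range perturbations depend on this placement.
* Background: per-channel median, window `0.20 D`, computed on a
  downsampled grid whenever the window exceeds 15 px and resized back
  (the background is smooth by construction, so the downsampling loses
  nothing the stage is meant to keep); dark/bright pixels are value-channel
  deviations beyond τ = 0.03 and are filled with the background estimate.
* Vessels: multiscale Hessian line measure `σ² ((−λ₂) − |λ₁|)` on the
  inverted green channel, scales `{0.002, 0.004, 0.008} D` (floored at
  σ = 1 px), hysteresis threshold at half the 99th percentile (low = high/2),
  removal of components that are small (< 0.0005 D²) or small-and-round
  (< 0.002 D² with eccentricity < 0.95 — lesion-sized blobs), then a 1-px
  dilation so the mask spans the full vessel width.  The line measure is
  zero for rotationally symmetric blobs by construction, which is what
  keeps microaneurysms out of the vessel mask.
* Optic disc: saliency product of (a) smoothed grayscale-closed value
  channel (closing fills the dark vessels crossing the disc), (b) a
  center-surround response tuned to disc-sized blobs, and (c) smoothed
  vessel density; the search excludes a `0.1 D` rim band (a macula-centered
  45–50° photograph never shows the disc at the FOV edge).  The radius is
  always `D/12`.
* Fovea: darkest smoothed value-channel point in the vessel-free annulus
  `[1.5, 3.5] R_OD` around the disc, restricted to a ±60° cone toward the
  FOV center; falls back (flagged) to `2.5 R_OD` toward the FOV center.
* Candidates: 8-connected components, minimum area 2 px.
* Features: entropy uses a 64-bin histogram of [0, 1] values, log base 2.
  Circle statistics include black pixels — on a sparse layer the fraction
  of non-black mass near a candidate is the signal.  The perimeter is the
  crack-boundary polygon length (count of exposed unit pixel edges; a
  10×10 square has perimeter 40).  The convex-hull area counts pixels whose
  centers lie inside the hull of the region's pixel centers, so convex
  regions have solidity exactly 1.  The line operator uses lengths
  `{R_OD/4, R_OD/2, R_OD}` (odd, ≥ 3) at 12 orientations, response = mean
  along the digital line minus mean of the L×L surround.  Distances to the
  disc and fovea are in units of `D`.
* Classifier: tanh–logistic perceptron trained by Møller's scaled conjugate
  gradient (σ = 1e-4, initial λ = 1e-6, ≤ 500 iterations, gradient norm
  tolerance 1e-6) on mean cross-entropy plus `reg_lambda` times the mean
  squared weight (biases unpenalized).  Defaults: 51 hidden units / 0.5 for
  red lesions, 55 / 0.4 for exudates; decision threshold 0.5.  Grid search,
  when requested, covers hidden units 1..100 and λ 0..1 step 0.1 with
  stratified 10-fold cross-validation; ties prefer fewer hidden units, then
  smaller λ.
* FCBF: equal-frequency discretization into 10 bins (ties by stable rank),
  relevance threshold δ = 0 (features with SU > 0 enter the scan).  The
  published selected subsets (24 RL / 34 EX indices) are the inference
  defaults; a fresh FCBF run on synthetic data selects different (and far
  fewer) features, which is expected — the published subsets were chosen on
  real clinical images.
* Evaluation: PPVp is counted per predicted region (a region is correct if
  it overlaps any true lesion pixel); a per-pixel variant is available.
  The pathological-image rule uses 30 predicted pixels.

## The synthetic study

The generator (`funduslayers.synth`) renders a circular FOV with an
orange-red background and illumination gradient, a branching vessel tree
converging on a bright disc of radius exactly `D/12`, a dark fovea,
tigroid texture (dark and bright), reflective streaks alongside the widest
vessels, and the three lesion classes, each with an exact pixel mask.
Structures are painted as residuals — per-channel differences against the
local background — with colors designed so that, *after the full
preprocessing chain*, each structure's observed residual lands inside its
intended HSV layer with margin (the generation-time assertion checks the
palette against the ranges).  Scenes default to 256 px on a side
(`D ≈ 240`); drawn sizes floor at 4–6 px so structures stay resolvable —
at a native fundus resolution (`D ≈ 1500+`) the floors are inactive.

The default study (also what `scripts/acceptance.py` runs) trains on 40
images and evaluates on 20 held-out images, half pathological, with
pathological scenes carrying 3–6 microaneurysms, 1–3 hemorrhages and 2–5
exudates.  Under these conditions held-out lesion-level sensitivity and
region-level precision are typically in the low-to-mid 90s (percent) for
red lesions and near 100 for exudates, and lesion-free images are flagged
normal at ≥ 90%.

What the generator does **not** emulate: camera optics and compression
artifacts, pigmentation and pathology diversity across patients, drusen
and laser scars, vessel tortuosity statistics, and graded lesion contrast
distributions.  Passing the synthetic suite therefore demonstrates that
the decomposition, feature, selection, training and evaluation machinery
is implemented correctly and behaves as designed under controlled
conditions — not that the published clinical operating points transfer.

## Known limitations

* A red lesion absorbed into the vessel mask is unrecoverable downstream;
  on the synthetic corpus this costs a few percent of lesion-level
  sensitivity (the dominant failure mode, and inherent to masking vessels
  before candidate extraction).
* Exudate candidates adjacent to major vessels can be captured by the
  reflective-features layer (the printed exudate and reflective hue ranges
  overlap and the confounder takes precedence).
* The range-perturbation robustness of the exudate mask does not hold at
  the reduced synthetic scale: the exudate candidate mask is small
  (~75 px/image), and two exchange terms — disc-edge pixels leaking past
  the exactly-`R_OD` exclusion circle under ~0.3 `R_OD` localization
  error, and equalization-amplified dim noise admitted when the value
  floor drops by 0.03 — each amount to 20–40% of it.  Both shrink with
  larger lesion mass per scene or native resolution.  The red-lesion mask
  passes the same perturbation test (< 15% area change).
* Fovea localization can be displaced by a dark hemorrhage inside the
  search annulus; only the fovea-distance feature degrades in that case.
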