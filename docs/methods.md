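# Methods

This note documents the models and procedures implemented in `spotid`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## The problem

A capture–mark–recapture (CMR) study photographs each captured animal and
records its tag. Tags are sometimes lost; the animal is then re-tagged as
a "new" individual and its capture history fragments. Fragmentation
deflates apparent survival: the model believes the original animal died.
If individuals carry stable, individually unique spot patterns, the
fragments can be re-joined by matching spot constellations across
photographs. The package implements that pipeline end to end and
quantifies its downstream effect on survival estimates.

## Synthetic data: what it emulates and what it does not

All evaluation runs on synthetic data generated by `spotid.synthetic`.

*Rendered photographs.* A fish-shaped body (an ellipse whose half-width
tapers by 45% toward the tail, making orientation recoverable from pixel
statistics) is drawn very dark (grey 30) on a light background (170),
with darker spots (10), Gaussian pixel noise (σ = 6) and mild optical
smoothing. The default frame is 2600×1040 px so the resolution-dependent
spot-blur formula of the baseline operates in the regime it was
calibrated for. Spot radii are 16–25 px on a ≈1900 px body — about 2–3%
of fork length, the scale of real charr spots — and spots keep off the
body outline (flank placement) and at least two radii apart (real spots
are distinct markings). Optional distractors emulate field clutter: a
dark ruler band with bright ticks, large dark debris, a lateral shadow
gradient. Spot centres are sampled in the *body frame*, so one seed
renders the same individual in any pose.

*Constellation pairs.* A re-capture is the original constellation under a
similarity transform (rotation up to ±10°, growth scale 1.0–1.3, a small
translation) plus per-coordinate Gaussian jitter (0.005 fish lengths),
with `floor(n·drop)` spots removed and new spots added away from existing
ones. These are the standard study conditions used in the tests; the
rotation models residual error of the PCA pre-alignment, the jitter
models segmentation noise. Spot turnover rates are free parameters, not
field estimates.

*Populations.* Individuals are all alive at the first occasion; survival
between occasions is Bernoulli(φ) and capture Bernoulli(p); animals never
captured are discarded. Tag loss strikes each recapture independently
with a fixed rate, assigning a fresh persistent identity.

What the generator does **not** emulate: photographic lighting and pose
variation, parr marks on juveniles, non-rigid body bending, segmentation
artefacts correlated along the outline, and observer effects. Passing the
synthetic suite therefore demonstrates the algorithms' correctness and
robustness in a controlled noise regime, not field-level accuracy.

## Baseline segmentation

Body: greyscale → Gaussian blur (σ₁ = 125 px at the reference resolution
of 5184 px, scaled proportionally for other sizes) → keep pixels < 80 →
connected components → the component whose centroid is nearest the image
centre (ties to the larger) → erosion with a small disc. Spots: blur at
σ₂(L) = ((L − 1882)/440)·2 + 19 for image length L (the larger image
dimension), adaptive mean threshold (block = round(4σ₂) forced odd,
offset 2 grey levels), restrict to the body mask, then keep regions with
circularity 4πA/P² ≥ 0.5 and area within [10⁻⁵, 5·10⁻³] of the body
area. The offset default of 2 was chosen because residual noise after
the heavy blur is ≈0.3 grey levels; larger offsets only detect the inner
cores of blurred spots and per-pixel recall collapses. Erosion, block
size and the shape-filter bounds are documented free parameters.

## Segmentation network

One encoder–decoder architecture serves both sub-tasks (body, spots):
encoder blocks of two 3×3 convolutions + ReLU with a constant number of
filters per layer, 50% dropout after each encoder block, 2×2 max-pooling;
a mirrored decoder with nearest-neighbour upsampling and skip
concatenations; a 1×1 sigmoid head. Pixelwise binary cross-entropy, Adam
(lr 10⁻³), He initialization. Inputs are letter-boxed to a square with
black padding; for the spot network the photograph is first cropped to
the body-mask bounding box so small spots survive down-scaling; placement
records invert the geometry exactly. Full-scale defaults are 512 px
inputs, depth 4, 64 filters, 150 epochs of 50 samples with rotation /
shear / zoom / flip / brightness augmentation; `UNetConfig.smoke()` (64
px, depth 3, 8 filters, no dropout) exists for CPU-scale verification,
where the network must overfit two images (loss halves within 50 epochs —
a wiring check, not a generalization claim). Predicted masks are
post-processed by hole filling, morphological closing and retention of
the central component; the binarization threshold is 0.5. The
forward/backward passes are written directly in numpy and verified
against finite differences.

## Normalization

The body mask's pixel coordinates are rotated so the first principal
axis is horizontal; the 180° ambiguity is resolved by requiring a
negative third central moment along the axis (a deterministic convention;
with the synthetic body shape it places the tapered tail at low x).
Coordinates are divided by the mask extent along the axis, so x spans
[0, 1]; y uses the same scale (aspect preserved). Aligned masks are
rasterized into a shared canonical frame (256×128 px, 200 px per unit
length) so any two records' masks can be overlaid directly. Alignment is
stable: re-aligning an aligned point set moves coordinates by < 10⁻⁶.

## Triangle-voting matcher

Spots closer than 3ε are deduplicated (ε = 0.0075 fish lengths by
default, ≈ √2× the re-capture jitter; the positional tolerance from
which the feature tolerances are propagated). Triangles are built from
each spot and pairs among its 25 nearest neighbours, deduplicated by
vertex set; no side-ratio or cosine pruning is applied (linear spot
patterns would be starved). Features per triangle: R = longest/shortest
side, C = cos of the angle between those sides, log perimeter,
handedness, and the angle between the shared vertex, the centroid and
the horizontal. Tolerances follow first-order error propagation from ε:
with F = ε²(1/r₃² − C/(r₃r₂) + 1/r₂²), t_R² = 2R²F and
t_C² = (1−C²)F + 3C²F².

Matching: candidate pairs are triangles inside each other's
k-neighbourhoods (k = 6) in the feature space (R, C, 0.25·angle[rad]) —
the angle is down-weighted so that a legitimate whole-pattern rotation
does not dominate the metric. Candidates must pass the tolerance test
((ΔR)² < t_R,A² + t_R,B², likewise for C), have equal handedness, agree
in centroid angle within 10°, and lie within 1.5 SD of the pair-set mean
log-magnification. Because a global rotation or growth shifts *every*
true pair identically, the angle and magnification windows are then
re-centred on robust (median/MAD) estimates of the global rotation and
log magnification and applied again; without this recentring the matcher
cannot separate true pairs from rogue pairs at the study noise level.
Among surviving candidates, each triangle keeps the partner with the
lowest tolerance-normalized difference.

Voting and assignment: each matched triangle votes for its three vertex
pairs; pairs are swept in descending vote order (ties broken by summed
normalized difference, then index). The literature describes the
stopping rules in one sentence that admits two readings; measured under
the study conditions, the strict reading (stop when votes halve relative
to the *first* pair, stop at the first conflict) caps recovery near 10%
and rejects half the true matches, which is incompatible with the
method's reported usefulness. The defaults therefore use the lenient
reading — stop when votes halve relative to the *preceding* pair (a
vote-cliff detector), skip pairs that would reuse an assigned point —
and both strict variants remain available (`drop_baseline`,
`reuse_policy`).

Verification: the whole procedure is re-run on the matched points. The
strict two-round rule (any shrinkage ⇒ "impossible to match") rejects
≈20% of true matches because typically exactly one weak pair fails to
reproduce; the default instead iterates to a fixed point, pruning
unstable pairs until the matched set reproduces itself (collapse below
three pairs ⇒ rejected). The two-round variant is available as
`verification="two_round"`.

Verification can only shrink the matched set, so the round-1 score
bounds the final score from above; comparisons whose bound is below 3.0
(well under the acceptance threshold) are rejected without running the
verification rounds — a pure compute saving on the overwhelming majority
of database comparisons, which are non-matches.

Score: (number of verified pairs) × (fraction of round-1 votes captured
by those pairs). Self-matches score ≈ n; matched re-captures typically
score 8–25; unrelated constellations ≈ 0–3.5. The open-set acceptance
threshold is 6.5, used as configuration.

## RANSAC matcher

Triangles from each spot's 15 nearest neighbours carry (L₂/L₁, L₁/L₀,
centroid angle, vertex coordinates ÷ 5); matched pairs are strict mutual
nearest neighbours in this 9-dimensional space. Each matched triangle
proposes a least-squares similarity transform from its ordered vertices
(closed-form; collinear sources are rejected). Candidates are screened
on a fixed subsample (≤ 384) of matched triangles: a triangle is an
inlier when the worst of its three vertex reprojection errors is at most
0.01 fish lengths (≈2× the jitter scale and a quarter of the minimum
spot separation — at looser thresholds the best spurious alignment of
two unrelated fish is near-identity and the mask gate loses power). The
85% triangle-inlier consensus acts as the *early-termination* criterion
of classical RANSAC — at the study noise the matched-pair set contains
only 10–40% true pairs even under an oracle transform, so 85% is not an
attainable acceptance bar; candidates that reach it but exceed the
disturbance cap are remembered by smallest disturbance, and otherwise
the best-consensus candidate within the cap is kept. The transformation
disturbance is |rotation°|/60 + |scale − 1|/2 + ‖translation‖₁/2 with a
cap of 1.0. The chosen transform is refined twice against the inlier
vertex pairs of *all* matched triangles (recovered rotations are then
within ≈0.3° and scales within ≈1%). The point-level score is
(inlier fraction of target spots) × (inlier fraction of source spots); a
pair is finally rejected, regardless of score, when the Dice overlap of
the transformed body masks falls below 0.75. The Sampson-style
first-order geometric error reduces, for this transform family, to the
Euclidean reprojection distance, which is what `pair_error` computes.

## Database, ensemble and history correction

Records are grouped into strictly increasing collections; a query is
compared only with earlier records. Rankings sort scored records by
descending score (ties by id) with unscorable comparisons ordered last.
Open-set decisions accept the top record iff its score reaches the
threshold (6.5 for the voting matcher; the RANSAC matcher's threshold is
a tuned configuration value, default 0.2). The ensemble is a simple OR;
when both matchers accept different identities the voting matcher wins
(it has the better false-positive behaviour). Accepted links merge
observed identities via union-find and corrected histories are the
element-wise OR of the fragments; merging is order-independent, and a
link between two records of the same collection is refused. In the
tag-loss studies only first appearances of an observed tag are queried,
against the most recent record of each previously known tag — the
records a field worker would actually need to check.

## CJS survival model

Conditional on first capture, aᵢ,ₜ ~ Bernoulli(aᵢ,ₜ₋₁·φ) and
yᵢ,ₜ ~ Bernoulli(aᵢ,ₜ·p) with uniform(0,1) priors on φ and p. The latent
alive states are marginalized by a forward recursion over the alive/dead
chain (individuals never seen again contribute the standard probability
of remaining unobserved after last capture), grouped over unique
histories for speed; for T ≤ 4 the implementation agrees with exhaustive
latent-path enumeration to 10⁻¹², and likelihoods over all continuation
histories sum to one. Sampling: random-walk Metropolis on
(logit φ, logit p) with the Jacobian correction, four chains, proposal
SD 0.18 (acceptance ≈0.3), first half of each chain discarded. A
latent-state Gibbs sampler (the death time after last capture has a
small categorical full conditional; φ and p then have conjugate Beta
updates) is provided as an independent cross-check and agrees within
Monte-Carlo error. The 95% highest-posterior-density interval is the
shortest sample window containing 95% of draws. With time-constant
parameters the final-interval product φ·p is weakly identified;
simulated studies use ≥ 10 occasions, where recovery is stable (n = 300,
T = 15 recovers φ = 0.78, p = 0.53 within ±0.02–0.03 typically).

## Problem sizes and numerical choices

The test suite runs everything at desk scale, chosen as the smallest
sizes at which the statistical claims are meaningful: re-identification
suites of 40 individuals with 15–60 spots across 5 perturbation seeds;
20 novel-individual queries and 50 unrelated-pair trials for open-set
behaviour; CJS recovery over 20 replicates of n = 300, T = 15; tag-loss
studies of n = 200, T = 12 (noisy constellations) and n = 40 (exact
equality check); 20 default renders for segmentation. The acceptance
script reports the same quantities at further reduced sizes. Determinism:
every stochastic step takes an explicit seed; per-comparison RANSAC
seeds are derived from the record ids by CRC32 so database ordering does
not matter.

## Known limitations

* The matchers assume constellations are pre-aligned within ≈10° and
  that relative growth is ≤ ×1.3 between captures.
* Reflections are deliberately not handled (photographs are always of
  the same flank).
* The mask gate relies on body-outline variation between individuals;
  with near-identical outlines its rejection power drops and the score
  threshold carries the open-set burden.
* The renderer's intensity model is a flat two-level body/background with
  Gaussian noise; real photographs vary in illumination and contrast.
* Survival model: no time-varying parameters, covariates, or explicit
  tag-loss-rate estimation.
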