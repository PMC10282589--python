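# Methods

`retvas` quantifies the retinal vasculature of colour fundus photographs and
measures the agreement of those quantities between two cameras photographing
the same eye — typically a desktop reference device and a handheld one.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Processing model

### Preprocessing

The green plane of the RGB photograph is the working image: haemoglobin
absorbs strongly in green, so vessels have their best contrast there.  The
field of view (FOV) — the illuminated circular area inside the rectangular
frame — is the largest connected component of pixels whose maximum channel
value exceeds a threshold (default 10/255, the surround of a fundus
photograph being near-black), morphologically closed and hole-filled.

Local contrast is restored by contrast-limited adaptive histogram
equalization (CLAHE): the frame is divided into a tile grid (default 8×8),
each tile's 256-bin histogram is clipped at a fraction of the tile pixel
count (default 0.01), and every pixel is remapped by bilinear interpolation
between the four nearest tile mappings.  One decision was open: whether the
tile histograms should see the black surround.  They do not — histograms are
accumulated from FOV pixels only, while the resulting mappings are applied
to the whole frame.  This keeps the surround from compressing the in-FOV
dynamic range in edge tiles.  The implementation is in-package because no
installed CLAHE accepts a pixel mask for its histograms.

### Vessel segmentation

Two scale-space features are computed from the equalized green image by
Gaussian-derivative convolution at a ladder of scales (default the √2 ladder
{1, 1.4, 2, 2.8, 4, 5.7, 8} px, spanning rendered vessel widths of roughly
2–10 px): the gradient magnitude and the maximum principal curvature of the
Hessian — the eigenvalue of larger magnitude, signed so that dark ridges
score positive.  Each response is normalized by σ^γ (γ = 1 by default) and
the per-pixel maximum over scales is kept.  With this normalization the
curvature response to a Gaussian ridge of profile sd σ₀ peaks at scale
σ₀/√2, so the ladder covers the target widths with a margin.

The binary mask comes from a multi-pass region growing in the
two-dimensional (standardized) feature plane:

1. **Seeds.** Background: pixels with both features below their FOV median.
   Vessel: curvature above the 95th FOV percentile.
2. **Growth.** Over three passes with relaxation k ∈ {1, 2, 3}, each class
   repeatedly annexes unlabelled 8-neighbours whose features lie within
   k·sd of the class's running mean.  The admission spread is the global
   FOV feature sd (unity after standardization) for both classes: a class's
   own sd would either collapse (background seeds are compressed below the
   median) or explode (vessel seeds are a heavy upper tail), and an
   inflating band runs away.  Pixels admissible to both classes go to the
   nearer class mean.
3. **Completion.** Remaining unlabelled pixels join the nearer class mean.
4. **Dark-vessel gate.** Vessels are intensity minima, so the final vessel
   set is intersected with pixels darker than the FOV grey median.  The
   ridge response is wider than the vessel (scale-space smearing), and
   without the gate the mask carries a bright flank rim that inflates
   vessel density — asymmetrically between arms of different vessel width,
   which biases paired differences.

An image with no usable vessel seeds yields an empty mask with a warning;
QC reads this as gross under-segmentation.  On clean synthetic reference
renders the chain reaches TPR ≈ 0.98 at FPR ≈ 0.004 against the generator's
mask truth.

### Optic-disc detection and masking

The optic disc (OD) must be removed before graph metrics so vascular trees
are rooted rather than joined across the disc.  Detection: (i) a square ROI
(side 0.30 of the FOV equivalent diameter) is centred on the brightest
box-filtered spot of the mean-of-channels image; (ii) the Shannon entropy of
each RGB channel's 256-bin histogram inside the ROI is measured and the
maximal-entropy channel is selected — "most informative" operationalized as
maximum entropy, an open choice documented here; (iii) a circular Hough
transform over a Sobel edge map votes for centre and radius (search range
0.04–0.10 of the FOV diameter, integer-pixel centres, 1-px radius steps).
The circumference-normalized accumulator peak is the confidence; below a
floor of 0.25 the image is flagged "OD not found" and counted unevaluable.
Ties break deterministically: larger radius, then smaller row, then smaller
column.  Vessel pixels within (1 + margin)·radius of the centre are then
removed; the margin (default 0.1) is exposed because the field protocol the
package mirrors does not state one.

### Skeleton graph

The OD-masked vessel mask is thinned to a 1-px, 8-connected medial skeleton
(boundary pixels removed without breaking connectivity).  Node taxonomy
follows the degree convention: degree 1 terminal, degree 3 bifurcation,
degree 4 crossing.  Raw thinning emits clumps of junction pixels; 8-connected
clusters of pixels with ≥3 skeleton neighbours collapse to a single node at
the cluster pixel nearest its centroid.  Consequences, both deliberate:

* a crossing that thins into an elongated junction near a bifurcation
  cannot be resolved as a degree-4 event and is read as bifurcation(s);
* up to ~2 px of chain length is absorbed when a collapsed cluster's
  flanking edges are spliced.

Edges are walked along degree-2 chains; length is the chain metric (1 per
orthogonal, √2 per diagonal step) — the alternative, raw pixel count, was
rejected because it overweights diagonal runs by √2.  Isolated closed loops
become a single edge anchored at a synthetic `cycle` node.  Terminal spurs
shorter than 3 px (default), a thinning artefact, are pruned to a fixed
point, which makes pruning idempotent; a free-standing terminal-to-terminal
edge is never deleted.  Degrees above 4, rare thinning artefacts, count as
crossings in the metrics.

### Morphometrics

Per image: vessel density (percentage of FOV pixels that are vessel — by
default from the *unmasked* vessel image, since the OD masking exists for
graph rooting; an `exclude_od` switch is provided), the edge-length list and
its normalized histogram (Freedman–Diaconis bins by default), external nodes
EN (terminals), internal nodes IN (bifurcations + crossings), edge count,
and the box-counting fractal dimension.

FD is computed on the skeleton, not the filled mask — the quantity of
interest is the complexity of the branching pattern, not vessel calibre.
Grids of mesh s = side/2^k (k = 1..7, side the longer bounding-box side,
anchored at the bounding-box origin, truncated below 2 px) are laid over the
skeleton; N(s) counts occupied boxes; FD is the least-squares slope of
log N(s) against log(1/s).  Mesh sizes where N(s) saturates at the skeleton
pixel count carry no scaling information and are excluded from the fit (the
standard plateau correction).  Anchors: a straight line fits slope 1.000, a
filled square 2.000, a Sierpiński gasket log 3/log 2 ± 0.05.

### Quality control and curation

The field protocol's evaluability judgement is replayed with automated
proxies; both flags also accept manual overrides.

* **Evaluability grid**: anchored on the detected disc, reaching 6.5 disc
  radii toward the macula, truncated at the vertical extremes (default 5%
  of the frame height); two quadrants (superior/inferior).  A quadrant is
  evaluable when some skeleton pixel reaches within 10 px of the outer arc
  and quadrant vessel density exceeds 1%; an image is evaluable with ≥1
  evaluable quadrant.
* **Under-segmentation**: with ground truth, recovered fraction
  |mask ∩ truth|/|truth| < 3/4.  Without truth, a coverage proxy: fewer
  than 3/4 of 12 angular FOV sectors contain skeleton pixels (ties pass).
* **Over-segmentation**: mask components that are blob-like rather than
  curvilinear (solidity > 0.5, area > 400 px²) exceeding 15% of mask area.

Curation keeps the pairs in which neither arm carries either flag and
reports a contingency of failures by arm.

### Agreement statistics

Differences are oriented reference − handheld throughout.  Per metric and
stratum (all pairs; curated pairs): Bland–Altman mean difference and limits
of agreement at ±1.96 sd of the differences (n−1 denominator); the
Bradley–Blackwood joint test of equal means and variances,
F = [(Σd² − SSE)/2]/[SSE/(n−2)] from the regression of differences on pair
means, df (2, n−2); and a separate regression of differences on *sums* with
a two-sided t-test on its slope (the two regressions are equivalent up to
slope scaling; both are reported because both conventions circulate).
Exact arm agreement (d ≡ 0) returns p = 1 by convention.  Edge-length
distributions are pooled per arm across the stratum's images and compared
with the two-sample Kolmogorov–Smirnov test (exact for small samples).

Categorical comparisons: conditional exact Fisher test for r×c tables
(r, c ≤ 3) by full enumeration of tables with fixed margins, summing the
probabilities of tables no more probable than the observed one; exact
McNemar test p = min(1, 2·P(X ≤ min(n01, n10))), X ~ Bin(n01+n10, ½); pooled
two-sample z-test of proportions.  All p-values are two-sided; no
multiple-testing correction is applied, matching common practice for this
design.  Monte-Carlo calibration at n = 56 shows both regression-based
tests holding their 5% size within ±2 points.

## Synthetic paired data

No fundus photographs ship with the package; the generator stands in for
them and defines the test conditions.

**Vessel tree.**  A planar rooted forest grows from the optic-disc rim
(disc placed nasally at 0.52 FOV radii; macula side opposite): per branch a
4-segment polyline with Gaussian heading jitter (sd 7°), terminating or
bifurcating with probability `branch_prob` until `depth_max`.  Child widths
taper by 0.8 per generation, lengths by 0.85; bifurcation angles are drawn
in [20°, 50°].  Defaults (8 roots, branch probability 0.85, depth 6, root
width 10 px at the 768×768 default raster) give a rasterized truth density
near 13% of the FOV, the value typical of healthy eyes on desktop cameras
and the regime the paired design assumes.  Rasterization strokes each
polyline with half-width (w−1)/2 so a width-w stroke spans exactly w pixels.

**Rendering.**  Background is a radial orange gradient with a bright,
rimmed disc, lightly smoothed; vessels subtract a fixed depth (default 60
grey levels in green) from the local background, so the rendered
vessel/background contrast is exact by construction.  Degradations apply in
a fixed order — erode vessels, vignette, contrast about the FOV mean,
brightness, Gaussian blur, additive Gaussian noise, clip to [0, 255] — so
any single knob is verifiable in isolation.

**Device arms.**  The reference profile is the identity.  The default
handheld profile (brightness 0.85, contrast 0.82, blur σ 0.8 px, noise sd 2,
vignette 0.45, vessel erosion 1 px) plus a per-eye ±25% uniform jitter on
its brightness/contrast gains emulates the underexposed, variable captures
of handheld photography.  Under these defaults the under-segmentation flag
fires on roughly a third of handheld images — the failure rate regime the
paired-comparison design has to survive — and the measured handheld density
runs 2–4 points below the reference arm.  The 1-px vessel erosion gives the
handheld arm a density deficit computable *exactly* from the two masks,
which is what the parameter-recovery tests use as truth.

**What the generator does not emulate** — and hence what passing tests do
not certify on real data: real optics (PSFs, chromatic aberration, specular
reflexes), pathology (lesions, haemorrhages, drusen), pigmentation
variation, tortuosity statistics of real vasculature, compression
artefacts, and inter-eye anatomical correlation.  The synthetic study
validates the machinery (segmentation, graph extraction, statistics,
curation arithmetic) under controlled truth, not clinical performance.

## Numerical choices and degenerate inputs

* Determinism everywhere: all randomness flows from integer seeds through
  `numpy.random.default_rng`; per-eye sub-seeds derive from a
  `SeedSequence` spawn of the master seed.  Identical profiles and seeds
  render bit-identical images; the synthetic and folder pipelines share one
  code path (the FOV is always re-detected from the render).
* Box-counting: float mesh sizes, `floor(coord/s)` box indices; fit
  excludes saturated meshes; empty skeletons are an error, as are fewer
  than 4 mesh sizes.
* Region growing statistics use running sums (exact, order-independent
  within a sweep); admission conflicts resolve by feature distance.
* Hough, quantile, and curation tie-breaks are all fixed and documented in
  the code; `prune_spurs` and CLAHE are deterministic by construction.
* Constant rasters: CLAHE maps them to a constant; features are ~0 up to
  the truncated-kernel residual (order 10⁻³ per grey level), which the
  seed-quantile logic treats as featureless.

## Problem sizes used in the distributed checks

The test suite and worked examples run at the package's default 768×768
raster where absolute geometry matters (disc radius, grid reach, deficit
recovery over 30 pairs) and at 256–384 px for property sweeps (degradation
monotonicity over 10 eyes, pipeline determinism over 5 pairs), a scale at
which every stage is exercised end to end.  Statistical calibrations use
2000 replicates at n = 56 pairs.

## Known limitations

* The region-growing schedule is an explicit reconstruction of a
  "multiple-pass" description, not a reimplementation of any published
  code; its seed quantiles and relaxation ladder are configurable.
* Junction-cluster collapse slightly shortens edges and can demote
  near-coincident crossings to bifurcations (see above).
* The truth-free under-segmentation proxy (sector coverage) is coarse: it
  detects missing regions, not uniformly thinned masks.
* The Fisher enumeration is exponential in table size; it is restricted to
  r, c ≤ 3, which covers the curation contingencies produced here.
* FD estimates on very sparse skeletons (a handful of edges) sit at the
  line anchor by construction and carry little information.
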