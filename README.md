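# retvas

Retinal vessel morphometrics and paired device-agreement analysis for colour
fundus photographs.

Handheld fundus cameras promise cheap, portable retinal screening, but their
images are darker, noisier and less consistent than those of desktop
machines.  Before vascular biomarkers measured on handheld images can be
trusted, the question is quantitative: *do the numbers agree with those from
a reference camera photographing the same eye?*  `retvas` implements the
full measurement chain needed to answer it — automatic vessel segmentation,
optic-disc masking, skeleton-graph morphometrics, segmentation-quality
curation — and the paired agreement statistics on top, together with a
synthetic paired-fundus generator that provides ground truth for validating
every stage.  It is written for researchers in ophthalmic imaging and
telemedicine who need a reproducible, testable desk-scale pipeline rather
than a clinical product.

## What it computes

Per image:

* **Vessel density** — % of field-of-view (FOV) pixels segmented as vessel.
* **Edge lengths** — the distribution of skeleton-graph segment lengths
  (chain metric: 1 per orthogonal, √2 per diagonal step).
* **Node counts** — external nodes EN (degree-1 terminals) and internal
  nodes IN (degree-3 bifurcations + degree-4 crossings), plus edge count.
* **Box-counting fractal dimension** — cover the vessel skeleton with grids
  of mesh *s*, count occupied boxes *N(s)*, and estimate

  FD_box = lim_{s→0} log N(s) / log(1/s),

  approximated by the least-squares slope of log N(s) vs log(1/s).
  FD lies between 1 (a line) and 2 (a plane-filling set).

Per paired study (reference arm vs handheld arm, same eye):

* **Bland–Altman** mean difference (reference − handheld) and limits of
  agreement at ±1.96 s.d. of the differences;
* **Bradley–Blackwood** F-test (regression of differences on pair means)
  jointly testing equal means and equal variances, plus a regression of
  differences on sums testing proportional bias;
* **Kolmogorov–Smirnov** comparison of pooled edge-length distributions;
* exact **Fisher**, exact **McNemar** and pooled **two-proportion z** tests
  for evaluability/curation contingencies;
* a curation step that drops pairs with under-segmented (< ¾ of vessels
  recovered) or over-segmented (lacework patches) masks, reporting both the
  unsupervised and the curated strata.

The segmentation itself is multi-scale: γ-normalized gradient magnitude and
maximum principal Hessian curvature, maximized over a √2 scale ladder, feed
a multi-pass region growing that labels every FOV pixel vessel or
background.  The optic disc is located by per-channel Shannon entropy in a
bright ROI followed by a circular Hough transform, and masked out before
graph extraction.  See `docs/methods.md` for the full model description and
the design decisions.

## Worked example

Run a complete synthetic paired study — 8 eyes, both arms rendered from the
same ground-truth vasculature, the handheld arm degraded and jittered — and
read the agreement report:

```
retvas run-all --n-eyes 8 --seed 3 --out demo_run
```

`demo_run/agreement.csv` from this exact command:

```
           metric      stratum  n  mean_diff  sd_diff  loa_low  loa_high  p_joint  p_slope
   vessel density unsupervised  8      4.383    1.250    1.933     6.834    0.000    0.378
   external nodes unsupervised  8    -99.750   90.269 -276.677    77.177    0.000    0.000
   internal nodes unsupervised  8     18.750   12.926   -6.584    44.084    0.017    0.404
            edges unsupervised  8    -17.375   47.812 -111.086    76.336    0.471    0.434
fractal dimension unsupervised  8      0.004    0.031   -0.057     0.065    0.761    0.522
   vessel density      curated  3      3.101    0.909    1.319     4.883    0.078    0.217
   external nodes      curated  3     -7.667    2.887  -13.325    -2.009    0.174    0.404
   internal nodes      curated  3     11.000    5.568    0.087    21.913    0.263    0.484
            edges      curated  3     16.667    8.737   -0.458    33.791    0.242    0.422
fractal dimension      curated  3     -0.017    0.005   -0.027    -0.006    0.002    0.006
```

Reading it: the handheld arm measures vessel density 4.4 points lower than
the reference on average (`mean_diff`, reference − handheld), a bias the
Bradley–Blackwood test finds decisive (`p_joint` < 0.001) with no evidence
of proportional bias (`p_slope` = 0.38).  Under-segmented handheld masks
fragment the skeleton, which *inflates* their terminal count — hence the
negative external-node difference.  `curation.json` for the same run shows
the mechanism: of 8 pairs, 5 were eliminated for handheld-arm
under-segmentation, leaving 3 curated pairs whose density bias (3.1 ± 0.9)
is tighter than the unsupervised one.  Fractal dimension barely moves
(|Δ| ≤ 0.02): FD is robust to photometric degradation as long as the major
trees are recovered.

The run directory also holds `metrics.csv` (per image), `qc.csv` (flags and
TPR/FPR against ground truth), `bland_altman_points.csv` (per-eye mean vs
difference, ready for plotting) and `config.json`, the resolved
configuration from which the whole run regenerates byte-identically.

Library use mirrors the CLI:

```python
import retvas

pairs = retvas.make_paired_dataset(8, seed=3, hh_jitter=0.25)
img_ref, img_hh, truth = pairs[0]
mask = retvas.segment_vessels(img_ref)
graph = retvas.skeleton_to_graph(retvas.skeletonize(mask))
fd = retvas.fractal_dimension(retvas.skeletonize(mask)).fd
```

Existing image folders are processed through a manifest CSV
(`eye_id, arm, path`) with `retvas compare manifest.csv --out report/`;
ground-truth-free QC proxies are used there.

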