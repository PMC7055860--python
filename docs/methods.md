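# Methods

`myoseg` measures the size, shape and myosin-heavy-chain (MyHC) type of every
muscle fiber in a transverse immunofluorescence section.  Its input is a
multi-channel image with one laminin channel (basement membrane, marking each
fiber's boundary) and up to three MyHC channels marking type I, IIa and IIb
fibers.  The pipeline has four stages: preprocessing, machine-learning
boundary segmentation, thresholding/particle extraction, and ROI-overlay
typing.  This note records the model, its assumptions, every tunable that
matters, and the numerical choices made where the design was open.

## Preprocessing

The laminin channel is contrast-stretched by percentile clipping
(`saturated_fraction`, default 0.35% — the common histogram "auto" default;
the fraction is split between the two tails), converted to 8 bits by mapping
the current `[min, max]` linearly onto `[0, 255]` (a constant plane maps to
0), and convolved with a fixed 5×5 high-pass matrix: every coefficient −1
except a centre of 24 and a single 0 in the bottom-right corner, so the
coefficients sum to 1 and constant regions are preserved while thin bright
boundaries are amplified.  The matrix is applied as a correlation (no kernel
flip) with replicate edge padding; output is clipped back to `[0, 255]`
(clipping, rather than rescaling, keeps the boundary/interior contrast
absolute).  The image is then cut into an n×n grid (`grid_factor` n ∈ [2, 5],
default 4 → 16 tiles); when a dimension is not divisible by n the last
row/column of tiles absorbs the remainder, and stitching is the exact inverse.

## Boundary segmentation

Two random-forest pixel classifiers are applied in sequence.  The *primary*
classifier is trained on a few hundred sparsely annotated pixels of two
classes — fiber boundary vs intra-fiber space — of the preprocessed laminin
plane.  Its output is a probability map rendered to 8 bits with the
dark-boundary convention `value = round(255·(1 − P(boundary)))`.  The
*iterative* classifier makes the same two-class call but is trained on the
primary classifier's probability maps, so it cleans residual noise and
sharpens boundary continuity.  A domain tag ("raw" vs "probmap") is stored
with each classifier and checked at call time so the two stages cannot be
swapped silently.

Per-pixel features, in fixed order: raw intensity; Gaussian blur at σ ∈
{1, 2, 4, 8, 16} px; Sobel gradient magnitude at each σ; the two Hessian
eigenvalues (larger, smaller) at each σ; difference of Gaussians for each
adjacent σ pair; grayscale maximum filter at radii {1, 2} px — 27 planes with
the defaults.  The dyadic σ ladder covers boundary widths seen at 10×
magnification; all σ are in pixels.  Forests default to 200 trees with
√n_features candidate features per split and a fixed seed from the
configuration, so a full train → classify → iterate run is bit-reproducible.

Tiles are classified one at a time to bound memory, but each tile is
classified on a window enlarged by 32 px of surrounding image (clipped at the
border) and cropped back to the tile core before stitching.  The margin
matters: the σ=16 features need real context, and classifying bare tiles
produces boundary gaps exactly at seam lines, which merge adjacent fibers
("2 as 1" errors).  No predictions are blended; tiles stay disjoint.

## Fiber extraction

The stitched probability map is blurred (Gaussian, `gaussian_sigma_post`,
default 2 px) and binarized at the Kapur maximum-entropy threshold of its
256-bin histogram: the split t maximizing the summed Shannon entropies of the
two normalized class histograms.  Splits leaving either class empty are
invalid and ties break to the smallest t.  The implementation accumulates the
class sums forward and backward (never as cumulative differences), so
near-empty tails keep full floating-point precision and the result agrees
exactly with an exhaustive scan.  Pixels at or below t are boundary (black);
8-connected white components become candidate fibers, and components touching
the image border are dropped by default (`exclude_edge_fibers`).

Morphometrics per ROI:

* **area** — pixel count × pixel area;
* **perimeter** — length of the outer 0.5-level marching-squares contour
  (which runs along pixel cracks) after a 3-point circular moving-average
  smoothing.  A raw staircase contour overestimates smooth boundaries by
  ~5%, which would push a digitised disk's circularity down to ~0.90; the
  one-step smoothing removes most of that bias (disk ≈ 0.98, 60 px square
  within 2% of π/4, 45°-rotated square near exact);
* **circularity** — 4πA/P², capped at 1.0 (discretisation can overshoot);
* **Feret / min Feret / Feret angle** — from the convex hull of boundary
  pixel centres: maximum pairwise vertex distance; rotating-calipers minimum
  width over hull edges; orientation of the maximal chord in [0°, 180°);
* **roundness** — 4A/(π·Feret²); **solidity** — area over convex-hull area
  (the hull area of pixel centres is rim-corrected by half a perimeter so a
  convex blob scores 1.0).

Four closed-interval gates remove non-fiber objects, checked in a fixed
order with the first failing gate reported: area 50–6000 µm² (interstitial
specks, vessels), circularity 0.3–1.0 (merged "2 as 1" dumbbells), minimum
Feret 5.5–60 µm (endomysial strips), Feret aspect ratio 1–4 (elongated
artifacts).  The defaults suit adult control muscle; dystrophic, regenerating
or neonatal tissue needs wider gates.  Gates are applied to pre-expansion
ROIs; kept ROIs are then dilated by a Euclidean disk of `roi_expand_px`
(default 2 px) so the mature ROI reaches the laminin-demarked boundary, and
morphometrics are re-measured on the expanded pixel set (a flag column
records this).  Gates are not re-applied after expansion, but post-expansion
values are logged so the difference stays visible.  Expanded ROIs may overlap
along shared boundaries; that is intended.

## Fiber typing

Per MyHC channel, each kept fiber's mean intensity is computed over its
expanded ROI (mean, population SD, min, max and mode are all reported).  A
per-channel threshold — manual from the configuration, or `auto` via the
Otsu split of the per-fiber mean-intensity distribution (an extension; the
classical flow is a manual prompt over the displayed histogram) — defines the
positive set of each type by strict `mean > threshold`.  A Freedman–Diaconis
histogram of the means is attached to every threshold for inspection.

Mixed and pure types are resolved by the black-and-white mask/modal
procedure: a positive set is rendered as black (0) ROIs on a white (255)
background; probing another set's ROIs for a modal value of 0 identifies
overlaps.  Pairwise probes give the mixed sets I/IIa, I/IIb, IIa/IIb; probing
the I set over the IIa/IIb-mixed mask gives I/IIa/IIb; each pure set is its
positive set stripped (modal 255) of its merged mixed masks; and IIx — for
which no antibody channel exists — is called by elimination: every gated
fiber left white by the merged mask of all three positive sets.  Masks are
built from pre-expansion ROIs, which are disjoint, so the modal procedure is
provably identical to direct set algebra (the test suite checks exact
agreement on 1,000 random membership tables); an exact black/white tie in a
probe resolves to 0, matching first-bin integer-histogram mode behaviour.
The eight final labels partition the gated fibers — the partition is
validated on every run — and IIx-containing hybrids (IIa/IIx, IIx/IIb) are
out of reach by construction, a stated limitation of the four-channel design.
I/IIb and I/IIa/IIb calls are biologically rare and sensitive to staining
irregularities but are kept so that no fiber is counted twice.

## Reporting

The run summary gives counts, proportions (they must sum to 1), mean CSA
overall and per label, and "total section size", which this package defines
as the area of the tissue mask — laminin channel blurred at σ=5 px, Otsu
threshold, holes filled, largest component kept — in mm², with the sum of
fiber CSAs alongside for transparency.  Histogram bin widths follow the
Freedman–Diaconis rule 2·IQR·n^(−1/3) with linearly interpolated quantiles;
a zero IQR falls back to range/√n with a warning.  The CSA section map paints
each fiber with a monotone colormap (viridis) over the observed CSA range.

Stain quality is the ratio of laminin intensity on boundary pixels to
intra-fiber pixels: the image is split into a 3×3 panel of locations, the
ratio of medians is taken wherever both classes have enough pixels, and the
overall ratio is the median over locations (medians resist hot pixels and
staining non-uniformity; the panel emulates measuring at several spread
locations).  Intra-fiber sampling is restricted to an eroded tissue mask so
the dark background around the section cannot bias the denominator.  A ratio
strictly above 5 is "good", at or below 5 "poor"; the label is decided on the
ratio rounded to two decimals — the reported precision — so a section sitting
exactly at the cutoff classifies as poor instead of flipping on ±0.01 noise.

## Synthetic sections

The generator emulates what the pipeline must handle, with full ground
truth.  Target fiber areas are drawn from a lognormal (median 900 µm²,
σ_log 0.35 — typical of adult mouse gastrocnemius at our defaults); an
elliptical tissue region is sized to hold exactly their sum; seeds are placed
by radius-aware dart throwing and a Laguerre (power) diagram tessellates the
tissue, with ~30 reweighting iterations (the first 12 also relax seeds toward
cell centroids, Lloyd-style) so realized cell areas track the targets.  Cell
cracks are widened into a laminin boundary band (default 3 px) at
`stain_ratio` (default 6) times the intra-fiber level; the tissue rim gets a
full-width band, as the basement membrane wraps the outermost fibers.  Each
fiber samples a type from the requested proportions (defaults
I/IIa/IIb/IIx = 0.10/0.30/0.40/0.20); a small fraction (default 1%, matching
the ~0.7% hybrid rate seen in real sections) lights two (rarely three)
channels.  MyHC channels render positive interiors bright (12000) over a
tissue background (1000); Gaussian noise (SD 50 ≈ 2.5% of the intra-fiber
laminin level) is added everywhere; rendering is 16-bit by default to
exercise the 8-bit conversion path.  Ground truth returns each cell's
polygon-area CSA (pixel count of its Laguerre cell, i.e. up to the boundary
midline), memberships, final label, and a per-pixel boundary/interior class
map from which sparse training annotations are sampled.

What the generator does *not* emulate: point-spread blur, vignetting,
stitching seams, staining gradients, tissue damage, regenerating
(embryonic-MyHC) fibers, or non-convex fiber profiles.  Passing the recovery
tests therefore shows the pipeline's logic is correct and robust to additive
noise and boundary contrast down to ratio 3, not that it reaches the same
accuracy on arbitrary real tissue.

## Detection scoring

Predicted fibers are matched to ground truth greedily by IoU (threshold 0.5)
between the mature (expanded) ROI and the true interiors.  Unmatched
predictions are false positives, subclassified "2 as 1" (spans ≥2 truths with
union-IoU ≥ 0.5), "1 as 2" (sibling duplicate of a matched truth) or
"non-fiber"; unmatched truths are false negatives; both rates use the
ground-truth fiber count as denominator.  CSA error is the signed relative
difference between a matched record's reported (post-expansion) CSA and the
true cell CSA.  The reported CSA sits ~9% below the cell area with the
default 2 px expansion against a 3 px boundary band — the expansion factor is
exactly the knob a user would raise to close that gap on their own stain.

## Problem sizes

The recovery experiment trains on one 1024×1024 section (~300 fibers,
400 annotated pixels per class) and evaluates three held-out good-quality
sections and one poor-quality (ratio 3) section at the same scale — enough
fibers (~900 good, ~300 poor) to resolve rates well below 1.5% while keeping
a full run in a few minutes on one CPU core.  Unit tests use 512×512 sections
with ~70 fibers.

## Known limitations

* Watershed-style splitting of genuinely merged fibers is deliberately out of
  scope; the circularity gate excludes most "2 as 1" objects instead.
* Typing thresholds assume a bimodal per-fiber mean-intensity distribution;
  `auto` misbehaves when a channel has (almost) no positive fibers.
* The morphometric gate defaults target healthy adult mouse muscle.
* IIx is inferred by elimination, so regenerating fibers without I/IIa/IIb
  staining are indistinguishable from IIx.
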