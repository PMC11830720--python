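# Methods

This note records the measurement conventions, the model behind the
synthetic data, the numerical choices, and what the test suite does and
does not demonstrate.

## Geometry and zones

The optic disc is reduced to a scalar: center = mask centroid, diameter
= `2·sqrt(area/π)` (equivalent-area circle). An elliptical or noisy
disc mask therefore yields a reproducible "disc diameter" (DD) without
boundary-tracing heuristics. Radial distances are measured from the
fitted circle's edge, `(d − R)`, not from the raw mask boundary. Zones
are half-open outward — A = (0, 0.5] DD, B = (0.5, 1] DD,
C = (1, 2] DD beyond the edge — so a point exactly on a boundary
belongs to the inner zone and the labels partition the plane.

## Centerline graph

Masks are thinned with a topology-preserving skeletonization. Skeleton
pixels with one 8-neighbor are endpoints; pixels with three or more are
junction pixels. Three cleanup passes make bifurcation counts stable on
thick vessels, whose junctions smear over several skeleton pixels:

1. adjacent junction pixels collapse to one centroid node;
2. tiny cycles (self-loops, or the shorter of two parallel edges)
   below `junction_merge_factor` (default 1.5) × local width are
   thinning artifacts and are removed;
3. junction nodes joined by a bridge shorter than the same threshold
   merge, and every incident polyline is extended to the merged node so
   no arc length is lost.

Degree-3 nodes are bifurcations. Degree-4 nodes are flagged
*crossing-suspect* — in a fundus projection an artery/vein crossing and
a trifurcation are indistinguishable without photometric cues — and are
excluded from branch statistics unless
`count_crossings_as_bifurcations` is set. Degree ≥ 5 nodes are skipped
with a log line.

Terminal spurs shorter than `spur_factor` (default 3) × local width are
pruned; thinning artifacts scale with caliber, so a fixed-µm threshold
would over- or under-prune depending on vessel size. Pruning is
idempotent.

**Width.** Per-point caliber is the classical proxy: twice the Euclidean
distance transform of the mask at the centerline, in µm. Two numerical
refinements matter at vessel scale (3–15 px): the EDT runs on a
2×-upsampled mask, halving the lattice quantization of distances, and
is sampled through a 3×3 local maximum because the thinned centerline
can sit a pixel off the medial axis. On strokes of known drawn width
(straight and meandering, all orientations) the estimator is unbiased
within ±0.15 px; the plain integer-grid 2·EDT is off by up to ±1 px
with orientation-dependent sign, which measurably distorts the
asymmetry index of thin daughter branches.

**Length.** Digital 8-connected paths overestimate Euclidean length by
up to ~8% (staircase effect). Arc lengths are therefore evaluated on an
endpoint-preserving moving average of the polyline
(`smooth_window_px = 7`); the window shrinks near the ends so chords —
hence tortuosity denominators — are untouched.

## Branch statistics (Zone C)

Daughter directions are least-squares line fits over the arc window
`[w_parent, w_parent + max(5 px, w_daughter)]` of chain length from the
node. The inner offset skips the junction region, where the skeleton of
two merging thick strokes bends toward their bisector; without it the
measured angle is biased upward by 10–20°. The bifurcation angle is the
angle between the two daughter directions (not parent–daughter angles).

The parent at a degree-3 node is the incident segment whose far end
lies closest to the disc center: retinal trees are rooted on the disc
margin, and this rule is robust where the widest-segment rule fails
(daughter and parent calibers differ by only ~11% under a cube-law
split, within raster width noise). Without disc information the widest
segment is used.

Asymmetry is the squared-caliber index `100·(1 − (w_s/w_l)²)` of the
daughter widths, each summarized as the median per-point caliber beyond
one parent-width of arc from the node (junction bulges inflate the
first few points). `branch_avg` is the mean count of Zone C
bifurcations per connected tree that approaches the disc within
`root_margin_dd` (0.25 DD) and reaches Zone C; trees with zero Zone C
bifurcations count as zeros. A per-image total is available via
`branch_avg_mode='total'`. When Zone C holds no bifurcation at all,
angle/asymmetry/branch averages are all missing (blank cells).

## Lengths, tortuosity, densities

Zone C length statistics are computed over the maximal Zone C runs of
each node-to-node centerline segment: `length_avg` is the mean smoothed
arc length (µm), `curvature_avg` the mean arc-chord ratio (runs with
numerically zero chord are excluded with a warning). Densities divide
the artery∪vein mask (area density) and the union of centerlines
(length density) by the analysis region — the full raster by default;
a config option restricts to the disk reaching 2 DD beyond the disc
edge. The defaults follow the reading that "overall" densities refer to
the whole field of view; both choices are one config key apart.

## Fractal spectrum

Box counting uses a single origin-anchored dyadic ladder from
`min(h, w)//4` down to 4 px (deterministic; `grid_offsets` enables
offset averaging for robustness studies). With per-box mass fractions
p: D0 is the slope of log N(ε) vs log(1/ε); D1 the slope of Σp·log p vs
log ε (the q→1 limit, avoiding the 1/(q−1) singularity); Dq =
τ(q)/(q−1) with τ(q) the slope of log Σp^q vs log ε. The singularity
length is α_max − α_min with α = dτ/dq evaluated numerically over
q ∈ [−3, 3] in steps of 0.5; negative-q moments use occupied boxes
only, and any q whose τ fit falls below R² = 0.90 is dropped (all
dropped ⇒ missing). Regression R² is always reported in the
diagnostics.

On exact fixtures the estimator is sharp: line/square/Sierpinski
capacity dimensions within ±0.05 of 1 / 2 / log3/log2 at R² ≥ 0.97, and
the binomial-cascade spectrum width matches its closed form within the
test tolerance. On sparse real centerline images the finite-size
ordering D0 ≥ D1 ≥ D2 can invert by a few hundredths — the three
regressions are estimated independently and only the asymptotic
dimensions are guaranteed monotone — which is why the diagnostics carry
the per-q fit quality.

## Caliber equivalents

CRAE/CRVE follow the revised Knudtson protocol: trunk caliber = median
per-point width of each segment's Zone B stretch; the six largest
trunks per class reduce by iterated pairing (sort, combine widest with
narrowest via `W = c·√(W₁²+W₂²)`, carry the odd median element) to a
single equivalent; AVR = CRAE/CRVE. c = 0.88 (arterial) and 0.95
(venular). The trunk count (6) is configurable; whether a study uses
six or all Zone B vessels varies in practice.

## Synthetic vascular trees

The simulator emulates what a 45° disc-centered photograph presents to
the pipeline, with every realized quantity recorded so recovery tests
compare against what was actually drawn.

Default canvas: 704 px, disc radius 64 px, 12 µm/px — a 1.54 mm disc
diameter and a field reaching exactly 2 DD beyond the disc edge.
Five trees per class root on the disc margin in interleaved angular
slots. Parameters (per class) sit at adult-retina scale: branching
angle 86 ± 10° arterial / 76 ± 10° venular, asymmetry target 44 / 38,
root calibers 100 / 135 µm, arc-chord tortuosity 1.10, trunk ≈ 1.75 mm
and branch ≈ 0.85 mm segments with two bifurcation generations.
Daughters split by a Murray cube law (`w_p³ = w_l³ + w_s³`) with the
caliber ratio set by the sampled asymmetry index; a fixed taper factor
can override. Segments meander as a raised-cosine displacement
`(a/2)(1 − cos 2πmt/L)` whose amplitude is solved numerically for the
target arc-chord ratio — the profile has zero displacement *and zero
slope* at both ends, so daughter headings at a node are exact and
analytic tortuosity targets hold per segment.

Growth is clearance-aware within a class: a new branch is truncated
where it would come within 2.5 px of another stroke (its own parent is
carved out of the test near the junction), and a branch left shorter
than max(12 px, 4.5 calibers) is dropped together with its planned
subtree. The keep-floor exists because a shorter stub is
indistinguishable from a thinning artifact — it sits below the spur
threshold — and a ground truth that retained it would be unmeasurable
in principle. A junction that loses one daughter is a continuation, not
a bifurcation, and the ground-truth segment chains walk through it
exactly as the measured skeleton does. Bifurcation endpoints are kept
5 px clear of the Zone B/C and outer boundaries so raster-level node
localization cannot flip a node's zone. Strokes are rasterized as exact
pixel-center coverage of the continuous centerline (unbiased caliber at
every orientation); artery and vein may overlap in projection, as real
vessels do — they live in separate masks.

Cohorts are seeded per image from `default_rng([seed, index])`, so any
image regenerates in isolation. The default two-group cohort realizes
an NPDR-like direction pattern against control: longer segments, fewer
venous branchings (branch probability 0.7), narrower venous angles and
asymmetry, thinner calibers (lower densities).

**What the simulator does not emulate:** photometric appearance,
segmentation errors (breaks, false vessels, edge noise), artery/vein
label confusion at crossings, pathology (microaneurysms, hemorrhages),
macular geometry, and the fine capillary bed below ~30 µm. Passing
recovery tests therefore demonstrates correctness of the measurement
chain on clean topology at fundus-like scale — not robustness to
segmentation failure modes.

## Cohort statistics

Continuous variables route through a distribution gate: parametric
(one-way ANOVA with unadjusted Fisher-LSD pairwise t-tests on the
pooled error variance; mean ± SD descriptives) only when every group
passes Shapiro–Wilk and Levene's test at α = 0.05; otherwise
Kruskal–Wallis with pairwise Mann–Whitney U and median (P25, P75)
descriptives. Pairwise comparisons are deliberately reported without
multiplicity adjustment, mirroring the LSD convention; a Holm option
exists but defaults off. Categorical variables use chi-square
contingency tests. Variables significant in the omnibus test enter a
single-block binary logistic regression (maximum likelihood; Wald χ²,
OR with 95% Wald CI; perfect separation is flagged and coefficients
suppressed). ROC analysis uses the empirical curve with trapezoidal
AUC; markers negatively associated with the outcome are
orientation-flipped so AUC ≥ 0.5, with the flip reported, and the
operating point maximizes Youden's J.

## Problem sizes in the test suite

The recovery and group-difference tests share one seeded cohort of
2 × 50 images at the default 704 px geometry; the logistic calibration
uses 200 replicates of n = 300; the AUC equivalence uses 100 random
fixtures. These sizes put sampling error well inside the asserted
tolerances while keeping the suite around two minutes on one core.

## Known limitations

- Artery–vein disentanglement at crossings is out of scope; degree-4
  exclusion is a conservative substitute.
- Sub-pixel centerline refinement is not attempted; tortuosity below
  ~0.5% of arc length is not resolvable at fundus resolution.
- The finite-q singularity length depends on the q-window; values are
  comparable within one configuration only.
- Density denominators depend on the field-of-view convention; compare
  cohorts measured with the same `density_region` setting only.
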