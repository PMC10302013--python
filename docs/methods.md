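# Methods

`shootpheno` is a tested re-implementation of an image-based shoot-phenotyping
workflow for greenhouse drought screens: single potted plants are imaged from
vertical and horizontal angles over a drought/recovery time course, silhouettes
are segmented, thirteen shape and color traits are quantified per image, and
the trait tables are screened with rank statistics and low-dimensional
embeddings. Because no public image set accompanies this kind of trial, the
package ships a synthetic-trial generator with pixel-level ground truth; every
downstream stage is validated against that truth or against independent
brute-force oracles.

## The simulated trial

The generator emulates a randomized drought screen: `n_varieties` (default 28)
varieties, each planted once per plot across `plots_unstressed + plots_treated`
plots (default 2 + 5); when `n_individuals` (default 180) is smaller than the
full plot × variety grid, the excess is trimmed from the last unstressed plot,
mirroring the space constraints such trials run into. Plants are imaged on a
day grid (default −7, 0, +7, +14, +21, +28 relative to treatment start) from
two views. Plot-to-treatment assignment, per-plant vigor, growth noise and
rendering are all driven by one root seed through independent seed sequences,
so a trial is a pure function of (config, varieties, stress model, seed).

**Growth.** Projected shoot area follows per-variety exponential growth
`A(d) = A0 · (1 + g)^(d − d0)` with `d0 = −7` (growth is anchored one week
before treatment). Drought multiplies each treatment day's factor by
`(1 − area_shrink_per_day)`; each recovery day adds `(1 + recovery_rate)` of
compensatory regrowth, applied only when there was an actual deficit. Setting
the shrink and yellowing rates to zero therefore makes treated and unstressed
trajectories — and the full state distributions — identical, which the tests
rely on as the null case. Observation noise is multiplicative lognormal
(`area_noise`, default σ = 0.08 per observation) on top of a per-plant lognormal
vigor factor (σ = 0.12).

**Stress defaults.** The source workflow reports no quantitative effect sizes,
so the defaults are chosen once as plausible for a severe 14-day deficit near
the permanent wilting point: `area_shrink_per_day = 0.05` (≈ 50% relative area
loss against the control trajectory over 14 days), `yellowing_per_day = 2.5`
8-bit levels along the green→red opponent axis (a clearly visible but not
saturating color shift, half-reverting during recovery), `recovery_rate =
0.02`/day. They are model parameters of the simulation, not estimates of any
measured biology.

**Height and nodes.** Hand-measured covariates share the plant's vigor factor
with area, giving the medium-to-strong positive correlations between
image-based area and manual height/node counts that such validation stages
expect (r ≈ 0.85 for height in the default trial). Node counts are Poisson
around a stage-dependent mean. Height and node growth pause while a plant is
under an active stress model (and only then).

**Rendering.** A plant is the union of 3–9 elliptical leaf lobes around the
plant center; the layout's global scale is calibrated against the rasterized
union so the truth-mask pixel count matches `true_area · px_per_mm²` to ≈ 1%.
The non-convex unions deliberately stress the hull/caliper/rectangle code.
Clutter is drawn behind the plant: a gray-brown pot (bottom rectangle in the
horizontal view, annulus in the vertical view), a near-white support strut and
soil-toned background noise. Per-lobe and per-pixel Gaussian color noise
(σ = 8 levels) is added. What the renderer does *not* emulate: occlusion of
leaves by the strut or pot, perspective, shading, specularity, soil texture,
wilting geometry (drought only shrinks and yellows, it does not curl leaves).
Passing segmentation tests therefore show correctness of the pipeline's logic
on controlled scenes, not robustness to real greenhouse imagery.

## Segmentation

The default path merges the RGB bands into an excess-green score
(2G − R − B, affinely rescaled to 0–255), takes a single Otsu threshold on the
256-bin histogram and keeps the above-threshold (green-dominant) class. The
alternative literal reading — binarize each band by its own Otsu threshold and
then merge the binaries — is a no-op cascade when followed by re-thresholding,
but is retained behind `band_mode="literal"` for comparison. The Otsu
implementation maximizes the between-class variance ω₀ω₁(μ₀ − μ₁)² over all
255 splits with ties broken toward the smallest threshold; it is checked
exactly against exhaustive search. Note that for well-separated bimodal
histograms the variance is constant across the empty inter-mode gap, so the
smallest-t rule lands at the start of the gap — any threshold in the gap
separates the classes identically.

After thresholding: obstacle-exclusion mask zeroed out, morphological opening
(disk radius 1 by default), components below 25 px dropped, 8-connected
labeling. An empty result (a dying plant can vanish) is a warning, never an
exception. Over a default noisy trial the median intersection-over-union
against truth masks is ≈ 0.999 (the worst images are heavily yellowed plants
whose excess-green contrast collapses — a real failure mode of this index).

## The thirteen traits

Five area traits (projected area, object sum area, caliper length, convex hull
area, min-area-rectangle area), five boundary traits (circumference, convex
hull circumference, min enclosing circle diameter, roundness = 4A/(πL²),
boundary-point roundness = |∂Ω|/(π(L/2)²)) and three color variances.

Geometry is computed over pixel centers: pixel (row, col) is the point
(x = col, y = row). A single pixel has caliper 0 and the hull of a 10×10 block
is a square of side 9; corner-based conventions (as in some imaging tools)
differ by O(1 px), and one consistent convention beats a mixed one. The
primitives are classical and exact: monotone-chain hull, rotating calipers for
the Feret diameter and the minimum-area rectangle (an optimal rectangle has a
side collinear with a hull edge), Welzl's randomized algorithm for the minimum
enclosing circle (the circle is unique, so the seed affects only the insertion
order). All are tested to 1e−9 against O(n²)/O(n³) brute-force enumeration.

Object convention: all retained components are pooled into one "projected
object" (default); a per-largest-component mode exists because the original
trait list is ambiguous for multi-object images, and `object_sum_area` always
sums all components. "Circumference" defaults to the traced contour length
(Moore-neighbor boundary walk, steps of 1 axial / √2 diagonal); a "literal"
mode returns π × MEC diameter, the trait list's literal wording (under which
circumference and hull circumference coincide, since an object and its hull
share their minimum enclosing circle). Undefined traits (empty ROI, < 2 points
for a caliper) are recorded as missing, never zero, so they cannot corrupt the
rank tests.

Color traits are within-ROI population variances (divide by n) of three
channels. The default `lab8` mode maps CIELAB to 8-bit opponent axes —
lightness 0–255, green (0) → red (255), blue (0) → yellow (255), neutral near
126–128 — matching the band semantics the trait descriptions imply; `rgb` mode
uses the raw bands, kept because the trait *names* say R/G/B. The mode is
recorded in every output row.

## Statistics

**Outlier filter.** Within each (trait, view, stage, treatment) cell, linear
quantile regressions of value on day are fitted at τ = 0.05 and 0.95 by
pinball-loss minimization (statsmodels `QuantReg`); rows strictly outside the
band are removed. Symmetric 5% tails are the mildest defensible default for a
method stated only as "quantile regression outlier removal". Cells with fewer
than 10 observations pass through with a logged warning. The filter is
approximately idempotent on clean data.

**Screening.** One Kruskal–Wallis row per (trait, view, stage) × grouping
(treatment, variety). H uses mid-ranks with the standard tie-correction
1 − ΣT/(N³ − N) — plant tables are full of tied integer pixel counts — and the
χ² upper tail with k − 1 degrees of freedom; all-constant input returns
H = 0, p = 1 by convention. Raw thresholds only (0.005 for image traits, 0.05
for hand measurements); a Benjamini–Hochberg column can be emitted but never
drives the significance flag, mirroring raw-threshold screening practice.

Two calibration caveats worth stating. First, the χ² p-value is asymptotic:
at n ≲ 30 it disagrees with the exact permutation p by far more than Monte-
Carlo noise, so implementation checks compare permutation distributions of H
(our rank-sum form vs the independent variance-decomposition form
H = (N − 1)·SSB/SST), not χ² vs permutation p. Second, the trial design is
stratified — every plot contains every variety — so pooled treatment tests are
conservative on the full design (measured type-I rate ≈ 0 at α = 0.05); the
type-I calibration therefore runs on zero-effect trials with a homogeneous
panel, where the null is exchangeable (measured rate 0.048).

## Embeddings

Trait columns are z-scored before any embedding — the 13 traits mix px, px²
and squared-level units. Rows with any missing trait are dropped, never
imputed. One embedding per timepoint class (before / after treatment /
recovering / after recovery).

PCA is an eigendecomposition of the column covariance, components
sign-anchored by making each loading vector's largest-magnitude entry
positive. t-SNE is the exact O(n²) algorithm: per-row Gaussian bandwidths
binary-searched until each conditional distribution's entropy matches
log(perplexity) within 1e−7 nats (measured deviation < 1e−6 bits at
perplexity 30), symmetrized affinities, Student-t similarities, KL gradient
descent with early exaggeration (×12 for 250 of 1000 iterations), momentum
0.5→0.8 and gain adaptation. Trait tables have a few hundred rows per
timepoint, where the exact gradient is fast and bit-deterministic for a fixed
seed. Separation is scored as the mean silhouette of treatment labels in the
embedding.

At desk scale, a stressed trial at end of recovery gives all-13-trait t-SNE
silhouettes ≈ 0.27 across seeds while zero-effect trials sit at ≈ 0; the
day +14 treatment screen flags the projected-area trait at p < 0.005 in
essentially every simulated replicate (12 unstressed vs 30 treated plants,
≈ 50% relative area loss).

## Problem sizes used by the validation suites

Geometry oracles run on 1,000 random point sets (sizes mostly 3–60 with a
tail to 500; the O(n³) hull-edge and O(n⁴) circle-enumeration oracles bound
the small sizes). The shared noisy trial for invariant and segmentation checks
has 27 plants × 4 days × 2 views = 216 images. Rank-test calibration uses 50
permutation datasets (10⁴ permutations each, scored by both H implementations
on common random numbers) and 200 zero-effect trials of 42 plants; the
screening-power suite renders 100 trials of 42 plants (2:5 plot ratio) at
day +14; the embedding suite uses 112-plant single-timepoint trials. These sizes are
the package's own desk-scale study conditions; the generator's defaults keep
the full 28-variety / 180-plant design.

## Known limitations

- The renderer's drought effect is area-dominant by construction, so the
  area-trait category alone discriminates treatment about as well as all 13
  traits combined; the claim that combined traits beat every single category
  is **not** reproduced under these conditions and is not asserted by any test.
- Excess-green segmentation degrades for strongly yellowed canopies (by
  design of the index); the literal per-band mode degrades further.
- The χ²-referenced Kruskal–Wallis p is anti-conservative/conservative at
  very small group sizes; the package reports it as the field does, but the
  calibration suites quantify it.
- No lens distortion, occlusion handling or photorealism; conclusions from
  synthetic trials are about pipeline correctness, not field robustness.
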