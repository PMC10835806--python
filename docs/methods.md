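# Methods

`cpdus` automates the image side of a DUS (distinctness, uniformity,
stability) examination for ornamental flowers: it quantifies a fixed
42-trait schema from four photographs per flower, benchmarks classifiers on
the resulting trait tables, and searches for a minimal "core" trait subset
with a genetic-algorithm (GA) wrapper.  This note records the models,
parameter choices and numerical conventions, and what the synthetic data do
and do not demonstrate.

## Trait schema

Traits F1–F10 describe the whole flower, F11–F26 the outer perianth whorl
and F27–F42 the inner whorl.  Twenty-eight correspond to guideline
characteristics; fourteen (F3–F8, F15, F22–F26, F29, F31) are additional
image-derived descriptors.  Geometric traits are in pixels/px²; colour means
on the 0–255 RGB scale; area fractions in percent; categorical states as
small integer codes defined in `cpdus.schema`.

The guideline names several quantities without formulas; the package uses
the standard morphometric definitions matching those names:

- maximum diameter — Feret diameter (largest pairwise boundary distance);
- equal circle area — π·(Feret/2)²;
- concave–convex ratio — solidity, area / convex-hull area;
- circularity — 4πA/P² (1 for a circle);
- compactness — P²/A;
- minimum rectangular length/width — sides of the minimum-area rotated
  bounding rectangle (length ≥ width).

## Image chain

RGB → BT.601 luma grayscale → thresholding (Otsu by default; the threshold
direction follows the background polarity, auto-detected from the 1-px
border median) → morphological closing (disk radius 2, configurable) →
largest connected component with holes filled → outer contour by marching
squares.

Contour area is the shoelace area of the traced polygon.  The perimeter is
measured on the polygon after a 5-vertex circular moving average: the raw
marching-squares staircase overestimates smooth boundaries by ~6%, which
would break the circle identity 4πA/P² = 1; the averaging removes the
digitisation bias while leaving genuine corners nearly intact.

Petal counts are peaks of the angular radius profile ρ(θ) (360 bins, 13-bin
circular smoothing) above the (min+max)/2 level, with a minimum separation
of ~12° and a prominence of 8% of the profile range.  A profile whose
relative range is below 4% is treated as petal-free (count 1, low
confidence).  Petal-level shape (min-rect length/width, apex angle, tip
offset) is measured on the lobe isolated by the angular sector between the
two valleys flanking the tallest peak.

Colour is described by 2-means clustering of the foreground pixels in a
hue-circular HSV embedding (S·cos H, S·sin H, V).  Colour statistics use the
pre-closing foreground (closed mask ∩ raw binarised mask): gap pixels
annexed by the closing are background-coloured and would otherwise
contaminate the clusters.  The larger cluster is the
main colour; the region is polychromatic only if the smaller cluster holds
≥5% of pixels *and* the cluster means are ≥30 RGB units apart — otherwise
the secondary colour is reported equal to the main one with a zero
percentage.  The secondary *distribution* class uses the normalised radial
position r/ρ(θ) of the secondary pixels.  Under the area measure the radius
of a uniformly painted region distributes like 2r, so a basal band painted
up to quantile f has mean (2/3)√f (≤0.52 for f ≤ 0.6), a marginal band has
mean ≥0.83, and stripes sit at 2/3 with a much larger spread.  The class
cuts are therefore: striped if sd > 0.21, basal if mean < 0.55, marginal if
mean > 0.75, striped otherwise, and "full" above 60% — note that with the
smaller-cluster convention the secondary share cannot exceed 50%, so the
full class is a guard rather than an expected outcome.

## Synthetic flowers

No public image set exists at this scale, so the package ships a renderer.
Each variety is an archetype: petal counts (outer mean 5–9, inner 3–6),
petal length 120–180 px and aspect 1.3–4.2 on a 512-px reference canvas,
a yellow base colour, a pinkish-purple secondary colour, a secondary
placement (basal / marginal / striped), an apex type, an openness
(extension) angle of 60–150°, and a colour group mirroring the classical
wintersweet division: concolor (inner secondary fraction 0), intermedius
(0.10–0.35) and patens (0.55–0.85).  Outer secondary fractions are 0 or
0.08–0.30, deliberately clear of the 5% polychromatic decision boundary.

Flowers are realised with ~4% dimension jitter and ±0.7 petal-count jitter,
then painted as rotated superellipse lobes (tip exponent 1.3/2.0/2.8 for
acute/obtuse/rounded apices) around a central receptacle disk that keeps the
whorl connected.  Basal/marginal secondary paint is placed by quantile of
the normalised radius, so the painted fraction hits the target almost
exactly; stripes are angular sectors.  The side view is a filled circular
sector with the realised extension angle.  Gaussian pixel noise (sd 5) is
added; backgrounds alternate dark (30,30,30) and light (235,235,235), and
light-background shots render the flower at 0.55 radiance — emulating the
shorter exposure a white background requires — so the silhouette stays
luma-separable in both polarities.

Ground truth records realised (not archetype) values; painted areas and
fractions are recorded as exact pixel counts.  Colour truth follows the same
smaller-cluster convention as the extractor: when more than half a whorl is
painted (patens), the paint colour is the main colour and the unpainted base
is the secondary, at the complementary placement.

Two render-free generators serve model-level experiments: an analytic
trait-table sampler (same archetypes, closed-form geometry, cheap at
thousands of rows) and `planted_table`, which builds tables with a known
informative subset — class centres on a circle by default, or one per axis
("onehot" scheme) when every informative column must be individually
essential — plus pure-noise and collinear-copy columns.

What passing tests show: the extractor recovers what this renderer encodes
(silhouettes on near-uniform backgrounds, two-colour petals, radially
symmetric whorls).  They do not show robustness to shadows, specular
highlights, overlapping scene clutter, white-balance drift or non-planar
flowers; none of these are modelled.

## Benchmark

Eight families — DT, GBM, kNN, LR, RF, SVM (RBF), XGBoost, LDA — with fixed
sensible hyperparameters (no tuning loop), each wrapped in a pipeline that
one-hot-encodes nominal traits and standardises the rest, fitted inside each
training fold only.  Evaluation reports both a stratified 0.75:0.25
held-out split and stratified 5-fold cross-validation (accuracy and
macro-F1, percent).  Trait importance uses permutation importance
(accuracy drop on the held-out split, 10 shuffles) uniformly for all
families, since several families have no native importance; ties break
toward the lower trait id.  XGBoost uses exact splits: at the
few-hundred-sample scale of these tables, histogram bin edges can misplace
points lying in an empty margin between classes.

## GA wrapper selection

A subset S is a binary chromosome; its cost is λ1·E(S) + λ2·N(S), where
E(S) is the stratified-CV error of the wrapped classifier (random forest by
default) on the columns of S and N(S) the subset length.  λ1 = 1 and λ2 =
(mean probe error)/(mean probe length) over 20 random subsets, clipping to
[1e-4, 1], so both terms share an order of magnitude and a shorter subset
wins among near-equal error rates.

Defaults: population 50, 20 generations, tournament size 3, single-point
crossover at rate 0.8, per-bit mutation at 1/d, elitism 1 (making the best
cost per generation non-increasing), stop at the generation limit (an
optional patience is off by default).  Chromosomes are repaired to be
non-empty.  Evaluations are memoised by bit pattern — repeat visits are
free, and an exhaustive search run after a GA on the same evaluator only
pays for subsets the GA never visited.  Repeated runs use independent
spawned seeds; the run with the highest accuracy (ties to the shorter
subset) is flagged as the core set.

## Downstream analyses

Pearson correlation with |r| ≥ 0.5 flagging; VIF per trait as 1/(1−R²) from
an OLS regression on all other traits (+inf sentinel at machine-exact
collinearity; constant columns excluded).  Confusion matrices carry
accuracy, per-class recall and the most-confused pairs.  t-SNE (perplexity
30, capped at (n−1)/3; PCA fallback under 50 samples) is summarised by
per-class intra radii and inter-centroid distances; class pairs closer than
the sum of their radii are reported as overlapping — only these summary
statistics are asserted, the embedding itself is illustrative.  Variety
clustering averages encoded traits per variety (z-scored numeric, one-hot
averaged nominals), runs k-means (k=3 by default, 10 restarts) and, because
k-means yields no hierarchy, also builds a Ward dendrogram on the same
means, exported as Newick with merge heights as branch lengths.

## Problem sizes

The test-suite and acceptance-script studies use desk-scale problem sizes
chosen to exercise every code path with stable statistics: rendered sets of
6 varieties × 20 flowers at 192–256 px, analytic tables of a few hundred
rows, GA-vs-exhaustive studies at d = 6–10 with a 3-fold CV forest of 30–60
trees, and planted-recovery studies at d = 42 with 5 informative traits.
Statistical assertions (recovery rates, oracle hit rates, collinearity
reduction) are majority votes over ≥5 seeds.

## Known limitations

- Categorical apex/margin states are scored from silhouette geometry only;
  incurved vs reflexed cannot be told apart in 2-D projection (both score
  as deflected; symmetric renders score straight).
- The angular-profile petal counter assumes a roughly radial rosette; it
  undercounts heavily overlapping whorls where valleys vanish.
- VIF requires more samples than traits; perfect collinearity is reported
  as a sentinel rather than dropped silently.
- The λ calibration assumes the probe error is representative; on exactly
  separable data λ2 hits its floor and subset length dominates the search.
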