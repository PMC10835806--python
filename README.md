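# cpdus

Automated trait quantification and core-trait selection for image-based DUS
(distinctness, uniformity, stability) testing of ornamental flowers.

Registering a new plant variety requires a DUS examination: scoring a fixed
catalogue of morphological characteristics for many individuals, today
largely by hand.  `cpdus` automates the flower side of that workflow for
rosette-type blossoms photographed in four standard views (front, outer
perianth, inner perianth, side):

1. **Quantify** 42 traits per flower — whole-flower geometry (Feret
   diameter, perimeter, area, solidity, circularity 4πA/P², compactness
   P²/A), per-whorl petal counts and min-rect dimensions, apex/margin
   states, and main/secondary colour statistics from 2-means HSV
   quantisation.
2. **Benchmark** eight classifier families (DT, GBM, kNN, LR, RF, SVM,
   XGBoost, LDA) on five feature groups (all / guideline subset / whole
   flower / outer whorl / inner whorl), with a stratified 0.75:0.25 split
   and 5-fold CV, plus a uniform permutation-importance ranking.
3. **Select** a minimal "core" trait subset with a genetic-algorithm
   wrapper whose fitness is

       Cost(S) = λ₁·E(S) + λ₂·N(S)

   where E(S) is the wrapped classifier's cross-validated error on subset S
   and N(S) its length; λ₂ is calibrated so both terms share an order of
   magnitude.  The GA uses tournament selection (size 3), single-point
   crossover, per-bit mutation and elitism (population 50, 20 generations
   by default), with memoised subset evaluations.
4. **Analyse** the result: Pearson |r| ≥ 0.5 flags and variance inflation
   factors (VIF = 1/(1−R²)), confusion matrices, t-SNE cluster-distance
   summaries, and per-variety k-means groups with a Ward dendrogram
   exported as Newick.

Because curated DUS image sets are rarely redistributable, the package
includes a seedable synthetic flower renderer (`cpdus.synthetic_flora`)
that emits both images and exact ground-truth trait vectors, with variety
archetypes covering the three classical wintersweet colour groups
(concolor / intermedius / patens).  Every stage is tested against this
ground truth and against independent oracles (exhaustive threshold scans,
naive morphology, exhaustive subset search).  See `docs/methods.md` for the
models, conventions and limitations.

## Worked example

```python
from cpdus.synthetic_flora import generate_dataset
from cpdus.traits import extract_table
from cpdus.bench import run_benchmark
from cpdus.gaselect import GAConfig, SubsetEvaluator, run_ga

generate_dataset(6, 20, seed=5, out_dir="flowers", size=256)
table = extract_table("flowers/manifest.csv")

report = run_benchmark(table, seed=0)
print(report.table("test_accuracy").round(1))

ev = SubsetEvaluator(table, cv=3, n_estimators=30, seed=0)
res = run_ga(ev, GAConfig(pop_size=16, generations=6, seed=0))
print(f"core set: {res.N} traits, CV accuracy {res.accuracy:.1f}%")
print(res.subset)
```

Output (6 synthetic varieties × 20 flowers, 480 images; held-out test
accuracy in percent):

```
group      all    dus  entirety  inner  outer
family
DT        96.7   90.0      96.7   90.0  100.0
GBM       96.7   96.7      96.7   90.0   96.7
LDA       33.3   33.3     100.0   33.3  100.0
LR       100.0  100.0      93.3  100.0   96.7
RF       100.0  100.0      96.7  100.0  100.0
SVM      100.0  100.0      96.7  100.0  100.0
XGBoost   96.7   93.3      93.3   90.0   90.0
kNN      100.0   96.7      96.7   86.7   90.0
core set: 12 traits, CV accuracy 100.0%
['F1', 'F4', 'F10', 'F13', 'F18', 'F23', 'F32', 'F35', 'F38', 'F40', 'F41', 'F42']
```

Six synthetic varieties are easy: most families are at or near 100% on the
full 42-trait set (LDA collapses there — its within-class scatter is
singular under the collinear trait block at this sample size, though it is
perfect on the smaller groups).  The GA then compresses the 42 traits to a
12-trait core set — spanning shape, openness, margin and both whorls'
colour — with no accuracy loss, which is exactly the trade the cost
function λ₁E + λ₂N is designed to make.

The same pipeline is available from the shell:

```bash
cpdus synth --varieties 6 --per-variety 20 --seed 5 --size 192 --out flowers
cpdus extract --manifest flowers/manifest.csv --out traits.csv
cpdus bench   --traits traits.csv --seed 0 --out report.csv
cpdus select  --traits traits.csv --runs 5 --seed 0 --out selection.json
cpdus analyze --traits traits.csv --subset selection.json --out-dir analysis/
```

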