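# woundbed

Automated assessment of chronic-wound photographs: segment the wound bed
from an ordinary RGB photograph, describe its tissue regions with a
color/texture feature bank, and classify each region as **granulation**
(red, healing), **slough** (yellow, fibrinous) or **necrotic** (black,
dead) tissue.  The tissue composition of a wound bed is the quantity
clinicians track to judge healing progress, and scoring it by eye is
subjective and slow; this package implements the full computational
pipeline for doing it reproducibly.

## Method

1. **Preprocessing.** Each RGB channel is median-filtered with a 5×5
   window to remove salt-and-pepper camera noise.
2. **Segmentation.** The image is converted to HSI; the saturation plane
   S = 1 − 3·min(R,G,B)/(R+G+B) separates wound from skin far better than
   any raw channel.  For every candidate threshold *t* ∈ [1, 255] each
   pixel gets a Gaussian membership grade
   μ(f) = exp(−(f − m_r)² / 2σ²) around its region's mean m_r, and the
   exponential fuzzy divergence

   D(A, B) = Σ_ij [2 − (1 − μ_A + μ_B) e^{μ_A−μ_B} − (1 − μ_B + μ_A) e^{μ_B−μ_A}]

   between the membership image and an ideally segmented image (μ ≡ 1) is
   minimized over *t*.  The raw mask is refined by morphological closing,
   opening, hole filling and largest-component selection.
3. **Features.** For each tissue region, 15 descriptors per channel over
   45 color channels (15 color spaces × 3 components) = **675 features**:
   population mean/std/variance/skewness/kurtosis, Shannon entropy, three
   local-contrast measures (T−A)/(T+A), and rotation-invariant local
   binary patterns LBP^ri plus local variance VAR at radii R = 1, 2, 3
   (P = 8, 16, 24 circular neighbors).
4. **Selection.** One-way ANOVA F across the three tissue classes;
   features with F > 21 are retained.
5. **Classification.** Gaussian naive Bayes and soft-margin one-vs-one
   SVMs (linear, quadratic, cubic polynomial, RBF kernels) on z-scored
   retained features.
6. **Evaluation.** 3×3 confusion matrix, per-class accuracy
   (diagonal/row-total), macro and micro overall accuracy, and Cohen's
   kappa κ = (p_o − p_e)/(1 − p_e).

Clinical wound photographs cannot ship with a code package, so a
synthetic-wound generator (`woundbed.synthetic`) renders skin-toned
images with elliptical wound beds partitioned into red/yellow/black
tissue sectors plus exact ground-truth masks; every pipeline stage is
tested against it.

## Worked example

```python
import json
from woundbed import make_benchmark, median_filter_rgb
from woundbed.pipeline import PipelineConfig, run_pipeline, report_dict

suite = make_benchmark(10, seed=42)              # 10 synthetic wounds
images = {w.image.id: median_filter_rgb(w.image) for w in suite}
regions = [r for w in suite for r in w.regions]  # 30 labeled tissue regions
truth = {w.image.id: w.wound_mask for w in suite}

result = run_pipeline(images, regions, PipelineConfig(seed=42),
                      wound_truth=truth)

seg = result.segmentations[suite[0].image.id]
print(f"threshold={seg.threshold}  divergence={seg.divergence:.3f}  "
      f"dice={result.dice_scores[suite[0].image.id]:.3f}")
print("retained features:", len(result.selection.retained), "of 675")
print(json.dumps(report_dict(result)["svm"]["per_class_accuracy_pct"]))
```

prints

```
threshold=63  divergence=0.748  dice=0.952
retained features: 397 of 675
{"granulation": 100.0, "slough": 100.0, "necrotic": 100.0}
```

The selected threshold 63 sits between the skin saturation mode (~42)
and the chromatic wound tissue (~120–140); Dice 0.952 is the overlap of
the refined mask with the true wound ellipse; the cubic-polynomial SVM
classifies all nine held-out regions (stratified 70/30 split) correctly.

The same flow is available from the shell:

```sh
woundbed synth --n 10 --seed 42 --out data/
woundbed segment --in data/synthetic-392022359.png --out-mask mask.png --report seg.json
woundbed run-all --n 10 --seed 42 --out results/
```

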