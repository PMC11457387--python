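# artifact

Artifact processing for histological whole-slide images (WSIs).

Histological slide preparation and scanning introduce artifacts — blood
(hemorrhage), out-of-focus blur, air bubbles, damaged tissue, and folded
tissue — that are diagnostically irrelevant and degrade downstream
computational-pathology models. This package detects those five artifact
classes at patch level and turns the predictions into slide-level quality
control: a segmentation map, a QC report, an artifact-free region-of-interest
(RoI) mask, and an artifact-refined image in which only clean tissue
survives. It is aimed at people building computational-pathology pipelines
who need to gate slides and patches before a diagnostic model sees them.

## Method

A slide `I` is reduced to tissue foreground by Otsu thresholding on the HSV
value channel of a low-resolution thumbnail, then tiled by a uniform
non-overlapping grid `T : I → {x_j}` of 224×224×3 patches. For supervised
data, a patch whose window overlaps an artifact annotation mask on ≥ 70% of
its area takes that artifact's class; everything else is artifact-free.

Each classifier is a backbone `φ` plus a three-layer fully connected head
with softmax output, `P(x) = σ(C(φ(x)))`. The detector is a **mixture of
experts (MoE)**: five binary experts, one per artifact class, each trained on
its artifact vs. artifact-free tissue (artifact-free is the positive class).
Their artifact probabilities `P_{ψ_i,0}` are fused by maximum:

    p_artifact = max_i P_{ψ_i,0},   p_afree = 1 − max_i P_{ψ_i,0}

A probability threshold `t_s` is learned on validation data from the ROC
curve — by default the most specific threshold whose sensitivity for the
artifact-free class still reaches the 98% floor — and prediction is

    class(x) = 0 (artifact-free)           if p_afree ≥ t_s
             = argmax-expert's class code  otherwise

A six-class multiclass model with the same thresholding rule is provided as
the computationally cheaper alternative.

Post-processing fills a matrix `M` with one cell per grid position
(`M[y/s, x/s] = k`), from which come the per-class percentages
`Per_k = N_k / N_tot · 100%`, the artifact-free fraction `ρ = N_0 / N_tot`
compared against a usability threshold `τ` (accept/discard), the binarized
RoI mask `M_ρ` after morphological closing, and the refined slide
`I ⊙ M_ρ` (Hadamard product with the nearest-neighbor-upsampled mask).

Everything is testable offline: `artifact.synthetic` renders deterministic
H&E-like patches and composite slides with known per-class ground truth, and
ground-truth "oracle experts" let the full pipeline be verified exactly.

## Worked example

```python
import numpy as np
import artifact as A
from artifact.pipeline import make_oracle_bundle

# 1. a synthetic slide with two artifact regions
spec = A.SyntheticWSISpec(
    width=1120, height=1120,
    regions=((2, 224, 224, 448, 448), (1, 672, 672, 224, 224)),
    base_texture_seed=7, tissue_fraction=0.9,
)
image, gt = A.generate_wsi(spec)

# 2. learn t_s on validation scores at the 98% sensitivity floor
rng = np.random.default_rng(0)
scores = np.concatenate([rng.beta(5, 2, 1000), rng.beta(2, 5, 1000)])
labels = np.concatenate([np.ones(1000, int), np.zeros(1000, int)])
sel = A.select_threshold(scores, labels)
print(f"t_s={sel.t_s:.3f}  TPR={sel.tpr:.3f}  FPR={sel.fpr:.3f}  AUC={sel.auc:.3f}")

# 3. run the MoE pipeline (ground-truth oracle experts for the demo)
bundle = make_oracle_bundle(gt, t_s=sel.t_s)
result = A.run_pipeline(image, A.PipelineConfig(pipeline="moe"), bundle=bundle)
r = result.report
print(f"N_tot={r.n_total}  rho={r.rho:.3f}  decision={r.decision}")
print("Per_k:", {k: round(v, 1) for k, v in r.percentages.items()})
```

prints

```
t_s=0.354  TPR=0.980  FPR=0.330  AUC=0.957
N_tot=25  rho=0.800  decision=accept
Per_k: {0: 80.0, 1: 4.0, 2: 16.0, 3: 0.0, 4: 0.0, 5: 0.0}
```

The learned threshold keeps 98.0% of artifact-free validation patches while
rejecting two thirds of artifact patches. On the slide, 25 foreground
patches are evaluated; 80% are artifact-free (`ρ = 0.80 ≥ τ = 0.5`, so the
slide is accepted), 16% are blur (class 2, the 448×448 region = 4 cells) and
4% blood (class 1, one cell). `result` also carries the segmentation grid,
the RoI mask and the refined image; with `out_dir=` all outputs plus a run
manifest are written to disk.

Real models are trained with `A.train_model` (SGD from lr 0.01,
reduce-on-plateau, batch 128, geometric augmentation, early stopping on
validation loss) and wrapped with `A.ClassifierExpert` into an
`A.ExpertBundle`. The same flow is scriptable through the CLI:

```sh
artifacts synth --spec spec.json --out slide/
artifacts train-expert --artifact-class blur --data dataset/ --out blur.npz
artifacts select-threshold --scores val_scores.csv --target-sens 0.98
artifacts run --wsi slide/wsi.tiff --pipeline moe --bundle bundle/ --tau 0.5 --out out/
```

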