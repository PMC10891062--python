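# ipb — iterative pseudo-balancing for colony microscopy classification

Semi-supervised classification of phase-contrast colony images with a
student–teacher meta-pseudo-label loop that **rebalances an imbalanced,
largely unlabeled dataset on the fly**: every epoch the teacher pseudo-labels
one random in-mask patch per unlabeled image, low-confidence labels are
dropped, and the surviving patches are resampled from a multinomial whose
class weights are inversely proportional to the teacher's estimated class
proportions — so the student always trains on a balanced stream, including
patches from multi-label images that carry no usable image-level label.

The package ships the complete surrounding stack:

| module               | what it does |
| -------------------- | ------------ |
| `ipb.synth`          | seeded synthetic colony-image generator (four texture-separable classes, multi-label composites, severe imbalance, CSV manifests) standing in for the request-only real dataset |
| `ipb.segmentation`   | 6-step morphological colony detection (blur → local entropy → Otsu → opening → hole fill → small-object removal) and ROI extraction |
| `ipb.patches`        | in-mask patch sampling with a coverage constraint, single-scale (128) and dual-scale (224 + 112 center crop) extraction, the five-transform augmentation stack, too-small-image resizing |
| `ipb.models`         | dual-stream and compact parallel-resolution classifiers plus a tiny test-scale variant, built on a NumPy layer kernel (`ipb.nn`) with exact reverse- **and** forward-mode derivatives |
| `ipb.training`       | teacher pre-training, pseudo-labeling with the 0.65 confidence filter, inverse-proportion multinomial resampling, student SGD step, exact teacher meta-gradient step, warm-up, best-student selection |
| `ipb.evaluation`     | stratified 80:10:10 splits with fold rotation, labeled-budget ablation arithmetic, per-class TPR/F1 from predicted-by-actual confusion matrices, Student-t fold comparison |
| `ipb.workbench`      | YAML run configuration, seed fan-out, the end-to-end experiment driver, and the paired balancing-on/off contrast harness |

The networks are implemented directly in NumPy (no deep-learning framework
is assumed): hand-written conv/batch-norm/linear layers with reverse-mode
backprop and an exact forward-mode JVP. The teacher update differentiates the
updated student's labeled-set loss **exactly** through the soft pseudo-label
pathway (verified against finite differences), instead of using a REINFORCE
approximation.

## CLI

```bash
ipb synth   --out-dir data --debris 36 --dense 39 --diff 7 --spread 105 --multilabel 27
ipb segment --input data/img000000.png --out-mask mask.png --out-rois rois.csv
ipb ipb-train --manifest data/manifest.csv --config run.yaml --outdir runs/r0
ipb ipb-eval  --checkpoint runs/r0/student_best.npz --manifest data/manifest.csv --out metrics.json
ipb compare   --a folds_a.json --b folds_b.json
```

`run.yaml` may override any subset of the configuration; an empty file means
the reference hyperparameters (SGD lr 0.005, momentum 0.9, weight decay 1e-4,
batch 32, confidence threshold 0.65, 200 + 200 epochs, 10 warm-up epochs).

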