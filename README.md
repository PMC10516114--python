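# miml

Multimodal, label-free cell classification that fuses features learned from
transit images with microfluidic biomechanical features — deformation index
(DI), transition time (TT), normalized maximum velocity (vmax) and,
optionally, deformation-index rate (DIR). The package ships a synthetic
constriction-transit generator, so every experiment runs end to end without
external data: two cell populations differing in stiffness are pushed through
a virtual constriction channel, rendered to grayscale frames, and classified
by image-only, mechanics-only, and fused models.

Everything runs on CPU with NumPy; the neural models (residual convolutional
encoder, feed-forward feature network, fusion head) are implemented on a
small in-package layer stack with manual backpropagation (`miml.nn`),
verified by numerical gradient checks.

## Layout

| module            | contents |
|-------------------|----------|
| `miml.synthetic`  | population sampling, phenomenological transit mechanics, anti-aliased frame rendering, dataset writer (PNG + manifest CSV) |
| `miml.features`   | segmentation (Otsu + largest component), moment-based ellipse fit, DI/TT/vmax/DIR, train-split-only min–max normalization |
| `miml.tabular`    | LR / SVM / DT / RF / KNN (scikit-learn) and a d→32→16→2 feature MLP; cross-validated model comparison |
| `miml.encoder`    | residual CNN encoder (7×7 stride-2 stem, 4 doubling stages, global average pooling) with classifier or identity head |
| `miml.fusion`     | MIML model: z1 ∥ z2 → Linear/BatchNorm/ReLU ×2 → softmax head; training, transfer fine-tuning, checkpoints |
| `miml.evaluation` | confusion counts, accuracy/precision/recall/F1, ROC/AUC, grouped stratified k-folds, Grad-CAM, t-SNE embedding |
| `miml.workflow`   | manifest I/O, leakage-safe splits, experiment recipes (tabular / cnn / miml / miml+dir / transfer) |
| `miml.benchmarks` | canonical data regimes: fusion benefit, no harm, transfer, DI round-trip, monotonicity, Grad-CAM localization |

## CLI

```bash
miml simulate --out ds --n-per-class 100 --overlap 0.5 --seed 0
miml split         --manifest ds/manifest.csv --out split.json --seed 0
miml train-tabular --manifest ds/manifest.csv --out metrics.csv --folds 5 --seed 0
miml train-cnn     --manifest ds/manifest.csv --out cnn.json --epochs 40 --seed 0
miml train-miml    --manifest ds/manifest.csv --out miml.json --checkpoint ck.npz \
                   --features di,tt,vmax --epochs 40 --seed 0
miml evaluate      --checkpoint ck.npz --manifest ds/manifest.csv --out eval.json
miml transfer      --pretrained ck.npz --manifest other/manifest.csv --out tr.json
miml embed         --checkpoint ck.npz --manifest ds/manifest.csv --out emb.csv
miml extract       --manifest ds/manifest.csv --out with_image_di.csv
```

Datasets are a manifest CSV (`cell_id, class, di, tt_ms, vmax_norm,
dir_per_ms, img_entry, img_squeezed`) plus 8-bit grayscale PNGs, two frames
per cell (entry and maximally squeezed). Splits are always stratified by
class and grouped by cell id so a cell's two images never straddle a split.

## Notes

- Determinism: every random operation draws from a named substream of the
  run seed; same seed ⇒ identical manifests, frames, splits and metrics.
- The benchmark regimes use entry frames only, because a squeezed frame's
  rendered shape would leak DI into the image route; the default training
  pipeline uses both frames with per-cell probability averaging.
- Checkpoints are single `.npz` archives embedding weights, encoder/fusion
  configs, normalization bounds and the class map.
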