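# protoseg

One-shot segmentation of brain tumors on MRI using a single foreground
prototype. Instead of training a dense segmentation network on hundreds of
labeled scans, the model conditions on **one** annotated support slice per
episode: the support slice's tumor pixels are encoded and pooled into a
256-dimensional prototype, and every query pixel is classified by how
similar its feature vector is to that prototype.

## The model

An encoder `f_θ` maps each 3-channel 256×256 slice to a 256-channel feature
grid at 1/8 resolution. Given support features `χ_s` and the binary tumor
mask `y`, the foreground prototype is the masked average

    ρ = Σ_{i,j} χ_s(i,j) · 1[y(i,j)=1] / Σ_{i,j} 1[y(i,j)=1].

Query features `χ_q` are scored with a negated, scaled cosine (Tucker
congruence) similarity

    R(i,j) = −α · ⟨χ_q(i,j), ρ⟩ / (‖χ_q(i,j)‖ ‖ρ‖),   α = 20,

so pixels matching the prototype score near −α. A learnable scalar threshold
β turns scores into a dense foreground probability via soft thresholding

    M(i,j) = 1 − σ(R(i,j) − β),

which is exactly 0.5 where `R = β`. Training is episodic: each iteration
samples a query slice and `C·K` support slices (all tumor-bearing, same
scan, distinct indices) and minimizes

    L_total = L_seg + λ·L_PAR,       λ = 1,

where `L_seg` is a class-weighted binary cross-entropy (foreground 1.0,
background 0.2) on the predicted query mask and `L_PAR` is a prototype
alignment regularizer that reverses the roles: a prototype pooled from the
query features under the predicted mask must segment the support slices.
Optimization is SGD (momentum 0.9, batch size 1, lr 1e-3 decayed ×0.97 every
1000 iterations, weight decay 5e-4), with β trained jointly.

Evaluation segments a whole query scan from the median tumor-bearing slice
of a support scan and reports Dice `2|X∩Y|/(|X|+|Y|)`, IoU `|X∩Y|/|X∪Y|`
and precision `TP/(TP+FP)` per volume, optionally aggregated over k-fold
cross-validation.

Everything is exercisable end-to-end on synthetic T2-like volumes produced
by the built-in generator — no downloads, no GPU.

## Worked example

```python
import numpy as np
import protoseg as ps

# 24 synthetic scans: bright ellipsoidal tumor on a darker brain ellipsoid
cfg = ps.SynthConfig(n_slices=60, grid=(96, 96))
stacks = [ps.preprocess_case(*ps.generate_case(cfg, 1000 + i)) for i in range(24)]
train_set, test_set = stacks[:20], stacks[20:]

model, hist = ps.train(train_set, ps.TrainConfig(iterations=2000, seed=7))
print(f"loss {hist[0].l_total:.3f} -> {hist[-1].l_total:.3f}")

support = train_set[0]
s = ps.select_support_slice(support.masks)          # median tumor slice
pred = ps.segment_query_volume(support, s, test_set[0], model)
rec = ps.compute_metrics(pred, test_set[0].masks)
print(f"dice {rec.dice:.3f}  iou {rec.iou:.3f}  precision {rec.precision:.3f}")
```

prints (about 5 minutes on one CPU)

```
loss 2.891 -> 0.710
dice 0.954  iou 0.912  precision 0.927
```

i.e. episodic training drops the total loss about fourfold and the one-shot
prototype recovers ~95% of the held-out tumor volume (Dice) with ~93% of
predicted tumor pixels correct (precision) on this separable synthetic
phantom.

The same pipeline is scriptable from the shell:

```sh
protoseg synth --n-cases 24 --seed 1 --out data/
protoseg train --data data/ --iterations 2000 --out run/
protoseg eval --data data/ --checkpoint run/checkpoint.npz --out results/
```

## Layout

- `protoseg.synth` — synthetic NIfTI volume/label generator (the test bed)
- `protoseg.preprocess` — intensity clipping, slice resampling, ROI crop,
  label merging, 256×256 standardization, affine augmentation
- `protoseg.episodes` — support/query episode sampling, batch assembly
- `protoseg.encoder` — pluggable encoders behind the (256-ch, ÷8) contract
- `protoseg.prototype` — masked average pooling, similarity, soft threshold
- `protoseg.training` — losses and the episodic SGD loop
- `protoseg.evaluation` — inference protocol, Dice/IoU/precision, k-fold CV
- `protoseg.autodiff` — minimal reverse-mode engine the model trains on
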