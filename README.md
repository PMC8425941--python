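# dwiseg

Volumetric segmentation of hyperintense tumors on diffusion-weighted MRI
(DWI): a 3D U-Net trained with the 1 − DSC objective, a semi-automatic
threshold + largest-connected-region baseline, Dice/Hausdorff evaluation,
and a seeded DWI phantom generator so everything is testable without
clinical data.

**Who it is for.** Researchers in medical image analysis who want a
self-contained, fully reproducible reference implementation of the
volume-to-volume U-Net segmentation recipe for rectal tumors on
high-b-value DWI — where the tumor appears as a bright structure on a
darker, noisy background — including the classic failure mode of
threshold-based segmentation when adjacent tissue matches tumor gray level.

## The model and the metrics

A binary segmentation B is scored against a ground-truth mask A by the
Dice similarity coefficient and the Hausdorff distance:

```
DSC(A, B) = 2 |A ∩ B| / (|A| + |B|)
HD(A, B)  = max( max_{a∈A} min_{b∈B} d(a, b),  max_{b∈B} min_{a∈A} d(b, a) )
```

The network is a symmetric 5-level volumetric U-Net: 3×3×3 "same"
convolutions with ReLU, 2×2×2 max-pooling down, 2×2×2 transposed
convolutions up, skip concatenations at matching resolution, and a
per-voxel probability head. A 256×256×32 input is reduced to a 16×16×2
bottleneck and restored to full size. Training minimizes the soft-Dice
loss `1 − (2Σp·a + ε)/(Σp + Σa + ε)` with Adam; the epoch with the best
validation DSC is kept. Forward pass and backpropagation are implemented
directly on NumPy arrays — no deep-learning framework required.

The default build reproduces the reference architecture census exactly —
21 3×3×3 convolutions, 4 poolings, 4 transposed convolutions, 4
concatenations — and, because per-level channel widths are not published,
`find_width_config` searches a documented configuration family for a width
ladder whose closed-form parameter count matches the published total of
6,832,321 exactly (see `docs/methods.md`).

The baseline (`semiauto`) segments in three steps: manually choose a lower
gray-level bound inside the tumor, keep voxels ≥ the bound, keep the
largest 3D connected region.

## Worked example

```python
import dwiseg as ds
from dwiseg.phantom import PhantomSpec
from dwiseg.semiauto import ThresholdSpec, semiauto_segment

# a 64x64x16 DWI-like phantom: bright ellipsoid tumor, Rician noise
img, truth = ds.generate_phantom(PhantomSpec(seed=21, n_specks=2,
                                             noise_sigma=15.0))
seg = semiauto_segment(img, ThresholdSpec(t_min=300.0))
print(f"tumor voxels: {truth.foreground_count}")
print(f"semi-automatic DSC: {ds.dice(truth, seg):.3f}")

net = ds.build_unet(ds.UNetConfig())
print("census:", ds.layer_census(net))
```

prints

```
tumor voxels: 1661
semi-automatic DSC: 1.000
census: LayerCensus(n_conv3=21, n_pool=4, n_transpose=4, n_concat=4)
```

On this clean phantom the tumor is the largest bright region, so
threshold + largest-component recovers it perfectly (DSC 1.0); on a
confounder phantom (`make_confounder_phantom`), where an equally bright
larger structure is present, the same baseline collapses to DSC < 0.1 —
the failure mode the learned model avoids.

A complete scaled experiment — 25 phantoms split 15/5/5, a reduced-width
U-Net (levels 3, widths 4/8/16), soft-Dice training for 25 epochs —
runs in a few minutes on one CPU:

```python
res = ds.run_phantom_experiment(
    n_cases=25, split=(15, 5, 5),
    net_config=ds.UNetConfig(levels=3, widths=(4, 8, 16)),
    train_config=ds.TrainConfig(learning_rate=1e-3, decay=1e-5, epochs=25),
    master_seed=1,
)
```

which selects epoch 19 (validation DSC 0.988) and scores the held-out
cases at DSC 0.988 ± 0.006 (median 0.987, min 0.979, max 0.994) with mean
Hausdorff distance 1.0 voxels: the network learns the tumor-segmentation
task on this phantom family and generalizes to unseen cases.

A command-line interface wraps the same functionality:

```
dwiseg phantom --n 60 --seed 7 --out cohort/
dwiseg preprocess --in x.nii.gz --out y.nii.gz --shape 256 256 32 --normalize zscore
dwiseg census
dwiseg train --data-dir cohort/ --split 40 10 10 --seed 1 --out model/
dwiseg predict --model model/model.npz --in x.nii.gz --out prob.nii.gz
dwiseg semiauto --in x.nii.gz --tmin 300 --out seg.nii.gz
dwiseg evaluate --truth-dir cohort/ --pred-dir preds/ --out-prefix eval
```

Every run writes a JSON manifest (resolved config, seeds, paths, version)
next to its outputs.

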