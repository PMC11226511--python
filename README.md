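# lka3d — 3D large-kernel attention U-Net toolkit

`lka3d` is a CPU-friendly toolkit for volumetric medical-image
segmentation built around a **3D large-kernel (LK) attention** mechanism.
Instead of query–key self-attention, the attention map is produced by a
large-receptive-field convolution that has been *decomposed* into three
cheap pieces, then used to gate the feature map multiplicatively.

## The idea

A dense C→C convolution with a cubic K×K×K kernel costs

```
N_O = C · (C·K³ + 1)                     parameters
```

which is prohibitive in 3D (a 21³ kernel at 32 channels already needs
9.48 M parameters).  Decomposing it into a **(2d−1)³ depthwise** conv, a
**(K/d)³ depthwise conv with dilation d**, and a **1×1×1 pointwise** conv
covers the same receptive field for

```
N_D = C · ((2d−1)³ + (K/d)³ + C + 3)     parameters
```

— 16.10 k instead of 9.48 M for K=21, d=3, C=32 (0.17 %).  Setting the
derivative of `N_D` with respect to a continuous d to zero gives
`24d² − 24d − 3K³/d⁴ + 6 = 0`; for K=21 the positive root is d ≈ 3.4159,
so d=3 is used in practice.  The attention module is

```
z = lReLU(GN(x));   A = σ(pointwise(DWD(DW(z))));   out = A ⊗ z + z
```

with A ∈ (0,1), so features are amplified by a factor in (1, 2) — the
gate selects, it never destroys.  The module drops into a six-scale 3D
U-Net (channels 32→512, deep supervision at the four finest scales);
placing a single equal-21 module at the middle decoder scale adds only
76.67 k parameters (+0.0759 %) to the ~101 M backbone.

Because no GPU framework is required, the networks run on a small
pure-NumPy autodiff engine with im2col-based 3D convolutions
(`lka3d.nn`) — practical for the desk-scale problems this package
targets: method development, teaching, synthetic-phantom studies, and
exact parameter/complexity accounting.

## Worked example

```python
>>> from lka3d.complexity import complexity_table, format_table, optimal_dilation
>>> print(format_table(complexity_table([32, 512], K=21, d=3)))
     C      N_PRM,O      N_PRM,D      D/O
    32       9.48 M      16.10 k    0.17%
   512    2427.72 M     503.30 k    0.02%
>>> round(optimal_dilation(21), 4)
3.4159
```

Parameter accounting of the network variants
(`python examples/03_network_variants.py`):

```
Base network:   100,988,988 parameters (100988.99 k)
Mid  network:   101,065,916 parameters (+76.93 k total, +76.67 k attention convs)
Full network:   101,435,036 parameters (+446.05 k total, +444.06 k attention convs)

Mid relative increase: 0.0759%
```

The Base network is the plain six-scale U-Net; Mid adds one equal-21
attention module at the middle decoder scale (40×48×32 grid, 128
channels); Full adds one module at every decoder scale.  Each variant
exceeds Base by exactly the closed-form parameter count of its modules.

Metric conventions (`python examples/04_metrics.py`):

```
Dice of one-voxel-shifted cubes: 0.500  (4 shared of 8+8)
HD95 of planes 3 voxels apart at 1 mm spacing: 3.0 mm
false-positive enhancing-tumor case: Dice 0, HD95 373.13 mm (penalty)
region voxel counts: {'ET': 1, 'TC': 9, 'WT': 17} (ET within TC within WT)
```

The `examples/` directory holds one short script per capability:
complexity analysis, the attention module, network variants, metrics,
and an end-to-end phantom training run.

## Command line

```bash
lka3d complexity --channels 32,64,128,256,512 --kernel 21 --dilation 3
lka3d phantom --dims 64,64,64 --classes 3 --seed 0 --out data/
lka3d train --config cfg.yaml --manifest data/manifest.csv --out run/
lka3d predict --ckpt run/best.npz --in case.nii.gz --out preds/ --save-attention
lka3d evaluate --pred preds/ --gt labels/ --out eval/ [--compare other_preds/]
```

`--save-attention` writes each attention map as a NIfTI volume aligned to
the input grid (nearest-neighbour upsampled), which is the model's local
explanation of where it looked.

## Scope

Multi-organ CT and multi-modal MR tumor segmentation are the intended
applications: softmax heads for exclusive organ classes, sigmoid heads
for nested tumor regions (enhancing tumor ⊆ tumor core ⊆ whole tumor),
weighted soft-Dice or BCE+Dice losses, the standard augmentation battery
(brightness, contrast, noise, blur, gamma, scaling, rotation, elastic,
flips), NIfTI I/O with spacing-aware resampling, and Dice/HD95 evaluation
with paired t-tests between model variants.  GPU-scale training on full
clinical datasets is out of scope; see `docs/methods.md` for the model
details, parameter choices and limitations.
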