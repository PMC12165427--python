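# glioseg3d

3D multimodal MRI glioma segmentation with an improved 3D U-Net:

- **phantom** — synthetic BraTS-style cases (4 co-registered modalities, nested
  necrotic-core / enhancing-rim / edema compartments, Gaussian noise, smooth
  polynomial bias fields) so the entire pipeline is testable with no external data;
- **preprocess** — MSE-driven deformable registration with a smoothness penalty,
  z-score normalization (truncated to [-5, 5], mapped onto [0, 1]), local-statistics
  noise estimation, bistable stochastic-resonance enhancement gated on PSNR, and
  brain-box cropping/resampling; an N4 bias-correction hook (SimpleITK if present,
  polynomial-fit fallback otherwise);
- **network** — residual encoder with strided downsampling, an ASPP bottleneck
  (1×1×1 conv, three 3×3×3 atrous convs at rates 6/12/18, global-average pooling),
  channel-attention skip fusion (MFAB), trilinear-upsampling decoder, and deep
  supervision heads summed at full resolution. Instance normalization and Leaky
  ReLU throughout; a 128³ input reaches an 8³ bottleneck (16× per axis);
- **loss** — compound Dice (Tversky-form, α/β) + Focal (exponent 2, weight λ)
  objective on softmax probabilities;
- **metrics** — DSC, recall, precision, IoU, HD95 over the WT/TC/ET regions
  (labels {1,2,4} / {1,4} / {4});
- **train** — Adam (lr 1e-3, weight decay 1e-4), seeded 80/20 splits,
  checkpointing, per-case + aggregate evaluation.

Everything runs on CPU with numpy/scipy only: the network is built on a small
purpose-written reverse-mode autodiff engine (`glioseg3d.autodiff`) providing 3D
convolution, instance norm, trilinear resize, and friends, each gradient-checked
against finite differences in the test suite.

## CLI

```sh
glioseg3d generate --num-cases 8 --grid-shape 64 64 64 --seed 0 --out data/raw
glioseg3d preprocess --manifest data/raw/manifest.json --out data/prep \
    --target-shape 64 64 64 --no-sr
glioseg3d train --manifest data/prep/manifest.json --checkpoint-dir ckpt \
    --epochs 20 --base-channels 16 --depth 4 --seed 0
glioseg3d predict --checkpoint ckpt/best.npz --t1 t1.nii.gz --t1c t1c.nii.gz \
    --t2 t2.nii.gz --flair flair.nii.gz --out seg.nii.gz
glioseg3d evaluate --checkpoint ckpt/best.npz --manifest data/prep/manifest.json \
    --out metrics.csv
glioseg3d run --config config.yaml          # full pipeline with stage caching
```

A pipeline config (YAML; unknown keys are rejected):

```yaml
version: 1
workdir: runs/demo
generate:   {num_cases: 8, grid_shape: [32, 32, 32], seed: 0}
preprocess: {target_shape: [32, 32, 32]}
network:    {base_channels: 16, depth: 4}
loss:       {alpha: 0.5, beta: 0.5, lambda: 1.0}
train:      {epochs: 20, learning_rate: 0.001, weight_decay: 0.0001, seed: 0}
```

## Conventions

- Label coding follows BraTS: {0 background, 1 necrotic/non-enhancing core,
  2 edema, 4 enhancing tumor}; internally classes are {0,1,2,3} with a 4↔3
  remap at the I/O boundary.
- Channels are stacked (T1, T1C, T2, FLAIR); grids are 0-based (x, y, z)
  matching the NIfTI affine; displacements are in voxels.
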