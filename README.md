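# sphfod

Voxel-wise white-matter fiber orientation distribution (FOD) estimation from
reduced multi-shell diffusion MRI, using an SO(3)-equivariant spherical CNN
that operates on per-shell spherical-harmonic (SH) coefficients.

The package contains:

- **`sphfod.sphharm`** — real symmetric (even-degree, lmax = 8 → 45
  coefficients) SH basis in MRtrix3-compatible ordering, forward/inverse
  spherical Fourier transforms on deterministic sphere samplings (Fibonacci /
  icosphere), and numerically constructed block-diagonal SH rotation
  operators used for equivariance testing.
- **`sphfod.simulate`** — synthetic multi-shell phantom generator emulating a
  reduced neonatal protocol (19/26/38 directions at b = 400/1000/2600 s/mm²,
  83 volumes total): axially symmetric tensor kernels, Funk–Hecke SH
  convolution, Rician noise, planted 1–3-fiber configurations with
  ground-truth FODs, and per-shell SH fitting.
- **`sphfod.model`** — the spherical CNN: degree-wise equivariant
  convolutions (one scalar weight per degree, shared over orders; bias on
  l = 0 only; residual connections when channel counts match), the
  ISFT → LeakyReLU → SFT spherical nonlinearity, a softmax shell-attention
  module (48-dim pooled features → 24 → 3 simplex weights), an
  encoder–decoder over 16/32/64 channels with a batch-normalized fully
  connected head, and an MLP baseline (4 × 256 + batch norm + ReLU).
- **`sphfod.train`** — spatial-domain MSE loss (amplitude differences after
  ISFT), AdamW with decoupled weight decay, learning-rate halving every 17
  epochs, gradient clipping at global norm 10, and percentile intensity
  normalization.
- **`sphfod.metrics`** — SH-domain MSE, angular correlation coefficient,
  channel-wise 3D SSIM, PSNR, FOD peak extraction (neighbor-graph local
  maxima with antipodal deduplication and off-grid Newton refinement),
  angular error and peak match rate.
- **`sphfod.io` / `sphfod.cli`** — NIfTI + FSL bvals/bvecs readers/writers,
  phantom serialization, run manifests, and the `sphfod` command-line tool.
- **`sphfod.nn`** — a self-contained numpy reverse-mode autodiff engine with
  the layers/optimizers the models need (no deep-learning framework
  dependency; gradients are verified against finite differences in the test
  suite).

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria; its learning
experiment trains the sCNN and the MLP baseline on a 20,000-voxel phantom on
one CPU and takes the bulk of the suite's runtime (~10–15 min).

## CLI

```bash
# 1. generate a synthetic phantom (DWI + bvals/bvecs + mask + ground-truth FOD)
sphfod simulate --n-voxels 5000 --seed 7 --snr 20 --out phantom/

# 2. train the spherical CNN (or --model mlp for the baseline)
sphfod train --data phantom/ --model scnn --epochs 20 --lr 1e-3 \
             --batch-size 1024 --nonlin-points 128 --dtype float32 --out run/

# 3. voxel-wise FOD prediction inside the mask -> 45-channel SH NIfTI
sphfod predict --dwi phantom/dwi.nii.gz --bvals phantom/bvals \
               --bvecs phantom/bvecs --mask phantom/mask.nii.gz \
               --checkpoint run/scnn.npz --out pred.nii.gz

# 4. compare two SH images: JSON metric report + per-voxel ACC / angular-error maps
sphfod evaluate pred.nii.gz phantom/fod_gt.nii.gz \
                --mask phantom/mask.nii.gz --out report.json
```

Every command writes a YAML manifest (seed, config, input digests) into its
output directory.  A global `--config experiment.yaml` supplies default
values for any subcommand option (CLI flags still win).

## Conventions

- SH basis: real, symmetric, orthonormal; coefficients ordered by ascending
  even degree l, then ascending order m (MRtrix3-compatible), so SH NIfTI
  volumes written here load in standard FOD viewers.
- Directions are 3D Cartesian unit vectors; gradients follow the FSL
  bvals/bvecs dialect (3×V text files); shells are grouped within
  ±50 s/mm².
- SH images are 4D NIfTI files with 45 volumes; masks are binary NIfTI.
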