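# tofrecon

Few-shot reconstruction toolkit for highly accelerated 3D time-of-flight MR
angiography (TOF-MRA). It packages the full pipeline:

* **`tofrecon.phantom_io`** — NIfTI volume I/O, overlapping-slab splitting
  (multi-slab acquisition geometry), and a synthetic TOF-like phantom
  (ellipsoidal head + bright tubular vessels) so everything runs offline.
* **`tofrecon.ksim`** — raw k-space simulation from magnitude volumes: phase
  synthesis (Gaussian-weighted complex noise corrupting the conjugate-symmetric
  k-space), boundary-centered coil-sensitivity synthesis (SoS-normalized),
  random polynomial bias fields, readout partial Fourier, and variable-density
  Poisson-disc ky–kz undersampling with a fully sampled calibration block.
* **`tofrecon.mri_ops`** — centered unitary FFTs, coil expand/reduce, RSS,
  SVD coil compression, center cropping, zero-filling and L1-wavelet (FISTA)
  compressed-sensing baselines (orthonormal Haar DWT included).
* **`tofrecon.varnet`** — an unrolled end-to-end variational network for 3D
  thin-slab inputs: sensitivity-estimation U-Net, cascaded refinement U-Nets,
  hard/soft data consistency that pins the acquired samples (including the
  partial-Fourier policy: the unacquired band is left to the network), and
  anisotropic 4/4/2 down/up-sampling (slice axis pooled only at the first two
  levels). Implemented in pure numpy with exact, finite-difference-verified
  manual backpropagation — no deep-learning framework required.
* **`tofrecon.metrics`** — PSNR, 3D SSIM, NMSE, axial MIP, reference-derived
  vessel masks (Frangi vesselness + brightness cue) and vessel-masked SSIM.
* **`tofrecon.training`** — the few-shot protocol: Adam + L1+SSIM loss,
  per-load Poisson-mask re-randomization, validation-based early stopping,
  pre-training and warm-started fine-tuning. Fully deterministic given a seed.

Default `VarNetConfig` hyperparameters reproduce the published model sizes:
29.9 M trainable parameters for the 2D baseline and 84.6 M for the 3D variant.

## CLI

```bash
tofrecon simulate --R 8 --coils 32 --pf 0.26 --calib 12 6 --seed 1 --out acq.h5
tofrecon mask --ny 64 --nz 24 --R 8 --out mask.npy
tofrecon recon --method zero_fill|cs|varnet3d --acq acq.h5 [--ckpt best.npz] --out rec.nii.gz
tofrecon evaluate --recon rec.nii.gz --ref ref.nii.gz --out metrics.json
tofrecon train pretrain --data acqs/ --R 8 --epochs 10 --out ckpt/
tofrecon train finetune --ckpt ckpt/best.npz --data twoslabs/ --out ckpt_ft/
tofrecon demo --seed 7 --out demo_out   # end-to-end phantom pipeline (~2 min)
```

`simulate` uses the built-in phantom when `--input` is omitted; pass any 3D
magnitude NIfTI (e.g. IXI volumes, optionally split with
`tofrecon.phantom_io.split_slabs`) otherwise. Every run writes a
resolved-config snapshot and an output manifest next to its artifacts.

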