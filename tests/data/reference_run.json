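{
  "description": "Committed reference for the scaled-down learning experiment: 20,000 train / 2,000 test voxels, SNR 20, Watson kappa 10 ground-truth kernel, Laplace-Beltrami-regularized per-shell SH inputs (ridge 3e-3), sCNN 26 epochs / batch 512 / lr 3e-3 / 128-point sampling / float32 / seed 1, MLP baseline identical except 5x training batches. Single CPU.",
  "experiment": {
    "n_voxels": 22000,
    "seed": 20250906,
    "snr": 20.0,
    "watson_kappa": 10.0,
    "fit_ridge": 0.003,
    "fit_regularizer": "laplace_beltrami",
    "epochs": 26,
    "batch_size": 512,
    "lr": 0.003,
    "sampling_points": 128
  },
  "scnn": {
    "acc_mean": 0.9357395087195923,
    "ae_mean": 9.512367335634204,
    "pmr": 0.8905,
    "mse": 0.04774230482473855,
    "psnr_db": 24.195239374096445
  },
  "mlp": {
    "acc_mean": 0.9316038817662243,
    "ae_mean": 11.007561046971093,
    "pmr": 0.8745,
    "mse": 0.04920715104126117,
    "psnr_db": 24.06399097437991
  },
  "tolerance": {
    "acc": 0.02,
    "ae_deg": 2.0,
    "pmr": 0.03
  }
}
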