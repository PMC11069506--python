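# ptoct

Photothermal OCT (PT-OCT) simulation, lock-in reconstruction, and neural
short-trace amplitude prediction.

## The problem

PT-OCT localises light-absorbing molecules inside scattering tissue: a pump
laser, intensity-modulated at a frequency *f*ₘ, heats absorbers and the
resulting thermoelastic optical-path-length oscillation modulates the OCT
phase.  The per-pixel photothermal amplitude is conventionally estimated by
lock-in demodulation of an M-scan phase record at *f*ₘ,

&nbsp;&nbsp;&nbsp;&nbsp;Â = (2/N) |Σₖ φ[k] e^(−i2π fₘ k/fs)|,

and image quality grows with the record length *N*.  High-SNR images
therefore need ~20 modulation cycles per pixel (864 samples at
fs = 21.6 kHz, *f*ₘ = 500 Hz), which makes acquisition slow.  This package
implements, end to end on synthetic data, the alternative: a small
fully-connected network (88 → 10 → 5 → 1, ReLU hidden layers, linear
output) that maps a ~2-cycle short trace (88 samples, referenced to its
first sample) directly to the amplitude that 20-cycle demodulation would
report.  The short trace carries more than its share of information because
it contains the bulk-heating transient (1 − e^(−t/τ)), which is itself
correlated with absorption — signal that the lock-in discards.

The package provides:

- `ptoct.synth` — a physics-based M-scan generator (modulated phase,
  exponential thermal transient, white + 1/f phase noise at the 14.6 mrad
  system floor, Lorentzian confocal depth falloff, depth-attenuated OCT
  intensity) that exposes its latent per-pixel amplitudes for ground-truth
  scoring;
- `ptoct.lockin` — exact-frequency and FFT-bin single-tone demodulation,
  the 20-dB intensity validity mask, GT/ST image formation and training-pair
  extraction;
- `ptoct.ptnet` — the network: forward pass, backpropagation, ADAM, and
  10-fold cross-validated training, all in plain numpy;
- `ptoct.metrics` — region-wise Michelson contrast, MSE and a single global
  SSIM, assembled into comparison reports;
- `ptoct.experiments` — seeded end-to-end studies: the phantom pipeline
  (in/out of focus), cycle-group and cross-sample generalization, and the
  input-length sweep.

## Worked example

```python
from ptoct import (PhantomLayout, SimulationConfig, simulate_phantom_mscan,
                   reconstruct_image, extract_training_pairs, NetworkConfig,
                   TrainConfig, train_kfold, predict_image,
                   regions_from_labels, metrics_report)

layout = PhantomLayout.bands(n_depth=110, n_lateral=160)   # P0..P3 power bands
cube, truth = simulate_phantom_mscan(layout, SimulationConfig(), seed=1)

gt = reconstruct_image(cube, n_use=864)   # 20-cycle lock-in (ground truth)
st = reconstruct_image(cube, n_use=88)    # 2-cycle lock-in (short trace)

pairs = extract_training_pairs(cube)      # one pair per masked pixel
tc = TrainConfig(pool_size=15000, epochs=40, batch_size=512, k_folds=10, seed=0)
folds, selected = train_kfold(pairs, NetworkConfig(), tc)
net = predict_image(selected.params, cube)

rep = metrics_report(gt, st, net, regions_from_labels(layout.region_labels))
```

Output for one absorber pixel and the whole image (printed by the code
above on this package's defaults):

```
latent: 0.105  GT: 0.0931  ST: 0.0256  NET: 0.0855      # radians
P0-P1 contrast GT/ST/NET: 86.5 / 22.6 / 63.9            # percent
overall SSIM vs GT  ST/NET: 29.6 / 96.8                 # percent
overall MSE  vs GT  ST/NET: 8.84e-04 / 4.63e-05
```

Reading it: the 2-cycle conventional estimate (0.0256 rad) badly
underestimates the 20-cycle amplitude (0.0931 rad) because the thermal
transient suppresses the early modulation; the network, fed the same 88
samples, recovers 0.0855 rad.  Over the image the network's error against
the GT is ~20× below the conventional short-trace error, and the contrast
between the non-absorbing band P0 and the weakest absorber band P1 rises
from 23% to 64% (86% in the GT).

A `ptoct` CLI wraps the same pipeline for shell use
(`ptoct simulate / reconstruct / train / infer / evaluate / experiment`);
M-scans travel as HDF5, images as float32 TIFF + JSON sidecar, models as
JSON.

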