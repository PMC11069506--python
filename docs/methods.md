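# Methods

## Forward model of the synthetic M-scan

Each pixel's OCT phase record is simulated as

φ[k] = A (1 − e^(−t_k/τ)) sin(2π fₘ t_k + ψ) + P_dc (1 − e^(−t_k/τ)) + w[k] + p[k],  t_k = k/fs,

with

- **A** — steady-state photothermal modulation amplitude,
  A = R · P · (f_ref/fₘ)^γ · C(z).  R is the responsivity
  (0.03 rad/mW at f_ref = 500 Hz, in focus), P the pump power of the
  pixel's phantom region, γ the thermal frequency-falloff exponent
  (default 1: the amplitude drops ~8× between 500 Hz and 4 kHz), and
  C(z) = 1/(1 + ((z − z_f)/z_R)²) the Lorentzian confocal factor
  (focal row z_f = 60, Rayleigh range z_R = 40 px by default).  This
  three-knob expression is a declared stand-in for a full thermal
  Green's-function solution: it reproduces the facts that matter for the
  reconstruction problem (linear in power, falls with modulation
  frequency, falls away from focus) without solving the bioheat equation.
- **τ** — thermal transient time constant, default 4 ms ≈ 2 modulation
  cycles at 500 Hz: the bulk-heating ramp dies out after a few cycles.
- **P_dc** — bulk-heating plateau, P_dc = R_dc · P · (f-independent
  scaling as above) with R_dc = 0.03 rad/mW.  The DC:AC ratio of 1 was
  chosen so the 2-cycle conventional estimate lands near one third of the
  20-cycle value, the regime observed on real systems; a much larger
  plateau would make short-window demodulation leakage-dominated, which
  real PT-OCT records do not show.
- **w** — white Gaussian phase noise at the system phase-stability floor,
  σ = 14.6 mrad.  Optionally the per-pixel σ follows
  max(floor, 10^(−SNR_dB/20)) for SNR-dependent noise.
- **p** — pink noise with PSD ∝ 1/f, synthesised by Hermitian spectral
  shaping of white Gaussian noise (DC bin zeroed, weights f^(−exp/2)
  normalised to unit RMS gain), default RMS 10 mrad.  No quantitative
  pink level is published for such systems; 10 mrad puts the pink and
  white components at comparable power, which is the interesting regime
  for short-window demodulation.
- ψ — thermal phase lag at t = 0, default 0 (unknown for real systems;
  configurable).

The OCT intensity image is surface level (45 dB) minus 0.25 dB per depth
pixel below the surface, the noise floor above it, plus 2 dB additive
Gaussian speckle on the dB scale — enough structure for the standard
20-dB-above-floor validity mask to carve out a realistic "meaningful
pixel" set; no speckle-resolved complex OCT field is simulated.  Depth is
the first image axis (row 0 on top), time the last; indices are 0-based.

What the generator does **not** emulate: depth-cumulative phase shadowing
below strong absorbers, speckle decorrelation of the phase, sample motion,
and any nonlinearity of the thermal response.  Tests passing on this
generator therefore show that the reconstruction and learning machinery
behaves as designed under the stated statistical structure — not that the
network transfers to artefacts the generator omits.

## Conventional reconstruction

The lock-in amplitude is the single-bin DFT magnitude
(2/N)|Σ φ[k] e^(−i2π fₘ k/fs)| over the first N samples.  Two modes:
`exact_freq` (correlation at exactly fₘ; the default) and `fft_bin`
(nearest DFT bin).  At fs = 21.6 kHz and fₘ = 500 Hz an 88-sample window
spans 2.04 cycles, so the FFT bin sits between bins and scallops;
`exact_freq` decouples results from that windowing artefact while
`fft_bin` is retained for fidelity to FFT-based pipelines.  Both agree
exactly on integer-cycle windows (multiples of 216 samples).  Traces are
referenced to their first sample before any use (OCT phase is relative;
referencing preserves the DC-ramp shape), no window, no detrending, no
averaging: the transient is deliberately kept in band.  The validity mask
is inclusive: intensity ≥ floor + 20 dB.

GT = 864-sample (20-cycle) demodulation; ST = 88-sample (2-cycle)
demodulation; both taken from the start of the record.  With the default
τ = 4 ms the decaying transient biases even the 864-sample GT by
≈ fs·τ/N ≈ 10% relative to the latent steady-state amplitude; this is a
property of the measurement convention, not an error, and it is why
parameter-recovery tests that check the demodulation path to 1% use a
transient-free configuration (τ → 0) with noise off.

## Network and training

Architecture 88-10-5-1 (two ReLU hidden layers, linear scalar output);
the input-length study uses n-40-20-5-1.  Weights start i.i.d. uniform on
±0.05, biases at zero (the published init range being unstated, ±0.05 is
a conventional small-uniform choice); inputs are first-sample-referenced
raw phase, unstandardised, so the transient ramp survives as a feature.
Loss is MSE; optimisation is mini-batch ADAM (lr 1e-3, β 0.9/0.999,
ε 1e-8 — the standard defaults, the published values being unstated),
batch 512, shuffling reseeded each epoch from the master seed, last
incomplete batch used.  No regularisation.  Training uses k-fold
cross-validation (k = 10): the pool is sampled without replacement,
partitioned into near-equal folds, one network trained per fold on the
rest, and the returned model chosen seeded-uniformly among folds; all
fold metrics are reported.  Negative image predictions are clipped at 0
(the amplitude is a magnitude) with the clip count logged.

Single-net training (the sweep studies) supports seeded random restarts
(`TrainConfig.restarts`, default 1; the sweep defaults use 2, keeping the
run with the lowest final training MSE): small uniformly initialised ReLU
networks occasionally die into a constant predictor, and a restart is the
standard guard.  The k-fold recipe keeps one run per fold.

Gradient correctness is established against central finite differences
(relative error < 1e-5 away from ReLU kinks, where finite differences are
invalid and the check point is redrawn) and the forward pass against an
independently loaded scikit-learn `MLPRegressor` with identical weights.

## Metrics

Michelson contrast between two regions uses the region-mean amplitudes,
C = 100·(L_max − L_min)/(L_max + L_min): per-pixel extrema over a noisy
region would be outlier-dominated and could never produce the near-zero
contrasts that a short-trace image shows between its weakest bands; a
literal per-pixel-extrema variant is provided for single-window use.
MSE is the plain pixel mean of squared differences over the jointly
masked region.  SSIM is computed once, globally, from population (1/n)
moments over the jointly masked pixels,

SSIM = (2μ_Aμ_B + C1)(2σ_AB + C2) / ((μ_A² + μ_B² + C1)(σ_A² + σ_B² + C2)),

with C1 = (0.01·L)², C2 = (0.03·L)², and L defaulting to the GT image's
masked maximum.  Contrast and SSIM are reported ×100.  For four regions
the contrast table pairs P0 with every other region plus adjacent
absorber pairs (5 pairs).

## Experiments and problem sizes

All studies are pure functions of (config, seed); reports carry a config
hash, the seed and the package version, and reruns are byte-identical.
The desk-scale defaults were sized so the whole suite runs in about a
minute per study on one CPU while keeping every comparison well above
Monte-Carlo noise:

- **phantom pipeline** — two 110×160 px cubes (in focus, and with the
  focal plane shifted 50 px), ~22 000 masked training pixels across both,
  pool 20 000, 40 epochs, k = 10.  Training pairs come from 70% of the
  columns of every power band; images and metrics from the held-out 30%
  (splitting within bands keeps all power levels in both partitions).
- **cycle-group study** — 110×60 px cube, 9 two-cycle groups of an
  18-cycle (792-sample) record, GT from the full record, one 88-input net
  per group (25 epochs, 2 restarts), 9×9 cross-test MSE matrix.  The
  diagonal-minimum property is asserted only for the transient-bearing
  groups 1–2; for later groups the envelope differences between adjacent
  groups shrink below the training-noise floor and the matrix is reported,
  not asserted.
- **cross-sample study** — three synthetic sample types that differ in
  signal *shape* at matched noise: a dye phantom (τ = 4 ms, DC:AC = 1,
  powers 0/1/2.25/3.5 mW), a lipid-plaque analogue (slower, τ = 6 ms,
  DC:AC = 2, pinker phase), and an adipose analogue (faster, τ = 2.5 ms,
  DC:AC ≈ 0.4).  Matching difficulty across types is what lets the 4×3
  cross-test matrix isolate distributional transfer; types that differ
  mainly in amplitude scale would confound transfer with test hardness.
- **input-length sweep** — 110×80 px cube, inputs of round(44·c) samples
  for c ∈ {1, 1.5, 2, 3, 4} (the acceptance check uses the integer grid),
  n-40-20-5-1 nets, 30 epochs, 2 restarts, GT from the first 880 samples
  (20 nominal cycles — the 864 vs 880 GT conventions of the base pipeline
  and this study are deliberately kept distinct).

## Known limitations

- The thermal stand-in has no depth diffusion: amplitude depends on depth
  only through the confocal factor, so axial blurring of real
  photothermal fields is absent.
- The phase record is Gaussian; real phase noise near the intensity mask
  boundary is heavier-tailed (phase wrapping is not simulated).
- The cycle-group diagonal-minimum property for group 2 is decided by a
  few-percent MSE margin at these problem sizes and flips in a minority
  of random replicates; the acceptance fraction is reported over 8
  replicates for stability.
- Networks are trained and evaluated on the same generator family;
  nothing here measures transfer to experimentally acquired phase data.
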