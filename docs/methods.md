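# Methods

`spectramt` implements a cross-temporal classification pipeline for NIR
reflectance spectra of shell eggs: reflectance calibration, Standard Normal
Variate (SNV) preprocessing, competitive adaptive reweighted sampling (CARS)
wavelength selection driven by PLS-DA, and a multi-task deep network
(1-D CNN + squeeze-and-excitation + Transformer encoder, "MT-CTSE") that
jointly classifies egg variety (3 classes) and storage period (day 1 / 20 /
40). Because no real hyperspectral egg data are publicly deposited, the
package ships a synthetic-spectra generator whose class structure and
storage-induced drift emulate the phenomenology of such data, giving every
stage a testable substrate with known ground truth.

## Synthetic spectra

A clean spectrum is a constant reflectance baseline (0.80) minus a sum of
Gaussian absorption bands:

    r(λ) = r_base − Σ_p d_p · m_p(variety) · (1 − δ_p)^day · exp(−(λ − c_p − s_p·day)² / 2w_p²)

on a 273-point grid over 1000–2500 nm. The seven bands follow standard NIR
assignments: O–H second overtone near 1200 nm, the 1450 nm O–H first
overtone and 1950 nm O–H combination band (water), C–H lipid bands at
1720/1780 nm, and N–H/C–O protein/carbohydrate bands at 2180/2280 nm.
Storage drift enters through the per-day fractional depth decay δ_p —
largest for the water and lipid bands (moisture loss, lipid oxidation) — and
the per-day centre shift s_p, sized so the variety-discriminative bands have
moved by roughly one grid spacing at day 40. Attenuation **and** shifting
together are what make the task cross-temporal: a variety classifier that is
unaware of storage stage sees late-day classes smeared along the wavelength
axis, while a model that also infers the stage can compensate the shift —
the coupling that makes joint variety/period modelling pay off. Variety
identity enters through the multipliers m_p: variety 1 is strongest at
1200 nm, variety 2 in the lipid region, variety 3 in the
protein/carbohydrate region.

Each of the 100 eggs per variety draws one log-normal per-peak depth jitter
(sd 0.12) held fixed across its three storage days — the biological
between-egg variability that makes the task hard and makes egg-level data
splits meaningful. Each (egg, day) sample receives one draw of acquisition
artefacts: a log-normal multiplicative scatter gain (log-sd 0.08), a Gaussian
baseline offset (sd 0.04) and a Gaussian wavelength-linear slope (sd 0.05).
The three replicate scans of a sample share those artefacts (they come from
sample placement and surface state, which do not change between immediate
rescans) and differ only by iid sensor noise (sd 0.002), so the replicate
coefficient of variation stays at instrument-stability levels. The scatter
gain is wavelength-dependent — g(λ) = exp(η + ζ·(t − 1/2)) with a per-sample
log-gain η (sd 0.08) and log-tilt ζ (sd 0.06) over the normalised wavelength
t — because scattering strength varies across the NIR range. SNV removes the
constant-gain and offset parts exactly; the gain tilt and the additive slope
(sd 0.05) survive it and act as structured per-sample nuisance the
classifier must learn to ignore.

Effect sizes were fixed once so that a linear classifier (LDA on all SNV
bands) reaches roughly 60–75% day-40 variety accuracy while the full deep
model exceeds 85% on held-out eggs — a separability regime comparable to
real storage studies, without copying any published number. What the
generator does **not** emulate: spatial texture within an egg, photon-noise
physics, wavelength-dependent instrument response, inter-day instrument
drift, or correlated biochemistry between bands; passing tests therefore
demonstrate correctness and the qualitative multi-task advantage under
drift, not field performance on real eggs.

Per-egg RNG substreams are keyed by (variety, egg index), so enlarging the
campaign never perturbs already-simulated eggs.

## Calibration and preprocessing

Two-point calibration converts raw counts to reflectance,
R = (raw − dark)/(white − dark), with a dead-pixel error wherever
white = dark; values outside [0, 1] are kept (SNV is location/scale
invariant, and clipping would bias noise). A 20 × 20 pixel region of
interest, centred by default, is averaged into one spectrum per scan; the
three replicate scans of a sample are averaged with a per-band CV check
(warn above 2%; sample sd, N−1). The analysis dataset is therefore one
spectrum per egg per day (900 samples). SNV standardises each spectrum to
zero mean and unit sample variance; a constant spectrum is an error naming
the scan.

## Band selection (CARS-PLS-DA)

PLS-DA is fitted by NIPALS on column-centred X and a one-hot class
indicator Y (no column scaling — rows are already SNV-standardised).
Degenerate components stop extraction early with a warning. The latent
count is chosen by Monte-Carlo cross-validation (default 80/20 splits; one
fit per split evaluated at every candidate count; ties to the smaller
count).

CARS runs R = 100 sampling iterations. Each iteration fits PLS-DA on a
random 80% subsample restricted to the currently retained bands, ranks
bands by mean |regression coefficient| across indicator columns (ties to
the lower index, for determinism), enforces the exponentially decreasing
retention count, then resamples that many bands with replacement with
probability proportional to weight (adaptive reweighted sampling); the
retained set is scored by 5-fold RMSECV on the indicator response over all
samples, with one fold partition shared across iterations so subsets
compete on equal folds. The schedule N_iter(r) = round(N_total·a·e^(−kr))
has a, k fixed by N_iter(1) = N_total and N_iter(R) = floor (= 2), forced
non-increasing after rounding. A power-law schedule N_total·(r/R)^α is
exposed as an alternative for comparison; note it grows with r, so the
exponential decay is the default.

Cross-temporal selection is two-stage: CARS per storage day (variety
labels), then a second CARS pass on the pooled all-day data restricted to
the union of the per-day selections. The pooled pass uses the joint
variety × day labelling so the final set serves both tasks. "Re-filtering"
is implemented as a genuine second CARS pass rather than a VIP threshold.
VIP scores quantify each final band's contribution;
VIP_j = sqrt(p·Σ_a SSY_a(w_ja/‖w_a‖)²/Σ_a SSY_a) with SSY_a the Y-variance
explained by component a, so Σ_j VIP_j² = p exactly.

## Network

The backbone runs: same-padded conv1d + ReLU stacks (sequence length
preserved, so spectral positions remain token positions), a linear lift of
the channel vector to d_model, a squeeze-and-excitation gate (global
average pool over the sequence, a two-layer bottleneck with ReLU then
sigmoid; the output-gate bias is initialised at +2 so the gate starts near
pass-through, sigmoid(2) ≈ 0.88, and learns to suppress channels — a
closed-at-0.5 gate initially halves every token relative to the
unit-amplitude positional encoding and measurably slows training),
sinusoidal positional encoding, and a four-layer post-norm Transformer
encoder (multi-head
scaled-dot-product attention, ReLU feed-forward, LayerNorm, residuals,
dropout 0.2; pre-norm available via config). Encoder outputs are globally
average-pooled and fed to one fully connected softmax head per task; in
multi-task mode the two heads read the same backbone parameters (hard
sharing — one storage, not copies). Positional encoding is added after the
SE gate, immediately before the encoder, following the order in which the
components are described. Ablation variants drop the CNN stack and/or SE
gate; single-task variants expose one head; pure-CNN baselines drop the
encoder.

The network and its training loop run on a small in-package reverse-mode
automatic-differentiation engine over NumPy arrays (`spectramt.nn`):
broadcast arithmetic, fused affine/conv1d/layer-norm/softmax/attention ops,
dropout, and an AdamW optimiser with decoupled weight decay. Float64 is the
default so analytic gradients check against central finite differences to
≤1e-3 relative on every block; training can switch to float32
(`TrainConfig.dtype`), which roughly halves CPU time and is the setting the
experiment harness uses.

## Training protocol

Joint loss L = α·CE(variety) + β·CE(period) with α = β = 0.5; single-task
variants optimise one term. Optimisation is AdamW (lr 0.001, weight decay
1e-4, decoupled; biases and norm affines excluded from decay) with cosine
annealing of the learning rate to 0 over the epoch budget (no restarts),
minibatch shuffling, and early stopping on validation loss with
best-weight restoration. The library default budget is 800 epochs, batch
32, patience 50.

All splits are at egg level and stratified by variety: an outer 80/20
train/test split (test isolated from band selection as well), an inner
validation slice (15% of training eggs) for early stopping, and an optional
egg-level 5-fold cross-validation utility that reports mean ± sd per fold.
No egg's scans ever cross a boundary.

## The experiment harness and its problem sizes

`reproduce` runs the whole design end-to-end and writes per-variant,
per-seed, per-slice reports: variety accuracy sliced by storage day,
period accuracy sliced by variety, pooled metrics, and mean ± sd comparison
tables. The harness defaults are chosen for a single desk CPU: replicate
averaging to 900 samples; CARS with 100 iterations but 100 (not 1000) MCCV
splits for the latent count; a dimensionality budget of 24 bands — when the
re-filtered cross-temporal set is larger, the highest-VIP bands are kept
(VIP thresholding as a final tightening of the two-stage selection); a
narrower network (d_model 32, FFN 64, conv channels 16/32, reduction 4 —
same four-layer depth and head count as the library defaults); 80 epochs,
batch 32, lr 0.0015 with a 5-epoch linear warmup (the post-norm encoder is
unstable without one), patience 20, float32. Five model seeds × five
variants (single-task, full multi-task, and the three ablations) complete
in roughly 12–15 minutes. Every run directory
contains the resolved config, global seed, stage-tagged log, input hash,
selected bands with VIP scores, and all report tables; all randomness
derives from the single global seed through named substreams, so reruns are
bit-identical on one platform.

## Evaluation conventions

Multi-class metrics are one-vs-rest per class: precision TP/(TP+FP), recall
TP/(TP+FN), F1 their harmonic mean; a zero denominator scores 0 and flags
the class. Overall accuracy is the fraction of correctly classified
samples. Single summary values use the unweighted macro mean over classes
(per-class values are always emitted); metrics are per sample (per averaged
scan), with no egg-level vote.

## Known limitations

- The synthetic generator is a band-amplitude model; conclusions about real
  egg spectra require real data.
- Under the default generator, storage-period discrimination between the two
  later stages is limited by per-egg depth variability (a 20-vs-40-day depth
  difference of ~10–15% against ~12% between-egg jitter), so synthetic
  period accuracy sits in the 60–70% range at desk scale; the variety task,
  the focus of the acceptance checks, is unaffected.
- The NumPy engine is CPU-only and single-threaded by design; it is sized
  for ~10²-band inputs and ~10³-sample datasets, not for large-scale
  training.
- RMSECV inside CARS scores the indicator response with a regression
  criterion, the standard chemometric practice, which is only a proxy for
  classification error.
- With hard parameter sharing and equal task weights, a strongly dominant
  task can in principle crowd out the other; the equal-weight default
  matches the study design rather than an optimised trade-off.
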