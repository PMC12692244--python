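# spectramt

Cross-temporal classification of egg variety and storage period from
near-infrared (1000–2500 nm) reflectance spectra.

Shell eggs of different commercial varieties look alike but differ in
composition, and all of them deteriorate in storage: water bands near
1450/1950 nm and lipid bands at 1700–1800 nm attenuate as eggs dry and
oxidise, so a classifier trained at one storage age degrades at another
("spectral drift"). `spectramt` implements a full pipeline for this problem,
aimed at chemometricians and food-quality researchers working with NIR/HSI
point spectra:

1. **Calibration** — two-point dark/white reflectance correction
   `R = (R_raw − R_dark)/(R_white − R_dark)`, 20×20-pixel ROI mean spectra,
   replicate-scan averaging with a coefficient-of-variation stability check.
2. **Preprocessing** — Standard Normal Variate (SNV): each spectrum is
   standardised to zero mean and unit variance, removing multiplicative
   scatter and baseline offsets.
3. **Wavelength selection** — competitive adaptive reweighted sampling
   (CARS) driven by PLS-DA regression coefficients, with an exponentially
   decreasing retention schedule `N_iter(r) = round(N_total·a·e^(−kr))`,
   Monte-Carlo cross-validation for the latent-variable count, RMSECV as
   the fitness criterion, a two-stage per-day → pooled re-filtering scheme
   for cross-temporal robustness, and VIP scores
   (`Σ_j VIP_j² = p`) for the final band set.
4. **Modelling** — MT-CTSE: a hard-parameter-shared multi-task network
   (1-D CNN → squeeze-and-excitation channel gate → sinusoidal positional
   encoding → 4-layer Transformer encoder → global average pool → one
   softmax head per task) trained with
   `L = α·CE(variety) + β·CE(period)`, α = β = 0.5, AdamW, cosine
   annealing, early stopping, egg-level stratified splits. Single-task and
   ablation variants (no SE, no CNN, neither, CNN-only) share the same
   code path.
5. **Evaluation** — accuracy, per-class and macro precision/recall/F1 from
   one-vs-rest confusion counts, sliced the way drift studies report them:
   variety accuracy per storage day, period accuracy per variety.

Because no real hyperspectral egg dataset is publicly deposited, the
package includes a first-class synthetic-spectra simulator
(`spectramt.synthspec`) with Gaussian absorption bands, storage-dependent
band decay, variety-specific band amplitudes, per-egg biological
variability, and the scatter/baseline artefacts SNV is meant to remove —
with exported ground truth for which bands are informative. The network
runs on a small built-in reverse-mode autodiff engine over NumPy
(`spectramt.nn`), verified against finite differences.

## Worked example

```python
import numpy as np
from spectramt import (default_egg_sim_config, simulate_dataset, snv_table,
                       stratified_egg_split, two_stage_select, CarsConfig,
                       ModelConfig, Variant, TrainConfig, build, fit,
                       evaluate_sliced)
from spectramt.io_calib import average_scan_replicates

cfg = default_egg_sim_config(seed=42)          # 3 varieties x 100 eggs x days {1,20,40}
table = simulate_dataset(cfg)                  # 2700 scans x 273 bands
snv = snv_table(average_scan_replicates(table))  # 900 samples, SNV rows

split = stratified_egg_split(snv, test_fraction=0.2, seed=42)
train_tab, test_tab = snv.select_eggs(split.train_eggs), snv.select_eggs(split.test_eggs)

stages = {d: train_tab.subset((train_tab.labels["day"] == d).to_numpy())
          for d in (1, 20, 40)}
sel = two_stage_select(stages, CarsConfig(R=100, lv_mccv_runs=100, max_lv=12, seed=7))
print(f"{len(sel.final)} cross-temporal bands, e.g. "
      f"{np.round(table.grid.values[sel.final[:5]], 1)} nm")

net = build(ModelConfig(n_bands_in=len(sel.final), conv_channels=(16, 32),
                        d_model=32, ffn_dim=64), Variant.MT_CTSE, seed=0)
net, hist = fit(net, train_tab, sel.final,
                TrainConfig(epochs=80, lr=0.0015, batch_size=32, warmup_epochs=5,
                            early_stop_patience=20, seed=0, dtype="float32"))
for rep in evaluate_sliced(net, test_tab, "by_day", sel.final):
    print(f"day {rep.slice_key:>2}: variety accuracy {rep.accuracy:.3f}, "
          f"macro F1 {rep.macro_f1:.3f}")
```

Output (exact values depend on the seeds):

```
47 cross-temporal bands, e.g. [1011.  1016.5 1027.6 1033.1 1044.1] nm
day  1: variety accuracy 0.933, macro F1 0.933
day 20: variety accuracy 0.967, macro F1 0.967
day 40: variety accuracy 0.933, macro F1 0.933
```

The per-day rows show that variety recognition holds up at day 40, where a
linear baseline on the same data drops to ~0.65–0.75 — the multi-task
backbone absorbs the storage drift instead of confusing it with variety.

The same experiment, over every variant and several seeds, is one command:

```sh
spectramt reproduce --seed 42 --out runs/exp1
```

which writes `reports.csv` (per variant × seed × slice) and
`comparison.csv` (mean ± sd) plus the selected bands, VIP scores, resolved
config, and a stage-tagged log.

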