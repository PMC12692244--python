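"""End-to-end reproducible experiment harness.

``reproduce`` runs the full study design on synthetic data: simulate ->
SNV -> two-stage CARS band selection (on the training portion only, so the
test set is isolated from variable selection) -> train the single-task,
multi-task and ablation variants over several model seeds -> evaluate both
slicings (variety accuracy per storage day, period accuracy per variety) and
emit comparison tables.

All randomness flows from one global seed through named substreams (sim,
split, cars, and per-seed training), so every stage is independently
replayable; each run directory holds the resolved config, seed, log, input
hashes and all result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import bandselect, evaluate, io_calib, model, preprocess, synthspec, train

logger = logging.getLogger("spectramt")

__all__ = ["PipelineConfig", "validate_config", "reproduce", "ReproduceResult"]


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Section):
    n_eggs_per_variety: int = 100
    scans_per_egg: int = 3
    scatter_gain_sd: float = 0.08
    scatter_tilt_sd: float = 0.06
    baseline_offset_sd: float = 0.04
    baseline_slope_sd: float = 0.05
    noise_sd: float = 0.002
    egg_effect_sd: float = 0.12


class CarsSection(_Section):
    R: int = 100
    mc_fraction: float = 0.8
    cv_folds: int = 5
    lv_mccv_runs: int = 100
    lv_mccv_fraction: float = 0.8
    max_lv: int = 12
    floor: int = 2
    # dimensionality budget: cap the final cross-temporal set at the
    # highest-VIP bands (0 disables)
    max_bands: int = 24


class ModelSection(_Section):
    # desk-scale architecture: half the library-default widths, same depth
    conv_channels: list[int] = Field(default_factory=lambda: [16, 32])
    conv_kernel: int = 5
    se_reduction: int = 4
    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 4
    ffn_dim: int = 64
    dropout: float = 0.2

    @model_validator(mode="after")
    def _check_heads(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )
        return self


class TrainSection(_Section):
    epochs: int = 80
    lr: float = 0.0015
    weight_decay: float = 1e-4
    batch_size: int = 32
    folds: int = 5
    early_stop_patience: int = 20
    warmup_epochs: int = 5
    val_fraction: float = 0.15
    alpha: float = 0.5
    beta: float = 0.5
    dtype: str = "float32"


class EvalSection(_Section):
    test_fraction: float = 0.2
    n_seeds: int = 5
    variants: list[str] = Field(default_factory=lambda: [
        "st_ctse_task1", "mt_ctse", "mt_cnn_transformer",
        "mt_transformer_se", "mt_transformer",
    ])

    @model_validator(mode="after")
    def _check_variants(self):
        for v in self.variants:
            model.Variant(v)  # raises on unknown
        return self


class PipelineConfig(_Section):
    seed: int = 42
    sim: SimSection = Field(default_factory=SimSection)
    cars: CarsSection = Field(default_factory=CarsSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)


def validate_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; empty/missing -> all defaults."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        loaded = yaml.safe_load(path.read_text())
        if loaded is not None:
            data = loaded
    if overrides:
        data = _deep_merge(data, overrides)
    return PipelineConfig.model_validate(data)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# Config -> stage objects
# ---------------------------------------------------------------------------

def _sim_config(cfg: PipelineConfig) -> synthspec.SimConfig:
    base = synthspec.default_egg_sim_config(seed=cfg.seed)
    return base.replace(**cfg.sim.model_dump())


def _cars_config(cfg: PipelineConfig, seed: int) -> bandselect.CarsConfig:
    kw = cfg.cars.model_dump()
    kw.pop("max_bands")  # applied in the pipeline, not inside cars_run
    return bandselect.CarsConfig(seed=seed, **kw)


def _model_config(cfg: PipelineConfig, n_bands: int) -> model.ModelConfig:
    kw = cfg.model.model_dump()
    kw["conv_channels"] = tuple(kw["conv_channels"])
    return model.ModelConfig(n_bands_in=n_bands, **kw)


def _train_config(cfg: PipelineConfig, seed: int) -> train.TrainConfig:
    t = cfg.train
    return train.TrainConfig(
        epochs=t.epochs, lr=t.lr, weight_decay=t.weight_decay,
        batch_size=t.batch_size, folds=t.folds,
        early_stop_patience=t.early_stop_patience, seed=seed,
        warmup_epochs=t.warmup_epochs,
        loss_weights=train.LossWeights(t.alpha, t.beta),
        val_fraction=t.val_fraction, dtype=t.dtype,
    )


# ---------------------------------------------------------------------------
# Reproduce
# ---------------------------------------------------------------------------

@dataclass
class ReproduceResult:
    out_dir: Path
    band_indices: np.ndarray
    reports: pd.DataFrame
    comparison: pd.DataFrame


def _substream_seeds(seed: int, n: int, tag: str) -> list[int]:
    """Named, collision-free 31-bit seeds derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    base = int.from_bytes(h[:4], "big")
    return [(base + i) % (2 ** 31) for i in range(n)]


def reproduce(config: PipelineConfig, out_dir) -> ReproduceResult:
    """Run the full synthetic experiment; see module docstring."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s [%(stage)s] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def log(stage: str, msg: str) -> None:
        logger.info(msg, extra={"stage": stage})

    t0 = time.time()
    try:
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))
        (out_dir / "seed.txt").write_text(str(config.seed))

        # --- simulate -----------------------------------------------------
        sim_cfg = _sim_config(config)
        table = synthspec.simulate_dataset(sim_cfg)
        sim_hash = hashlib.sha256(table.X.tobytes()).hexdigest()
        log("simulate", f"{len(table)} scans, {table.n_bands} bands, sha256 {sim_hash[:16]}")

        # --- preprocess ---------------------------------------------------
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", RuntimeWarning)
            averaged = io_calib.average_scan_replicates(table)
        if caught:
            log("preprocess", f"replicate-CV stability warnings on "
                f"{len(caught)} sample(s) (deep-trough bands)")
        snv = preprocess.snv_table(averaged)
        log("preprocess", f"replicate scans averaged to {len(averaged)} samples; "
            "row-wise SNV applied")

        # --- outer split (test isolated from band selection) ---------------
        split_seed = _substream_seeds(config.seed, 1, "split")[0]
        split = train.stratified_egg_split(snv, config.eval.test_fraction, split_seed)
        train_tab = snv.select_eggs(split.train_eggs)
        test_tab = snv.select_eggs(split.test_eggs)
        (out_dir / "test_eggs.txt").write_text("\n".join(split.test_eggs))
        log("split", f"{len(split.train_eggs)} train eggs, {len(split.test_eggs)} test eggs")

        # --- band selection -------------------------------------------------
        cars_seed = _substream_seeds(config.seed, 1, "cars")[0]
        stages = {
            int(d): train_tab.subset((train_tab.labels["day"] == d).to_numpy())
            for d in sorted(train_tab.labels["day"].unique())
        }
        two = bandselect.two_stage_select(stages, _cars_config(config, cars_seed))
        bands = two.final
        joint = (train_tab.labels["variety"].astype(str) + "|"
                 + train_tab.labels["day"].astype(str)).tolist()
        Yj = bandselect.one_hot(joint, sorted(set(joint)))

        def _vip_for(idx):
            m = bandselect.fit_plsda(train_tab.X[:, idx], Yj,
                                     min(two.refilter.n_latent, len(idx)))
            return bandselect.vip(m).scores

        if config.cars.max_bands and bands.size > config.cars.max_bands:
            # dimensionality budget: keep the highest-VIP bands of the
            # re-filtered set (VIP threshold as a final tightening step)
            v = _vip_for(bands)
            keep = np.sort(np.argsort(-v)[:config.cars.max_bands])
            bands = bands[keep]
        wavelengths = table.grid.values[bands]
        vip_scores = _vip_for(bands)
        (out_dir / "bands.json").write_text(json.dumps({
            "per_stage": {str(k): v.selected.tolist() for k, v in two.per_stage.items()},
            "union": two.union.tolist(),
            "final": bands.tolist(),
            "wavelength_nm": wavelengths.tolist(),
            "vip": vip_scores.tolist(),
            "rmsecv_refilter": two.refilter.rmsecv.tolist(),
        }, indent=1))
        log("select-bands", f"{bands.size} cross-temporal bands: "
            f"{np.round(wavelengths, 1).tolist()}")

        # --- train & evaluate ----------------------------------------------
        model_cfg = _model_config(config, bands.size)
        seeds = _substream_seeds(config.seed, config.eval.n_seeds, "train")
        rows = []
        for si, s in enumerate(seeds):
            for vname in config.eval.variants:
                variant = model.Variant(vname)
                net = model.build(model_cfg, variant, seed=s)
                net, hist = train.fit(net, train_tab, bands, _train_config(config, s))
                log("train", f"seed {si} {vname}: {hist.n_epochs} epochs, "
                    f"best {hist.best_epoch}, val loss {min(hist.val_loss):.4f}")
                for task in variant.tasks:
                    rep = evaluate.evaluate_pooled(net, test_tab, task, bands)
                    rep.seed = si
                    rows.append(rep.to_row())
                slicings = []
                if model.TASK_VARIETY in variant.tasks:
                    slicings.append("by_day")
                if model.TASK_PERIOD in variant.tasks:
                    slicings.append("by_variety")
                for sl in slicings:
                    for rep in evaluate.evaluate_sliced(net, test_tab, sl, bands):
                        rep.seed = si
                        rows.append(rep.to_row())
        reports = pd.DataFrame(rows)
        reports.to_csv(out_dir / "reports.csv", index=False)
        comparison = evaluate.compare([out_dir])
        comparison.to_csv(out_dir / "comparison.csv", index=False)
        log("evaluate", f"wrote {len(reports)} report rows; "
            f"total {time.time() - t0:.0f}s")
        return ReproduceResult(out_dir=out_dir, band_indices=bands,
                               reports=reports, comparison=comparison)
    except Exception:
        logger.exception("pipeline failed", extra={"stage": "fatal"})
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
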