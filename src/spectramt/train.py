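"""Egg-level data splitting, the joint multi-task loss, and the training loop.

Splits are always at egg level: all scans of one egg, across every storage
day, land on one side of any boundary, so no egg leaks between training,
validation and test.  Training uses AdamW with decoupled weight decay, a
cosine-annealed learning rate over the epoch budget, minibatch shuffling, and
early stopping on validation loss with best-weight restoration.  The total
loss is the weighted sum alpha * L_variety + beta * L_period of per-task
cross-entropies (alpha = beta = 0.5 by default); single-task variants
degenerate to one term.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import TASK_PERIOD, TASK_VARIETY, ModelConfig, Network, Variant, build
from .nn import AdamW, Tensor
from .synthspec import SpectraTable

__all__ = [
    "LossWeights",
    "TrainConfig",
    "SplitSpec",
    "History",
    "stratified_egg_split",
    "task_loss",
    "joint_loss",
    "task_targets",
    "cosine_lr",
    "fit",
    "cross_validate",
]

LOG_CLAMP = 1e-12


@dataclass(frozen=True)
class LossWeights:
    alpha_task1: float = 0.5  # variety task
    beta_task2: float = 0.5   # storage-period task

    def __post_init__(self) -> None:
        if self.alpha_task1 < 0 or self.beta_task2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 800
    lr: float = 0.001
    weight_decay: float = 1e-4
    batch_size: int = 32
    folds: int = 5
    early_stop_patience: int = 50
    seed: int = 42
    loss_weights: LossWeights = field(default_factory=LossWeights)
    val_fraction: float = 0.15
    lr_min: float = 0.0
    warmup_epochs: int = 0  # linear ramp before the cosine decay
    dtype: str = "float64"  # "float32" roughly halves CPU training time

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SplitSpec:
    train_eggs: tuple[str, ...]
    test_eggs: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_eggs) & set(self.test_eggs):
            raise ValueError("train and test egg sets overlap")


@dataclass
class History:
    lr: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    train_loss_variety: list = field(default_factory=list)
    train_loss_period: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_acc_variety: list = field(default_factory=list)
    train_acc_period: list = field(default_factory=list)
    val_acc_variety: list = field(default_factory=list)
    val_acc_period: list = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_egg_split(table: SpectraTable, test_fraction: float = 0.2,
                         seed: int = 42) -> SplitSpec:
    """Random per-variety split of egg ids; all scans of an egg stay together."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.Generator(np.random.PCG64(seed))
    train: list[str] = []
    test: list[str] = []
    eggs_by_variety = table.labels.groupby("variety", sort=True)["egg_id"].unique()
    for variety, eggs in eggs_by_variety.items():
        eggs = sorted(eggs)
        if len(eggs) < 5:
            raise ValueError(f"variety {variety!r} has only {len(eggs)} eggs (< 5)")
        eggs = list(rng.permutation(eggs))
        n_test = int(round(test_fraction * len(eggs)))
        n_test = min(max(n_test, 1), len(eggs) - 1)
        test.extend(eggs[:n_test])
        train.extend(eggs[n_test:])
    return SplitSpec(train_eggs=tuple(sorted(train)), test_eggs=tuple(sorted(test)))


def _egg_folds(table: SpectraTable, k: int, seed: int) -> dict[str, int]:
    """Egg-level stratified fold assignment (round-robin within variety)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    assignment: dict[str, int] = {}
    for variety, eggs in table.labels.groupby("variety", sort=True)["egg_id"].unique().items():
        eggs = list(rng.permutation(sorted(eggs)))
        for i, egg in enumerate(eggs):
            assignment[egg] = i % k
    return assignment


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _as_one_hot(labels, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return labels.astype(float)
    Y = np.zeros((labels.size, n_classes))
    Y[np.arange(labels.size), labels.astype(int)] = 1.0
    return Y


def task_loss(probabilities: np.ndarray, labels) -> float:
    """Mean cross-entropy -1/N sum_i sum_k y_ik log p_ik.

    ``labels`` may be integer class indices or a one-hot matrix; probability
    rows must sum to one within 1e-6; the log is clamped at 1e-12.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2:
        raise ValueError("probabilities must be 2-D (samples x classes)")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"row {bad} sums to {sums[bad]:.6f}, not 1")
    Y = _as_one_hot(labels, p.shape[1])
    return float(-(Y * np.log(np.clip(p, LOG_CLAMP, None))).sum() / p.shape[0])


def joint_loss(p1, y1, p2, y2, weights: LossWeights = LossWeights()) -> float:
    """alpha * L_task1 + beta * L_task2."""
    return (weights.alpha_task1 * task_loss(p1, y1)
            + weights.beta_task2 * task_loss(p2, y2))


def _graph_ce(logits: Tensor, y_idx: np.ndarray) -> Tensor:
    """Differentiable mean cross-entropy from logits (stable log-softmax)."""
    logp = logits.log_softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(y_idx.size), y_idx] = 1.0
    return -(logp * Tensor(onehot)).sum() / y_idx.size


# ---------------------------------------------------------------------------
# Targets and schedule
# ---------------------------------------------------------------------------

def task_targets(table: SpectraTable) -> dict[str, tuple[np.ndarray, list]]:
    """Integer targets and class orderings for both tasks."""
    varieties = sorted(table.labels["variety"].unique())
    days = sorted(table.labels["day"].unique())
    v_idx = table.labels["variety"].map({c: i for i, c in enumerate(varieties)}).to_numpy()
    d_idx = table.labels["day"].map({c: i for i, c in enumerate(days)}).to_numpy()
    return {TASK_VARIETY: (v_idx, varieties), TASK_PERIOD: (d_idx, days)}


def cosine_lr(epoch: int, config: TrainConfig) -> float:
    """Cosine annealing from lr to lr_min over the epoch budget, no restarts.

    An optional linear warmup over the first ``warmup_epochs`` stabilises the
    early training of the post-norm encoder; the cosine then runs over the
    remaining epochs.
    """
    w = config.warmup_epochs
    if w > 0 and epoch < w:
        return config.lr * (epoch + 1) / w
    span = config.epochs - w
    if span <= 1:
        return config.lr
    t = (epoch - w) / (span - 1)
    return config.lr_min + 0.5 * (config.lr - config.lr_min) * (1.0 + np.cos(np.pi * t))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _task_weights(variant: Variant, w: LossWeights) -> dict[str, float]:
    if variant.is_multitask:
        return {TASK_VARIETY: w.alpha_task1, TASK_PERIOD: w.beta_task2}
    return {variant.tasks[0]: 1.0}


def _eval_loss_acc(net: Network, X: np.ndarray, targets: dict,
                   weights: dict[str, float], chunk: int = 512):
    """Eval-mode weighted loss and per-task accuracy over a dataset."""
    losses = {t: 0.0 for t in net.variant.tasks}
    correct = {t: 0 for t in net.variant.tasks}
    n = X.shape[0]
    for lo in range(0, n, chunk):
        xb = X[lo:lo + chunk]
        logits = net.logits(xb)
        for t, z in logits.items():
            y = targets[t][0][lo:lo + chunk]
            logp = z.log_softmax(axis=-1).data
            losses[t] += -logp[np.arange(y.size), y].sum()
            correct[t] += int((z.data.argmax(axis=1) == y).sum())
    total = sum(weights[t] * losses[t] / n for t in net.variant.tasks)
    acc = {t: correct[t] / n for t in net.variant.tasks}
    return float(total), {t: float(losses[t] / n) for t in losses}, acc


def fit(network: Network, table: SpectraTable, band_indices,
        config: TrainConfig) -> tuple[Network, History]:
    """Train one network on the given (SNV-preprocessed) table.

    A ``val_fraction`` egg-level stratified slice of the table is held out for
    early stopping; the best-validation-loss weights are restored at the end.
    Training metrics are running averages over the epoch's minibatches;
    validation metrics come from a full eval-mode pass.
    """
    band_indices = np.asarray(band_indices, dtype=int)
    ss = np.random.SeedSequence(config.seed)
    s_split, s_shuffle, s_drop = ss.spawn(3)

    old_dtype = nn.get_default_dtype()
    nn.set_default_dtype(config.dtype)
    for p in network.parameters():
        p.data = p.data.astype(nn.get_default_dtype())

    val_split = stratified_egg_split(
        table, test_fraction=config.val_fraction,
        seed=int(s_split.generate_state(1)[0] % (2 ** 31)))
    tr_tab = table.select_eggs(val_split.train_eggs)
    va_tab = table.select_eggs(val_split.test_eggs)

    Xtr = tr_tab.X[:, band_indices]
    Xva = va_tab.X[:, band_indices]
    ttr = task_targets(tr_tab)
    tva = task_targets(va_tab)
    weights = _task_weights(network.variant, config.loss_weights)

    shuffle_rng = np.random.Generator(np.random.PCG64(s_shuffle))
    drop_rng = np.random.Generator(np.random.PCG64(s_drop))
    opt = AdamW(network.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)

    hist = History()
    try:
        _run_epochs(network, config, opt, Xtr, ttr, Xva, tva, weights,
                    shuffle_rng, drop_rng, hist)
    finally:
        nn.set_default_dtype(old_dtype)
    network.load_state(hist._best_state)
    hist.best_epoch = hist._best_epoch
    return network, hist


def _run_epochs(network, config, opt, Xtr, ttr, Xva, tva, weights,
                shuffle_rng, drop_rng, hist) -> None:
    best_val = np.inf
    best_state = network.state()
    best_epoch = -1
    n = Xtr.shape[0]

    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        opt.lr = lr
        order = shuffle_rng.permutation(n)
        run_loss = {t: 0.0 for t in network.variant.tasks}
        run_correct = {t: 0 for t in network.variant.tasks}
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            logits = network.logits(Xtr[idx], training=True, rng=drop_rng)
            loss = None
            for t, z in logits.items():
                y = ttr[t][0][idx]
                lt = _graph_ce(z, y)
                run_loss[t] += float(lt.data) * idx.size
                run_correct[t] += int((z.data.argmax(axis=1) == y).sum())
                term = lt * weights[t]
                loss = term if loss is None else loss + term
            opt.zero_grad()
            loss.backward()
            opt.step()

        val_total, _, val_acc = _eval_loss_acc(network, Xva, tva, weights)
        hist.lr.append(float(lr))
        hist.train_loss.append(sum(weights[t] * run_loss[t] / n
                                   for t in network.variant.tasks))
        hist.train_loss_variety.append(run_loss.get(TASK_VARIETY, 0.0) / n)
        hist.train_loss_period.append(run_loss.get(TASK_PERIOD, 0.0) / n)
        hist.train_acc_variety.append(run_correct.get(TASK_VARIETY, 0) / n)
        hist.train_acc_period.append(run_correct.get(TASK_PERIOD, 0) / n)
        hist.val_loss.append(val_total)
        hist.val_acc_variety.append(val_acc.get(TASK_VARIETY, np.nan))
        hist.val_acc_period.append(val_acc.get(TASK_PERIOD, np.nan))

        if val_total < best_val - 1e-12:
            best_val = val_total
            best_state = network.state()
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stop_patience:
            break

    hist._best_state = best_state
    hist._best_epoch = best_epoch


def cross_validate(table: SpectraTable, config: TrainConfig, variant: Variant,
                   model_config: ModelConfig, band_indices):
    """Egg-level stratified k-fold cross-validation within the training set.

    Returns per-fold histories and held-out per-task accuracies with their
    mean and sample sd across folds.
    """
    assignment = _egg_folds(table, config.folds, config.seed)
    fold_of = table.labels["egg_id"].map(assignment).to_numpy()
    histories = []
    accs: dict[str, list[float]] = {t: [] for t in variant.tasks}
    for f in range(config.folds):
        tr = table.subset(fold_of != f)
        te = table.subset(fold_of == f)
        net = build(model_config, variant, seed=config.seed + f)
        fold_cfg = dataclasses.replace(config, seed=config.seed * 1000 + f)
        net, hist = fit(net, tr, band_indices, fold_cfg)
        histories.append(hist)
        preds = net.predict(te.X[:, np.asarray(band_indices, dtype=int)])
        targets = task_targets(te)
        for t in variant.tasks:
            accs[t].append(float((preds[t] == targets[t][0]).mean()))
    summary = {
        t: {"mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "per_fold": v}
        for t, v in accs.items()
    }
    return histories, summary
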