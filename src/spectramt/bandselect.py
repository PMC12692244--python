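"""CARS-PLS-DA wavelength selection with VIP scoring.

Competitive adaptive reweighted sampling (CARS) selects informative wavelengths
by repeatedly (i) fitting a PLS-DA model on a Monte-Carlo subsample of the
calibration set, (ii) forcibly retaining the top-N bands by mean absolute
regression coefficient, where N follows an exponentially decreasing schedule,
(iii) resampling bands with probability proportional to coefficient magnitude
(adaptive reweighted sampling), and (iv) scoring each run's retained set by
k-fold RMSECV on the class-indicator response.  The run with minimal RMSECV
defines the selection.

For data spanning several storage stages, a two-stage strategy selects bands
per stage first, merges the stage selections, and re-filters the union with a
second CARS pass on the pooled data, yielding a cross-temporal band set.
Variable importance in projection (VIP) scores quantify each surviving band's
contribution; their squares average to one by construction.

PLS-DA is fitted by NIPALS on a one-hot class-indicator response, with
columns centred (not scaled — rows are already SNV-standardised upstream).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .synthspec import SpectraTable

__all__ = [
    "EdfSchedule",
    "PlsdaModel",
    "CarsConfig",
    "CarsResult",
    "TwoStageResult",
    "VipScores",
    "one_hot",
    "fit_plsda",
    "choose_n_latent",
    "edf_counts",
    "rmsecv",
    "cars_run",
    "two_stage_select",
    "vip",
]


# ---------------------------------------------------------------------------
# Response coding
# ---------------------------------------------------------------------------

def one_hot(labels, classes) -> np.ndarray:
    """Class-indicator matrix; rows sum to one, column order = class order."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    labels = list(labels)
    unknown = sorted({l for l in labels if l not in index}, key=str)
    if unknown:
        raise ValueError(f"labels outside class set {classes}: {unknown}")
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, index[l]] = 1.0
    return Y


# ---------------------------------------------------------------------------
# NIPALS PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """PLS model on centred X and indicator Y (NIPALS, PLS2).

    Stores X-weights ``W`` (p x A, unit columns), X-loadings ``P`` (p x A),
    Y-loadings ``Q`` (K x A), per-component score sums of squares ``tss`` and
    explained-Y sums of squares ``ssy`` (A,), plus centring vectors.  The
    coefficient matrix for the first k components is
    ``B_k = W_k (P_k' W_k)^{-1} Q_k'``.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    tss: np.ndarray
    ssy: np.ndarray

    @property
    def n_latent(self) -> int:
        return self.W.shape[1]

    @property
    def n_bands(self) -> int:
        return self.W.shape[0]

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """(bands x classes) regression coefficients for first k components."""
        k = self.n_latent if k is None else k
        if not (1 <= k <= self.n_latent):
            raise ValueError(f"k must be in [1, {self.n_latent}]")
        Wk, Pk, Qk = self.W[:, :k], self.P[:, :k], self.Q[:, :k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, Qk.T)

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        return (np.asarray(X) - self.x_mean) @ self.coefficients(k) + self.y_mean


def fit_plsda(X: np.ndarray, Y: np.ndarray, n_latent: int,
              max_iter: int = 200, tol: float = 1e-10) -> PlsdaModel:
    """Sequential NIPALS extraction of up to ``n_latent`` components.

    X and Y are column-centred only (no scaling).  A degenerate component
    (vanishing weight or score norm, e.g. after the residual is exhausted)
    terminates extraction early with a warning; the returned model then holds
    fewer components than requested.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if not (1 <= n_latent <= min(n - 1, p)):
        raise ValueError(f"n_latent must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean

    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    Q = np.zeros((Y.shape[1], n_latent))
    tss = np.zeros(n_latent)
    ssy = np.zeros(n_latent)
    eps = np.finfo(float).eps
    a = 0
    for a in range(n_latent):
        u = F[:, np.argmax((F ** 2).sum(axis=0))]
        if (u ** 2).sum() < eps * 100:
            warnings.warn(f"degenerate component {a + 1}: Y residual exhausted",
                          RuntimeWarning, stacklevel=2)
            break
        t_old = None
        for _ in range(max_iter):
            w = E.T @ u
            wn = np.linalg.norm(w)
            if wn < eps * 100:
                break
            w /= wn
            t = E @ w
            tt = t @ t
            if tt < eps * 100:
                break
            q = F.T @ t / tt
            qn = q @ q
            if qn < eps * 100:
                break
            u = F @ q / qn
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                t_old = t
                break
            t_old = t
        if t_old is None or (t_old @ t_old) < eps * 100 or np.linalg.norm(w) < eps * 100:
            warnings.warn(f"degenerate component {a + 1}: extraction terminated early",
                          RuntimeWarning, stacklevel=2)
            break
        t = t_old
        tt = t @ t
        p_load = E.T @ t / tt
        q = F.T @ t / tt
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a] = w, p_load, q
        tss[a] = tt
        ssy[a] = tt * (q @ q)  # Y variance captured by component a
        a += 1
    if a == 0:
        raise ValueError("no PLS component could be extracted (constant X or Y)")
    return PlsdaModel(x_mean, y_mean, W[:, :a], P[:, :a], Q[:, :a], tss[:a], ssy[:a])


def choose_n_latent(X: np.ndarray, Y: np.ndarray, config: "CarsConfig",
                    rng: np.random.Generator) -> int:
    """Latent-variable count by Monte-Carlo cross-validation.

    For every candidate count 1..max_lv, the mean held-out RMSE over
    ``lv_mccv_runs`` random splits at ``lv_mccv_fraction`` calibration ratio is
    computed (one fit per split, truncated to each count); the argmin wins,
    ties going to the smaller count.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    n_cal = int(round(config.lv_mccv_fraction * n))
    if n_cal < 2 or n_cal >= n:
        raise ValueError(f"cannot split {n} samples at fraction {config.lv_mccv_fraction}")
    max_lv = min(config.max_lv, n_cal - 1, X.shape[1])
    if max_lv < 1:
        raise ValueError("too few samples/bands for even one latent variable")
    sse = np.zeros(max_lv)
    count = np.zeros(max_lv)
    for _ in range(config.lv_mccv_runs):
        perm = rng.permutation(n)
        cal, val = perm[:n_cal], perm[n_cal:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_plsda(X[cal], Y[cal], max_lv)
        for k in range(1, model.n_latent + 1):
            resid = Y[val] - model.predict(X[val], k)
            sse[k - 1] += (resid ** 2).mean()
            count[k - 1] += 1
    valid = count > 0
    mean_rmse = np.full(max_lv, np.inf)
    mean_rmse[valid] = np.sqrt(sse[valid] / count[valid])
    return int(np.argmin(mean_rmse)) + 1  # argmin takes first (smallest) on ties


# ---------------------------------------------------------------------------
# Exponentially decreasing retention schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdfSchedule:
    """Per-run retained band counts N_iter(r), r = 1..R."""

    counts: np.ndarray
    N_total: int
    R: int
    floor: int = 2
    schedule: str = "exponential"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.size != self.R:
            raise ValueError("counts must have length R")
        # the power-law alternative grows with r by construction, so the
        # non-increase invariant applies to the decreasing default only
        if self.schedule == "exponential" and np.any(np.diff(c) > 0):
            raise ValueError("retention schedule must be non-increasing")
        object.__setattr__(self, "counts", c)

    def __getitem__(self, r: int) -> int:
        """Retained count for run r (1-based)."""
        return int(self.counts[r - 1])


def edf_counts(N_total: int, R: int, floor: int = 2,
               schedule: str = "exponential", alpha: float | None = None) -> EdfSchedule:
    """Retention schedule for R sampling runs over N_total initial bands.

    ``schedule="exponential"`` (default): N_iter(r) = round(N_total * a * e^{-k r})
    with a, k fixed by N_iter(1) = N_total and N_iter(R) = floor, then forced
    non-increasing after rounding.  ``schedule="power"`` exposes the power-law
    form N_total * (r/R)**alpha for a user-supplied alpha (note this form
    grows with r; it is provided for comparison, not as the default).
    """
    if floor < 2:
        raise ValueError("floor must be >= 2")
    if N_total <= floor:
        raise ValueError(f"N_total ({N_total}) must exceed floor ({floor})")
    if R < 2:
        raise ValueError("R must be >= 2")
    r = np.arange(1, R + 1)
    if schedule == "exponential":
        k = np.log(N_total / floor) / (R - 1)
        a = np.exp(k)
        counts = np.round(N_total * a * np.exp(-k * r)).astype(int)
        counts = np.minimum.accumulate(counts)  # monotone after rounding
        counts = np.clip(counts, floor, N_total)
        counts[0], counts[-1] = N_total, floor
    elif schedule == "power":
        if alpha is None:
            raise ValueError("power schedule requires alpha")
        counts = np.round(N_total * (r / R) ** alpha).astype(int)
        counts = np.clip(counts, floor, N_total)
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    return EdfSchedule(counts=counts, N_total=N_total, R=R, floor=floor,
                       schedule=schedule)


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarsConfig:
    R: int = 100
    mc_fraction: float = 0.8
    cv_folds: int = 5
    lv_mccv_runs: int = 1000
    lv_mccv_fraction: float = 0.8
    max_lv: int = 15
    floor: int = 2
    schedule: str = "exponential"
    alpha: float | None = None
    n_latent: int | None = None  # set to skip the MCCV latent-variable search
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 < self.mc_fraction < 1.0 and 0.0 < self.lv_mccv_fraction < 1.0):
            raise ValueError("sampling fractions must lie in (0, 1)")
        if self.R < 2:
            raise ValueError("R must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class CarsResult:
    retained_sets: list[np.ndarray]
    rmsecv: np.ndarray
    best_run: int
    selected: np.ndarray
    n_latent: int
    schedule: EdfSchedule
    seed: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.selected, self.retained_sets[self.best_run]):
            raise ValueError("selected set must equal the best run's retained set")


def rmsecv(X: np.ndarray, Y: np.ndarray, n_latent: int, folds: np.ndarray) -> float:
    """Root mean squared error of k-fold cross-validation on the indicator Y.

    ``folds`` assigns each sample a fold id; the partition is supplied by the
    caller so that competing band subsets are scored on identical folds.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    sse, m = 0.0, 0
    for f in np.unique(folds):
        te = folds == f
        tr = ~te
        lv = min(n_latent, int(tr.sum()) - 1, X.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_plsda(X[tr], Y[tr], lv)
        resid = Y[te] - model.predict(X[te])
        sse += (resid ** 2).sum()
        m += resid.size
    return float(np.sqrt(sse / m))


def cars_run(X_snv: np.ndarray, labels, config: CarsConfig,
             classes=None) -> CarsResult:
    """One full CARS selection on SNV-preprocessed spectra.

    Per run r = 1..R: fit PLS-DA on an ``mc_fraction`` Monte-Carlo subsample
    restricted to the currently retained bands; rank bands by mean absolute
    coefficient over response columns (ties to the lower index); enforce the
    EDF count N_iter(r); adaptively resample N_iter(r) bands with replacement
    with probability proportional to weight; score the resulting retained set
    by k-fold RMSECV over all samples.  The retained set of the
    minimal-RMSECV run is the selection (ties to the earlier run).
    """
    X = np.asarray(X_snv, dtype=float)
    labels = np.asarray(list(labels))
    if classes is None:
        classes = sorted(set(labels.tolist()), key=str)
    Y = one_hot(labels, classes)
    n, p = X.shape
    counts = np.bincount(np.searchsorted(np.unique(labels), labels))
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    if p < config.floor:
        raise ValueError(f"need >= {config.floor} bands")

    rng = np.random.Generator(np.random.PCG64(config.seed))
    schedule = edf_counts(p, config.R, config.floor, config.schedule, config.alpha)

    if config.n_latent is not None:
        lv = config.n_latent
    else:
        lv = choose_n_latent(X, Y, config, rng)

    # one fold partition shared by all runs for comparable RMSECV
    folds = rng.permutation(n) % config.cv_folds
    n_sub = max(2, int(round(config.mc_fraction * n)))

    retained = np.arange(p)
    retained_sets: list[np.ndarray] = []
    rmse = np.empty(config.R)
    for r in range(1, config.R + 1):
        sub = rng.choice(n, size=n_sub, replace=False)
        lv_r = min(lv, retained.size, n_sub - 1)
        if lv_r < lv:
            warnings.warn(
                f"run {r}: retained set smaller than n_latent, clamping to {lv_r}",
                RuntimeWarning, stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_plsda(X[np.ix_(sub, retained)], Y[sub], lv_r)
        w = np.abs(model.coefficients()).mean(axis=1)
        n_keep = min(schedule[r], retained.size)
        # enforced selection: top n_keep by weight, ties to lower band index
        order = np.lexsort((retained, -w))
        kept = retained[order[:n_keep]]
        w_kept = w[order[:n_keep]]
        # adaptive reweighted sampling: N_total weighted draws with
        # replacement (a fixed large draw count keeps the unique retained set
        # tracking the EDF schedule instead of compounding a shrink factor)
        if w_kept.sum() <= 0:
            probs = np.full(kept.size, 1.0 / kept.size)
        else:
            probs = w_kept / w_kept.sum()
        sampled = rng.choice(kept, size=p, replace=True, p=probs)
        retained = np.unique(sampled)
        retained_sets.append(retained.copy())
        lv_cv = min(lv, retained.size)
        rmse[r - 1] = rmsecv(X[:, retained], Y, lv_cv, folds)

    best = int(np.argmin(rmse))
    return CarsResult(
        retained_sets=retained_sets,
        rmsecv=rmse,
        best_run=best,
        selected=retained_sets[best].copy(),
        n_latent=lv,
        schedule=schedule,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Two-stage cross-temporal selection
# ---------------------------------------------------------------------------

@dataclass
class TwoStageResult:
    per_stage: dict
    union: np.ndarray
    refilter: CarsResult
    final: np.ndarray


def _stage_labels(table: SpectraTable, task: str):
    if task == "variety":
        return table.labels["variety"].to_numpy()
    if task == "day":
        return table.labels["day"].astype(str).to_numpy()
    if task == "joint":
        return (table.labels["variety"].astype(str) + "|"
                + table.labels["day"].astype(str)).to_numpy()
    raise ValueError(f"unknown task {task!r}")


def two_stage_select(tables_by_stage: dict, config: CarsConfig,
                     stage_task: str = "variety",
                     pooled_task: str = "joint") -> TwoStageResult:
    """Cross-temporal band selection.

    Stage 1 runs CARS independently on each storage stage (labels =
    ``stage_task``, default variety; the day is constant within a stage).
    Stage 2 unions the per-stage selections and re-filters by a second CARS
    pass on the pooled all-stage data restricted to that union, with labels =
    ``pooled_task`` (default the variety x day joint labelling, so the final
    set serves both tasks).  Final indices refer to the shared grid.
    """
    stages = dict(tables_by_stage)
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    ref = next(iter(stages.values())).grid
    for t in stages.values():
        if not np.array_equal(t.grid.values, ref.values):
            raise ValueError("stages must share one wavelength grid")

    per_stage = {}
    union: np.ndarray = np.array([], dtype=int)
    for i, (key, table) in enumerate(sorted(stages.items(), key=lambda kv: str(kv[0]))):
        stage_cfg = dataclasses.replace(config, seed=config.seed + i + 1)
        res = cars_run(table.X, _stage_labels(table, stage_task), stage_cfg)
        per_stage[key] = res
        union = np.union1d(union, res.selected)

    pooled_labels = np.concatenate([
        _stage_labels(t, pooled_task)
        for _, t in sorted(stages.items(), key=lambda kv: str(kv[0]))
    ])
    pooled_X = np.vstack([
        t.X for _, t in sorted(stages.items(), key=lambda kv: str(kv[0]))
    ])[:, union]
    refilter_cfg = dataclasses.replace(config, seed=config.seed)
    refit = cars_run(pooled_X, pooled_labels, refilter_cfg)
    final = union[refit.selected]
    return TwoStageResult(per_stage=per_stage, union=union,
                          refilter=refit, final=final)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

@dataclass
class VipScores:
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if np.any(s < 0):
            raise ValueError("VIP scores must be non-negative")
        object.__setattr__(self, "scores", s)


def vip(model: PlsdaModel) -> VipScores:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with p
    bands and SSY_a the Y variance explained by component a; consequently
    sum_j VIP_j^2 = p.
    """
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("model explains zero Y variance; VIP undefined")
    wn = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    p = model.n_bands
    scores = np.sqrt(p * (wn ** 2 @ model.ssy) / total)
    return VipScores(scores=scores)
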