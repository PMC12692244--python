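"""MT-CTSE-Net: multi-task CNN + squeeze-and-excitation + Transformer network.

The shared backbone runs, in order: a stack of same-padded 1-D convolutions
with ReLU (local spectral features over the CARS-selected bands), a linear
lift to the token width d_model, a squeeze-and-excitation (SE) channel gate,
sinusoidal positional encoding, and a four-layer Transformer encoder
(multi-head self-attention + feed-forward, layer norm, residuals, dropout).
Encoder outputs are globally average-pooled over the sequence axis and fed to
task heads — a fully connected softmax classifier per task.  Hard parameter
sharing means both heads read the very same backbone parameters.

Variants ablate the CNN stack and/or the SE gate, drop the Transformer
entirely (pure-CNN baselines), or expose a single head (single-task mode);
they differ only in which components are present, never in how the shared
components are built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .nn import Parameter, Tensor, scaled_dot_attention

__all__ = [
    "ModelConfig",
    "Variant",
    "SEBlock",
    "MultiHeadAttention",
    "EncoderLayer",
    "Network",
    "se_block",
    "positional_encoding",
    "attention",
    "multi_head",
    "build",
    "forward",
]

TASK_VARIETY = "variety"
TASK_PERIOD = "period"


@dataclass(frozen=True)
class ModelConfig:
    n_bands_in: int = 21
    conv_channels: tuple[int, ...] = (32, 64)
    conv_kernel: int = 5
    se_reduction: int = 4
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 4
    ffn_dim: int = 128
    dropout: float = 0.2
    n_classes_task1: int = 3
    n_classes_task2: int = 3
    pre_norm: bool = False

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd (same padding)")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")


class Variant(Enum):
    MT_CTSE = "mt_ctse"
    MT_CNN_TRANSFORMER = "mt_cnn_transformer"
    MT_TRANSFORMER_SE = "mt_transformer_se"
    MT_TRANSFORMER = "mt_transformer"
    MT_CNN = "mt_cnn"
    ST_CTSE_TASK1 = "st_ctse_task1"
    ST_CTSE_TASK2 = "st_ctse_task2"
    ST_TRANSFORMER_TASK1 = "st_transformer_task1"
    ST_TRANSFORMER_TASK2 = "st_transformer_task2"
    ST_CNN_TASK1 = "st_cnn_task1"
    ST_CNN_TASK2 = "st_cnn_task2"

    @property
    def has_cnn(self) -> bool:
        return self in {Variant.MT_CTSE, Variant.MT_CNN_TRANSFORMER, Variant.MT_CNN,
                        Variant.ST_CTSE_TASK1, Variant.ST_CTSE_TASK2,
                        Variant.ST_CNN_TASK1, Variant.ST_CNN_TASK2}

    @property
    def has_se(self) -> bool:
        return self in {Variant.MT_CTSE, Variant.MT_TRANSFORMER_SE,
                        Variant.ST_CTSE_TASK1, Variant.ST_CTSE_TASK2}

    @property
    def has_transformer(self) -> bool:
        return self not in {Variant.MT_CNN, Variant.ST_CNN_TASK1, Variant.ST_CNN_TASK2}

    @property
    def tasks(self) -> tuple[str, ...]:
        if self.value.startswith("mt_"):
            return (TASK_VARIETY, TASK_PERIOD)
        return (TASK_VARIETY,) if self.value.endswith("task1") else (TASK_PERIOD,)

    @property
    def is_multitask(self) -> bool:
        return len(self.tasks) == 2


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = int(shape[-1])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Parameter(_glorot(rng, (d_in, d_out)))
        self.b = Parameter(np.zeros(d_out), no_decay=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.affine(self.W, self.b)

    def params(self):
        return [self.W, self.b]


class ConvBlock:
    """Same-padded conv1d + ReLU."""

    def __init__(self, rng, kernel: int, c_in: int, c_out: int):
        self.W = Parameter(_glorot(rng, (kernel, c_in, c_out)))
        self.b = Parameter(np.zeros(c_out), no_decay=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d_same(self.W, self.b).relu()

    def params(self):
        return [self.W, self.b]


class SEBlock:
    """Squeeze-and-excitation channel gate.

    Squeeze: global average pool over the sequence axis.  Excitation: a
    bottleneck of two fully connected layers (ReLU then sigmoid), gates in
    (0, 1) per channel.  Reweight: multiply the input channel-wise.  The
    output-gate bias is initialised at +2 so the gate opens near identity
    (sigmoid(2) ~ 0.88) and learns to suppress channels, rather than
    starting by halving every channel.
    """

    def __init__(self, rng, channels: int, reduction: int):
        hidden = max(1, channels // reduction)
        self.W1 = Parameter(_glorot(rng, (channels, hidden)))
        self.b1 = Parameter(np.zeros(hidden), no_decay=True)
        self.W2 = Parameter(_glorot(rng, (hidden, channels)))
        self.b2 = Parameter(np.full(channels, 2.0), no_decay=True)

    def __call__(self, U: Tensor) -> Tensor:
        pooled = U.mean(axis=1)                 # (B, C) squeeze
        gates = (pooled.affine(self.W1, self.b1).relu()
                 .affine(self.W2, self.b2)).sigmoid()
        B, C = gates.shape
        return U * gates.reshape(B, 1, C)       # reweight

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]


def se_block(U, params: SEBlock) -> Tensor:
    """Functional form of the SE gate (accepts Tensor or ndarray input)."""
    U = U if isinstance(U, Tensor) else Tensor(U)
    return params(U)


def positional_encoding(L: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding, (L, d_model).

    PE(pos, 2i) = sin(pos / 10000^(2i/d)), PE(pos, 2i+1) = cos(same).
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even for sinusoidal encoding")
    pos = np.arange(L)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((L, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def attention(Q, K, V, return_weights: bool = False):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V."""
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    d_k = Q.shape[-1]
    if K.shape[-1] != d_k:
        raise ValueError("Q and K must share the key dimension")
    ndim = len(K.shape)
    swap = tuple(range(ndim - 2)) + (ndim - 1, ndim - 2)
    scores = (Q @ K.transpose(swap)) * (1.0 / np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    ctx = weights @ V
    return (ctx, weights) if return_weights else ctx


class MultiHeadAttention:
    def __init__(self, rng, d_model: int, n_heads: int):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def _split(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        return x.reshape(B, L, self.h, self.d_k).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        ctx = scaled_dot_attention(q, k, v)            # (B, h, L, d_k)
        merged = ctx.transpose((0, 2, 1, 3)).reshape(B, L, D)
        return self.wo(merged)

    def params(self):
        return self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()


def multi_head(X, params: MultiHeadAttention) -> Tensor:
    """Functional multi-head attention over a (B, L, d_model) input."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    return params(X)


class LayerNorm:
    def __init__(self, d: int):
        self.gamma = Parameter(np.ones(d), no_decay=True)
        self.beta = Parameter(np.zeros(d), no_decay=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)

    def params(self):
        return [self.gamma, self.beta]


class EncoderLayer:
    """Transformer encoder layer (post-norm by default).

    post-norm: X1 = LN(X + Drop(MHA(X))); X' = LN(X1 + Drop(FFN(X1)))
    pre-norm:  X1 = X + Drop(MHA(LN(X))); X' = X1 + Drop(FFN(LN(X1)))
    """

    def __init__(self, rng, cfg: ModelConfig):
        self.mha = MultiHeadAttention(rng, cfg.d_model, cfg.n_heads)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ff1 = Linear(rng, cfg.d_model, cfg.ffn_dim)
        self.ff2 = Linear(rng, cfg.ffn_dim, cfg.d_model)
        self.ln2 = LayerNorm(cfg.d_model)
        self.p_drop = cfg.dropout
        self.pre_norm = cfg.pre_norm

    def _ffn(self, x: Tensor) -> Tensor:
        return self.ff2(self.ff1(x).relu())

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if self.pre_norm:
            x = x + self.mha(self.ln1(x)).dropout(self.p_drop, rng, training)
            return x + self._ffn(self.ln2(x)).dropout(self.p_drop, rng, training)
        x1 = self.ln1(x + self.mha(x).dropout(self.p_drop, rng, training))
        return self.ln2(x1 + self._ffn(x1).dropout(self.p_drop, rng, training))

    def params(self):
        return (self.mha.params() + self.ln1.params() + self.ff1.params()
                + self.ff2.params() + self.ln2.params())


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class Network:
    """Backbone + task heads for one variant of the architecture."""

    def __init__(self, config: ModelConfig, variant: Variant, seed: int = 0):
        self.config = config
        self.variant = variant
        rng = np.random.Generator(np.random.PCG64(seed))

        self.convs: list[ConvBlock] = []
        c = 1
        if variant.has_cnn:
            for c_out in config.conv_channels:
                self.convs.append(ConvBlock(rng, config.conv_kernel, c, c_out))
                c = c_out
        self.lift = Linear(rng, c, config.d_model)
        self.se = SEBlock(rng, config.d_model, config.se_reduction) if variant.has_se else None
        if variant.has_transformer:
            self.pe = positional_encoding(config.n_bands_in, config.d_model)
            self.encoder = [EncoderLayer(rng, config) for _ in range(config.n_layers)]
        else:
            self.pe = None
            self.encoder = []
        n_classes = {TASK_VARIETY: config.n_classes_task1,
                     TASK_PERIOD: config.n_classes_task2}
        self.heads = {t: Linear(rng, config.d_model, n_classes[t])
                      for t in variant.tasks}

    # -- parameters --------------------------------------------------------

    def backbone_params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for blk in self.convs:
            ps += blk.params()
        ps += self.lift.params()
        if self.se is not None:
            ps += self.se.params()
        for layer in self.encoder:
            ps += layer.params()
        return ps

    def head_params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for t in self.variant.tasks:
            ps += self.heads[t].params()
        return ps

    def parameters(self) -> list[Tensor]:
        return self.backbone_params() + self.head_params()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward -----------------------------------------------------------

    def logits(self, X, training: bool = False,
               rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        """Per-task unnormalised scores for a (B, n_bands_in) batch."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.n_bands_in:
            raise ValueError(
                f"expected (batch, {self.config.n_bands_in}) input, got {X.shape}"
            )
        B, L = X.shape
        x = Tensor(X).reshape(B, L, 1)
        for blk in self.convs:
            x = blk(x)
        x = self.lift(x)
        if self.se is not None:
            x = self.se(x)
        if self.encoder:
            x = x + Tensor(self.pe)
            x = x.dropout(self.config.dropout, rng, training)
            for layer in self.encoder:
                x = layer(x, training=training, rng=rng)
        pooled = x.mean(axis=1)                       # GAP over sequence axis
        return {t: self.heads[t](pooled) for t in self.variant.tasks}

    def predict_proba(self, X) -> dict[str, np.ndarray]:
        """Per-task class probabilities (softmax rows), eval mode."""
        return {t: z.softmax(axis=-1).data for t, z in self.logits(X).items()}

    def predict(self, X) -> dict[str, np.ndarray]:
        return {t: p.argmax(axis=1) for t, p in self.predict_proba(X).items()}

    # -- serialisation -----------------------------------------------------

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match network layout")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=float)

    def save(self, path) -> None:
        """Single-file checkpoint embedding config and variant."""
        path = Path(path)
        meta = {"variant": self.variant.value,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.config.__dict__.items()}}
        arrays = {f"p{i}": a for i, a in enumerate(self.state())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            cfg_kw = dict(meta["config"])
            cfg_kw["conv_channels"] = tuple(cfg_kw["conv_channels"])
            net = cls(ModelConfig(**cfg_kw), Variant(meta["variant"]))
            state = [z[f"p{i}"] for i in range(len(net.parameters()))]
        net.load_state(state)
        return net


def build(config: ModelConfig, variant: Variant, seed: int = 0) -> Network:
    """Construct a network for the given variant."""
    return Network(config, variant, seed=seed)


def forward(network: Network, X) -> dict[str, np.ndarray]:
    """Eval-mode class probabilities for a batch of spectra."""
    return network.predict_proba(X)
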