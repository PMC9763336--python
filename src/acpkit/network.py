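"""Bi-LSTM sequence classifiers with optional attention layers.

Two architectures over an Lmax x d encoded peptide matrix:

* **basic** - Bi-LSTM (n units per direction) -> dense(dense_units, ReLU)
  -> dense(2, softmax).  The Bi-LSTM contribution is the concatenation of
  the final hidden states of the forward and backward passes (2n values).
* **selfatt** - Bi-LSTM returning per-position outputs (Lmax x 2n) ->
  additive self-attention relating every position pair -> attention
  pooling (softmax-weighted sum over positions) -> the same dense head.

The attention pooling layer scores position j of the hidden matrix h as
e_j = h_j . W + b_j, weights alpha = softmax(e), and pools sum_j alpha_j
h_j.  The self-attention layer scores each ordered position pair (t, t')
as e_{t,t'} = sigmoid(W_a . tanh(x_t W_t + x_{t'} W_x + b_t) + b_a),
row-normalizes a_t = softmax(e_t), and emits l_t = sum_{t'} a_{t,t'} x_{t'}.

For the *embedding* feature scheme the fixed per-residue encoding is
replaced by a trainable 20 x 36 lookup applied to the one-hot (bpf) input
and learned jointly with the rest of the network.

All parameters live in a plain dict of autodiff Tensors; models serialize
to a single ``.npz`` archive holding the weights plus a JSON metadata
entry (config, standardization snapshot, channel names, training log), and
a reloaded model reproduces predictions bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np

from .autodiff import Tensor, concat, no_grad, softmax
from .encoders import (
    SCHEME_DIMS,
    EncodedPeptide,
    FeatureScheme,
    StandardizedTable,
    channel_names as scheme_channel_names,
    default_standardized_table,
)
from .sequence_io import LMAX

ARCHITECTURES = ("basic", "selfatt")


@dataclass
class ModelConfig:
    """Hyper-parameters of one model fit."""

    scheme: str = "mix"
    architecture: str = "basic"
    n_units: int = 64          # Bi-LSTM units per direction
    dense_units: int = 50      # first fully connected layer width
    epochs: int = 45
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    attention_hidden: int = 32  # score-path width of the self-attention layer
    mask_padding: bool = False  # freeze LSTM state past the true length
    lmax: int = LMAX

    def __post_init__(self) -> None:
        self.scheme = FeatureScheme(self.scheme).name
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        for name in ("n_units", "dense_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def input_scheme(self) -> str:
        """Scheme of the encoded input matrices fed to the network."""
        return "bpf" if self.scheme == "embedding" else self.scheme

    @property
    def lstm_input_dim(self) -> int:
        return 36 if self.scheme == "embedding" else SCHEME_DIMS[self.scheme]


@dataclass(frozen=True)
class AttentionParams:
    """Trainable weights of the attention pooling layer: W in R^{2n}, b in R^{Lmax}."""

    W: np.ndarray
    b: np.ndarray


@dataclass(frozen=True)
class SelfAttentionParams:
    """Trainable weights of the additive self-attention layer."""

    W_t: np.ndarray  # (2n, k)
    W_x: np.ndarray  # (2n, k)
    b_t: np.ndarray  # (k,)
    W_a: np.ndarray  # (k,)
    b_a: float


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_parameters(config: ModelConfig) -> dict[str, Tensor]:
    rng = np.random.default_rng(config.seed)
    n, L = config.n_units, config.lmax
    d = config.lstm_input_dim
    params: dict[str, np.ndarray] = {}
    if config.scheme == "embedding":
        params["emb"] = _glorot(rng, (20, 36))
    for direction in ("f", "b"):
        params[f"lstm_{direction}_Wx"] = _glorot(rng, (d, 4 * n))
        params[f"lstm_{direction}_Wh"] = _glorot(rng, (n, 4 * n))
        bias = np.zeros(4 * n)
        bias[n: 2 * n] = 1.0  # forget-gate bias 1 stabilizes early training
        params[f"lstm_{direction}_b"] = bias
    if config.architecture == "selfatt":
        k = config.attention_hidden
        params["sa_Wt"] = _glorot(rng, (2 * n, k))
        params["sa_Wx"] = _glorot(rng, (2 * n, k))
        params["sa_bt"] = np.zeros(k)
        params["sa_Wa"] = _glorot(rng, (k, 1))
        params["sa_ba"] = np.zeros(1)
        params["att_W"] = _glorot(rng, (2 * n, 1))
        params["att_b"] = np.zeros(L)
    params["d1_W"] = _glorot(rng, (2 * n, config.dense_units))
    params["d1_b"] = np.zeros(config.dense_units)
    params["d2_W"] = _glorot(rng, (config.dense_units, 2))
    params["d2_b"] = np.zeros(2)
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Layer cores (Tensor-level, used for both training and inference)
# ---------------------------------------------------------------------------

def _lstm_direction(
    X: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor, n: int,
    reverse: bool, mask: np.ndarray | None = None,
) -> list[Tensor]:
    """Run one LSTM direction; returns per-time hidden states (time order)."""
    B, L, _ = X.shape
    h = Tensor(np.zeros((B, n)))
    c = Tensor(np.zeros((B, n)))
    hs: list[Tensor] = [None] * L  # type: ignore[list-item]
    times = range(L - 1, -1, -1) if reverse else range(L)
    for t in times:
        xt = X[:, t, :]
        z = xt @ Wx + h @ Wh + b
        i = z[:, 0:n].sigmoid()
        f = z[:, n: 2 * n].sigmoid()
        g = z[:, 2 * n: 3 * n].tanh()
        o = z[:, 3 * n: 4 * n].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        if mask is not None:
            mt = Tensor(mask[:, t: t + 1])
            c = mt * c_new + (1.0 - mt) * c
            h = mt * h_new + (1.0 - mt) * h
        else:
            c, h = c_new, h_new
        hs[t] = h
    return hs


def _attention_pool_core(h: Tensor, W: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
    B, L, width = h.shape
    e = (h @ W).reshape(B, L) + b
    alpha = softmax(e, axis=-1)
    pooled = (alpha.reshape(B, 1, L) @ h).reshape(B, width)
    return pooled, alpha


def _self_attention_core(
    x: Tensor, Wt: Tensor, Wx: Tensor, bt: Tensor, Wa: Tensor, ba: Tensor
) -> tuple[Tensor, Tensor]:
    B, L, width = x.shape
    k = Wt.shape[1]
    P = (x @ Wt).reshape(B, L, 1, k)
    Q = (x @ Wx).reshape(B, 1, L, k)
    H = (P + Q + bt).tanh()                      # (B, L, L, k)
    E = ((H @ Wa).reshape(B, L, L) + ba).sigmoid()
    A = softmax(E, axis=-1)                      # rows over t'
    out = A @ x                                  # (B, L, width)
    return out, A


# ---------------------------------------------------------------------------
# Public single-array layer operations (numpy in, numpy out)
# ---------------------------------------------------------------------------

def attention_pool(
    h: np.ndarray, params: AttentionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pool an (Lmax x 2n) hidden matrix to a 2n-vector; returns (pooled, alpha).

    Batched (B x Lmax x 2n) input yields batched outputs.
    """
    h = np.asarray(h, dtype=float)
    single = h.ndim == 2
    if single:
        h = h[None]
    L, width = h.shape[1], h.shape[2]
    if params.W.shape != (width,) or params.b.shape != (L,):
        raise ValueError(
            f"attention params expect W{(width,)}, b{(L,)}; "
            f"got W{params.W.shape}, b{params.b.shape}"
        )
    with no_grad():
        pooled, alpha = _attention_pool_core(
            Tensor(h), Tensor(params.W.reshape(-1, 1)), Tensor(params.b)
        )
    if single:
        return pooled.data[0], alpha.data[0]
    return pooled.data, alpha.data


def self_attention(
    x: np.ndarray, params: SelfAttentionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Apply additive self-attention to an (Lmax x 2n) matrix.

    Returns (output, attention matrix a) with each row of `a` summing to 1.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    width = x.shape[2]
    k = params.W_t.shape[1]
    if params.W_t.shape[0] != width or params.W_x.shape != params.W_t.shape:
        raise ValueError(
            f"self-attention weight shapes {params.W_t.shape}/{params.W_x.shape} "
            f"do not match input width {width}"
        )
    with no_grad():
        out, A = _self_attention_core(
            Tensor(x),
            Tensor(params.W_t),
            Tensor(params.W_x),
            Tensor(params.b_t),
            Tensor(np.reshape(params.W_a, (k, 1))),
            Tensor(np.atleast_1d(params.b_a)),
        )
    if single:
        return out.data[0], A.data[0]
    return out.data, A.data


# ---------------------------------------------------------------------------
# Model forward pass
# ---------------------------------------------------------------------------

def _forward_core(
    params: dict[str, Tensor], config: ModelConfig, X: Tensor,
    lengths: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """Return (logits, penultimate activations) for an input batch tensor."""
    n = config.n_units
    B, L, _ = X.shape
    if config.scheme == "embedding":
        X = X @ params["emb"]
    mask = None
    if config.mask_padding:
        if lengths is None:
            raise ValueError("mask_padding requires true lengths")
        mask = (np.arange(L)[None, :] < lengths[:, None]).astype(float)
    hs_f = _lstm_direction(
        X, params["lstm_f_Wx"], params["lstm_f_Wh"], params["lstm_f_b"], n,
        reverse=False, mask=mask,
    )
    hs_b = _lstm_direction(
        X, params["lstm_b_Wx"], params["lstm_b_Wh"], params["lstm_b_b"], n,
        reverse=True, mask=mask,
    )
    if config.architecture == "basic":
        feat = concat([hs_f[-1], hs_b[0]], axis=1)
    else:
        rows = [
            concat([hf.reshape(B, 1, n), hb.reshape(B, 1, n)], axis=2)
            for hf, hb in zip(hs_f, hs_b)
        ]
        H = concat(rows, axis=1)  # (B, L, 2n)
        S, _ = _self_attention_core(
            H, params["sa_Wt"], params["sa_Wx"], params["sa_bt"],
            params["sa_Wa"], params["sa_ba"],
        )
        feat, _ = _attention_pool_core(S, params["att_W"], params["att_b"])
    z1 = (feat @ params["d1_W"] + params["d1_b"]).relu()
    logits = z1 @ params["d2_W"] + params["d2_b"]
    return logits, z1


@dataclass
class TrainedModel:
    """A (possibly untrained) network plus its full encoding provenance."""

    config: ModelConfig
    params: dict[str, Tensor]
    standardization: StandardizedTable
    channel_names: list[str]
    training_log: list[dict] = field(default_factory=list)

    # chunk sizes bound peak memory of the (B, L, L, k) self-attention score
    _CHUNK = {"basic": 1024, "selfatt": 64}

    def _check_batch(self, batch) -> np.ndarray:
        if isinstance(batch, np.ndarray):
            X = batch
        else:
            expected = self.config.input_scheme
            for ep in batch:
                if isinstance(ep, EncodedPeptide) and ep.scheme.name != expected:
                    raise ValueError(
                        f"scheme mismatch: model expects {expected!r} input, "
                        f"got {ep.scheme.name!r}"
                    )
            X = np.stack([ep.matrix for ep in batch])
        d_expected = SCHEME_DIMS[self.config.input_scheme]
        if X.ndim != 3 or X.shape[2] != d_expected:
            raise ValueError(
                f"input must be (B, {self.config.lmax}, {d_expected}); got {X.shape}"
            )
        return X

    def _run(self, batch, penultimate: bool) -> np.ndarray:
        X = self._check_batch(batch)
        chunk = self._CHUNK[self.config.architecture]
        lengths = None
        if self.config.mask_padding:
            # pad rows are all-zero; real rows contain a one-hot block
            lengths = np.count_nonzero(X.any(axis=2), axis=1)
        outs = []
        with no_grad():
            for lo in range(0, X.shape[0], chunk):
                logits, z1 = _forward_core(
                    self.params, self.config, Tensor(X[lo: lo + chunk]),
                    lengths=None if lengths is None else lengths[lo: lo + chunk],
                )
                out = z1 if penultimate else softmax(logits, axis=-1)
                outs.append(out.data)
        return np.concatenate(outs, axis=0)

    def forward(self, batch) -> np.ndarray:
        """Per-peptide (P(non-ACP), P(ACP)) probability pairs."""
        return self._run(batch, penultimate=False)

    predict_proba = forward

    def predict_acp_probability(self, batch) -> np.ndarray:
        return self.forward(batch)[:, 1]

    def penultimate_features(self, batch) -> np.ndarray:
        """Activations of the first fully connected layer (dense_units wide)."""
        return self._run(batch, penultimate=True)

    @property
    def attention_params(self) -> AttentionParams:
        if self.config.architecture != "selfatt":
            raise ValueError("basic architecture has no attention layer")
        return AttentionParams(
            W=self.params["att_W"].data.reshape(-1).copy(),
            b=self.params["att_b"].data.copy(),
        )

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "format_version": 1,
            "config": asdict(self.config),
            "standardization": self.standardization.to_dict(),
            "channel_names": self.channel_names,
            "training_log": self.training_log,
        }
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            params = {
                k: Tensor(archive[k].copy(), requires_grad=True)
                for k in archive.files
                if k != "__meta__"
            }
        return cls(
            config=ModelConfig(**meta["config"]),
            params=params,
            standardization=StandardizedTable.from_dict(meta["standardization"]),
            channel_names=meta["channel_names"],
            training_log=meta["training_log"],
        )


def build_model(config: ModelConfig) -> TrainedModel:
    """Construct an untrained model with seed-deterministic initial weights."""
    return TrainedModel(
        config=config,
        params=init_parameters(config),
        standardization=default_standardized_table(),
        channel_names=scheme_channel_names(config.scheme),
    )
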