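"""Dual-input attention-BiLSTM network for TCR-peptide binding prediction.

The TCR branch embeds the padded CDR3β token indices, runs a bidirectional
LSTM (hidden states ``h_i`` are the concatenation of the forward state
``h_i->`` and backward state ``h_i<-``), and pools the per-position states
with a learned attention head::

    u_i = tanh(W_A h_i + b_A)
    a_i = softmax_i(u_i . u)          (max-subtracted for stability)
    r   = sum_i a_i h_i

The peptide branch concatenates the padded peptide's embedding rows into one
vector and passes it through ReLU MLP layers.  The two features are
concatenated and classified by a ReLU MLP with a logistic output unit, so the
score is a probability in (0, 1); the binary decision is ``score > 0.5`` by
default.  Training minimises mean binary cross-entropy.

Everything here is plain NumPy with hand-written reverse-mode gradients and
an Adam optimiser: the model is small (tens of thousands of weights) and runs
comfortably on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .encoding import EmbeddingTable, EncodedBatch, Vocabulary, max_len_for

__all__ = [
    "ModelConfig",
    "ModelParams",
    "AttentionOutput",
    "ForwardTrace",
    "ModelError",
    "init_model",
    "bilstm_encode",
    "attention_pool",
    "peptide_encode",
    "classify",
    "bce_loss",
    "forward",
    "forward_batch",
    "predict_proba",
    "loss_and_grads",
    "Adam",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7  # probability clamp inside the loss


class ModelError(ValueError):
    """Fatal model configuration or numerical error."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the dual-input network.

    ``lstm_hidden`` is the hidden size per direction (the pooled TCR feature
    has dimension ``2 * lstm_hidden``).  ``attn_dim`` defaults to the
    concatenated state width.  Dropout is applied to the pooled TCR feature
    and after every hidden MLP layer, in training mode only — never to the
    attention weights.

    ``attn_input`` selects what the attention scores are computed from: the
    per-position token embeddings (``"embedding"``, the default) or the
    BiLSTM states themselves (``"hidden"``); the weighted sum is always over
    the BiLSTM states.  Embedding-based scores reflect which residues the
    model weights, and on motif-implanted data they tend to localize on the
    implanted motif; hidden-state scores drift to the terminal positions,
    whose bidirectional states summarize the whole sequence.  Both readings
    appear in the literature on attention-pooled recurrent classifiers.
    """

    embed_dim: int = 70
    lstm_hidden: int = 80
    lstm_layers: int = 1
    dropout_rate: float = 0.1
    attn_dim: int | None = None
    attn_input: str = "embedding"  # "embedding" or "hidden"; see class docstring
    pep_hidden: tuple[int, ...] = (64,)
    clf_hidden: tuple[int, ...] = (64,)
    decision_threshold: float = 0.5
    mask_placeholder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.embed_dim, self.lstm_hidden, self.lstm_layers) < 1:
            raise ModelError("all dimensions must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ModelError("dropout_rate must lie in [0, 1)")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ModelError("decision_threshold must lie in (0, 1)")
        if any(h < 1 for h in tuple(self.pep_hidden) + tuple(self.clf_hidden)):
            raise ModelError("hidden sizes must be >= 1")
        if self.attn_input not in ("embedding", "hidden"):
            raise ModelError("attn_input must be 'embedding' or 'hidden'")

    @property
    def d_a(self) -> int:
        return self.attn_dim if self.attn_dim is not None else 2 * self.lstm_hidden


@dataclass
class ModelParams:
    """All weights of the network, keyed by name, plus the config and vocabularies."""

    cfg: ModelConfig
    arrays: dict[str, np.ndarray]
    vocab_t: Vocabulary
    vocab_p: Vocabulary

    def copy(self) -> "ModelParams":
        return ModelParams(
            cfg=self.cfg,
            arrays={k: v.copy() for k, v in self.arrays.items()},
            vocab_t=self.vocab_t,
            vocab_p=self.vocab_p,
        )


@dataclass
class AttentionOutput:
    """Softmax attention weights over positions and the pooled 2h feature."""

    weights: np.ndarray  # (L,) nonnegative, sums to 1
    pooled: np.ndarray  # (2h,)


@dataclass
class ForwardTrace:
    """Per-record intermediate quantities of one forward pass."""

    hidden: np.ndarray  # (L, 2h) BiLSTM states
    attention: AttentionOutput
    pep_feature: np.ndarray
    fused: np.ndarray
    prob: float


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def init_model(
    cfg: ModelConfig, tcr_emb: EmbeddingTable, pep_emb: EmbeddingTable
) -> ModelParams:
    """Initialise all weights (Glorot-uniform matrices, zero biases), copying
    the given embedding tables as trainable parameters."""
    if tcr_emb.dim != cfg.embed_dim or pep_emb.dim != cfg.embed_dim:
        raise ModelError(
            f"embedding dim mismatch: config {cfg.embed_dim}, "
            f"tables {tcr_emb.dim}/{pep_emb.dim}"
        )
    rng = np.random.default_rng(cfg.seed)
    h = cfg.lstm_hidden
    arrays: dict[str, np.ndarray] = {
        "tcr_emb": tcr_emb.vectors.copy(),
        "pep_emb": pep_emb.vectors.copy(),
    }
    in_dim = cfg.embed_dim
    for layer in range(cfg.lstm_layers):
        for direction in ("fwd", "bwd"):
            prefix = f"lstm{layer}_{direction}"
            arrays[f"{prefix}_Wx"] = _glorot(rng, (in_dim, 4 * h))
            arrays[f"{prefix}_Wh"] = _glorot(rng, (h, 4 * h))
            # zero gate biases: short initial memory keeps per-position states
            # local, which lets the attention head resolve informative regions
            arrays[f"{prefix}_b"] = np.zeros(4 * h, dtype=np.float32)
        in_dim = 2 * h

    attn_in = cfg.embed_dim if cfg.attn_input == "embedding" else 2 * h
    arrays["attn_W"] = _glorot(rng, (attn_in, cfg.d_a))
    arrays["attn_b"] = np.zeros(cfg.d_a, dtype=np.float32)
    arrays["attn_u"] = _glorot(rng, (cfg.d_a, 1))[:, 0]

    # peptide MLP input is the flattened padded peptide embedding, L_p * d
    dim = max_len_for("peptide", pep_emb.vocab.granularity) * cfg.embed_dim
    for i, width in enumerate(cfg.pep_hidden):
        arrays[f"pep_W{i}"] = _glorot(rng, (dim, width))
        arrays[f"pep_b{i}"] = np.zeros(width, dtype=np.float32)
        dim = width

    dim = 2 * h + dim
    for i, width in enumerate(cfg.clf_hidden):
        arrays[f"clf_W{i}"] = _glorot(rng, (dim, width))
        arrays[f"clf_b{i}"] = np.zeros(width, dtype=np.float32)
        dim = width
    arrays["out_W"] = _glorot(rng, (dim, 1))
    arrays["out_b"] = np.zeros(1, dtype=np.float32)

    return ModelParams(cfg=cfg, arrays=arrays, vocab_t=tcr_emb.vocab, vocab_p=pep_emb.vocab)


def count_parameters(params: ModelParams) -> int:
    """Total trainable scalar count (embeddings included)."""
    return int(sum(v.size for v in params.arrays.values()))


# ---------------------------------------------------------------------------
# Primitive forward pieces


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_direction(
    X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Run one LSTM direction over ``X`` (B, L, in); returns H (B, L, h) + cache."""
    B, L, _ = X.shape
    h = Wh.shape[0]
    dtype = X.dtype
    XW = X @ Wx  # (B, L, 4h), all input projections at once
    H = np.zeros((B, L, h), dtype=dtype)
    C = np.zeros((B, L, h), dtype=dtype)
    gates = np.zeros((B, L, 4 * h), dtype=dtype)
    h_t = np.zeros((B, h), dtype=dtype)
    c_t = np.zeros((B, h), dtype=dtype)
    for t in range(L):
        z = XW[:, t] + h_t @ Wh + b
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h : 2 * h])
        g = np.tanh(z[:, 2 * h : 3 * h])
        o = _sigmoid(z[:, 3 * h :])
        c_t = f * c_t + i * g
        h_t = o * np.tanh(c_t)
        gates[:, t, :h] = i
        gates[:, t, h : 2 * h] = f
        gates[:, t, 2 * h : 3 * h] = g
        gates[:, t, 3 * h :] = o
        C[:, t] = c_t
        H[:, t] = h_t
    return H, {"X": X, "H": H, "C": C, "gates": gates, "Wx": Wx, "Wh": Wh}


def _lstm_direction_backward(cache: dict, dH: np.ndarray) -> tuple[np.ndarray, dict]:
    """Backprop through one LSTM direction.  Returns dX and weight grads."""
    X, H, C, gates = cache["X"], cache["H"], cache["C"], cache["gates"]
    Wx, Wh = cache["Wx"], cache["Wh"]
    B, L, h = H.shape
    dtype = H.dtype
    dZ = np.zeros((B, L, 4 * h), dtype=dtype)
    dh_next = np.zeros((B, h), dtype=dtype)
    dc_next = np.zeros((B, h), dtype=dtype)
    for t in range(L - 1, -1, -1):
        i = gates[:, t, :h]
        f = gates[:, t, h : 2 * h]
        g = gates[:, t, 2 * h : 3 * h]
        o = gates[:, t, 3 * h :]
        c_t = C[:, t]
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, h), dtype=dtype)
        tc = np.tanh(c_t)
        dh = dH[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dZ[:, t] = dz
        dh_next = dz @ Wh.T
        dc_next = dc * f
    H_prev = np.concatenate([np.zeros((B, 1, h), dtype=dtype), H[:, :-1]], axis=1)
    flat_dZ = dZ.reshape(B * L, 4 * h)
    grads = {
        "Wx": X.reshape(B * L, -1).T @ flat_dZ,
        "Wh": H_prev.reshape(B * L, h).T @ flat_dZ,
        "b": flat_dZ.sum(axis=0),
    }
    dX = dZ @ Wx.T
    return dX, grads


def _mlp_forward(
    x: np.ndarray,
    params: ModelParams,
    prefix: str,
    n_layers: int,
    training: bool,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, list[dict]]:
    """ReLU MLP stack with inverted dropout after each hidden layer."""
    p = params.cfg.dropout_rate
    caches = []
    for i in range(n_layers):
        W = params.arrays[f"{prefix}_W{i}"]
        b = params.arrays[f"{prefix}_b{i}"]
        z = x @ W + b
        a = np.maximum(z, 0.0)
        mask = None
        out = a
        if training and p > 0.0:
            mask = (rng.random(a.shape) >= p).astype(a.dtype) / (1.0 - p)
            out = a * mask
        caches.append({"x": x, "z": z, "mask": mask, "W": W})
        x = out
    return x, caches


def _mlp_backward(
    dx: np.ndarray, caches: list[dict], grads: dict, prefix: str
) -> np.ndarray:
    for i in range(len(caches) - 1, -1, -1):
        c = caches[i]
        if c["mask"] is not None:
            dx = dx * c["mask"]
        dz = dx * (c["z"] > 0)
        grads[f"{prefix}_W{i}"] = c["x"].T @ dz
        grads[f"{prefix}_b{i}"] = dz.sum(axis=0)
        dx = dz @ c["W"].T
    return dx


# ---------------------------------------------------------------------------
# Full forward / backward


def forward_batch(
    params: ModelParams,
    batch: EncodedBatch,
    training: bool = False,
    rng: np.random.Generator | None = None,
    need_cache: bool = False,
) -> tuple[np.ndarray, dict | None]:
    """Batched forward pass.  Returns probabilities (B,) and, on request, the
    cache needed for backprop (also carrying hidden states and attention)."""
    cfg = params.cfg
    A = params.arrays
    if training and cfg.dropout_rate > 0.0 and rng is None:
        raise ModelError("training-mode forward with dropout requires an rng")

    X = A["tcr_emb"][batch.cdr3_idx]  # (B, L, d)
    layer_caches = []
    inp = X
    for layer in range(cfg.lstm_layers):
        Hf, cf = _lstm_direction(
            inp, A[f"lstm{layer}_fwd_Wx"], A[f"lstm{layer}_fwd_Wh"], A[f"lstm{layer}_fwd_b"]
        )
        Hb_rev, cb = _lstm_direction(
            inp[:, ::-1],
            A[f"lstm{layer}_bwd_Wx"],
            A[f"lstm{layer}_bwd_Wh"],
            A[f"lstm{layer}_bwd_b"],
        )
        Hb = Hb_rev[:, ::-1]
        inp = np.concatenate([Hf, Hb], axis=2)  # (B, L, 2h)
        layer_caches.append((cf, cb))
    H = inp

    # attention pooling: scores from the embeddings or the hidden states,
    # the weighted sum always over the hidden states
    S = X if cfg.attn_input == "embedding" else H
    U = np.tanh(S @ A["attn_W"] + A["attn_b"])  # (B, L, d_a)
    scores = U @ A["attn_u"]  # (B, L)
    if cfg.mask_placeholder:
        pad = batch.cdr3_idx == params.vocab_t.placeholder_index
        scores = np.where(pad, -1e9, scores)
    scores = scores - scores.max(axis=1, keepdims=True)
    ex = np.exp(scores)
    attn = ex / ex.sum(axis=1, keepdims=True)  # (B, L)
    pooled = np.einsum("bl,blk->bk", attn, H)

    p_drop = cfg.dropout_rate
    pooled_mask = None
    pooled_out = pooled
    if training and p_drop > 0.0:
        pooled_mask = (rng.random(pooled.shape) >= p_drop).astype(pooled.dtype) / (
            1.0 - p_drop
        )
        pooled_out = pooled * pooled_mask

    P = A["pep_emb"][batch.pep_idx]  # (B, L_p, d)
    pep_in = P.reshape(P.shape[0], -1)
    pep_out, pep_caches = _mlp_forward(
        pep_in, params, "pep", len(cfg.pep_hidden), training, rng
    )

    fused = np.concatenate([pooled_out, pep_out], axis=1)
    clf_out, clf_caches = _mlp_forward(
        fused, params, "clf", len(cfg.clf_hidden), training, rng
    )
    logits = (clf_out @ A["out_W"])[:, 0] + A["out_b"][0]
    probs = _sigmoid(logits)
    if not np.all(np.isfinite(probs)):
        raise ModelError("non-finite activation in forward pass (divergence)")

    cache = None
    if need_cache:
        cache = {
            "X": X,
            "H": H,
            "S": S,
            "U": U,
            "attn": attn,
            "pooled": pooled,
            "pooled_mask": pooled_mask,
            "pep_in": pep_in,
            "pep_out": pep_out,
            "pep_caches": pep_caches,
            "fused": fused,
            "clf_out": clf_out,
            "clf_caches": clf_caches,
            "probs": probs,
            "layer_caches": layer_caches,
        }
    return probs, cache


def bce_loss(y, y_hat) -> float:
    """Mean binary cross-entropy, probabilities clamped to [1e-7, 1-1e-7]."""
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    p = np.clip(np.atleast_1d(np.asarray(y_hat, dtype=np.float64)), _EPS, 1.0 - _EPS)
    if y.shape != p.shape:
        raise ModelError("labels and probabilities must have matching shapes")
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def loss_and_grads(
    params: ModelParams,
    batch: EncodedBatch,
    training: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean BCE over the batch and its gradient for every weight array."""
    cfg = params.cfg
    A = params.arrays
    probs, cache = forward_batch(params, batch, training=training, rng=rng, need_cache=True)
    y = batch.labels.astype(probs.dtype)
    loss = bce_loss(y, probs)

    B = len(batch)
    grads: dict[str, np.ndarray] = {}
    dlogits = (probs - y) / B  # exact gradient of mean BCE through the sigmoid

    grads["out_W"] = cache["clf_out"].T @ dlogits[:, None]
    grads["out_b"] = np.array([dlogits.sum()], dtype=A["out_b"].dtype)
    d_clf_out = dlogits[:, None] @ A["out_W"].T
    d_fused = _mlp_backward(d_clf_out, cache["clf_caches"], grads, "clf")

    two_h = 2 * cfg.lstm_hidden
    d_pooled_out = d_fused[:, :two_h]
    d_pep_out = d_fused[:, two_h:]

    d_pep_in = _mlp_backward(d_pep_out, cache["pep_caches"], grads, "pep")
    dP = d_pep_in.reshape(batch.pep_idx.shape + (cfg.embed_dim,))
    g_pep_emb = np.zeros_like(A["pep_emb"])
    np.add.at(g_pep_emb, batch.pep_idx.ravel(), dP.reshape(-1, cfg.embed_dim))
    grads["pep_emb"] = g_pep_emb

    d_pooled = d_pooled_out
    if cache["pooled_mask"] is not None:
        d_pooled = d_pooled * cache["pooled_mask"]

    H, S, U, attn = cache["H"], cache["S"], cache["U"], cache["attn"]
    # pooled = sum_l a_l h_l
    d_attn = np.einsum("bk,blk->bl", d_pooled, H)
    dH = attn[:, :, None] * d_pooled[:, None, :]
    # softmax backward
    d_scores = attn * (d_attn - np.sum(d_attn * attn, axis=1, keepdims=True))
    dU = d_scores[:, :, None] * A["attn_u"][None, None, :]
    grads["attn_u"] = np.einsum("bl,blk->k", d_scores, U)
    d_pre = dU * (1.0 - U * U)
    Bsz, L, _ = H.shape
    grads["attn_W"] = S.reshape(Bsz * L, -1).T @ d_pre.reshape(Bsz * L, -1)
    grads["attn_b"] = d_pre.sum(axis=(0, 1))
    dS = d_pre @ A["attn_W"].T
    dX_attn = None
    if cfg.attn_input == "embedding":
        dX_attn = dS
    else:
        dH = dH + dS

    h = cfg.lstm_hidden
    for layer in range(cfg.lstm_layers - 1, -1, -1):
        cf, cb = cache["layer_caches"][layer]
        dHf = dH[:, :, :h]
        dHb = dH[:, :, h:]
        dX_f, g_f = _lstm_direction_backward(cf, dHf)
        dX_b_rev, g_b = _lstm_direction_backward(cb, dHb[:, ::-1])
        dX = dX_f + dX_b_rev[:, ::-1]
        for name, g in g_f.items():
            grads[f"lstm{layer}_fwd_{name}"] = g
        for name, g in g_b.items():
            grads[f"lstm{layer}_bwd_{name}"] = g
        dH = dX  # input of this layer is the output of the previous one

    dX_total = dH if dX_attn is None else dH + dX_attn
    g_tcr_emb = np.zeros_like(A["tcr_emb"])
    np.add.at(g_tcr_emb, batch.cdr3_idx.ravel(), dX_total.reshape(-1, cfg.embed_dim))
    grads["tcr_emb"] = g_tcr_emb
    return loss, grads


# ---------------------------------------------------------------------------
# Single-record convenience operations


def bilstm_encode(params: ModelParams, cdr3_row: np.ndarray) -> np.ndarray:
    """Hidden states (L, 2h) for one padded CDR3 index row."""
    cfg = params.cfg
    A = params.arrays
    X = A["tcr_emb"][np.asarray(cdr3_row)][None]
    inp = X
    for layer in range(cfg.lstm_layers):
        Hf, _ = _lstm_direction(
            inp, A[f"lstm{layer}_fwd_Wx"], A[f"lstm{layer}_fwd_Wh"], A[f"lstm{layer}_fwd_b"]
        )
        Hb_rev, _ = _lstm_direction(
            inp[:, ::-1],
            A[f"lstm{layer}_bwd_Wx"],
            A[f"lstm{layer}_bwd_Wh"],
            A[f"lstm{layer}_bwd_b"],
        )
        inp = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
    return inp[0]


def attention_pool(
    params: ModelParams, hidden: np.ndarray, score_input: np.ndarray | None = None
) -> AttentionOutput:
    """Attention-weighted pooling of per-position hidden states (L, 2h).

    Scores are computed from ``score_input`` (defaults to ``hidden`` itself,
    the Eq.-style reading; pass the embedding rows for an ``attn_input =
    "embedding"`` model).
    """
    hidden = np.asarray(hidden)
    if hidden.ndim != 2 or hidden.shape[0] == 0:
        raise ModelError("attention_pool expects a non-empty (L, 2h) matrix")
    S = hidden if score_input is None else np.asarray(score_input)
    A = params.arrays
    U = np.tanh(S @ A["attn_W"] + A["attn_b"])
    scores = U @ A["attn_u"]
    scores = scores - scores.max()
    ex = np.exp(scores)
    weights = ex / ex.sum()
    return AttentionOutput(weights=weights, pooled=weights @ hidden)


def peptide_encode(params: ModelParams, pep_row: np.ndarray) -> np.ndarray:
    """Peptide feature x' for one padded peptide index row (evaluation mode)."""
    A = params.arrays
    x = A["pep_emb"][np.asarray(pep_row)].reshape(1, -1)
    out, _ = _mlp_forward(x, params, "pep", len(params.cfg.pep_hidden), False, None)
    return out[0]


def classify(params: ModelParams, tcr_feature: np.ndarray, pep_feature: np.ndarray) -> float:
    """Fusion-MLP probability for one (TCR feature, peptide feature) pair."""
    fused = np.concatenate([np.asarray(tcr_feature), np.asarray(pep_feature)])[None]
    if not np.all(np.isfinite(fused)):
        raise ModelError("non-finite input feature")
    out, _ = _mlp_forward(fused, params, "clf", len(params.cfg.clf_hidden), False, None)
    logit = (out @ params.arrays["out_W"] + params.arrays["out_b"]).item()
    if not np.isfinite(logit):
        raise ModelError("non-finite activation (divergence)")
    return float(_sigmoid(np.array([logit]))[0])


def forward(
    params: ModelParams,
    batch: EncodedBatch,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> list[ForwardTrace]:
    """Per-record forward traces (hidden states, attention, features, probability)."""
    probs, cache = forward_batch(params, batch, training=training, rng=rng, need_cache=True)
    traces = []
    for i in range(len(batch)):
        traces.append(
            ForwardTrace(
                hidden=cache["H"][i],
                attention=AttentionOutput(
                    weights=cache["attn"][i], pooled=cache["pooled"][i]
                ),
                pep_feature=cache["pep_out"][i],
                fused=cache["fused"][i],
                prob=float(probs[i]),
            )
        )
    return traces


def predict_proba(params: ModelParams, batch: EncodedBatch) -> np.ndarray:
    """Evaluation-mode binding probabilities for a batch."""
    probs, _ = forward_batch(params, batch, training=False)
    return probs


# ---------------------------------------------------------------------------
# Optimiser


class Adam:
    """Adam optimiser over a ModelParams arrays dict."""

    def __init__(
        self,
        params: ModelParams,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays.items()}

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(params.arrays[k].dtype, copy=False)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params.arrays[k] -= (
                self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            )


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(params: ModelParams, path: str) -> None:
    """Write config + vocabularies + named weight arrays to one .npz archive."""
    meta = {
        "config": asdict(params.cfg),
        "vocab_t": {"granularity": params.vocab_t.granularity, "tokens": list(params.vocab_t.tokens)},
        "vocab_p": {"granularity": params.vocab_p.granularity, "tokens": list(params.vocab_p.tokens)},
        "names": sorted(params.arrays),
    }
    payload = {f"arr_{k}": v for k, v in params.arrays.items()}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path: str) -> ModelParams:
    """Restore a checkpoint; evaluation-mode predictions are bit-identical."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
        arrays = {name: data[f"arr_{name}"] for name in meta["names"]}
    cfg_d = dict(meta["config"])
    cfg_d["pep_hidden"] = tuple(cfg_d["pep_hidden"])
    cfg_d["clf_hidden"] = tuple(cfg_d["clf_hidden"])
    cfg = ModelConfig(**cfg_d)

    def _vocab(d: dict) -> Vocabulary:
        tokens = tuple(d["tokens"])
        return Vocabulary(
            granularity=d["granularity"],
            tokens=tokens,
            index_of={t: i for i, t in enumerate(tokens)},
        )

    return ModelParams(
        cfg=cfg,
        arrays=arrays,
        vocab_t=_vocab(meta["vocab_t"]),
        vocab_p=_vocab(meta["vocab_p"]),
    )
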