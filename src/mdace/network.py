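"""CNN-LSTM feature extractor g(x; theta) and softmax classifier h(g(x); W).

The model maps a one-hot encoded peptide window (W positions x 21 residue
categories) to a fixed-size embedding and a two-class probability:

    one-hot (B, W, 21)
      -> 1-D convolution, 21 in-channels, 128 out-channels, kernel 3, pad 1
      -> ReLU
      -> average pooling, kernel 2, stride 2 (floor division on odd lengths)
      -> LSTM, hidden size 128, single layer, unidirectional
      -> final hidden state  = embedding (B, M) with M = 128
      -> affine map + softmax = class probabilities (B, 2)

The embedding dimensionality M is what the domain-alignment KL loss
consumes, so M always equals the LSTM hidden size.  Everything runs in
float64 NumPy: a forward pass is a pure function of (parameters, input),
and two runs with identical seeds are bit-identical.  Backpropagation is
implemented by hand (no autograd framework is assumed at runtime) and is
validated against finite differences in the test suite.

An alternative layer order with the pooling applied to the LSTM output
sequence instead of the convolution output is selectable via
``ArchitectureConfig.pool_position = "after_lstm"``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .sequence_data import ALPHABET

CHECKPOINT_FORMAT = "mdace-checkpoint-1"


class NetworkError(ValueError):
    pass


@dataclass
class ArchitectureConfig:
    input_channels: int = 21
    conv_channels: int = 128
    kernel_size: int = 3
    padding: int = 1
    pool_kernel: int = 2
    pool_stride: int = 2
    lstm_hidden: int = 128          # M: the embedding dimensionality
    n_classes: int = 2
    pool_position: str = "after_conv"   # or "after_lstm"
    seed: int = 0

    def __post_init__(self):
        if self.conv_channels < 1:
            raise NetworkError("conv_channels must be >= 1")
        if self.lstm_hidden < 2:
            raise NetworkError("lstm_hidden must be >= 2")
        if self.kernel_size % 2 != 1:
            raise NetworkError("kernel_size must be odd")
        if self.pool_position not in ("after_conv", "after_lstm"):
            raise NetworkError(f"unknown pool_position {self.pool_position!r}")


@dataclass
class ModelState:
    """Extractor parameters theta, classifier parameters W, and the config."""

    params: dict[str, np.ndarray]
    config: ArchitectureConfig
    alphabet: str = ALPHABET
    train_seed: int | None = None

    def copy(self) -> "ModelState":
        return ModelState({k: v.copy() for k, v in self.params.items()},
                          self.config, self.alphabet, self.train_seed)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(self.config),
            "alphabet": self.alphabet,
            "train_seed": self.train_seed,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != CHECKPOINT_FORMAT:
            raise NetworkError(f"unrecognized checkpoint format {payload.get('format')!r}")
        config = ArchitectureConfig(**payload["config"])
        params = {k: np.array(v, dtype=np.float64) for k, v in payload["params"].items()}
        return cls(params=params, config=config, alphabet=payload["alphabet"],
                   train_seed=payload.get("train_seed"))


def init_model(config: ArchitectureConfig | None = None) -> ModelState:
    """Seeded uniform fan-in initialization; same seed => identical parameters."""
    config = config or ArchitectureConfig()
    rng = np.random.default_rng(config.seed)
    C_in, C_out, K = config.input_channels, config.conv_channels, config.kernel_size
    H = config.lstm_hidden

    def uniform(shape, scale):
        return rng.uniform(-scale, scale, size=shape)

    conv_scale = 1.0 / np.sqrt(C_in * K)
    lstm_scale = 1.0 / np.sqrt(H)
    params = {
        "conv_W": uniform((C_out, C_in, K), conv_scale),
        "conv_b": uniform((C_out,), conv_scale),
        "lstm_Wx": uniform((4 * H, C_out), lstm_scale),
        "lstm_Wh": uniform((4 * H, H), lstm_scale),
        "lstm_b": uniform((4 * H,), lstm_scale),
        "cls_W": uniform((H, config.n_classes), lstm_scale),
        "cls_b": uniform((config.n_classes,), lstm_scale),
    }
    return ModelState(params=params, config=config)


# ---------------------------------------------------------------------------
# Layer primitives (forward + backward)
# ---------------------------------------------------------------------------

def _conv1d_forward(x, W, b, padding):
    # x: (B, C_in, L); W: (C_out, C_in, K); im2col + one BLAS matmul
    B, C_in, L = x.shape
    C_out, _, K = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    L_out = L + 2 * padding - K + 1
    xcol = np.empty((B, C_in * K, L_out))
    for k in range(K):
        xcol[:, k * C_in:(k + 1) * C_in, :] = xp[:, :, k:k + L_out]
    out = np.matmul(W.transpose(0, 2, 1).reshape(C_out, K * C_in), xcol)
    out += b[None, :, None]
    return out, xcol


def _conv1d_backward(d_out, xcol, W, padding, L):
    B, C_out, L_out = d_out.shape
    _, C_in, K = W.shape
    W2 = W.transpose(0, 2, 1).reshape(C_out, K * C_in)   # (O, K*C)
    dW2 = np.matmul(d_out, xcol.transpose(0, 2, 1)).sum(axis=0)
    dW = dW2.reshape(C_out, K, C_in).transpose(0, 2, 1).copy()
    d_xcol = np.matmul(W2.T, d_out)                      # (B, K*C, L_out)
    d_xp = np.zeros((B, C_in, L + 2 * padding))
    for k in range(K):
        d_xp[:, :, k:k + L_out] += d_xcol[:, k * C_in:(k + 1) * C_in, :]
    db = d_out.sum(axis=(0, 2))
    dx = d_xp[:, :, padding:padding + L] if padding else d_xp
    return dx, dW, db


def _avgpool1d_forward(x, kernel, stride):
    # x: (B, C, L) -> (B, C, T), floor division on the trailing remainder
    B, C, L = x.shape
    T = (L - kernel) // stride + 1
    if T < 1:
        raise NetworkError(
            f"sequence length {L} too short for pooling (minimum {kernel})"
        )
    out = np.zeros((B, C, T))
    for t in range(T):
        out[:, :, t] = x[:, :, t * stride:t * stride + kernel].mean(axis=2)
    return out


def _avgpool1d_backward(d_out, kernel, stride, L):
    B, C, T = d_out.shape
    dx = np.zeros((B, C, L))
    for t in range(T):
        dx[:, :, t * stride:t * stride + kernel] += d_out[:, :, t:t + 1] / kernel
    return dx


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _lstm_forward(x, Wx, Wh, b):
    # x: (B, T, D); gate order i, f, g, o
    B, T, D = x.shape
    H = Wh.shape[1]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = {"x": x, "i": [], "f": [], "g": [], "o": [], "c": [], "h": [],
             "c_prev": [], "h_prev": []}
    hs = np.zeros((B, T, H))
    x_proj = x.reshape(B * T, D) @ Wx.T  # hoist the input projection out of the loop
    x_proj = x_proj.reshape(B, T, 4 * H)
    for t in range(T):
        z = x_proj[:, t, :] + h @ Wh.T + b
        zi, zf, zg, zo = np.split(z, 4, axis=1)
        i, f, g, o = _sigmoid(zi), _sigmoid(zf), np.tanh(zg), _sigmoid(zo)
        cache["c_prev"].append(c)
        cache["h_prev"].append(h)
        c = f * c + i * g
        h = o * np.tanh(c)
        for name, val in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("h", h)):
            cache[name].append(val)
        hs[:, t, :] = h
    return hs, cache


def _lstm_backward(d_hs, cache, Wx, Wh):
    # d_hs: (B, T, H) gradient on every hidden state
    x = cache["x"]
    B, T, D = x.shape
    H = Wh.shape[1]
    dWh = np.zeros_like(Wh)
    dx = np.zeros_like(x)
    dz_all = np.zeros((B, T, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
        c, c_prev, h_prev = cache["c"][t], cache["c_prev"][t], cache["h_prev"][t]
        dh = d_hs[:, t, :] + dh_next
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dh * o * (1 - tanh_c ** 2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dzi = di * i * (1 - i)
        dzf = df * f * (1 - f)
        dzg = dg * (1 - g ** 2)
        dzo = do * o * (1 - o)
        dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)  # (B, 4H)
        dz_all[:, t, :] = dz
        dWh += dz.T @ h_prev
        dh_next = dz @ Wh
    dz_flat = dz_all.reshape(B * T, 4 * H)
    dWx = dz_flat.T @ x.reshape(B * T, D)
    db = dz_flat.sum(axis=0)
    dx = (dz_flat @ Wx).reshape(B, T, D)
    return dx, dWx, dWh, db


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Full model forward / backward
# ---------------------------------------------------------------------------

def forward(model: ModelState, X: np.ndarray) -> dict:
    """Run the full network on encoded windows X of shape (B, W, A).

    Returns a cache dict with ``embedding`` (B, M), ``logits`` and
    ``probs`` (B, n_classes), plus intermediates needed for backprop.
    """
    if X.ndim != 3:
        raise NetworkError(f"expected (B, W, A) input, got shape {X.shape}")
    cfg = model.config
    if X.shape[2] != cfg.input_channels:
        raise NetworkError(
            f"input has {X.shape[2]} channels, config expects {cfg.input_channels}")
    p = model.params
    x = np.transpose(X, (0, 2, 1))  # (B, A, W) channels-first
    conv, xcol = _conv1d_forward(x, p["conv_W"], p["conv_b"], cfg.padding)
    relu = np.maximum(conv, 0.0)
    cache = {"x_len": x.shape[2], "xcol": xcol, "conv": conv}

    if cfg.pool_position == "after_conv":
        pooled = _avgpool1d_forward(relu, cfg.pool_kernel, cfg.pool_stride)
        cache["relu_len"] = relu.shape[2]
        lstm_in = np.transpose(pooled, (0, 2, 1))  # (B, T, C)
        hs, lstm_cache = _lstm_forward(lstm_in, p["lstm_Wx"], p["lstm_Wh"], p["lstm_b"])
        embedding = hs[:, -1, :]
    else:  # after_lstm: pool the LSTM hidden-state sequence along time
        lstm_in = np.transpose(relu, (0, 2, 1))
        hs, lstm_cache = _lstm_forward(lstm_in, p["lstm_Wx"], p["lstm_Wh"], p["lstm_b"])
        hs_cf = np.transpose(hs, (0, 2, 1))  # (B, H, T)
        pooled_h = _avgpool1d_forward(hs_cf, cfg.pool_kernel, cfg.pool_stride)
        cache["hs_len"] = hs.shape[1]
        embedding = pooled_h[:, :, -1]

    logits = embedding @ p["cls_W"] + p["cls_b"]
    probs = softmax(logits)
    cache.update({"lstm": lstm_cache, "hs_T": hs.shape[1], "embedding": embedding,
                  "logits": logits, "probs": probs})
    return cache


def backward(model: ModelState, cache: dict, d_embedding: np.ndarray | None = None,
             d_logits: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Backpropagate gradients supplied on the embedding and/or the logits.

    Returns a dict of parameter gradients matching ``model.params`` keys.
    """
    cfg = model.config
    p = model.params
    emb = cache["embedding"]
    B, H = emb.shape
    d_emb = np.zeros_like(emb) if d_embedding is None else d_embedding.copy()
    grads = {"cls_W": np.zeros_like(p["cls_W"]), "cls_b": np.zeros_like(p["cls_b"])}
    if d_logits is not None:
        grads["cls_W"] = emb.T @ d_logits
        grads["cls_b"] = d_logits.sum(axis=0)
        d_emb += d_logits @ p["cls_W"].T

    T = cache["hs_T"]
    if cfg.pool_position == "after_conv":
        d_hs = np.zeros((B, T, H))
        d_hs[:, -1, :] = d_emb
        dx_lstm, dWx, dWh, db_lstm = _lstm_backward(d_hs, cache["lstm"],
                                                    p["lstm_Wx"], p["lstm_Wh"])
        d_pooled = np.transpose(dx_lstm, (0, 2, 1))  # (B, C, T)
        d_relu = _avgpool1d_backward(d_pooled, cfg.pool_kernel, cfg.pool_stride,
                                     cache["relu_len"])
    else:
        T_pool = (cache["hs_len"] - cfg.pool_kernel) // cfg.pool_stride + 1
        d_pooled_h = np.zeros((B, H, T_pool))
        d_pooled_h[:, :, -1] = d_emb
        d_hs_cf = _avgpool1d_backward(d_pooled_h, cfg.pool_kernel, cfg.pool_stride,
                                      cache["hs_len"])
        d_hs = np.transpose(d_hs_cf, (0, 2, 1))
        dx_lstm, dWx, dWh, db_lstm = _lstm_backward(d_hs, cache["lstm"],
                                                    p["lstm_Wx"], p["lstm_Wh"])
        d_relu = np.transpose(dx_lstm, (0, 2, 1))

    d_conv = d_relu * (cache["conv"] > 0)
    _, dW_conv, db_conv = _conv1d_backward(d_conv, cache["xcol"], p["conv_W"],
                                           cfg.padding, cache["x_len"])
    grads.update({"lstm_Wx": dWx, "lstm_Wh": dWh, "lstm_b": db_lstm,
                  "conv_W": dW_conv, "conv_b": db_conv})
    return grads


# ---------------------------------------------------------------------------
# Public inference operations
# ---------------------------------------------------------------------------

def extract_features(model: ModelState, X: np.ndarray) -> np.ndarray:
    """Embedding g(x) of shape (B, M) for encoded windows X (B, W, A)."""
    return forward(model, X)["embedding"]


def predict_proba(model: ModelState, X: np.ndarray) -> np.ndarray:
    """Class probabilities h(g(x)) of shape (B, n_classes); rows on the simplex.

    Column 1 is the acetylation probability used for ranking and ROC.
    """
    return forward(model, X)["probs"]
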