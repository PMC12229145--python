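"""Loss family, dynamic source-domain weighting, and the training modes.

The total training objective combines the target-domain classification loss
with, for each source domain j, a weighted sum of that domain's
classification loss and a KL domain-difference loss:

    L_total = L_C^T + sum_j alpha_j * (L_C^{S_j} + L_KL^{S_j})

* L_C is mean binary cross-entropy over a batch (probabilities clamped at
  eps before the log).
* L_KL compares the *feature distributions* of target and source: the batch
  of embeddings g(x) is averaged over the batch, softmax-normalized over
  its M dimensions into a probability vector, epsilon-smoothed, and the KL
  divergence KL(p_target || p_source) is taken.
* alpha is a simplex-valued weight vector over source domains recomputed
  from the per-domain divergences D_j.  Three modes exist:
  ``similarity`` (default): alpha = softmax(-D), so sources whose feature
  distribution is *closer* to the target get more weight; ``literal``:
  alpha = softmax(+D), the formula as printed in the method's description
  (which rewards dissimilarity and is kept selectable for comparison); and
  ``uniform``: alpha_j = 1/N.

D_j is smoothed across steps by an exponential moving average before the
softmax, since per-batch divergences are noisy.  alpha is treated as a
constant within each gradient step: no gradient flows through the
weighting.

Four training modes map onto the ablation arms:
``mdda`` (adaptive weights, all sources), ``uniform`` (equal weights, all
sources), ``ssda`` (single source domain), ``ssdt`` (target-only direct
training, no adaptation terms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import network
from .network import ModelState
from .sequence_data import DomainDataset
from .evaluation import roc_auc

EPS_CLAMP = 1e-7     # probability clamp inside the cross-entropy
EPS_SMOOTH = 1e-8    # distribution smoothing before the KL

TRAINING_MODES = ("mdda", "uniform", "ssda", "ssdt")


class AdaptationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Loss primitives
# ---------------------------------------------------------------------------

def classification_loss(probabilities: np.ndarray, labels: np.ndarray,
                        eps: float = EPS_CLAMP) -> float:
    """Mean binary cross-entropy of positive-class probabilities vs labels."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise AdaptationError("empty batch")
    if p.shape != y.shape:
        raise AdaptationError(f"shape mismatch {p.shape} vs {y.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def embedding_distribution(embeddings: np.ndarray,
                           eps: float = EPS_SMOOTH) -> np.ndarray:
    """Softmax over the M dimensions of the batch-mean embedding, smoothed.

    Output lies on the M-simplex with every entry >= eps/(1+M*eps) > 0.
    """
    emb = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if not np.all(np.isfinite(emb)):
        raise AdaptationError("non-finite embeddings")
    mean = emb.mean(axis=0)
    p = network.softmax(mean)
    p = p + eps
    return p / p.sum()


def kl_domain_loss(p_target: np.ndarray, p_source: np.ndarray) -> float:
    """KL(p_target || p_source) = sum_k pT[k] * log(pT[k] / pS[k]), natural log."""
    pT = np.asarray(p_target, dtype=float)
    pS = np.asarray(p_source, dtype=float)
    if pT.shape != pS.shape:
        raise AdaptationError(f"length mismatch {pT.shape} vs {pS.shape}")
    return float(np.sum(pT * np.log(pT / pS)))


@dataclass
class DomainWeights:
    """Simplex-valued weights alpha over source domains plus their divergences."""

    alpha: np.ndarray
    divergences: np.ndarray
    mode: str = "similarity"

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.divergences = np.asarray(self.divergences, dtype=float)


def domain_weights(divergences: Sequence[float], mode: str = "similarity") -> DomainWeights:
    """Map per-source KL divergences D to weights alpha on the simplex.

    similarity: alpha = softmax(-D) (closer sources weigh more).
    literal:    alpha = softmax(+D), the printed form.
    uniform:    alpha_j = 1/N regardless of D.
    """
    D = np.asarray(divergences, dtype=float)
    if D.size == 0:
        raise AdaptationError("need at least one source domain")
    if not np.all(np.isfinite(D)):
        raise AdaptationError("divergences must be finite")
    if mode == "similarity":
        alpha = network.softmax(-D)
    elif mode == "literal":
        alpha = network.softmax(D)
    elif mode == "uniform":
        alpha = np.full(D.size, 1.0 / D.size)
    else:
        raise AdaptationError(f"unknown weight mode {mode!r}")
    return DomainWeights(alpha=alpha, divergences=D, mode=mode)


@dataclass
class LossBreakdown:
    """Component record for one evaluation of the total loss."""

    total: float
    target_classification: float
    source_classification: list[float]
    source_kl: list[float]
    weights: DomainWeights | None

    def recompose(self) -> float:
        """Re-sum the components; must match ``total`` within 1e-6."""
        s = self.target_classification
        if self.weights is not None:
            for a, lc, lkl in zip(self.weights.alpha, self.source_classification,
                                  self.source_kl):
                s += a * (lc + lkl)
        return s


@dataclass
class DomainBatch:
    X: np.ndarray            # (B, W, A) one-hot
    y: np.ndarray            # (B,)
    domain: str
    is_target: bool = False


def total_loss(target_batch: DomainBatch, source_batches: Sequence[DomainBatch],
               model: ModelState, weights: DomainWeights | None) -> LossBreakdown:
    """Evaluate L_total = L_C^T + sum_j alpha_j (L_C^{S_j} + L_KL^{S_j})."""
    if source_batches:
        if weights is None or len(weights.alpha) != len(source_batches):
            raise AdaptationError("weights length must equal number of source batches")
    t_cache = network.forward(model, target_batch.X)
    l_ct = classification_loss(t_cache["probs"][:, 1], target_batch.y)
    p_t = embedding_distribution(t_cache["embedding"])
    src_c, src_kl = [], []
    total = l_ct
    for j, sb in enumerate(source_batches or []):
        s_cache = network.forward(model, sb.X)
        lc = classification_loss(s_cache["probs"][:, 1], sb.y)
        p_s = embedding_distribution(s_cache["embedding"])
        lkl = kl_domain_loss(p_t, p_s)
        src_c.append(lc)
        src_kl.append(lkl)
        total += weights.alpha[j] * (lc + lkl)
    return LossBreakdown(total=float(total), target_classification=l_ct,
                         source_classification=src_c, source_kl=src_kl,
                         weights=weights if source_batches else None)


# ---------------------------------------------------------------------------
# Analytic gradients of the composite loss
# ---------------------------------------------------------------------------

def _ce_logit_grad(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits) through the fused softmax-CE form: (p - y)/B."""
    B = probs.shape[0]
    grad = probs.copy()
    grad[np.arange(B), y.astype(int)] -= 1.0
    return grad / B


def _distribution_grads(emb_t: np.ndarray, emb_s: np.ndarray,
                        eps: float = EPS_SMOOTH) -> tuple[np.ndarray, np.ndarray, float]:
    """KL of smoothed batch-mean softmax distributions and its embedding grads.

    Returns (d_emb_target, d_emb_source, kl_value).
    """
    def dist_and_jacobian_input(emb):
        mean = emb.mean(axis=0)
        s = network.softmax(mean)
        z = s.sum() + eps * s.size     # == 1 + M*eps
        p = (s + eps) / z
        return s, p

    s_t, p_t = dist_and_jacobian_input(emb_t)
    s_s, p_s = dist_and_jacobian_input(emb_s)
    kl = float(np.sum(p_t * np.log(p_t / p_s)))
    M = s_t.size
    z = 1.0 + eps * M
    # dKL/dp, chained through p = (s+eps)/z (linear) and softmax(mean(emb))
    g_pt = np.log(p_t / p_s) + 1.0
    g_ps = -p_t / p_s
    g_st = g_pt / z
    g_ss = g_ps / z
    d_mean_t = s_t * (g_st - np.dot(g_st, s_t))
    d_mean_s = s_s * (g_ss - np.dot(g_ss, s_s))
    d_emb_t = np.broadcast_to(d_mean_t / emb_t.shape[0], emb_t.shape).copy()
    d_emb_s = np.broadcast_to(d_mean_s / emb_s.shape[0], emb_s.shape).copy()
    return d_emb_t, d_emb_s, kl


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-2):
        self.lr = lr

    def step(self, params, grads):
        for k in params:
            params[k] -= self.lr * grads[k]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    mode: str = "mdda"                   # mdda | uniform | ssda | ssdt
    epochs: int = 100
    batch_size: int = 64                 # per domain
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    eps_clamp: float = EPS_CLAMP
    eps_smooth: float = EPS_SMOOTH
    weight_momentum: float = 0.9         # EMA momentum on the divergences D_j
    patience: int = 10                   # early stopping + best-val-AUC checkpoint selection; 0 disables both
    weight_mode: str | None = None       # override; defaults derived from mode

    def __post_init__(self):
        if self.mode not in TRAINING_MODES:
            raise AdaptationError(f"unknown training mode {self.mode!r}")

    def resolved_weight_mode(self) -> str:
        if self.weight_mode is not None:
            return self.weight_mode
        return "uniform" if self.mode == "uniform" else "similarity"


@dataclass
class TrainingTrace:
    """Per-epoch record of losses, alpha trajectories and validation AUC."""

    rows: list[dict] = field(default_factory=list)
    source_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def final_alpha(self) -> np.ndarray:
        if not self.rows or not self.source_names:
            return np.zeros(0)
        last = self.rows[-1]
        return np.array([last[f"alpha_{n}"] for n in self.source_names])


def _check_mode_sources(mode: str, n_sources: int) -> None:
    if mode == "ssdt" and n_sources != 0:
        raise AdaptationError("ssdt is target-only: source list must be empty")
    if mode == "ssda" and n_sources != 1:
        raise AdaptationError("ssda takes exactly one source domain")
    if mode in ("mdda", "uniform") and n_sources < 1:
        raise AdaptationError(f"mode {mode!r} requires at least one source domain")


class _BatchCycler:
    """Seeded, reshuffling round-robin batch sampler over one split."""

    def __init__(self, X, y, batch_size, rng):
        self.X, self.y = X, y
        self.batch_size = min(batch_size, len(y))
        self.rng = rng
        self._order = []

    def next(self):
        if len(self._order) < self.batch_size:
            self._order = list(self.rng.permutation(len(self.y)))
        idx = [self._order.pop() for _ in range(self.batch_size)]
        return self.X[idx], self.y[idx]


def train(model: ModelState, target: DomainDataset,
          sources: Sequence[DomainDataset] = (),
          config: TrainingConfig | None = None) -> tuple[ModelState, TrainingTrace]:
    """Train the shared extractor and classifier under the configured mode.

    Per step, one batch is drawn from the target and from each source; the
    per-source divergences D_j are computed from the current embedding
    distributions and EMA-smoothed; alpha is recomputed from the smoothed
    divergences; and the gradient of L_total updates theta and W jointly.
    The returned model is the best-validation-AUC checkpoint (the final
    model when no usable validation split exists).
    """
    config = config or TrainingConfig()
    sources = list(sources)
    _check_mode_sources(config.mode, len(sources))
    weight_mode = config.resolved_weight_mode()

    Xt, yt = target.encoded("train")
    if len(yt) == 0:
        raise AdaptationError("target training split is empty")
    Xv, yv = target.encoded("validation")
    has_val = len(yv) > 0 and len(np.unique(yv)) == 2
    select_best = config.patience > 0   # patience=0: fixed epochs, final model
    if select_best and not has_val:
        raise AdaptationError(
            "early stopping requires a validation split with both classes; "
            "set patience=0 to disable")

    rng = np.random.default_rng(config.seed)
    model = model.copy()
    model.train_seed = config.seed
    if config.optimizer == "adam":
        opt = Adam(model.params, lr=config.learning_rate)
    elif config.optimizer == "sgd":
        opt = SGD(model.params, lr=config.learning_rate)
    else:
        raise AdaptationError(f"unknown optimizer {config.optimizer!r}")

    t_cycler = _BatchCycler(Xt, yt, config.batch_size, rng)
    s_cyclers = []
    for src in sources:
        Xs, ys = src.encoded("train")
        if len(ys) == 0:
            raise AdaptationError(f"source {src.species!r} training split is empty")
        s_cyclers.append(_BatchCycler(Xs, ys, config.batch_size, rng))

    steps_per_epoch = max(1, math.ceil(len(yt) / config.batch_size))
    ema_D: np.ndarray | None = None
    trace = TrainingTrace(source_names=[s.species for s in sources])
    best_auc = -np.inf
    best_model = model.copy()
    stale = 0

    for epoch in range(config.epochs):
        ep_total = ep_lct = 0.0
        ep_lc_src = np.zeros(len(sources))
        ep_kl_src = np.zeros(len(sources))
        ep_alpha = np.zeros(len(sources))
        for _ in range(steps_per_epoch):
            xb, yb = t_cycler.next()
            t_cache = network.forward(model, xb)
            l_ct = classification_loss(t_cache["probs"][:, 1], yb, config.eps_clamp)
            d_logits_t = _ce_logit_grad(t_cache["probs"], yb)
            d_emb_t = np.zeros_like(t_cache["embedding"])

            src_caches, src_d_logits, src_d_emb = [], [], []
            D, lc_src = [], []
            for cyc in s_cyclers:
                xs, ys = cyc.next()
                s_cache = network.forward(model, xs)
                lc = classification_loss(s_cache["probs"][:, 1], ys, config.eps_clamp)
                g_t, g_s, kl = _distribution_grads(t_cache["embedding"],
                                                  s_cache["embedding"],
                                                  config.eps_smooth)
                src_caches.append(s_cache)
                src_d_logits.append(_ce_logit_grad(s_cache["probs"], ys))
                src_d_emb.append(g_s)
                D.append(kl)
                lc_src.append(lc)
                # target embedding also receives the KL gradient (scaled later)
                s_cache["_g_t"] = g_t

            if sources:
                D = np.array(D)
                ema_D = D if ema_D is None else (config.weight_momentum * ema_D
                                                 + (1 - config.weight_momentum) * D)
                w = domain_weights(ema_D, weight_mode)
                alpha = w.alpha
            else:
                alpha = np.zeros(0)

            total = l_ct
            for j in range(len(sources)):
                total += alpha[j] * (lc_src[j] + D[j])
                d_emb_t += alpha[j] * src_caches[j]["_g_t"]

            grads = network.backward(model, t_cache, d_embedding=d_emb_t,
                                     d_logits=d_logits_t)
            for j in range(len(sources)):
                g_j = network.backward(model, src_caches[j],
                                       d_embedding=alpha[j] * src_d_emb[j],
                                       d_logits=alpha[j] * src_d_logits[j])
                for k in grads:
                    grads[k] += g_j[k]
            opt.step(model.params, grads)

            ep_total += total
            ep_lct += l_ct
            if sources:
                ep_lc_src += lc_src
                ep_kl_src += D
                ep_alpha += alpha

        row = {"epoch": epoch, "mode": config.mode, "seed": config.seed,
               "loss_total": ep_total / steps_per_epoch,
               "loss_c_target": ep_lct / steps_per_epoch}
        for j, name in enumerate(trace.source_names):
            row[f"loss_c_{name}"] = ep_lc_src[j] / steps_per_epoch
            row[f"loss_kl_{name}"] = ep_kl_src[j] / steps_per_epoch
            row[f"alpha_{name}"] = ep_alpha[j] / steps_per_epoch
        if has_val:
            val_scores = network.predict_proba(model, Xv)[:, 1]
            row["val_auc"] = roc_auc(yv, val_scores)
        trace.rows.append(row)

        if select_best:
            if row["val_auc"] > best_auc:
                best_auc = row["val_auc"]
                best_model = model.copy()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if not select_best:
        best_model = model.copy()
    return best_model, trace
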