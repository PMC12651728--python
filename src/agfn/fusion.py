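"""Graph-attention fusion model and the fold training loop.

Per-patient dual-scale temporal representations are fused with static
features, then refined by two multi-head attention layers restricted to
each node's DA-KNN neighborhood (plus a self-loop, so a patient's own state
always contributes).  Gaussian edge weights enter the attention logits as
additive log-biases, so the softmax renormalizes a product of learned
relevance and embedding proximity.  A sigmoid output head produces six
independent outcome probabilities; training minimizes summed per-outcome
binary cross-entropy with AdamW, cosine learning-rate annealing,
global-norm gradient clipping at 1.0, periodic graph refresh with annealed
k_base, and early stopping on mean validation ROC-AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import _autodiff as ad
from ._autodiff import Tensor
from .graph import PatientGraph, attach_heldout, refresh_graph
from .nn import AdamW, Linear, Module, clip_grad_norm, cosine_lr, params_hash
from .preprocess import PatientTensor
from .temporal import LTGRUConfig, STCNNConfig, TemporalEncoder, stack_inputs

__all__ = ["FusionConfig", "FusionModel", "ModelState", "neighborhood_attention",
           "predict_proba", "train_fold", "predict_heldout", "bce_loss"]

N_OUTCOMES = 6


@dataclass(frozen=True)
class FusionConfig:
    heads: int = 4
    hidden: int = 64
    dropout: float = 0.3
    lr: float = 1e-3   # top of the search range; full-batch steps are few
    grad_clip: float = 1.0
    max_epochs: int = 50
    patience: int = 15
    weight_decay: float = 1e-4
    seed: int = 0
    st: STCNNConfig = field(default_factory=STCNNConfig)
    lt: LTGRUConfig = field(default_factory=LTGRUConfig)

    def __post_init__(self):
        if self.heads not in (2, 4, 8):
            raise ValueError("heads must be one of {2, 4, 8}")
        if self.hidden not in (64, 128, 256):
            raise ValueError("hidden must be one of {64, 128, 256}")
        if not 0.1 <= self.dropout <= 0.5:
            raise ValueError("dropout must lie in [0.1, 0.5]")
        if not 1e-5 <= self.lr <= 1e-3:
            raise ValueError("learning rate must lie in [1e-5, 1e-3]")
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")

    @property
    def d_k(self) -> int:
        return self.hidden // self.heads


def neighborhood_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                           neighbor_sets: list[np.ndarray],
                           edge_bias: list[np.ndarray] | None = None
                           ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Single-head scaled dot-product attention restricted to neighborhoods.

    Reference (non-autograd) implementation used for audits and tests:
    returns the attended output and the per-node attention weight vectors,
    each summing to 1 over the node's neighbor set.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    d_k = Q.shape[1]
    out = np.zeros((len(neighbor_sets), V.shape[1]))
    weights = []
    for i, nb in enumerate(neighbor_sets):
        if len(nb) == 0:
            raise ValueError(f"node {i} has an empty neighborhood")
        logits = K[nb] @ Q[i] / np.sqrt(d_k)
        if edge_bias is not None:
            logits = logits + edge_bias[i]
        logits -= logits.max()
        a = np.exp(logits)
        a /= a.sum()
        weights.append(a)
        out[i] = a @ V[nb]
    return out, weights


class GraphAttentionLayer(Module):
    """Multi-head attention over a masked (neighborhood) adjacency."""

    def __init__(self, d_model: int, heads: int, d_k: int,
                 rng: np.random.Generator):
        self.heads, self.d_k = heads, d_k
        self.Wq = Linear(d_model, heads * d_k, rng)
        self.Wk = Linear(d_model, heads * d_k, rng)
        self.Wv = Linear(d_model, heads * d_k, rng)
        self.Wo = Linear(heads * d_k, d_model, rng)

    def __call__(self, x_q: Tensor, x_kv: Tensor, mask: np.ndarray,
                 bias: np.ndarray, x_kv_diag: Tensor | None = None,
                 diag_sel: np.ndarray | None = None) -> Tensor:
        """x_q [Nq,dm] attends into x_kv [Nkv,dm] where mask is True.

        ``x_kv_diag`` substitutes each query's *own* key/value with a second
        source: used by the attribution pathway, where a node's own state is
        differentiated while its neighbors stay frozen.  ``diag_sel``
        [Nq, Nkv] marks which kv column is each query's self (identity when
        omitted, requiring Nq == Nkv).
        """
        nq = x_q.shape[0]
        outs = []
        eye = None
        if x_kv_diag is not None:
            eye = np.eye(nq) if diag_sel is None else \
                np.asarray(diag_sel, dtype=float)
        scale = 1.0 / np.sqrt(self.d_k)
        Q = self.Wq(x_q).reshape(nq, self.heads, self.d_k)
        K = self.Wk(x_kv).reshape(x_kv.shape[0], self.heads, self.d_k)
        V = self.Wv(x_kv).reshape(x_kv.shape[0], self.heads, self.d_k)
        if x_kv_diag is not None:
            Kd = self.Wk(x_kv_diag).reshape(nq, self.heads, self.d_k)
            Vd = self.Wv(x_kv_diag).reshape(nq, self.heads, self.d_k)
        for h in range(self.heads):
            Qh, Kh, Vh = Q[:, h, :], K[:, h, :], V[:, h, :]
            logits = (Qh @ Kh.T) * scale + bias
            if x_kv_diag is not None:
                diag = ((Qh * Kd[:, h, :]).sum(axis=1, keepdims=True)) * scale
                self_bias = (bias * eye).sum(axis=1, keepdims=True)
                logits = logits * (1.0 - eye) + (diag + self_bias) * eye
            A = ad.softmax(logits, axis=1, mask=mask)
            if x_kv_diag is None:
                outs.append(A @ Vh)
            else:
                off = (A * (1.0 - eye)) @ Vh
                diag_w = (A * eye).sum(axis=1, keepdims=True)
                outs.append(off + diag_w * Vd[:, h, :])
        out = self.Wo(ad.concatenate(outs, axis=1))
        return x_q + ad.relu(out)  # residual keeps the node's own signal


class FusionModel(Module):
    """Temporal encoders + input projection + 2 graph-attention layers + head."""

    def __init__(self, n_temporal_channels: int, n_static: int,
                 config: FusionConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = TemporalEncoder(n_temporal_channels, config.st,
                                       config.lt, rng)
        self.proj = Linear(self.encoder.out_dim + n_static, config.hidden, rng)
        self.gat1 = GraphAttentionLayer(config.hidden, config.heads,
                                        config.d_k, rng)
        self.gat2 = GraphAttentionLayer(config.hidden, config.heads,
                                        config.d_k, rng)
        self.head = Linear(config.hidden, N_OUTCOMES, rng)
        self._drop_rng = np.random.default_rng(config.seed + 1)

    # -- building blocks -----------------------------------------------------
    def node_rep(self, temporal: Tensor, static: Tensor,
                 training: bool = False) -> Tensor:
        h = ad.relu(self.proj(ad.concatenate(
            [self.encoder.encode(temporal), static], axis=1)))
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = (self._drop_rng.random(h.shape) < keep) / keep
            h = h * mask
        return h

    def logits_train(self, temporal: Tensor, static: Tensor,
                     mask: np.ndarray, bias: np.ndarray,
                     training: bool = False) -> Tensor:
        h = self.node_rep(temporal, static, training)
        h = self.gat1(h, h, mask, bias)
        h = self.gat2(h, h, mask, bias)
        return self.head(h)

    def logits_attached(self, ho_temporal: Tensor, ho_static: Tensor,
                        tr_temporal: Tensor, tr_static: Tensor,
                        ho_mask: np.ndarray, ho_bias: np.ndarray,
                        tr_mask: np.ndarray, tr_bias: np.ndarray) -> Tensor:
        """Held-out nodes attend into frozen training nodes at each layer.

        ``ho_mask``/``ho_bias`` are [Nho, Ntr + Nho]: columns 0..Ntr-1 are
        the node's training neighbors, column Ntr+i its self-loop.
        """
        h_tr = self.node_rep(tr_temporal, tr_static)
        h_ho = self.node_rep(ho_temporal, ho_static)
        for layer in (self.gat1, self.gat2):
            kv = ad.concatenate([h_tr, h_ho], axis=0)
            h_ho_new = layer(h_ho, kv, ho_mask, ho_bias)
            h_tr = layer(h_tr, h_tr, tr_mask, tr_bias)
            h_ho = h_ho_new
        return self.head(h_ho)


def predict_proba(logits: Tensor) -> Tensor:
    """Six independent outcome probabilities (multi-label sigmoid head)."""
    return ad.sigmoid(logits)


def bce_loss(logits: Tensor, labels: np.ndarray,
             outcome_mask: np.ndarray | None = None) -> Tensor:
    """Summed per-outcome binary cross-entropy, mean over patients."""
    y = np.asarray(labels, dtype=float)
    p = ad.sigmoid(logits)
    eps = 1e-9
    ll = ad.log(p + eps) * y + ad.log(1.0 - p + eps) * (1.0 - y)
    if outcome_mask is not None:
        ll = ll * np.asarray(outcome_mask, dtype=float)[None, :]
    return -(ll.mean(axis=0)).sum()


def _graph_mask_bias(graph: PatientGraph) -> tuple[np.ndarray, np.ndarray]:
    n = graph.n_nodes
    mask = np.eye(n, dtype=bool)
    bias = np.zeros((n, n))
    for i, (nb, w) in enumerate(zip(graph.neighbors, graph.weights)):
        mask[i, nb] = True
        bias[i, nb] = np.log(np.maximum(w, 1e-300))
    return mask, bias


def _attached_mask_bias(n_train: int, neighbors, weights
                        ) -> tuple[np.ndarray, np.ndarray]:
    n_ho = len(neighbors)
    mask = np.zeros((n_ho, n_train + n_ho), dtype=bool)
    bias = np.zeros((n_ho, n_train + n_ho))
    for i, (nb, w) in enumerate(zip(neighbors, weights)):
        mask[i, nb] = True
        bias[i, nb] = np.log(np.maximum(w, 1e-300))
        mask[i, n_train + i] = True  # self-loop
    return mask, bias


@dataclass
class ModelState:
    """Frozen per-fold artifact: weights + graph + preprocessing identity."""

    model: FusionModel
    graph: PatientGraph
    config: FusionConfig
    preprocessor_hash: str
    train_log: list[dict]
    best_epoch: int
    best_val_auc: float
    fold_id: int = -1

    def checkpoint_hash(self) -> str:
        return params_hash(self.model.state_dict())


def _mean_auc(y: np.ndarray, p: np.ndarray) -> float:
    aucs = []
    for k in range(y.shape[1]):
        if len(np.unique(y[:, k])) == 2:
            aucs.append(roc_auc_score(y[:, k], p[:, k]))
    return float(np.mean(aucs)) if aucs else float("nan")


def train_fold(train_tensors: list[PatientTensor], train_labels: np.ndarray,
               val_tensors: list[PatientTensor], val_labels: np.ndarray,
               graph: PatientGraph, config: FusionConfig = FusionConfig(),
               preprocessor_hash: str = "", fold_id: int = -1) -> ModelState:
    """Train one fold; fully reproducible given the config seed."""
    tr_temp, tr_stat = stack_inputs(train_tensors)
    va_temp, va_stat = stack_inputs(val_tensors)
    y_tr = np.asarray(train_labels, float)
    y_va = np.asarray(val_labels, float)
    outcome_mask = (y_tr.sum(axis=0) > 0).astype(float)
    if (outcome_mask == 0).any():
        warnings.warn("outcomes with no positive training labels are skipped: "
                      f"{np.nonzero(outcome_mask == 0)[0].tolist()}",
                      stacklevel=2)

    model = FusionModel(tr_temp.shape[2], tr_stat.shape[1], config)
    opt = AdamW(model.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)
    x_tr, s_tr = Tensor(tr_temp), Tensor(tr_stat)
    x_va, s_va = Tensor(va_temp), Tensor(va_stat)

    encoder = getattr(graph, "_encoder", None)

    def _refresh(g, epoch):
        g2 = refresh_graph(g, g.embeddings, epoch, config.max_epochs)
        if encoder is not None:
            g2._encoder = encoder
        return g2

    # start annealed: small k_base, ramping to target over the first 20%
    graph = _refresh(graph, 0)
    mask, bias = _graph_mask_bias(graph)
    nb_va, w_va, _ = attach_heldout(graph, _embed_for(graph, val_tensors))
    va_mask, va_bias = _attached_mask_bias(graph.n_nodes, nb_va, w_va)

    best_state, best_auc, best_epoch, since_best = None, -np.inf, -1, 0
    log: list[dict] = []
    for epoch in range(config.max_epochs):
        if epoch > 0 and epoch % graph.config.refresh_every == 0:
            graph = _refresh(graph, epoch)
            mask, bias = _graph_mask_bias(graph)
        opt.lr = cosine_lr(config.lr, epoch, config.max_epochs)
        logits = model.logits_train(x_tr, s_tr, mask, bias, training=True)
        loss = bce_loss(logits, y_tr, outcome_mask)
        opt.zero_grad()
        loss.backward()
        clip_grad_norm(model.parameters(), config.grad_clip)
        opt.step()

        va_logits = model.logits_attached(x_va, s_va, x_tr, s_tr,
                                          va_mask, va_bias, mask, bias)
        val_auc = _mean_auc(y_va, predict_proba(va_logits).data)
        log.append({"epoch": epoch, "train_loss": float(loss.data),
                    "val_auc": val_auc, "lr": opt.lr,
                    "k_mean": float(graph.k.mean())})
        if val_auc > best_auc:
            best_auc, best_epoch, since_best = val_auc, epoch, 0
            best_state = model.state_dict()
            best_graph = graph
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
        graph = best_graph
    return ModelState(model=model, graph=graph, config=config,
                      preprocessor_hash=preprocessor_hash, train_log=log,
                      best_epoch=best_epoch, best_val_auc=float(best_auc),
                      fold_id=fold_id)


def _embed_for(graph: PatientGraph, tensors: list[PatientTensor]) -> np.ndarray:
    """Look up the frozen contrastive embeddings attached to the tensors."""
    enc = getattr(graph, "_encoder", None)
    if enc is None:
        raise RuntimeError("graph carries no encoder; use pipeline.run_fold "
                           "or set graph._encoder")
    from .embed import summary_features

    return enc.embed(summary_features(tensors))


def predict_heldout(state: ModelState, tensors: list[PatientTensor],
                    train_tensors: list[PatientTensor]) -> np.ndarray:
    """Predict held-out patients through frozen preprocessing, graph and weights."""
    for pt in tensors:
        if pt._fit is not None and state.preprocessor_hash \
                and pt._fit.content_hash() != state.preprocessor_hash:
            raise ValueError("tensor was preprocessed with a different fit "
                             "than this model's frozen preprocessor")
    ho_temp, ho_stat = stack_inputs(tensors)
    tr_temp, tr_stat = stack_inputs(train_tensors)
    nb, w, _ = attach_heldout(state.graph, _embed_for(state.graph, tensors))
    ho_mask, ho_bias = _attached_mask_bias(state.graph.n_nodes, nb, w)
    tr_mask, tr_bias = _graph_mask_bias(state.graph)
    logits = state.model.logits_attached(
        Tensor(ho_temp), Tensor(ho_stat), Tensor(tr_temp), Tensor(tr_stat),
        ho_mask, ho_bias, tr_mask, tr_bias)
    return predict_proba(logits).data
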