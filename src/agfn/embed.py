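"""Outcome-aligned patient embeddings via supervised contrastive learning.

For each of the six outcomes, a one-vs-rest supervised contrastive objective
pulls patients with the same label together and pushes different labels
apart in an L2-normalized embedding space (cosine similarity, temperature
tau).  Positive pairs are reweighted by the inverse prevalence of their
outcome so rare, high-risk phenotypes are not swamped by common ones; the
six per-outcome losses are summed into a single objective.  The encoder — a
two-layer perceptron over the patient's statics plus per-variable summary
statistics (mean, trend, last value) of the pre-censoring window — is
retrained inside each cross-validation fold and its weights frozen before
any held-out patient is embedded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .nn import AdamW, Linear, Module, clip_grad_norm
from .preprocess import PatientTensor

__all__ = ["EmbedConfig", "ContrastiveEncoder", "contrastive_loss",
           "train_encoder", "summary_features"]


@dataclass(frozen=True)
class EmbedConfig:
    dim: int = 16
    hidden: int = 64
    tau: float = 0.1          # broad optimum 0.05-0.2; collapse below, blur above
    epochs: int = 60
    lr: float = 1e-3
    batch_size: int = 512     # anchors per contrastive batch
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.dim < 2:
            raise ValueError("embedding dim must be at least 2")


def summary_features(tensors: list[PatientTensor]) -> np.ndarray:
    """Encoder input: statics + per-variable (mean, slope, last) summaries."""
    rows = []
    for pt in tensors:
        rows.append(np.concatenate([
            pt.statics, pt.X.mean(axis=0), pt.slope, pt.X[-1],
            pt.slope_defined,
        ]))
    return np.asarray(rows)


def _l2_normalize(h: Tensor) -> Tensor:
    norm = ((h * h).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    return h / norm


def _log_prob_matrix(embeddings: Tensor, tau: float) -> Tensor:
    """log softmax of cosine similarities over a != i, shared by all outcomes."""
    n = embeddings.shape[0]
    E = _l2_normalize(embeddings)
    logits = (E @ E.T) * (1.0 / tau)
    off_diag = ~np.eye(n, dtype=bool)
    # log denominator over a != i, numerically shifted by the detached row max
    shift = np.where(off_diag, logits.data, -np.inf).max(axis=1, keepdims=True)
    z = ad.exp(logits - shift) * off_diag.astype(float)
    log_den = ad.log(z.sum(axis=1, keepdims=True)) + shift
    return logits - log_den


def _supcon_from_log_prob(log_prob: Tensor, labels: np.ndarray,
                          pos_weight: float, neg_weight: float,
                          warn_empty: bool = True) -> Tensor | None:
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    off_diag = ~np.eye(n, dtype=bool)
    pos_mask = ((labels[:, None] == labels[None, :]) & off_diag).astype(float)
    n_pos = pos_mask.sum(axis=1)
    valid = n_pos > 0
    if not valid.any():
        if warn_empty:
            warnings.warn("no anchor has a positive pair; contrastive loss "
                          "is 0", stacklevel=3)
        return None
    per_anchor = -(log_prob * pos_mask).sum(axis=1) / np.maximum(n_pos, 1.0)
    w = np.where(labels == 1, pos_weight, neg_weight) * valid
    w = w / w[valid].mean()
    return (per_anchor * w).sum() * (1.0 / valid.sum())


def contrastive_loss(embeddings: Tensor, labels: np.ndarray, tau: float,
                     pos_weight: float = 1.0, neg_weight: float = 1.0) -> Tensor:
    """One-vs-rest supervised contrastive loss (cosine similarity).

    Anchors whose positive set is empty contribute nothing and are excluded
    from the average.  ``pos_weight``/``neg_weight`` reweight anchors of the
    two classes (inverse-prevalence weighting); weights are normalized to
    mean 1 over the valid anchors so the loss scale is weight-invariant.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    labels = np.asarray(labels).astype(int)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples")
    loss = _supcon_from_log_prob(_log_prob_matrix(embeddings, tau), labels,
                                 pos_weight, neg_weight)
    return embeddings.sum() * 0.0 if loss is None else loss


class ContrastiveEncoder(Module):
    """Two-layer perceptron, output L2-normalized onto the unit sphere."""

    def __init__(self, n_features: int, config: EmbedConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.fc1 = Linear(n_features, config.hidden, rng)
        self.fc2 = Linear(config.hidden, config.dim, rng)
        self.frozen = False

    def forward(self, x: Tensor) -> Tensor:
        return _l2_normalize(self.fc2(ad.tanh(self.fc1(x))))

    def embed(self, features: np.ndarray) -> np.ndarray:
        """Map feature rows to unit-norm embeddings without touching weights."""
        return self.forward(Tensor(np.asarray(features, dtype=float))).data


def train_encoder(features: np.ndarray, labels: np.ndarray,
                  config: EmbedConfig = EmbedConfig(),
                  ) -> tuple[ContrastiveEncoder, np.ndarray]:
    """Train on training-fold patients only; returns (frozen encoder, embeddings).

    ``labels`` is [N, n_outcomes] binary; each outcome contributes a
    one-vs-rest loss weighted by its inverse prevalence.
    """
    features = np.asarray(features, dtype=float)
    labels = np.atleast_2d(np.asarray(labels).astype(int))
    if labels.shape[0] != features.shape[0]:
        labels = labels.T
    n = features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training patients")
    enc = ContrastiveEncoder(features.shape[1], config)
    opt = AdamW(enc.parameters(), lr=config.lr)
    prev = labels.mean(axis=0)
    live = [k for k in range(labels.shape[1]) if 0.0 < prev[k] < 1.0]
    if not live:
        warnings.warn("all outcomes degenerate; encoder left at init",
                      stacklevel=2)
        enc.frozen = True
        return enc, enc.embed(features)
    rng = np.random.default_rng(config.seed + 17)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if len(idx) < 2:
                continue
            emb = enc.forward(Tensor(features[idx]))
            log_prob = _log_prob_matrix(emb, config.tau)
            total = None
            for k in live:
                lk = _supcon_from_log_prob(log_prob, labels[idx, k],
                                           pos_weight=1.0 / prev[k],
                                           neg_weight=1.0 / (1.0 - prev[k]),
                                           warn_empty=False)
                if lk is not None:
                    total = lk if total is None else total + lk
            if total is None:
                continue
            opt.zero_grad()
            total.backward()
            clip_grad_norm(enc.parameters(), 1.0)
            opt.step()
    enc.frozen = True
    return enc, enc.embed(features)
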