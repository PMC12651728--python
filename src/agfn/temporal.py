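"""Dual-scale temporal encoding of patient trajectories.

Two complementary encoders read the hourly grid:

* **ST-CNN** — a gated 1-D convolution, y_t = sigmoid(W_g * X_{t:t+w}) ⊙
  relu(W_c * X_{t:t+w}), max-pooled over time.  The sigmoid gate suppresses
  noise while letting transient excursions (the acute-event signature)
  through; max pooling keeps the strongest local response.
* **LT-GRU** — a gated recurrent unit whose extra gate g_t mixes the
  previous hidden state with an exponential moving average of earlier
  hidden states, g_t = sigmoid(W_g x_t + U_g(beta*h_{t-1} +
  (1-beta)*EMA(h_{t-2}))).  The effective update gate z_t ⊙ g_t keeps h_t a
  convex combination of h_{t-1} and the candidate state, which both bounds
  the state and slows the overwriting of slowly-drifting risk signals.
  The EMA recursion is EMA_t = beta*h_t + (1-beta)*EMA_{t-1} with
  EMA_0 = h_0 = 0, and the gate at step t reads the EMA up to t-2.

Imputed values enter the encoders directly; the observation mask and the
stepwise differences ride along as extra input channels so the network can
distinguish measured from imputed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .nn import Linear, Module
from .preprocess import PatientTensor

__all__ = ["STCNNConfig", "LTGRUConfig", "STCNN", "LTGRU", "lt_gru_step",
           "TemporalEncoder", "stack_inputs"]


@dataclass(frozen=True)
class STCNNConfig:
    window: int = 6    # hours; matches the hyperacute 0-6 h phase
    channels: int = 32


@dataclass(frozen=True)
class LTGRUConfig:
    hidden: int = 32
    beta: float = 0.9  # single decay factor shared by EMA and gate mixing

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


def stack_inputs(tensors: list[PatientTensor]) -> tuple[np.ndarray, np.ndarray]:
    """Batch tensors into (temporal [N,T,3D], static [N,S]) model inputs.

    Temporal channels per variable: imputed value, observation mask,
    stepwise difference.  The static side carries the encoded statics plus
    per-variable slopes and their defined-flags.
    """
    temporal = np.stack([np.concatenate([pt.X, pt.M, pt.delta], axis=1)
                         for pt in tensors])
    static = np.stack([np.concatenate([pt.statics, pt.slope,
                                       pt.slope_defined]) for pt in tensors])
    return temporal, static


class STCNN(Module):
    """Gated short-term 1-D convolutional encoder."""

    def __init__(self, n_channels_in: int, config: STCNNConfig,
                 rng: np.random.Generator):
        self.config = config
        w, c = config.window, config.channels
        self.gate = Linear(w * n_channels_in, c, rng)
        self.content = Linear(w * n_channels_in, c, rng)

    def forward_window(self, window: Tensor) -> Tensor:
        """Apply the gated convolution to one [w, D] window."""
        flat = window.reshape(1, -1)
        return (ad.sigmoid(self.gate(flat)) * ad.relu(self.content(flat)))

    def __call__(self, x: Tensor) -> Tensor:
        """x: [N, T, D] -> gated features [N, T, c] ('same' length, end-padded)."""
        n, t, d = x.shape
        w = self.config.window
        if w > t:
            raise ValueError(f"window {w} exceeds sequence length {t}")
        pad = Tensor(np.zeros((n, w - 1, d)))
        xp = ad.concatenate([x, pad], axis=1)          # [N, T+w-1, D]
        idx = np.arange(t)[:, None] + np.arange(w)[None, :]
        windows = xp[:, idx, :].reshape(n, t, w * d)
        return ad.sigmoid(self.gate(windows)) * ad.relu(self.content(windows))

    def encode(self, x: Tensor) -> Tensor:
        """Max-pool the gated features over time -> [N, c]."""
        return self(x).max(axis=1)


def lt_gru_step(x_t: Tensor, h_prev: Tensor, ema_tm2: Tensor, params: dict,
                beta: float) -> Tensor:
    """One LT-GRU update; h_t is elementwise convex in (h_prev, candidate)."""
    z = ad.sigmoid(params["Wz"](x_t) + params["Uz"](h_prev))
    r = ad.sigmoid(params["Wr"](x_t) + params["Ur"](h_prev))
    h_tilde = ad.tanh(params["Wh"](x_t) + params["Uh"](r * h_prev))
    g = ad.sigmoid(params["Wg"](x_t)
                   + params["Ug"](h_prev * beta + ema_tm2 * (1.0 - beta)))
    zg = z * g
    return (1.0 - zg) * h_prev + zg * h_tilde


class LTGRU(Module):
    """Long-term GRU with EMA-stabilized gating."""

    def __init__(self, n_in: int, config: LTGRUConfig, rng: np.random.Generator):
        self.config = config
        h = config.hidden
        for name in ("Wz", "Wr", "Wh", "Wg"):
            setattr(self, name, Linear(n_in, h, rng))
        for name in ("Uz", "Ur", "Uh", "Ug"):
            setattr(self, name, Linear(h, h, rng))

    def _params(self) -> dict:
        return {k: getattr(self, k)
                for k in ("Wz", "Uz", "Wr", "Ur", "Wh", "Uh", "Wg", "Ug")}

    def encode(self, x: Tensor) -> Tensor:
        """x: [N, T, D] -> final hidden state [N, hidden]."""
        n, t, _ = x.shape
        beta = self.config.beta
        h = Tensor(np.zeros((n, self.config.hidden)))
        ema_prev = h          # EMA through h_{t-1}
        ema_prev2 = h         # EMA through h_{t-2}, read by the gate
        params = self._params()
        for step in range(t):
            x_t = x[:, step, :]
            h_new = lt_gru_step(x_t, h, ema_prev2, params, beta)
            ema_prev2 = ema_prev
            ema_prev = h_new * beta + ema_prev * (1.0 - beta)
            h = h_new
        return h


class TemporalEncoder(Module):
    """Fused dual-scale representation H_i = [h_ST ; h_LT]."""

    def __init__(self, n_channels_in: int, st: STCNNConfig, lt: LTGRUConfig,
                 rng: np.random.Generator):
        self.st_cnn = STCNN(n_channels_in, st, rng)
        self.lt_gru = LTGRU(n_channels_in, lt, rng)

    @property
    def out_dim(self) -> int:
        return self.st_cnn.config.channels + self.lt_gru.config.hidden

    def encode(self, x: Tensor) -> Tensor:
        if x.shape[1] == 0:  # empty time axis: statics-only fallback upstream
            return Tensor(np.zeros((x.shape[0], self.out_dim)))
        return ad.concatenate([self.st_cnn.encode(x), self.lt_gru.encode(x)],
                              axis=1)
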