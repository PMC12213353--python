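"""Numpy implementation of the age-regression network and its gradients.

Architecture, applied to a (standardized) time-frequency graph of shape
(C, F, T):

1. trainable triangular filter layer: contract F bins to M bands with
   ``W_f = sigmoid(W) * W_L`` (see :mod:`eegage.filterbank`);
2. flatten channels x bands to one feature vector of length D = C*M per
   time frame, giving a length-T sequence;
3. a stack of unidirectional GRU layers (hidden size H);
4. attention pooling over frames: scores softmax(tanh(a_t . w_att));
5. affine head H -> 1 followed by Softplus, so the predicted age is
   strictly positive.

Everything is explicit numpy with hand-derived backpropagation; analytic
gradients are validated against central finite differences in the test
suite. The GRU follows the standard gating

    r_t = sigmoid(W_ir x_t + b_ir + W_hr h_{t-1} + b_hr)
    z_t = sigmoid(W_iz x_t + b_iz + W_hz h_{t-1} + b_hz)
    n_t = tanh(W_in x_t + b_in + r_t * (W_hn h_{t-1} + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

with gates stored row-stacked in order (r, z, n).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def softplus(x):
    """Numerically stable log(1 + e^x); strictly positive for all finite x."""
    return np.logaddexp(0.0, x)


def attention_pool(frames: np.ndarray, w_att: np.ndarray):
    """Attention pooling of frame encodings.

    Parameters
    ----------
    frames
        (H, T) single sample or (N, T, H) batch of frame encodings.
    w_att
        (H,) trainable score vector.

    Returns
    -------
    pooled
        (H,) or (N, H): sum_t score_t * frame_t.
    scores
        (T,) or (N, T) softmax weights, non-negative, summing to 1 per sample.
    """
    if frames.ndim == 2:  # (H, T) convenience layout
        pooled, scores = attention_pool(frames.T[None], w_att)
        return pooled[0], scores[0]
    s = np.tanh(frames @ w_att)  # (N, T)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    scores = e / e.sum(axis=1, keepdims=True)
    pooled = np.einsum("nt,nth->nh", scores, frames)
    return pooled, scores


class GRULayer:
    """One unidirectional GRU layer with explicit forward/backward."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden_size)
        def u(*shape):
            return rng.uniform(-k, k, size=shape)
        self.W_ih = u(3 * hidden_size, input_size)
        self.W_hh = u(3 * hidden_size, hidden_size)
        self.b_ih = u(3 * hidden_size)
        self.b_hh = u(3 * hidden_size)
        self.hidden_size = hidden_size
        self.input_size = input_size

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {
            f"{prefix}.W_ih": self.W_ih,
            f"{prefix}.W_hh": self.W_hh,
            f"{prefix}.b_ih": self.b_ih,
            f"{prefix}.b_hh": self.b_hh,
        }

    def forward(self, x: np.ndarray, want_cache: bool):
        """x: (N, T, D) -> outputs (N, T, H), optional cache for backward."""
        n_batch, n_steps, _ = x.shape
        hid = self.hidden_size
        h = np.zeros((n_batch, hid))
        outs = np.empty((n_batch, n_steps, hid))
        cache = [] if want_cache else None
        gi_all = x @ self.W_ih.T + self.b_ih  # hoisted input projections
        for t in range(n_steps):
            gh = h @ self.W_hh.T + self.b_hh
            gi = gi_all[:, t]
            r = expit(gi[:, :hid] + gh[:, :hid])
            z = expit(gi[:, hid:2 * hid] + gh[:, hid:2 * hid])
            gh_n = gh[:, 2 * hid:]
            n = np.tanh(gi[:, 2 * hid:] + r * gh_n)
            h_new = (1.0 - z) * n + z * h
            if want_cache:
                cache.append((h, r, z, n, gh_n))
            h = h_new
            outs[:, t] = h
        return outs, cache

    def backward(self, x: np.ndarray, d_out: np.ndarray, cache):
        """Backprop through time; returns (dx, grads dict keyed like params)."""
        hid = self.hidden_size
        n_batch, n_steps, _ = x.shape
        dW_ih = np.zeros_like(self.W_ih)
        dW_hh = np.zeros_like(self.W_hh)
        db_ih = np.zeros_like(self.b_ih)
        db_hh = np.zeros_like(self.b_hh)
        dx = np.empty_like(x)
        dh = np.zeros((n_batch, hid))
        for t in range(n_steps - 1, -1, -1):
            h_prev, r, z, n, gh_n = cache[t]
            dh = dh + d_out[:, t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * gh_n
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            g_i = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            g_h = np.concatenate([dr_pre, dz_pre, dn_pre * r], axis=1)
            dW_ih += g_i.T @ x[:, t]
            dW_hh += g_h.T @ h_prev
            db_ih += g_i.sum(axis=0)
            db_hh += g_h.sum(axis=0)
            dx[:, t] = g_i @ self.W_ih
            dh = dh_prev + g_h @ self.W_hh
        return dx, {"W_ih": dW_ih, "W_hh": dW_hh, "b_ih": db_ih, "b_hh": db_hh}


class AgeNet:
    """Filterbank + GRU stack + attention + softplus head, with gradients."""

    def __init__(
        self,
        n_channels: int,
        fb_mask: np.ndarray,
        hidden_size: int = 64,
        n_gru_layers: int = 2,
        rng: np.random.Generator | None = None,
        fb_init_scale: float = 1.0,
    ):
        rng = rng or np.random.default_rng(0)
        self.n_channels = n_channels
        self.fb_mask = np.asarray(fb_mask, dtype=np.float64)
        self.n_bins, self.n_filters = self.fb_mask.shape
        self.hidden_size = hidden_size
        self.fb_W = rng.normal(0.0, fb_init_scale, size=self.fb_mask.shape)
        d_in = n_channels * self.n_filters
        self.gru_layers = []
        for layer in range(n_gru_layers):
            self.gru_layers.append(GRULayer(d_in if layer == 0 else hidden_size, hidden_size, rng))
        k = 1.0 / np.sqrt(hidden_size)
        self.w_att = rng.uniform(-k, k, size=hidden_size)
        self.head_w = rng.uniform(-k, k, size=hidden_size)
        self.head_b = np.zeros(1)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        p = {"fb_W": self.fb_W, "w_att": self.w_att, "head_w": self.head_w, "head_b": self.head_b}
        for i, layer in enumerate(self.gru_layers):
            p.update(layer.params(f"gru{i}"))
        return p

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        for name, value in params.items():
            own[name][...] = value

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    # -- forward ------------------------------------------------------------
    def effective_filters(self) -> np.ndarray:
        return expit(self.fb_W) * self.fb_mask

    def forward(self, graphs: np.ndarray, want_cache: bool = False):
        """graphs: (N, C, F, T) -> predicted ages (N,). Optionally keep caches."""
        n_batch, n_chan, n_bins, n_steps = graphs.shape
        if n_chan != self.n_channels or n_bins != self.n_bins:
            raise ValueError(
                f"input (C={n_chan}, F={n_bins}) does not match model "
                f"(C={self.n_channels}, F={self.n_bins})"
            )
        wf = self.effective_filters()
        x = np.einsum("fm,ncft->ncmt", wf, graphs)
        seq = np.ascontiguousarray(x.transpose(0, 3, 1, 2)).reshape(
            n_batch, n_steps, n_chan * self.n_filters
        )
        layer_inputs = [seq]
        gru_caches = []
        out = seq
        for layer in self.gru_layers:
            out, cache = layer.forward(out, want_cache)
            gru_caches.append(cache)
            layer_inputs.append(out)
        pooled, scores = attention_pool(out, self.w_att)
        pre = pooled @ self.head_w + self.head_b[0]
        y = softplus(pre)
        if not want_cache:
            return y
        cache = {
            "graphs": graphs,
            "layer_inputs": layer_inputs,
            "gru_caches": gru_caches,
            "frames": out,
            "pooled": pooled,
            "scores": scores,
            "pre": pre,
        }
        return y, cache

    # -- backward -----------------------------------------------------------
    def backward(self, dy: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. every parameter, given dL/dy (N,)."""
        frames = cache["frames"]          # (N, T, H)
        scores = cache["scores"]          # (N, T)
        pooled = cache["pooled"]          # (N, H)
        d_pre = dy * expit(cache["pre"])  # softplus'(x) = sigmoid(x)
        grads: dict[str, np.ndarray] = {}
        grads["head_w"] = pooled.T @ d_pre
        grads["head_b"] = np.array([d_pre.sum()])
        d_pooled = d_pre[:, None] * self.head_w[None, :]
        # attention backward
        d_scores = np.einsum("nth,nh->nt", frames, d_pooled)
        d_frames = scores[:, :, None] * d_pooled[:, None, :]
        s_pre = np.tanh(frames @ self.w_att)
        ds = scores * (d_scores - (scores * d_scores).sum(axis=1, keepdims=True))
        ds_pre = ds * (1.0 - s_pre * s_pre)
        grads["w_att"] = np.einsum("nt,nth->h", ds_pre, frames)
        d_frames += ds_pre[:, :, None] * self.w_att[None, None, :]
        # GRU stack backward
        d_out = d_frames
        for i in range(len(self.gru_layers) - 1, -1, -1):
            layer = self.gru_layers[i]
            d_out, layer_grads = layer.backward(
                cache["layer_inputs"][i], d_out, cache["gru_caches"][i]
            )
            for name, g in layer_grads.items():
                grads[f"gru{i}.{name}"] = g
        # filterbank backward: d_out is now dL/d(seq) of shape (N, T, C*M)
        graphs = cache["graphs"]
        n_batch, n_steps = d_out.shape[:2]
        dx = d_out.reshape(n_batch, n_steps, self.n_channels, self.n_filters).transpose(
            0, 2, 3, 1
        )
        d_wf = np.einsum("ncft,ncmt->fm", graphs, dx)
        sig = expit(self.fb_W)
        grads["fb_W"] = d_wf * self.fb_mask * sig * (1.0 - sig)
        return grads

    def loss_and_grads(self, graphs: np.ndarray, ages: np.ndarray, loss: str = "mae"):
        """Mean loss over the batch and its parameter gradients."""
        y, cache = self.forward(graphs, want_cache=True)
        resid = y - ages
        n = ages.size
        if loss == "mae":
            value = float(np.abs(resid).mean())
            dy = np.sign(resid) / n
        elif loss == "mse":
            value = float((resid**2).mean())
            dy = 2.0 * resid / n
        else:
            raise ValueError(f"unknown loss {loss!r}")
        return value, y, self.backward(dy, cache)

    def predict(self, graphs: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Forward pass in batches (no caches)."""
        outs = [
            self.forward(graphs[i:i + batch_size])
            for i in range(0, graphs.shape[0], batch_size)
        ]
        return np.concatenate(outs) if outs else np.empty(0)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, p in self.params.items():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
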