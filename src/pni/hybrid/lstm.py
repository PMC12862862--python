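"""Minimal stacked (bi)LSTM regressor in numpy.

Implements exactly what the temporal branch needs: a per-timestep embedding,
a stack of LSTM layers (optionally bidirectional), inverted dropout, a
linear head on the final hidden state, mean-squared-error loss, Adam, and
early stopping on validation loss.  Gradients are hand-derived
backpropagation-through-time and are verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

from ..config import TemporalBranchConfig


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMCellLayer:
    """One unidirectional LSTM layer over full sequences."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator, prefix: str):
        s_in = 1.0 / np.sqrt(d_in)
        s_h = 1.0 / np.sqrt(d_h)
        self.d_in, self.d_h, self.prefix = d_in, d_h, prefix
        self.params = {
            f"{prefix}.Wx": rng.uniform(-s_in, s_in, (d_in, 4 * d_h)),
            f"{prefix}.Wh": rng.uniform(-s_h, s_h, (d_h, 4 * d_h)),
            f"{prefix}.b": np.zeros(4 * d_h),
        }
        # forget-gate bias starts at 1 (standard trick for gradient flow)
        self.params[f"{prefix}.b"][d_h:2 * d_h] = 1.0

    def forward(self, x: np.ndarray, params: dict) -> np.ndarray:
        B, T, _ = x.shape
        H = self.d_h
        Wx, Wh, b = (params[f"{self.prefix}.Wx"], params[f"{self.prefix}.Wh"],
                     params[f"{self.prefix}.b"])
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._gates = np.empty((T, B, 4 * H))
        self._c = np.empty((T, B, H))
        self._h = np.empty((T, B, H))
        pre = x @ Wx + b
        for t in range(T):
            a = pre[:, t] + h @ Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            self._gates[t] = np.concatenate([i, f, g, o], axis=1)
            self._c[t] = c
            self._h[t] = h
        return np.transpose(self._h, (1, 0, 2))

    def backward(self, dh_out: np.ndarray, params: dict, grads: dict) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        H = self.d_h
        Wx, Wh = params[f"{self.prefix}.Wx"], params[f"{self.prefix}.Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = (self._gates[t][:, :H], self._gates[t][:, H:2 * H],
                          self._gates[t][:, 2 * H:3 * H], self._gates[t][:, 3 * H:])
            c = self._c[t]
            tc = np.tanh(c)
            c_prev = self._c[t - 1] if t > 0 else np.zeros((B, H))
            h_prev = self._h[t - 1] if t > 0 else np.zeros((B, H))
            dh = dh_out[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(0)
            dx[:, t] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
        grads[f"{self.prefix}.Wx"] = grads.get(f"{self.prefix}.Wx", 0) + dWx
        grads[f"{self.prefix}.Wh"] = grads.get(f"{self.prefix}.Wh", 0) + dWh
        grads[f"{self.prefix}.b"] = grads.get(f"{self.prefix}.b", 0) + db
        return dx


class BiLSTMLayer:
    """Two opposite-direction LSTM halves, outputs concatenated."""

    def __init__(self, d_in: int, d_total: int, rng, prefix: str):
        self.fwd = LSTMCellLayer(d_in, d_total // 2, rng, f"{prefix}.f")
        self.bwd = LSTMCellLayer(d_in, d_total // 2, rng, f"{prefix}.b")
        self.params = {**self.fwd.params, **self.bwd.params}
        self.d_h = d_total

    def forward(self, x, params):
        hf = self.fwd.forward(x, params)
        hb = self.bwd.forward(x[:, ::-1], params)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dh_out, params, grads):
        H = self.d_h // 2
        dxf = self.fwd.backward(dh_out[:, :, :H], params, grads)
        dxb = self.bwd.backward(dh_out[:, ::-1, H:], params, grads)[:, ::-1]
        return dxf + dxb


class TemporalNet:
    """Embedding -> stacked (bi)LSTM -> linear head on the last hidden state."""

    def __init__(self, d_in: int, n_out: int, config: TemporalBranchConfig):
        config.validate()
        self.config = config
        self.n_out = n_out
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        e = config.embed_dim
        s = 1.0 / np.sqrt(d_in)
        self.params["embed.W"] = rng.uniform(-s, s, (d_in, e))
        self.params["embed.b"] = np.zeros(e)
        self.layers = []
        d = e
        for k, (size, bi) in enumerate(zip(config.layer_sizes, config.bidirectional)):
            layer = (BiLSTMLayer if bi else LSTMCellLayer)(d, size, rng, f"lstm{k}")
            self.layers.append(layer)
            self.params.update(layer.params)
            d = size
        s = 1.0 / np.sqrt(d)
        self.params["head.W"] = rng.uniform(-s, s, (d, n_out))
        self.params["head.b"] = np.zeros(n_out)
        self.hidden_dim = d
        self._rng = np.random.default_rng(config.seed + 1)

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        p = self.params
        h = x @ p["embed.W"] + p["embed.b"]
        self._drop_masks = []
        keep = 1.0 - self.config.dropout
        for idx, layer in enumerate(self.layers):
            if train and self.config.dropout > 0:
                mask = (self._rng.random(h.shape) < keep) / keep
                self._drop_masks.append(mask)
                h = h * mask
            else:
                self._drop_masks.append(None)
            h = layer.forward(h, p)
        self._h_last = h[:, -1, :]
        self._embed_in = x
        return self._h_last @ p["head.W"] + p["head.b"]

    def backward(self, dy: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        grads["head.W"] = self._h_last.T @ dy
        grads["head.b"] = dy.sum(0)
        dh_last = dy @ p["head.W"].T
        B, T = self._embed_in.shape[:2]
        dh = None
        for layer, mask in zip(reversed(self.layers), reversed(self._drop_masks)):
            if dh is None:
                dh = np.zeros((B, T, layer.d_h))
                dh[:, -1, :] = dh_last
            dh = layer.backward(dh, p, grads)
            if mask is not None:
                dh = dh * mask
        grads["embed.W"] = np.einsum("btd,bte->de", self._embed_in, dh)
        grads["embed.b"] = dh.sum((0, 1))
        return grads

    # -- training -------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, X_val=None, y_val=None,
            verbose: bool = False) -> dict:
        cfg = self.config
        y = np.atleast_2d(y.T).T if y.ndim == 1 else y
        if y_val is not None and y_val.ndim == 1:
            y_val = y_val[:, None]
        # standardise targets internally so training is scale-free; predict()
        # maps back to the original outcome scale
        self._y_mean = y.mean(0)
        self._y_sd = np.where(y.std(0) > 0, y.std(0), 1.0)
        y = (y - self._y_mean) / self._y_sd
        if y_val is not None:
            y_val = (y_val - self._y_mean) / self._y_sd
        n = len(X)
        rng = np.random.default_rng(cfg.seed + 2)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        b1, b2 = cfg.adam_betas
        eps = 1e-8
        step = 0
        best_loss, best_params, best_epoch = np.inf, None, 0
        history = {"train": [], "val": []}
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                yhat = self.forward(X[idx], train=True)
                err = yhat - y[idx]
                loss = float((err ** 2).mean())
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf loss at epoch {epoch}, step {step}; "
                        f"lr={cfg.learning_rate}, batch={len(idx)}")
                ep_loss += loss * len(idx)
                grads = self.backward(2.0 * err / err.size)
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
                for k, g in grads.items():
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g ** 2
                    self.params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
            history["train"].append(ep_loss / n)
            if X_val is not None:
                val_loss = float(((self._predict_scaled(X_val) - y_val) ** 2).mean())
            else:
                val_loss = history["train"][-1]
            history["val"].append(val_loss)
            if val_loss < best_loss - 1e-9:
                best_loss, best_epoch = val_loss, epoch
                best_params = {k: p.copy() for k, p in self.params.items()}
            elif epoch - best_epoch >= cfg.early_stop_patience:
                break
            if verbose:
                print(f"epoch {epoch}: train {history['train'][-1]:.5f} val {val_loss:.5f}")
        if best_params is not None:
            self.params = best_params
        history["best_epoch"] = best_epoch
        history["stopped_epoch"] = epoch
        return history

    def _predict_scaled(self, X: np.ndarray) -> np.ndarray:
        return np.concatenate([self.forward(X[i:i + 256]) for i in range(0, len(X), 256)])

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = self._predict_scaled(X)
        if hasattr(self, "_y_mean"):
            out = out * self._y_sd + self._y_mean
        return out

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Final-layer last-timestep hidden representation."""
        outs = []
        for i in range(0, len(X), 256):
            self.forward(X[i:i + 256])
            outs.append(self._h_last.copy())
        return np.concatenate(outs)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))
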