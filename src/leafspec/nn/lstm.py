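"""A multi-layer (optionally bidirectional) LSTM encoder with backprop.

Inputs are ``(batch, length, features)``; the encoder returns the final
hidden states of the last layer, concatenated across directions —
``(batch, hidden)`` or ``(batch, 2 * hidden)`` — which is the summary the
regression head consumes.  Gate order is (input, forget, cell, output).
"""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["LSTMEncoder"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _LSTMCellStack:
    """Parameters and forward/backward for one layer in one direction."""

    def __init__(self, input_size: int, hidden_size: int, rng, dtype) -> None:
        H = hidden_size
        scale = 1.0 / np.sqrt(H)
        self.params = {
            "Wx": (rng.uniform(-scale, scale, (input_size, 4 * H))).astype(dtype),
            "Wh": (rng.uniform(-scale, scale, (H, 4 * H))).astype(dtype),
            "b": np.zeros(4 * H, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.H = H

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x, training):
        """x: (N, L, D) -> outputs (N, L, H)."""
        N, L, _ = x.shape
        H = self.H
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((N, H), dtype=x.dtype)
        c = np.zeros((N, H), dtype=x.dtype)
        ys = np.empty((N, L, H), dtype=x.dtype)
        cache = [] if training else None
        for t in range(L):
            z = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if training:
                cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            ys[:, t] = h
        self._cache = cache
        return ys

    def backward(self, dys, dh_last=None):
        """dys: (N, L, H) gradient on every output; returns dx (N, L, D)."""
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        H = self.H
        N, L, _ = dys.shape
        dx = np.empty((N, L, Wx.shape[0]), dtype=dys.dtype)
        dh = np.zeros((N, H), dtype=dys.dtype) if dh_last is None else dh_last.copy()
        dc = np.zeros((N, H), dtype=dys.dtype)
        for t in range(L - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dh + dys[:, t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.grads["Wx"] += xt.T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
        return dx


class LSTMEncoder(Layer):
    """Stacked (bi-)directional LSTM returning the final hidden state(s)."""

    def __init__(self, input_size: int, hidden_size: int = 100, num_layers: int = 2,
                 bidirectional: bool = True, rng=None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.cells: list[list[_LSTMCellStack]] = []
        d_in = input_size
        n_dir = 2 if bidirectional else 1
        for _ in range(num_layers):
            self.cells.append(
                [_LSTMCellStack(d_in, hidden_size, rng, dtype) for _ in range(n_dir)]
            )
            d_in = hidden_size * n_dir

    @property
    def output_size(self) -> int:
        return self.hidden_size * (2 if self.bidirectional else 1)

    def forward(self, x, training=False, rng=None):
        """x: (N, L, D) -> (N, output_size) final hidden summary."""
        self._L = x.shape[1]
        for cells in self.cells:
            outs = [cells[0].forward(x, training)]
            if self.bidirectional:
                # Reverse time for the backward direction, then restore order.
                outs.append(cells[1].forward(x[:, ::-1], training)[:, ::-1])
            x = np.concatenate(outs, axis=2)
        # Final state: last timestep of the forward pass, first timestep of
        # the (time-restored) backward pass.
        H = self.hidden_size
        if self.bidirectional:
            return np.concatenate([x[:, -1, :H], x[:, 0, H:]], axis=1)
        return x[:, -1]

    def backward(self, dy):
        N = dy.shape[0]
        H, L = self.hidden_size, self._L
        n_dir = 2 if self.bidirectional else 1
        # Seed the top layer's output gradient from the final-state summary.
        dtop = np.zeros((N, L, H * n_dir), dtype=dy.dtype)
        dtop[:, -1, :H] = dy[:, :H]
        if self.bidirectional:
            dtop[:, 0, H:] = dy[:, H:]
        dcur = dtop
        for cells in reversed(self.cells):
            dfwd = cells[0].backward(np.ascontiguousarray(dcur[..., :H]))
            if self.bidirectional:
                dbwd = cells[1].backward(np.ascontiguousarray(dcur[:, ::-1, H:]))[:, ::-1]
                dcur = dfwd + dbwd
            else:
                dcur = dfwd
        return dcur

    def zero_grad(self):
        for cells in self.cells:
            for cell in cells:
                cell.zero_grad()

    def named_params(self):
        for li, cells in enumerate(self.cells):
            for di, cell in enumerate(cells):
                for k in cell.params:
                    yield f"l{li}d{di}.{k}", cell.params, cell.grads, k

    def state_dict(self):
        return {
            f"l{li}d{di}": {k: v.copy() for k, v in cell.params.items()}
            for li, cells in enumerate(self.cells)
            for di, cell in enumerate(cells)
        }

    def load_state_dict(self, state):
        for li, cells in enumerate(self.cells):
            for di, cell in enumerate(cells):
                for k in cell.params:
                    cell.params[k][...] = state[f"l{li}d{di}"][k]
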