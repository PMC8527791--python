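"""Brute-force oracle for the dilated 1-D convolution, shared across tests."""

import numpy as np


def brute_force_conv(x, W, B, dilation, activation="identity"):
    """Direct per-position summation with 'same' zero padding, stride 1."""
    C_out, C_in, k = W.shape
    L = x.shape[1]
    pad = dilation * (k - 1) // 2
    y = np.zeros((C_out, L))
    for co in range(C_out):
        for pos in range(L):
            acc = B[co]
            for ci in range(C_in):
                for j in range(k):
                    src = pos + dilation * j - pad
                    if 0 <= src < L:
                        acc += W[co, ci, j] * x[ci, src]
            y[co, pos] = acc
    if activation == "relu":
        y = np.maximum(y, 0)
    return y
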