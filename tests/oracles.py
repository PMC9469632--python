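"""Independent scalar (loop-based) reference implementations.

These deliberately avoid numpy vectorisation and the package's own forward
code: every gate equation is evaluated element by element, so agreement with
the vectorised path is a genuine cross-check.
"""

import math


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def scalar_gru_step(x, h_prev, cell):
    """One GRU step computed with explicit Python loops."""
    H, D = cell.W_r.shape
    r = [_sigmoid(sum(cell.W_r[i][j] * x[j] for j in range(D))
                  + sum(cell.U_r[i][j] * h_prev[j] for j in range(H))
                  + cell.b_r[i]) for i in range(H)]
    z = [_sigmoid(sum(cell.W_z[i][j] * x[j] for j in range(D))
                  + sum(cell.U_z[i][j] * h_prev[j] for j in range(H))
                  + cell.b_z[i]) for i in range(H)]
    hc = [math.tanh(sum(cell.W[i][j] * x[j] for j in range(D))
                    + sum(cell.U[i][j] * r[j] * h_prev[j] for j in range(H))
                    + cell.b_h[i]) for i in range(H)]
    return [z[i] * h_prev[i] + (1.0 - z[i]) * hc[i] for i in range(H)]


def scalar_bigru(vectors, forward_cell, backward_cell):
    """Final forward and backward hidden states, concatenated, via loops."""
    H = forward_cell.W_r.shape[0]
    hf = [0.0] * H
    for x in vectors:
        hf = scalar_gru_step(list(x), hf, forward_cell)
    hb = [0.0] * H
    for x in reversed(list(vectors)):
        hb = scalar_gru_step(list(x), hb, backward_cell)
    return hf + hb
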