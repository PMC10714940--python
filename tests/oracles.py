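"""Independent scalar-loop reference implementations used by the tests.

Everything here is written with explicit Python loops over scalars and the
closed-form gate/attention/softmax formulas, deliberately sharing no code
with the package's vectorized implementations.
"""

import math

import numpy as np


def bilinear_ref(fm, py, px):
    """Scalar bilinear interpolation with zero padding."""
    H, W = fm.shape
    y0, x0 = math.floor(py), math.floor(px)
    fy, fx = py - y0, px - x0
    total = 0.0
    for dy, dx, cf in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                       (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy, xx = y0 + dy, x0 + dx
        if 0 <= yy < H and 0 <= xx < W:
            total += cf * fm[yy, xx]
    return total


def deform_conv_ref(x, w, b, offsets, stride=1, padding=0):
    """Brute-force deformable convolution: loop over every output location,
    tap and channel, sampling x at a_0 + a_i + Δa_i bilinearly."""
    C, H, W = x.shape
    O, _, kh, kw = w.shape
    OH = (H + 2 * padding - kh) // stride + 1
    OW = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((O, OH, OW))
    for o in range(O):
        for i in range(OH):
            for j in range(OW):
                acc = 0.0 if b is None else float(b[o])
                for t in range(kh * kw):
                    u, v = divmod(t, kw)
                    py = i * stride - padding + u + offsets[2 * t, i, j]
                    px = j * stride - padding + v + offsets[2 * t + 1, i, j]
                    for c in range(C):
                        acc += w[o, c, u, v] * bilinear_ref(x[c], py, px)
                out[o, i, j] = acc
    return out


def _sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


def lstm_step_ref(x, h, c, p):
    """One LSTM cell update, elementwise.  p maps gate names to
    (W_x (in,hid), W_h (hid,hid), b (hid,)) arrays."""
    hid = h.size

    def gate(Wx, Wh, b, j):
        return sum(Wx[k, j] * x[k] for k in range(x.size)) + \
            sum(Wh[k, j] * h[k] for k in range(hid)) + b[j]

    h_new, c_new = np.zeros(hid), np.zeros(hid)
    for j in range(hid):
        i_j = _sigmoid(gate(*p["i"], j))
        f_j = _sigmoid(gate(*p["f"], j))
        g_j = math.tanh(gate(*p["c"], j))
        o_j = _sigmoid(gate(*p["o"], j))
        c_new[j] = f_j * c[j] + i_j * g_j
        h_new[j] = o_j * math.tanh(c_new[j])
    return h_new, c_new


def run_lstm_ref(xs, p, hid):
    h, c = np.zeros(hid), np.zeros(hid)
    out = []
    for x in xs:
        h, c = lstm_step_ref(x, h, c, p)
        out.append(h.copy())
    return out


def bilstm_ref(xs, p1, p2, hid):
    """Layer 1 forward over xs, layer 2 over layer-1 states reversed,
    columns re-ordered to original time order; returns (hid, T)."""
    h1 = run_lstm_ref(xs, p1, hid)
    h2 = run_lstm_ref(h1[::-1], p2, hid)[::-1]
    return np.stack(h2, axis=1)


def softmax_ref(z):
    e = [math.exp(v) for v in z]
    s = sum(e)
    return np.array([v / s for v in e])


def attention_ref(H, w):
    """M = tanh(H); alpha = softmax(w^T M); R = H alpha^T — scalar loops."""
    D, T = H.shape
    M = np.vectorize(math.tanh)(H)
    z = [sum(w[d] * M[d, t] for d in range(D)) for t in range(T)]
    alpha = softmax_ref(z)
    R = np.array([sum(alpha[t] * H[d, t] for t in range(T)) for d in range(D)])
    return R, alpha


def classify_ref(r, w1, b1, w2, b2):
    """affine -> rectifier -> affine -> softmax, scalar loops."""
    h = [max(0.0, sum(r[i] * w1[i, j] for i in range(len(r))) + b1[j])
         for j in range(len(b1))]
    z = [sum(h[j] * w2[j, k] for j in range(len(h))) + b2[k]
         for k in range(len(b2))]
    return softmax_ref(z)


def lstm_params_to_ref(p):
    """Convert a model_core.LSTMParams to the oracle's dict form."""
    return {"i": (p.W_ix.data, p.W_ih.data, p.b_i.data),
            "f": (p.W_fx.data, p.W_fh.data, p.b_f.data),
            "c": (p.W_cx.data, p.W_ch.data, p.b_c.data),
            "o": (p.W_ox.data, p.W_oh.data, p.b_o.data)}
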