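"""Independent brute-force oracles used by the test suite.

Everything here is written as plain scalar loops, deliberately sharing no
code with the vectorized implementation it checks.
"""

import math

import numpy as np


def loop_softmax_row(row):
    m = max(row)
    e = [math.exp(v - m) for v in row]
    s = sum(e)
    return [v / s for v in e]


def loop_spatial_attention(M, w_q, b_q, w_k, b_k, lam):
    """Scalar-loop channel attention: returns (s3, s4, S)."""
    H, W = M.shape
    F = len(w_q)
    # query/key features per channel: concatenation over maps f of w*M[i]+b
    def feat(i, w, b):
        out = []
        for f in range(F):
            for t in range(W):
                out.append(w[f] * M[i, t] + b[f])
        return out

    scores = [[0.0] * H for _ in range(H)]
    for i in range(H):
        qi = feat(i, w_q, b_q)
        for j in range(H):
            kj = feat(j, w_k, b_k)
            scores[i][j] = sum(a * b for a, b in zip(qi, kj))
    s3 = np.array([loop_softmax_row(r) for r in scores])
    s4 = np.zeros_like(M)
    for i in range(H):
        for t in range(W):
            s4[i, t] = sum(s3[i, j] * M[j, t] for j in range(H))
    S = lam * s4 + M
    return s3, s4, S


def loop_temporal_attention(M, w_q, b_q, w_k, b_k, lam):
    """Scalar-loop time-step attention: returns (t3, t4, T)."""
    H, W = M.shape
    F = len(w_q)

    def feat(p, w, b):
        out = []
        for f in range(F):
            for c in range(H):
                out.append(w[f] * M[c, p] + b[f])
        return out

    scores = [[0.0] * W for _ in range(W)]
    for p in range(W):
        qp = feat(p, w_q, b_q)
        for q in range(W):
            kq = feat(q, w_k, b_k)
            scores[p][q] = sum(a * b for a, b in zip(qp, kq))
    t3 = np.array([loop_softmax_row(r) for r in scores])
    t4 = np.zeros_like(M)
    for c in range(H):
        for p in range(W):
            t4[c, p] = sum(t3[p, q] * M[c, q] for q in range(W))
    T = lam * t4 + M
    return t3, t4, T


def loop_ems(x, decay, eps_var):
    """Sample-by-sample exponential moving standardization of a 1-D sequence."""
    out = []
    m = x[0]
    v = 0.0
    for t in range(len(x)):
        m = decay * m + (1 - decay) * x[t]
        v = decay * v + (1 - decay) * (x[t] - m) ** 2
        out.append((x[t] - m) / max(math.sqrt(v), math.sqrt(eps_var)))
    return np.array(out)
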