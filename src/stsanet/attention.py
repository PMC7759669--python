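"""Spatial and temporal self-attention on raw EEG epochs.

Both modules share one topology.  An epoch ``M`` (H channels x W time
steps) is projected by two independent 1x1 convolutions into F = 8 feature
maps each; the maps are flattened along the non-attended axis, their dot
products give an n x n similarity matrix, and a row-wise softmax turns it
into a row-stochastic attention map.  The attended ("predicted") signal is
the attention-weighted average of M along the attended axis, and the module
output is the residual form

    out = lambda * predicted + M,

with ``lambda`` a trainable scalar initialized to 0, so each module starts
as the identity.  The spatial module attends over channels (n = H, map
s3 in R^{H x H}); the temporal module attends over time steps (n = W, map
t3 in R^{W x W}), each updated time step being a convex combination of all
input time steps.

The forward/backward pairs here are the training engine's building blocks;
the public ``spatial_attention`` / ``temporal_attention`` functions wrap
them for single epochs and return the full :class:`AttentionOutput`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import DataError

__all__ = [
    "AttentionParams",
    "AttentionMap",
    "AttentionOutput",
    "row_softmax",
    "spatial_attention",
    "temporal_attention",
]

N_FEATURE_MAPS = 8  # F: maps produced by each 1x1 projection

# Attention weights below this are exact zeros.  The cutoff is far below
# the 1e-5 row-sum tolerance; it exists because subnormal weights (and the
# subnormal products they spawn in backward) trap to microcode and slow
# the 1125 x 1125 matrix products by orders of magnitude.
WEIGHT_FLUSH = 1e-20


def _flush_subnormals(a: np.ndarray) -> np.ndarray:
    """Zero entries whose magnitude is below the dtype's normal range."""
    if a.dtype.kind == "f":
        np.copyto(a, 0.0, where=np.abs(a) < np.finfo(a.dtype).tiny)
    return a


@dataclass
class AttentionParams:
    """Parameters of one self-attention module.

    The input is a single H x W map, so each 1x1 convolution to F maps is
    a per-map scalar weight plus bias: ``proj[f] = w[f] * M + b[f]``.
    ``lam`` is the residual scalar (lambda_1 for the spatial module,
    lambda_2 for the temporal one), trainable and initialized to 0.
    """

    w_query: np.ndarray
    b_query: np.ndarray
    w_key: np.ndarray
    b_key: np.ndarray
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.w_query = np.asarray(self.w_query, dtype=float)
        self.b_query = np.asarray(self.b_query, dtype=float)
        self.w_key = np.asarray(self.w_key, dtype=float)
        self.b_key = np.asarray(self.b_key, dtype=float)
        if not (
            self.w_query.shape
            == self.b_query.shape
            == self.w_key.shape
            == self.b_key.shape
        ) or self.w_query.ndim != 1 or self.w_query.size < 1:
            raise ValueError("projection parameters must be equal-length 1-D arrays")

    @property
    def n_maps(self) -> int:
        return self.w_query.size

    @classmethod
    def init(cls, n_maps: int = N_FEATURE_MAPS, rng: np.random.Generator | None = None):
        """Xavier-uniform projection weights, zero biases, lambda = 0."""
        rng = np.random.default_rng() if rng is None else rng
        limit = np.sqrt(6.0 / (1 + n_maps))  # fan_in 1, fan_out n_maps for a 1x1 conv
        return cls(
            w_query=rng.uniform(-limit, limit, n_maps),
            b_query=np.zeros(n_maps),
            w_key=rng.uniform(-limit, limit, n_maps),
            b_key=np.zeros(n_maps),
            lam=0.0,
        )


@dataclass
class AttentionMap:
    """A square, nonnegative, row-stochastic weight map."""

    W_att: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W_att, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("attention map must be square")
        if np.any(W < 0) or np.any(W > 1):
            raise ValueError("attention weights must lie in [0, 1]")
        if not np.allclose(W.sum(axis=1), 1.0, atol=1e-5):
            raise ValueError("attention map rows must sum to 1")
        self.W_att = W

    @property
    def n(self) -> int:
        return self.W_att.shape[0]


@dataclass
class AttentionOutput:
    """Feature signal, predicted signal and the attention map behind them."""

    feature: np.ndarray    # S or T = lam * predicted + M
    predicted: np.ndarray  # s4 or t4
    map: AttentionMap


def row_softmax(scores: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax along the last axis.

    The row maximum is subtracted before exponentiation, so arbitrarily
    large score magnitudes are handled; adding a constant to a row leaves
    its output unchanged.  Subnormal exponentials are flushed to exact
    zero: they are meaningless at the map's tolerance but, left in place,
    denormal arithmetic slows the downstream matrix products by orders of
    magnitude.
    """
    s = np.asarray(scores)
    m = s.max(axis=-1, keepdims=True)
    e = np.exp(s - m)
    out = e / e.sum(axis=-1, keepdims=True)
    if out.dtype.kind == "f":
        np.copyto(out, 0.0, where=out < WEIGHT_FLUSH)
    return out


# ---------------------------------------------------------------------------
# batched forward/backward cores (leading batch axis)
# ---------------------------------------------------------------------------


def spatial_forward(Mb: np.ndarray, p: AttentionParams):
    """Batched spatial attention.  ``Mb`` is (N, H, W); returns (S, cache)."""
    N, H, W = Mb.shape
    F = p.n_maps
    w_q = p.w_query.astype(Mb.dtype)
    w_k = p.w_key.astype(Mb.dtype)
    # rows of s21 / columns of s22: per-channel concatenation over the F
    # projected maps, built directly in (n, h, f, w) layout
    s21 = (
        Mb[:, :, None, :] * w_q[:, None] + p.b_query.astype(Mb.dtype)[:, None]
    ).reshape(N, H, F * W)
    s22 = (
        Mb[:, :, None, :] * w_k[:, None] + p.b_key.astype(Mb.dtype)[:, None]
    ).reshape(N, H, F * W)
    scores = s21 @ s22.transpose(0, 2, 1)          # (N, H, H)
    s3 = row_softmax(scores)
    s4 = s3 @ Mb                                   # weighted channel mixture
    S = Mb + Mb.dtype.type(p.lam) * s4
    cache = (Mb, s21, s22, s3, s4)
    return S, cache


def spatial_backward(dS: np.ndarray, cache, p: AttentionParams):
    Mb, s21, s22, s3, s4 = cache
    N, H, W = Mb.shape
    F = p.n_maps
    lam = Mb.dtype.type(p.lam)
    dlam = float(np.sum(dS * s4))
    ds4 = lam * dS
    dM = dS.copy()
    ds3 = ds4 @ Mb.transpose(0, 2, 1)
    dM += s3.transpose(0, 2, 1) @ ds4
    dscores = _flush_subnormals(
        s3 * (ds3 - (ds3 * s3).sum(axis=-1, keepdims=True))
    )
    ds21 = (dscores @ s22).reshape(N, H, F, W)
    ds22 = (dscores.transpose(0, 2, 1) @ s21).reshape(N, H, F, W)
    dw_q = np.einsum("nhfw,nhw->f", ds21, Mb, optimize=True)
    db_q = ds21.sum(axis=(0, 1, 3))
    dw_k = np.einsum("nhfw,nhw->f", ds22, Mb, optimize=True)
    db_k = ds22.sum(axis=(0, 1, 3))
    dM += np.einsum("nhfw,f->nhw", ds21, p.w_query.astype(Mb.dtype), optimize=True)
    dM += np.einsum("nhfw,f->nhw", ds22, p.w_key.astype(Mb.dtype), optimize=True)
    grads = {
        "w_query": dw_q, "b_query": db_q,
        "w_key": dw_k, "b_key": db_k, "lam": dlam,
    }
    return dM, grads


def temporal_forward(Mb: np.ndarray, p: AttentionParams):
    """Batched temporal attention.  ``Mb`` is (N, H, W); returns (T, cache)."""
    N, H, W = Mb.shape
    F = p.n_maps
    Mt = np.ascontiguousarray(Mb.transpose(0, 2, 1))  # (N, W, H)
    # rows of t21 / columns of t22: per-time-step concatenation over the F
    # projected maps, built directly in (n, w, f, h) layout
    t21 = (
        Mt[:, :, None, :] * p.w_query.astype(Mb.dtype)[:, None]
        + p.b_query.astype(Mb.dtype)[:, None]
    ).reshape(N, W, F * H)
    t22 = (
        Mt[:, :, None, :] * p.w_key.astype(Mb.dtype)[:, None]
        + p.b_key.astype(Mb.dtype)[:, None]
    ).reshape(N, W, F * H)
    scores = t21 @ t22.transpose(0, 2, 1)          # (N, W, W)
    t3 = row_softmax(scores)
    # t4[., c, p] = sum_q t3[., p, q] * M[., c, q]: convex combination of
    # all time steps for each updated time step
    t4 = Mb @ t3.transpose(0, 2, 1)
    T = Mb + Mb.dtype.type(p.lam) * t4
    cache = (Mb, t21, t22, t3, t4)
    return T, cache


def temporal_backward(dT: np.ndarray, cache, p: AttentionParams):
    Mb, t21, t22, t3, t4 = cache
    N, H, W = Mb.shape
    F = p.n_maps
    lam = Mb.dtype.type(p.lam)
    dlam = float(np.sum(dT * t4))
    dt4 = lam * dT
    dM = dT + dt4 @ t3
    dt3 = dt4.transpose(0, 2, 1) @ Mb              # (N, W, W)
    dscores = _flush_subnormals(
        t3 * (dt3 - (dt3 * t3).sum(axis=-1, keepdims=True))
    )
    dt21 = (dscores @ t22).reshape(N, W, F, H)
    dt22 = (dscores.transpose(0, 2, 1) @ t21).reshape(N, W, F, H)
    dw_q = np.einsum("nwfh,nhw->f", dt21, Mb, optimize=True)
    db_q = dt21.sum(axis=(0, 1, 3))
    dw_k = np.einsum("nwfh,nhw->f", dt22, Mb, optimize=True)
    db_k = dt22.sum(axis=(0, 1, 3))
    dM += np.einsum("nwfh,f->nhw", dt21, p.w_query.astype(Mb.dtype), optimize=True)
    dM += np.einsum("nwfh,f->nhw", dt22, p.w_key.astype(Mb.dtype), optimize=True)
    grads = {
        "w_query": dw_q, "b_query": db_q,
        "w_key": dw_k, "b_key": db_k, "lam": dlam,
    }
    return dM, grads


# ---------------------------------------------------------------------------
# public single-epoch API
# ---------------------------------------------------------------------------


def _check_epoch(M: np.ndarray, min_rows: int, axis_name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise DataError("epoch must be a 2-D channels x samples matrix")
    if not np.all(np.isfinite(M)):
        raise DataError("epoch contains non-finite values")
    n = M.shape[0] if axis_name == "channel" else M.shape[1]
    if n == 1:
        warnings.warn(
            f"single-{axis_name} input: attention map degenerates to [[1]]",
            stacklevel=3,
        )
    return M


def spatial_attention(M: np.ndarray, params: AttentionParams) -> AttentionOutput:
    """Channel self-attention: ``S = lambda_1 * s4 + M``.

    Each channel of the predicted signal s4 is a weighted sum of all
    channels of ``M``, the weights being the row-stochastic map s3 built
    from dot-product similarities of the 1x1-projected features.
    """
    M = _check_epoch(M, 2, "channel")
    S, cache = spatial_forward(M[None], params)
    _, _, _, s3, s4 = cache
    return AttentionOutput(feature=S[0], predicted=s4[0], map=AttentionMap(s3[0]))


def temporal_attention(M: np.ndarray, params: AttentionParams) -> AttentionOutput:
    """Time-step self-attention: ``T = lambda_2 * t4 + M``."""
    M = _check_epoch(M, 2, "time-step")
    T, cache = temporal_forward(M[None], params)
    _, _, _, t3, t4 = cache
    return AttentionOutput(feature=T[0], predicted=t4[0], map=AttentionMap(t3[0]))
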