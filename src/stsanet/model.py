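"""The parallel spatial-temporal self-attention CNN.

An epoch M is fed in parallel through the spatial and temporal attention
modules; the raw signal and both attention outputs are stacked into
C1 = {M, S, T} (3 maps) and classified by a shallow-ConvNet-style head:

    Conv2 (1 x 25, 3 -> 40 maps, valid)      (3, H, W)  -> (40, H, W-24)
    Conv3 (H x 1, 40 -> 40 maps, no bias)    -> (40, 1, W-24)
    batch normalization (per map)
    square activation  x -> x^2
    average pooling 1 x 75, stride 1 x 15    -> (40, 1, Wp)
    log activation     x -> log(max(x, eps))
    dropout p
    Conv4 (1 x Wp, 40 -> n_classes)          -> (n_classes, 1, 1)
    log-softmax

The square/pool/log sequence makes the head a learned band-power
estimator, which is why it suits oscillatory (mu/beta ERD-ERS) features.

Everything is plain NumPy with hand-derived backward passes; training-time
gradients flow through both attention softmaxes and all head layers.
Gradients are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import attention as att
from .attention import AttentionParams

__all__ = [
    "ModelConfig",
    "LogProbOutput",
    "NotFittedError",
    "ConfigurationError",
    "STSANet",
    "concat_features",
    "count_parameters",
    "shape_trace",
    "nll_loss",
    "save_checkpoint",
    "load_checkpoint",
]


class NotFittedError(RuntimeError):
    """Prediction was requested before parameters were initialized/trained."""


class ConfigurationError(ValueError):
    """The layer chain cannot be built for the given geometry."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters (single source of truth).

    Defaults reproduce the published geometry for 22-channel, 1125-sample
    epochs: F = 8 attention maps, 40 head maps, 1 x 25 temporal kernel,
    all-channel spatial kernel, 1 x 75 pooling with stride 1 x 15, four
    classes.  ``bn_eps`` and ``bn_momentum`` are the batch-normalization
    constant and running-statistics momentum; ``dropout_p`` the dropout
    rate between the log activation and the classifier convolution.
    """

    n_channels: int = 22
    n_samples: int = 1125
    att_maps: int = 8
    head_maps: int = 40
    temporal_kernel: int = 25
    pool_kernel: int = 75
    pool_stride: int = 15
    n_classes: int = 4
    dropout_p: float = 0.5
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    eps_log: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")
        if self.conv2_out_width < 1:
            raise ConfigurationError(
                f"Conv2: width {self.n_samples} too small for a "
                f"1x{self.temporal_kernel} valid kernel"
            )
        if self.conv2_out_width < self.pool_kernel:
            raise ConfigurationError(
                f"AvgPooling: Conv2 output width {self.conv2_out_width} is "
                f"smaller than the 1x{self.pool_kernel} pooling kernel"
            )

    @property
    def conv2_out_width(self) -> int:
        return self.n_samples - self.temporal_kernel + 1

    @property
    def pooled_width(self) -> int:
        return (self.conv2_out_width - self.pool_kernel) // self.pool_stride + 1


@dataclass
class LogProbOutput:
    """Per-class log-probabilities for one epoch."""

    logp: np.ndarray

    def __post_init__(self) -> None:
        lp = np.asarray(self.logp, dtype=float)
        if lp.ndim != 1:
            raise ValueError("logp must be a vector")
        if np.any(lp > 1e-7):
            raise ValueError("log-probabilities must be <= 0")
        if abs(np.exp(lp).sum() - 1.0) > 1e-5:
            raise ValueError("exp(logp) must sum to 1")
        self.logp = lp


def concat_features(M: np.ndarray, S: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Stack raw and attention features as C1 = {M, S, T}, shape (3, H, W)."""
    M, S, T = (np.asarray(a) for a in (M, S, T))
    if not (M.shape == S.shape == T.shape) or M.ndim != 2:
        raise ValueError("M, S, T must be equal-shape 2-D matrices")
    return np.stack([M, S, T], axis=0)


def shape_trace(config: ModelConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Named intermediate shapes of attention modules and head.

    For the default 22 x 1125 geometry this reproduces the published
    architecture tables row by row (s21 22 x 9000, t3 1125 x 1125, C2
    (40, 22, 1101), C4 (40, 1, 69), C5 (4, 1, 1), ...).
    """
    H, W, F = config.n_channels, config.n_samples, config.att_maps
    W2, Wp = config.conv2_out_width, config.pooled_width
    return [
        ("M", (H, W)),
        ("s11", (F, H, W)),
        ("s12", (F, H, W)),
        ("s21", (H, F * W)),
        ("s22", (F * W, H)),
        ("s3", (H, H)),
        ("s4", (H, W)),
        ("S", (H, W)),
        ("t11", (F, H, W)),
        ("t12", (F, H, W)),
        ("t21", (W, F * H)),
        ("t22", (F * H, W)),
        ("t3", (W, W)),
        ("t4", (H, W)),
        ("T", (H, W)),
        ("C1", (3, H, W)),
        ("C2", (config.head_maps, H, W2)),
        ("C3", (config.head_maps, 1, W2)),
        ("C4", (config.head_maps, 1, Wp)),
        ("C5", (config.n_classes, 1, 1)),
    ]


def count_parameters(config: ModelConfig) -> tuple[int, dict[str, int]]:
    """Exact trainable-parameter count with a per-layer breakdown."""
    F = config.att_maps
    Hm = config.head_maps
    per_attention = 4 * F + 1  # two 1x1 projections (weight+bias) + lambda
    breakdown = {
        "spatial_attention": per_attention,
        "temporal_attention": per_attention,
        "conv2": Hm * (3 * config.temporal_kernel) + Hm,
        "conv3": Hm * Hm * config.n_channels,  # no bias (absorbed by BN)
        "batchnorm": 2 * Hm,
        "conv4": config.n_classes * (Hm * config.pooled_width) + config.n_classes,
    }
    return sum(breakdown.values()), breakdown


def nll_loss(logp: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. ``logp``."""
    n = logp.shape[0]
    loss = -float(np.mean(logp[np.arange(n), y]))
    dlogp = np.zeros_like(logp)
    dlogp[np.arange(n), y] = -1.0 / n
    return loss, dlogp


class STSANet:
    """Trainable network: parallel attention modules + shallow conv head.

    Parameters live in ``self.params`` (dict of named float arrays);
    batch-normalization running statistics in ``self.buffers``.  ``forward``
    returns log-probabilities and, when training, a cache consumed by
    ``backward``.
    """

    ATT_KEYS = ("w_query", "b_query", "w_key", "b_key", "lam")

    def __init__(self, config: ModelConfig, dtype=np.float32) -> None:
        self.config = config
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.fitted = False

    # -- parameters -------------------------------------------------------

    def init_parameters(self, seed: int | None = None) -> None:
        """Xavier-uniform weights, zero biases, lambda_1 = lambda_2 = 0."""
        cfg = self.config
        rng = np.random.default_rng(seed)

        def xavier(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, shape).astype(self.dtype)

        F, Hm, K = cfg.att_maps, cfg.head_maps, cfg.n_classes
        kt, H, Wp = cfg.temporal_kernel, cfg.n_channels, cfg.pooled_width
        p = {}
        for mod in ("spatial", "temporal"):
            p[f"{mod}.w_query"] = xavier((F,), 1, F)
            p[f"{mod}.b_query"] = np.zeros(F, self.dtype)
            p[f"{mod}.w_key"] = xavier((F,), 1, F)
            p[f"{mod}.b_key"] = np.zeros(F, self.dtype)
            p[f"{mod}.lam"] = np.zeros((), self.dtype)
        p["conv2.weight"] = xavier((Hm, 3, kt), 3 * kt, Hm * kt)
        p["conv2.bias"] = np.zeros(Hm, self.dtype)
        p["conv3.weight"] = xavier((Hm, Hm, H), Hm * H, Hm * H)
        p["bn.gamma"] = np.ones(Hm, self.dtype)
        p["bn.beta"] = np.zeros(Hm, self.dtype)
        p["conv4.weight"] = xavier((K, Hm, Wp), Hm * Wp, K * Wp)
        p["conv4.bias"] = np.zeros(K, self.dtype)
        self.params = p
        self.buffers = {
            "bn.running_mean": np.zeros(Hm, self.dtype),
            "bn.running_var": np.ones(Hm, self.dtype),
        }
        self.fitted = False

    def _im2col(self, C1: np.ndarray, kt: int, W2: int) -> np.ndarray:
        """Unfold time windows: (N, 3, H, W) -> (N, 3*kt, H*W2)."""
        N, C, H, _ = C1.shape
        col5 = np.empty((N, C, kt, H, W2), self.dtype)
        for k in range(kt):
            col5[:, :, k] = C1[:, :, :, k : k + W2]
        return col5.reshape(N, C * kt, H * W2)

    def _col2im(self, dcol: np.ndarray, N: int, H: int, W: int,
                kt: int, W2: int) -> np.ndarray:
        """Adjoint of :meth:`_im2col` (overlap-add)."""
        d5 = dcol.reshape(N, 3, kt, H, W2)
        dC1 = np.zeros((N, 3, H, W), self.dtype)
        for k in range(kt):
            dC1[:, :, :, k : k + W2] += d5[:, :, k]
        return dC1

    def _att_params(self, module: str) -> AttentionParams:
        p = self.params
        return AttentionParams(
            w_query=p[f"{module}.w_query"],
            b_query=p[f"{module}.b_query"],
            w_key=p[f"{module}.w_key"],
            b_key=p[f"{module}.b_key"],
            lam=float(p[f"{module}.lam"]),
        )

    def state_copy(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        state.update({k: v.copy() for k, v in self.buffers.items()})
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        for k in self.buffers:
            self.buffers[k] = state[k].copy()

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        want_cache: bool = False,
    ):
        """Log-probabilities for a batch ``X`` of shape (N, H, W).

        ``train=True`` uses batch statistics for normalization, applies
        dropout (requires ``rng``) and updates the running statistics.
        """
        if not self.params:
            raise NotFittedError("call init_parameters() or load a checkpoint first")
        cfg = self.config
        X = np.ascontiguousarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[1:] != (cfg.n_channels, cfg.n_samples):
            raise ValueError(
                f"expected batch of ({cfg.n_channels}, {cfg.n_samples}) epochs, "
                f"got {X.shape}"
            )
        N = X.shape[0]
        Hm, W2, Wp, K = cfg.head_maps, cfg.conv2_out_width, cfg.pooled_width, cfg.n_classes

        sp, tp = self._att_params("spatial"), self._att_params("temporal")
        S, cache_s = att.spatial_forward(X, sp)
        T, cache_t = att.temporal_forward(X, tp)
        C1 = np.stack([X, S, T], axis=1)  # (N, 3, H, W)

        # Conv2: 1 x kt valid convolution over time, 3 -> Hm maps,
        # realized as im2col + one batched gemm
        kt = cfg.temporal_kernel
        K2 = self.params["conv2.weight"]
        col = self._im2col(C1, kt, W2)  # (N, 3*kt, H*W2)
        C2r = np.matmul(K2.reshape(Hm, 3 * kt), col)
        C2r += self.params["conv2.bias"][:, None]
        C2 = C2r.reshape(N, Hm, cfg.n_channels, W2)

        # Conv3: full-height spatial convolution, no bias
        W3 = self.params["conv3.weight"].reshape(Hm, Hm * cfg.n_channels)
        C3 = np.matmul(W3, C2.reshape(N, Hm * cfg.n_channels, W2))  # (N, Hm, W2)

        # batch normalization per feature map
        eps = cfg.bn_eps
        if train:
            mu = C3.mean(axis=(0, 2))
            var = C3.var(axis=(0, 2))
            m = cfg.bn_momentum
            nelem = N * W2
            unbias = nelem / max(nelem - 1, 1)
            self.buffers["bn.running_mean"] = (
                (1 - m) * self.buffers["bn.running_mean"] + m * mu
            ).astype(self.dtype)
            self.buffers["bn.running_var"] = (
                (1 - m) * self.buffers["bn.running_var"] + m * var * unbias
            ).astype(self.dtype)
        else:
            mu = self.buffers["bn.running_mean"]
            var = self.buffers["bn.running_var"]
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (C3 - mu[:, None]) * inv_std[:, None]
        B = self.params["bn.gamma"][:, None] * xhat + self.params["bn.beta"][:, None]

        sq = B * B

        # average pooling 1 x pool_kernel, stride pool_stride
        pk, ps = cfg.pool_kernel, cfg.pool_stride
        idx = np.arange(Wp) * ps
        cs = np.concatenate(
            [np.zeros_like(sq[..., :1]), np.cumsum(sq, axis=-1)], axis=-1
        )
        pooled = (cs[..., idx + pk] - cs[..., idx]) / pk  # (N, Hm, Wp)

        logx = np.log(np.maximum(pooled, cfg.eps_log))

        if train:
            if cfg.dropout_p > 0:
                if rng is None:
                    raise ValueError("training forward with dropout needs an rng")
                keep = (rng.random(logx.shape) >= cfg.dropout_p).astype(self.dtype)
                dropped = logx * keep / (1.0 - cfg.dropout_p)
            else:
                keep = None
                dropped = logx
        else:
            keep = None
            dropped = logx

        # Conv4: full-extent classifier convolution
        W4 = self.params["conv4.weight"].reshape(K, Hm * Wp)
        logits = dropped.reshape(N, Hm * Wp) @ W4.T + self.params["conv4.bias"]

        # log-softmax
        mx = logits.max(axis=1, keepdims=True)
        z = logits - mx
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        logp = z - lse

        if not want_cache:
            return logp
        cache = dict(
            X=X, cache_s=cache_s, cache_t=cache_t, col=col,
            C2=C2, C3=C3, xhat=xhat, inv_std=inv_std, B=B, sq=sq,
            pooled=pooled, logx=logx, keep=keep, dropped=dropped, logp=logp,
            train=train,
        )
        return logp, cache

    # -- backward ---------------------------------------------------------

    def backward(self, dlogp: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of the scalar loss for every trainable parameter."""
        cfg = self.config
        p = self.params
        X = cache["X"]
        N = X.shape[0]
        Hm, W2, Wp, K = cfg.head_maps, cfg.conv2_out_width, cfg.pooled_width, cfg.n_classes
        H, kt = cfg.n_channels, cfg.temporal_kernel
        grads: dict[str, np.ndarray] = {}

        # log-softmax
        probs = np.exp(cache["logp"])
        dlogits = dlogp - probs * dlogp.sum(axis=1, keepdims=True)

        # Conv4
        W4 = p["conv4.weight"].reshape(K, Hm * Wp)
        dropped_r = cache["dropped"].reshape(N, Hm * Wp)
        grads["conv4.weight"] = (dlogits.T @ dropped_r).reshape(K, Hm, Wp)
        grads["conv4.bias"] = dlogits.sum(axis=0)
        ddropped = (dlogits @ W4).reshape(N, Hm, Wp)

        # dropout
        if cache["keep"] is not None:
            dlogx = ddropped * cache["keep"] / (1.0 - cfg.dropout_p)
        else:
            dlogx = ddropped

        # log activation (clamped below at eps_log)
        pooled = cache["pooled"]
        dpooled = np.where(
            pooled > cfg.eps_log, dlogx / np.maximum(pooled, cfg.eps_log), 0.0
        ).astype(self.dtype)

        # average pooling
        pk, ps = cfg.pool_kernel, cfg.pool_stride
        dsq = np.zeros_like(cache["sq"])
        for i in range(Wp):
            dsq[..., i * ps : i * ps + pk] += dpooled[..., i : i + 1] / pk

        # square
        dB = 2.0 * cache["B"] * dsq

        # batch normalization
        gamma = p["bn.gamma"]
        xhat, inv_std = cache["xhat"], cache["inv_std"]
        grads["bn.gamma"] = (dB * xhat).sum(axis=(0, 2))
        grads["bn.beta"] = dB.sum(axis=(0, 2))
        if cache["train"]:
            nelem = N * W2
            dxhat = dB * gamma[:, None]
            dC3 = (
                inv_std[:, None]
                * (
                    dxhat
                    - dxhat.mean(axis=(0, 2), keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
                )
            ).astype(self.dtype)
        else:
            dC3 = (dB * gamma[:, None] * inv_std[:, None]).astype(self.dtype)

        # Conv3
        W3 = p["conv3.weight"].reshape(Hm, Hm * H)
        C2r = cache["C2"].reshape(N, Hm * H, W2)
        grads["conv3.weight"] = (
            np.einsum("now,ncw->oc", dC3, C2r).reshape(Hm, Hm, H)
        )
        dC2 = np.matmul(W3.T, dC3).reshape(N, Hm, H, W2)

        # Conv2
        K2 = p["conv2.weight"]
        grads["conv2.bias"] = dC2.sum(axis=(0, 2, 3))
        dC2r = dC2.reshape(N, Hm, -1)
        col = cache["col"]
        grads["conv2.weight"] = np.einsum(
            "noj,ncj->oc", dC2r, col, optimize=True
        ).reshape(Hm, 3, kt)
        dcol = np.matmul(K2.reshape(Hm, 3 * kt).T, dC2r)
        dC1 = self._col2im(dcol, N, H, cfg.n_samples, kt, W2)

        # split C1 gradient into raw / spatial / temporal paths
        dX = dC1[:, 0].copy()
        dS = np.ascontiguousarray(dC1[:, 1])
        dT = np.ascontiguousarray(dC1[:, 2])
        dM_s, g_s = att.spatial_backward(dS, cache["cache_s"], self._att_params("spatial"))
        dM_t, g_t = att.temporal_backward(dT, cache["cache_t"], self._att_params("temporal"))
        dX += dM_s + dM_t
        for key, g in g_s.items():
            grads[f"spatial.{key}"] = np.asarray(g, self.dtype)
        for key, g in g_t.items():
            grads[f"temporal.{key}"] = np.asarray(g, self.dtype)
        grads["_input"] = dX
        return grads

    # -- inference --------------------------------------------------------

    def head_forward(self, C1: np.ndarray, train: bool = False,
                     rng: np.random.Generator | None = None) -> np.ndarray:
        """Run only the classification head on pre-stacked (N, 3, H, W) input.

        Used for the attention-off baseline: with both lambdas frozen at 0
        the full forward equals ``head_forward`` on {M, M, M}.
        """
        # re-use forward by temporarily treating C1 slices; simplest is to
        # run the full forward with attention disabled via lam == 0 when
        # C1 == {M, M, M}; for arbitrary C1 run the head explicitly.
        cfg = self.config
        N = C1.shape[0]
        # Explicit head pass (mirrors forward(); kept in sync by the
        # baseline-equivalence test).
        Hm, W2, Wp, K = cfg.head_maps, cfg.conv2_out_width, cfg.pooled_width, cfg.n_classes
        kt = cfg.temporal_kernel
        C1 = np.ascontiguousarray(C1, dtype=self.dtype)
        K2 = self.params["conv2.weight"]
        col = self._im2col(C1, kt, W2)
        C2r = np.matmul(K2.reshape(Hm, 3 * kt), col)
        C2r += self.params["conv2.bias"][:, None]
        C2 = C2r.reshape(N, Hm, cfg.n_channels, W2)
        W3 = self.params["conv3.weight"].reshape(Hm, Hm * cfg.n_channels)
        C3 = np.matmul(W3, C2.reshape(N, Hm * cfg.n_channels, W2))
        if train:
            mu = C3.mean(axis=(0, 2))
            var = C3.var(axis=(0, 2))
        else:
            mu = self.buffers["bn.running_mean"]
            var = self.buffers["bn.running_var"]
        inv_std = 1.0 / np.sqrt(var + cfg.bn_eps)
        xhat = (C3 - mu[:, None]) * inv_std[:, None]
        B = self.params["bn.gamma"][:, None] * xhat + self.params["bn.beta"][:, None]
        sq = B * B
        pk, ps = cfg.pool_kernel, cfg.pool_stride
        idx = np.arange(Wp) * ps
        cs = np.concatenate(
            [np.zeros_like(sq[..., :1]), np.cumsum(sq, axis=-1)], axis=-1
        )
        pooled = (cs[..., idx + pk] - cs[..., idx]) / pk
        logx = np.log(np.maximum(pooled, cfg.eps_log))
        if train and cfg.dropout_p > 0:
            if rng is None:
                raise ValueError("training head pass with dropout needs an rng")
            keep = (rng.random(logx.shape) >= cfg.dropout_p).astype(self.dtype)
            logx = logx * keep / (1.0 - cfg.dropout_p)
        W4 = self.params["conv4.weight"].reshape(K, Hm * Wp)
        logits = logx.reshape(N, Hm * Wp) @ W4.T + self.params["conv4.bias"]
        mx = logits.max(axis=1, keepdims=True)
        z = logits - mx
        return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

    def predict_logp(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Evaluation-mode log-probabilities (dropout off, running BN stats)."""
        if not self.params:
            raise NotFittedError("model has no parameters; fit or load first")
        out = []
        for i in range(0, X.shape[0], batch_size):
            out.append(self.forward(X[i : i + batch_size], train=False))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Argmax class labels; ties resolve to the lowest class index."""
        if not self.fitted:
            raise NotFittedError("model is not trained; call fit or load a checkpoint")
        return np.argmax(self.predict_logp(X, batch_size), axis=1)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: STSANet, history: dict | None = None) -> None:
    """Write config + parameters + BN statistics (+ history) to one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(model.config))
        f.attrs["fitted"] = bool(model.fitted)
        gp = f.create_group("params")
        for k, v in model.params.items():
            gp.create_dataset(k, data=v)
        gb = f.create_group("buffers")
        for k, v in model.buffers.items():
            gb.create_dataset(k, data=v)
        if history is not None:
            f.attrs["history"] = json.dumps(history)


def load_checkpoint(path) -> tuple[STSANet, dict | None]:
    import h5py

    with h5py.File(path, "r") as f:
        config = ModelConfig(**json.loads(f.attrs["config"]))
        model = STSANet(config)
        model.params = {k: f["params"][k][()] for k in f["params"]}
        model.buffers = {k: f["buffers"][k][()] for k in f["buffers"]}
        model.fitted = bool(f.attrs["fitted"])
        history = json.loads(f.attrs["history"]) if "history" in f.attrs else None
    return model, history
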