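"""CNN feature extractor + softmax classifier for windowed sensor segments.

Architecture (time axis only is convolved; channels ride along untouched,
treating the [T x C] window as a single-channel image):

    conv(L x 1, K kernels) -> maxpool(P x 1) ->
    conv(L x 1, K kernels) -> maxpool(P x 1) ->
    FC(fc_units) + ReLU   <- feature tap ->
    FC(n_classes) -> softmax

Convolutions are valid (no padding); pooling is non-overlapping with stride
equal to the pool length; ReLU follows each convolution and the first FC
layer.  Forward and backward passes are written directly in NumPy (verified
against central finite differences in the test suite), with Adam or plain
SGD parameter updates.

The *feature tap* after the first fully connected layer is where all
adaptation losses operate; setting ``fc_units=2`` gives the 2-D diagnostic
projection mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sensordata import WindowSet

__all__ = [
    "NetConfig",
    "TrainState",
    "build_network",
    "extract_features",
    "predict",
    "forward",
    "forward_backward",
    "apply_gradients",
    "param_checksum",
    "MLPHead",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetConfig:
    """Hyperparameters of the CNN stack.

    Defaults follow the reference geometry: 50 convolution kernels of size
    5x1, 3x1 pooling, and a 1024-unit first FC layer (2 units for the 2-D
    diagnostic projection).
    """

    n_classes: int
    in_shape: tuple[int, int]  # (T, C)
    n_conv_kernels: int = 50
    conv_kernel_len: int = 5
    pool_len: int = 3
    fc_units: int = 1024

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.fc_units < 1:
            raise ValueError("fc_units must be >= 1")
        self.in_shape = (int(self.in_shape[0]), int(self.in_shape[1]))
        self.time_trace()  # raises if the stack exhausts the time axis

    def time_trace(self) -> list[int]:
        """Lengths of the time axis after each conv/pool stage.

        Raises with the minimum workable T when the input is too short.
        """
        L, P = self.conv_kernel_len, self.pool_len
        t = self.in_shape[0]
        trace = []
        for _ in range(2):
            t = t - L + 1  # valid convolution
            trace.append(t)
            t = t // P  # non-overlapping pooling
            trace.append(t)
        if trace[-1] < 1 or min(trace) < 1:
            t_min = self._min_t()
            raise ValueError(
                f"time axis exhausted: T={self.in_shape[0]} leaves trace {trace}; "
                f"minimum T for this stack is {t_min}"
            )
        return trace

    def _min_t(self) -> int:
        L, P = self.conv_kernel_len, self.pool_len
        t = P  # conv2 output must reach the pool length for pool2 >= 1
        t = t + L - 1  # before conv2
        t = t * P  # before pool1 (smallest multiple works)
        t = t + L - 1  # before conv1
        return t

    @property
    def flat_dim(self) -> int:
        return self.time_trace()[-1] * self.in_shape[1] * self.n_conv_kernels


@dataclass
class TrainState:
    """Opaque handle on network parameters and optimizer state."""

    config: NetConfig
    params: dict[str, np.ndarray]
    t: int = 0  # iteration counter
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    adam_m: dict[str, np.ndarray] = field(default_factory=dict)
    adam_v: dict[str, np.ndarray] = field(default_factory=dict)


def build_network(config: NetConfig, seed: int = 0, learning_rate: float = 1e-4,
                  optimizer: str = "adam") -> TrainState:
    """Initialize the network deterministically from ``seed`` (He init)."""
    rng = np.random.default_rng(seed)
    K, L = config.n_conv_kernels, config.conv_kernel_len

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    params = {
        "W1": he((K, L), L),
        "b1": np.zeros(K),
        "W2": he((K, K, L), K * L),
        "b2": np.zeros(K),
        "Wf": he((config.flat_dim, config.fc_units), config.flat_dim),
        "bf": np.zeros(config.fc_units),
        "Wo": he((config.fc_units, config.n_classes), config.fc_units),
        "bo": np.zeros(config.n_classes),
    }
    return TrainState(config=config, params=params,
                      learning_rate=learning_rate, optimizer=optimizer)


def _as_windows(x) -> np.ndarray:
    if isinstance(x, WindowSet):
        x = x.data
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"expected windows of shape [N, T, C], got {x.shape}")
    return x


def _pool(a: np.ndarray, P: int):
    """Non-overlapping max pool along axis 1; returns pooled, the reshaped
    window view and the usable time length (for the backward mask)."""
    B, T = a.shape[:2]
    Tp = T // P
    r = a[:, : Tp * P].reshape(B, Tp, P, *a.shape[2:])
    pooled = r.max(axis=2)
    return pooled, r, Tp * P


def _unpool(d: np.ndarray, r: np.ndarray, pooled: np.ndarray, P: int, T_full: int) -> np.ndarray:
    """Scatter pooled-gradient d back through the max; ties share the gradient
    equally (exact ties only arise at ReLU zeros, where the downstream ReLU
    mask annihilates them)."""
    mask = r == pooled[:, :, None]
    counts = mask.sum(axis=2, keepdims=True)
    out = mask * (d[:, :, None] / counts)
    B, Tp = d.shape[:2]
    out = out.reshape(B, Tp * P, *d.shape[2:])
    if Tp * P < T_full:
        pad = np.zeros((B, T_full - Tp * P, *d.shape[2:]))
        out = np.concatenate([out, pad], axis=1)
    return out


def forward(state: TrainState, windows, want_cache: bool = False):
    """Run the network; returns (logits, features) and optionally the cache
    of intermediates needed by :func:`forward_backward`."""
    cfg = state.config
    x = _as_windows(windows)
    if x.shape[1:] != cfg.in_shape:
        raise ValueError(f"window shape {x.shape[1:]} does not match net in_shape {cfg.in_shape}")
    p = state.params
    L, P = cfg.conv_kernel_len, cfg.pool_len
    if x.shape[0] == 0:
        empty_f = np.zeros((0, cfg.fc_units))
        empty_l = np.zeros((0, cfg.n_classes))
        return (empty_l, empty_f, None) if want_cache else (empty_l, empty_f)

    # convolutions as reshaped matmuls (BLAS-backed)
    win1 = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(x, L, axis=1))  # [B,T1,C,L]
    B, T1, C, _ = win1.shape
    z1 = (win1.reshape(-1, L) @ p["W1"].T).reshape(B, T1, C, -1) + p["b1"]
    a1 = np.maximum(z1, 0.0)
    p1, r1, used1 = _pool(a1, P)

    win2 = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(p1, L, axis=1))  # [B,T2,C,K,L]
    T2 = win2.shape[1]
    K = win2.shape[3]
    z2 = (win2.reshape(-1, K * L) @ p["W2"].reshape(-1, K * L).T).reshape(
        B, T2, C, -1) + p["b2"]
    a2 = np.maximum(z2, 0.0)
    p2, r2, used2 = _pool(a2, P)

    flat = p2.reshape(p2.shape[0], -1)
    zf = flat @ p["Wf"] + p["bf"]
    feats = np.maximum(zf, 0.0)
    logits = feats @ p["Wo"] + p["bo"]

    if not want_cache:
        return logits, feats
    cache = dict(x=x, win1=win1, z1=z1, a1=a1, r1=r1, p1=p1,
                 win2=win2, z2=z2, a2=a2, r2=r2, p2=p2,
                 flat=flat, zf=zf, feats=feats)
    return logits, feats, cache


def forward_backward(state: TrainState, cache: dict, d_logits: np.ndarray,
                     d_features: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Backward pass: gradients of a scalar loss given its sensitivities at the
    logits and (optionally) an extra sensitivity injected at the feature tap
    (center loss, MMD, reversed domain loss, critic signal)."""
    cfg = state.config
    p = state.params
    L, P = cfg.conv_kernel_len, cfg.pool_len
    feats, flat, zf = cache["feats"], cache["flat"], cache["zf"]

    grads = {}
    grads["Wo"] = feats.T @ d_logits
    grads["bo"] = d_logits.sum(axis=0)
    d_feats = d_logits @ p["Wo"].T
    if d_features is not None:
        d_feats = d_feats + d_features
    d_zf = d_feats * (zf > 0)
    grads["Wf"] = flat.T @ d_zf
    grads["bf"] = d_zf.sum(axis=0)
    d_flat = d_zf @ p["Wf"].T
    d_p2 = d_flat.reshape(cache["p2"].shape)

    d_a2 = _unpool(d_p2, cache["r2"], cache["p2"], P, cache["a2"].shape[1])
    d_z2 = d_a2 * (cache["z2"] > 0)
    K = cache["p1"].shape[-1]
    win2_flat = cache["win2"].reshape(-1, K * L)
    dz2_flat = d_z2.reshape(-1, d_z2.shape[-1])
    grads["W2"] = (dz2_flat.T @ win2_flat).reshape(p["W2"].shape)
    grads["b2"] = dz2_flat.sum(axis=0)
    d_p1 = np.zeros_like(cache["p1"])
    T2 = d_z2.shape[1]
    for l in range(L):
        d_p1[:, l : l + T2] += (dz2_flat @ p["W2"][:, :, l]).reshape(d_z2.shape)

    d_a1 = _unpool(d_p1, cache["r1"], cache["p1"], P, cache["a1"].shape[1])
    d_z1 = d_a1 * (cache["z1"] > 0)
    win1_flat = cache["win1"].reshape(-1, L)
    dz1_flat = d_z1.reshape(-1, d_z1.shape[-1])
    grads["W1"] = dz1_flat.T @ win1_flat
    grads["b1"] = dz1_flat.sum(axis=0)
    return grads


def apply_gradients(state: TrainState, grads: dict[str, np.ndarray]) -> None:
    """One optimizer step (Adam by default, plain SGD selectable); increments t."""
    state.t += 1
    lr = state.learning_rate
    if state.optimizer == "sgd":
        for k, g in grads.items():
            state.params[k] -= lr * g
        return
    b1, b2, eps = 0.9, 0.999, 1e-8
    for k, g in grads.items():
        m = state.adam_m.setdefault(k, np.zeros_like(g))
        v = state.adam_v.setdefault(k, np.zeros_like(g))
        m += (1 - b1) * (g - m)
        v += (1 - b2) * (g * g - v)
        mhat = m / (1 - b1**state.t)
        vhat = v / (1 - b2**state.t)
        state.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
    if not all(np.all(np.isfinite(p)) for p in state.params.values()):
        raise FloatingPointError(f"non-finite network parameters after step {state.t}")


def extract_features(state: TrainState, windows, batch: int = 256) -> np.ndarray:
    """Features at the first-FC tap, [N, fc_units]; deterministic at inference."""
    x = _as_windows(windows)
    out = [forward(state, x[i : i + batch])[1] for i in range(0, len(x), batch)] or [
        np.zeros((0, state.config.fc_units))
    ]
    return np.vstack(out)


def predict(state: TrainState, windows, batch: int = 256) -> np.ndarray:
    """Argmax class prediction; ties break toward the lowest class index."""
    x = _as_windows(windows)
    outs = [forward(state, x[i : i + batch])[0] for i in range(0, len(x), batch)] or [
        np.zeros((0, state.config.n_classes))
    ]
    return np.vstack(outs).argmax(axis=1)


def param_checksum(state: TrainState) -> float:
    """Cheap deterministic digest of all parameters (for identity checks)."""
    return float(sum(np.sum(v * np.cos(i + 1.0)) for i, v in enumerate(
        state.params[k] for k in sorted(state.params))))


class MLPHead:
    """One-hidden-layer ReLU MLP used as the DANN domain classifier and the
    Wasserstein critic, with its own Adam state.

    ``f(x) = relu(x W1 + b1) W2 + b2``.  :meth:`input_gradient` returns
    d f/d x for a scalar-output head (needed by the gradient penalty), and
    :meth:`penalty_grads` the closed-form parameter gradient of
    ``mean_i (||grad_x f(x_i)|| - 1)^2`` (ReLU masks held locally constant).
    """

    def __init__(self, in_dim: int, hidden: int, out_dim: int, seed: int = 0,
                 learning_rate: float = 1e-4) -> None:
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, out_dim)),
            "b2": np.zeros(out_dim),
        }
        self.learning_rate = learning_rate
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, want_cache: bool = False):
        z = x @ self.params["W1"] + self.params["b1"]
        h = np.maximum(z, 0.0)
        out = h @ self.params["W2"] + self.params["b2"]
        if want_cache:
            return out, dict(x=x, z=z, h=h)
        return out

    def backward(self, cache: dict, d_out: np.ndarray):
        """Returns (param grads, gradient w.r.t. the input features)."""
        grads = {
            "W2": cache["h"].T @ d_out,
            "b2": d_out.sum(axis=0),
        }
        d_h = d_out @ self.params["W2"].T
        d_z = d_h * (cache["z"] > 0)
        grads["W1"] = cache["x"].T @ d_z
        grads["b1"] = d_z.sum(axis=0)
        d_x = d_z @ self.params["W1"].T
        return grads, d_x

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d f / d x per row, for a scalar-output head."""
        if self.params["W2"].shape[1] != 1:
            raise ValueError("input_gradient requires a scalar-output head")
        z = x @ self.params["W1"] + self.params["b1"]
        mask = (z > 0).astype(np.float64)  # [m, H]
        u = mask * self.params["W2"][:, 0][None, :]  # [m, H]
        return u @ self.params["W1"].T  # [m, d]

    def penalty_grads(self, x: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        """Gradient penalty ``mean_i (||grad_x f(x_i)|| - 1)^2`` and its
        parameter gradients (W1, W2 only; biases do not enter)."""
        z = x @ self.params["W1"] + self.params["b1"]
        mask = (z > 0).astype(np.float64)  # [m, H]
        w2 = self.params["W2"][:, 0]  # [H]
        u = mask * w2[None, :]  # [m, H]
        g = u @ self.params["W1"].T  # [m, d]
        norms = np.sqrt(np.sum(g * g, axis=1))  # [m]
        m = len(x)
        penalty = float(np.mean((norms - 1.0) ** 2))
        safe = np.maximum(norms, 1e-12)
        r = (2.0 / m) * (norms - 1.0)[:, None] * g / safe[:, None]  # dP/dg, [m, d]
        gW1 = r.T @ u  # [d, H]
        gW2 = (mask * (g @ self.params["W1"])).T @ ((norms - 1.0) / safe)[:, None] * (2.0 / m)
        return penalty, {
            "W1": gW1,
            "b1": np.zeros_like(self.params["b1"]),
            "W2": gW2,
            "b2": np.zeros_like(self.params["b2"]),
        }

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            m = self._m.setdefault(k, np.zeros_like(g))
            v = self._v.setdefault(k, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            self.params[k] -= self.learning_rate * (m / (1 - b1**self.t)) / (
                np.sqrt(v / (1 - b2**self.t)) + eps
            )


def save_checkpoint(state: TrainState, path: str | Path) -> None:
    """Persist the network as one .npz container with the config embedded."""
    cfg = state.config
    meta = dict(n_classes=cfg.n_classes, in_shape=list(cfg.in_shape),
                n_conv_kernels=cfg.n_conv_kernels, conv_kernel_len=cfg.conv_kernel_len,
                pool_len=cfg.pool_len, fc_units=cfg.fc_units,
                t=state.t, learning_rate=state.learning_rate, optimizer=state.optimizer)
    np.savez(path, __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state.params)


def load_checkpoint(path: str | Path) -> TrainState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__config__"]).decode())
        params = {k: z[k] for k in z.files if k != "__config__"}
    cfg = NetConfig(n_classes=meta["n_classes"], in_shape=tuple(meta["in_shape"]),
                    n_conv_kernels=meta["n_conv_kernels"],
                    conv_kernel_len=meta["conv_kernel_len"],
                    pool_len=meta["pool_len"], fc_units=meta["fc_units"])
    return TrainState(config=cfg, params=params, t=meta["t"],
                      learning_rate=meta["learning_rate"], optimizer=meta["optimizer"])
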