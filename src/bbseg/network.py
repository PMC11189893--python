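"""The 15-layer dual-output convolutional network, in NumPy.

Architecture (counted layers: 6 conv + 3 max-pool + 4 dense + 2 heads = 15):

* three blocks of [3x3 conv, 3x3 conv, 2x2 max-pool]; blocks 2 and 3 add a
  residual skip from their input, projected by average pooling to the output
  spatial size followed by a 1x1 convolution (projections are uncounted,
  as is conventional for residual nets);
* with the default 25x25xS input the spatial path is 25 -> 12 -> 6 -> 2
  (block 3 opens with a valid-padded conv, 6 -> 4, then pools to 2), so a
  2x2x96 feature map enters the flatten;
* four dense layers, then two scalar heads: a sigmoid class probability
  (inside vs outside a region) and a linear distance-to-edge output.

Forward and backward passes are written against im2col matrix products;
the optimizer lives in :mod:`bbseg.training`.  Everything is seeded and
deterministic, so predictions are a pure function of (weights, input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    """Shape plan for the network.

    ``conv_widths`` are the channel counts of the three conv blocks,
    ``dense_widths`` the four hidden dense layer sizes.  The defaults give
    the canonical 2x2x96 pre-flatten map and 15 counted layers.
    """

    patch_side: int = 25
    n_channels: int = 4  # number of stacked scale (x color) planes
    conv_widths: tuple[int, int, int] = (24, 48, 96)
    dense_widths: tuple[int, int, int, int] = (384, 96, 48, 16)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.patch_side != 25:
            raise BuildError(
                "patch_side=25 is the only supported input side for the "
                "default 25->12->6->2 pooling plan"
            )
        if self.n_channels < 1:
            raise BuildError("n_channels must be >= 1")
        if len(self.dense_widths) != 4:
            raise BuildError("exactly four dense layers are required")

    @property
    def counted_layers(self) -> int:
        """Conv + pool + dense + head layers, the conventional count."""
        return 6 + 3 + len(self.dense_widths) + 2

    @property
    def preflatten_shape(self) -> tuple[int, int, int]:
        return (2, 2, self.conv_widths[2])

    @property
    def flat_size(self) -> int:
        h, w, c = self.preflatten_shape
        return h * w * c


# ---------------------------------------------------------------------------
# layer primitives (NHWC)


def _conv_forward(x, W, b, pad):
    """3x3 (or 1x1) convolution via im2col; W is (kh*kw*Cin, Cout)."""
    n, _, _, cin = x.shape
    k = int(np.sqrt(W.shape[0] // cin))
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,Ho,Wo,C,k,k)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))  # (...,k,k,C)
    n_, ho, wo = cols.shape[:3]
    flat = cols.reshape(n_ * ho * wo, k * k * cin)
    y = (flat @ W + b).reshape(n_, ho, wo, -1)
    return y, (flat, x.shape, k, pad)


def _conv_backward(dy, W, cache):
    flat, xp_shape, k, pad = cache
    n, ho, wo, cout = dy.shape
    dyf = dy.reshape(-1, cout)
    dW = flat.T @ dyf
    db = dyf.sum(axis=0)
    cin = xp_shape[3]
    dcols = (dyf @ W.T).reshape(n, ho, wo, k, k, cin)
    dxp = np.zeros(xp_shape, dtype=dy.dtype)
    for u in range(k):
        for v in range(k):
            dxp[:, u : u + ho, v : v + wo, :] += dcols[:, :, :, u, v, :]
    if pad:
        dxp = dxp[:, pad:-pad, pad:-pad, :]
    return dxp, dW, db


def _maxpool_forward(x):
    """2x2 max pool, stride 2, floor (odd trailing row/col dropped)."""
    n, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    win = (
        x[:, : 2 * ho, : 2 * wo]
        .reshape(n, ho, 2, wo, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, ho, wo, c, 4)
    )
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def _maxpool_backward(dy, cache):
    idx, xshape = cache
    n, h, w, c = xshape
    ho, wo = h // 2, w // 2
    g = np.zeros((n, ho, wo, c, 4), dtype=dy.dtype)
    np.put_along_axis(g, idx[..., None], dy[..., None], axis=-1)
    g = (
        g.reshape(n, ho, wo, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, 2 * ho, 2 * wo, c)
    )
    dx = np.zeros(xshape, dtype=dy.dtype)
    dx[:, : 2 * ho, : 2 * wo] = g
    return dx


def _avgpool_forward(x, factor):
    n, h, w, c = x.shape
    ho, wo = h // factor, w // factor
    y = x.reshape(n, ho, factor, wo, factor, c).mean(axis=(2, 4))
    return y


def _avgpool_backward(dy, factor):
    n, ho, wo, c = dy.shape
    g = dy[:, :, None, :, None, :] / (factor * factor)
    g = np.broadcast_to(g, (n, ho, factor, wo, factor, c))
    return g.reshape(n, ho * factor, wo * factor, c)


def _relu(x):
    return np.maximum(x, 0)


# ---------------------------------------------------------------------------


class DualHeadCNN:
    """Built network: parameters, forward pass, and full backward pass."""

    # (name, kind, in_ch, out_ch, pad) for the six counted convs
    _CONV_PLAN = [
        ("c1a", 1), ("c1b", 1),   # block 1, same padding, 25 -> 25
        ("c2a", 1), ("c2b", 1),   # block 2, same padding, 12 -> 12
        ("c3a", 0), ("c3b", 1),   # block 3: valid (6 -> 4) then same
    ]

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        w1, w2, w3 = spec.conv_widths
        conv_io = {
            "c1a": (spec.n_channels, w1), "c1b": (w1, w1),
            "c2a": (w1, w2), "c2b": (w2, w2),
            "c3a": (w2, w3), "c3b": (w3, w3),
        }
        for name, _pad in self._CONV_PLAN:
            cin, cout = conv_io[name]
            self._add_conv(rng, name, 3, cin, cout)
        # residual projections for blocks 2 and 3 (uncounted, 1x1)
        self._add_conv(rng, "p2", 1, w1, w2)
        self._add_conv(rng, "p3", 1, w2, w3)
        sizes = [spec.flat_size, *spec.dense_widths]
        for i in range(4):
            self._add_dense(rng, f"d{i}", sizes[i], sizes[i + 1])
        self._add_dense(rng, "head_class", sizes[-1], 1)
        self._add_dense(rng, "head_dist", sizes[-1], 1)

    def _add_conv(self, rng, name, k, cin, cout):
        fan_in = k * k * cin
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
        self.params[f"{name}_W"] = w.astype(self.dtype)
        self.params[f"{name}_b"] = np.zeros(cout, dtype=self.dtype)

    def _add_dense(self, rng, name, fan_in, fan_out):
        if name.startswith("head"):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        self.params[f"{name}_W"] = w.astype(self.dtype)
        self.params[f"{name}_b"] = np.zeros(fan_out, dtype=self.dtype)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Class logit and raw distance output for a batch of patch stacks.

        ``x`` is (N, patch, patch, channels).  Returns ``(logit, dist)``
        each of shape (N,); with ``keep_cache`` also returns the cache
        needed by :meth:`backward`.
        """
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (self.spec.patch_side, self.spec.patch_side, self.spec.n_channels):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec "
                f"{(self.spec.patch_side, self.spec.patch_side, self.spec.n_channels)}"
            )
        P = self.params
        cache: dict = {}

        def conv(name, inp, pad):
            y, cc = _conv_forward(inp, P[f"{name}_W"], P[f"{name}_b"], pad)
            cache[name] = cc
            return y

        # block 1: 25 -> 12
        a = _relu(conv("c1a", x, 1)); cache["a_c1a"] = a
        b = _relu(conv("c1b", a, 1)); cache["a_c1b"] = b
        p1, cache["pool1"] = _maxpool_forward(b)
        # block 2 (+skip): 12 -> 6
        a = _relu(conv("c2a", p1, 1)); cache["a_c2a"] = a
        b = conv("c2b", a, 1)
        h2, cache["pool2"] = _maxpool_forward(b)
        s2 = conv("p2", _avgpool_forward(p1, 2), 0)
        z2 = h2 + s2; r2 = _relu(z2); cache["z2"] = z2
        # block 3 (+skip): 6 -> 2  (valid conv 6->4 first)
        a = _relu(conv("c3a", r2, 0)); cache["a_c3a"] = a
        b = conv("c3b", a, 1)
        h3, cache["pool3"] = _maxpool_forward(b)
        s3 = conv("p3", _avgpool_forward(r2, 3), 0)
        z3 = h3 + s3; r3 = _relu(z3); cache["z3"] = z3
        if r3.shape[1:] != self.spec.preflatten_shape:
            raise BuildError(
                f"pre-flatten map {r3.shape[1:]} != {self.spec.preflatten_shape}"
            )
        flat = r3.reshape(r3.shape[0], -1)
        h = flat
        for i in range(4):
            z = h @ P[f"d{i}_W"] + P[f"d{i}_b"]
            cache[f"dz{i}"] = z; cache[f"din{i}"] = h
            h = _relu(z)
        cache["dense_out"] = h
        logit = (h @ P["head_class_W"] + P["head_class_b"])[:, 0]
        dist = (h @ P["head_dist_W"] + P["head_dist_b"])[:, 0]
        if keep_cache:
            cache["x"] = x
            return logit, dist, cache
        return logit, dist

    def predict(self, x: np.ndarray):
        """Class probability and raw distance for a batch of stacks."""
        logit, dist = self.forward(x)
        return _sigmoid(logit), dist

    # -- backward ----------------------------------------------------------

    def backward(self, dlogit: np.ndarray, ddist: np.ndarray, cache: dict):
        """Gradients of a scalar loss w.r.t. every parameter.

        ``dlogit``/``ddist`` are dLoss/dlogit and dLoss/ddist per sample.
        Returns a dict aligned with :attr:`params`.
        """
        P = self.params
        g = {k: np.zeros_like(v) for k, v in P.items()}
        h = cache["dense_out"]
        g["head_class_W"] = h.T @ dlogit[:, None]
        g["head_class_b"] = dlogit.sum(keepdims=True)
        g["head_dist_W"] = h.T @ ddist[:, None]
        g["head_dist_b"] = ddist.sum(keepdims=True)
        dh = dlogit[:, None] @ P["head_class_W"].T + ddist[:, None] @ P["head_dist_W"].T
        for i in range(3, -1, -1):
            dz = dh * (cache[f"dz{i}"] > 0)
            g[f"d{i}_W"] = cache[f"din{i}"].T @ dz
            g[f"d{i}_b"] = dz.sum(axis=0)
            dh = dz @ P[f"d{i}_W"].T

        def convb(name, dy):
            dx, dW, db = _conv_backward(dy, P[f"{name}_W"], cache[name])
            g[f"{name}_W"] = dW
            g[f"{name}_b"] = db
            return dx

        dr3 = dh.reshape((-1,) + self.spec.preflatten_shape)
        dz3 = dr3 * (cache["z3"] > 0)
        # skip branch of block 3
        dr2_skip = _avgpool_backward(convb("p3", dz3), 3)
        # main branch of block 3
        db_ = _maxpool_backward(dz3, cache["pool3"])
        da = convb("c3b", db_)
        da = da * (cache["a_c3a"] > 0)
        dr2 = convb("c3a", da) + dr2_skip
        dz2 = dr2 * (cache["z2"] > 0)
        dp1_skip = _avgpool_backward(convb("p2", dz2), 2)
        db_ = _maxpool_backward(dz2, cache["pool2"])
        da = convb("c2b", db_)
        da = da * (cache["a_c2a"] > 0)
        dp1 = convb("c2a", da) + dp1_skip
        db_ = _maxpool_backward(dp1, cache["pool1"])
        db_ = db_ * (cache["a_c1b"] > 0)
        da = convb("c1b", db_)
        da = da * (cache["a_c1a"] > 0)
        convb("c1a", da)
        return g

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        """Save weights plus spec/provenance to an .npz checkpoint."""
        meta = {
            "spec": {
                "patch_side": self.spec.patch_side,
                "n_channels": self.spec.n_channels,
                "conv_widths": list(self.spec.conv_widths),
                "dense_widths": list(self.spec.dense_widths),
                "activation": self.spec.activation,
            },
            "provenance": provenance or {},
        }
        np.savez(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "DualHeadCNN":
        data = np.load(Path(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        s = meta["spec"]
        spec = NetworkSpec(
            patch_side=s["patch_side"],
            n_channels=s["n_channels"],
            conv_widths=tuple(s["conv_widths"]),
            dense_widths=tuple(s["dense_widths"]),
            activation=s["activation"],
        )
        net = cls(spec)
        for k in net.params:
            net.params[k] = data[k]
        net.provenance = meta["provenance"]
        return net


def _sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build(spec: NetworkSpec, seed: int = 0) -> DualHeadCNN:
    """Construct an untrained network with seeded initialization."""
    return DualHeadCNN(spec, seed=seed)
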