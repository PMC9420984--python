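"""Multiscale-kernel 3D convolutional network (ERN) in pure NumPy.

Architecture (multiscale variant), for input blocks ``9 x 9 x T``:

    input (1 channel)
      |-- conv3d 3x3x4, pad 1 -> ReLU -> maxpool 1x1x2   (branch a)
      |-- conv3d 3x3x5, pad 1 -> ReLU -> maxpool 1x1x2   (branch b)
    concat feature maps
      -> conv3d 3x3x4, pad 1 -> ReLU -> maxpool 1x1x2
      -> dropout -> fully connected -> softmax over classes

The two branch kernels share the 3x3 spatial footprint but differ in temporal
extent (4 vs 5 samples); after the stride-2 temporal pooling both branches
have the same temporal length (floor(127/2) = floor(126/2) = 63 for T = 128),
so the maps concatenate without cropping.  The ``same_scale`` ablation
variant gives branch b the 3x3x4 kernel as well.

Convolutions run as im2col + BLAS matmul in float32; gradients are exact
(validated against finite differences in the test suite).  Output sizes
follow O = (I - K + 2P)/S + 1 per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ERNConfig",
    "ERN",
    "conv_output_size",
    "pooled_size",
    "build_ern",
]


def conv_output_size(I: int, K: int, P: int = 1, S: int = 1) -> int:
    """Output size of one convolution dimension: (I - K + 2P)/S + 1.

    Raises if the result is fractional or non-positive.
    """
    if S < 1:
        raise ValueError("stride must be >= 1")
    span = I - K + 2 * P
    if span < 0 or span % S:
        raise ValueError(
            f"convolution of size-{K} kernel over {I} (+2*{P} pad) at stride {S} "
            "does not produce an integer number of positions"
        )
    return span // S + 1


def pooled_size(T: int, pool: int = 2, stride: int = 2) -> int:
    """Output length of a pooling window: floor((T - pool)/stride) + 1."""
    if T < pool:
        raise ValueError(f"cannot pool window of {pool} over only {T} samples")
    return (T - pool) // stride + 1


@dataclass(frozen=True)
class ERNConfig:
    """Architecture description of the emotion recognition network.

    Defaults reproduce the published architecture: parallel 3x3x4 / 3x3x5
    branches of 32 maps each, a 64-map 3x3x4 head, 1x1x2 max pooling after
    every convolution, dropout 0.6 before the classifier.
    """

    branch_a_kernel: tuple[int, int, int] = (3, 3, 4)
    branch_b_kernel: tuple[int, int, int] = (3, 3, 5)
    pool_kernel: tuple[int, int, int] = (1, 1, 2)
    branch_maps: int = 32
    head_maps: int = 64
    head_kernel: tuple[int, int, int] = (3, 3, 4)
    padding: int = 1
    dropout_p: float = 0.6
    n_classes: int = 4
    variant: str = "multiscale"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.variant not in ("multiscale", "same_scale"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def effective_branch_b_kernel(self) -> tuple[int, int, int]:
        return self.branch_a_kernel if self.variant == "same_scale" else self.branch_b_kernel


# ---------------------------------------------------------------------------
# layers

class _Conv3D:
    """3D convolution with symmetric zero padding.

    Activations are channels-last, ``(batch, H, W, T, C)``.  The temporal
    axis is unfolded once into contiguous (k3, C) blocks; each of the k1*k2
    spatial kernel offsets is then a single GEMM over the whole padded plane
    whose result is accumulated at the shifted output location.  This keeps
    every copy and accumulation contiguous, at the price of computing the
    convolution on padded border positions that are then discarded.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel, padding: int,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.padding = tuple(kernel), padding
        k1, k2, k3 = self.kernel
        fan_in = in_ch * k1 * k2 * k3
        self.W = (rng.standard_normal((k1, k2, k3, in_ch, out_ch)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        # large scratch arrays are reused across calls: fresh allocations of
        # this size pay heavily for page faults every training step
        self._bufs: dict[str, np.ndarray] = {}
        self._shapes = None

    @property
    def params(self):
        return [self.W, self.b]

    def out_spatial(self, shape):
        return tuple(
            conv_output_size(i, k, self.padding, 1)
            for i, k in zip(shape, self.kernel)
        )

    def _buf(self, name: str, shape) -> np.ndarray:
        arr = self._bufs.get(name)
        if arr is None or arr.shape != tuple(shape):
            arr = np.empty(shape, dtype=np.float32)
            self._bufs[name] = arr
        return arr

    def forward(self, x: np.ndarray) -> np.ndarray:
        P = self.padding
        k1, k2, k3 = self.kernel
        C, F = self.in_ch, self.out_ch
        B = x.shape[0]
        Hp, Wp, Tp = (s + 2 * P for s in x.shape[1:4])
        o1, o2, o3 = self.out_spatial(x.shape[1:4])
        x_p = self._buf("x_p", (B, Hp, Wp, Tp, C))
        x_p[...] = 0.0
        x_p[:, P:Hp - P, P:Wp - P, P:Tp - P, :] = x
        # temporal unfold: U[b,p1,p2,t,k,c] = x_p[b,p1,p2,t+k,c]; o3 = Tp-k3+1
        U = self._buf("U", (B, Hp, Wp, o3, k3, C))
        for k in range(k3):
            U[:, :, :, :, k, :] = x_p[:, :, :, k:k + o3, :]
        # one small GEMM per spatial kernel offset; every copy moves whole
        # (o3, k3, C) blocks, which are contiguous in U
        A = self._buf("A", (B, o1, o2, o3, k3, C))
        A2 = A.reshape(B * o1 * o2 * o3, k3 * C)
        G = self._buf("G", (B * o1 * o2 * o3, F))
        out = self._buf("out", (B, o1, o2, o3, F))
        out[:] = self.b
        out2 = out.reshape(-1, F)
        Wf = self.W.reshape(k1, k2, k3 * C, F)
        for i in range(k1):
            for j in range(k2):
                np.copyto(A, U[:, i:i + o1, j:j + o2])
                np.matmul(A2, Wf[i, j], out=G)
                out2 += G
        self._shapes = (B, Hp, Wp, o1, o2, o3)
        return out

    def backward(self, dout: np.ndarray):
        B, Hp, Wp, o1, o2, o3 = self._shapes
        k1, k2, k3 = self.kernel
        C, F = self.in_ch, self.out_ch
        P = self.padding
        U = self._bufs["U"]
        dout2 = dout.reshape(-1, F)
        db = dout2.sum(axis=0)
        dW = np.empty_like(self.W)
        Wf = self.W.reshape(k1, k2, k3 * C, F)
        A = self._bufs["A"]
        A2 = A.reshape(B * o1 * o2 * o3, k3 * C)
        dA = self._buf("dA", (B, o1, o2, o3, k3, C))
        dA2 = dA.reshape(B * o1 * o2 * o3, k3 * C)
        dU = self._buf("dU", (B, Hp, Wp, o3, k3, C))
        dU[...] = 0.0
        for i in range(k1):
            for j in range(k2):
                np.copyto(A, U[:, i:i + o1, j:j + o2])
                dW[i, j] = (A2.T @ dout2).reshape(k3, C, F)
                np.matmul(dout2, Wf[i, j].T, out=dA2)
                dU[:, i:i + o1, j:j + o2] += dA
        # fold the temporal unfold back onto the padded input
        dx_p = self._buf("x_p", (B, Hp, Wp, o3 + k3 - 1, C))
        dx_p[...] = 0.0
        for k in range(k3):
            dx_p[:, :, :, k:k + o3, :] += dU[:, :, :, :, k, :]
        dx = dx_p[:, P:-P or None, P:-P or None, P:-P or None, :]
        return dx, [dW, db]


class _TemporalMaxPool:
    """Max pooling with a 1x1xpool kernel at stride = pool along time
    (channels-last: time is axis -2)."""

    def __init__(self, pool: int = 2):
        self.pool = pool
        self._bufs: dict[str, np.ndarray] = {}

    def _buf(self, name: str, shape, dtype=np.float32) -> np.ndarray:
        arr = self._bufs.get(name)
        if arr is None or arr.shape != tuple(shape) or arr.dtype != dtype:
            arr = np.empty(shape, dtype=dtype)
            self._bufs[name] = arr
        return arr

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pool
        B, H, W, T, C = x.shape
        To = pooled_size(T, p, p)
        self._in_T = T
        if p == 2:  # pairwise compare beats a general argmax
            x0 = x[:, :, :, 0:To * 2:2, :]
            x1 = x[:, :, :, 1:To * 2:2, :]
            mask = self._buf("mask", x0.shape, np.bool_)
            np.greater(x1, x0, out=mask)
            out = self._buf("out", x0.shape)
            np.copyto(out, x0)
            np.copyto(out, x1, where=mask)
            return out
        xr = np.ascontiguousarray(
            x[:, :, :, : To * p, :]
        ).reshape(B, H, W, To, p, C)
        self._idx = xr.argmax(axis=4)
        return xr.max(axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.pool
        B, H, W, To, C = dout.shape
        dx = self._buf("dx", (B, H, W, self._in_T, C))
        dx[...] = 0.0
        if p == 2:
            mask = self._bufs["mask"]
            np.copyto(dx[:, :, :, 1:To * 2:2, :], dout, where=mask)
            np.copyto(dx[:, :, :, 0:To * 2:2, :], dout, where=~mask)
            return dx
        dxr = np.zeros((B, H, W, To, p, C), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[:, :, :, :, None, :],
                          dout[:, :, :, :, None, :], axis=4)
        dx[:, :, :, : To * p, :] = dxr.reshape(B, H, W, To * p, C)
        return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ERN:
    """The multiscale 3D CNN with explicit forward/backward passes.

    Accepts input blocks of shape ``(batch, 9, 9, T)`` (a leading channel
    axis of size 1 is added internally); emits class probabilities.
    """

    def __init__(self, cfg: ERNConfig | None = None, input_shape=(9, 9, 128),
                 seed: int = 0):
        self.cfg = cfg or ERNConfig()
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        c = self.cfg
        pool = c.pool_kernel[2]
        self.branch_a = _Conv3D(1, c.branch_maps, c.branch_a_kernel, c.padding, rng)
        self.branch_b = _Conv3D(1, c.branch_maps, c.effective_branch_b_kernel,
                                c.padding, rng)
        self.pool_a = _TemporalMaxPool(pool)
        self.pool_b = _TemporalMaxPool(pool)
        self.head = _Conv3D(2 * c.branch_maps, c.head_maps, c.head_kernel,
                            c.padding, rng)
        self.pool_head = _TemporalMaxPool(pool)

        h, w, T = self.input_shape
        sa = self.branch_a.out_spatial((h, w, T))
        sb = self.branch_b.out_spatial((h, w, T))
        ta, tb = pooled_size(sa[2], pool, pool), pooled_size(sb[2], pool, pool)
        if (sa[0], sa[1]) != (sb[0], sb[1]) or ta != tb:
            raise ValueError(
                f"branch outputs {sa[:2]}x{ta} vs {sb[:2]}x{tb} cannot concatenate"
            )
        sh = self.head.out_spatial((sa[0], sa[1], ta))
        th = pooled_size(sh[2], pool, pool)
        self._feat_shape = (sh[0], sh[1], th, c.head_maps)
        n_features = int(np.prod(self._feat_shape))
        self.fc_W = (rng.standard_normal((n_features, c.n_classes)) *
                     np.sqrt(2.0 / n_features)).astype(np.float32)
        self.fc_b = np.zeros(c.n_classes, dtype=np.float32)
        self._bufs: dict[str, np.ndarray] = {}

    def _f32_buf(self, name: str, shape) -> np.ndarray:
        arr = self._bufs.get(name)
        if arr is None or arr.shape != tuple(shape):
            arr = np.empty(shape, dtype=np.float32)
            self._bufs[name] = arr
        return arr

    def _bool_buf(self, name: str, shape) -> np.ndarray:
        arr = self._bufs.get(name)
        if arr is None or arr.shape != tuple(shape):
            arr = np.empty(shape, dtype=np.bool_)
            self._bufs[name] = arr
        return arr

    # -- parameters -------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return (self.branch_a.params + self.branch_b.params + self.head.params
                + [self.fc_W, self.fc_b])

    def parameter_count(self) -> int:
        """Total number of trainable scalars."""
        return int(sum(p.size for p in self.params))

    def set_params(self, values) -> None:
        for p, v in zip(self.params, values):
            p[...] = v

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return logits for a (batch, 9, 9, T) input block."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError(f"expected (batch, H, W, T) input, got {x.shape}")
        x5 = x[..., None]  # trailing channel axis
        relu = lambda v, key: (  # in-place ReLU; mask reused across steps
            np.greater(v, 0, out=self._bool_buf(key, v.shape)),
            np.maximum(v, 0, out=v),
        )[1]
        a = self.branch_a.forward(x5)
        a = relu(a, "a_mask")
        a_pool = self.pool_a.forward(a)
        b = self.branch_b.forward(x5)
        b = relu(b, "b_mask")
        b_pool = self.pool_b.forward(b)
        m = self.cfg.branch_maps
        merged = self._f32_buf("merged", (*a_pool.shape[:-1], 2 * m))
        merged[..., :m] = a_pool
        merged[..., m:] = b_pool
        h = self.head.forward(merged)
        h = relu(h, "h_mask")
        h_pool = self.pool_head.forward(h)
        feats = h_pool.reshape(len(x), -1)
        if train and self.cfg.dropout_p > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - self.cfg.dropout_p
            u = self._f32_buf("drop_u", feats.shape)
            rng.random(out=u, dtype=np.float32)
            mask = self._f32_buf("drop_mask", feats.shape)
            np.multiply(u < keep, np.float32(1.0 / keep), out=mask)
            feats = feats * mask
            self._drop_mask = mask
        else:
            self._drop_mask = None
        self._cache = feats
        return feats @ self.fc_W + self.fc_b

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) in evaluation mode."""
        return _softmax(self.forward(x, train=False))

    def backward(self, dlogits: np.ndarray):
        """Gradient of the loss w.r.t. every parameter, given d loss/d logits."""
        feats = self._cache
        dW_fc = feats.T @ dlogits
        db_fc = dlogits.sum(axis=0)
        dfeats = dlogits @ self.fc_W.T
        if self._drop_mask is not None:
            dfeats *= self._drop_mask
        dh_pool = dfeats.reshape(len(dlogits), *self._feat_shape)
        dh = self.pool_head.backward(dh_pool)
        dh *= self._bufs["h_mask"]
        dmerged, head_grads = self.head.backward(dh)
        m = self.cfg.branch_maps
        da = self.pool_a.backward(dmerged[..., :m])
        da *= self._bufs["a_mask"]
        db = self.pool_b.backward(dmerged[..., m:])
        db *= self._bufs["b_mask"]
        _, a_grads = self.branch_a.backward(da)
        _, b_grads = self.branch_b.backward(db)
        self._cache = None
        return a_grads + b_grads + head_grads + [dW_fc, db_fc]

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True,
                       rng: np.random.Generator | None = None):
        """Mean cross-entropy over the batch and its parameter gradients."""
        logits = self.forward(x, train=train, rng=rng)
        probs = _softmax(logits)
        n = len(y)
        eps = np.finfo(np.float32).tiny
        loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
        dlogits = probs.astype(np.float32)
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        return loss, self.backward(dlogits)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint (npz) with config and weights."""
        path = Path(path)
        cfg = self.cfg
        meta = dict(
            branch_a_kernel=cfg.branch_a_kernel, branch_b_kernel=cfg.branch_b_kernel,
            pool_kernel=cfg.pool_kernel, branch_maps=cfg.branch_maps,
            head_maps=cfg.head_maps, head_kernel=cfg.head_kernel,
            padding=cfg.padding, dropout_p=cfg.dropout_p,
            n_classes=cfg.n_classes, variant=cfg.variant,
        )
        np.savez(
            path,
            _meta=np.array(repr(meta)),
            _input_shape=np.array(self.input_shape),
            **{f"p{i}": p for i, p in enumerate(self.params)},
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ERN":
        import ast

        with np.load(path, allow_pickle=False) as f:
            meta = ast.literal_eval(str(f["_meta"]))
            for k in ("branch_a_kernel", "branch_b_kernel", "pool_kernel",
                      "head_kernel"):
                meta[k] = tuple(meta[k])
            net = cls(ERNConfig(**meta), input_shape=tuple(f["_input_shape"]))
            net.set_params([f[f"p{i}"] for i in range(len(net.params))])
        return net


def build_ern(cfg: ERNConfig | None = None, input_shape=(9, 9, 128),
              seed: int = 0) -> ERN:
    """Construct the network for the given architecture config."""
    return ERN(cfg, input_shape=input_shape, seed=seed)
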