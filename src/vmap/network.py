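"""Multi-input multi-output ConvMixer for censored category prediction.

The four view images are concatenated into a 12-channel stack and
processed by a minimal ConvMixer (defaults: depth 4, 16 filters, patch
size 4): a strided patch-embedding convolution, then ``depth`` mixer
blocks (9x9 depthwise spatial convolution with a residual connection,
followed by a pointwise channel convolution; GELU activations and batch
normalization after every convolution), global average pooling, and two
parallel linear heads — one per task — each normalized by softmax into a
probability vector (p_pre, p_1, ..., p_K, p_free) of length K + 2.

Everything, including backpropagation and the Adam optimizer, is
implemented on plain numpy arrays.  Each layer caches its forward pass
and implements an explicit backward pass; the chain runs all the way to
the input stack, which is what the saliency module relies on.

Array layout is (batch, channels, height, width) in float32.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import fft as spfft


from .errors import ConfigurationError, InputError
from .synthmap.mesh import VIEWS



@dataclass(frozen=True)
class ArchConfig:
    """Backbone hyperparameters; defaults follow the minimal recipe."""

    depth: int = 4
    filters: int = 16
    patch_size: int = 4
    side: int = 256
    n_bins: int = 12
    kernel_size: int = 9
    in_channels: int = 12  # four RGB views, channel-concatenated
    fusion: str = "concat"

    def __post_init__(self):
        if self.depth < 1 or self.filters < 1:
            raise ConfigurationError("depth and filters must be positive")
        if self.side % self.patch_size != 0:
            raise ConfigurationError("image side must be divisible by the patch size")
        if self.fusion != "concat":
            raise ConfigurationError("only channel-concatenation fusion is implemented")

    @property
    def n_outputs(self) -> int:
        return self.n_bins + 2


@dataclass
class ModelOutput:
    """Per-task probability vectors over (pre, bin 1..K, event-free)."""

    pvi: np.ndarray  # (B, K+2)
    bepvi: np.ndarray

    def task(self, task: str) -> np.ndarray:
        return self.pvi if task == "PVI" else self.bepvi

    def cif(self, task: str) -> np.ndarray:
        """Cumulative incidence F(m) = sum_{k<=m} p_k, shape (B, K)."""
        p = self.task(task)
        return np.cumsum(p[:, 1:-1], axis=1)


# ----------------------------------------------------------------------
# preprocessing / augmentation


def preprocess(images: np.ndarray) -> np.ndarray:
    """Scale a (4, S, S, 3) uint8 view set to a (12, S, S) float stack.

    Channels 0-2 are the AP image, then PA, INF, SUP, each scaled from
    zero to one.
    """
    images = np.asarray(images)
    if images.shape[0] != len(VIEWS) or images.shape[-1] != 3:
        raise InputError("expected a (4, S, S, 3) view stack")
    if images.shape[1] != images.shape[2]:
        raise InputError("views must be square and equally sized")
    scaled = images.astype(np.float32) / 255.0
    return np.concatenate([scaled[i].transpose(2, 0, 1) for i in range(len(VIEWS))], axis=0)


def random_flip(stack: np.ndarray, rng: np.random.Generator, force: bool | None = None) -> np.ndarray:
    """Left-right mirror of ALL channels jointly, with probability 1/2.

    Flipping the whole 12-channel stack preserves the positional
    relationship across the four views; a subset is never flipped.
    """
    flip = bool(rng.uniform() < 0.5) if force is None else bool(force)
    if not flip:
        return stack
    return stack[..., ::-1].copy()


# ----------------------------------------------------------------------
# layers


class _Layer:
    params: tuple = ()

    def zero_grad(self):
        for name in self.params:
            getattr(self, "g_" + name).fill(0.0)

    def param_pairs(self):
        return [(getattr(self, n), getattr(self, "g_" + n)) for n in self.params]


class PatchEmbed(_Layer):
    """Strided convolution = per-patch flatten + dense projection."""

    params = ("W", "b")

    def __init__(self, in_channels: int, filters: int, patch: int, rng):
        fan_in = in_channels * patch * patch
        self.patch = patch
        self.W = (rng.standard_normal((fan_in, filters)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.g_W = np.zeros_like(self.W)
        self.g_b = np.zeros_like(self.b)

    def forward(self, x):
        B, C, H, W = x.shape
        p = self.patch
        h, w = H // p, W // p
        cols = (
            x.reshape(B, C, h, p, w, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(B, h, w, C * p * p)
        )
        self._cols = cols
        self._xshape = x.shape
        y = cols @ self.W + self.b
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy):
        B, F, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1)
        self.g_W += self._cols.reshape(-1, self.W.shape[0]).T @ dyf.reshape(-1, F)
        self.g_b += dyf.sum(axis=(0, 1, 2))
        dcols = dyf @ self.W.T
        Bx, C, H, W = self._xshape
        p = self.patch
        dx = (
            dcols.reshape(B, h, w, C, p, p)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(Bx, C, H, W)
        )
        return dx


class DepthwiseConv(_Layer):
    """Same-padding depthwise spatial convolution (one kernel per channel).

    Evaluated in the frequency domain.  With y = corr(x_pad, K) cropped to
    the input size, the forward pass, the kernel gradient corr(x_pad, dy)
    and the input gradient conv(dy, K) are each one batched FFT product;
    the transform size N >= H + k - 1 guarantees no circular wrap-around.
    """

    params = ("K", "b")

    def __init__(self, channels: int, kernel: int, rng):
        fan_in = kernel * kernel
        self.kernel = kernel
        self.K = (rng.standard_normal((channels, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(channels, dtype=np.float32)
        self.g_K = np.zeros_like(self.K)
        self.g_b = np.zeros_like(self.b)

    def forward(self, x):
        k, pad = self.kernel, self.kernel // 2
        B, C, H, W = x.shape
        N = spfft.next_fast_len(H + k - 1)
        M = spfft.next_fast_len(W + k - 1)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        fxp = spfft.rfft2(xp, s=(N, M))
        self._fxp, self._hw, self._nm = fxp, (H, W), (N, M)
        fk = spfft.rfft2(self.K, s=(N, M))
        self._fk = fk
        y = spfft.irfft2(fxp * np.conj(fk), s=(N, M))[..., :H, :W]
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        k, pad = self.kernel, self.kernel // 2
        H, W = self._hw
        N, M = self._nm
        self.g_b += dy.sum(axis=(0, 2, 3))
        fdy = spfft.rfft2(dy, s=(N, M))
        self.g_K += spfft.irfft2((self._fxp * np.conj(fdy)).sum(axis=0), s=(N, M))[:, :k, :k]
        return spfft.irfft2(fdy * self._fk, s=(N, M))[..., pad : pad + H, pad : pad + W]


class PointwiseConv(_Layer):
    """1x1 convolution mixing channels."""

    params = ("W", "b")

    def __init__(self, in_channels: int, out_channels: int, rng):
        self.W = (rng.standard_normal((in_channels, out_channels)) * np.sqrt(2.0 / in_channels)).astype(
            np.float32
        )
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.g_W = np.zeros_like(self.W)
        self.g_b = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        y = np.einsum("bchw,cd->bdhw", x, self.W, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        self.g_W += np.einsum("bchw,bdhw->cd", self._x, dy, optimize=True)
        self.g_b += dy.sum(axis=(0, 2, 3))
        return np.einsum("bdhw,cd->bchw", dy, self.W, optimize=True)


class BatchNorm(_Layer):
    """Per-channel normalization: batch statistics in training, frozen
    running statistics at inference."""

    params = ("gamma", "beta")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.g_gamma = np.zeros_like(self.gamma)
        self.g_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, train = self._cache
        self.g_gamma += np.sum(dy * xhat, axis=(0, 2, 3))
        self.g_beta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = np.sum(dxhat * xhat, axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (dxhat - s1 / n - xhat * s2 / n)


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))
_GELU_A = np.float32(0.044715)


class GELU(_Layer):
    """Gaussian error linear unit (tanh form, evaluated in float32)."""

    def forward(self, x):
        u = _GELU_C * (x + _GELU_A * x * x * x)
        t = np.tanh(u)
        self._cache = (x, t)
        return 0.5 * x * (1.0 + t)

    def backward(self, dy):
        x, t = self._cache
        du = _GELU_C * (1.0 + 3.0 * _GELU_A * x * x)
        return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du)


class Dense(_Layer):
    params = ("W", "b")

    def __init__(self, n_in: int, n_out: int, rng):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(1.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.g_W = np.zeros_like(self.W)
        self.g_b = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.g_W += self._x.T @ dy
        self.g_b += dy.sum(axis=0)
        return dy @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_vjp(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. logits given probabilities and grad w.r.t. probs."""
    inner = np.sum(dp * p, axis=-1, keepdims=True)
    return p * (dp - inner)


# ----------------------------------------------------------------------
# model


class ConvMixerNet:
    """The backbone plus two category-distribution heads.

    Fully convolutional with global average pooling, so the trainable
    parameter count does not depend on the input side length.
    """

    def __init__(self, arch: ArchConfig, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        F = arch.filters
        self.stem = PatchEmbed(arch.in_channels, F, arch.patch_size, rng)
        self.stem_act = GELU()
        self.stem_bn = BatchNorm(F)
        self.blocks = []
        for _ in range(arch.depth):
            self.blocks.append(
                {
                    "dw": DepthwiseConv(F, arch.kernel_size, rng),
                    "dw_act": GELU(),
                    "dw_bn": BatchNorm(F),
                    "pw": PointwiseConv(F, F, rng),
                    "pw_act": GELU(),
                    "pw_bn": BatchNorm(F),
                }
            )
        self.head_pvi = Dense(F, arch.n_outputs, rng)
        self.head_bepvi = Dense(F, arch.n_outputs, rng)

    # -- plumbing -------------------------------------------------------
    def _layers(self):
        yield self.stem
        yield self.stem_act
        yield self.stem_bn
        for blk in self.blocks:
            yield from blk.values()
        yield self.head_pvi
        yield self.head_bepvi

    def zero_grad(self):
        for layer in self._layers():
            layer.zero_grad()

    def param_pairs(self):
        pairs = []
        for layer in self._layers():
            pairs.extend(layer.param_pairs())
        return pairs

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.param_pairs()))

    # -- forward / backward ----------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False):
        """Logit pair for a (B, 12, S, S) batch; caches for backward."""
        if x.ndim != 4 or x.shape[1] != self.arch.in_channels:
            raise InputError(
                f"expected (B, {self.arch.in_channels}, S, S) input, got {x.shape}"
            )
        h = self.stem.forward(x.astype(np.float32, copy=False))
        h = self.stem_act.forward(h)
        h = self.stem_bn.forward(h, train)
        for blk in self.blocks:
            r = blk["dw"].forward(h)
            r = blk["dw_act"].forward(r)
            r = blk["dw_bn"].forward(r, train)
            h = h + r  # residual over the spatial-mixing branch
            h = blk["pw"].forward(h)
            h = blk["pw_act"].forward(h)
            h = blk["pw_bn"].forward(h, train)
        self._pool_hw = h.shape[2] * h.shape[3]
        feat = h.mean(axis=(2, 3))
        z_pvi = self.head_pvi.forward(feat)
        z_bep = self.head_bepvi.forward(feat)
        return z_pvi, z_bep

    def backward_from_logits(self, dz_pvi: np.ndarray, dz_bep: np.ndarray) -> np.ndarray:
        """Backpropagate to parameters AND back to the input; returns dx."""
        dfeat = self.head_pvi.backward(dz_pvi) + self.head_bepvi.backward(dz_bep)
        B, F = dfeat.shape
        hw = self._pool_hw
        side = int(np.sqrt(hw))
        dh = np.broadcast_to(dfeat[:, :, None, None], (B, F, side, side)) / hw
        dh = np.ascontiguousarray(dh)
        for blk in reversed(self.blocks):
            dh = blk["pw_bn"].backward(dh)
            dh = blk["pw_act"].backward(dh)
            dh = blk["pw"].backward(dh)
            dr = blk["dw_bn"].backward(dh)
            dr = blk["dw_act"].backward(dr)
            dh = dh + blk["dw"].backward(dr)
        dh = self.stem_bn.backward(dh)
        dh = self.stem_act.backward(dh)
        return self.stem.backward(dh)

    def forward(self, x: np.ndarray) -> ModelOutput:
        """Inference-mode probability vectors for a batch of stacks."""
        z_pvi, z_bep = self.forward_logits(x, train=False)
        return ModelOutput(pvi=softmax(z_pvi), bepvi=softmax(z_bep))

    def input_gradients(self, x: np.ndarray, task: str, d_probs: np.ndarray) -> np.ndarray:
        """Gradient of d_probs . p_task with respect to the input stack.

        ``d_probs`` is the (K+2,) gradient of a scalar functional of the
        task's probability vector.  Runs in inference mode; parameter
        gradients accumulated along the way are cleared.
        """
        z_pvi, z_bep = self.forward_logits(x, train=False)
        dz_pvi = np.zeros_like(z_pvi)
        dz_bep = np.zeros_like(z_bep)
        if task == "PVI":
            dz_pvi = softmax_vjp(softmax(z_pvi), np.broadcast_to(d_probs, z_pvi.shape))
        elif task == "bePVI":
            dz_bep = softmax_vjp(softmax(z_bep), np.broadcast_to(d_probs, z_bep.shape))
        else:
            raise InputError(f"unknown task {task!r}")
        dx = self.backward_from_logits(dz_pvi, dz_bep)
        self.zero_grad()
        return dx

    # -- persistence ------------------------------------------------------
    def _state_arrays(self) -> dict:
        state = {}
        for i, layer in enumerate(self._layers()):
            for name in layer.params:
                state[f"l{i}_{name}"] = getattr(layer, name)
            if isinstance(layer, BatchNorm):
                state[f"l{i}_running_mean"] = layer.running_mean
                state[f"l{i}_running_var"] = layer.running_var
        return state

    def save(self, path) -> None:
        buf = io.BytesIO()
        np.savez(buf, **self._state_arrays())
        with open(path, "wb") as fh:
            header = json.dumps(asdict(self.arch)).encode()
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "ConvMixerNet":
        with open(path, "rb") as fh:
            n = int.from_bytes(fh.read(8), "little")
            arch = ArchConfig(**json.loads(fh.read(n).decode()))
            data = np.load(io.BytesIO(fh.read()))
        model = cls(arch, seed=0)
        state = model._state_arrays()
        if set(state) != set(data.files):
            raise ConfigurationError("checkpoint does not match the architecture")
        for i, layer in enumerate(model._layers()):
            for name in layer.params:
                stored = data[f"l{i}_{name}"]
                if stored.shape != getattr(layer, name).shape:
                    raise ConfigurationError("checkpoint does not match the architecture")
                setattr(layer, name, stored.astype(np.float32))
                setattr(layer, "g_" + name, np.zeros_like(stored, dtype=np.float32))
            if isinstance(layer, BatchNorm):
                layer.running_mean = data[f"l{i}_running_mean"].astype(np.float32)
                layer.running_var = data[f"l{i}_running_var"].astype(np.float32)
        return model


def build_model(arch: ArchConfig, seed: int = 0) -> ConvMixerNet:
    """Construct a ConvMixer with deterministic initialization."""
    return ConvMixerNet(arch, seed=seed)


class Adam:
    """Adaptive-moment gradient descent over a model's parameter pairs."""

    def __init__(self, model: ConvMixerNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        pairs = model.param_pairs()
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.model.param_pairs(), self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
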