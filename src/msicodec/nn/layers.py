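"""Minimal 1-D neural network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
releases it on ``backward``.  Parameters and their gradients live in parallel
dicts so the optimizer can iterate them generically.  Shapes follow the
convolution convention ``(batch, channels, length)``.

Strided 1-D convolution is evaluated as a short loop over kernel taps, each
tap a strided matmul; its transpose (used both for the transposed-convolution
layer and for input gradients) is the matching scatter-add.  This keeps the
whole network dependency-free and fast enough for spectra of a few thousand
bins on a single CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Linear",
    "Conv1d",
    "ConvTranspose1d",
    "BatchNorm1d",
    "ReLU",
    "Reshape",
    "Sequential",
]


def _windows(xp: np.ndarray, out_len: int, k: int, stride: int) -> np.ndarray:
    """Strided view (n, c, out_len, k) of sliding windows over the last axis."""
    n, c, _ = xp.shape
    s0, s1, s2 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, out_len, k), strides=(s0, s1, s2 * stride, s2),
        writeable=False,
    )


def conv1d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                   stride: int, padding: int) -> np.ndarray:
    """y[n,o,t] = b[o] + sum_{i,k} W[o,i,k] x[n,i,t*s - p + k]."""
    n, c_in, length = x.shape
    c_out, _, k = weight.shape
    out_len = (length + 2 * padding - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    win = _windows(xp, out_len, k, stride)
    y = np.tensordot(win, weight, axes=([1, 3], [1, 2]))  # (n, t, o)
    y = np.ascontiguousarray(y.transpose(0, 2, 1))
    y += bias[None, :, None]
    return y


def conv1d_input_grad(grad_y: np.ndarray, weight: np.ndarray, stride: int,
                      padding: int, in_len: int) -> np.ndarray:
    """Scatter-add transpose of :func:`conv1d_forward` w.r.t. its input."""
    n, c_out, out_len = grad_y.shape
    _, c_in, k = weight.shape
    buf = np.zeros((n, c_in, in_len + 2 * padding), dtype=grad_y.dtype)
    for tap in range(k):
        contrib = np.matmul(weight[:, :, tap].T, grad_y)  # (i,o) @ (n,o,t)
        buf[:, :, tap: tap + out_len * stride: stride] += contrib
    return buf[:, :, padding: padding + in_len]


def conv1d_weight_grad(x: np.ndarray, grad_y: np.ndarray, k: int, stride: int,
                       padding: int) -> tuple[np.ndarray, np.ndarray]:
    n, c_in, length = x.shape
    _, c_out, out_len = grad_y.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    win = _windows(xp, out_len, k, stride)
    g_w = np.tensordot(grad_y, win, axes=([0, 2], [0, 2]))  # (o, i, k)
    g_b = grad_y.sum(axis=(0, 2))
    return g_w, g_b


class Layer:
    """Base class: parameter dict, gradient dict, forward/backward protocol."""

    def __init__(self, dtype=np.float64) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True
        self.dtype = np.dtype(dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """Arrays to persist (parameters plus any running statistics)."""
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key in self.params:
            self.params[key] = np.asarray(state[key], dtype=self.dtype)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__(dtype)
        self.params["w"] = _kaiming(rng, (out_features, in_features), in_features, dtype)
        self.params["b"] = np.zeros(out_features, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        out = grad @ self.params["w"]
        del self._x
        return out


class Conv1d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int,
                 padding: int, rng: np.random.Generator, dtype=np.float64):
        super().__init__(dtype)
        self.stride, self.padding, self.k = stride, padding, kernel_size
        self.params["w"] = _kaiming(rng, (c_out, c_in, kernel_size), c_in * kernel_size,
                                    dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def out_length(self, in_len: int) -> int:
        return (in_len + 2 * self.padding - self.k) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return conv1d_forward(x, self.params["w"], self.params["b"],
                              self.stride, self.padding)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"], self.grads["b"] = conv1d_weight_grad(
            self._x, grad, self.k, self.stride, self.padding)
        out = conv1d_input_grad(grad, self.params["w"], self.stride,
                                self.padding, self._x.shape[2])
        del self._x
        return out


class ConvTranspose1d(Layer):
    """Transposed convolution; the adjoint of :class:`Conv1d`.

    Weight shape ``(c_in, c_out, k)``.  Output length is
    ``(L - 1) * stride - 2 * padding + k + output_padding``.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int,
                 padding: int, output_padding: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__(dtype)
        if output_padding >= stride:
            raise ValueError("output_padding must be smaller than stride")
        self.stride, self.padding, self.k = stride, padding, kernel_size
        self.output_padding = output_padding
        self.params["w"] = _kaiming(rng, (c_in, c_out, kernel_size), c_in * kernel_size,
                                    dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def out_length(self, in_len: int) -> int:
        return (in_len - 1) * self.stride - 2 * self.padding + self.k + self.output_padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c_in, in_len = x.shape
        out_len = self.out_length(in_len)
        buf_len = (in_len - 1) * self.stride + self.k
        buf = np.zeros((n, self.params["b"].size, max(buf_len, out_len + 2 * self.padding)),
                       dtype=x.dtype)
        for tap in range(self.k):
            contrib = np.matmul(self.params["w"][:, :, tap].T, x)  # (o,i) @ (n,i,t)
            buf[:, :, tap: tap + in_len * self.stride: self.stride] += contrib
        y = buf[:, :, self.padding: self.padding + out_len]
        return y + self.params["b"][None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, c_in, in_len = x.shape
        out_len = grad.shape[2]
        # pad grad so gather positions t*s - p + k exist for all taps
        gp = np.pad(grad, ((0, 0), (0, 0), (self.padding, self.padding)))
        extra = (in_len - 1) * self.stride + self.k - gp.shape[2]
        if extra > 0:
            gp = np.pad(gp, ((0, 0), (0, 0), (0, extra)))
        win = _windows(gp, in_len, self.k, self.stride)  # (n, o, t_in, k)
        g_w = np.tensordot(x, win, axes=([0, 2], [0, 2]))  # (i, o, k)
        # g_x[n,i,t] = sum_{o,k} W[i,o,k] * win[n,o,t,k]
        g_x = np.tensordot(win, self.params["w"], axes=([1, 3], [1, 2]))  # (n, t, i)
        g_x = np.ascontiguousarray(g_x.transpose(0, 2, 1))
        self.grads["w"] = g_w
        self.grads["b"] = grad.sum(axis=(0, 2))
        del self._x
        return g_x


class BatchNorm1d(Layer):
    """Per-feature normalization to zero mean / unit variance over the batch.

    Works on ``(batch, features)`` and ``(batch, channels, length)`` input;
    for the latter, statistics pool over batch and length.  Inference uses
    exponential running statistics accumulated during training.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        super().__init__(dtype)
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(num_features, dtype=dtype)
        self.params["beta"] = np.zeros(num_features, dtype=dtype)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def _axes(self, x: np.ndarray):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        return v[None, :] if x.ndim == 2 else v[None, :, None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = self._axes(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - self._shape(x, mean)) * self._shape(x, self._inv_std)
        return self._shape(x, self.params["gamma"]) * self._xhat + self._shape(x, self.params["beta"])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = self._axes(grad)
        m = np.prod([grad.shape[a] for a in axes])
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self._shape(grad, self.params["gamma"])
        if self.training:
            mean_g = g.mean(axis=axes)
            mean_gx = (g * self._xhat).mean(axis=axes)
            out = (g - self._shape(g, mean_g) - self._xhat * self._shape(g, mean_gx)) \
                * self._shape(g, self._inv_std)
        else:
            out = g * self._shape(g, self._inv_std)
        del self._xhat
        return out

    def state(self) -> dict[str, np.ndarray]:
        s = dict(self.params)
        s["running_mean"] = self.running_mean
        s["running_var"] = self.running_var
        return s

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        super().load_state(state)
        self.running_mean = np.asarray(state["running_mean"], dtype=self.dtype)
        self.running_var = np.asarray(state["running_var"], dtype=self.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        del self._mask
        return out


class Reshape(Layer):
    """Static reshape of the non-batch dimensions."""

    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape[1:]
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape((grad.shape[0],) + self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def set_training(self, training: bool) -> None:
        for layer in self.layers:
            layer.training = training
            if isinstance(layer, Sequential):
                layer.set_training(training)

    def parameter_items(self):
        """Yield (unique key, layer, name) for every trainable parameter."""
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                for key, sub, name in layer.parameter_items():
                    yield f"{i}.{key}", sub, name
            else:
                for name in layer.params:
                    yield f"{i}.{name}", layer, name

    def state(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for key, arr in layer.state().items():
                out[f"{i}.{key}"] = arr
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            prefix = f"{i}."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            layer.load_state(sub)
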