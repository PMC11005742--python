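"""Sequential container and parameter bookkeeping."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def train(self, mode: bool = True):
        for layer in self.layers:
            layer.train(mode)

    def _walk(self):
        from .layers import Residual

        for i, layer in enumerate(self.layers):
            if isinstance(layer, Residual):
                for j, inner in enumerate(layer.inner.layers):
                    yield f"{i}.{j}", inner
            else:
                yield str(i), layer

    def named_params(self):
        """Yield (name, params-dict, grads-dict) for every parameterised layer."""
        for name, layer in self._walk():
            if layer.params:
                yield name, layer.params, layer.grads

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._walk():
            for k, v in layer.params.items():
                out[f"{name}.{k}"] = v.copy()
            if hasattr(layer, "running_mean"):
                out[f"{name}.running_mean"] = layer.running_mean.copy()
                out[f"{name}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, layer in self._walk():
            for k in layer.params:
                layer.params[k][...] = state[f"{name}.{k}"]
            if hasattr(layer, "running_mean"):
                layer.running_mean[...] = state[f"{name}.running_mean"]
                layer.running_var[...] = state[f"{name}.running_var"]
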