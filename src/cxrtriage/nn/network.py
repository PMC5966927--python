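"""Sequential network assembled from :class:`~cxrtriage.architecture.LayerSpec`."""

from __future__ import annotations

import io
import json

import numpy as np

from ..architecture import LayerSpec, output_shapes
from .layers import BatchNorm, Conv2D, Dense, Dropout, Layer, MaxPool2D, Upsample2D


class Network:
    """Ordered runtime layers plus the architecture they realise.

    ``tagged`` maps a LayerSpec tag (e.g. ``"bottleneck"``) to the index of
    the runtime layer whose *output* carries that tag, letting training
    loops attach activation penalties at marked points.
    """

    def __init__(self, arch: list[LayerSpec], layers: list[Layer], tagged: dict[str, int]):
        self.arch = arch
        self.layers = layers
        self.tagged = tagged

    def forward(self, x: np.ndarray, train: bool = False,
                record: dict[int, np.ndarray] | None = None) -> np.ndarray:
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if record is not None and i in record:
                record[i] = x
        return x

    def backward(self, dout: np.ndarray,
                 inject: dict[int, np.ndarray] | None = None) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if inject and i in inject:
                dout = dout + inject[i]
            dout = self.layers[i].backward(dout)
        return dout

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def weight_matrices(self) -> list[np.ndarray]:
        """Multi-dimensional weights only (for L1/L2 penalties)."""
        return [p for layer in self.layers for p in layer.params if p.ndim > 1]

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_p{j}"] = p
            if isinstance(layer, BatchNorm):
                arrays[f"layer{i}_rmean"] = layer.running_mean
                arrays[f"layer{i}_rvar"] = layer.running_var
        return arrays

    def save(self, path) -> None:
        """Single-file archive: architecture JSON + weight blobs."""
        arch_json = json.dumps([spec.__dict__ for spec in self.arch])
        np.savez(path, __arch__=np.frombuffer(arch_json.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as data:
            arch_json = bytes(data["__arch__"]).decode()
            arch = [LayerSpec(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in d.items()})
                    for d in json.loads(arch_json)]
            net = build_network(arch, np.random.default_rng(0))
            for i, layer in enumerate(net.layers):
                for j, p in enumerate(layer.params):
                    p[...] = data[f"layer{i}_p{j}"]
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = data[f"layer{i}_rmean"]
                    layer.running_var[...] = data[f"layer{i}_rvar"]
        return net


def build_network(arch: list[LayerSpec], rng: np.random.Generator) -> Network:
    """Instantiate runtime layers for an architecture (seeded weight init)."""
    shapes = output_shapes(arch)
    layers: list[Layer] = []
    tagged: dict[str, int] = {}
    for spec, in_shape in zip(arch[1:], shapes[:-1]):
        if spec.kind == "conv2d":
            layers.append(Conv2D(in_shape[2], spec.filters, spec.activation, rng,
                                 kernel=spec.kernel))
        elif spec.kind == "maxpool2d":
            layers.append(MaxPool2D())
        elif spec.kind == "upsample2d":
            layers.append(Upsample2D())
        elif spec.kind == "dense":
            layers.append(Dense(in_shape[0], spec.units, spec.activation, rng))
        elif spec.kind == "batchnorm":
            layers.append(BatchNorm(in_shape[-1]))
        elif spec.kind == "dropout":
            layers.append(Dropout(spec.rate, rng))
        if spec.tag:
            tagged[spec.tag] = len(layers) - 1
    return Network(arch, layers, tagged)
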