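"""Layer descriptors with deterministic shape and parameter-count semantics.

The two fixed architectures of the pipeline — the convolutional sparse
denoising autoencoder (CSDAE) and the feed-forward classification head —
are expressed as ordered lists of :class:`LayerSpec`.  Shapes and parameter
counts are derivable without instantiating any weights, which makes the
printed architecture tables checkable facts rather than framework output.

Conventions: convolutions are 3x3, same-padded, stride 1; pools and
upsamples are 2x2; parameter counts follow the usual dense-framework rules
(conv: (kh*kw*c_in + 1)*filters, dense: (in + 1)*units, batchnorm:
4*channels counting the running statistics, everything else: 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field


_KINDS = {"input", "conv2d", "maxpool2d", "upsample2d", "dense", "batchnorm", "dropout"}


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a feed-forward architecture.

    Parameters
    ----------
    kind:
        One of ``input``, ``conv2d``, ``maxpool2d``, ``upsample2d``,
        ``dense``, ``batchnorm``, ``dropout``.
    filters:
        Output channels (conv2d only).
    units:
        Output width (dense / 1-D input only).
    rate:
        Dropout rate (dropout only).
    activation:
        ``relu``, ``sigmoid`` or ``linear`` for conv2d/dense layers.
    shape:
        For ``input`` layers: the input shape, either ``(H, W, C)`` or
        ``(D,)``.
    tag:
        Free-form marker; the CSDAE tags its bottleneck pool so the
        sparsity penalty knows where to attach.
    """

    kind: str
    filters: int | None = None
    units: int | None = None
    rate: float | None = None
    activation: str = "linear"
    shape: tuple[int, ...] | None = None
    tag: str | None = None
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


def output_shapes(layers: list[LayerSpec]) -> list[tuple[int, ...]]:
    """Propagate shapes through the stack; raises on inconsistency."""
    if not layers or layers[0].kind != "input" or layers[0].shape is None:
        raise ValueError("architecture must start with an input layer carrying a shape")
    shapes: list[tuple[int, ...]] = [tuple(layers[0].shape)]
    cur = shapes[0]
    for spec in layers[1:]:
        if spec.kind == "conv2d":
            if len(cur) != 3:
                raise ValueError("conv2d requires a (H, W, C) input")
            cur = (cur[0], cur[1], int(spec.filters))
        elif spec.kind == "maxpool2d":
            if len(cur) != 3 or cur[0] % 2 or cur[1] % 2:
                raise ValueError(f"maxpool2d needs even spatial dims, got {cur}")
            cur = (cur[0] // 2, cur[1] // 2, cur[2])
        elif spec.kind == "upsample2d":
            if len(cur) != 3:
                raise ValueError("upsample2d requires a (H, W, C) input")
            cur = (cur[0] * 2, cur[1] * 2, cur[2])
        elif spec.kind == "dense":
            if len(cur) != 1:
                raise ValueError("dense requires a flat input")
            cur = (int(spec.units),)
        elif spec.kind in ("batchnorm", "dropout"):
            pass
        elif spec.kind == "input":
            raise ValueError("input layer allowed only at position 0")
        shapes.append(cur)
    return shapes


def count_parameters(layers: list[LayerSpec]) -> list[int]:
    """Per-layer trainable+statistic parameter counts (framework convention).

    Conv counts are independent of spatial size (weight sharing); batchnorm
    counts the scale, shift and two running statistics (4 per channel).
    """
    shapes = output_shapes(layers)
    counts: list[int] = []
    for spec, in_shape in zip(layers, [None] + shapes[:-1]):
        if spec.kind == "conv2d":
            c_in = in_shape[2]
            counts.append((spec.kernel * spec.kernel * c_in + 1) * spec.filters)
        elif spec.kind == "dense":
            counts.append((in_shape[0] + 1) * spec.units)
        elif spec.kind == "batchnorm":
            counts.append(4 * in_shape[-1])
        else:
            counts.append(0)
    return counts


def csdae_architecture(side: int = 512) -> list[LayerSpec]:
    """The CSDAE encoder-decoder: 16-8-8 / 8-8-16 channel plan, 3x3 convs.

    Three 2x2 pools reduce ``side`` to ``side/8`` at the 8-channel
    bottleneck; three upsamples restore it.  The final conv maps back to a
    single channel through a sigmoid so outputs live in [0, 1].  ``side``
    must be divisible by 8.
    """
    if side % 8:
        raise ValueError(f"side must be divisible by 8, got {side}")
    return [
        LayerSpec("input", shape=(side, side, 1)),
        LayerSpec("conv2d", filters=16, activation="relu"),
        LayerSpec("maxpool2d"),
        LayerSpec("conv2d", filters=8, activation="relu"),
        LayerSpec("maxpool2d"),
        LayerSpec("conv2d", filters=8, activation="relu"),
        LayerSpec("maxpool2d", tag="bottleneck"),
        LayerSpec("conv2d", filters=8, activation="relu"),
        LayerSpec("upsample2d"),
        LayerSpec("conv2d", filters=8, activation="relu"),
        LayerSpec("upsample2d"),
        # 8 -> 16 filters here: reproduces the printed 1168-parameter count
        # and the 16-channel shape entering the last upsample.
        LayerSpec("conv2d", filters=16, activation="relu"),
        LayerSpec("upsample2d"),
        LayerSpec("conv2d", filters=1, activation="sigmoid"),
    ]


def head_architecture(input_dim: int = 512, dropout_rate: float = 0.25) -> list[LayerSpec]:
    """The classification head on 512-dim transfer features.

    Three (batchnorm, dropout, dense) blocks; the two hidden dense layers
    keep the 512 width, the final dense maps to a single sigmoid unit whose
    output is the abnormality probability C1.
    """
    return [
        LayerSpec("input", shape=(input_dim,)),
        LayerSpec("batchnorm"),
        LayerSpec("dropout", rate=dropout_rate),
        LayerSpec("dense", units=512, activation="relu"),
        LayerSpec("batchnorm"),
        LayerSpec("dropout", rate=dropout_rate),
        LayerSpec("dense", units=512, activation="relu"),
        LayerSpec("batchnorm"),
        LayerSpec("dropout", rate=dropout_rate),
        LayerSpec("dense", units=1, activation="sigmoid"),
    ]
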