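"""Architecture configurations, complexity calculus, layer planning and
parameter counting for AID-U-Net.

An AID-U-Net is a U-Net-style encoder/decoder whose direct contracting path
descends ``K`` levels and whose decoder is preceded by a nested excursion: a
sub-expansive path rising ``d`` levels from the bottleneck and a paired
sub-contracting path descending back to level ``K``.  ``d = 0`` degenerates
to a conventional U-Net of depth ``K``.

Everything in this module is closed-form: no tensors are allocated.  The
:class:`LayerGraph` produced by :func:`plan_layers` is the single source of
truth from which both the runnable model (``aidunet.network``) and the
learnable-parameter count (:func:`count_parameters`) derive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "ArchConfig",
    "ComplexitySummary",
    "BlockSpec",
    "LayerSpec",
    "LayerGraph",
    "complexity_unet",
    "complexity_aid",
    "plan_layers",
    "count_parameters",
]

CONV_KERNEL = 3  # spatial extent of every in-block convolution, same padding
UPCONV_KERNEL = 2  # transposed-convolution kernel, stride 2


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchConfig:
    """Complete specification of one AID-U-Net instance.

    Parameters
    ----------
    direct_depth:
        ``K``, the number of down-sampling steps on the direct contracting
        path (also the number of up-sampling steps on the direct expansive
        path).
    sub_depth:
        ``d``, the depth of the nested sub-expansive/sub-contracting
        excursion; must satisfy ``0 <= d <= K``.  ``d = 0`` yields a
        conventional U-Net of depth ``K``.
    filter_factor:
        Exponent ``N_f``; the top level carries ``2**N_f`` filters and the
        count doubles at each contracting step.
    dims:
        Spatial dimensionality, 2 or 3.
    in_channels:
        Channels of one input patch (e.g. 3 for RGB, 4 for multi-modal
        volumes).
    num_classes:
        Segmentation classes, at least 2.
    input_extent:
        Per-axis spatial size of one patch.  Every axis must be divisible by
        ``2**K`` so each 2x2 max-pool acts on even axes.
    dropout_rate:
        Dropout probability applied at the end of each block, in [0, 1).
    """

    direct_depth: int
    sub_depth: int = 0
    filter_factor: int = 5
    dims: int = 2
    in_channels: int = 3
    num_classes: int = 2
    input_extent: tuple[int, ...] = (256, 256)
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.direct_depth < 1:
            raise ValueError("direct_depth K must be a positive integer")
        if self.sub_depth < 0:
            raise ValueError("sub_depth d must be non-negative")
        if self.sub_depth > self.direct_depth:
            raise ValueError(
                f"sub-path depth d={self.sub_depth} exceeds the direct-path "
                f"depth K={self.direct_depth}; the admissible range of "
                "sub-path lengths has maximum K"
            )
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.filter_factor < 1:
            raise ValueError("filter_factor N_f must be positive")
        if self.in_channels < 1:
            raise ValueError("in_channels must be positive")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        extent = tuple(int(e) for e in self.input_extent)
        object.__setattr__(self, "input_extent", extent)
        if len(extent) != self.dims:
            raise ValueError(
                f"input_extent has {len(extent)} axes but dims={self.dims}"
            )
        step = 2 ** self.direct_depth
        for axis, e in enumerate(extent):
            if e <= 0 or e % step:
                raise ValueError(
                    f"input_extent axis {axis} ({e}) is not divisible by "
                    f"2**K = {step}"
                )

    def filters(self, level: int) -> int:
        """Filter count at depth ``level`` (level 0 = top): ``2**(N_f + level)``."""
        return 2 ** (self.filter_factor + level)


# ---------------------------------------------------------------------------
# Complexity calculus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexitySummary:
    """Worst-case complexity order split into its two geometric sums.

    ``s1`` sums ``2**n`` over the direct path (n = 0..K), ``s2`` over the
    sub-path levels (n = K-d..K); ``order = s1 + s2``.
    """

    s1: int
    s2: int

    @property
    def order(self) -> int:
        return self.s1 + self.s2


def complexity_unet(depth: int) -> int:
    """Worst-case complexity order of a conventional U-Net.

    The per-level work forms a geometric sequence with first term 1 and ratio
    2, so a network of contracting depth ``depth`` has order
    ``2**(depth + 1) - 1``.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return 2 ** (depth + 1) - 1


def complexity_aid(direct_depth: int, sub_depth: int) -> ComplexitySummary:
    """Worst-case complexity order of an AID-U-Net(K, d).

    The direct path contributes ``S1 = 2**(K+1) - 1`` and the sub-path
    excursion over levels ``K-d..K`` contributes ``S2 = 2**(K+1) - 2**(K-d)``,
    for a total order ``2**(K+2) - 2**(K-d) - 1``.  For equal total depth
    ``K + d = N`` this is strictly below the conventional U-Net order
    whenever ``d >= 1``.
    """
    if direct_depth < 1:
        raise ValueError("direct_depth K must be positive")
    if sub_depth < 0:
        raise ValueError("sub_depth d must be non-negative")
    if sub_depth > direct_depth:
        raise ValueError(
            f"sub-path depth d={sub_depth} exceeds direct-path depth "
            f"K={direct_depth}; sub-paths are limited to length K"
        )
    k, d = direct_depth, sub_depth
    s1 = 2 ** (k + 1) - 1
    s2 = 2 ** (k + 1) - 2 ** (k - d)
    return ComplexitySummary(s1=s1, s2=s2)


# ---------------------------------------------------------------------------
# Layer planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One learnable layer inside a block.

    ``kind`` is ``conv`` (3x3/3x3x3 same padding, stride 1), ``upconv``
    (2-kernel stride-2 transposed convolution) or ``head`` (1-kernel
    convolution to class scores).  ``batch_norm`` marks a trainable
    normalization (one gamma/beta pair per output channel) immediately after
    the layer.
    """

    kind: str
    kernel: int
    in_channels: int
    out_channels: int
    batch_norm: bool = False

    def parameter_count(self, dims: int) -> int:
        n = self.kernel ** dims * self.in_channels * self.out_channels
        n += self.out_channels  # bias
        if self.batch_norm:
            n += 2 * self.out_channels  # gamma, beta
        return n


@dataclass(frozen=True)
class BlockSpec:
    """One planned block of the network graph.

    ``role`` is one of ``contract``, ``sub-expand``, ``sub-contract``,
    ``expand``, ``head``.  Connection fields hold indices into the graph's
    block list (``None`` where not applicable): ``pool_from`` (input arrives
    through a 2x max-pool), ``upconv_from`` (input arrives through the
    block's transposed convolution) and ``concat_with`` (skip source whose
    output is concatenated, channel-wise, with the up-convolved input).
    """

    index: int
    role: str
    level: int
    filters: int
    layers: tuple[LayerSpec, ...]
    pool_from: int | None = None
    upconv_from: int | None = None
    concat_with: int | None = None

    @property
    def layer_count(self) -> int:
        """Primitive layers in the block (convs, norms, activations, dropout,
        pool/up-conv/concat connectors)."""
        n = 0
        if self.pool_from is not None:
            n += 1
        if self.concat_with is not None:
            n += 1
        for spec in self.layers:
            n += 1  # conv / upconv itself
            if spec.batch_norm:
                n += 1
            if spec.kind == "conv":
                n += 1  # ReLU
        if self.role != "head":
            n += 1  # dropout
        else:
            n += 1  # softmax
        return n


@dataclass(frozen=True)
class LayerGraph:
    """The planned block graph of one AID-U-Net instance."""

    config: ArchConfig
    blocks: tuple[BlockSpec, ...]

    @property
    def total_layer_count(self) -> int:
        return sum(b.layer_count for b in self.blocks)

    def level_sequence(self) -> list[int]:
        """Depth index of every block in execution order (head excluded)."""
        return [b.level for b in self.blocks if b.role != "head"]

    def iter_layers(self) -> Iterator[LayerSpec]:
        for block in self.blocks:
            yield from block.layers

    def to_dict(self) -> dict:
        return {
            "config": {
                "direct_depth": self.config.direct_depth,
                "sub_depth": self.config.sub_depth,
                "filter_factor": self.config.filter_factor,
                "dims": self.config.dims,
                "in_channels": self.config.in_channels,
                "num_classes": self.config.num_classes,
                "input_extent": list(self.config.input_extent),
                "dropout_rate": self.config.dropout_rate,
            },
            "blocks": [
                {
                    "index": b.index,
                    "role": b.role,
                    "level": b.level,
                    "filters": b.filters,
                    "pool_from": b.pool_from,
                    "upconv_from": b.upconv_from,
                    "concat_with": b.concat_with,
                    "layers": [
                        {
                            "kind": s.kind,
                            "kernel": s.kernel,
                            "in_channels": s.in_channels,
                            "out_channels": s.out_channels,
                            "batch_norm": s.batch_norm,
                        }
                        for s in b.layers
                    ],
                }
                for b in self.blocks
            ],
            "total_layer_count": self.total_layer_count,
            "parameter_count": count_parameters(self),
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _conv_pair(in_ch: int, out_ch: int) -> tuple[LayerSpec, LayerSpec]:
    # Two same-padded convolutions; the initial one is followed by batch
    # normalization (this single-norm-per-block convention reproduces the
    # published parameter counts of the reference configurations).
    return (
        LayerSpec("conv", CONV_KERNEL, in_ch, out_ch, batch_norm=True),
        LayerSpec("conv", CONV_KERNEL, out_ch, out_ch, batch_norm=False),
    )


def plan_layers(config: ArchConfig) -> LayerGraph:
    """Plan the block graph for ``config``.

    Traversal of depth levels: ``0 -> K`` on the direct contracting path,
    ``K -> K-d`` on the sub-expansive path, ``K-d -> K`` on the
    sub-contracting path, then ``K -> 0`` on the direct expansive path,
    followed by the 1-kernel classification head.  Every expansive block
    (sub- or direct) concatenates the same-level direct contracting block's
    output with its up-convolved input; the direct expansive path starts
    from the sub-contracting output at level ``K`` (the bottleneck itself
    feeds the decoder only through the sub-excursion when ``d > 0``).
    """
    k, d = config.direct_depth, config.sub_depth
    blocks: list[BlockSpec] = []
    contract_at_level: dict[int, int] = {}

    def add(block: BlockSpec) -> int:
        blocks.append(block)
        return block.index

    prev = None
    # Direct contracting path: levels 0..K (level K is the bottleneck block).
    for level in range(k + 1):
        f = config.filters(level)
        in_ch = config.in_channels if level == 0 else config.filters(level - 1)
        idx = add(
            BlockSpec(
                index=len(blocks),
                role="contract",
                level=level,
                filters=f,
                layers=_conv_pair(in_ch, f),
                pool_from=prev if level > 0 else None,
            )
        )
        contract_at_level[level] = idx
        prev = idx

    # Sub-expansive path: levels K-1 .. K-d.
    for level in range(k - 1, k - d - 1, -1):
        f = config.filters(level)
        f_below = config.filters(level + 1)
        skip = contract_at_level[level]
        layers = (
            LayerSpec("upconv", UPCONV_KERNEL, f_below, f),
            *_conv_pair(2 * f, f),
        )
        prev = add(
            BlockSpec(
                index=len(blocks),
                role="sub-expand",
                level=level,
                filters=f,
                layers=layers,
                upconv_from=prev,
                concat_with=skip,
            )
        )

    # Sub-contracting path: levels K-d+1 .. K.
    for level in range(k - d + 1, k + 1):
        f = config.filters(level)
        in_ch = config.filters(level - 1)
        prev = add(
            BlockSpec(
                index=len(blocks),
                role="sub-contract",
                level=level,
                filters=f,
                layers=_conv_pair(in_ch, f),
                pool_from=prev,
            )
        )

    # Direct expansive path: levels K-1 .. 0.
    for level in range(k - 1, -1, -1):
        f = config.filters(level)
        f_below = config.filters(level + 1)
        skip = contract_at_level[level]
        layers = (
            LayerSpec("upconv", UPCONV_KERNEL, f_below, f),
            *_conv_pair(2 * f, f),
        )
        prev = add(
            BlockSpec(
                index=len(blocks),
                role="expand",
                level=level,
                filters=f,
                layers=layers,
                upconv_from=prev,
                concat_with=skip,
            )
        )

    # Classification head: 1-kernel convolution to class scores + softmax.
    add(
        BlockSpec(
            index=len(blocks),
            role="head",
            level=0,
            filters=config.num_classes,
            layers=(
                LayerSpec("head", 1, config.filters(0), config.num_classes),
            ),
        )
    )
    return LayerGraph(config=config, blocks=tuple(blocks))


def count_parameters(graph: LayerGraph) -> int:
    """Exact count of trainable scalars in the planned network.

    Counts convolution and transposed-convolution kernels and biases plus
    batch-normalization scale/shift (gamma/beta) pairs; running statistics
    are not trainable and are excluded.
    """
    dims = graph.config.dims
    return sum(spec.parameter_count(dims) for spec in graph.iter_layers())
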