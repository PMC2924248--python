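"""Converging hierarchy of weight-shared SFA nodes.

Each layer tiles the previous layer's feature map with overlapping
square receptive fields on a regular grid.  One node per layer is
trained on patches from *all* grid locations (weight sharing) and then
replicated across the layer, so a single node sees grid_side^2 x T
training samples.  Layers are trained sequentially from the bottom up,
each on the previous layers' outputs for its own stimulus stream.

The default geometry is the full-scale architecture: a 155x155 image
tiled by 10x10 fields with overlap 5 (30x30 nodes), then 4x4 fields
with overlap 2 (14x14), 4x4 with overlap 2 (6x6), and a single top node
over the 6x6 map, whose 64 outputs, ordered by slowness, are the
feature vector handed to the reinforcement learners.  Scaled geometries
that preserve the tiling invariants are first-class configurations for
desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sfa import (
    InvalidInputError,
    NodeSpec,
    SFANode,
    fit_sfa_node_streamed,
)


class ConfigurationError(ValueError):
    """Raised when a layer geometry or hierarchy config is inconsistent."""


@dataclass(frozen=True)
class LayerGeometry:
    """Tiling of a square map by overlapping square receptive fields."""

    prev_side: int
    field_side: int
    overlap: int

    @property
    def stride(self) -> int:
        return self.field_side - self.overlap

    @property
    def grid_side(self) -> int:
        return (self.prev_side - self.field_side) // self.stride + 1


def plan_geometry(prev_side: int, field_side: int, overlap: int) -> LayerGeometry:
    """Validate and build one layer's tiling.

    Requires 0 <= overlap < field_side <= prev_side and that the fields
    cover the previous side exactly: (prev - field) divisible by stride.
    """
    if not (0 <= overlap < field_side <= prev_side):
        raise ConfigurationError(
            f"need 0 <= overlap < field_side <= prev_side, got "
            f"prev={prev_side}, field={field_side}, overlap={overlap}"
        )
    stride = field_side - overlap
    if (prev_side - field_side) % stride != 0:
        raise ConfigurationError(
            f"fields of side {field_side} with stride {stride} do not tile "
            f"side {prev_side} exactly"
        )
    geom = LayerGeometry(prev_side, field_side, overlap)
    assert (geom.grid_side - 1) * geom.stride + geom.field_side == prev_side
    return geom


@dataclass(frozen=True)
class LayerSpec:
    field_side: int
    overlap: int
    node: NodeSpec


@dataclass(frozen=True)
class HierarchyConfig:
    """Full hierarchy description.

    ``samples_lower`` frames train the lower layers and ``samples_upper``
    the remaining ones (``n_lower_layers`` marks the split); the random
    walk generating both streams uses identical parameters.
    """

    image_side: int = 155
    layers: tuple[LayerSpec, ...] = (
        LayerSpec(10, 5, NodeSpec(sfa1_dim=32, sfa2_dim=32)),
        LayerSpec(4, 2, NodeSpec(sfa1_dim=32, sfa2_dim=32)),
        LayerSpec(4, 2, NodeSpec(sfa1_dim=42, sfa2_dim=32)),
        LayerSpec(6, 0, NodeSpec(sfa1_dim=52, sfa2_dim=64)),
    )
    samples_lower: int = 50_000
    samples_upper: int = 200_000
    n_lower_layers: int = 2

    def geometries(self) -> list[LayerGeometry]:
        side = self.image_side
        geoms = []
        for i, layer in enumerate(self.layers):
            try:
                geom = plan_geometry(side, layer.field_side, layer.overlap)
            except ConfigurationError as err:
                raise ConfigurationError(f"layer {i + 1}: {err}") from err
            geoms.append(geom)
            side = geom.grid_side
        if side != 1:
            raise ConfigurationError(
                f"hierarchy does not converge to a single top node (ends at {side}x{side})"
            )
        return geoms

    @property
    def top_output_dim(self) -> int:
        return self.layers[-1].node.sfa2_dim

    def with_criterion(self, criterion: str) -> "HierarchyConfig":
        layers = tuple(
            replace(l, node=replace(l.node, criterion=criterion)) for l in self.layers
        )
        return replace(self, layers=layers)


def desk_config(
    image_side: int = 63,
    samples_lower: int = 10_000,
    samples_upper: int = 10_000,
    top_dim: int = 32,
) -> HierarchyConfig:
    """Three-layer reduced-resolution profile preserving the tiling ratios.

    63x63 image -> 9x9 fields, overlap 3 (10x10 grid) -> 4x4 fields,
    overlap 2 (4x4 grid) -> single top node.
    """
    return HierarchyConfig(
        image_side=image_side,
        layers=(
            LayerSpec(9, 3, NodeSpec(sfa1_dim=32, sfa2_dim=32)),
            LayerSpec(4, 2, NodeSpec(sfa1_dim=32, sfa2_dim=32)),
            LayerSpec(4, 0, NodeSpec(sfa1_dim=32, sfa2_dim=top_dim)),
        ),
        samples_lower=samples_lower,
        samples_upper=samples_upper,
        n_lower_layers=2,
    )


def _as_maps(maps) -> np.ndarray:
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim == 3:  # (T, S, S) raw grayscale -> single channel
        maps = maps[..., None]
    if maps.ndim != 4 or maps.shape[1] != maps.shape[2]:
        raise InvalidInputError(
            f"expected (T, side, side[, channels]) feature maps, got {maps.shape}"
        )
    return maps


def _patch(maps: np.ndarray, geometry: LayerGeometry, row: int, col: int) -> np.ndarray:
    r0, c0 = row * geometry.stride, col * geometry.stride
    f = geometry.field_side
    block = maps[:, r0 : r0 + f, c0 : c0 + f, :]
    # flatten row-major over pixels, channels innermost (serialization contract)
    return block.reshape(maps.shape[0], -1)


def iter_location_series(maps, geometry: LayerGeometry):
    """Yield one (T, field_side^2 * channels) series per grid location, row-major."""
    maps = _as_maps(maps)
    if maps.shape[1] != geometry.prev_side:
        raise InvalidInputError(
            f"map side {maps.shape[1]} does not match geometry side {geometry.prev_side}"
        )
    for row in range(geometry.grid_side):
        for col in range(geometry.grid_side):
            yield _patch(maps, geometry, row, col)


def gather_patches(maps, geometry: LayerGeometry) -> np.ndarray:
    """All receptive-field patches as one sample block.

    Returns (grid_side^2 * T, field_side^2 * channels); locations are
    emitted row-major with each location's T samples contiguous.  For
    fitting SFA statistics use :func:`iter_location_series` so temporal
    differences never cross location boundaries.
    """
    return np.concatenate(list(iter_location_series(maps, geometry)), axis=0)


def apply_node_to_maps(node: SFANode, maps, geometry: LayerGeometry) -> np.ndarray:
    """Apply one shared node at every grid location; returns (T, G, G, out).

    All locations are gathered into one sample block so the node runs as
    a few large matrix products; long sequences are processed in chunks
    to bound the memory of the quadratic expansion.
    """
    maps = _as_maps(maps)
    T, C = maps.shape[0], maps.shape[3]
    g, f = geometry.grid_side, geometry.field_side
    starts = np.arange(g) * geometry.stride
    span = starts[:, None] + np.arange(f)[None, :]  # (g, f)
    rows = span[:, :, None, None]
    cols = span[None, None, :, :]
    from .sfa import expanded_dim

    per_frame = g * g * expanded_dim(node.spec.sfa1_dim) * 8
    chunk = max(1, int(3e8 // max(per_frame, 1)))
    out = np.empty((T, g, g, node.output_dim), dtype=np.float64)
    for t0 in range(0, T, chunk):
        block = maps[t0 : t0 + chunk]
        tb = block.shape[0]
        patches = block[:, rows, cols, :]  # (tb, g, f, g, f, C)
        patches = patches.transpose(0, 1, 3, 2, 4, 5).reshape(tb * g * g, f * f * C)
        out[t0 : t0 + chunk] = node.apply(patches).reshape(tb, g, g, -1)
    return out


@dataclass
class HierarchicalModel:
    """Trained stack of shared nodes; maps an image to its slow-feature vector."""

    config: HierarchyConfig
    nodes: list[SFANode]

    @property
    def output_dim(self) -> int:
        return self.nodes[-1].output_dim

    def forward(self, image, n_out: int | None = None) -> np.ndarray:
        """Project one image; optionally keep only the ``n_out`` slowest outputs."""
        return self.forward_batch(np.asarray(image)[None], n_out=n_out)[0]

    def forward_batch(self, frames, n_out: int | None = None) -> np.ndarray:
        maps = _as_maps(frames)
        if maps.shape[1] != self.config.image_side:
            raise InvalidInputError(
                f"image side {maps.shape[1]} does not match configured "
                f"side {self.config.image_side}"
            )
        for node, geom in zip(self.nodes, self.config.geometries()):
            maps = apply_node_to_maps(node, maps, geom)
        out = maps[:, 0, 0, :]
        if n_out is not None:
            if not (1 <= n_out <= out.shape[1]):
                raise InvalidInputError(f"n_out {n_out} not in [1, {out.shape[1]}]")
            out = out[:, :n_out]
        return out


def train_hierarchy(stream_factory, config: HierarchyConfig, seed: int) -> HierarchicalModel:
    """Train all layers bottom-up with weight sharing.

    ``stream_factory(n_frames, seed)`` must return an (n, side, side)
    image sequence with the random-walk statistics of the environment
    module.  Lower layers train on one stream of ``samples_lower``
    frames, upper layers on a second stream of ``samples_upper`` frames
    generated with identical random-walk parameters.
    """
    geoms = config.geometries()
    nodes: list[SFANode] = []

    def _train_block(layer_indices, n_frames, stream_seed):
        maps = _as_maps(stream_factory(n_frames, stream_seed))
        if maps.shape[0] < n_frames:
            raise InvalidInputError(
                f"stream supplied {maps.shape[0]} frames, need {n_frames}"
            )
        # replay the already-trained layers on this stream
        for node, geom in zip(nodes, [geoms[i] for i in range(len(nodes))]):
            maps = apply_node_to_maps(node, maps, geom)
        for k in layer_indices:
            geom = geoms[k]
            layer = config.layers[k]
            input_dim = geom.field_side**2 * maps.shape[3]
            node = fit_sfa_node_streamed(
                lambda m=maps, g=geom: iter_location_series(m, g),
                input_dim,
                layer.node,
                seed=(int(seed) * 1000003 + k) % (2**31 - 1),
            )
            nodes.append(node)
            if k < len(config.layers) - 1:
                maps = apply_node_to_maps(node, maps, geom)

    n_layers = len(config.layers)
    split = min(config.n_lower_layers, n_layers)
    _train_block(range(split), config.samples_lower, int(seed) % (2**31 - 1))
    if split < n_layers:
        _train_block(
            range(split, n_layers),
            config.samples_upper,
            (int(seed) + 1) % (2**31 - 1),
        )
    return HierarchicalModel(config=config, nodes=nodes)


def substitute_pca(config: HierarchyConfig) -> HierarchyConfig:
    """PCA-baseline variant: identical tiling, expansion, and dimensions,
    but every node ranks components by explained variance instead of
    slowness."""
    return config.with_criterion("variance")


def train_pca_hierarchy(stream_factory, config: HierarchyConfig, seed: int) -> HierarchicalModel:
    return train_hierarchy(stream_factory, substitute_pca(config), seed)
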