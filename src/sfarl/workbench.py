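"""Shared plumbing: seeds, YAML configs, HDF5 model containers, fixtures.

All randomness flows from explicit integer seeds.  A single root seed
is fanned out to independent subsystems by hashing a string label into
a :class:`numpy.random.SeedSequence`, so batch runs get independent but
reproducible streams and no function touches global random state.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .environment import TaskConfig, WorldConfig, watermaze_world, generate_training_stream
from .hierarchy import HierarchicalModel, HierarchyConfig, LayerSpec
from .sfa import LinearSFAModel, NodeSpec, SFANode

CONTAINER_VERSION = 1


class ConfigError(ValueError):
    """Raised with the offending field name when a config is invalid."""


# ---------------------------------------------------------------------------
# seeds


def _label_hash(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def child_seed(root_seed: int, label: str, index: int = 0) -> int:
    """Deterministic sub-seed below 2**31 for a named subsystem."""
    ss = np.random.SeedSequence([int(root_seed), _label_hash(label), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def rng_for(root_seed: int, label: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(root_seed), _label_hash(label), int(index)])
    )


# ---------------------------------------------------------------------------
# configuration files


_CONFIG_TYPES = {"world": WorldConfig, "task": TaskConfig}


def save_config(path, world: WorldConfig | None = None, task: TaskConfig | None = None) -> None:
    doc = {}
    if world is not None:
        doc["world"] = asdict(world)
    if task is not None:
        doc["task"] = asdict(task)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> dict:
    """Load a YAML config; defaults fill missing fields, bad fields raise.

    Returns {"world": WorldConfig, "task": TaskConfig} for the sections
    present in the file.  Unknown fields and constraint violations raise
    :class:`ConfigError` naming the field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {}
    for section, cls in _CONFIG_TYPES.items():
        if section not in doc:
            continue
        entries = doc[section] or {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key in entries:
            if key not in known:
                raise ConfigError(f"{section}.{key}: unknown field")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in entries.items()
        }
        try:
            out[section] = cls(**coerced)
        except ValueError as err:
            raise ConfigError(f"{section}.{err}") from err
    return out


# ---------------------------------------------------------------------------
# model containers


def _write_linear(group: h5py.Group, model: LinearSFAModel) -> None:
    group.create_dataset("input_mean", data=model.input_mean)
    group.create_dataset("projection", data=model.projection)
    group.create_dataset("delta_values", data=model.delta_values)
    group.attrs["criterion"] = model.criterion


def _read_linear(group: h5py.Group) -> LinearSFAModel:
    return LinearSFAModel(
        input_mean=group["input_mean"][...],
        projection=group["projection"][...],
        delta_values=group["delta_values"][...],
        criterion=str(group.attrs["criterion"]),
    )


def save_model(model: HierarchicalModel, path) -> None:
    """Write a trained hierarchy to an HDF5 container (bit-exact round trip)."""
    cfg = model.config
    with h5py.File(path, "w") as fh:
        fh.attrs["container_version"] = CONTAINER_VERSION
        fh.attrs["image_side"] = cfg.image_side
        fh.attrs["samples_lower"] = cfg.samples_lower
        fh.attrs["samples_upper"] = cfg.samples_upper
        fh.attrs["n_lower_layers"] = cfg.n_lower_layers
        for i, (layer, node) in enumerate(zip(cfg.layers, model.nodes)):
            g = fh.create_group(f"layer{i}")
            g.attrs["field_side"] = layer.field_side
            g.attrs["overlap"] = layer.overlap
            spec = node.spec
            g.attrs["sfa1_dim"] = spec.sfa1_dim
            g.attrs["sfa2_dim"] = spec.sfa2_dim
            g.attrs["noise_variance"] = spec.noise_variance
            g.attrs["clip_bound"] = -1.0 if spec.clip_bound is None else spec.clip_bound
            g.attrs["criterion"] = spec.criterion
            _write_linear(g.create_group("sfa1"), node.sfa1)
            _write_linear(g.create_group("sfa2"), node.sfa2)


def load_model(path) -> HierarchicalModel:
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("container_version", -1))
        if version != CONTAINER_VERSION:
            raise ConfigError(
                f"container_version: expected {CONTAINER_VERSION}, found {version}"
            )
        layer_keys = sorted(
            (k for k in fh if k.startswith("layer")), key=lambda k: int(k[5:])
        )
        layers, nodes = [], []
        for key in layer_keys:
            g = fh[key]
            clip = float(g.attrs["clip_bound"])
            spec = NodeSpec(
                sfa1_dim=int(g.attrs["sfa1_dim"]),
                sfa2_dim=int(g.attrs["sfa2_dim"]),
                noise_variance=float(g.attrs["noise_variance"]),
                clip_bound=None if clip < 0 else clip,
                criterion=str(g.attrs["criterion"]),
            )
            layers.append(
                LayerSpec(int(g.attrs["field_side"]), int(g.attrs["overlap"]), spec)
            )
            nodes.append(
                SFANode(spec=spec, sfa1=_read_linear(g["sfa1"]), sfa2=_read_linear(g["sfa2"]))
            )
        config = HierarchyConfig(
            image_side=int(fh.attrs["image_side"]),
            layers=tuple(layers),
            samples_lower=int(fh.attrs["samples_lower"]),
            samples_upper=int(fh.attrs["samples_upper"]),
            n_lower_layers=int(fh.attrs["n_lower_layers"]),
        )
    return HierarchicalModel(config=config, nodes=nodes)


# ---------------------------------------------------------------------------
# frame export


def save_frames_png(frames, directory) -> list:
    """Write a frame sequence as 8-bit grayscale PNGs (frame_00000.png, ...)."""
    try:
        from PIL import Image
    except ImportError as err:  # pragma: no cover
        raise ImportError("PNG export needs pillow (install the 'plot' extra)") from err
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(frames)):
        img = Image.fromarray((np.clip(frame, 0, 1) * 255).astype(np.uint8), mode="L")
        path = directory / f"frame_{i:05d}.png"
        img.save(path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# fixture streams


def make_fixture_stream(kind: str, n: int, seed: int, resolution: int = 31):
    """Tiny deterministic image sequences for unit tests.

    kinds: "watermaze" (single non-rotated fish), "variable_targets"
    (fish + cross + disk with identity switching), "single-latent"
    (the only slow variable is the agent's x-position; the latent
    trajectory is returned alongside the frames).

    Returns (frames, info) where info holds the per-frame world states
    and, for "single-latent", the latent under ``info["latent"]``.
    """
    rng = rng_for(seed, f"fixture-{kind}")
    if kind == "watermaze":
        cfg = watermaze_world(resolution)
        frames, states = generate_training_stream(n, cfg, rng, return_states=True)
        return frames, {"states": states, "world": cfg}
    if kind == "variable_targets":
        cfg = WorldConfig(resolution=resolution)
        frames, states = generate_training_stream(n, cfg, rng, return_states=True)
        return frames, {"states": states, "world": cfg}
    if kind == "single-latent":
        cfg = watermaze_world(resolution)
        frames, states = generate_training_stream(n, cfg, rng, return_states=True)
        # freeze the y coordinate so x-position is the only slow latent
        from .environment import render

        latent = np.empty(n)
        for t, st in enumerate(states):
            st.agent_pos[1] = 0.0
            frames[t] = render(st, cfg)
            latent[t] = st.agent_pos[0]
        return frames, {"states": states, "world": cfg, "latent": latent}
    raise ConfigError(f"kind: unknown fixture kind {kind!r}")
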