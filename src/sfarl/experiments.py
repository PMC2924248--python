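"""Experiment orchestration: training runs, baselines, and their metrics.

The water-maze run trains the population Q-learner on the slowest
hierarchy outputs and reports per-episode escape latencies plus a
navigation map of greedy movement directions.  The variable-targets run
trains two branch neurons (forward speed, logistic soma; angular
velocity, tanh soma) in parallel batched traces and reports smoothed
reward and latency curves.  Baseline arms swap in PCA features, the
point-neuron network, or the hand-crafted state vector while sharing
every other code path.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .agents import (
    BranchNeuron,
    QPopulation,
    RewardFilter,
    SimpleNetwork,
    batch_step,
    branch_forward,
    pg_update,
    population_direction,
    simple_forward,
    simple_update,
)
from .environment import (
    TaskConfig,
    WorldConfig,
    WorldState,
    init_episode,
    render,
    variable_targets_step,
    watermaze_step,
    watermaze_world,
    generate_training_stream,
)
from .hierarchy import (
    HierarchicalModel,
    desk_config,
    train_hierarchy,
    train_pca_hierarchy,
)
from .workbench import child_seed, rng_for


# ---------------------------------------------------------------------------
# metrics


def smooth_curve(raw, window: int) -> np.ndarray:
    """Non-overlapping block means; a trailing partial block is dropped."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    n_blocks = raw.size // window
    if n_blocks == 0:
        raise ValueError(f"series of length {raw.size} shorter than window {window}")
    return raw[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)


def plateau_episode(
    mean_curve, final_window: int = 20, run_window: int = 20, tolerance: float = 0.2
) -> int:
    """First episode from which the running mean stays near the final level.

    The final level is the mean over the last ``final_window`` episodes;
    the running mean is a trailing moving average of ``run_window``
    episodes (matching the final window by default, so both averages
    carry comparable sampling noise).  Returns the first index k such that every running mean
    from k onward lies within ``tolerance`` (relative) of the final
    level.  Returns the last index if the curve never settles.
    """
    curve = np.asarray(mean_curve, dtype=np.float64)
    final = float(curve[-final_window:].mean())
    running = np.array(
        [curve[max(0, k - run_window + 1) : k + 1].mean() for k in range(curve.size)]
    )
    ok = np.abs(running - final) <= tolerance * abs(final)
    settled = np.flip(np.logical_and.accumulate(np.flip(ok)))
    idx = np.nonzero(settled)[0]
    return int(idx[0]) if idx.size else int(curve.size - 1)


# ---------------------------------------------------------------------------
# feature extractors


def hierarchy_feature_fn(model: HierarchicalModel, world_cfg: WorldConfig, n_out: int):
    """State -> the n_out slowest hierarchy outputs of the rendered view."""

    def features(state: WorldState) -> np.ndarray:
        return model.forward(render(state, world_cfg), n_out=n_out)

    return features


def hierarchy_batch_feature_fn(model: HierarchicalModel, world_cfg: WorldConfig, n_out: int):
    """States -> feature matrix; renders and projects all states at once."""

    def features(states) -> np.ndarray:
        frames = np.stack([render(st, world_cfg) for st in states])
        return model.forward_batch(frames, n_out=n_out)

    return features


def encode_state_vector(state: WorldState) -> np.ndarray:
    """Hand-crafted compact encoding of the world state.

    Component order: agent position (x, y), orientation (phi / pi),
    identity (+1 for type A, -1 for type B), then each object's (x, y).
    Positions are already in arena units of order one and the angle is
    scaled to [-1, 1), so all components have comparable range.
    """
    return np.concatenate(
        [
            state.agent_pos,
            [state.agent_angle / np.pi],
            [1.0 if state.agent_identity == 0 else -1.0],
            state.object_pos.ravel(),
        ]
    )


# ---------------------------------------------------------------------------
# water maze


@dataclass
class WatermazeResult:
    latencies: np.ndarray          # (n_seeds, n_episodes)
    mean_curve: np.ndarray         # (n_episodes,)
    std_curve: np.ndarray
    populations: list[QPopulation]

    @property
    def plateau(self) -> int:
        return plateau_episode(self.mean_curve)


def run_watermaze_seed(
    feature_fn,
    world_cfg: WorldConfig,
    task_cfg: TaskConfig,
    seed: int,
    n_episodes: int,
    n_features: int,
    agent_kwargs: dict | None = None,
) -> tuple[np.ndarray, QPopulation]:
    """Train one Q-population for ``n_episodes``; returns escape latencies."""
    rng = rng_for(seed, "watermaze-seed")
    pop = QPopulation(n_features=n_features, **(agent_kwargs or {}))
    pop.initialize_weights(rng)
    latencies = np.empty(n_episodes)
    for ep in range(n_episodes):
        state = init_episode(task_cfg, world_cfg, rng)
        pop.reset_trace()
        features = feature_fn(state)
        t = 0
        while True:
            action = pop.act(features, rng)
            outcome = watermaze_step(state, action, task_cfg, world_cfg, step_index=t)
            next_features = feature_fn(outcome.state)
            # terminal only on goal: a timeout cut-off still bootstraps
            pop.update(outcome.reward, next_features, done=outcome.info["goal"])
            if outcome.info["wall_hit"]:
                pop.interrupt_exploration()
            state, features = outcome.state, next_features
            t += 1
            if outcome.done:
                break
        latencies[ep] = t
    return latencies, pop


def run_watermaze(
    model: HierarchicalModel,
    world_cfg: WorldConfig,
    task_cfg: TaskConfig,
    seeds,
    n_episodes: int = 100,
    n_features: int = 16,
    agent_kwargs: dict | None = None,
) -> WatermazeResult:
    """The water-maze experiment on the ``n_features`` slowest outputs."""
    feature_fn = hierarchy_feature_fn(model, world_cfg, n_features)
    all_lat, pops = [], []
    for seed in seeds:
        lat, pop = run_watermaze_seed(
            feature_fn, world_cfg, task_cfg, seed, n_episodes, n_features, agent_kwargs
        )
        all_lat.append(lat)
        pops.append(pop)
    latencies = np.asarray(all_lat)
    return WatermazeResult(
        latencies=latencies,
        mean_curve=latencies.mean(axis=0),
        std_curve=latencies.std(axis=0),
        populations=pops,
    )


def navigation_map(
    pop: QPopulation,
    feature_fn,
    world_cfg: WorldConfig,
    grid_n: int = 8,
    margin: float = 0.1,
):
    """Greedy movement direction at a grid of probe positions.

    Returns (positions (n, 2), angles (n,)) for an evenly spaced grid
    inside the arena; this is the most-likely action of the trained
    policy, evaluated without exploration.
    """
    lo, hi = world_cfg.bounds
    ticks = np.linspace(lo + margin, hi - margin, grid_n)
    rng = np.random.default_rng(0)  # only consulted on exact population-vector ties
    positions, angles = [], []
    for y in ticks:
        for x in ticks:
            state = WorldState(
                agent_pos=np.array([x, y]),
                agent_vel=np.zeros(2),
                agent_angle=0.0,
                agent_ang_vel=0.0,
                agent_identity=0,
                object_pos=np.zeros((world_cfg.n_objects, 2)),
                object_vel=np.zeros((world_cfg.n_objects, 2)),
            )
            q = pop.q_values(feature_fn(state))
            angles.append(population_direction(q, pop.dirs, rng))
            positions.append([x, y])
    return np.asarray(positions), np.asarray(angles)


# ---------------------------------------------------------------------------
# variable targets (batched traces)


def controller_forward(agent, x, rng):
    if isinstance(agent, BranchNeuron):
        return branch_forward(agent, x, rng)
    if isinstance(agent, SimpleNetwork):
        return simple_forward(agent, x, rng)
    raise TypeError(type(agent).__name__)


def controller_update(agent, internals, x, reward, filt):
    if isinstance(agent, BranchNeuron):
        return pg_update(agent, internals, x, reward, filt)
    if isinstance(agent, SimpleNetwork):
        return simple_update(agent, internals, reward, filt)
    raise TypeError(type(agent).__name__)


class VariableTargetsTrace:
    """One parallel episode of the variable-targets task.

    Holds its own world state, step counter, and reward baselines; the
    controller parameters live in the shared agents dict and are
    updated by :func:`sfarl.agents.batch_step`.
    """

    def __init__(self, world_cfg, task_cfg, feature_fn, rng, filter_tau: float = 50.0):
        self.world_cfg = world_cfg
        self.task_cfg = task_cfg
        self.feature_fn = feature_fn
        self.filter_tau = filter_tau
        self.done = False
        self.last_reward = 0.0
        self.last_speed_output = 0.0
        self.completed_latencies: list[int] = []
        self.filters = {
            "speed": RewardFilter(tau=filter_tau),
            "turn": RewardFilter(tau=filter_tau),
        }
        self.reset(rng)

    def reset(self, rng):
        self.state = init_episode(self.task_cfg, self.world_cfg, rng)
        self.step_index = 0
        self.done = False

    def step(self, agents, rng, features=None):
        x = self.feature_fn(self.state) if features is None else features
        v, int_v = controller_forward(agents["speed"], x, rng)
        omega, int_w = controller_forward(agents["turn"], x, rng)
        outcome = variable_targets_step(
            self.state, v, omega, self.task_cfg, self.world_cfg, self.step_index
        )
        deltas = {
            "speed": controller_update(agents["speed"], int_v, x, outcome.reward, self.filters["speed"]),
            "turn": controller_update(agents["turn"], int_w, x, outcome.reward, self.filters["turn"]),
        }
        self.state = outcome.state
        self.step_index += 1
        self.last_reward = outcome.reward
        self.last_speed_output = v
        self.done = outcome.done
        if outcome.done:
            self.completed_latencies.append(self.step_index)
        return deltas


@dataclass
class VariableTargetsResult:
    reward_per_step: np.ndarray    # mean over traces, one entry per batch step
    reward_curve: np.ndarray       # smoothed
    latencies: np.ndarray          # completed-episode lengths, in completion order
    speed_outputs: np.ndarray      # speed-neuron outputs over the final window
    agents: dict
    reward_window: int

    @property
    def final_reward(self) -> float:
        return float(self.reward_curve[-1])

    @property
    def initial_reward(self) -> float:
        return float(self.reward_curve[0])


def make_controllers(n_features: int, kind: str = "branch", n_branches: int = 50,
                     n_hidden: int = 50, **kwargs) -> dict:
    """Speed (logistic soma) and turn (tanh soma) controllers."""
    if kind == "branch":
        return {
            "speed": BranchNeuron(n_features, n_branches=n_branches, soma="logistic", **kwargs),
            "turn": BranchNeuron(n_features, n_branches=n_branches, soma="tanh", **kwargs),
        }
    if kind == "simple":
        return {
            "speed": SimpleNetwork(n_features, n_hidden=n_hidden, soma="logistic", **kwargs),
            "turn": SimpleNetwork(n_features, n_hidden=n_hidden, soma="tanh", **kwargs),
        }
    raise ValueError(f"unknown controller kind {kind!r}")


def run_variable_targets(
    feature_fn,
    n_features: int,
    world_cfg: WorldConfig,
    task_cfg: TaskConfig,
    seed: int,
    n_updates: int = 2000,
    n_traces: int = 100,
    controller: str = "branch",
    controller_kwargs: dict | None = None,
    reward_window: int | None = None,
    batch_feature_fn=None,
    init_scale: float | None = None,
) -> VariableTargetsResult:
    """Batched policy-gradient training on the variable-targets task.

    ``n_updates`` batch steps are simulated; each advances all
    ``n_traces`` episodes by one time step and applies the averaged
    deltas once.  ``batch_feature_fn(states)`` may compute all traces'
    features in one call (rendering and projecting a whole batch is much
    cheaper than per-trace calls).  The reward curve is block-averaged
    over ``reward_window`` batch steps (default: a tenth of the run).
    """
    rng = rng_for(seed, "variable-targets")
    agents = make_controllers(n_features, controller, **(controller_kwargs or {}))
    for agent in agents.values():
        if init_scale is None:
            agent.initialize(rng)
        else:
            agent.initialize(rng, scale=init_scale)
    traces = [
        VariableTargetsTrace(world_cfg, task_cfg, feature_fn, rng)
        for _ in range(n_traces)
    ]
    reward_per_step = np.empty(n_updates)
    speed_tail = []
    window = reward_window or max(1, n_updates // 10)
    for step in range(n_updates):
        if batch_feature_fn is not None:
            feats = batch_feature_fn([tr.state for tr in traces])
            batch_step(agents, traces, rng, features=feats)
        else:
            batch_step(agents, traces, rng)
        reward_per_step[step] = np.mean([tr.last_reward for tr in traces])
        if step >= n_updates - window:
            speed_tail.extend(tr.last_speed_output for tr in traces)
    latencies = np.array(
        [lat for tr in traces for lat in tr.completed_latencies], dtype=np.float64
    )
    return VariableTargetsResult(
        reward_per_step=reward_per_step,
        reward_curve=smooth_curve(reward_per_step, window),
        latencies=latencies,
        speed_outputs=np.asarray(speed_tail),
        agents=agents,
        reward_window=window,
    )


def feature_count_sweep(
    model: HierarchicalModel,
    world_cfg: WorldConfig,
    task_cfg: TaskConfig,
    seed: int,
    counts=(16, 22, 28, 32, 64),
    **run_kwargs,
) -> dict[int, VariableTargetsResult]:
    """Independent control-training runs using the n slowest outputs each."""
    results = {}
    for n in counts:
        if n > model.output_dim:
            raise ValueError(f"count {n} exceeds available outputs {model.output_dim}")
        feats = hierarchy_feature_fn(model, world_cfg, n)
        results[n] = run_variable_targets(
            feats, n, world_cfg, task_cfg, child_seed(seed, "sweep", n), **run_kwargs
        )
    return results


def pca_baseline(
    stream_factory,
    config,
    world_cfg: WorldConfig,
    task_cfg: TaskConfig,
    seed: int,
    n_features: int | None = None,
    **run_kwargs,
) -> tuple[HierarchicalModel, VariableTargetsResult]:
    """Train the PCA-variant hierarchy and run the identical control training."""
    model = train_pca_hierarchy(stream_factory, config, child_seed(seed, "pca-hierarchy"))
    n = n_features or model.output_dim
    feats = hierarchy_feature_fn(model, world_cfg, n)
    return model, run_variable_targets(
        feats, n, world_cfg, task_cfg, child_seed(seed, "pca-control"), **run_kwargs
    )


# ---------------------------------------------------------------------------
# desk-scale water-maze profile (hierarchy + Q-learning end to end)


def watermaze_stream_factory(world_cfg: WorldConfig):
    def factory(n_frames: int, seed: int):
        return generate_training_stream(n_frames, world_cfg, np.random.default_rng(seed))

    return factory


def train_watermaze_hierarchy(
    seed: int,
    image_side: int = 63,
    n_frames: int = 10_000,
    top_dim: int = 32,
) -> tuple[HierarchicalModel, WorldConfig]:
    """Reduced-resolution hierarchy trained on the water-maze stimulus walk."""
    world_cfg = watermaze_world(image_side)
    config = desk_config(
        image_side, samples_lower=n_frames, samples_upper=n_frames, top_dim=top_dim
    )
    model = train_hierarchy(
        watermaze_stream_factory(world_cfg), config, child_seed(seed, "hierarchy")
    )
    return model, world_cfg


def run_watermaze_profile(
    seed: int,
    image_side: int = 63,
    n_frames: int = 10_000,
    n_seeds: int = 10,
    n_episodes: int = 100,
    n_features: int = 16,
    task_cfg: TaskConfig | None = None,
) -> WatermazeResult:
    """End-to-end desk-scale water-maze experiment: train the hierarchy on a
    random-walk stream, then run Q-learning on the 16 slowest features for
    ``n_seeds`` independent sets of episodes."""
    model, world_cfg = train_watermaze_hierarchy(seed, image_side, n_frames)
    task = task_cfg or TaskConfig()
    seeds = [child_seed(seed, "episodes", i) for i in range(n_seeds)]
    return run_watermaze(model, world_cfg, task, seeds, n_episodes, n_features)


# ---------------------------------------------------------------------------
# manifests and exports


def write_manifest(path, seeds, **configs) -> None:
    """YAML snapshot of configs + seeds, sufficient to re-run bit-for-bit."""
    doc = {"seeds": [int(s) for s in seeds]}
    for name, cfg in configs.items():
        doc[name] = dataclasses.asdict(cfg) if dataclasses.is_dataclass(cfg) else cfg
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_curve_csv(path, curve, label: str = "value") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", label])
        for i, v in enumerate(np.asarray(curve)):
            writer.writerow([i, float(v)])
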