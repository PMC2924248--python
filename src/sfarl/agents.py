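"""Reward-modulated neural learners.

Two controllers operate on the slow-feature vector:

* ``QPopulation`` — a ring of M linear neurons with uniformly spaced
  preferred directions.  Each neuron's output is its Q-value for a
  movement in its preferred direction; the greedy action is the angle
  of the population vector (the Q-weighted sum of preferred-direction
  unit vectors).  Learning is TD(lambda) Q-learning with a Gaussian
  activity profile around the chosen action as the post-synaptic factor
  of the eligibility trace.

* ``BranchNeuron`` — a single neuron with K nonlinear dendritic
  branches.  Branch k computes b_k = tanh(w_k . x); the somatic input
  is u = sum_k q_k b_k + bias + xi with uniform exploration noise xi,
  and the output is a bounded nonlinearity of u.  Both synaptic weights
  and branch-soma couplings are trained by node perturbation: the
  update correlates the injected noise with the deviation of the reward
  from its exponential low-pass baseline, which performs stochastic
  gradient ascent on the expected reward.

* ``SimpleNetwork`` — the point-neuron baseline: a two-layer
  feed-forward net of sigmoidal neurons, each perturbed and updated
  independently by the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidUseError(RuntimeError):
    """Raised when internals from a stale forward pass are reused."""


# ---------------------------------------------------------------------------
# population Q-learning


def q_forward(weights: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Linear Q-values, one per neuron: Q_a = w_a . y (no bias)."""
    weights = np.asarray(weights, dtype=np.float64)
    features = np.asarray(features, dtype=np.float64)
    if weights.shape[1] != features.shape[0]:
        raise ValueError(
            f"feature dimension {features.shape[0]} does not match weights {weights.shape}"
        )
    return weights @ features


def population_direction(
    q: np.ndarray, dirs: np.ndarray, rng: np.random.Generator | None = None
) -> float:
    """Angle of the population vector sum_a Q_a (cos phi_a, sin phi_a).

    A resultant of magnitude below 1e-12 carries no directional
    information; the angle is then drawn uniformly (requires ``rng``).
    """
    q = np.asarray(q, dtype=np.float64)
    dirs = np.asarray(dirs, dtype=np.float64)
    vx = float(q @ np.cos(dirs))
    vy = float(q @ np.sin(dirs))
    if np.hypot(vx, vy) < 1e-12:
        if rng is None:
            rng = np.random.default_rng()
        return float(rng.uniform(-np.pi, np.pi))
    return float(np.arctan2(vy, vx))


def select_action(greedy_angle: float, epsilon: float, rng: np.random.Generator) -> float:
    """Epsilon-greedy: the greedy angle, or uniform on the circle w.p. epsilon."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if rng.uniform() < epsilon:
        return float(rng.uniform(0.0, 2 * np.pi))
    return float(greedy_angle)


def _circ_diff(a, b):
    return (np.asarray(a) - np.asarray(b) + np.pi) % (2 * np.pi) - np.pi


def gaussian_activity(chosen_angle: float, dirs: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian profile over the ring, peaked at the chosen action."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = _circ_diff(np.asarray(dirs, dtype=np.float64), chosen_angle)
    return np.exp(-(d**2) / (2 * sigma**2))


@dataclass
class QPopulation:
    """Population-coded linear Q-learner.

    gamma   : discount factor
    epsilon : exploration probability
    lam     : eligibility-trace decay (0 disables the trace memory)
    eta0/eta_tau : decaying learning rate eta_t = eta0 / (1 + t/eta_tau)
    sigma_prof   : width of the Gaussian action profile (radians)
    """

    n_features: int
    n_neurons: int = 36
    gamma: float = 0.98
    epsilon: float = 0.05
    lam: float = 0.92
    eta0: float = 2e-2
    eta_tau: float = 2e5
    sigma_prof: float | None = None
    init_scale: float = 0.01
    explore_persist: float = 25.0
    delta_clip: float | None = 1.0
    bias_input: bool = True

    def __post_init__(self):
        if self.sigma_prof is None:
            self.sigma_prof = 1.5 * 2 * np.pi / self.n_neurons
        self.dirs = 2 * np.pi * np.arange(self.n_neurons) / self.n_neurons
        # slow features are zero-mean signals, but a value function needs a
        # representable constant level; a unit bias input provides it
        self._d = self.n_features + (1 if self.bias_input else 0)
        self.weights = np.zeros((self.n_neurons, self._d))
        self.eligibility = np.zeros_like(self.weights)
        self.t = 0
        self._pending = None
        self._explore_dir = None
        self._explore_left = 0

    def initialize_weights(self, rng: np.random.Generator) -> None:
        """Small random weights so the initial greedy policy is a smooth
        (random) flow field rather than per-step diffusion."""
        self.weights = rng.normal(0.0, self.init_scale, size=self.weights.shape)

    @property
    def eta(self) -> float:
        return self.eta0 / (1.0 + self.t / self.eta_tau)

    def _augment(self, features: np.ndarray) -> np.ndarray:
        if self.bias_input and features.shape[0] == self.n_features:
            return np.concatenate([features, [1.0]])
        return features

    def q_values(self, features: np.ndarray) -> np.ndarray:
        return q_forward(self.weights, self._augment(np.asarray(features, dtype=np.float64)))

    def reset_trace(self) -> None:
        self.eligibility[:] = 0.0
        self._pending = None
        self._explore_left = 0

    def interrupt_exploration(self) -> None:
        """End a persistent exploratory movement early (e.g. at a wall)."""
        self._explore_left = 0

    def act(self, features: np.ndarray, rng: np.random.Generator) -> float:
        """Steps 1-5 of the learning cycle: Q-values, population vector,
        epsilon-greedy choice, Gaussian profile, trace update.

        Exploration operates at the level of movements rather than single
        time steps: when the epsilon coin selects exploration, a random
        direction is held for a geometric number of steps (mean
        ``explore_persist``; 1 recovers per-step epsilon-greedy).  TD
        learning is off-policy, so the persistent behaviour policy does
        not bias the value estimate.
        """
        features = self._augment(np.asarray(features, dtype=np.float64))
        q = q_forward(self.weights, features)
        exploratory = True
        if self._explore_left > 0:
            self._explore_left -= 1
            action = float(self._explore_dir)
        else:
            greedy = population_direction(q, self.dirs, rng)
            action = select_action(greedy, self.epsilon, rng)
            exploratory = action != greedy or self.epsilon >= 1.0
            if exploratory:
                self._explore_dir = action
                self._explore_left = int(rng.geometric(1.0 / self.explore_persist)) - 1
        profile = gaussian_activity(action, self.dirs, self.sigma_prof)
        # Watkins-style trace: exploratory actions invalidate the backward
        # credit of the max-bootstrapped TD error, so the trace restarts.
        if exploratory:
            self.eligibility[:] = 0.0
        # replacing trace: decay, then overwrite synapses where the current
        # profile(x)feature contribution dominates the decayed memory — this
        # bounds the trace when the state lingers (e.g. at a wall) and keeps
        # the bootstrapped updates stable
        inc = np.outer(profile, features)
        decayed = self.gamma * self.lam * self.eligibility
        replace_mask = np.abs(inc) > np.abs(decayed)
        self.eligibility = np.where(replace_mask, inc, decayed)
        q_chosen = float(profile @ q) / float(profile.sum())
        self._pending = (q_chosen,)
        return action

    def update(self, reward: float, next_features: np.ndarray, done: bool) -> float:
        """Steps 7-8: TD error and the eligibility-gated weight update.

        delta = R + gamma * max_a Q(s', a) - Q(s, a_chosen), with no
        bootstrap on terminal transitions.  Returns the TD error.
        """
        if self._pending is None:
            raise InvalidUseError("update() called before act()")
        (q_chosen,) = self._pending
        self._pending = None
        if done:
            target = float(reward)
        else:
            # bootstrap from the value of the greedy *population* action,
            # read out with the same Gaussian profile used for Q(s, a):
            # a raw per-neuron max inflates the estimate (the max chases
            # the largest noise excursion on the ring and the bootstrap
            # amplifies it), while this readout-consistent greedy target
            # stays bounded by the actual reward scale
            q_next = self.q_values(np.asarray(next_features, dtype=np.float64))
            greedy_next = population_direction(q_next, self.dirs)
            prof_next = gaussian_activity(greedy_next, self.dirs, self.sigma_prof)
            q_greedy = float(prof_next @ q_next) / float(prof_next.sum())
            target = float(reward) + self.gamma * q_greedy
        delta = target - q_chosen
        if self.delta_clip is not None:
            delta = float(np.clip(delta, -self.delta_clip, self.delta_clip))
        self.weights += self.eta * delta * self.eligibility
        self.t += 1
        return delta


def q_learning_step(pop: QPopulation, features: np.ndarray, execute, rng: np.random.Generator):
    """One full Q-learning cycle against an environment callback.

    ``execute(action_angle)`` must apply the action and return
    ``(reward, next_features, done)``.  Returns the executed action,
    the callback result, and the TD error.
    """
    action = pop.act(features, rng)
    reward, next_features, done = execute(action)
    delta = pop.update(reward, next_features, done)
    return action, (reward, next_features, done), delta


# ---------------------------------------------------------------------------
# reward baseline


@dataclass
class RewardFilter:
    """Exponential low-pass of the reward; the node-perturbation baseline.

    The filtered value is a convex combination of past rewards: the
    first update sets it to that reward, thereafter
    Rbar <- (1 - 1/tau) Rbar + (1/tau) R.
    """

    tau: float = 50.0
    value: float = 0.0
    _seen: bool = False

    def update(self, reward: float) -> float:
        if not self._seen:
            self.value = float(reward)
            self._seen = True
        else:
            alpha = 1.0 / self.tau
            self.value = (1.0 - alpha) * self.value + alpha * float(reward)
        return self.value


# ---------------------------------------------------------------------------
# branch neuron


def _soma(kind: str, u):
    if kind == "tanh":
        return np.tanh(u)
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-u))
    raise ValueError(f"unknown soma nonlinearity {kind!r}")


@dataclass
class BranchNeuron:
    """Single neuron with K nonlinear dendritic branches (see module docs)."""

    n_features: int
    n_branches: int = 50
    soma: str = "tanh"
    noise_halfwidth: float = 0.5
    eta_w: float = 1e-2
    eta_q: float = 5e-2
    eta_b: float = 5e-2

    def __post_init__(self):
        _soma(self.soma, 0.0)  # validate
        self.w = np.zeros((self.n_branches, self.n_features))
        self.q = np.zeros(self.n_branches)
        self.bias = 0.0

    def initialize(self, rng: np.random.Generator, scale: float = 3.0,
                   coupling_scale: float = 0.1) -> None:
        """Strong random branch weights (total input scale ~``scale``)
        make the branches a rich fixed nonlinear basis from the start;
        the weak couplings are then learned as a fast, nearly linear
        readout while the branch weights refine slowly.  With weights
        and couplings both near zero the two gradient factors (q_k for
        the weights, b_k for the couplings) vanish together and
        learning never starts."""
        self.w = rng.normal(0.0, scale / np.sqrt(self.n_features), size=self.w.shape)
        self.q = rng.normal(0.0, coupling_scale, size=self.q.shape)
        self.bias = 0.0

    def parameters(self) -> dict:
        return {"w": self.w, "q": self.q, "bias": np.array([self.bias])}


def branch_forward(
    neuron: BranchNeuron,
    x: np.ndarray,
    rng: np.random.Generator | None = None,
    xi: float | None = None,
):
    """Noisy forward pass; returns (output, internals for the update rule).

    ``xi`` fixes the exploration noise explicitly (for tests); otherwise
    it is drawn uniformly from +-noise_halfwidth using ``rng``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != neuron.n_features:
        raise ValueError(f"expected {neuron.n_features} features, got {x.shape[0]}")
    if xi is None:
        if rng is None:
            raise ValueError("either rng or a fixed xi is required")
        xi = float(rng.uniform(-neuron.noise_halfwidth, neuron.noise_halfwidth))
    pre = neuron.w @ x
    b = np.tanh(pre)
    u = float(neuron.q @ b) + neuron.bias + float(xi)
    y = float(_soma(neuron.soma, u))
    internals = {"x": x, "pre": pre, "b": b, "u": u, "xi": float(xi)}
    return y, internals


def pg_update(
    neuron: BranchNeuron,
    internals: dict,
    x: np.ndarray,
    reward: float,
    filt: RewardFilter,
) -> dict:
    """Node-perturbation policy-gradient deltas (not yet applied).

    delta_w_kj = eta_w (R - Rbar) xi q_k sech^2(w_k . x) x_j
    delta_q_k  = eta_q (R - Rbar) xi b_k
    delta_bias = eta_b (R - Rbar) xi

    The baseline uses the filtered reward *before* seeing R; the filter
    is advanced afterwards.  No eligibility traces are used.
    """
    x = np.asarray(x, dtype=np.float64)
    if internals["x"].shape != x.shape or not np.array_equal(internals["x"], x):
        raise InvalidUseError("internals do not match the provided input vector")
    factor = (float(reward) - filt.value) * internals["xi"]
    sech2 = 1.0 - internals["b"] ** 2
    deltas = {
        "w": neuron.eta_w * factor * (neuron.q * sech2)[:, None] * x[None, :],
        "q": neuron.eta_q * factor * internals["b"],
        "bias": np.array([neuron.eta_b * factor]),
    }
    filt.update(reward)
    return deltas


def apply_deltas(neuron, deltas: dict) -> None:
    if isinstance(neuron, BranchNeuron):
        neuron.w += deltas["w"]
        neuron.q += deltas["q"]
        neuron.bias += float(deltas["bias"][0])
    elif isinstance(neuron, SimpleNetwork):
        neuron.w1 += deltas["w1"]
        neuron.b1 += deltas["b1"]
        neuron.w2 += deltas["w2"]
        neuron.b2 += float(deltas["b2"][0])
    else:
        raise TypeError(f"cannot apply deltas to {type(neuron).__name__}")


# ---------------------------------------------------------------------------
# point-neuron baseline


@dataclass
class SimpleNetwork:
    """Two-layer feed-forward net of independently perturbed point neurons."""

    n_features: int
    n_hidden: int = 50
    soma: str = "tanh"
    noise_halfwidth: float = 0.5
    eta: float = 1e-2

    def __post_init__(self):
        _soma(self.soma, 0.0)
        self.w1 = np.zeros((self.n_hidden, self.n_features))
        self.b1 = np.zeros(self.n_hidden)
        self.w2 = np.zeros(self.n_hidden)
        self.b2 = 0.0

    def initialize(self, rng: np.random.Generator, scale: float = 3.0,
                   readout_scale: float = 0.1) -> None:
        self.w1 = rng.normal(0.0, scale / np.sqrt(self.n_features), size=self.w1.shape)
        self.b1 = np.zeros(self.n_hidden)
        self.w2 = rng.normal(0.0, readout_scale, size=self.w2.shape)
        self.b2 = 0.0


def simple_forward(net: SimpleNetwork, x: np.ndarray, rng: np.random.Generator | None = None,
                   xi_hidden: np.ndarray | None = None, xi_out: float | None = None):
    """Noisy forward pass; each neuron carries its own exploration noise."""
    x = np.asarray(x, dtype=np.float64)
    if xi_hidden is None or xi_out is None:
        if rng is None:
            raise ValueError("either rng or fixed noise is required")
        xi_hidden = rng.uniform(-net.noise_halfwidth, net.noise_halfwidth, size=net.n_hidden)
        xi_out = float(rng.uniform(-net.noise_halfwidth, net.noise_halfwidth))
    h = np.tanh(net.w1 @ x + net.b1 + xi_hidden)
    u = float(net.w2 @ h) + net.b2 + float(xi_out)
    y = float(_soma(net.soma, u))
    internals = {"x": x, "h": h, "xi_hidden": np.asarray(xi_hidden, dtype=np.float64),
                 "xi_out": float(xi_out)}
    return y, internals


def simple_update(
    net: SimpleNetwork,
    internals: dict,
    reward: float,
    filt: RewardFilter,
) -> dict:
    """Per-neuron node-perturbation deltas; every neuron optimizes the
    shared reward independently of the others."""
    factor = float(reward) - filt.value
    deltas = {
        "w1": net.eta * factor * internals["xi_hidden"][:, None] * internals["x"][None, :],
        "b1": net.eta * factor * internals["xi_hidden"],
        "w2": net.eta * factor * internals["xi_out"] * internals["h"],
        "b2": np.array([net.eta * factor * internals["xi_out"]]),
    }
    filt.update(reward)
    return deltas


# ---------------------------------------------------------------------------
# batched traces


def average_deltas(delta_list: list[dict]) -> dict:
    if not delta_list:
        raise ValueError("empty delta list")
    keys = delta_list[0].keys()
    return {k: np.mean([d[k] for d in delta_list], axis=0) for k in keys}


def batch_step(agents: dict, traces: list, rng: np.random.Generator, features=None) -> None:
    """Simulate one time step in every parallel trace, then apply the
    trace-averaged parameter deltas once.

    ``agents`` maps names to shared BranchNeuron/SimpleNetwork objects.
    Every trace must implement ``step(agents, rng) -> {name: deltas}``
    and expose ``done``; finished traces are re-initialized via
    ``trace.reset(rng)`` while the others simply continue.  ``features``
    may supply a precomputed row of input features per trace.
    """
    if not traces:
        raise ValueError("batch_step needs at least one trace")
    if features is None:
        all_deltas = [trace.step(agents, rng) for trace in traces]
    else:
        all_deltas = [
            trace.step(agents, rng, features=features[i])
            for i, trace in enumerate(traces)
        ]
    for name, agent in agents.items():
        apply_deltas(agent, average_deltas([d[name] for d in all_deltas]))
    for trace in traces:
        if trace.done:
            trace.reset(rng)
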