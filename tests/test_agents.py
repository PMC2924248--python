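"""Population Q-learning, branch-neuron policy gradient, and baselines."""

import copy

import numpy as np
import pytest
from scipy import stats

from sfarl.agents import (
    BranchNeuron,
    InvalidUseError,
    QPopulation,
    RewardFilter,
    SimpleNetwork,
    apply_deltas,
    average_deltas,
    batch_step,
    branch_forward,
    gaussian_activity,
    pg_update,
    population_direction,
    q_forward,
    select_action,
    simple_forward,
    simple_update,
)


class TestQForward:
    def test_zero_weights_zero_q(self):
        assert not q_forward(np.zeros((4, 3)), np.ones(3)).any()

    def test_one_hot_reads_out_single_weight(self):
        w = np.zeros((3, 4))
        w[1, 2] = 0.7
        x = np.zeros(4)
        x[2] = 1.0
        np.testing.assert_allclose(q_forward(w, x), [0.0, 0.7, 0.0])

    def test_linearity(self, rng):
        w = rng.normal(size=(5, 3))
        x = rng.normal(size=3)
        np.testing.assert_allclose(q_forward(w, 2.5 * x), 2.5 * q_forward(w, x))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            q_forward(rng.normal(size=(5, 3)), rng.normal(size=4))


class TestPopulationDirection:
    dirs = 2 * np.pi * np.arange(8) / 8

    def test_one_hot_points_at_preferred_direction(self):
        q = np.zeros(8)
        q[2] = 1.0  # phi = pi/2
        assert population_direction(q, self.dirs) == pytest.approx(np.pi / 2)

    def test_equal_pair_bisects(self):
        q = np.zeros(8)
        q[0] = q[2] = 1.0
        assert population_direction(q, self.dirs) == pytest.approx(np.pi / 4)

    def test_symmetric_ring_takes_random_branch(self):
        q = np.ones(8)  # resultant cancels exactly
        a = population_direction(q, self.dirs, np.random.default_rng(5))
        b = population_direction(q, self.dirs, np.random.default_rng(5))
        assert -np.pi <= a < np.pi
        assert a == b  # seeded tie-break is reproducible


class TestSelectAction:
    def test_greedy_when_epsilon_zero(self, rng):
        for _ in range(20):
            assert select_action(1.234, 0.0, rng) == 1.234

    def test_uniform_when_epsilon_one(self):
        rng = np.random.default_rng(17)
        draws = np.array([select_action(0.0, 1.0, rng) for _ in range(10_000)])
        counts, _ = np.histogram(draws, bins=16, range=(0, 2 * np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_epsilon_validated(self, rng):
        with pytest.raises(ValueError):
            select_action(0.0, 1.5, rng)


class TestGaussianActivity:
    dirs = 2 * np.pi * np.arange(12) / 12

    def test_peak_at_chosen_direction(self):
        act = gaussian_activity(self.dirs[3], self.dirs, 0.5)
        assert act[3] == pytest.approx(1.0)
        assert act.argmax() == 3

    def test_symmetry_about_chosen_angle(self):
        act = gaussian_activity(self.dirs[0], self.dirs, 0.7)
        np.testing.assert_allclose(act[1:], act[1:][::-1], atol=1e-12)

    def test_narrow_profile_approaches_one_hot(self):
        act = gaussian_activity(self.dirs[4], self.dirs, 1e-3)
        assert act[4] == pytest.approx(1.0)
        assert np.delete(act, 4).max() < 1e-8


class TestQLearning:
    def test_single_state_value_converges_to_reward(self):
        # gamma = 0, lambda = 0, constant reward r: the TD fixed point is
        # Q = r for every action that keeps being chosen
        rng = np.random.default_rng(3)
        pop = QPopulation(
            n_features=1, n_neurons=8, gamma=0.0, lam=0.0, epsilon=1.0,
            eta0=0.2, eta_tau=1e12, explore_persist=1.0, bias_input=False,
            delta_clip=None,
        )
        x = np.ones(1)
        for _ in range(4000):
            pop.act(x, rng)
            pop.update(1.0, x, done=False)
        q = pop.q_values(x)
        # the profile-weighted readout (the value actually learned against)
        # settles to r; individual neurons agree to within the profile width
        for angle in pop.dirs:
            g = gaussian_activity(angle, pop.dirs, pop.sigma_prof)
            assert float(g @ q) / g.sum() == pytest.approx(1.0, abs=1e-3)
        assert np.all(np.abs(q - 1.0) < 0.05)

    def test_zero_td_error_is_fixed_point(self):
        rng = np.random.default_rng(4)
        pop = QPopulation(n_features=3, epsilon=0.0, bias_input=False)
        before = pop.weights.copy()  # all-zero weights, zero reward
        pop.act(np.array([1.0, -1.0, 0.5]), rng)
        delta = pop.update(0.0, np.array([0.2, 0.1, 0.0]), done=False)
        assert delta == 0.0
        np.testing.assert_array_equal(pop.weights, before)

    def test_q_values_do_not_depend_on_epsilon(self, rng):
        x = rng.normal(size=4)
        a = QPopulation(n_features=4, epsilon=0.0)
        b = QPopulation(n_features=4, epsilon=0.9)
        w = rng.normal(size=a.weights.shape)
        a.weights = w.copy()
        b.weights = w.copy()
        np.testing.assert_array_equal(a.q_values(x), b.q_values(x))

    def test_update_requires_act(self):
        pop = QPopulation(n_features=2)
        with pytest.raises(InvalidUseError):
            pop.update(0.0, np.zeros(2), done=False)


class TestRewardFilter:
    def test_first_update_initializes(self):
        f = RewardFilter(tau=10)
        assert f.update(0.5) == 0.5

    def test_stays_convex_combination(self, rng):
        f = RewardFilter(tau=5)
        rewards = rng.uniform(-1, 1, size=200)
        for r in rewards:
            f.update(r)
            assert rewards.min() - 1e-12 <= f.value <= rewards.max() + 1e-12


class TestBranchNeuron:
    def test_zero_parameters_zero_output(self):
        n = BranchNeuron(3, n_branches=2, soma="tanh")
        y, _ = branch_forward(n, np.array([1.0, 2.0, 3.0]), xi=0.0)
        assert y == 0.0

    def test_single_branch_closed_form(self):
        n = BranchNeuron(1, n_branches=1, soma="tanh")
        n.w[0, 0] = 1.0
        n.q[0] = 1.0
        y, _ = branch_forward(n, np.array([0.5]), xi=0.0)
        assert y == pytest.approx(np.tanh(np.tanh(0.5)), abs=1e-6)
        assert y == pytest.approx(0.4319, abs=1e-4)

    def test_output_bounded_by_soma(self, rng):
        n = BranchNeuron(4, n_branches=6, soma="logistic")
        n.initialize(rng, scale=10.0, coupling_scale=5.0)
        for _ in range(50):
            y, _ = branch_forward(n, rng.normal(size=4) * 10, rng)
            assert 0.0 < y < 1.0

    def test_dimension_mismatch(self, rng):
        n = BranchNeuron(3)
        with pytest.raises(ValueError):
            branch_forward(n, np.zeros(5), rng)


class TestPGUpdate:
    def _neuron(self, rng, d=3, k=2):
        n = BranchNeuron(d, n_branches=k, eta_w=1.0, eta_q=1.0, eta_b=1.0)
        n.initialize(rng, scale=1.0, coupling_scale=0.5)
        return n

    def test_reward_at_baseline_gives_zero_update(self, rng):
        n = self._neuron(rng)
        x = rng.normal(size=3)
        y, info = branch_forward(n, x, rng)
        filt = RewardFilter(tau=10)
        filt.update(0.7)
        deltas = pg_update(n, info, x, 0.7, filt)
        assert not any(d.any() for d in deltas.values())

    def test_zero_noise_gives_zero_update(self, rng):
        n = self._neuron(rng)
        x = rng.normal(size=3)
        y, info = branch_forward(n, x, xi=0.0)
        filt = RewardFilter(tau=10)
        filt.update(0.0)
        deltas = pg_update(n, info, x, 1.0, filt)
        assert not any(d.any() for d in deltas.values())

    def test_stale_internals_rejected(self, rng):
        n = self._neuron(rng)
        x = rng.normal(size=3)
        _, info = branch_forward(n, x, rng)
        filt = RewardFilter(tau=10)
        with pytest.raises(InvalidUseError):
            pg_update(n, info, x + 1.0, 1.0, filt)

    def test_expected_update_follows_gradient(self):
        # compare against a finite-difference gradient of the expected
        # reward on a one-step bandit (full oracle battery runs in the
        # acceptance suite; this is a single smoke instance)
        cos = _gradient_cosine(seed=0)
        assert cos > 0.9


def _expected_reward(neuron, x, target, n_grid=2001):
    xis = np.linspace(-neuron.noise_halfwidth, neuron.noise_halfwidth, n_grid)
    b = np.tanh(neuron.w @ x)
    u = neuron.q @ b + neuron.bias + xis
    y = np.tanh(u) if neuron.soma == "tanh" else 1.0 / (1.0 + np.exp(-u))
    return float(np.mean(-((y - target) ** 2)))


def _gradient_cosine(seed, d=None, k=None, n_grid=401):
    """Cosine between the xi-averaged update rule and the finite-difference
    gradient of expected reward for one random bandit instance.

    The noise half-width is narrowed to 0.1: node perturbation equals
    gradient ascent in the small-noise regime, whereas with wide noise an
    optimum inside the noise interval legitimately reweights the update.
    """
    rng = np.random.default_rng(seed)
    d = d or int(rng.integers(2, 5))
    k = k or int(rng.integers(1, 4))
    x = rng.normal(size=d)
    target = rng.uniform(-0.5, 0.5)
    neuron = BranchNeuron(
        d, n_branches=k, eta_w=1.0, eta_q=1.0, eta_b=1.0, noise_halfwidth=0.1
    )
    neuron.initialize(rng, scale=1.5, coupling_scale=0.5)

    base = _expected_reward(neuron, x, target)
    acc = None
    xis = np.linspace(-neuron.noise_halfwidth, neuron.noise_halfwidth, n_grid)
    for xi in xis:  # deterministic average over the noise distribution
        y, info = branch_forward(neuron, x, xi=float(xi))
        filt = RewardFilter(tau=10)
        filt.value, filt._seen = base, True
        deltas = pg_update(neuron, info, x, -((y - target) ** 2), filt)
        if acc is None:
            acc = {key: val.copy() for key, val in deltas.items()}
        else:
            for key in acc:
                acc[key] += deltas[key]
    g_rule = np.concatenate([acc["w"].ravel(), acc["q"], acc["bias"]])

    eps = 1e-5
    g_fd = []
    for name, idx in (
        [("w", (i, j)) for i in range(k) for j in range(d)]
        + [("q", (i,)) for i in range(k)]
        + [("bias", ())]
    ):
        plus, minus = copy.deepcopy(neuron), copy.deepcopy(neuron)
        for n_, sign in ((plus, +eps), (minus, -eps)):
            if name == "w":
                n_.w[idx] += sign
            elif name == "q":
                n_.q[idx[0]] += sign
            else:
                n_.bias += sign
        g_fd.append(
            (_expected_reward(plus, x, target) - _expected_reward(minus, x, target))
            / (2 * eps)
        )
    g_fd = np.array(g_fd)
    return float(
        g_rule @ g_fd / (np.linalg.norm(g_rule) * np.linalg.norm(g_fd) + 1e-30)
    )


class TestSimpleNetwork:
    def test_reward_at_baseline_gives_zero_update(self, rng):
        net = SimpleNetwork(3, n_hidden=4)
        net.initialize(rng)
        x = rng.normal(size=3)
        _, info = simple_forward(net, x, rng)
        filt = RewardFilter(tau=10)
        filt.update(0.3)
        deltas = simple_update(net, info, 0.3, filt)
        assert not any(d.any() for d in deltas.values())

    def test_reduces_to_branch_neuron_forward(self, rng):
        # one hidden neuron with unit readout, no hidden noise == one
        # branch with unit coupling
        w = rng.normal(size=3)
        net = SimpleNetwork(3, n_hidden=1, soma="tanh")
        net.w1[0] = w
        net.w2[0] = 1.0
        net.b2 = 0.2
        branch = BranchNeuron(3, n_branches=1, soma="tanh")
        branch.w[0] = w
        branch.q[0] = 1.0
        branch.bias = 0.2
        x = rng.normal(size=3)
        y_net, _ = simple_forward(net, x, xi_hidden=np.zeros(1), xi_out=0.13)
        y_branch, _ = branch_forward(branch, x, xi=0.13)
        assert y_net == pytest.approx(y_branch)


class _StubTrace:
    def __init__(self, deltas, done=False):
        self.deltas = deltas
        self.done = done
        self.resets = 0

    def step(self, agents, rng, features=None):
        return self.deltas

    def reset(self, rng):
        self.resets += 1
        self.done = False


class TestBatchStep:
    def _agent(self):
        n = BranchNeuron(2, n_branches=1)
        return n

    def test_single_trace_applies_its_delta(self, rng):
        agent = self._agent()
        d = {"w": np.ones((1, 2)), "q": np.ones(1), "bias": np.array([0.5])}
        batch_step({"a": agent}, [_StubTrace({"a": d})], rng)
        np.testing.assert_array_equal(agent.w, np.ones((1, 2)))
        assert agent.bias == 0.5

    def test_average_of_traces_applied_once(self, rng):
        agent = self._agent()
        d1 = {"w": np.zeros((1, 2)), "q": np.zeros(1), "bias": np.array([0.0])}
        d2 = {"w": np.ones((1, 2)), "q": np.ones(1), "bias": np.array([1.0])}
        batch_step({"a": agent}, [_StubTrace({"a": d1}), _StubTrace({"a": d2})], rng)
        np.testing.assert_array_equal(agent.w, 0.5 * np.ones((1, 2)))

    def test_finished_traces_reset(self, rng):
        agent = self._agent()
        d = {"a": {"w": np.zeros((1, 2)), "q": np.zeros(1), "bias": np.array([0.0])}}
        done_trace = _StubTrace(d, done=True)
        live_trace = _StubTrace(d, done=False)
        batch_step({"a": agent}, [done_trace, live_trace], rng)
        assert done_trace.resets == 1
        assert live_trace.resets == 0

    def test_empty_trace_list_rejected(self, rng):
        with pytest.raises(ValueError):
            batch_step({}, [], rng)

    def test_average_deltas_validates(self):
        with pytest.raises(ValueError):
            average_deltas([])
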