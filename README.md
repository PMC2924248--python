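# sfarl — slow features + reward-modulated control

`sfarl` is a research library for studying how an agent can learn
closed-loop behaviour directly from raw, high-dimensional visual input
by splitting the problem into two biologically motivated stages:

1. **Unsupervised compression by temporal slowness.** A converging
   hierarchy of slow-feature-analysis (SFA) nodes turns a rendered
   grayscale view of a 2D world (24,025 pixels at full scale) into a
   handful of slowly varying features. Each node solves, by a
   generalized eigendecomposition, the problem of finding instantaneous
   readouts y_j(t) that minimize Δ(y_j) = ⟨ẏ_j²⟩ subject to zero mean,
   unit variance, and decorrelation; a quadratic expansion between two
   linear stages gives each node degree-2 nonlinearity, so the slow
   features of a four-layer stack are high-degree polynomials of the
   pixels. Nodes are weight-shared across receptive-field locations and
   layers are trained sequentially bottom-up.
2. **Reward-modulated control on the slow features.** Two small neural
   learners are provided: a population-coded Q-learner (a ring of
   linear neurons whose population vector is the greedy movement
   direction, trained by TD(λ) with a Gaussian action profile) and a
   branch-neuron policy-gradient controller (nonlinear dendritic
   branches, node-perturbation updates that climb the reward gradient
   by correlating injected somatic noise with reward deviations from a
   running baseline).

The package also contains the simulated world that generates both the
training stimuli (velocity-capped random walks of a fish sprite and two
marker objects, rendered procedurally) and two benchmark tasks: a
Morris-water-maze-style navigation task with sparse rewards, and a
variable-targets task in which the rewarded object depends on the
fish's visual identity.

The intended audience is computational-neuroscience and
representation-learning researchers who want a compact, fully seeded,
pure-Python testbed for slowness-based state representations and
three-factor learning rules.

## A worked example

`examples/hierarchy_latent_recovery.py` trains a three-layer hierarchy
on 3,000 rendered frames of a fish walking along the x-axis of a small
arena and then checks what the slowest features encode:

```
pixels in: 1521, features out: 16
best |corr| of a top-8 feature with x-position: 0.992
```

The network never sees coordinates — only pixels — yet its slowest
output *is* the fish's position, which is exactly the property that
makes the features a usable state space for reinforcement learning.

`examples/watermaze_learning.py` runs the full pipeline (pixels → slow
features → population Q-learning) at the 63×63 desk scale for two seed
sets and prints the mean escape latency per 10-episode block together
with the trained policy's navigation map:

```
mean escape latency per 10-episode block:
   [347, 306, 141, 130, 127, 177]
navigation map: mean cos(angle, goal direction) = 0.55
```

Latency falling from ~350 to ~130–180 steps and a positive mean cosine
toward the (invisible) goal show the agent has learned where the target
is from raw images alone. The other examples demonstrate the SFA
eigen-solution on mixed sinusoids, node-perturbation learning on a
one-step bandit, and the variable-targets controller on the compact
state encoding.

## Library layout

| module | contents |
|---|---|
| `sfarl.sfa` | delta values, linear SFA / PCA stages, quadratic expansion, the hierarchy node |
| `sfarl.hierarchy` | receptive-field tiling, weight-shared training, the image → feature map |
| `sfarl.environment` | world state, random-walk stimuli, sprite rendering, the two tasks |
| `sfarl.agents` | population Q-learning, branch-neuron and point-neuron policy gradient, batched traces |
| `sfarl.experiments` | experiment drivers, learning-curve metrics, baselines (PCA front end, state vector) |
| `sfarl.workbench` | seed fan-out, YAML configs, HDF5 model containers, fixture streams |

`docs/methods.md` documents the models, parameter defaults, numerical
safeguards, and the limits of the desk-scale experiments.

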