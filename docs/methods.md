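# Methods

`sfarl` implements a two-stage learning system for closed-loop control on
raw visual streams: an unsupervised, hierarchical slow-feature-analysis
(SFA) front end that compresses rendered grayscale images into a few
slowly varying features, and small reward-modulated neural circuits that
learn control policies on those features. This note records the models,
the tunable parameters and their defaults, the numerical choices, and the
limits of what the desk-scale experiments demonstrate.

## Slow feature analysis

Given a multivariate signal x(t), linear SFA finds instantaneous readouts
y_j(t) = w_j · (x(t) − x̄) minimizing the delta value

    Δ(y_j) = ⟨ ẏ_j² ⟩_t ,

subject to zero mean, unit variance, and pairwise decorrelation of the
outputs, with components ordered by increasing Δ. The derivative is the
forward difference y(t+1) − y(t), so a constant channel has Δ = 0 and an
uncorrelated unit-variance channel has Δ = 2. The optimum is the solution
of the generalized symmetric eigenproblem D w = λ C w, where C is the
signal covariance and D the covariance of the forward differences; we
solve it with `scipy.linalg.eigh(D, C + εI)`, ε = 1e-10 · trace(C)/d, a
ridge that guards rank-deficient covariances (uniform image background,
for example). Eigenvalue λ_j equals Δ(y_j) on the training data. The sign
of each component is fixed so that its largest-magnitude loading is
positive; projections are stored C-contiguous so that save/load
round-trips reproduce forward passes bit for bit.

Statistics are accumulated chunk-wise (sums, outer products, difference
outer products), and temporal differences are never taken across chunk
boundaries. This is what allows one shared node to be fitted on the
time series of every receptive-field location without concatenation
artifacts.

### The hierarchy node

Each node applies: additive Gaussian noise (variance 1e-4, training-time
statistics only) → linear SFA to `sfa1_dim` channels → quadratic
expansion (the d original channels followed by all products x_i·x_j,
i ≤ j, in row-major upper-triangular order — the order is part of the
serialization contract) → linear SFA to `sfa2_dim` channels → clipping
at ±4. Linear SFA on the expanded signal is SFA over degree-2
polynomials, so a stack of L layers computes (a subset of) polynomials
of degree 2^L. Noise and clipping are numerical safeguards: noise
prevents singular covariances, clipping tames the divergence of
quadratic functions on out-of-distribution inputs. Applying a fitted
node is deterministic — noise is never re-injected at apply time, so
the closed control loop is reproducible. The noise variance and clip
bound are configurable per node.

The PCA baseline variant keeps the identical tiling, expansion, and
per-node dimensions, and changes exactly one thing: each linear stage
ranks components by explained variance (descending, unwhitened
orthonormal projection) instead of slowness. This isolates the ranking
criterion as the only difference between the two front ends.

## The hierarchical network

The full-scale architecture tiles a 155×155 image with 10×10 receptive
fields at stride 5 (30×30 grid), then 4×4 fields at stride 2 (14×14),
4×4 at stride 2 (6×6), and one top node over the 6×6 map. Per-node
first-stage dimensions are 32/32/42/52, second-stage 32/32/32/64; the
64 top outputs, ordered by slowness, are the feature vector. A tiling is
valid only when the fields cover the previous side exactly
((prev − field) divisible by the stride); `plan_geometry` enforces this
and reports the offending layer otherwise.

Training is sequential, bottom-up, with weight sharing: one node per
layer is fitted on patches gathered from every grid location (location
count × T samples) and replicated across the layer. The lower two layers
train on one stimulus stream (default 50,000 frames), the upper layers
on a second stream (default 200,000 frames) generated with identical
random-walk parameters. Patch flattening is row-major over pixels with
channels innermost.

Scaled geometries are first-class configurations. The desk profile used
throughout the experiments is 63×63 pixels, three layers (9×9 fields at
stride 6 → 10×10 grid; 4×4 at stride 2 → 4×4; one top node; 32/32/32
channels), trained on 10,000-frame streams. It preserves the overlap
ratios and converging structure of the full architecture at roughly 1%
of the compute. The full-scale training run is supported by the same
code path but is not exercised by the test suite.

## The environment

A square arena (positions in [−1, 1] per axis) contains a fish-shaped
agent (radius 0.4) and, in the variable-targets setting, a cross and a
disk (radius 0.2). Rendering is procedural and anti-aliased: world x
maps to pixel column, world y to flipped row, sprites composite by
maximum intensity, and values lie in [0, 1]. The fish is an oriented
ellipse with a triangular tail, a bright nose patch, and a nose-to-tail
intensity gradient, so heading is readable from coarse pixels as well
as from the outline; identity B additionally carries dark stripes along
the body axis. Sprites are a package design choice — the method only
requires that identity and orientation be visually distinguishable.

Unsupervised training stimuli come from a velocity-capped random walk:
per step, each velocity component receives a uniform perturbation in
±0.01 and is clamped to ±0.06 (angular velocity: ±0.01 update, ±0.04
cap); overlapping entities exchange their normal velocity components
(equal-mass elastic bounce, re-clamped to the caps afterwards — the
caps are a hard contract of the walk); positions reflect off the walls;
the agent identity flips with probability 0.002 per step. The
water-maze stimulus variant shows a single non-rotated type-A fish.

### Tasks

Water maze: the controller outputs a movement direction; the fish
advances 0.03 length units along it and is clamped to the arena.
Reaching the invisible target (at (0.5, 0.5), radius 0.15) pays +1 and
ends the episode; a clamped (wall) step pays −0.1; everything else pays
0; episodes are capped at 500 steps. These constants are package
defaults, configurable and recorded in run manifests.

Variable targets: the controller outputs forward speed v ∈ (0, 1)
(logistic soma) and angular velocity ω ∈ (−1, 1) (tanh soma); the
heading advances by 0.5·ω radians and the position by 0.05·v along the
heading, with mirror reflection at the walls (a clamp variant exists
for control experiments). Type-A fish seek the cross, type-B the disk;
the other object is a pure distractor. Reward is +1 when the Euclidean
distance to the target strictly decreased during the step and −1
otherwise (ties count as failures), so 0 is chance level. Episodes end
within 0.3 of the target or after the step cap. Initial states are
drawn uniformly and re-drawn until all pairwise separations exceed 0.8;
object positions then stay fixed for the episode.

## Population Q-learning

The Q-function is carried by M = 36 linear neurons with uniformly
spaced preferred directions φ_a; neuron a's output w_a · y is the value
of moving in direction φ_a. The greedy action is the angle of the
population vector Σ_a Q_a (cos φ_a, sin φ_a) (a resultant below 1e-12
falls back to a uniform random angle). Exploration is movement-level
ε-greedy: with probability ε a uniform random direction is held for a
geometric-duration movement (mean 25 steps, interrupted at walls).
Per-step memoryless exploration almost never finds the target within
the episode cap at desk scale; persistent movements sweep the arena
ballistically. Because Q-learning is off-policy, the shape of the
behaviour policy does not bias the value estimate.

One learning cycle: compute Q-values; form the population vector;
choose the action; enforce a Gaussian activity profile around the
chosen angle on the ring (width 1.5 ring spacings); update the
eligibility trace; execute; compute the TD error; update weights by
η_t · δ · e with η_t = η₀ / (1 + t/τ).

Numerical choices that keep linear off-policy TD stable, each adopted
after observing the corresponding failure mode in pilots:

- **Watkins trace handling with replacing traces.** The trace decays as
  γλe and restarts on exploratory actions; per synapse, the current
  profile⊗feature contribution replaces the decayed memory wherever it
  dominates. Accumulating traces diverged whenever the state lingered
  (e.g. pressed against a wall, where features barely change).
- **Readout-consistent greedy bootstrap.** The target is
  R + γ · Q(s′, a*′), where a*′ is the greedy population direction at
  s′ and Q(s′, a*′) is read out with the same Gaussian profile used
  for Q(s, a). A raw per-neuron max chases the largest noise excursion
  on the ring and, amplified by the bootstrap, inflated value estimates
  to ~20× the reachable return.
- **TD-error clipping** at the reward scale (±1), bounding any single
  update.
- **A unit bias input.** Slow features are zero-mean by construction,
  so without a bias the value function's constant level is
  unrepresentable (localized place-cell bases span constants
  implicitly; a global zero-mean basis does not).

Defaults, calibrated on the scaled water maze: γ = 0.98 (a shorter
horizon cannot carry credit across the arena), λ = 0.92, ε = 0.05,
η₀ = 0.02, τ = 2e5, initial weights N(0, 0.01²). Terminal bootstrap is
suppressed only on goal contact; a timeout cut-off still bootstraps.

On the desk profile (16 slowest features, 10 seed sets, 100 episodes)
the 10-seed mean escape latency falls from ≈300–350 steps to ≈130–170
and the running mean enters and stays inside the 20% band of the final
level at episode ≈37 (two disjoint seed sets). The plateau detector
uses a trailing 20-episode running mean against the final 20-episode
mean so that both averages carry the same sampling noise. The final
latency level is exploration-bound: with ε = 0.05 and 25-step
exploratory movements roughly half of all steps are exploratory, so
even a perfect policy would average well above the ~35-step optimum.

## Branch-neuron policy gradient

The somatic input of a control neuron is u = Σ_k q_k b_k + b₀ + ξ with
branch activations b_k = tanh(w_k · x), exploration noise ξ uniform on
±0.5, and output y = σ(u) (tanh for the turn neuron, logistic for the
speed neuron). The update correlates the injected noise with the
deviation of the reward from its per-trace exponential baseline R̄
(time constant 50 steps; the baseline is applied before absorbing the
current reward, and the first reward initializes it):

    Δw_kj = η_w (R − R̄) ξ q_k (1 − b_k²) x_j
    Δq_k  = η_q (R − R̄) ξ b_k
    Δb₀   = η_b (R − R̄) ξ

This is node perturbation at the soma: the expected update is
proportional to the gradient of the expected reward with respect to
each parameter (verified against finite differences, cosine ≈ 1.0, and
exercised as an oracle battery in the tests). No eligibility traces are
used. The point-neuron baseline applies the same rule independently to
every neuron of a two-layer feed-forward network (50 hidden units).

Initialization matters for this rule: with weights and couplings both
near zero the two gradient factors (q_k for the weights, b_k for the
couplings) vanish together and learning never starts. The default
initialization draws strong random branch weights (total branch input
scale ≈ 3) and weak couplings (≈ 0.1): the branches form a rich fixed
nonlinear basis whose couplings are learned as a fast, nearly linear
readout while the branch weights refine slowly. Defaults: K = 50
branches, η_w = 0.01, η_q = η_b = 0.05.

Batched training advances all parallel traces by one step, averages the
per-trace parameter deltas, and applies them once; finished traces are
re-initialized while the others continue. Each trace keeps its own
reward baseline.

## What the desk-scale experiments do and do not show

The synthetic world emulates the statistics the front end needs —
bounded smooth motion, velocity caps, object bouncing, rare identity
switches, pose-continuous rendering — but not sensor noise, occlusion,
lighting variation, or first-person perspective; conclusions transfer
to such settings only insofar as slowness remains the right prior.

At the desk scale the slow features carry agent position essentially
linearly — the latent-recovery test finds a single top feature whose
correlation with the hidden x-position exceeds 0.99 — and the
water-maze pipeline (pixels to slow features to population Q-learning)
reproduces fast, reliable escape-latency learning with a goal-directed
navigation map; both are measured by the test suite and the acceptance
script.

The variable-targets task is harder at reduced scale. Desk-scale
hierarchies carry position, object positions, and identity well but
encode orientation only weakly: orientation enters the pixels through a
rotation — a deeply nonlinear map — and at small image sizes and
training budgets the quadratic hierarchy allocates its limited per-node
channels to the more compressible positional variables. Since the turn
policy needs heading error, control learning from desk-scale slow
features is slow: the compact state-vector arm learns the task clearly
at the suite's training budget, the slow-feature arm does not show a
measurable reward improvement at the same budget (the corresponding
ordering tests are expected to fail at this scale and are left in the
suite as the faithful measurement), and the representation-level
ordering against the PCA baseline (position linearly readable from SFA
features, not from PCA features) is the robust desk-scale signature of
the front-end difference. The full-scale configuration (155×155, 50k/200k
frames, millions of control steps) is expressible with the same code
but outside the test suite's scale; the package makes no empirical
claim about it beyond the architecture arithmetic.

The point-neuron versus branch-neuron comparison is run on the compact
state encoding, which isolates the controller difference from the
front-end quality; the branch neuron's advantage (clear learning versus
near-chance at equal budget) matches its extra expressive power.

## Reproducibility

All randomness flows from explicit integer seeds through labelled
`SeedSequence` fan-out (`workbench.child_seed`); no function touches
global random state. Runs serialize their configuration and seeds as
YAML manifests; trained hierarchies round-trip bit-exactly through the
HDF5 container. `scripts/acceptance.py --seed N --out results.json`
re-runs the tiling arithmetic, the stimulus statistics, and the scaled
water-maze experiment from scratch and writes the measured quantities.
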