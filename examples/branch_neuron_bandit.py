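"""Node-perturbation learning on a one-step bandit.

A single branch neuron receives a fixed input and is rewarded by
R = -(y - 0.7)^2.  The only learning signal is the correlation between
the injected somatic noise and the reward's deviation from its slow
baseline; the output climbs to the target without any explicit
gradient computation.
"""

import numpy as np

from sfarl import BranchNeuron, RewardFilter, branch_forward, pg_update
from sfarl.agents import apply_deltas

rng = np.random.default_rng(0)
x = rng.normal(size=4)
neuron = BranchNeuron(4, n_branches=3, eta_w=0.05, eta_q=0.05, eta_b=0.05)
neuron.initialize(rng, scale=1.0, coupling_scale=0.3)
baseline = RewardFilter(tau=30)

outputs = []
for step in range(4000):
    y, internals = branch_forward(neuron, x, rng)
    reward = -((y - 0.7) ** 2)
    apply_deltas(neuron, pg_update(neuron, internals, x, reward, baseline))
    outputs.append(y)

print(f"mean output, first 100 steps: {np.mean(outputs[:100]):+.3f}")
print(f"mean output, last 100 steps:  {np.mean(outputs[-100:]):+.3f}  (target 0.7)")
# The residual spread around 0.7 is the exploration noise the neuron
# needs to keep estimating the gradient.
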