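"""Scaled water maze end to end: pixels -> slow features -> Q-learning.

Trains a reduced-resolution hierarchy on a random-walk stimulus stream,
then runs the population Q-learner on the 16 slowest features for two
seed sets.  Escape latency (steps to reach the invisible target) falls
as the value map forms.  ~4 minutes.
"""

import numpy as np

from sfarl import TaskConfig
from sfarl.experiments import (
    hierarchy_feature_fn,
    navigation_map,
    run_watermaze,
    train_watermaze_hierarchy,
)

model, world = train_watermaze_hierarchy(seed=1, image_side=63, n_frames=6000)
task = TaskConfig()
result = run_watermaze(model, world, task, seeds=[11, 12], n_episodes=60)

print("mean escape latency per 10-episode block:")
print("  ", [int(v) for v in result.mean_curve.reshape(6, 10).mean(axis=1)])

pos, ang = navigation_map(
    result.populations[0], hierarchy_feature_fn(model, world, 16), world, grid_n=5
)
goal = np.asarray(task.target_pos)
to_goal = np.arctan2(goal[1] - pos[:, 1], goal[0] - pos[:, 0])
print(f"navigation map: mean cos(angle, goal direction) = "
      f"{np.cos(ang - to_goal).mean():.2f}")
# Latency dropping over blocks and a positive mean cosine show the
# greedy policy pointing toward the (never rendered) target.
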