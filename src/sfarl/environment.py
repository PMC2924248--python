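"""Simulated 2D world: random-walk stimuli, sprite rendering, and tasks.

An agent (a fish) and up to two marker objects (a cross and a filled
disk) move in a square arena.  The world is rendered from a bird's-eye
view to a square grayscale image that is the only input the learning
system sees.  Two closed-loop tasks are defined on top of the same
world:

* a water-maze task — a single non-rotated fish must find an invisible
  fixed target; the controller outputs a movement direction and the
  rewards are sparse (goal reward, wall penalty, otherwise zero);
* a variable-targets task — the fish carries one of two identities,
  each associated with a different target object (type A seeks the
  cross, type B the disk); the controller outputs forward speed and
  angular velocity, and each step is rewarded +1 if it brought the
  agent strictly closer to its target and -1 otherwise.

Unsupervised training stimuli are produced by a velocity-capped random
walk: every step each velocity component gets a uniform perturbation,
is clamped, positions bounce off the walls (and objects off each
other), and the agent identity flips with a small probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidTaskError(ValueError):
    """Raised when a step function is used with the wrong task kind."""


class EpisodeInitError(RuntimeError):
    """Raised when no valid initial state can be drawn."""


@dataclass(frozen=True)
class WorldConfig:
    """Arena geometry and random-walk parameters (world units / per step)."""

    bounds: tuple[float, float] = (-1.0, 1.0)
    resolution: int = 155
    agent_radius: float = 0.4
    object_radius: float = 0.2
    max_speed: float = 0.06
    max_speed_update: float = 0.01
    max_ang_speed: float = 0.04
    max_ang_update: float = 0.01
    identity_switch_prob: float = 0.002
    n_objects: int = 2
    rotate_agent: bool = True
    switch_identity: bool = True

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds: lower bound must be below upper bound")
        if self.agent_radius * 2 > (hi - lo) or self.object_radius * 2 > (hi - lo):
            raise ValueError("bounds: radii do not fit inside the arena")
        if not 0.0 <= self.identity_switch_prob <= 1.0:
            raise ValueError("identity_switch_prob: must be a probability in [0, 1]")


def watermaze_world(resolution: int = 155) -> WorldConfig:
    """Water-maze stimulus world: only the non-rotated type-A fish is shown."""
    return WorldConfig(
        resolution=resolution, n_objects=0, rotate_agent=False, switch_identity=False
    )


@dataclass
class WorldState:
    """Pose and velocities of every entity; identity 0 = type A, 1 = type B."""

    agent_pos: np.ndarray
    agent_vel: np.ndarray
    agent_angle: float
    agent_ang_vel: float
    agent_identity: int
    object_pos: np.ndarray  # (n_objects, 2); row 0 = cross, row 1 = disk
    object_vel: np.ndarray

    def copy(self) -> "WorldState":
        return WorldState(
            self.agent_pos.copy(),
            self.agent_vel.copy(),
            float(self.agent_angle),
            float(self.agent_ang_vel),
            int(self.agent_identity),
            self.object_pos.copy(),
            self.object_vel.copy(),
        )


def wrap_angle(angle: float) -> float:
    return float((angle + np.pi) % (2 * np.pi) - np.pi)


def initial_state(cfg: WorldConfig, rng: np.random.Generator) -> WorldState:
    lo, hi = cfg.bounds
    return WorldState(
        agent_pos=rng.uniform(lo, hi, size=2),
        agent_vel=np.zeros(2),
        agent_angle=float(rng.uniform(-np.pi, np.pi)) if cfg.rotate_agent else 0.0,
        agent_ang_vel=0.0,
        agent_identity=int(rng.integers(0, 2)) if cfg.switch_identity else 0,
        object_pos=rng.uniform(lo, hi, size=(cfg.n_objects, 2)),
        object_vel=np.zeros((cfg.n_objects, 2)),
    )


def _bounce_axis(pos: float, vel: float, lo: float, hi: float) -> tuple[float, float]:
    if pos < lo:
        return 2 * lo - pos, -vel
    if pos > hi:
        return 2 * hi - pos, -vel
    return pos, vel


def random_walk_step(state: WorldState, cfg: WorldConfig, rng: np.random.Generator) -> WorldState:
    """One step of the training-stimulus random walk.

    Velocities receive uniform perturbations in +-max_speed_update and
    are clamped to +-max_speed componentwise (angular velocity with its
    own caps); entities whose discs overlap and approach exchange their
    normal velocity components (equal-mass elastic bounce); positions
    advance by the velocities and reflect off the walls; the identity
    flips with probability identity_switch_prob.
    """
    s = state.copy()
    lo, hi = cfg.bounds
    n_ent = 1 + cfg.n_objects
    vel = np.vstack([s.agent_vel[None, :], s.object_vel])
    pos = np.vstack([s.agent_pos[None, :], s.object_pos])
    radii = np.array([cfg.agent_radius] + [cfg.object_radius] * cfg.n_objects)

    vel = vel + rng.uniform(-cfg.max_speed_update, cfg.max_speed_update, size=vel.shape)
    vel = np.clip(vel, -cfg.max_speed, cfg.max_speed)

    # pairwise bounce: exchange velocity components along the line of centers
    for i in range(n_ent):
        for j in range(i + 1, n_ent):
            d = pos[i] - pos[j]
            dist = float(np.hypot(*d))
            if dist < radii[i] + radii[j] and dist > 1e-12:
                normal = d / dist
                vi, vj = float(vel[i] @ normal), float(vel[j] @ normal)
                if vi - vj < 0:  # approaching
                    vel[i] += (vj - vi) * normal
                    vel[j] += (vi - vj) * normal
    # exchanging normal components can mix axes; the speed caps are a hard
    # contract of the walk, so re-clamp after collision resolution
    vel = np.clip(vel, -cfg.max_speed, cfg.max_speed)

    pos = pos + vel
    for k in range(n_ent):
        for ax in range(2):
            pos[k, ax], vel[k, ax] = _bounce_axis(pos[k, ax], vel[k, ax], lo, hi)

    s.agent_pos, s.object_pos = pos[0], pos[1:]
    s.agent_vel, s.object_vel = vel[0], vel[1:]

    if cfg.rotate_agent:
        w = s.agent_ang_vel + rng.uniform(-cfg.max_ang_update, cfg.max_ang_update)
        s.agent_ang_vel = float(np.clip(w, -cfg.max_ang_speed, cfg.max_ang_speed))
        s.agent_angle = wrap_angle(s.agent_angle + s.agent_ang_vel)
    if cfg.switch_identity and rng.uniform() < cfg.identity_switch_prob:
        s.agent_identity = 1 - s.agent_identity
    return s


# ---------------------------------------------------------------------------
# rendering


def _pixel_grid(cfg: WorldConfig) -> tuple[np.ndarray, np.ndarray, float]:
    lo, hi = cfg.bounds
    px = (hi - lo) / cfg.resolution
    centers = lo + (np.arange(cfg.resolution) + 0.5) * px
    X = centers[None, :]          # world x increases with pixel column
    Y = centers[::-1][:, None]    # world y increases upward (row 0 = top)
    return X, Y, px


def _soft(d: np.ndarray, px: float) -> np.ndarray:
    # anti-aliased coverage from a signed inside-distance (world units)
    return np.clip(d / px + 0.5, 0.0, 1.0)


def _draw_disk(X, Y, px, pos, radius) -> np.ndarray:
    return _soft(radius - np.hypot(X - pos[0], Y - pos[1]), px)


def _draw_cross(X, Y, px, pos, radius) -> np.ndarray:
    dx, dy = np.abs(X - pos[0]), np.abs(Y - pos[1])
    w = 0.28 * radius
    bar_h = np.minimum(_soft(radius - dx, px), _soft(w - dy, px))
    bar_v = np.minimum(_soft(w - dx, px), _soft(radius - dy, px))
    return np.maximum(bar_h, bar_v)


def _draw_fish(X, Y, px, pos, angle, identity, radius) -> np.ndarray:
    dx, dy = X - pos[0], Y - pos[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy     # along the body axis, nose at +u
    v = -s * dx + c * dy
    a, b = radius, 0.55 * radius
    # body: ellipse with an approximate inside-distance for anti-aliasing
    q = np.hypot(u / a, v / b)
    body = _soft((1.0 - q) * b, px)
    # tail: triangle widening toward the rear — makes the sprite anisotropic
    rear = -u - 0.6 * a
    half_w = 0.7 * b * np.clip(rear / (0.8 * a), 0.0, 1.0)
    in_rear = np.minimum(_soft(rear, px), _soft(0.8 * a - rear, px))
    tail = np.minimum(in_rear, _soft(half_w - np.abs(v), px))
    # the intensity gradient runs nose-bright to tail-dark, so heading is
    # readable from coarse pixels, not only from the outline
    head_grad = 0.55 + 0.45 * np.clip((u + a) / (2 * a), 0.0, 1.0)
    nose = _soft(0.35 * b - np.hypot(u - 0.75 * a, v), px)
    shape = np.maximum(body, tail)
    if identity == 0:
        texture = head_grad
    else:
        # identity B: darker, striped along the body axis
        texture = head_grad * (0.55 + 0.35 * np.cos(2 * np.pi * u / (0.8 * radius)))
    return np.maximum(shape * texture, nose)


def render(state: WorldState, cfg: WorldConfig) -> np.ndarray:
    """Deterministic grayscale rendering, pixel values in [0, 1].

    World x maps to pixel column, world y to flipped row (y up), using
    pixel centers; sprites are composited by maximum intensity with
    anti-aliased edges so intensities vary continuously with pose.
    """
    X, Y, px = _pixel_grid(cfg)
    img = np.zeros((cfg.resolution, cfg.resolution))
    if cfg.n_objects >= 1:
        img = np.maximum(img, _draw_cross(X, Y, px, state.object_pos[0], cfg.object_radius))
    if cfg.n_objects >= 2:
        img = np.maximum(img, _draw_disk(X, Y, px, state.object_pos[1], cfg.object_radius))
    img = np.maximum(
        img,
        _draw_fish(X, Y, px, state.agent_pos, state.agent_angle,
                   state.agent_identity, cfg.agent_radius),
    )
    return np.clip(img, 0.0, 1.0)


def generate_training_stream(
    n: int,
    cfg: WorldConfig,
    rng: np.random.Generator,
    return_states: bool = False,
):
    """Render ``n`` consecutive frames of the random walk.

    Returns an (n, resolution, resolution) float32 array, plus the list
    of world states when ``return_states`` is set.
    """
    if n < 1:
        raise ValueError("need at least one frame")
    state = initial_state(cfg, rng)
    frames = np.empty((n, cfg.resolution, cfg.resolution), dtype=np.float32)
    states = []
    for t in range(n):
        state = random_walk_step(state, cfg, rng)
        frames[t] = render(state, cfg)
        if return_states:
            states.append(state.copy())
    return (frames, states) if return_states else frames


# ---------------------------------------------------------------------------
# tasks


@dataclass(frozen=True)
class TaskConfig:
    """Task dynamics and reward constants.

    Water maze: the controller outputs a direction; the fish advances
    ``step_length`` along it and the position is clamped to the arena.
    Variable targets: the controller outputs speed v and angular
    velocity omega; the orientation advances by ang_scale*omega and the
    position by speed_scale*v along the heading, with mirror (default)
    or clamp boundary handling.
    """

    kind: str = "watermaze"  # "watermaze" | "variable_targets"
    target_pos: tuple[float, float] = (0.5, 0.5)
    goal_radius: float = 0.15
    step_length: float = 0.03
    goal_reward: float = 1.0
    wall_penalty: float = -0.1
    max_steps: int = 500
    speed_scale: float = 0.05
    ang_scale: float = 0.5
    step_reward: float = 1.0
    min_separation: float = 0.8
    boundary_mode: str = "mirror"  # "mirror" | "clamp"
    vt_goal_radius: float = 0.3

    def __post_init__(self):
        if self.goal_radius <= 0 or self.vt_goal_radius <= 0:
            raise ValueError("goal_radius: must be > 0")
        if self.max_steps <= 0:
            raise ValueError("max_steps: must be > 0")
        if self.kind not in ("watermaze", "variable_targets"):
            raise ValueError(f"kind: unknown task kind {self.kind!r}")
        if self.boundary_mode not in ("mirror", "clamp"):
            raise ValueError(f"boundary_mode: unknown mode {self.boundary_mode!r}")


@dataclass
class StepOutcome:
    state: WorldState
    reward: float
    done: bool
    info: dict


def init_episode(
    task_cfg: TaskConfig, world_cfg: WorldConfig, rng: np.random.Generator
) -> WorldState:
    """Draw a valid initial state.

    Positions, orientation, and identity are uniform; variable-targets
    draws are rejected until all pairwise separations exceed
    ``min_separation`` (object positions stay fixed for the episode);
    water-maze starts are redrawn if already inside the goal radius.
    """
    lo, hi = world_cfg.bounds
    for _ in range(10_000):
        state = initial_state(world_cfg, rng)
        state.agent_vel[:] = 0.0
        state.object_vel[:] = 0.0
        if task_cfg.kind == "watermaze":
            state.agent_angle = 0.0
            state.agent_identity = 0
            if np.hypot(*(state.agent_pos - np.asarray(task_cfg.target_pos))) > task_cfg.goal_radius:
                return state
        else:
            pts = np.vstack([state.agent_pos[None, :], state.object_pos])
            seps = [
                np.hypot(*(pts[i] - pts[j]))
                for i in range(len(pts))
                for j in range(i + 1, len(pts))
            ]
            if min(seps) >= task_cfg.min_separation:
                return state
    raise EpisodeInitError(
        "could not draw a valid initial state in 10,000 attempts; "
        "check min_separation against the arena size"
    )


def watermaze_step(
    state: WorldState,
    direction: float,
    task_cfg: TaskConfig,
    world_cfg: WorldConfig,
    step_index: int = 0,
) -> StepOutcome:
    """Advance the fish ``step_length`` along ``direction`` (radians).

    The position is hard-clamped to the arena; clamping yields the wall
    penalty, reaching the (invisible) target yields the goal reward,
    every other step is reward 0.
    """
    if task_cfg.kind != "watermaze":
        raise InvalidTaskError("watermaze_step used with a non-watermaze TaskConfig")
    s = state.copy()
    lo, hi = world_cfg.bounds
    raw = s.agent_pos + task_cfg.step_length * np.array(
        [np.cos(direction), np.sin(direction)]
    )
    clamped = np.clip(raw, lo, hi)
    wall_hit = bool(np.any(raw != clamped))
    s.agent_pos = clamped
    dist = float(np.hypot(*(s.agent_pos - np.asarray(task_cfg.target_pos))))
    goal = dist <= task_cfg.goal_radius
    reward = task_cfg.goal_reward if goal else (task_cfg.wall_penalty if wall_hit else 0.0)
    done = goal or (step_index + 1 >= task_cfg.max_steps)
    return StepOutcome(s, reward, done, {"wall_hit": wall_hit, "distance": dist, "goal": goal})


def _mirror_axis(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    x = (x - lo) % (2 * span)
    return lo + (x if x <= span else 2 * span - x)


def target_index(state: WorldState) -> int:
    """Type A (identity 0) seeks the cross (object 0), type B the disk."""
    return 0 if state.agent_identity == 0 else 1


def variable_targets_step(
    state: WorldState,
    v: float,
    omega: float,
    task_cfg: TaskConfig,
    world_cfg: WorldConfig,
    step_index: int = 0,
) -> StepOutcome:
    """Speed/turn dynamics with the distance-progress reward.

    phi += ang_scale * omega; the position advances speed_scale * v
    along (cos phi, sin phi) with mirror or clamp boundary handling.
    The reward is +step_reward when the Euclidean distance to the
    identity's target object strictly decreased and -step_reward
    otherwise; the distractor never affects the outcome.
    """
    if task_cfg.kind != "variable_targets":
        raise InvalidTaskError("variable_targets_step used with a non-variable-targets TaskConfig")
    s = state.copy()
    lo, hi = world_cfg.bounds
    target = s.object_pos[target_index(s)]
    dist_before = float(np.hypot(*(s.agent_pos - target)))
    s.agent_angle = wrap_angle(s.agent_angle + task_cfg.ang_scale * float(omega))
    step = task_cfg.speed_scale * float(v) * np.array(
        [np.cos(s.agent_angle), np.sin(s.agent_angle)]
    )
    raw = s.agent_pos + step
    if task_cfg.boundary_mode == "mirror":
        s.agent_pos = np.array([_mirror_axis(raw[0], lo, hi), _mirror_axis(raw[1], lo, hi)])
    else:
        s.agent_pos = np.clip(raw, lo, hi)
    dist_after = float(np.hypot(*(s.agent_pos - target)))
    reward = task_cfg.step_reward if dist_after < dist_before else -task_cfg.step_reward
    goal = dist_after <= task_cfg.vt_goal_radius
    done = goal or (step_index + 1 >= task_cfg.max_steps)
    return StepOutcome(
        s, reward, done, {"distance": dist_after, "goal": goal, "wall_hit": bool(np.any(raw != s.agent_pos))}
    )
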