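"""Core update rules of the minimal proprioceptive-kinesthetic (PK) model.

Agents are constant-speed points on a periodic square of side ``L``.
Each agent carries a heading ``theta`` in ``(-pi, pi]`` and a PK skill
``p > 0`` that divides every noise term: a skilled agent (high ``p``)
perceives its own position and motion accurately, an unskilled one is
buffeted by the noise.

One synchronous update step:

1.  Base heading.  With the social term active, the base heading of
    agent ``i`` is the circular mean of all headings within the
    interaction radius ``r`` (minimum-image periodic distance, counting
    the agent itself) — the two-agent instance of Vicsek alignment.
    Otherwise it is the agent's own heading.
2.  Heading update.  The new heading is the weighted scalar sum

        theta' = wrap( alpha * wrap(base + xi2/p)
                     + beta  * wrap(theta_g + xi3/p) )

    where ``theta_g`` is the environmental gradient heading at the
    agent's *actual* position (not the noise-perturbed perceived one)
    and ``xi2, xi3`` are fresh uniform draws on ``[-xi, xi]``.  With the
    environment disabled (``beta = 0``) this reduces to
    ``wrap(base + xi2/p)``.
3.  Position update.  ``x' = (x + xi1/p + kappa * u(theta')) mod L``
    per coordinate, with ``u = (cos theta', sin theta')`` and ``xi1`` a
    2-vector of independent uniform draws on ``[-xi, xi]``.

All headings are computed from the time-``t`` snapshot before any
position is advanced.  The per-step draw order is fixed — for each
agent in index order: ``xi2``, ``xi3``, ``xi1_x``, ``xi1_y`` — so a
scalar reference loop can replay the exact stream of the vectorized
stepper.  ``xi3`` is drawn even when the environment term is off, to
keep the stream layout independent of the configuration flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import SimulationConfig
from .environment import GaussianField, gradient_angle

__all__ = [
    "AgentState",
    "NoiseDraws",
    "Trajectory",
    "wrap_angle",
    "heading_self",
    "periodic_distance",
    "circular_mean_in_radius",
    "heading_update",
    "position_update",
    "step",
    "simulate",
]

_TWO_PI = 2.0 * math.pi
_WEIGHT_TOL = 1e-12


@dataclass
class AgentState:
    """Position in ``[0, L)^2``, heading in ``(-pi, pi]``, and skill ``p``."""

    position: np.ndarray
    heading: float
    p: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.p <= 0:
            raise ValueError(f"skill p must be positive, got {self.p}")


@dataclass(frozen=True)
class NoiseDraws:
    """One agent's noise draws for one step: xi1 (2-vector), xi2, xi3."""

    xi1: np.ndarray
    xi2: float
    xi3: float

    @classmethod
    def from_row(cls, row: np.ndarray) -> "NoiseDraws":
        """Unpack the fixed draw layout (xi2, xi3, xi1_x, xi1_y)."""
        return cls(xi1=np.asarray(row[2:4], dtype=float),
                   xi2=float(row[0]), xi3=float(row[1]))


@dataclass(frozen=True)
class Trajectory:
    """One run: ``n_steps + 1`` snapshots of positions and headings.

    ``positions`` has shape ``(n_steps + 1, n_agents, 2)`` and
    ``headings`` shape ``(n_steps + 1, n_agents)``.
    """

    positions: np.ndarray
    headings: np.ndarray
    config: SimulationConfig

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def heading_increments(self) -> np.ndarray:
        """Per-step heading changes, wrapped to ``(-pi, pi]``.

        For self-only dynamics each increment is exactly ``xi2/p`` (noise
        is small compared with pi), so these recover the raw noise stream.
        """
        return wrap_angle(np.diff(self.headings, axis=0))

    def states(self, t: int) -> list[AgentState]:
        """Snapshot at step ``t`` as a list of :class:`AgentState`."""
        return [
            AgentState(self.positions[t, i].copy(), float(self.headings[t, i]),
                       self.config.p[i])
            for i in range(self.n_agents)
        ]


def wrap_angle(theta):
    """Wrap an angle (radians) to the half-open interval ``(-pi, pi]``.

    Accepts scalars or arrays.  ``-pi`` maps to ``pi``.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_angle requires finite input")
    # exact identity inside the target interval (no modular round-trip)
    wrapped = np.where((arr > -math.pi) & (arr <= math.pi),
                       arr, math.pi - (math.pi - arr) % _TWO_PI)
    return float(wrapped) if np.ndim(theta) == 0 else wrapped


def heading_self(theta: float, xi2: float, p: float) -> float:
    """Self-only heading update: ``wrap(theta + xi2 / p)``."""
    if p <= 0:
        raise ValueError(f"skill p must be positive, got {p}")
    return wrap_angle(theta + xi2 / p)


def periodic_distance(a, b, L: float) -> float:
    """Minimum-image Euclidean distance on the ``L``-periodic torus."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d -= L * np.round(d / L)
    return float(np.linalg.norm(d, axis=-1)) if np.ndim(d) == 1 else np.linalg.norm(d, axis=-1)


def circular_mean_in_radius(states: Sequence[AgentState], i: int, r: float,
                            L: float) -> float:
    """Circular mean heading over all agents within radius ``r`` of agent ``i``.

    The neighbourhood uses minimum-image periodic distance and counts the
    agent itself.  With no neighbour besides itself, the agent's own heading
    is returned unchanged.
    """
    xi = states[i].position
    sines, cosines = [], []
    for s in states:
        if periodic_distance(xi, s.position, L) <= r:
            sines.append(math.sin(s.heading))
            cosines.append(math.cos(s.heading))
    if len(sines) == 1:
        return states[i].heading
    return wrap_angle(math.atan2(np.mean(sines), np.mean(cosines)))


def heading_update(theta_base: float, theta_g: float, draws: NoiseDraws,
                   p: float, alpha: float, beta: float,
                   mixing: str = "scalar") -> float:
    """Weighted heading update mixing the self/social and gradient terms.

    ``theta_base`` is the agent's own heading (self-only dynamics) or the
    neighbourhood circular mean (social dynamics); ``theta_g`` is the
    gradient heading at the agent's position.  Each bracketed term carries
    its own noise draw divided by the skill, is wrapped to ``(-pi, pi]``,
    and the result of the scalar weighted sum is wrapped again.
    """
    if p <= 0:
        raise ValueError(f"skill p must be positive, got {p}")
    if abs(alpha + beta - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"alpha + beta must equal 1, got {alpha} + {beta}")
    term_self = wrap_angle(theta_base + draws.xi2 / p)
    term_env = wrap_angle(theta_g + draws.xi3 / p)
    if mixing == "scalar":
        return wrap_angle(alpha * term_self + beta * term_env)
    if mixing == "circular":
        y = alpha * math.sin(term_self) + beta * math.sin(term_env)
        x = alpha * math.cos(term_self) + beta * math.cos(term_env)
        return wrap_angle(math.atan2(y, x))
    raise ValueError(f"unknown mixing {mixing!r}")


def position_update(state: AgentState, new_heading: float, xi1,
                    config: SimulationConfig) -> np.ndarray:
    """Advance one agent: ``(x + xi1/p + kappa * u(theta')) mod L``."""
    if state.p <= 0:
        raise ValueError(f"skill p must be positive, got {state.p}")
    u = np.array([math.cos(new_heading), math.sin(new_heading)])
    return (state.position + np.asarray(xi1, dtype=float) / state.p
            + config.kappa * u) % config.L


# ---------------------------------------------------------------------------
# Vectorized stepping kernel
#
# Arrays carry a leading replicate axis R so that a whole ensemble advances
# in lock-step: pos (R, n, 2), theta (R, n), noise (R, n, 4) with the draw
# layout (xi2, xi3, xi1_x, xi1_y).  A single run is the R = 1 case.
# ---------------------------------------------------------------------------

def _social_base(pos: np.ndarray, theta: np.ndarray, r: float,
                 L: float) -> np.ndarray:
    """Per-agent circular-mean base heading over neighbours within ``r``."""
    disp = pos[:, :, np.newaxis, :] - pos[:, np.newaxis, :, :]
    disp -= L * np.round(disp / L)
    within = np.linalg.norm(disp, axis=-1) <= r          # (R, n, n), diag True
    count = within.sum(axis=-1)
    sin_m = (within * np.sin(theta)[:, np.newaxis, :]).sum(axis=-1) / count
    cos_m = (within * np.cos(theta)[:, np.newaxis, :]).sum(axis=-1) / count
    mean = wrap_angle(np.arctan2(sin_m, cos_m))
    # An isolated agent keeps its heading exactly (no atan2 round-trip).
    return np.where(count == 1, theta, mean)


def _step_arrays(pos: np.ndarray, theta: np.ndarray, noise: np.ndarray,
                 config: SimulationConfig, p: np.ndarray,
                 field: GaussianField | None):
    """One synchronous step on replicate-stacked arrays; returns new arrays."""
    xi2 = noise[..., 0]
    xi3 = noise[..., 1]
    xi1 = noise[..., 2:4]

    if config.social_enabled and config.n_agents > 1:
        base = _social_base(pos, theta, config.r, config.L)
    else:
        base = theta

    term_self = wrap_angle(base + xi2 / p)
    if config.env_enabled:
        theta_g = gradient_angle(pos, field, fallback=theta)
        term_env = wrap_angle(theta_g + xi3 / p)
        if config.angle_mixing == "scalar":
            new_theta = wrap_angle(config.alpha * term_self
                                   + config.beta * term_env)
        else:
            y = config.alpha * np.sin(term_self) + config.beta * np.sin(term_env)
            x = config.alpha * np.cos(term_self) + config.beta * np.cos(term_env)
            new_theta = wrap_angle(np.arctan2(y, x))
    else:
        # beta = 0 by config validation: the update is the self term alone.
        new_theta = term_self

    u = np.stack([np.cos(new_theta), np.sin(new_theta)], axis=-1)
    new_pos = (pos + xi1 / p[..., np.newaxis] + config.kappa * u) % config.L
    return new_pos, new_theta


def _p_array(config: SimulationConfig) -> np.ndarray:
    return np.asarray(config.p, dtype=float)


def step(states: Sequence[AgentState], config: SimulationConfig,
         rng: np.random.Generator) -> list[AgentState]:
    """Advance all agents one synchronous step, drawing noise from ``rng``.

    Draw order: one ``uniform(-xi, xi)`` block of shape ``(n_agents, 4)``
    laid out as (xi2, xi3, xi1_x, xi1_y) per agent — byte-identical to the
    stream :func:`simulate` consumes.
    """
    n = len(states)
    if n != config.n_agents:
        raise ValueError(f"got {n} states for n_agents={config.n_agents}")
    noise = rng.uniform(-config.xi, config.xi, size=(n, 4))
    pos = np.stack([s.position for s in states])[np.newaxis]
    theta = np.array([s.heading for s in states])[np.newaxis]
    field = GaussianField(config.L) if config.env_enabled else None
    new_pos, new_theta = _step_arrays(pos, theta, noise[np.newaxis], config,
                                      _p_array(config), field)
    return [AgentState(new_pos[0, i], float(new_theta[0, i]), states[i].p)
            for i in range(n)]


def initial_conditions(config: SimulationConfig, rng: np.random.Generator):
    """Random initial snapshot: positions uniform on ``[0, L)^2``, headings
    uniform on ``(-pi, pi]``.  Draw order: positions block, then headings."""
    pos = rng.uniform(0.0, config.L, size=(config.n_agents, 2))
    theta = wrap_angle(rng.uniform(-math.pi, math.pi, size=config.n_agents))
    return pos, theta


def simulate(config: SimulationConfig) -> Trajectory:
    """Run one full simulation from ``config`` (seeded, fully reproducible).

    Returns a :class:`Trajectory` with ``n_steps + 1`` snapshots.  The
    noise for the whole run is drawn in one block after the initial
    conditions; because uniform variates come off the generator stream
    sequentially, this is draw-for-draw identical to calling :func:`step`
    repeatedly with the same generator.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_agents, config.n_steps
    positions = np.empty((T + 1, n, 2))
    headings = np.empty((T + 1, n))
    positions[0], headings[0] = initial_conditions(config, rng)
    noise = rng.uniform(-config.xi, config.xi, size=(T, n, 4))
    field = GaussianField(config.L) if config.env_enabled else None
    p = _p_array(config)
    pos, theta = positions[0][np.newaxis], headings[0][np.newaxis]
    for t in range(T):
        pos, theta = _step_arrays(pos, theta, noise[t][np.newaxis], config, p,
                                  field)
        positions[t + 1], headings[t + 1] = pos[0], theta[0]
    return Trajectory(positions=positions, headings=headings, config=config)
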