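"""Simulation configuration.

A :class:`SimulationConfig` holds every model parameter of the minimal
proprioceptive-kinesthetic (PK) agent model: the periodic square of side
``L``, the constant step length ``kappa``, the shared noise half-width
``xi``, the per-agent PK skill ``p`` (all noise terms enter divided by
``p``, so high skill means low effective noise), the heading-mixing
weights ``alpha`` (self / social term) and ``beta`` (environmental
gradient term), the interaction radius ``r`` of the social alignment
term, and the observables' parameters (arrival tolerance and
coordination threshold).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["SimulationConfig", "DEFAULT_ARRIVAL_EPSILON"]

#: Arrival tolerance used when none is given: the task counts as solved when
#: every agent is simultaneously within this Euclidean distance of the field
#: center.  Calibrated once against the chance-level two-agent search regime
#: (social alignment only, no gradient term) and then frozen; see
#: docs/methods.md.  Equal to r/2: two agents both inside the disk are
#: mutually within the interaction radius, so arrival is coordinated.
DEFAULT_ARRIVAL_EPSILON = 0.5

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulation run.

    Parameters
    ----------
    L
        Side length of the periodic square arena (length units).
    kappa
        Distance travelled per time step (constant speed).
    xi
        Half-width of the uniform noise: every noise draw is uniform on
        ``[-xi, xi]`` and enters the dynamics divided by the agent's skill.
    p
        PK skill per agent, in ``(0, 100]``.  A scalar is broadcast to all
        agents.
    alpha, beta
        Heading-mixing weights for the self/social term and the
        environmental-gradient term; must satisfy ``alpha + beta == 1``.
    r
        Interaction radius of the social alignment term (length units).
    n_steps
        Number of update steps (a run produces ``n_steps + 1`` snapshots).
    n_agents
        Number of agents (the model is studied with 1 or 2).
    seed
        Seed for the run's random generator.
    env_enabled
        Whether the environmental gradient term is active.  When disabled,
        ``beta`` must be 0.
    social_enabled
        Whether the social alignment term is active (headings averaged over
        neighbours within ``r``).
    arrival_epsilon
        Arrival tolerance: all agents within this plain Euclidean distance
        of the field center counts as task success.
    coordination_threshold
        Ensemble-mean order parameter (over the final window of a run) at or
        above which the agents are judged coordinated.
    angle_mixing
        ``"scalar"`` (default): the heading update is the literal weighted
        sum of angle values, each bracketed term and the result wrapped to
        ``(-pi, pi]``.  ``"circular"``: weighted circular mean of the two
        terms (resultant-vector direction).
    """

    L: float = 5.0
    kappa: float = 0.05
    xi: float = 0.5
    p: tuple[float, ...] = (50.0,)
    alpha: float = 1.0
    beta: float = 0.0
    r: float = 1.0
    n_steps: int = 2500
    n_agents: int = 1
    seed: int = 0
    env_enabled: bool = False
    social_enabled: bool = False
    arrival_epsilon: float = DEFAULT_ARRIVAL_EPSILON
    coordination_threshold: float = 0.95
    angle_mixing: str = "scalar"

    def __post_init__(self) -> None:
        p = self.p
        if isinstance(p, (int, float)):
            p = (float(p),) * self.n_agents
        else:
            p = tuple(float(v) for v in p)
            if len(p) == 1 and self.n_agents > 1:
                p = p * self.n_agents
        object.__setattr__(self, "p", p)
        self._validate()

    def _validate(self) -> None:
        if not self.L > 0:
            raise ValueError(f"L must be positive, got {self.L}")
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not self.xi >= 0:
            raise ValueError(f"xi must be non-negative, got {self.xi}")
        if self.n_agents < 1:
            raise ValueError(f"n_agents must be >= 1, got {self.n_agents}")
        if len(self.p) != self.n_agents:
            raise ValueError(
                f"p has {len(self.p)} entries for {self.n_agents} agents"
            )
        for v in self.p:
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"skill p must be positive and finite, got {v}")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.alpha + self.beta - 1.0) > _WEIGHT_TOL:
            raise ValueError(
                f"alpha + beta must equal 1, got {self.alpha} + {self.beta}"
            )
        if not self.env_enabled and self.beta != 0.0:
            raise ValueError("beta must be 0 when the environment term is disabled")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")
        if not self.arrival_epsilon > 0:
            raise ValueError(
                f"arrival_epsilon must be positive, got {self.arrival_epsilon}"
            )
        if not (0.0 < self.coordination_threshold <= 1.0):
            raise ValueError(
                "coordination_threshold must lie in (0, 1], got "
                f"{self.coordination_threshold}"
            )
        if self.angle_mixing not in ("scalar", "circular"):
            raise ValueError(
                f"angle_mixing must be 'scalar' or 'circular', got {self.angle_mixing!r}"
            )

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["p"] = list(self.p)
        return d

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}
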