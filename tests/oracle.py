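"""Independent scalar reference implementation used as a test oracle.

A naive per-agent, pure-Python (math module) re-implementation of one
synchronous update step and of the run-level observables.  It is kept
deliberately loop-based and free of numpy vector operations so that it
exercises none of the code paths of the package's vectorized stepper;
fed the same noise draws, the two must agree.
"""

from __future__ import annotations

import math

TWO_PI = 2.0 * math.pi


def wrap(a: float) -> float:
    if -math.pi < a <= math.pi:
        return a
    return math.pi - (math.pi - a) % TWO_PI


def oracle_step(positions, headings, skills, noise, cfg):
    """One synchronous step.

    positions: list of (x, y); headings: list of floats; skills: list of p;
    noise: per agent a 4-tuple (xi2, xi3, xi1x, xi1y); cfg: SimulationConfig.
    Returns (new_positions, new_headings).
    """
    n = len(positions)
    cx = cy = cfg.L / 2.0
    new_headings = []
    for i in range(n):
        if cfg.social_enabled and n > 1:
            sines, cosines = [], []
            for j in range(n):
                dx = positions[i][0] - positions[j][0]
                dy = positions[i][1] - positions[j][1]
                dx -= cfg.L * round(dx / cfg.L)
                dy -= cfg.L * round(dy / cfg.L)
                if math.hypot(dx, dy) <= cfg.r:
                    sines.append(math.sin(headings[j]))
                    cosines.append(math.cos(headings[j]))
            if len(sines) == 1:
                base = headings[i]
            else:
                base = wrap(math.atan2(sum(sines) / len(sines),
                                       sum(cosines) / len(cosines)))
        else:
            base = headings[i]
        xi2, xi3 = noise[i][0], noise[i][1]
        p = skills[i]
        term_self = wrap(base + xi2 / p)
        if cfg.env_enabled:
            gx = -(positions[i][0] - cx)
            gy = -(positions[i][1] - cy)
            conc = math.exp(-(gx * gx + gy * gy) / 2.0) / TWO_PI
            norm = math.hypot(gx, gy) * conc
            if norm <= 1e-12:
                theta_g = headings[i]
            else:
                theta_g = math.atan2(gy * conc / norm + 0.0, gx * conc / norm)
            term_env = wrap(theta_g + xi3 / p)
            if cfg.angle_mixing == "scalar":
                nh = wrap(cfg.alpha * term_self + cfg.beta * term_env)
            else:
                nh = wrap(math.atan2(
                    cfg.alpha * math.sin(term_self) + cfg.beta * math.sin(term_env),
                    cfg.alpha * math.cos(term_self) + cfg.beta * math.cos(term_env)))
        else:
            nh = term_self
        new_headings.append(nh)
    new_positions = []
    for i in range(n):
        p = skills[i]
        x = (positions[i][0] + noise[i][2] / p
             + cfg.kappa * math.cos(new_headings[i])) % cfg.L
        y = (positions[i][1] + noise[i][3] / p
             + cfg.kappa * math.sin(new_headings[i])) % cfg.L
        new_positions.append((x, y))
    return new_positions, new_headings


def brute_force_periodic_distance(a, b, L: float) -> float:
    """Minimum Euclidean distance over the 9 periodic image translates."""
    best = math.inf
    for sx in (-L, 0.0, L):
        for sy in (-L, 0.0, L):
            d = math.hypot(a[0] - (b[0] + sx), a[1] - (b[1] + sy))
            best = min(best, d)
    return best
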