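"""The heterogeneous environment: a static Gaussian concentration field.

The arena carries a single circular Gaussian concentration bump of unit
variance centered at ``(L/2, L/2)``:

.. math::

    N(x, y) = \\frac{1}{2\\pi}
              \\exp\\!\\left(-\\frac{(x - L/2)^2 + (y - L/2)^2}{2}\\right)

Agents interact with it through its gradient field
``g = (dN/dx, dN/dy)``, which always points toward the center.  Only the
direction of ``g`` enters the heading dynamics: the gradient heading is
``theta_g = atan2(g_y, g_x)`` of the normalized gradient (quadrant
correct; a single-argument arctangent of the ratio would lose the
quadrant and could never steer an agent "downhill-to-uphill").

The field is defined on the plain square ``[0, L]^2``; no periodic
images of the bump are summed.  An agent that wraps across a boundary
simply sees the single-bump gradient at its new coordinates.  The
gradient is computed analytically (finite differences are kept only as
a test oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaussianField", "concentration", "gradient", "gradient_angle"]

#: Gradient norms at or below this are treated as degenerate (the exact
#: field center), and the caller-supplied fallback heading is used.
DEGENERATE_GRADIENT_TOL = 1e-12


@dataclass(frozen=True)
class GaussianField:
    """Gaussian concentration bump of unit variance centered in the arena."""

    L: float = 5.0

    @property
    def center(self) -> np.ndarray:
        return np.array([self.L / 2.0, self.L / 2.0])


def concentration(pos, field: GaussianField):
    """Concentration ``N`` at ``pos`` (last axis = (x, y)); vectorized."""
    pos = np.asarray(pos, dtype=float)
    d2 = np.sum((pos - field.center) ** 2, axis=-1)
    return np.exp(-d2 / 2.0) / (2.0 * np.pi)


def gradient(pos, field: GaussianField):
    """Analytic gradient of the concentration at ``pos``; vectorized.

    ``g = -(pos - center) * N(pos)``: antiparallel to the offset from the
    center, so it always points uphill toward the bump.
    """
    pos = np.asarray(pos, dtype=float)
    offset = pos - field.center
    n = concentration(pos, field)
    return -offset * n[..., np.newaxis]


def gradient_angle(pos, field: GaussianField, fallback):
    """Heading of the normalized gradient at ``pos``; vectorized.

    At (or numerically at) the field center the gradient vanishes and its
    direction is undefined; there the ``fallback`` heading (broadcast
    against ``pos``) is returned, which in the dynamics is the agent's
    current heading.
    """
    pos = np.asarray(pos, dtype=float)
    g = gradient(pos, field)
    norm = np.linalg.norm(g, axis=-1)
    degenerate = norm <= DEGENERATE_GRADIENT_TOL
    # atan2 of the normalized gradient; normalization cancels in atan2, but
    # guard the degenerate points against 0/0 anyway.
    safe = np.where(degenerate, 1.0, norm)
    # "+ 0.0" maps a signed zero to +0.0 so the branch-cut angle is +pi,
    # keeping the result in (-pi, pi]
    ang = np.arctan2(g[..., 1] / safe + 0.0, g[..., 0] / safe)
    out = np.where(degenerate, fallback, ang)
    return float(out) if np.ndim(out) == 0 else out
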