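"""Observables: order parameter, arrival detection, ensemble statistics.

The coordination observable is the Vicsek order parameter

    v_a = (1 / (n * kappa)) * || sum_i kappa * (cos theta_i, sin theta_i) ||

which is 1 for perfectly aligned headings and 0 for anti-aligned ones
(``kappa`` cancels algebraically but is kept for fidelity to the model's
velocity vectors).  Task success is both-agents-simultaneously within a
plain Euclidean distance ``epsilon`` of the concentration-field center;
the first such step is the first-arrival time ``tau``.  Runs are not
stopped at arrival, so order-parameter statistics always use full-length
runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "RunRecord",
    "EnsembleResult",
    "order_parameter",
    "order_parameter_series",
    "first_arrival",
    "final_window_mean_va",
    "ensemble_stats",
    "tau_normalize",
]


@dataclass(frozen=True)
class RunRecord:
    """Per-replicate outcome: success flag, first-arrival step (or None),
    and the mean order parameter over the final window of the run."""

    success: bool
    tau: Optional[int]
    final_va: float


@dataclass(frozen=True)
class EnsembleResult:
    """Aggregate of ``n_experiments`` replicate runs.

    ``mean_tau`` is averaged over *successful* runs only and is ``None``
    when no run succeeds.  ``tau_norm`` is filled by sweep-level min-max
    normalization (``None`` for a standalone ensemble).  ``coordinated``
    is the judgment ``mean_va >= coordination_threshold``.
    """

    n_experiments: int
    success_rate: float
    mean_tau: Optional[float]
    mean_va: float
    coordinated: bool
    tau_norm: Optional[float] = None
    per_run: tuple[RunRecord, ...] = field(default=(), repr=False)


def order_parameter(headings, kappa: float = 0.05) -> float:
    """Normalized magnitude of the summed velocity vectors, in ``[0, 1]``."""
    headings = np.asarray(headings, dtype=float)
    if headings.size == 0:
        raise ValueError("order_parameter requires at least one heading")
    n = headings.shape[-1]
    vx = kappa * np.cos(headings)
    vy = kappa * np.sin(headings)
    va = np.hypot(vx.sum(axis=-1), vy.sum(axis=-1)) / (n * kappa)
    return float(va) if np.ndim(va) == 0 else va


def order_parameter_series(traj: Trajectory) -> np.ndarray:
    """Per-snapshot order parameter of a run, shape ``(n_steps + 1,)``."""
    return order_parameter(traj.headings, traj.config.kappa)


def first_arrival(traj: Trajectory, epsilon: float) -> Optional[int]:
    """First step at which every agent is within ``epsilon`` of the center.

    Plain (non-periodic) Euclidean distance to ``(L/2, L/2)``; the center
    is interior so periodicity is irrelevant.  Returns ``None`` if the
    run never arrives.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    center = traj.config.L / 2.0
    dist = np.linalg.norm(traj.positions - center, axis=-1)
    all_in = np.all(dist <= epsilon, axis=-1)
    idx = np.flatnonzero(all_in)
    return int(idx[0]) if idx.size else None


def window_length(n_steps: int, window: float) -> int:
    """Number of trailing snapshots in the final observation window."""
    if not (0.0 < window <= 1.0):
        raise ValueError(f"window must lie in (0, 1], got {window}")
    return max(1, int(round(window * n_steps)))


def final_window_mean_va(traj: Trajectory, window: float = 0.1) -> float:
    """Mean order parameter over the final ``window`` fraction of a run."""
    w = window_length(traj.n_steps, window)
    return float(order_parameter_series(traj)[-w:].mean())


def ensemble_stats(runs: Sequence[Trajectory], epsilon: float,
                   coordination_threshold: float = 0.95,
                   window: float = 0.1) -> EnsembleResult:
    """Aggregate replicate runs into an :class:`EnsembleResult`.

    Success rate is the fraction of runs with a first arrival; ``mean_tau``
    averages first-arrival times over successful runs only (``None`` if
    none); ``mean_va`` averages each run's final-window mean order
    parameter over all runs.
    """
    if len(runs) == 0:
        raise ValueError("ensemble_stats requires at least one run")
    records = []
    for traj in runs:
        tau = first_arrival(traj, epsilon)
        records.append(RunRecord(success=tau is not None, tau=tau,
                                 final_va=final_window_mean_va(traj, window)))
    taus = [r.tau for r in records if r.success]
    mean_va = float(np.mean([r.final_va for r in records]))
    return EnsembleResult(
        n_experiments=len(runs),
        success_rate=len(taus) / len(runs),
        mean_tau=float(np.mean(taus)) if taus else None,
        mean_va=mean_va,
        coordinated=mean_va >= coordination_threshold,
        per_run=tuple(records),
    )


def tau_normalize(taus) -> np.ndarray:
    """Min-max normalize first-arrival times across a sweep: min -> 0, max -> 1.

    NaN entries (cells with no successful run) pass through as NaN.
    Raises if fewer than two distinct finite values are supplied.
    """
    arr = np.asarray(taus, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or finite.max() == finite.min():
        raise ValueError(
            "tau_normalize needs at least two distinct finite values"
        )
    return (arr - finite.min()) / (finite.max() - finite.min())
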