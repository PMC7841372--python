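"""Seeded ensemble runner and the parameter sweeps of the study.

``run_ensemble`` advances all replicates of an ensemble in lock-step on
replicate-stacked arrays.  Each replicate's random stream is generated
from its own derived seed exactly as :func:`pk_agents.dynamics.simulate`
would, so the vectorized ensemble reproduces a run-by-run scalar
recomputation draw for draw — a property the test suite asserts.

The sweep functions reproduce the study's figure-level experiments:

- ``experiment_self``: one agent, no environment, no partner — heading
  jitter and trajectory organization as a function of skill ``p`` and
  noise ``xi``.
- ``experiment_single_agent_env``: one agent with the gradient term on
  (``alpha = beta = 0.5``) — success rate and normalized first-arrival
  time vs ``p``.
- ``experiment_two_agent_coordination``: two agents, alignment only —
  order parameter vs ``xi`` and over the ``(p1, p2)`` plane.
- ``experiment_joint_task``: two agents with both social and
  environmental coupling — success rate, first-arrival time, and order
  parameter vs ``p`` for several ``(alpha, beta)`` mixes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dynamics import GaussianField, _p_array, _step_arrays, initial_conditions, wrap_angle
from .metrics import EnsembleResult, RunRecord, order_parameter, tau_normalize, window_length

__all__ = [
    "SweepResult",
    "derive_seeds",
    "run_ensemble",
    "experiment_self",
    "experiment_single_agent_env",
    "experiment_two_agent_coordination",
    "experiment_joint_task",
    "calibrate_arrival_epsilon",
    "minimal_coordination_skill",
]

RESULT_COLUMNS = [
    "p1", "p2", "xi", "alpha", "beta", "n_experiments",
    "s", "mean_tau", "tau_norm", "mean_va", "coordinated",
]


@dataclass(frozen=True)
class SweepResult:
    """Tidy table of ensemble statistics over a parameter grid.

    ``table`` has one row per grid cell with columns
    ``(p1, p2, xi, alpha, beta, n_experiments, s, mean_tau, tau_norm,
    mean_va, coordinated)``, sorted by grid coordinates.
    """

    table: pd.DataFrame
    base_config: SimulationConfig
    master_seed: int
    kind: str = ""


def derive_seeds(master_seed: int, n: int, salt: Sequence[int] = ()) -> np.ndarray:
    """Deterministic child seeds (each below 2**31) for replicates or cells.

    Different ``salt`` tuples (e.g. cell indices) give disjoint streams.
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(s) for s in salt]])
    return (ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)).astype(np.int64)


def run_ensemble(config: SimulationConfig, n_experiments: int, seed: int,
                 window: float = 0.1,
                 salt: Sequence[int] = ()) -> EnsembleResult:
    """Run ``n_experiments`` independent replicates of ``config``.

    Replicate ``k`` is identical to ``simulate(config.replace(seed=s_k))``
    with ``s_k = derive_seeds(seed, n_experiments, salt)[k]``.  Fully
    reproducible from ``(config, seed)``.
    """
    if n_experiments < 1:
        raise ValueError(f"n_experiments must be >= 1, got {n_experiments}")
    seeds = derive_seeds(seed, n_experiments, salt)
    R, n, T = n_experiments, config.n_agents, config.n_steps

    pos = np.empty((R, n, 2))
    theta = np.empty((R, n))
    noise = np.empty((R, T, n, 4))
    for k, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        pos[k], theta[k] = initial_conditions(config, rng)
        noise[k] = rng.uniform(-config.xi, config.xi, size=(T, n, 4))

    field_ = GaussianField(config.L) if config.env_enabled else None
    p = _p_array(config)
    center = config.L / 2.0
    eps = config.arrival_epsilon

    va = np.empty((R, T + 1))
    va[:, 0] = order_parameter(theta, config.kappa)
    tau = np.full(R, -1, dtype=np.int64)
    dist = np.linalg.norm(pos - center, axis=-1)
    arrived = np.all(dist <= eps, axis=-1)
    tau[arrived] = 0

    for t in range(T):
        pos, theta = _step_arrays(pos, theta, noise[:, t], config, p, field_)
        va[:, t + 1] = order_parameter(theta, config.kappa)
        pending = tau < 0
        if pending.any():
            dist = np.linalg.norm(pos[pending] - center, axis=-1)
            hit = np.all(dist <= eps, axis=-1)
            idx = np.flatnonzero(pending)[hit]
            tau[idx] = t + 1

    w = window_length(T, window)
    final_va = va[:, -w:].mean(axis=1)
    success = tau >= 0
    records = tuple(
        RunRecord(success=bool(success[k]),
                  tau=int(tau[k]) if success[k] else None,
                  final_va=float(final_va[k]))
        for k in range(R)
    )
    taus = tau[success]
    mean_va = float(final_va.mean())
    return EnsembleResult(
        n_experiments=R,
        success_rate=float(success.mean()),
        mean_tau=float(taus.mean()) if taus.size else None,
        mean_va=mean_va,
        coordinated=mean_va >= config.coordination_threshold,
        per_run=records,
    )


def _row(p1, p2, xi, alpha, beta, res: EnsembleResult) -> dict:
    return {
        "p1": p1, "p2": p2, "xi": xi, "alpha": alpha, "beta": beta,
        "n_experiments": res.n_experiments, "s": res.success_rate,
        "mean_tau": math.nan if res.mean_tau is None else res.mean_tau,
        "tau_norm": math.nan if res.tau_norm is None else res.tau_norm,
        "mean_va": res.mean_va, "coordinated": res.coordinated,
    }


def _finish(rows: list[dict], base: SimulationConfig, seed: int,
            kind: str) -> SweepResult:
    table = (pd.DataFrame(rows, columns=RESULT_COLUMNS)
             .sort_values(["alpha", "xi", "p1", "p2"], kind="mergesort")
             .reset_index(drop=True))
    return SweepResult(table=table, base_config=base, master_seed=seed,
                       kind=kind)


# ---------------------------------------------------------------------------
# Figure-level experiments
# ---------------------------------------------------------------------------

#: Skill grid used by the sweeps: a superset of every spot value the study
#: names (1, 10, 20, 40, 50, 100).
DEFAULT_P_GRID = (1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0)
DEFAULT_XI_GRID = (0.1, 0.5, 1.0, 2.5, 5.0)
DEFAULT_ALPHA_BETA = ((1.0, 0.0), (0.95, 0.05), (0.5, 0.5), (0.05, 0.95))


def experiment_self(p_list: Iterable[float] = (1.0, 10.0, 100.0),
                    xi_list: Iterable[float] = (0.5, 2.5, 5.0),
                    config: SimulationConfig | None = None,
                    n_experiments: int = 50,
                    seed: int = 0):
    """Self-only dynamics: heading-jitter statistics per ``(xi, p)`` cell.

    Returns ``(table, trajectories)``: a DataFrame with the pooled sample
    standard deviation of per-step heading increments next to the exact
    law ``xi / (p * sqrt(3))`` (std of a uniform variate on
    ``[-xi/p, xi/p]``), and one representative :class:`Trajectory` per
    cell for facsimile plotting.
    """
    from .dynamics import simulate

    base = config or SimulationConfig(n_agents=1, n_steps=250)
    base = base.replace(env_enabled=False, social_enabled=False,
                        beta=0.0, alpha=1.0, n_agents=1)
    rows, trajectories = [], {}
    for ci, xi in enumerate(xi_list):
        for cj, p in enumerate(p_list):
            seeds = derive_seeds(seed, n_experiments, salt=(ci, cj))
            incs = []
            for k, s in enumerate(seeds):
                traj = simulate(base.replace(xi=xi, p=(p,), seed=int(s)))
                if k == 0:
                    trajectories[(xi, p)] = traj
                incs.append(traj.heading_increments().ravel())
            pooled = np.concatenate(incs)
            rows.append({
                "p1": p, "xi": xi,
                "increment_std": float(pooled.std(ddof=1)),
                "predicted_std": xi / (p * math.sqrt(3.0)),
                "n_experiments": n_experiments,
            })
    table = (pd.DataFrame(rows).sort_values(["xi", "p1"], kind="mergesort")
             .reset_index(drop=True))
    return table, trajectories


def experiment_single_agent_env(p_list: Iterable[float] = DEFAULT_P_GRID,
                                config: SimulationConfig | None = None,
                                n_experiments: int = 500,
                                seed: int = 0) -> SweepResult:
    """Single agent with the gradient term on (``alpha = beta = 0.5``).

    Success rate ``s`` and mean first-arrival time vs ``p``; ``tau_norm``
    is the min-max normalization of the mean arrival times across the
    sweep.
    """
    base = (config or SimulationConfig()).replace(
        n_agents=1, p=(50.0,), env_enabled=True, social_enabled=False,
        alpha=0.5, beta=0.5)
    rows = []
    for cj, p in enumerate(p_list):
        cfg = base.replace(p=(p,))
        res = run_ensemble(cfg, n_experiments, seed, salt=(cj,))
        rows.append(_row(p, math.nan, cfg.xi, 0.5, 0.5, res))
    result = _finish(rows, base, seed, kind="env")
    taus = result.table["mean_tau"].to_numpy()
    if np.isfinite(taus).sum() >= 2 and np.nanmax(taus) > np.nanmin(taus):
        result.table["tau_norm"] = tau_normalize(taus)
    return result


def experiment_two_agent_coordination(
        p_list: Iterable[float] = DEFAULT_P_GRID,
        xi_list: Iterable[float] = (0.5,),
        config: SimulationConfig | None = None,
        n_experiments: int = 500,
        seed: int = 0,
        p_grid: Iterable[tuple[float, float]] | None = None) -> SweepResult:
    """Two agents, alignment only (``alpha = 1, beta = 0``, no gradient).

    Sweeps ``p1 = p2 = p`` over ``p_list`` for each ``xi``; optionally
    also an explicit list of ``(p1, p2)`` pairs (heatmap cells) at each
    ``xi``.
    """
    base = (config or SimulationConfig()).replace(
        n_agents=2, p=(50.0, 50.0), env_enabled=False, social_enabled=True,
        alpha=1.0, beta=0.0)
    rows = []
    for ci, xi in enumerate(xi_list):
        cells = [(p, p) for p in p_list]
        if p_grid is not None:
            cells += [tuple(c) for c in p_grid]
        for cj, (p1, p2) in enumerate(cells):
            cfg = base.replace(xi=xi, p=(p1, p2))
            res = run_ensemble(cfg, n_experiments, seed, salt=(ci, cj))
            rows.append(_row(p1, p2, xi, 1.0, 0.0, res))
    return _finish(rows, base, seed, kind="coord")


def experiment_joint_task(
        alpha_beta_list: Iterable[tuple[float, float]] = DEFAULT_ALPHA_BETA,
        p_list: Iterable[float] = DEFAULT_P_GRID,
        config: SimulationConfig | None = None,
        n_experiments: int = 500,
        seed: int = 0,
        p_grid: Iterable[tuple[float, float]] | None = None) -> SweepResult:
    """Two agents with social and environmental coupling both active.

    For each ``(alpha, beta)`` mix and each ``p1 = p2 = p`` cell (plus
    optional explicit ``(p1, p2)`` pairs), reports success rate, mean
    first-arrival time, and final-window order parameter.
    """
    base = (config or SimulationConfig()).replace(
        n_agents=2, p=(50.0, 50.0), env_enabled=True, social_enabled=True,
        alpha=0.5, beta=0.5)
    rows = []
    for ci, (alpha, beta) in enumerate(alpha_beta_list):
        cells = [(p, p) for p in p_list]
        if p_grid is not None:
            cells += [tuple(c) for c in p_grid]
        for cj, (p1, p2) in enumerate(cells):
            cfg = base.replace(alpha=alpha, beta=beta, p=(p1, p2))
            res = run_ensemble(cfg, n_experiments, seed, salt=(ci, cj))
            rows.append(_row(p1, p2, cfg.xi, alpha, beta, res))
    return _finish(rows, base, seed, kind="joint")


#: Candidate arrival tolerances scanned by the one-off epsilon calibration.
CALIBRATION_EPSILONS = (0.05, 0.1, 0.25, 0.5)


def calibrate_arrival_epsilon(target_s: float = 0.4,
                              epsilons: Sequence[float] = CALIBRATION_EPSILONS,
                              config: SimulationConfig | None = None,
                              n_experiments: int = 500,
                              seed: int = 0) -> tuple[float, pd.DataFrame]:
    """One-off calibration of the arrival tolerance (the model's only free
    observable parameter).

    The anchor regime is the chance-level two-agent search: alignment only
    (``alpha = 1, beta = 0``), high skill, no gradient guidance.  For each
    candidate tolerance the anchor ensemble is run and the tolerance whose
    success rate is closest to ``target_s`` is returned, together with the
    scan table.  The shipped default ``DEFAULT_ARRIVAL_EPSILON`` is the
    result of this procedure at full scale, frozen once; see
    docs/methods.md.
    """
    base = (config or SimulationConfig()).replace(
        n_agents=2, p=(100.0, 100.0), env_enabled=False, social_enabled=True,
        alpha=1.0, beta=0.0)
    rows = []
    for ci, eps in enumerate(epsilons):
        res = run_ensemble(base.replace(arrival_epsilon=eps), n_experiments,
                           seed, salt=(ci,))
        rows.append({"epsilon": eps, "s": res.success_rate,
                     "mean_tau": math.nan if res.mean_tau is None
                     else res.mean_tau})
    table = pd.DataFrame(rows)
    best = float(table.loc[(table["s"] - target_s).abs().idxmin(), "epsilon"])
    return best, table


def minimal_coordination_skill(result: SweepResult,
                               xi: float | None = None) -> Optional[float]:
    """Smallest equal-skill ``p`` in a sweep whose cell is coordinated.

    Considers only diagonal cells (``p1 == p2``), optionally restricted to
    one ``xi``; returns ``None`` if no cell coordinates.
    """
    t = result.table
    mask = t["p1"] == t["p2"]
    if xi is not None:
        mask &= t["xi"] == xi
    coord = t[mask & t["coordinated"].astype(bool)]
    return float(coord["p1"].min()) if len(coord) else None
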