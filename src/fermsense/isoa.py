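"""Improved seagull optimization algorithm (ISOA).

Bound-constrained minimization by a population metaheuristic that
alternates a *migration* move (collision-avoidance drift toward the best
agent found so far) with a *spiral attack* move.  The "improved" variant
replaces the classic linear decay of the migration weight ``A`` with a
nonlinear tangent schedule

    A(t) = -f_c * tan(t / T * pi/4 - pi/4),

which falls quickly from ``f_c`` early on (preserving population
diversity / global search) and flattens toward 0 late (local
refinement).

The update per agent is

    Cs = A * Pos                      (collision avoidance)
    B  = 2 * A^2 * rand               (one uniform draw per agent)
    Ms = B * (bestPos - Pos)          (drift toward the incumbent best)
    Ds = |Cs + Ms|                    (elementwise magnitude)
    theta ~ U(0, 2*pi)                (one draw per agent)
    r = u * exp(v * theta)
    s = (r cos theta)(r sin theta)(r theta)    (spiral factor, scalar)
    Pos <- Ds * s + anchor

where ``anchor`` is the incumbent best (``attack_anchor="best"``, the
default) or the agent's own previous position (``attack_anchor="self"``).
Agents that leave the box are re-drawn uniformly inside it by default
(``oob_rule="resample"``): an infeasible spiral move carries no
information, and snapping it to the boundary piles the population onto
the box corners and stalls the search.  ``clip`` and ``reflect`` rules
are available.  The best-so-far is updated elitistically, so the
best-fitness history is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "OptimizationError",
    "weight_A",
    "init_state",
    "isoa_step",
    "isoa_minimize",
    "trace_frame",
]


class OptimizationError(RuntimeError):
    """Raised when the objective returns a non-finite value."""


@dataclass
class SwarmConfig:
    """Run-time parameters of an ISOA minimization.

    Parameters
    ----------
    population : int
        Number of agents (>= 2).
    max_iter : int
        Number of update sweeps (>= 1).
    f_c : float
        Initial migration weight; the schedule decays it to 0.
    u, v : float
        Spiral shape constants, r = u * exp(v * theta).
    lower, upper : float or sequence
        Box bounds; broadcast to the problem dimension.
    seed : int
        Seed of the single generator owned by the run.
    attack_anchor : {"best", "self"}
        Reference point the spiral move is taken around.
    oob_rule : {"resample", "clip", "reflect"}
        How agents leaving the box are repaired.
    """

    population: int = 30
    max_iter: int = 200
    f_c: float = 2.0
    u: float = 1.0
    v: float = 1.0
    lower: float | Sequence[float] = -1.0
    upper: float | Sequence[float] = 1.0
    seed: int = 0
    attack_anchor: str = "best"
    oob_rule: str = "resample"

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.attack_anchor not in ("best", "self"):
            raise ValueError("attack_anchor must be 'best' or 'self'")
        if self.oob_rule not in ("resample", "clip", "reflect"):
            raise ValueError("oob_rule must be 'resample', 'clip' or 'reflect'")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lower, dtype=float), (dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.upper, dtype=float), (dim,)).copy()
        if not np.all(lb < ub):
            raise ValueError("lower must be < upper elementwise")
        return lb, ub


@dataclass
class SwarmState:
    positions: np.ndarray          # (population, dim)
    fitness: np.ndarray            # (population,)
    best_pos: np.ndarray           # (dim,)
    best_fitness: float
    t: int = 0
    history: list[float] = field(default_factory=list)


def weight_A(t: int, cfg: SwarmConfig) -> float:
    """Nonlinear tangent weight schedule.

    A(0) = f_c, A(max_iter) = 0, strictly decreasing in between.
    """
    if not 0 <= t <= cfg.max_iter:
        raise ValueError("t must lie in [0, max_iter]")
    return -cfg.f_c * np.tan(t / cfg.max_iter * np.pi / 4.0 - np.pi / 4.0)


def _evaluate(objective: Callable[[np.ndarray], float], positions: np.ndarray) -> np.ndarray:
    fit = np.empty(positions.shape[0])
    for i, pos in enumerate(positions):
        val = float(objective(pos))
        if not np.isfinite(val):
            raise OptimizationError(f"objective returned non-finite value at position {pos!r}")
        fit[i] = val
    return fit


def init_state(
    objective: Callable[[np.ndarray], float],
    dim: int,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """Uniform initialization in the box; best agent recorded."""
    lb, ub = cfg.bounds(dim)
    pos = rng.uniform(lb, ub, size=(cfg.population, dim))
    fit = _evaluate(objective, pos)
    ibest = int(np.argmin(fit))
    return SwarmState(
        positions=pos,
        fitness=fit,
        best_pos=pos[ibest].copy(),
        best_fitness=float(fit[ibest]),
        t=0,
        history=[float(fit[ibest])],
    )


def isoa_step(
    state: SwarmState,
    objective: Callable[[np.ndarray], float],
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """One migration + spiral-attack sweep over the population."""
    dim = state.positions.shape[1]
    lb, ub = cfg.bounds(dim)
    t_next = state.t + 1
    A = weight_A(t_next, cfg)

    pos = state.positions
    Cs = A * pos
    B = 2.0 * A * A * rng.uniform(size=(cfg.population, 1))
    Ms = B * (state.best_pos[None, :] - pos)
    Ds = np.abs(Cs + Ms)

    theta = rng.uniform(size=(cfg.population, 1)) * 2.0 * np.pi
    r = cfg.u * np.exp(theta * cfg.v)
    spiral = (r * np.cos(theta)) * (r * np.sin(theta)) * (r * theta)

    anchor = state.best_pos[None, :] if cfg.attack_anchor == "best" else pos
    new_pos = Ds * spiral + anchor
    if cfg.oob_rule == "clip":
        new_pos = np.clip(new_pos, lb, ub)
    elif cfg.oob_rule == "reflect":
        span = ub - lb
        folded = (new_pos - lb) % (2.0 * span)
        new_pos = lb + np.where(folded > span, 2.0 * span - folded, folded)
    else:  # resample: re-draw infeasible agents uniformly in the box
        bad = ((new_pos < lb) | (new_pos > ub)).any(axis=1)
        if bad.any():
            new_pos[bad] = rng.uniform(lb, ub, size=(int(bad.sum()), dim))
    new_fit = _evaluate(objective, new_pos)

    best_pos = state.best_pos
    best_fit = state.best_fitness
    i = int(np.argmin(new_fit))
    if new_fit[i] < best_fit:
        best_fit = float(new_fit[i])
        best_pos = new_pos[i].copy()

    return SwarmState(
        positions=new_pos,
        fitness=new_fit,
        best_pos=best_pos,
        best_fitness=best_fit,
        t=t_next,
        history=state.history + [best_fit],
    )


def isoa_minimize(
    objective: Callable[[np.ndarray], float],
    dim: int,
    cfg: SwarmConfig,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run a full seeded ISOA minimization over the box.

    Returns
    -------
    best_pos : ndarray (dim,)
    best_fitness : float
    history : ndarray (max_iter + 1,)
        Best-so-far fitness after initialization and each sweep
        (non-increasing).
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_state(objective, dim, cfg, rng)
    for _ in range(cfg.max_iter):
        state = isoa_step(state, objective, cfg, rng)
    return state.best_pos, state.best_fitness, np.asarray(state.history)


def trace_frame(history: np.ndarray):
    """(iteration, best_fitness) table of a run's history, for CSV export."""
    import pandas as pd

    history = np.asarray(history, dtype=float)
    return pd.DataFrame({"iteration": np.arange(len(history)),
                         "best_fitness": history})
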