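"""System-level free energy over an ensemble of two-agent subsystems.

The collective is modelled as M replicate dyads (2M agents), each in its own
copy of the environment differing only in food-source placement.  Seen from
the system scale, each agent is a point particle at position ``psi_i`` whose
food source ``psi0_i`` plays the role of a sensory state.  The system-level
free energy is

    F_Sigma = sum_psi q(psi) ln q(psi) + (k_Sigma / 2M) * sum_i d(psi_i, psi0_i)^2

where ``q`` is the empirical distribution of the 2M positions and ``d`` the
ring distance.  This is the divergence between the empirical density and a
generative density ``exp(-k_Sigma * d^2)`` per agent, with the generative
model's constant log-normaliser dropped (it is undefined for the collective
and position-independent), so only relative and temporal comparisons of
``F_Sigma`` are meaningful.  The trace of ``F_Sigma`` over an entire run of
the agent-level model is read as a single system-level inference step:
a collective that is good at approximate inference drives it down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .agent_core import AgentParams, DyadResult, simulate_dyad
from .belief_space import circ_dist
from .world import WorldConfig

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleState",
    "ReplicateSpec",
    "EnsembleResult",
    "empirical_density",
    "system_free_energy",
    "f_sigma_trace",
    "run_ensemble",
]


@dataclass(frozen=True)
class EnsembleState:
    """Positions and food sources of all 2M agents, plus the coupling gain."""

    positions: tuple
    food_positions: tuple
    n_cells: int
    k_sigma: float = 1.0

    def __post_init__(self):
        if len(self.positions) == 0 or len(self.positions) != len(self.food_positions):
            raise ValueError("positions and food_positions must be non-empty and equal length")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")


def empirical_density(positions, n_cells: int) -> np.ndarray:
    """Empirical distribution of agent positions over the ring."""
    pos = np.asarray(positions, dtype=int)
    if pos.size == 0:
        raise ValueError("at least one position is required")
    counts = np.bincount(pos % n_cells, minlength=n_cells)
    return counts / pos.size


def system_free_energy(state: EnsembleState) -> float:
    """System-level free energy of a configuration (lower is better).

    Negative entropy of the empirical position distribution (``0 ln 0 = 0``)
    plus the mean squared ring distance of each agent from its own food
    source, weighted by ``k_sigma``.  Zero when every agent sits on a single
    shared cell that is also every food source; minimal over positions with
    a fixed multiplicity pattern exactly when all distances vanish.
    """
    q = empirical_density(state.positions, state.n_cells)
    nz = q[q > 0]
    neg_entropy = float(np.sum(nz * np.log(nz)))
    d = circ_dist(np.asarray(state.positions), np.asarray(state.food_positions), state.n_cells)
    quad = state.k_sigma * float(np.sum(np.asarray(d, dtype=float) ** 2)) / len(state.positions)
    return neg_entropy + quad


def f_sigma_trace(position_history: np.ndarray, food_positions, n_cells: int,
                  k_sigma: float = 1.0) -> np.ndarray:
    """``F_Sigma`` at every epoch; ``position_history`` has shape ``(T, 2M)``."""
    return np.array([
        system_free_energy(EnsembleState(tuple(row), tuple(food_positions), n_cells, k_sigma))
        for row in np.asarray(position_history, dtype=int)
    ])


@dataclass(frozen=True)
class ReplicateSpec:
    """Everything needed to run one replicate dyad: its world, agents and seeds."""

    cfg: WorldConfig
    params_a: AgentParams
    params_b: AgentParams
    desires_a: np.ndarray
    desires_b: np.ndarray
    imputed_a: np.ndarray
    imputed_b: np.ndarray
    start_a: int
    start_b: int
    seed_a: object
    seed_b: object


@dataclass
class EnsembleResult:
    """Joint and per-replicate free-energy traces plus the raw dyad records."""

    f_sigma: np.ndarray                 # joint trace, shape (epochs + 1,)
    f_sigma_per_replicate: np.ndarray   # shape (epochs + 1, M)
    dyads: list                         # list[DyadResult], length M
    food_positions: np.ndarray          # shape (2M,)


def run_ensemble(replicates, epochs: int, k_sigma: float = 1.0,
                 record_beliefs: bool = False) -> EnsembleResult:
    """Run M independent two-agent simulations and score the collective.

    Each replicate runs in its own environment (typically identical up to
    food-source placement) with its own RNG substreams, so the ensemble is
    reproducible and replicates are statistically independent.  The joint
    trace pools all 2M agents into one empirical density per epoch; the
    per-replicate decomposition applies the same formula to each dyad alone
    (useful for dispersion estimates across replicates).
    """
    if len(replicates) < 1:
        raise ValueError("at least one replicate is required")
    dyads = []
    for idx, rep in enumerate(replicates):
        logger.debug("replicate %d/%d starting (start=%d, center=%d)",
                     idx + 1, len(replicates), rep.start_a, rep.cfg.center)
        try:
            rng_a = np.random.default_rng(rep.seed_a)
            rng_b = np.random.default_rng(rep.seed_b)
            dyads.append(simulate_dyad(
                rep.cfg, rep.params_a, rep.params_b,
                rep.desires_a, rep.desires_b, rep.imputed_a, rep.imputed_b,
                rep.start_a, rep.start_b, epochs, rng_a, rng_b,
                record_beliefs=record_beliefs,
            ))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"replicate {idx} failed: {exc}") from exc

    n = replicates[0].cfg.n_cells
    food = np.array([[rep.cfg.center, rep.cfg.center] for rep in replicates]).reshape(-1)
    # (epochs + 1, 2M) matrix of all agent positions
    pos = np.concatenate([d.psi for d in dyads], axis=1)
    joint = f_sigma_trace(pos, food, n, k_sigma)
    per_rep = np.stack(
        [f_sigma_trace(d.psi, food[2 * i:2 * i + 2], n, k_sigma)
         for i, d in enumerate(dyads)],
        axis=1,
    )
    return EnsembleResult(f_sigma=joint, f_sigma_per_replicate=per_rep,
                          dyads=dyads, food_positions=food)
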