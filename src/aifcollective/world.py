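"""The circular 1-D environment.

A world is a ring of ``n_cells`` cells with a chemical field emitted from a
single source cell (``center``, by default co-located with the shared
target).  The probability that an agent's 1-bit chemical sensor fires decays
exponentially with ring distance from the source::

    P(s = 1 | psi) = k * exp(-omega * d(psi, center)),    P(s = 0) = 1 - P(s = 1)

``k`` is the agent's *perceptiveness* (the maximum sensory probability, an
agent property), while ``omega`` and ``center`` are environmental.  The
agent's generative model uses the same expression, i.e. its sensory model is
correct.  Partner observation is a noiseless channel: each agent perceives
the exact position offset ``delta = (psi_own - psi_partner) mod N`` and the
partner's last realised action.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .belief_space import circ_dist

__all__ = [
    "WorldConfig",
    "Observation",
    "chemical_prob",
    "chemical_profile",
    "sample_chemical",
    "observe_partner",
]


@dataclass(frozen=True)
class WorldConfig:
    """Ring-world geometry and chemical-field parameters.

    ``targets`` maps the labels ``shared``, ``a`` and ``b`` to cell indices;
    ``center`` is the chemical-field source (the food source).  When target
    layout is randomised across runs, relative distances between targets are
    preserved and ``center`` moves with the shared target.
    """

    n_cells: int = 60
    center: int = 30
    targets: dict = field(default_factory=lambda: {"shared": 30, "a": 15, "b": 45})
    omega: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 3:
            raise ValueError("n_cells must be at least 3")
        if not 0 <= self.center < self.n_cells:
            raise ValueError("center must lie in [0, n_cells)")
        for name, pos in self.targets.items():
            if not 0 <= pos < self.n_cells:
                raise ValueError(f"target {name!r} out of range: {pos}")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    def shifted(self, offset: int) -> "WorldConfig":
        """Translate the whole layout by ``offset`` cells (mod N).

        Preserves all relative distances between targets and the field
        center; used to randomise the shared-target position across runs.
        """
        n = self.n_cells
        return WorldConfig(
            n_cells=n,
            center=(self.center + offset) % n,
            targets={k: (v + offset) % n for k, v in self.targets.items()},
            omega=self.omega,
            seed=self.seed,
        )


@dataclass(frozen=True)
class Observation:
    """One epoch's sensory triple: own chemical bit, partner offset, partner's last action."""

    s_own: int = 0
    delta: int = 0
    a_pp: int = 0


def _check_k(k: float) -> None:
    if not 0.0 < k < 1.0:
        raise ValueError(f"perceptiveness k must lie in (0, 1), got {k}")


def chemical_prob(psi: int, k: float, cfg: WorldConfig) -> float:
    """P(s = 1) at cell ``psi`` for an agent with perceptiveness ``k``."""
    _check_k(k)
    d = circ_dist(psi, cfg.center, cfg.n_cells)
    return float(k * np.exp(-cfg.omega * d))

_profile_cache: dict = {}


def chemical_profile(k: float, cfg: WorldConfig) -> np.ndarray:
    """P(s = 1) over every cell; shape ``(n_cells,)``.

    ``chemical_profile(...)`` and ``1 - chemical_profile(...)`` are the two
    sensory likelihood vectors the agents' generative models use.  Cached
    per ``(k, n_cells, center, omega)``; treat the result as read-only.
    """
    _check_k(k)
    key = (k, cfg.n_cells, cfg.center, cfg.omega)
    prof = _profile_cache.get(key)
    if prof is None:
        d = circ_dist(np.arange(cfg.n_cells), cfg.center, cfg.n_cells)
        prof = k * np.exp(-cfg.omega * d)
        prof.flags.writeable = False
        if len(_profile_cache) > 256:
            _profile_cache.clear()
        _profile_cache[key] = prof
    return prof


def sample_chemical(psi: int, k: float, cfg: WorldConfig, rng: np.random.Generator) -> int:
    """Bernoulli draw of the chemical bit at ``psi``."""
    p = chemical_prob(psi, k, cfg)
    return int(rng.random() < p)


def observe_partner(psi_own: int, psi_partner: int, a_partner_prev: int, n_cells: int):
    """Noiseless partner channel: returns ``(delta, a_pp)``.

    ``delta = (psi_own - psi_partner) mod N`` so that ``psi = phi + delta``;
    ``a_pp`` relays the partner's last realised action verbatim.
    """
    delta = (psi_own - psi_partner) % n_cells
    return delta, int(a_partner_prev)
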