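"""The active-inference agent: generative models, free energy, action and belief updates.

Each agent maintains four log-belief vectors: actual and desired beliefs
about its own position, and actual and desired beliefs about its partner's
position.  One epoch runs in lockstep for both agents, acting on the
current observation and updating beliefs for the *expected* effects of the
chosen actions before the move is realised:

1. select the action pair (own move, expected partner move) that minimises
   the joint free energy evaluated at the *desired* distributions;
2. update beliefs by projected gradient descent on the free energy of the
   current observation under the chosen actions;
3. move (actions always have their intended effect on the ring);
4. sense at the new cell (chemical bit; the partner's new offset and
   realised action, noiselessly) — consumed by the next epoch.

The joint free energy couples the two inference problems through the
*alterity* gate: the partner-model density, shifted into own-position
coordinates by the (expected) offset, re-ranged by ``alpha`` and multiplied
into the sensory model, and symmetrically the sensory density gates the
partner term through ``alpha**2`` (second-order Theory of Mind — the agent
assumes its partner models it with the same alterity).  At ``alpha = 0``
the gates are exactly neutral and each agent reduces to an independent
single-agent chemotaxis model.

Numerical conventions: generative densities are clamped to ``[e^-10, 1]``
(no overconfidence); the alterity gate is applied in the normalised form
``alpha * N * p + (1 - alpha)`` so that ``alpha = 0`` multiplies by exactly
1 — this differs from re-ranging the raw density only by a constant
``ln N`` per divergence term, which affects no gradient or action choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .belief_space import B_FLOOR, DENSITY_FLOOR, encode, shift
from .world import Observation, WorldConfig, chemical_profile, observe_partner, sample_chemical

__all__ = [
    "ACTIONS",
    "CANDIDATE_ORDER",
    "AgentParams",
    "AgentState",
    "sensory_posterior",
    "partner_action_probs",
    "partner_action_profile",
    "partner_posterior",
    "agent_free_energy",
    "select_actions",
    "update_beliefs",
    "agent_step",
    "step_pair",
    "simulate_dyad",
    "DyadResult",
    "initial_state",
]

logger = logging.getLogger(__name__)

#: action alphabet, in index order used by probability triples
ACTIONS = (-1, 0, 1)
#: deterministic candidate/tie-break order for action selection
CANDIDATE_ORDER = (0, 1, -1)

#: gradient infinity-norm below which descent stops early (stationary point)
GRAD_TOL = 1e-12
#: maximum step-halvings per descent iteration before giving up on the step
MAX_HALVINGS = 40


@dataclass(frozen=True)
class AgentParams:
    """Cognitive parameters of one agent.

    k      -- physical perceptiveness, the peak chemical-sensor probability, in (0, 1)
    alpha  -- alterity (Theory-of-Mind intensity), in [0, 1]
    gamma  -- goal alignment of the pair, in [0, 1] (applied when desires are built)
    xi     -- stand-still ceiling of the partner-action model, in (0, 1]
    gd_rate, gd_steps -- gradient-descent step size and iteration count per epoch
    """

    k: float
    alpha: float = 0.0
    gamma: float = 0.0
    xi: float = 0.9
    gd_rate: float = 5.0
    gd_steps: int = 30

    def __post_init__(self):
        if not 0.0 < self.k < 1.0:
            raise ValueError("k must lie in (0, 1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 < self.xi <= 1.0:
            raise ValueError("xi must lie in (0, 1]")
        if self.gd_rate <= 0 or self.gd_steps < 1:
            raise ValueError("gd_rate must be positive and gd_steps >= 1")


@dataclass
class AgentState:
    """Full state tuple of one agent: position, observation, beliefs, actions."""

    psi: int
    obs: Observation
    b_own: np.ndarray
    b_star_own: np.ndarray
    b_partner: np.ndarray
    b_star_partner: np.ndarray
    a_own: int = 0
    a_partner: int = 0


def _clamp_density(p: np.ndarray) -> np.ndarray:
    return np.clip(p, DENSITY_FLOOR, 1.0)


def _kl(q: np.ndarray, log_r: np.ndarray) -> float:
    """KL divergence of a strictly positive simplex vector from a log-density."""
    return float(np.sum(q * (np.log(q) - log_r)))


# ---------------------------------------------------------------------------
# generative densities
# ---------------------------------------------------------------------------

def sensory_posterior(b_own, a_own: int, s_own: int, k: float, cfg: WorldConfig) -> np.ndarray:
    """Sensory-model density over the next own position.

    ``p[psi'] = P(s_own | psi' - a_own) * q[psi' - a_own]`` with the prior
    ``q = softmax(b_own)``; actions are assumed fully effective (Kronecker
    transition), so the whole density is a circular shift of likelihood
    times prior.  Entries are clamped to ``[e^-10, 1]``.
    """
    q = encode(b_own)
    p1 = chemical_profile(k, cfg)
    like = p1 if s_own else 1.0 - p1
    return _clamp_density(shift(like * q, a_own))


def partner_action_profile(b_star_partner, xi: float) -> np.ndarray:
    """Partner-action model over all positions; shape ``(3, N)``.

    Row ``j`` gives ``P(a = ACTIONS[j] | phi)`` for every position ``phi``.
    The partner is modelled as acting mechanistically on its desires: the
    stand-still probability is ``xi * q*[phi] / max(q*)`` (so exactly ``xi``
    at a global desire maximum) and the remaining mass is split between the
    two moves in proportion to the desirability of the destination cells.
    """
    q_star = encode(b_star_partner)
    n = q_star.size
    p0 = xi * q_star / q_star.max()
    left = np.roll(q_star, 1)    # q*[phi - 1]
    right = np.roll(q_star, -1)  # q*[phi + 1]
    side_mass = (1.0 - p0) / (left + right)
    out = np.empty((3, n))
    out[0] = side_mass * left
    out[1] = p0
    out[2] = side_mass * right
    return out


def partner_action_probs(phi: int, b_star_partner, xi: float) -> dict:
    """``{-1: P, 0: P, +1: P}`` for the partner's next action at position ``phi``."""
    profile = partner_action_profile(b_star_partner, xi)
    return {a: float(profile[j, phi]) for j, a in enumerate(ACTIONS)}


_action_profile_cache: dict = {}


def _action_profile_cached(b_star_partner: np.ndarray, xi: float) -> np.ndarray:
    # desires are constant within a run, so the (3, N) profile is memoised
    key = (xi, b_star_partner.tobytes())
    prof = _action_profile_cache.get(key)
    if prof is None:
        prof = partner_action_profile(b_star_partner, xi)
        prof.flags.writeable = False
        if len(_action_profile_cache) > 256:
            _action_profile_cache.clear()
        _action_profile_cache[key] = prof
    return prof


def partner_posterior(
    b_partner,
    b_own,
    b_star_partner,
    delta: int,
    a_pp: int,
    a_partner: int,
    xi: float,
    n_cells: int | None = None,
) -> np.ndarray:
    """Partner-model density over the next partner position ``phi'``.

    Product of three factors, each back-shifted to ``phi'`` coordinates by
    the expected partner action:

    * the own-position belief evaluated at ``phi' - a_partner + delta``
      (the observed offset ties the two positions together);
    * the likelihood of the observed previous action ``a_pp``, evaluated at
      the backtracked position ``phi' - a_partner - a_pp``;
    * the prior partner belief at ``phi' - a_partner``.

    Entries clamped to ``[e^-10, 1]``.
    """
    q_own = encode(b_own)
    q_par = encode(b_partner)
    like = _action_profile_cached(np.asarray(b_star_partner, dtype=float), xi)[ACTIONS.index(a_pp)]
    p = (
        shift(q_own, a_partner - delta)
        * shift(like, a_partner + a_pp)
        * shift(q_par, a_partner)
    )
    return _clamp_density(p)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def _gate(alpha: float, p_shifted: np.ndarray) -> np.ndarray:
    """Normalised alterity gate ``alpha * N * p + (1 - alpha)``.

    ``alpha = 0`` yields exactly 1 everywhere (partner evidence ignored);
    ``alpha = 1`` yields ``N * p`` (full coupling, constant offset aside).
    """
    return alpha * p_shifted.size * p_shifted + (1.0 - alpha)


def _joint_targets(state: AgentState, a_own: int, a_partner: int, params: AgentParams,
                   cfg: WorldConfig, delta_prime: int | None = None):
    """Clamped gated densities ``(r_own, r_partner)`` for a candidate action pair."""
    p_own = sensory_posterior(state.b_own, a_own, state.obs.s_own, params.k, cfg)
    p_par = partner_posterior(
        state.b_partner, state.b_own, state.b_star_partner,
        state.obs.delta, state.obs.a_pp, a_partner, params.xi,
    )
    if delta_prime is None:
        delta_prime = (state.obs.delta + a_own - a_partner) % cfg.n_cells
    r_own = _clamp_density(p_own * _gate(params.alpha, shift(p_par, delta_prime)))
    r_par = _clamp_density(p_par * _gate(params.alpha ** 2, shift(p_own, -delta_prime)))
    return r_own, r_par


def agent_free_energy(
    b_own_next,
    b_partner_next,
    state: AgentState,
    a_own: int,
    a_partner: int,
    params: AgentParams,
    cfg: WorldConfig,
    delta_prime: int | None = None,
) -> float:
    """Joint variational free energy of candidate beliefs under a candidate action pair.

    Sum of two KL divergences: candidate own-belief against the gated
    sensory density, and candidate partner-belief against the gated partner
    density.  ``delta_prime`` is the own/partner offset used to align the
    two densities; by default it is predicted from the current offset and
    the candidate actions (action selection), while the belief update passes
    the freshly observed post-move offset.
    """
    r_own, r_par = _joint_targets(state, a_own, a_partner, params, cfg, delta_prime)
    return _kl(encode(b_own_next), np.log(r_own)) + _kl(encode(b_partner_next), np.log(r_par))


# ---------------------------------------------------------------------------
# action selection
# ---------------------------------------------------------------------------

def select_actions(state: AgentState, params: AgentParams, cfg: WorldConfig):
    """Choose the action pair minimising F evaluated at the desired beliefs.

    All nine candidate pairs are scored with the variational side fixed at
    the desire distributions (``q*_own``, ``q*_partner``); the first strict
    minimum in the fixed order (own-major ``0, +1, -1``; partner minor the
    same) wins, making selection deterministic under exact ties.

    Returns ``(a_own, a_partner, f_min)``.
    """
    qs_own = encode(state.b_star_own)
    qs_par = encode(state.b_star_partner)
    ent_own = float(np.sum(qs_own * np.log(qs_own)))
    ent_par = float(np.sum(qs_par * np.log(qs_par)))

    p_own = {a: sensory_posterior(state.b_own, a, state.obs.s_own, params.k, cfg)
             for a in CANDIDATE_ORDER}
    p_par = {a: partner_posterior(state.b_partner, state.b_own, state.b_star_partner,
                                  state.obs.delta, state.obs.a_pp, a, params.xi)
             for a in CANDIDATE_ORDER}

    best = None
    for ao in CANDIDATE_ORDER:
        for ap in CANDIDATE_ORDER:
            dp = (state.obs.delta + ao - ap) % cfg.n_cells
            r_own = _clamp_density(p_own[ao] * _gate(params.alpha, shift(p_par[ap], dp)))
            r_par = _clamp_density(p_par[ap] * _gate(params.alpha ** 2, shift(p_own[ao], -dp)))
            f = (ent_own - float(np.sum(qs_own * np.log(r_own)))
                 + ent_par - float(np.sum(qs_par * np.log(r_par))))
            if best is None or f < best[2]:
                best = (ao, ap, f)
    return best


# ---------------------------------------------------------------------------
# belief update
# ---------------------------------------------------------------------------

def _descend(b0: np.ndarray, log_r: np.ndarray, rate: float, steps: int):
    """Projected gradient descent of ``KL(softmax(b) || exp(log_r))`` over ``b``.

    Entries are projected into ``[-10, 0]`` after every step; if a step
    would increase F the step size is halved for that step (backtracking),
    so F is non-increasing across accepted iterations.  Returns the final
    vector and the number of halvings performed.
    """
    b = b0
    f = _kl(encode(b), log_r)
    halvings = 0
    for _ in range(steps):
        q = encode(b)
        u = np.log(q) - log_r
        g = q * (u - np.sum(q * u))
        if np.max(np.abs(g)) < GRAD_TOL:
            break
        eta = rate
        trial = np.clip(b - eta * g, B_FLOOR, 0.0)
        f_trial = _kl(encode(trial), log_r)
        n_halve = 0
        while f_trial > f and n_halve < MAX_HALVINGS:
            eta *= 0.5
            n_halve += 1
            trial = np.clip(b - eta * g, B_FLOOR, 0.0)
            f_trial = _kl(encode(trial), log_r)
        if n_halve:
            halvings += n_halve
            logger.debug("descent step halved %d time(s); F %.6g -> %.6g", n_halve, f, f_trial)
        if f_trial > f:  # no usable step at this scale
            break
        b, f = trial, f_trial
    return b, halvings


def update_beliefs(
    state: AgentState,
    a_own: int,
    a_partner: int,
    params: AgentParams,
    cfg: WorldConfig,
    delta_prime: int | None = None,
):
    """Gradient-descent belief update for the expected effects of the chosen actions.

    Uses the observation currently stored in ``state`` (the one that also
    informed action selection).  The two divergence terms decouple in the
    candidate beliefs, so each is descended separately against its gated
    density; descent starts from the current beliefs shifted by the
    corresponding action (the predictive step).  Returned vectors are
    re-canonicalised into ``[-10, 0]`` with max entry 0.

    Returns ``(b_own_next, b_partner_next)``.
    """
    r_own, r_par = _joint_targets(state, a_own, a_partner, params, cfg, delta_prime)
    b1, _ = _descend(shift(state.b_own, a_own), np.log(r_own), params.gd_rate, params.gd_steps)
    b2, _ = _descend(shift(state.b_partner, a_partner), np.log(r_par), params.gd_rate, params.gd_steps)
    b1 = np.maximum(b1 - b1.max(), B_FLOOR)
    b2 = np.maximum(b2 - b2.max(), B_FLOOR)
    return b1, b2


# ---------------------------------------------------------------------------
# the epoch loop
# ---------------------------------------------------------------------------

def initial_state(psi: int, partner_psi: int, b_star_own, b_star_partner,
                  k: float, cfg: WorldConfig, rng: np.random.Generator) -> AgentState:
    """Agent state at epoch 0: uniform beliefs and an initial observation."""
    n = cfg.n_cells
    s = sample_chemical(psi, k, cfg, rng)
    delta, a_pp = observe_partner(psi, partner_psi, 0, n)
    return AgentState(
        psi=int(psi),
        obs=Observation(s_own=s, delta=delta, a_pp=a_pp),
        b_own=np.zeros(n),
        b_star_own=np.asarray(b_star_own, dtype=float).copy(),
        b_partner=np.zeros(n),
        b_star_partner=np.asarray(b_star_partner, dtype=float).copy(),
    )


def agent_step(
    state: AgentState,
    params: AgentParams,
    cfg: WorldConfig,
    rng: np.random.Generator,
    partner_new_psi: int,
    partner_action: int,
):
    """One epoch for a single agent given the partner's resolved move.

    (In lockstep both agents act from the same epoch-start snapshot; the
    partner's post-move position and realised action are needed only for
    the end-of-epoch sensing.  See :func:`step_pair` for the two-agent
    driver.)  Order: select actions, update beliefs for their expected
    effects, move, sense at the new position.

    Returns ``(new_state, f_selected)``.
    """
    a_own, a_partner, f_sel = select_actions(state, params, cfg)
    b_own, b_par = update_beliefs(state, a_own, a_partner, params, cfg)
    psi_new = (state.psi + a_own) % cfg.n_cells
    s_new = sample_chemical(psi_new, params.k, cfg, rng)
    delta_new, a_pp = observe_partner(psi_new, partner_new_psi, partner_action, cfg.n_cells)
    new = replace(
        state,
        psi=psi_new,
        obs=Observation(s_own=s_new, delta=delta_new, a_pp=a_pp),
        a_own=a_own,
        a_partner=a_partner,
    )
    new.b_own = b_own
    new.b_partner = b_par
    return new, f_sel


def step_pair(
    state_a: AgentState,
    state_b: AgentState,
    params_a: AgentParams,
    params_b: AgentParams,
    cfg: WorldConfig,
    rng_a: np.random.Generator,
    rng_b: np.random.Generator,
):
    """Lockstep epoch for both agents of a dyad.

    Both agents select and update from the same epoch-start snapshot, both
    move, then both sense the post-move world (the observation the next
    epoch will act on).  Each agent draws its chemical sample from its own
    RNG substream.

    Returns ``(new_state_a, new_state_b, f_a, f_b)``.
    """
    n = cfg.n_cells
    sel_a = select_actions(state_a, params_a, cfg)
    sel_b = select_actions(state_b, params_b, cfg)
    upd_a = update_beliefs(state_a, sel_a[0], sel_a[1], params_a, cfg)
    upd_b = update_beliefs(state_b, sel_b[0], sel_b[1], params_b, cfg)
    psi_a = (state_a.psi + sel_a[0]) % n
    psi_b = (state_b.psi + sel_b[0]) % n

    def perceive(state, sel, upd, psi_new, partner_psi, partner_action, params, rng):
        s_new = sample_chemical(psi_new, params.k, cfg, rng)
        delta, a_pp = observe_partner(psi_new, partner_psi, partner_action, n)
        new = replace(
            state,
            psi=psi_new,
            obs=Observation(s_own=s_new, delta=delta, a_pp=a_pp),
            a_own=sel[0],
            a_partner=sel[1],
        )
        new.b_own, new.b_partner = upd
        return new

    new_a = perceive(state_a, sel_a, upd_a, psi_a, psi_b, sel_b[0], params_a, rng_a)
    new_b = perceive(state_b, sel_b, upd_b, psi_b, psi_a, sel_a[0], params_b, rng_b)
    return new_a, new_b, sel_a[2], sel_b[2]


@dataclass
class DyadResult:
    """Trajectory record of one two-agent run.

    ``psi`` has shape ``(epochs + 1, 2)`` (positions including the start);
    ``s``, ``a`` and ``f`` have shape ``(epochs, 2)``.  Belief snapshots are
    the end-state vectors; ``belief_history`` (own-position beliefs, shape
    ``(epochs + 1, 2, N)``) is kept only when requested.
    """

    psi: np.ndarray
    s: np.ndarray
    a: np.ndarray
    f: np.ndarray
    final_a: AgentState
    final_b: AgentState
    belief_history: np.ndarray | None = None


def simulate_dyad(
    cfg: WorldConfig,
    params_a: AgentParams,
    params_b: AgentParams,
    desires_a,
    desires_b,
    imputed_a,
    imputed_b,
    start_a: int,
    start_b: int,
    epochs: int,
    rng_a: np.random.Generator,
    rng_b: np.random.Generator,
    record_beliefs: bool = False,
) -> DyadResult:
    """Run one two-agent subsystem for ``epochs`` lockstep epochs.

    ``desires_*`` are each agent's own composed log-desires; ``imputed_*``
    the desires each agent attributes to its partner.  Deterministic given
    the two RNG substreams.
    """
    state_a = initial_state(start_a, start_b, desires_a, imputed_a, params_a.k, cfg, rng_a)
    state_b = initial_state(start_b, start_a, desires_b, imputed_b, params_b.k, cfg, rng_b)

    psi = np.empty((epochs + 1, 2), dtype=int)
    s = np.empty((epochs, 2), dtype=int)
    a = np.empty((epochs, 2), dtype=int)
    f = np.empty((epochs, 2))
    psi[0] = (state_a.psi, state_b.psi)
    hist = None
    if record_beliefs:
        hist = np.empty((epochs + 1, 2, cfg.n_cells))
        hist[0, 0] = state_a.b_own
        hist[0, 1] = state_b.b_own

    for t in range(epochs):
        state_a, state_b, f_a, f_b = step_pair(
            state_a, state_b, params_a, params_b, cfg, rng_a, rng_b
        )
        psi[t + 1] = (state_a.psi, state_b.psi)
        s[t] = (state_a.obs.s_own, state_b.obs.s_own)
        a[t] = (state_a.a_own, state_b.a_own)
        f[t] = (f_a, f_b)
        if record_beliefs:
            hist[t + 1, 0] = state_a.b_own
            hist[t + 1, 1] = state_b.b_own

    return DyadResult(psi=psi, s=s, a=a, f=f, final_a=state_a, final_b=state_b,
                      belief_history=hist)
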