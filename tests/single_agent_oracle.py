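"""Deliberately simple single-agent chemotaxis reference implementation.

Implements the original one-agent model — no partner terms at all — as an
independent oracle for the two-agent implementation's reduction at
``alpha = 0`` (where the partner gate is exactly neutral and the own-belief
inference decouples from everything social).  The generative density is
built by literal summation over the three causal factors (Kronecker
transition, sensory likelihood at the pre-action cell, belief prior), not
by vectorised shifts; only the belief-codec primitives are shared with the
package.

The free energy is ``KL(softmax(b') || p)`` with the density clamped to
``[e^-10, 1]``; action selection enumerates the three moves with the fixed
tie-break order (0, +1, -1) scoring F at the desire distribution, and the
belief update is projected gradient descent with backtracking step-halving
— the same mathematical conventions as the package, independently coded.
"""

from __future__ import annotations

import numpy as np

from aifcollective.belief_space import encode

B_FLOOR = -10.0
FLOOR = float(np.exp(-10.0))
ORDER = (0, 1, -1)
GRAD_TOL = 1e-12
MAX_HALVINGS = 40


def oracle_likelihood(s, k, cfg):
    """Sensory likelihood vector P(s | psi) = k^s (1-k)^(1-s)-style decay model."""
    n = cfg.n_cells
    d = np.array([min((psi - cfg.center) % n, (cfg.center - psi) % n) for psi in range(n)])
    ps1 = k * np.exp(-cfg.omega * d)
    return ps1 if s else 1.0 - ps1


def oracle_density(b, s, a, k, cfg):
    """Literal three-factor generative density over the next position.

    ``p[psi'] = sum_psi delta(psi', psi + a) * P(s | psi) * q[psi]``
    evaluated cell by cell, then clamped to ``[e^-10, 1]``.
    """
    n = cfg.n_cells
    q = encode(b)
    like = oracle_likelihood(s, k, cfg)
    p = np.zeros(n)
    for psi_next in range(n):
        for psi in range(n):
            if psi_next == (psi + a) % n:
                p[psi_next] += like[psi] * q[psi]
    return np.clip(p, FLOOR, 1.0)


def oracle_free_energy(b_next, b, s, a, k, cfg):
    """F(b', b, s, a) = KL(q(b') || p(. , s | b, a)), clamped density."""
    q_next = encode(b_next)
    p = oracle_density(b, s, a, k, cfg)
    return float(np.sum(q_next * (np.log(q_next) - np.log(p))))


def oracle_select(b, b_star, s, k, cfg):
    """Pick the move minimising F at the desire distribution; first min wins."""
    qs = encode(b_star)
    best_a, best_f = None, None
    for a in ORDER:
        p = oracle_density(b, s, a, k, cfg)
        f = float(np.sum(qs * (np.log(qs) - np.log(p))))
        if best_f is None or f < best_f:
            best_a, best_f = a, f
    return best_a, best_f


def oracle_update(b, s, a, k, cfg, rate, steps):
    """Projected gradient descent of F on b', starting from the predicted belief."""
    n = cfg.n_cells
    p = oracle_density(b, s, a, k, cfg)
    log_p = np.log(p)
    bb = np.roll(b, a % n)  # predictive shift
    f = _kl(bb, log_p)
    for _ in range(steps):
        q = encode(bb)
        u = np.log(q) - log_p
        g = q * (u - np.sum(q * u))
        if np.max(np.abs(g)) < GRAD_TOL:
            break
        eta = rate
        trial = np.clip(bb - eta * g, B_FLOOR, 0.0)
        f_trial = _kl(trial, log_p)
        halve = 0
        while f_trial > f and halve < MAX_HALVINGS:
            eta *= 0.5
            halve += 1
            trial = np.clip(bb - eta * g, B_FLOOR, 0.0)
            f_trial = _kl(trial, log_p)
        if f_trial > f:
            break
        bb, f = trial, f_trial
    return np.maximum(bb - bb.max(), B_FLOOR)


def _kl(b, log_p):
    q = encode(b)
    return float(np.sum(q * (np.log(q) - log_p)))


def oracle_step(b, psi, s, b_star, k, cfg, rate, steps):
    """One epoch: select on the current observation, update beliefs for the
    expected effect of the chosen action, then move.

    The caller senses the new chemical bit at ``psi_next`` afterwards (so it
    controls the random stream).  Returns ``(b_next, psi_next, a)``.
    """
    a, _ = oracle_select(b, b_star, s, k, cfg)
    b_next = oracle_update(b, s, a, k, cfg, rate, steps)
    psi_next = (psi + a) % cfg.n_cells
    return b_next, psi_next, a


def run_oracle(cfg, k, b_star, start, epochs, rng, rate, steps):
    """Full single-agent run; mirrors the package's epoch loop and RNG usage."""
    from aifcollective.world import sample_chemical

    b = np.zeros(cfg.n_cells)
    psi = int(start)
    s = sample_chemical(psi, k, cfg, rng)
    traj_psi = [psi]
    traj_a, traj_s, beliefs = [], [], [b.copy()]
    for _ in range(epochs):
        b, psi, a = oracle_step(b, psi, s, b_star, k, cfg, rate, steps)
        s = sample_chemical(psi, k, cfg, rng)
        traj_psi.append(psi)
        traj_a.append(a)
        traj_s.append(s)
        beliefs.append(b.copy())
    return (np.array(traj_psi), np.array(traj_a), np.array(traj_s), np.array(beliefs))
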