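"""Belief-space primitives for agents on a circular 1-D world.

Agents represent a distribution over the ``N`` ring positions as a
*log-belief vector* ``b`` with entries in ``B = [-10, 0]``.  The codec pair
:func:`encode` / :func:`decode` converts between log-beliefs and the
probability simplex: ``encode`` is a numerically stable softmax, and
``decode`` maps ``q`` back via ``b_i = ln q_i - ln max(q)`` so the largest
entry is exactly 0, flooring at -10 for numerical stability.  The floor
doubles as an overconfidence guard: no position is ever believed impossible.

Also provided: :func:`rerange` (the affine "squishing" map used to gate
partner evidence), circular shifting, and ring distance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "B_FLOOR",
    "DENSITY_FLOOR",
    "PROB_TOL",
    "encode",
    "decode",
    "rerange",
    "shift",
    "circ_dist",
]

#: lower bound of the log-belief range B
B_FLOOR = -10.0
#: lower bound e^-10 for generative-density entries
DENSITY_FLOOR = float(np.exp(B_FLOOR))
#: tolerance for probability-vector normalisation checks
PROB_TOL = 1e-9


def _as_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector, got shape {arr.shape}")
    return arr


def encode(b) -> np.ndarray:
    """Softmax-decode a log-belief vector into a probability distribution.

    Uses the max-subtraction form ``exp(b_i - max(b)) / sum(...)`` for
    numerical stability.  Invariant to adding a constant to every entry.
    """
    arr = _as_vector(b, "b")
    e = np.exp(arr - arr.max())
    return e / np.sum(e)


def decode(q) -> np.ndarray:
    """Convert a probability distribution back to a canonical log-belief vector.

    Returns ``b_i = ln q_i - ln max(q)`` floored at -10, so the maximum
    entry is exactly 0.  Non-positive entries map to the floor rather than
    raising.  ``decode`` after ``encode`` is idempotent on its image.
    """
    arr = _as_vector(q, "q")
    if np.any(arr < -PROB_TOL) or abs(float(np.sum(arr)) - 1.0) > PROB_TOL:
        raise ValueError("q is not a normalised probability distribution")
    m = arr.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(arr > 0.0, np.log(np.maximum(arr, 1e-300)) - np.log(m), B_FLOOR)
    return np.maximum(b, B_FLOOR)


def rerange(q, alpha: float) -> np.ndarray:
    """Re-range ("squish") a distribution: ``alpha * q + (1 - alpha) / N``.

    Maps the simplex into itself, compressing the entry range to
    ``[(1-alpha)/N, alpha + (1-alpha)/N]``; ``alpha=1`` is the identity and
    ``alpha=0`` gives the uniform distribution.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    arr = _as_vector(q, "q")
    return alpha * arr + (1.0 - alpha) / arr.size


def shift(v, x: int) -> np.ndarray:
    """Circularly shift ``v`` so that ``result[i] = v[(i - x) mod N]``."""
    arr = _as_vector(v, "v")
    return np.roll(arr, int(x) % arr.size)


def circ_dist(i, j, n: int):
    """Shortest ring distance between positions ``i`` and ``j`` (mod ``n``).

    Accepts scalars or arrays; the result is at most ``n // 2``.
    """
    d = np.mod(np.asarray(i) - np.asarray(j), n)
    out = np.minimum(d, n - d)
    if out.ndim == 0:
        return int(out)
    return out
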