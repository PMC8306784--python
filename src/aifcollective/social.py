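"""Desire (target-encoding) construction and Goal Alignment.

Desires are log-belief vectors whose decoded distributions peak at target
cells.  Each target contributes an equal-height discretised bell curve
(log-space height 0 at the peak, floored at -10); ``peak_width`` is the
Gaussian sigma in cells, and width 0 degenerates to point masses.

Goal Alignment blends shared and private desires in log space::

    b* <- clamp(b*_shared + (1 - gamma) * b*_private)

with ``gamma = 0`` weighting private and shared goals equally and
``gamma = 1`` suppressing private goals entirely.  The same composition is
applied to an agent's own desires and to the desires it imputes to its
partner, so alignment is a property of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .belief_space import B_FLOOR, circ_dist, decode
from .world import WorldConfig

__all__ = ["DesireSpec", "compose_desires", "make_desire_distribution"]


@dataclass(frozen=True)
class DesireSpec:
    """Peak layout and alignment level for one agent's desires."""

    shared_peaks: tuple = ()
    private_peaks: tuple = ()
    peak_width: float = 2.0
    gamma: float = 0.0

    def __post_init__(self):
        if not (self.shared_peaks or self.private_peaks):
            raise ValueError("at least one desire peak is required")
        if self.peak_width < 0:
            raise ValueError("peak_width must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


def compose_desires(b_star_shared, b_star_private, gamma: float) -> np.ndarray:
    """Blend shared and private log-desires with alignment ``gamma``.

    Addition happens in log-belief space, after which the result is
    re-canonicalised (max entry 0, floor -10).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    shared = np.asarray(b_star_shared, dtype=float)
    private = np.asarray(b_star_private, dtype=float)
    if shared.shape != private.shape:
        raise ValueError("shared and private desire vectors must have equal length")
    b = shared + (1.0 - gamma) * private
    return np.maximum(b - b.max(), B_FLOOR)


def _bump_weights(peaks, width: float, n: int) -> np.ndarray:
    """Sum of equal-height bell curves (probability space, unnormalised)."""
    w = np.zeros(n)
    for p in peaks:
        d = circ_dist(np.arange(n), int(p), n).astype(float)
        if width == 0.0:
            w += (d == 0.0).astype(float)
        else:
            w += np.exp(-(d ** 2) / (2.0 * width ** 2))
    return w


def make_desire_distribution(spec: DesireSpec, cfg: WorldConfig) -> np.ndarray:
    """Build a canonical log-desire vector from a peak layout.

    All peaks are encoded with equal desirability: the decoded distribution
    has equal local maxima at every peak cell (overlapping bumps superpose
    and are re-clamped).  Shared and private peaks are blended through
    :func:`compose_desires` with ``spec.gamma``.
    """
    n = cfg.n_cells
    for p in tuple(spec.shared_peaks) + tuple(spec.private_peaks):
        if not 0 <= int(p) < n:
            raise ValueError(f"desire peak {p} outside [0, {n})")

    def log_bump(peaks):
        if not peaks:
            return np.full(n, B_FLOOR)
        w = _bump_weights(peaks, spec.peak_width, n)
        return decode(w / np.sum(w))

    if spec.shared_peaks and spec.private_peaks:
        return compose_desires(log_bump(spec.shared_peaks), log_bump(spec.private_peaks), spec.gamma)
    # single family: alignment has nothing to suppress
    return log_bump(tuple(spec.shared_peaks) + tuple(spec.private_peaks))
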