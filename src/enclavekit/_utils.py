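"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a log-normal with arithmetic
    mean ``mean`` and arithmetic standard deviation ``sd``.

    sigma^2 = ln(1 + sd^2/mean^2),  mu = ln(mean) - sigma^2/2.
    A zero ``sd`` degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def wrap_nematic(angle):
    """Wrap angles to the nematic fundamental domain (-pi/2, pi/2]."""
    a = np.mod(np.asarray(angle, dtype=float) + np.pi / 2.0, np.pi)
    a = np.where(a == 0.0, np.pi, a)
    return a - np.pi / 2.0


def nematic_difference(a, b):
    """Smallest nematic angle increment from ``a`` to ``b`` in (-pi/2, pi/2]."""
    return wrap_nematic(np.asarray(b) - np.asarray(a))


def unit(angle):
    """Unit vector(s) for angle(s), shape (..., 2)."""
    angle = np.asarray(angle, dtype=float)
    return np.stack([np.cos(angle), np.sin(angle)], axis=-1)
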