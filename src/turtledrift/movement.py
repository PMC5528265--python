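"""Habitat-driven swimming: heading sampling and velocity composition.

Headings are measured clockwise from geographic North, with unit direction
vector d = (north, east) = (cos(theta), sin(theta)).  A heading is drawn
each day from a von Mises distribution whose mean is the direction of the
habitat gradient and whose concentration is kappa = alpha*|grad h|; a zero
gradient gives exactly uniform headings.  The swimming speed is
Vm*(1 - h): full speed in hostile habitat, zero in perfect habitat.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np

__all__ = [
    "Velocity",
    "heading_of_gradient",
    "sample_heading",
    "sample_headings",
    "swimming_velocity",
    "calibrate_v0",
    "ground_velocity",
]

log = logging.getLogger(__name__)

KAPPA_MAX = 1.0e4


class Velocity(NamedTuple):
    """Horizontal velocity components in m/s."""

    east: float
    north: float


def heading_of_gradient(dhdx, dhdy):
    """Heading angle (radians from North, clockwise) of a gradient vector.

    ``dhdx`` is the eastward and ``dhdy`` the northward component.  A zero
    vector maps to heading 0 (the value is irrelevant: kappa is then 0 and
    the draw uniform).
    """
    return np.arctan2(dhdx, dhdy)


def sample_headings(dhdx, dhdy, alpha, rng, kappa_max: float = KAPPA_MAX):
    """Vectorized daily heading draws for many agents.

    theta ~ vonMises(mu = direction of grad h, kappa = alpha*|grad h|),
    exactly uniform on (-pi, pi] where the gradient vanishes.  kappa is
    capped at ``kappa_max`` to avoid numerical degeneracy on extreme
    synthetic gradients (logged when the cap binds).
    """
    dhdx = np.asarray(dhdx, dtype=float)
    dhdy = np.asarray(dhdy, dtype=float)
    mu = heading_of_gradient(dhdx, dhdy)
    kappa = alpha * np.hypot(dhdx, dhdy)
    n_capped = int(np.sum(kappa > kappa_max))
    if n_capped:
        log.info("kappa cap %.3g reached for %d draws", kappa_max, n_capped)
        kappa = np.minimum(kappa, kappa_max)
    theta = rng.vonmises(mu, kappa)
    # numpy returns [-pi, pi); fold the closed end onto pi
    return np.where(theta <= -np.pi, np.pi, theta)


def sample_heading(grad, alpha, rng) -> float:
    """Single heading draw from one gradient vector (dhdx, dhdy)."""
    return float(sample_headings(grad[0], grad[1], alpha, rng))


def swimming_velocity(vm, h, theta):
    """Swimming velocity for max speed ``vm``, habitat ``h`` and heading ``theta``.

    Speed vm*(1-h) along d = (cos(theta) north, sin(theta) east).  Returns a
    :class:`Velocity` for scalar input, component arrays otherwise.
    """
    h = np.asarray(h, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("habitat index must lie in [0, 1]")
    vm = np.asarray(vm, dtype=float)
    if np.any(vm < 0):
        raise ValueError("maximum sustainable speed must be non-negative")
    speed = vm * (1.0 - h)
    east = speed * np.sin(theta)
    north = speed * np.cos(theta)
    if east.ndim == 0:
        return Velocity(float(east), float(north))
    return east, north


def calibrate_v0(avg_speed: float, h_avg: float) -> float:
    """Speed scale v0 from an observed mean speed at mean habitat ``h_avg``.

    The operational speed law gives Vs ~ v0*(1-h) for near-adult sizes, so
    v0 = avg_speed / (1 - h_avg).
    """
    if not 0 <= h_avg < 1:
        raise ValueError("h_avg must lie in [0, 1)")
    return avg_speed / (1.0 - h_avg)


def ground_velocity(vc, vs):
    """Velocity over ground: componentwise sum of current and swimming."""
    if isinstance(vc, Velocity) or (isinstance(vc, tuple) and np.ndim(vc[0]) == 0):
        return Velocity(float(vc[0]) + float(vs[0]), float(vc[1]) + float(vs[1]))
    return vc[0] + vs[0], vc[1] + vs[1]
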