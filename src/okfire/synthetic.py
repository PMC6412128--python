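"""Canonical synthetic scenarios: the study conditions for tests and demos.

Each scenario fixes an origin triplet and firing parameters exhibiting one
qualitative regime of the model (sharp strong origins, partial licencing of
the middle origin, obscuring of the middle origin).  The noise defaults
``b = 0.1`` and ``tau = 50`` represent deep Okazaki-fragment coverage boxed
at 50 bp: a 10% uniform-fragmentation background and ~14% multiplicative
noise per box (log-noise s.d. ``1/sqrt(tau)``).
"""

from __future__ import annotations

import numpy as np

from .model_core import FiringParams, OriginTriplet
from .noise_model import NoiseParams

__all__ = [
    "standard_triplet",
    "strong_origins",
    "partial_licencing",
    "obscured_middle",
    "recovery_truth",
    "default_noise",
]

#: Origin spacing used throughout the demo scenarios: N1 = 1300, N2 = 1300 bp.
def standard_triplet() -> OriginTriplet:
    return OriginTriplet((200, 1500, 2800))


def default_noise() -> NoiseParams:
    return NoiseParams(b=0.1, tau=50.0)


def strong_origins() -> FiringParams:
    """Fully licenced origins with staggered firing.

    Firing-time differences t2 - t1 ~ N(700, 141^2) and t3 - t2 ~ N(300,
    282^2); the averaged profile shows clean tanh-like transitions between
    each pair of origins.
    """
    mu = np.array([-433.33, 266.67, 566.67])  # diffs 700, 300; sum = 0
    sigma = np.array([100.0, 100.0, 263.7])  # hypot pairs: 141, 282
    return FiringParams(mu, sigma, np.ones(3))


def partial_licencing() -> FiringParams:
    """Middle origin unlicenced in 70% of cells, equal firing times.

    All firing times ~ N(100, 100^2); obscuring is negligible at these
    spacings, so the jump at the middle origin is approximately q2 = 0.3.
    """
    return FiringParams(np.full(3, 100.0), np.full(3, 100.0), np.array([1.0, 0.3, 1.0]))


def obscured_middle() -> FiringParams:
    """Middle origin obscured from the left in ~70% of cells.

    t1 ~ N(-602, 196^2), t2 ~ N(800, 100^2), t3 ~ N(100, 100^2): the left
    origin fires much earlier, and its rightward fork usually reaches the
    middle origin (1300 bp away) before the latter fires.
    """
    return FiringParams(
        np.array([-602.0, 800.0, 100.0]), np.array([196.0, 100.0, 100.0]), np.ones(3)
    )


def recovery_truth() -> FiringParams:
    """Ground truth for parameter-recovery studies.

    The staggered-firing scenario of :func:`strong_origins` with partial
    licencing everywhere (q = 0.9, 0.7, 0.9), exercising the joint
    estimation of licencing, firing times and noise.
    """
    return FiringParams(
        np.array([-433.33, 266.67, 566.67]),
        np.array([100.0, 100.0, 263.7]),
        np.array([0.9, 0.7, 0.9]),
    )
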