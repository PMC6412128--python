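"""Observation model: multiplicative log-normal noise on strand intensities.

The boxed, normalized strand counts are modelled as the averaged profile
mixed with a uniform random-fragmentation background and corrupted by
multiplicative log-normal noise of unit mean::

    X_f = ((1 - b) F_ave + 0.5 b) * exp(N(-0.5/tau, 1/tau))
    X_r = ((1 - b) (1 - F_ave) + 0.5 b) * exp(N(-0.5/tau, 1/tau))

``b`` in [0, 1] weights the background (random fragments land on either
strand with equal probability, hence the 0.5), and ``tau`` is the precision
(inverse variance) of the log-noise.  The shifted log-mean makes the noise
factor have expectation exactly 1, matching the normalization of the data
(forward plus reverse counts average to 1 across the region).  A single
``(b, tau)`` is shared by both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import AveragedProfile

__all__ = [
    "NoiseParams",
    "BoxedCounts",
    "expected_intensity",
    "generate_counts",
    "floor_counts",
    "loglikelihood",
]


@dataclass(frozen=True)
class NoiseParams:
    """Background weight ``b`` in [0, 1] and log-noise precision ``tau`` > 0."""

    b: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("background weight b must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("noise precision tau must be positive")


@dataclass
class BoxedCounts:
    """Normalized per-box strand counts -- the observation vector.

    ``c_f`` / ``c_r`` are dimensionless forward/reverse counts per 50-bp box
    (or ``s_box``), normalized so that the mean of ``c_f + c_r`` over boxes is
    1.  ``n_norm`` is the raw normalization constant (counts per bp) and
    ``b_chr`` the chromosome strand-bias factor applied to the reverse
    strand, when the counts came from real coverage.
    """

    c_f: np.ndarray
    c_r: np.ndarray
    box_starts: np.ndarray
    s_box: int
    n_norm: Optional[float] = None
    b_chr: Optional[float] = None
    chrom: str = "chr"

    def __post_init__(self) -> None:
        self.c_f = np.asarray(self.c_f, dtype=float)
        self.c_r = np.asarray(self.c_r, dtype=float)
        self.box_starts = np.asarray(self.box_starts, dtype=float)
        if not (self.c_f.shape == self.c_r.shape == self.box_starts.shape):
            raise ValueError("c_f, c_r and box_starts must have equal shapes")
        if np.any(self.c_f < 0) or np.any(self.c_r < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_boxes(self) -> int:
        return self.c_f.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"box_start": self.box_starts.astype(int), "c_f": self.c_f, "c_r": self.c_r}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, s_box: Optional[int] = None, chrom: str = "chr") -> "BoxedCounts":
        df = pd.read_csv(path, sep="\t")
        starts = df["box_start"].to_numpy(dtype=float)
        if s_box is None:
            if starts.size < 2:
                raise ValueError("cannot infer s_box from a single box; pass it explicitly")
            s_box = int(round(starts[1] - starts[0]))
        return cls(df["c_f"].to_numpy(), df["c_r"].to_numpy(), starts, s_box, chrom=chrom)

    def to_bedgraphs(self, path_f, path_r) -> None:
        for path, c in ((path_f, self.c_f), (path_r, self.c_r)):
            pd.DataFrame(
                {
                    "chrom": self.chrom,
                    "start": self.box_starts.astype(int),
                    "end": (self.box_starts + self.s_box).astype(int),
                    "value": c,
                }
            ).to_csv(path, sep="\t", index=False, header=False)


def expected_intensity(profile_values: np.ndarray, noise: NoiseParams):
    """Per-box mean intensities ``(m_f, m_r)``; ``m_f + m_r == 1`` exactly."""
    f = np.asarray(profile_values, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("profile values must lie in [0, 1]")
    m_f = (1.0 - noise.b) * f + 0.5 * noise.b
    return m_f, 1.0 - m_f


def generate_counts(
    profile: AveragedProfile, noise: NoiseParams, rng: np.random.Generator
) -> BoxedCounts:
    """Draw synthetic boxed counts from the observation model."""
    m_f, m_r = expected_intensity(profile.values, noise)
    sd = np.sqrt(1.0 / noise.tau)
    mean_log = -0.5 / noise.tau
    c_f = m_f * np.exp(rng.normal(mean_log, sd, size=m_f.shape))
    c_r = m_r * np.exp(rng.normal(mean_log, sd, size=m_r.shape))
    return BoxedCounts(
        c_f, c_r, profile.box_starts, profile.s_box, chrom=profile.triplet.chrom
    )


def floor_counts(c_f: np.ndarray, c_r: np.ndarray):
    """Floor counts at half the smallest positive value across both strands.

    The log-normal density is undefined at zero; zero boxes (possible in real
    data after normalization) are lifted to a small positive floor before
    taking logs.
    """
    pooled = np.concatenate([np.ravel(c_f), np.ravel(c_r)])
    positive = pooled[pooled > 0]
    if positive.size == 0:
        raise ValueError("all counts are zero; no signal in the region")
    eps = 0.5 * positive.min()
    return np.maximum(c_f, eps), np.maximum(c_r, eps)


def loglikelihood(
    counts: BoxedCounts,
    profile_values: np.ndarray,
    noise: NoiseParams,
    floor: bool = True,
) -> float:
    """Log-likelihood of boxed counts under the log-normal noise model.

    Sum over boxes and both strands of the log-normal log-density
    ``-0.5 ln(2 pi / tau) - ln x - (tau / 2)(ln x - ln m + 0.5 / tau)^2``
    with ``m`` the expected intensity of the strand at that box.

    With ``floor=True`` zero counts are first lifted via :func:`floor_counts`;
    with ``floor=False`` a zero count is an error.
    """
    m_f, m_r = expected_intensity(profile_values, noise)
    if np.any(m_f <= 0) or np.any(m_r <= 0):
        raise ValueError("expected intensities must be positive (is b = 0 with a flat profile?)")
    c_f, c_r = counts.c_f, counts.c_r
    if floor:
        c_f, c_r = floor_counts(c_f, c_r)
    elif np.any(c_f <= 0) or np.any(c_r <= 0):
        raise ValueError("zero counts in the likelihood; enable flooring or clean the data")
    tau = noise.tau
    total = 0.0
    for x, m in ((c_f, m_f), (c_r, m_r)):
        e = np.log(x) - np.log(m) + 0.5 / tau
        total += np.sum(-0.5 * np.log(2.0 * np.pi / tau) - np.log(x) - 0.5 * tau * e**2)
    if not np.isfinite(total):
        raise ValueError("non-finite log-likelihood")
    return float(total)
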