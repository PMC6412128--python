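"""Posterior post-processing: licencing/obscuring summaries, collision and
firing-difference densities, firing-order probabilities and replication-time
reconstruction.

Licencing and obscuring posteriors are reported as medians with lower/upper
quartiles, since these distributions are often highly skewed; quartiles use
the midpoint convention (``np.quantile(..., method="midpoint")``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model_core import FiringParams, OriginTriplet, simulate_population
from .noise_model import NoiseParams
from .inference import ChainSet

__all__ = [
    "summarize_licencing",
    "summarize_obscuring",
    "collision_density",
    "firing_diff_density",
    "prob_fires_earlier",
    "firing_order_table",
    "point_estimates",
    "median_replication_time",
    "ReplicationTimeProfile",
    "CollisionDensity",
    "FiringDiffDensity",
]

_PAIR_CODES = {(0, 1): 0, (1, 2): 1, (0, 2): 2}


def _mqq(v: np.ndarray) -> tuple[float, float, float]:
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75], method="midpoint")
    return float(q25), float(med), float(q75)


def summarize_licencing(chains: ChainSet) -> pd.DataFrame:
    """Median and lower/upper quartiles of each q_i over pooled samples."""
    rows = []
    for i in range(3):
        v = chains.pooled(f"q_{i + 1}")
        q25, med, q75 = _mqq(v)
        rows.append(
            {
                "origin": chains.triplet.names[i],
                "q25": q25,
                "median": med,
                "q75": q75,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def summarize_obscuring(chains: ChainSet) -> pd.DataFrame:
    """Quartile summary of directed obscuring fractions, with significance.

    One row per directed pair (origin i obscured by origin j); end origins
    are one-sided by construction (no forks enter from outside the triplet).
    Significance against zero uses a Gaussian approximation to the posterior
    of the obscuring fraction (fit mean and variance, one-sided p-value).
    """
    obsc = chains.obscuring.reshape(-1, 3, 3)
    rows = []
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            v = obsc[:, i, j]
            q25, med, q75 = _mqq(v)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            p = float(norm.cdf(0.0, loc=mean, scale=sd)) if sd > 0 else (1.0 if mean == 0 else 0.0)
            rows.append(
                {
                    "obscured": chains.triplet.names[i],
                    "by": chains.triplet.names[j],
                    "direction": "left" if j < i else "right",
                    "q25": q25,
                    "median": med,
                    "q75": q75,
                    "mean": mean,
                    "sd": sd,
                    "p_vs_zero": p,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CollisionDensity:
    """Histogram of inferred collision points for one origin pair."""

    pair: tuple[int, int]
    points: np.ndarray
    hist: np.ndarray
    edges: np.ndarray
    realized_fraction: float


def collision_density(
    chains: ChainSet, pair: tuple[int, int], bin_width: Optional[float] = None
) -> CollisionDensity:
    """Density of collision points for a pair, plus its realized fraction.

    The realized fraction is the posterior-mean fraction of cells in which
    forks from this pair actually collide (for the end pair (0, 2): with the
    middle origin unrealized).  Histogram bins default to the box width.
    """
    code = _PAIR_CODES[tuple(pair)]
    mask = chains.sub_pairs.reshape(-1, 2) == code
    points = chains.sub_collisions.reshape(-1, 2)[mask]
    points = points[np.isfinite(points)]
    frac = float(chains.pair_frac.reshape(-1, 3)[:, code].mean())
    x1, _, x3 = chains.triplet.positions
    bw = bin_width if bin_width is not None else 50.0
    edges = np.arange(x1, x3 + bw, bw)
    hist, edges = np.histogram(points, bins=edges, density=points.size > 0)
    return CollisionDensity(tuple(pair), points, hist, edges, frac)


@dataclass
class FiringDiffDensity:
    """Pooled latent firing-time differences t_j - t_i, both origins licenced.

    ``threshold`` is the inter-origin distance N_ij: mass beyond +N_ij
    corresponds to cells where origin j is obscured by origin i's fork, and
    mass below -N_ij to the converse.
    """

    pair: tuple[int, int]
    diffs: np.ndarray
    threshold: float
    empty: bool

    def mass_beyond_threshold(self) -> tuple[float, float]:
        if self.empty:
            return (float("nan"), float("nan"))
        below = float((self.diffs < -self.threshold).mean())
        above = float((self.diffs > self.threshold).mean())
        return below, above


def firing_diff_density(chains: ChainSet, pair: tuple[int, int]) -> FiringDiffDensity:
    """Density of t_j - t_i from latent cells with both origins licenced."""
    i, j = pair
    lic = chains.sub_licenced.reshape(-1, 3)
    t = chains.sub_times.reshape(-1, 3)
    both = lic[:, i] & lic[:, j]
    diffs = t[both, j] - t[both, i]
    x = chains.triplet.x
    return FiringDiffDensity(tuple(pair), diffs, float(abs(x[j] - x[i])), diffs.size == 0)


def prob_fires_earlier(mean_diff: float, sd: float) -> float:
    """Gaussian plug-in probability that origin i+1 fires before origin i.

    With the firing-time difference t_{i+1} - t_i modelled as Gaussian with
    the given mean and s.d., returns ``pi(t_{i+1} < t_i) = Phi(-mean / sd)``.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(norm.cdf(-mean_diff / sd))


def firing_order_table(chains: ChainSet) -> pd.DataFrame:
    """Firing-order probabilities for neighbouring pairs, two conventions.

    ``pi_plugin`` plugs the posterior means of mu_{i+1} - mu_i and
    sqrt(sigma_i^2 + sigma_{i+1}^2) into the Gaussian formula;
    ``pi_sample_mean`` averages the same formula over posterior samples.
    The two can differ for skewed posteriors.
    """
    rows = []
    for i in range(2):
        mu_i = chains.pooled(f"mu_{i + 1}")
        mu_j = chains.pooled(f"mu_{i + 2}")
        s_i = chains.pooled(f"sigma_{i + 1}")
        s_j = chains.pooled(f"sigma_{i + 2}")
        diff = mu_j - mu_i
        sd = np.hypot(s_i, s_j)
        plugin = prob_fires_earlier(float(diff.mean()), float(sd.mean()))
        per_sample = norm.cdf(-diff / sd)
        rows.append(
            {
                "pair": f"{chains.triplet.names[i]}{chains.triplet.names[i + 1]}",
                "mean_diff": float(diff.mean()),
                "sd_diff": float(sd.mean()),
                "pi_plugin": plugin,
                "pi_sample_mean": float(per_sample.mean()),
                "pi_sample_sd": float(per_sample.std(ddof=1)) if per_sample.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def point_estimates(chains: ChainSet) -> tuple[FiringParams, NoiseParams]:
    """Per-parameter posterior medians (mu recentred to sum to zero)."""
    med = np.median(chains.theta.reshape(-1, 11), axis=0)
    fp = FiringParams(med[0:3], med[3:6], np.clip(med[6:9], 0.0, 1.0)).recentred()
    return fp, NoiseParams(float(med[9]), float(med[10]))


@dataclass
class ReplicationTimeProfile:
    """Median and 5th/95th percentile replication time per box, in minutes."""

    positions: np.ndarray
    median: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    nu_kb_per_min: float
    anchor_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions.astype(int),
                "t_median_min": self.median,
                "t_p5_min": self.p5,
                "t_p95_min": self.p95,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def median_replication_time(
    params: FiringParams,
    triplet: OriginTriplet,
    nu_kb_per_min: float,
    anchor_min: float = 0.0,
    K: int = 1000,
    rng: Optional[np.random.Generator] = None,
    s_box: int = 50,
    max_resample: int = 1000,
) -> ReplicationTimeProfile:
    """Reconstruct replication times from (point-estimate) firing parameters.

    Simulates ``K`` admissible cells; the replication time of a position is
    the earliest fork arrival ``min_i (t_i + |x - x_i|)`` over realized
    origins, in rbp.  Times are anchored at the earliest mean firing time and
    scaled to minutes by the fork velocity ``nu`` (kb/min):
    ``(T_rbp - min_i mu_i) / (1000 nu) + anchor``.
    """
    if nu_kb_per_min <= 0:
        raise ValueError("fork velocity must be positive")
    if K < 100:
        raise ValueError("K must be >= 100 for stable percentiles")
    if rng is None:
        rng = np.random.default_rng()
    pop = simulate_population(params, triplet, K, rng, max_resample=max_resample)
    xm = triplet.box_midpoints(s_box)
    t_rbp = pop.replication_times(xm)
    minutes = (t_rbp - params.mu.min()) / (1000.0 * nu_kb_per_min) + anchor_min
    p5, med, p95 = np.percentile(minutes, [5, 50, 95], axis=0)
    return ReplicationTimeProfile(xm, med, p5, p95, nu_kb_per_min, anchor_min)
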