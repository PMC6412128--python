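"""Stochastic model of DNA replication over a triplet of neighbouring origins.

The model describes one S-phase of one cell as follows.  Three replication
origins sit at genomic positions ``x1 < x2 < x3``.  Each origin *i* is
licenced (competent to fire) with probability ``q_i``, independently of the
others.  A licenced origin has a potential firing time ``t_i`` drawn from a
Gaussian ``N(mu_i, sigma_i^2)``.  Replication forks move bidirectionally at a
common constant speed, so time is conveniently measured in replicated base
pairs (rbp): one time unit replicates one base pair.  Fork termination is
passive -- converging forks annihilate where they meet -- and a fork arriving
at a licenced origin before that origin fires inactivates it ("origin
obscuring", also called passive replication).  An origin that is licenced and
not obscured is *realized*: it actually launches a pair of forks.

Okazaki fragments are synthesized on the lagging strand, so the strand on
which a locus yields fragments records the direction of the fork that
replicated it.  A single cell therefore contributes a binary profile over the
region: 1 where a rightward-moving fork passed (forward-strand fragments,
under the default convention), 0 where a leftward-moving fork passed.
Averaging ``M`` cells yields the smooth population profile ``F_ave`` whose
local level encodes firing-time differences and whose jumps at origins equal
the realized-firing fraction of each origin.

Cells in which either no origin is realized, or a single *end* origin
replicates the whole region (a "double overrun"), give a constant profile
that is indistinguishable from background; such cells are excluded by
rejection, i.e. the generative model is conditioned on admissible states.

Closed-form oracles for the two-origin profile, one-sided obscuring
probabilities and collision-point distributions are provided for testing the
simulator and the inference machinery against independent analytic results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DegenerateModelError",
    "OriginTriplet",
    "FiringParams",
    "SimConfig",
    "CellState",
    "Population",
    "AveragedProfile",
    "simulate_cell",
    "simulate_population",
    "cell_profile",
    "average_profile",
    "two_origin_profile_closed_form",
    "obscuring_probability_closed_form",
    "collision_normal_params",
]

N_ORIGINS = 3


class DegenerateModelError(RuntimeError):
    """Rejection sampling failed to produce admissible cells.

    Raised when the parameter regime makes admissible (non-prohibited) cell
    states vanishingly rare, e.g. ``q = (1, 0, 0)`` where the only licenced
    origin is an end origin and every cell is a double overrun.
    """


@dataclass(frozen=True)
class OriginTriplet:
    """Three origin positions on one chromosome, 0-based coordinates.

    Parameters
    ----------
    positions
        Strictly increasing genomic coordinates ``(x1, x2, x3)`` in bp.
    names
        Origin labels, e.g. ARS names.
    chrom
        Chromosome identifier (used only for I/O).
    """

    positions: tuple[float, float, float]
    names: tuple[str, str, str] = ("O1", "O2", "O3")
    chrom: str = "chr"

    def __post_init__(self) -> None:
        pos = tuple(float(p) for p in self.positions)
        if len(pos) != N_ORIGINS:
            raise ValueError("an origin triplet needs exactly three positions")
        if not (pos[0] < pos[1] < pos[2]):
            raise ValueError(f"origin positions must be strictly increasing, got {pos}")
        object.__setattr__(self, "positions", pos)

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)

    @property
    def N1(self) -> float:
        """Distance O1-O2 in bp."""
        return self.positions[1] - self.positions[0]

    @property
    def N2(self) -> float:
        """Distance O2-O3 in bp."""
        return self.positions[2] - self.positions[1]

    @property
    def length(self) -> float:
        return self.positions[2] - self.positions[0]

    def n_boxes(self, s_box: int) -> int:
        return int(self.length // s_box)

    def box_starts(self, s_box: int) -> np.ndarray:
        n = self.n_boxes(s_box)
        return self.positions[0] + s_box * np.arange(n, dtype=float)

    def box_midpoints(self, s_box: int) -> np.ndarray:
        return self.box_starts(s_box) + 0.5 * s_box


@dataclass(frozen=True)
class FiringParams:
    """Per-origin firing parameters: Gaussian firing times and licencing.

    ``mu`` and ``sigma`` are the mean and s.d. of the potential firing time of
    each origin, in rbp; ``q`` is the per-cell licencing probability.  Only
    firing-time *differences* are observable, so ``mu`` is identified by the
    convention ``sum(mu) = 0``; :meth:`recentred` enforces it.
    """

    mu: np.ndarray
    sigma: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        q = np.asarray(self.q, dtype=float)
        for name, a in (("mu", mu), ("sigma", sigma), ("q", q)):
            if a.shape != (N_ORIGINS,):
                raise ValueError(f"{name} must have shape (3,), got {a.shape}")
        if not np.all(sigma > 0):
            raise ValueError("all sigma must be > 0")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("licencing probabilities must lie in [0, 1]")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "q", q)

    def recentred(self) -> "FiringParams":
        """Return an equivalent parameter set with ``sum(mu) = 0``."""
        return FiringParams(self.mu - self.mu.mean(), self.sigma, self.q)


@dataclass(frozen=True)
class SimConfig:
    """Population-simulation settings.

    ``M`` is the number of cells averaged into a profile (default 4992, the
    production value; profiles are then piecewise constant in steps of 1/M).
    ``s_box`` is the box width in bp used for profile discretisation.
    ``forward_is_rightward`` maps rightward-moving forks to forward-strand
    Okazaki fragments (profile value 1); set False to flip the convention.
    """

    M: int = 4992
    s_box: int = 50
    max_resample: int = 1000
    forward_is_rightward: bool = True

    def __post_init__(self) -> None:
        if self.M < 1 or self.s_box < 1 or self.max_resample < 1:
            raise ValueError("M, s_box and max_resample must all be >= 1")


def _draw_raw(params: FiringParams, M: int, rng: np.random.Generator):
    lic = rng.random((M, N_ORIGINS)) < params.q
    t = rng.normal(params.mu, params.sigma, size=(M, N_ORIGINS))
    return lic, np.where(lic, t, 0.0)


def _realized_from(lic: np.ndarray, t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Realized origins: licenced and firing strictly before any fork arrives.

    The replication front from the licenced origin set reaches position ``y``
    at time ``min_j (t_j + |y - x_j|)``; the minimiser is always reachable
    (an obscured intermediate origin never delays the front), so blocking by
    intermediate origins is accounted for automatically.  Ties (a fork
    arriving exactly at the firing time) count as obscured.
    """
    tt = np.where(lic, t, np.inf)
    d = np.abs(x[:, None] - x[None, :])
    arrivals = tt[:, None, :] + d[None, :, :]  # (M, i, j): from origin j at x_i
    idx = np.arange(N_ORIGINS)
    arrivals[:, idx, idx] = np.inf
    first = arrivals.min(axis=2)
    return lic & (tt < first)


def _admissible_mask(realized: np.ndarray) -> np.ndarray:
    n = realized.sum(axis=1)
    return (n >= 2) | ((n == 1) & realized[:, 1])


@dataclass
class Population:
    """A batch of admissible single-cell latent states.

    Arrays are ``(M, 3)``: ``licenced`` (bool), ``times`` (rbp, zero where not
    licenced) and ``realized`` (bool).  ``n_rejected`` counts prohibited draws
    discarded by rejection.
    """

    triplet: OriginTriplet
    licenced: np.ndarray
    times: np.ndarray
    realized: np.ndarray
    n_rejected: int = 0

    @property
    def M(self) -> int:
        return self.licenced.shape[0]

    def realized_fraction(self) -> np.ndarray:
        """Fraction of cells in which each origin launched forks."""
        return self.realized.mean(axis=0)

    def obscuring_matrix(self) -> np.ndarray:
        """``(3, 3)`` matrix: fraction of cells with origin i obscured by j.

        Obscuring is attributed to the realized origin whose fork arrives
        first at the obscured position; ``j < i`` means obscured from the
        left, ``j > i`` from the right.
        """
        x = self.triplet.x
        tr = np.where(self.realized, self.times, np.inf)
        d = np.abs(x[:, None] - x[None, :])
        arrivals = tr[:, None, :] + d[None, :, :]
        idx = np.arange(N_ORIGINS)
        arrivals[:, idx, idx] = np.inf
        jstar = arrivals.argmin(axis=2)
        obscured = self.licenced & ~self.realized
        out = np.zeros((N_ORIGINS, N_ORIGINS))
        for i in range(N_ORIGINS):
            mask = obscured[:, i]
            if mask.any():
                out[i] = np.bincount(jstar[mask, i], minlength=N_ORIGINS)
        return out / self.M

    def collision_points(self, pair: tuple[int, int]) -> np.ndarray:
        """Collision coordinates for an adjacent realized pair.

        ``pair`` is ``(0, 1)``, ``(1, 2)`` or ``(0, 2)``; the last one is only
        realized in cells where the middle origin is not.  The collision point
        of realized origins i < j with no realized origin between them is
        ``(x_i + x_j + t_j - t_i) / 2``.
        """
        i, j = pair
        mask = self.realized[:, i] & self.realized[:, j]
        if pair == (0, 2):
            mask &= ~self.realized[:, 1]
        x = self.triplet.x
        t = self.times
        return 0.5 * (x[i] + x[j] + t[mask, j] - t[mask, i])

    def pair_realized_fraction(self, pair: tuple[int, int]) -> float:
        i, j = pair
        mask = self.realized[:, i] & self.realized[:, j]
        if pair == (0, 2):
            mask &= ~self.realized[:, 1]
        return float(mask.mean())

    def profile_bits(
        self, midpoints: np.ndarray, forward_is_rightward: bool = True, chunk: int = 1024
    ) -> np.ndarray:
        """Binary single-cell profiles ``(M, n_boxes)`` evaluated at midpoints."""
        x = self.triplet.x
        out = np.empty((self.M, midpoints.size), dtype=np.uint8)
        dist = np.abs(midpoints[None, :] - x[:, None])  # (3, nb)
        for lo in range(0, self.M, chunk):
            hi = min(lo + chunk, self.M)
            tr = np.where(self.realized[lo:hi], self.times[lo:hi], np.inf)
            arr = tr[:, :, None] + dist[None, :, :]  # (m, 3, nb)
            jstar = arr.argmin(axis=1)
            out[lo:hi] = (x[jstar] <= midpoints[None, :]).astype(np.uint8)
        if not forward_is_rightward:
            out = 1 - out
        return out

    def replication_times(self, positions: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """Replication time (rbp) of each position in each cell, ``(M, n)``."""
        x = self.triplet.x
        dist = np.abs(positions[None, :] - x[:, None])
        out = np.empty((self.M, positions.size))
        for lo in range(0, self.M, chunk):
            hi = min(lo + chunk, self.M)
            tr = np.where(self.realized[lo:hi], self.times[lo:hi], np.inf)
            out[lo:hi] = (tr[:, :, None] + dist[None, :, :]).min(axis=1)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Columnar export of the latent states (debugging aid)."""
        cols = {}
        for i in range(N_ORIGINS):
            cols[f"licenced_{i + 1}"] = self.licenced[:, i]
            cols[f"time_{i + 1}"] = np.where(self.licenced[:, i], self.times[:, i], np.nan)
            cols[f"realized_{i + 1}"] = self.realized[:, i]
        return pd.DataFrame(cols)


def simulate_population(
    params: FiringParams,
    triplet: OriginTriplet,
    M: int,
    rng: np.random.Generator,
    max_resample: int = 1000,
) -> Population:
    """Draw ``M`` admissible cells, rejecting prohibited configurations.

    Prohibited states (no realized origin, or an end origin replicating the
    whole region alone) are resampled; after ``max_resample`` fruitless rounds
    a :class:`DegenerateModelError` is raised.
    """
    x = triplet.x
    lic_parts, t_parts, real_parts = [], [], []
    need = M
    rejected = 0
    for _ in range(max_resample):
        lic, t = _draw_raw(params, need, rng)
        realized = _realized_from(lic, t, x)
        ok = _admissible_mask(realized)
        rejected += int(need - ok.sum())
        if ok.any():
            lic_parts.append(lic[ok])
            t_parts.append(t[ok])
            real_parts.append(realized[ok])
            need -= int(ok.sum())
        if need == 0:
            return Population(
                triplet,
                np.concatenate(lic_parts),
                np.concatenate(t_parts),
                np.concatenate(real_parts),
                n_rejected=rejected,
            )
    raise DegenerateModelError(
        "admissible cell states are (almost surely) unreachable for these "
        f"parameters; {rejected} prohibited draws in {max_resample} rounds"
    )


@dataclass
class CellState:
    """One cell's latent replication realization."""

    triplet: OriginTriplet
    licenced: np.ndarray
    times: np.ndarray
    realized: np.ndarray
    #: (obscured origin, obscuring origin, "left"|"right") -- direction of the
    #: incoming fork.
    obscuring_events: list[tuple[int, int, str]] = field(default_factory=list)
    #: ((i, j), collision coordinate in bp) for adjacent realized pairs.
    collisions: list[tuple[tuple[int, int], float]] = field(default_factory=list)


def _cell_from_population(pop: Population, row: int) -> CellState:
    x = pop.triplet.x
    lic = pop.licenced[row]
    t = pop.times[row]
    realized = pop.realized[row]
    events: list[tuple[int, int, str]] = []
    tr = np.where(realized, t, np.inf)
    for i in range(N_ORIGINS):
        if lic[i] and not realized[i]:
            arr = np.array(
                [tr[j] + abs(x[i] - x[j]) if j != i else np.inf for j in range(N_ORIGINS)]
            )
            j = int(arr.argmin())
            events.append((i, j, "left" if j < i else "right"))
    collisions: list[tuple[tuple[int, int], float]] = []
    prev = -1
    for j in range(N_ORIGINS):
        if realized[j]:
            if prev >= 0:
                collisions.append(((prev, j), 0.5 * (x[prev] + x[j] + t[j] - t[prev])))
            prev = j
    return CellState(pop.triplet, lic, t, realized, events, collisions)


def simulate_cell(
    params: FiringParams,
    triplet: OriginTriplet,
    rng: np.random.Generator,
    max_resample: int = 1000,
) -> CellState:
    """Simulate one admissible cell (see :func:`simulate_population`)."""
    pop = simulate_population(params, triplet, 1, rng, max_resample=max_resample)
    return _cell_from_population(pop, 0)


def cell_profile(
    state: CellState, triplet: OriginTriplet, s_box: int, forward_is_rightward: bool = True
) -> np.ndarray:
    """Binary per-box profile of one cell: 1 where a rightward fork passed.

    Boxes are half-open ``[start, start + s_box)`` intervals tiling
    ``[x1, x3)``; each box takes the value of the piecewise-constant profile
    at its midpoint (breakpoint localisation error at most ``s_box / 2``).
    """
    xm = triplet.box_midpoints(s_box)
    x = triplet.x
    tr = np.where(state.realized, state.times, np.inf)
    arr = tr[:, None] + np.abs(xm[None, :] - x[:, None])
    jstar = arr.argmin(axis=0)
    bits = (x[jstar] <= xm).astype(np.uint8)
    return bits if forward_is_rightward else 1 - bits


@dataclass
class AveragedProfile:
    """Population-averaged Okazaki-fragment profile ``F_ave`` over boxes.

    ``values[k]`` is the fraction of the ``M`` simulated cells whose forward
    strand at box ``k`` was replicated as Okazaki fragments; every value is a
    multiple of ``1/M``.
    """

    values: np.ndarray
    box_starts: np.ndarray
    s_box: int
    M: int
    triplet: OriginTriplet

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"box_start": self.box_starts.astype(int), "F_ave": self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path) -> None:
        """Write as 4-column bedGraph (0-based, half-open boxes)."""
        df = pd.DataFrame(
            {
                "chrom": self.triplet.chrom,
                "start": self.box_starts.astype(int),
                "end": (self.box_starts + self.s_box).astype(int),
                "value": self.values,
            }
        )
        df.to_csv(path, sep="\t", index=False, header=False)


def average_profile(
    params: FiringParams,
    triplet: OriginTriplet,
    config: SimConfig,
    rng: np.random.Generator,
) -> AveragedProfile:
    """Mean of ``config.M`` admissible single-cell profiles."""
    pop = simulate_population(params, triplet, config.M, rng, config.max_resample)
    bits = pop.profile_bits(
        triplet.box_midpoints(config.s_box), forward_is_rightward=config.forward_is_rightward
    )
    values = bits.sum(axis=0) / config.M
    return AveragedProfile(values, triplet.box_starts(config.s_box), config.s_box, config.M, triplet)


def two_origin_profile_closed_form(
    x, x_i: float, x_j: float, mu_i: float, mu_j: float, sigma_i: float, sigma_j: float
):
    """Analytic two-origin profile: P(position x replicated by i's right fork).

    With both origins always licenced and no third origin, position ``x``
    between the origins is replicated by origin i's rightward fork exactly
    when the collision point falls to the right of ``x``, which happens with
    probability ``Phi((mu_j - mu_i + x_i + x_j - 2 x) / sqrt(si^2 + sj^2))``.
    This is the tanh-like transition connecting neighbouring origins.
    """
    if sigma_i <= 0 or sigma_j <= 0:
        raise ValueError("firing-time standard deviations must be positive")
    s = np.hypot(sigma_i, sigma_j)
    return norm.cdf((mu_j - mu_i + x_i + x_j - 2.0 * np.asarray(x, dtype=float)) / s)


def obscuring_probability_closed_form(
    mu_neighbour: float, sigma_neighbour: float, mu_self: float, sigma_self: float, distance: float
) -> float:
    """One-sided obscuring probability of an origin by one neighbour.

    Probability that the neighbour's fork (launched at ``t ~ N(mu_neighbour,
    sigma_neighbour^2)``, travelling ``distance`` bp at unit speed) arrives
    before the origin's own firing time ``N(mu_self, sigma_self^2)``:
    ``Phi((mu_self - mu_neighbour - distance) / sqrt(s_self^2 + s_nb^2))``.
    Valid when the neighbour is always licenced and no third origin
    interferes with this event.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if sigma_neighbour <= 0 or sigma_self <= 0:
        raise ValueError("firing-time standard deviations must be positive")
    s = np.hypot(sigma_neighbour, sigma_self)
    return float(norm.cdf((mu_self - mu_neighbour - distance) / s))


def collision_normal_params(
    pair: tuple[int, int], triplet: OriginTriplet, params: FiringParams
) -> tuple[float, float]:
    """Mean and s.d. of the collision point of a pair, no-obscuring regime.

    ``x_ij ~ N((x_i + x_j + mu_j - mu_i)/2, (sigma_i^2 + sigma_j^2)/4)``.
    """
    i, j = pair
    x = triplet.x
    mean = 0.5 * (x[i] + x[j] + params.mu[j] - params.mu[i])
    sd = 0.5 * float(np.hypot(params.sigma[i], params.sigma[j]))
    return float(mean), sd
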