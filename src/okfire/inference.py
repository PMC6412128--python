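"""Reversible-jump MCMC inference of firing/licencing/noise parameters.

The posterior targeted is over the firing parameters (mu, sigma, q per
origin), the noise parameters (b, tau) and the latent population of M cells
(per-cell licenced sets and firing times, conditioned on admissibility).
The averaged profile entering the likelihood is the empirical mean of the M
latent single-cell profiles, so the model dimension varies with the number
of licenced origins per cell -- hence the reversible-jump licencing moves.

Priors: mu_i ~ N(0, (N1 + N2)^2) -- the likelihood constrains only
firing-time differences, so a proper weakly informative prior on the scale
of the region size pins the (unobservable) common time offset; sigma^2 ~
InverseGamma(0.01, 0.01), q ~ Beta(1, 1), b ~ Uniform(0, 1), tau ~
Gamma(0.01, 0.01); conjugate where the structure allows.  Reported mu
samples follow the conventional sum-to-zero normalization.

The default M = 512 is a desk-scale compromise; production analyses should
use M = 4992 (lower M introduces 1/M discretization artefacts into the
reconstructed profile).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import N_ORIGINS, FiringParams, OriginTriplet, simulate_population
from .noise_model import BoxedCounts, NoiseParams, floor_counts

__all__ = [
    "MCMCConfig",
    "MCMCState",
    "ChainSet",
    "init_state",
    "sweep",
    "run_sweeps",
    "sample_posterior",
    "gelman_rubin",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = (
    "mu_1",
    "mu_2",
    "mu_3",
    "sigma_1",
    "sigma_2",
    "sigma_3",
    "q_1",
    "q_2",
    "q_3",
    "b",
    "tau",
)

_PRODUCTION_M = 4992


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    ``burn_in`` sweeps are discarded (proposal scales adapt there), then
    ``n_samples`` sweeps are run recording every ``thin``-th state.  ``M`` is
    the latent population size; ``cell_fraction`` the fraction of cells whose
    latent variables are refreshed per sweep.  ``n_sub`` cells are stored per
    retained sample to support collision/firing-difference densities.
    ``update_*`` flags freeze parameter blocks (used by toy validations and
    sensitivity checks).
    """

    n_chains: int = 3
    burn_in: int = 5000
    n_samples: int = 15000
    thin: int = 10
    M: int = 512
    cell_fraction: float = 0.1
    seed: int = 0
    max_resample: int = 1000
    n_sub: int = 32
    adapt: bool = True
    target_accept: float = 0.3
    step_time: Optional[float] = None
    step_log_tau: float = 0.3
    step_logit_b: float = 0.3
    mu_prior_sd: Optional[float] = None  # default: N1 + N2 (region size in rbp)
    sigma_a0: float = 0.01
    sigma_b0: float = 0.01
    q_a: float = 1.0
    q_b: float = 1.0
    tau_a: float = 0.01
    tau_b: float = 0.01
    rhat_threshold: float = 1.1
    update_times: bool = True
    update_licencing: tuple[bool, bool, bool] = (True, True, True)
    update_mu: bool = True
    update_sigma: bool = True
    update_q: tuple[bool, bool, bool] = (True, True, True)
    update_b: bool = True
    update_tau: bool = True
    init_params: Optional[FiringParams] = None
    init_noise: Optional[NoiseParams] = None

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in + 1, self.n_samples, self.thin, self.M) < 1:
            raise ValueError("chain/sweep counts must be positive")
        if not 0.0 < self.cell_fraction <= 1.0:
            raise ValueError("cell_fraction must lie in (0, 1]")

    @property
    def n_update(self) -> int:
        return max(1, int(round(self.cell_fraction * self.M)))


@dataclass
class MCMCState:
    """Mutable chain state: parameters, latent population, cached tallies."""

    triplet: OriginTriplet
    theta: np.ndarray  # packed: mu(3), sigma(3), q(3), b, tau
    licenced: np.ndarray
    times: np.ndarray
    tallies: np.ndarray
    step: np.ndarray  # per-origin time steps (3), log-tau, logit-b

    @property
    def firing_params(self) -> FiringParams:
        return FiringParams(self.theta[0:3].copy(), self.theta[3:6].copy(), self.theta[6:9].copy())

    @property
    def noise_params(self) -> NoiseParams:
        return NoiseParams(float(self.theta[9]), float(self.theta[10]))

    def recompute_tallies(self, midpoints: np.ndarray) -> np.ndarray:
        """Tallies recomputed from scratch (checkpoint for the incremental cache)."""
        fresh = np.zeros_like(self.tallies)
        _kernels.recompute_tallies(self.licenced, self.times, self.triplet.x, midpoints, fresh)
        return fresh


def _prepare_logs(counts: BoxedCounts) -> tuple[np.ndarray, np.ndarray]:
    c_f, c_r = floor_counts(counts.c_f, counts.c_r)
    return np.log(c_f), np.log(c_r)


def estimate_tau_moments(counts: BoxedCounts) -> float:
    """Method-of-moments noise precision from adjacent-box log differences.

    Differencing neighbouring boxes removes the slowly varying profile, so
    ``Var(diff(log c)) ~ 2 / tau`` per strand.
    """
    lf, lr = _prepare_logs(counts)
    v = np.mean([np.var(np.diff(lf), ddof=1), np.var(np.diff(lr), ddof=1)])
    if v <= 0:
        return 1e6
    return float(np.clip(2.0 / v, 0.1, 1e6))


def init_state(
    counts: BoxedCounts,
    triplet: OriginTriplet,
    config: MCMCConfig,
    rng: np.random.Generator,
) -> MCMCState:
    """Deterministic-given-seed initial state.

    mu starts at 0, sigma at 0.15 max(N1, N2), q at 0.9, b at 0.05; tau by
    method of moments on the log counts.  The latent population is drawn
    from the prior conditioned on admissibility.
    """
    if np.all(counts.c_f == 0) and np.all(counts.c_r == 0):
        raise ValueError("degenerate counts: all zero")
    if config.init_params is not None:
        fp = config.init_params.recentred()
    else:
        s0 = 0.15 * max(triplet.N1, triplet.N2)
        fp = FiringParams(np.zeros(3), np.full(3, s0), np.full(3, 0.9))
    if config.init_noise is not None:
        npar = config.init_noise
    else:
        npar = NoiseParams(0.05, estimate_tau_moments(counts))
    pop = simulate_population(fp, triplet, config.M, rng, max_resample=config.max_resample)
    theta = np.concatenate([fp.mu, fp.sigma, fp.q, [npar.b, npar.tau]])
    xm = triplet.box_midpoints(counts.s_box)
    tallies = np.zeros(xm.size, dtype=np.int64)
    _kernels.recompute_tallies(pop.licenced, pop.times, triplet.x, xm, tallies)
    step_t = config.step_time if config.step_time is not None else 0.5 * float(fp.sigma[0])
    shift0 = 0.2 * step_t
    step = np.array(
        [step_t, step_t, step_t, config.step_log_tau, config.step_logit_b]
        + [shift0, shift0, shift0, 0.1]
    )
    return MCMCState(triplet, theta, pop.licenced, pop.times, tallies, step)


def _pack_flags(config: MCMCConfig, triplet: OriginTriplet):
    upd = np.array(
        [
            config.update_times,
            config.update_mu,
            config.update_sigma,
            config.update_b,
            config.update_tau,
        ],
        dtype=np.int8,
    )
    updq = np.array(config.update_q, dtype=np.int8)
    lic_idx = np.array(
        [i for i in range(N_ORIGINS) if config.update_licencing[i]], dtype=np.int64
    )
    mu_sd = config.mu_prior_sd if config.mu_prior_sd is not None else triplet.N1 + triplet.N2
    pri = np.array(
        [
            config.sigma_a0,
            config.sigma_b0,
            config.q_a,
            config.q_b,
            config.tau_a,
            config.tau_b,
            float(mu_sd) ** 2,
        ]
    )
    return upd, updq, lic_idx, pri


def run_sweeps(
    state: MCMCState,
    counts: BoxedCounts,
    config: MCMCConfig,
    n_sweeps: int,
    record_every: int = 0,
    adapt: bool = False,
    seed: Optional[int] = None,
) -> Optional[dict]:
    """Advance the chain by ``n_sweeps`` full sweeps in place.

    With ``record_every > 0`` returns the recorded arrays (theta, realized
    fractions, obscuring matrix, pair fractions, cell subsample); otherwise
    returns None.  ``seed`` reseeds the kernel RNG (pass once per chain).
    """
    if seed is not None:
        _kernels.seed_rng(int(seed) % 2**31)
    lcf, lcr = _prepare_logs(counts)
    xm = state.triplet.box_midpoints(counts.s_box)
    if xm.size != lcf.size:
        raise ValueError("counts geometry does not match the triplet")
    upd, updq, lic_idx, pri = _pack_flags(config, state.triplet)
    n_rec = n_sweeps // record_every if record_every > 0 else 0
    n_sub = config.n_sub if record_every > 0 else 0
    out_theta = np.zeros((max(n_rec, 1), 11))
    out_rfrac = np.zeros((max(n_rec, 1), 3))
    out_obsc = np.zeros((max(n_rec, 1), 3, 3))
    out_pairfrac = np.zeros((max(n_rec, 1), 3))
    out_sub_lic = np.zeros((max(n_rec, 1), n_sub, 3), dtype=np.bool_)
    out_sub_t = np.zeros((max(n_rec, 1), n_sub, 3))
    out_sub_coll = np.full((max(n_rec, 1), n_sub, 2), np.nan)
    out_sub_pair = np.full((max(n_rec, 1), n_sub, 2), -1, dtype=np.int8)
    acc = np.zeros(12)
    _kernels.run_chain(
        lcf,
        lcr,
        state.triplet.x,
        xm,
        state.licenced,
        state.times,
        state.tallies,
        state.theta,
        n_sweeps,
        config.n_update,
        state.step,
        1 if adapt else 0,
        config.target_accept,
        upd,
        updq,
        lic_idx,
        pri,
        record_every,
        out_theta,
        out_rfrac,
        out_obsc,
        out_pairfrac,
        out_sub_lic,
        out_sub_t,
        out_sub_coll,
        out_sub_pair,
        acc,
    )
    if not np.all(np.isfinite(state.theta)):
        raise RuntimeError(f"non-finite parameter state after sweeps: {state.theta}")
    if record_every == 0:
        return None
    return {
        "theta": out_theta[:n_rec],
        "realized_frac": out_rfrac[:n_rec],
        "obscuring": out_obsc[:n_rec],
        "pair_frac": out_pairfrac[:n_rec],
        "sub_licenced": out_sub_lic[:n_rec],
        "sub_times": out_sub_t[:n_rec],
        "sub_collisions": out_sub_coll[:n_rec],
        "sub_pairs": out_sub_pair[:n_rec],
        "acceptance": acc,
    }


def sweep(
    state: MCMCState, counts: BoxedCounts, config: MCMCConfig, seed: Optional[int] = None
) -> MCMCState:
    """One full MCMC sweep (moves 1-5), mutating and returning ``state``."""
    run_sweeps(state, counts, config, 1, record_every=0, adapt=False, seed=seed)
    return state


@dataclass
class ChainSet:
    """Retained posterior samples from several independent chains.

    ``theta`` has shape ``(n_chains, n_samples, 11)`` with columns
    :data:`PARAM_NAMES`; population summaries (realized fractions, directed
    obscuring fractions, adjacent-pair collision fractions) are per retained
    sample, and a small latent-cell subsample supports density summaries.
    """

    triplet: OriginTriplet
    config: MCMCConfig
    theta: np.ndarray
    realized_frac: np.ndarray
    obscuring: np.ndarray
    pair_frac: np.ndarray
    sub_licenced: np.ndarray
    sub_times: np.ndarray
    sub_collisions: np.ndarray
    sub_pairs: np.ndarray
    acceptance: np.ndarray
    param_names: tuple = PARAM_NAMES

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    def pooled(self, name: str) -> np.ndarray:
        """Pooled post-burn-in samples of one scalar parameter."""
        return self.theta[:, :, self.param_names.index(name)].ravel()

    def to_frame(self) -> pd.DataFrame:
        n_c, n_s, _ = self.theta.shape
        df = pd.DataFrame(self.theta.reshape(-1, len(self.param_names)), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_s))
        df.insert(1, "sample", np.tile(np.arange(n_s), n_c))
        return df

    def gelman_rubin_report(self) -> dict[str, float]:
        """R-hat per parameter; NaN flags a degenerate (zero-variance) chain."""
        report = {}
        for k, name in enumerate(self.param_names):
            chains = self.theta[:, :, k]
            try:
                report[name] = gelman_rubin(chains)
            except ValueError:
                report[name] = float("nan")
        return report

    def converged(self, threshold: Optional[float] = None) -> bool:
        thr = threshold if threshold is not None else self.config.rhat_threshold
        vals = [v for v in self.gelman_rubin_report().values() if np.isfinite(v)]
        return bool(vals) and max(vals) < thr

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            theta=self.theta,
            realized_frac=self.realized_frac,
            obscuring=self.obscuring,
            pair_frac=self.pair_frac,
            sub_licenced=self.sub_licenced,
            sub_times=self.sub_times,
            sub_collisions=self.sub_collisions,
            sub_pairs=self.sub_pairs,
            acceptance=self.acceptance,
            positions=np.asarray(self.triplet.positions),
            names=np.asarray(self.triplet.names),
            chrom=np.asarray(self.triplet.chrom),
            config=np.asarray(json.dumps(_config_to_jsonable(self.config))),
        )

    @classmethod
    def load(cls, path) -> "ChainSet":
        with np.load(path, allow_pickle=False) as z:
            cfg_dict = json.loads(str(z["config"]))
            for key in ("update_licencing", "update_q"):
                cfg_dict[key] = tuple(cfg_dict[key])
            config = MCMCConfig(**cfg_dict)
            triplet = OriginTriplet(
                tuple(z["positions"].tolist()),
                tuple(str(n) for n in z["names"]),
                str(z["chrom"]),
            )
            return cls(
                triplet,
                config,
                z["theta"],
                z["realized_frac"],
                z["obscuring"],
                z["pair_frac"],
                z["sub_licenced"],
                z["sub_times"],
                z["sub_collisions"],
                z["sub_pairs"],
                z["acceptance"],
            )


def _config_to_jsonable(config: MCMCConfig) -> dict:
    d = {}
    for k, v in asdict(config).items():
        if k in ("init_params", "init_noise"):
            continue
        d[k] = list(v) if isinstance(v, tuple) else v
    return d


def sample_posterior(
    counts: BoxedCounts, triplet: OriginTriplet, config: MCMCConfig
) -> ChainSet:
    """Run ``config.n_chains`` independent chains and collect retained samples.

    Burn-in sweeps (with proposal adaptation) are discarded; each chain then
    records every ``thin``-th of ``n_samples`` sweeps.  Non-convergence by
    the Gelman-Rubin criterion is a warning, not an error.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains)
    recs = []
    acc = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        kseed = int(child.generate_state(1, dtype=np.uint32)[0]) % 2**31
        state = init_state(counts, triplet, config, rng)
        run_sweeps(state, counts, config, config.burn_in, adapt=config.adapt, seed=kseed)
        rec = run_sweeps(state, counts, config, config.n_samples, record_every=config.thin)
        logger.info(
            "chain %d: %d retained samples, acceptance (time/rj/tau/b): "
            "%.2f %.2f %.2f %.2f",
            k,
            rec["theta"].shape[0],
            _rate(rec["acceptance"], 0),
            _rate(rec["acceptance"], 2),
            _rate(rec["acceptance"], 4),
            _rate(rec["acceptance"], 6),
        )
        recs.append(rec)
        acc.append(rec["acceptance"])
    cs = ChainSet(
        triplet,
        config,
        np.stack([r["theta"] for r in recs]),
        np.stack([r["realized_frac"] for r in recs]),
        np.stack([r["obscuring"] for r in recs]),
        np.stack([r["pair_frac"] for r in recs]),
        np.stack([r["sub_licenced"] for r in recs]),
        np.stack([r["sub_times"] for r in recs]),
        np.stack([r["sub_collisions"] for r in recs]),
        np.stack([r["sub_pairs"] for r in recs]),
        np.stack(acc),
    )
    if config.M < _PRODUCTION_M:
        logger.warning(
            "M = %d latent cells (desk scale); production analyses use M = %d -- "
            "lower M introduces profile discretization artefacts",
            config.M,
            _PRODUCTION_M,
        )
    if config.n_chains >= 2 and not cs.converged():
        warnings.warn(
            "Gelman-Rubin diagnostic above threshold; chains may not have converged",
            stacklevel=2,
        )
    return cs


def _rate(acc: np.ndarray, k: int) -> float:
    return float(acc[k] / acc[k + 1]) if acc[k + 1] > 0 else float("nan")


def gelman_rubin(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction for one scalar parameter.

    ``chains`` is ``(m, n)``: m >= 2 chains of equal length n >= 2.  Returns
    ``sqrt(((n-1)/n W + B/n) / W)`` with W the mean within-chain variance and
    B the between-chain variance of the chain means times n.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    B = n * chains.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))
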